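# Template run configuration for an 8-bacterial-species DNA-standard-style
# mock community (e.g. a ZymoBIOMICS D6300-like standard).
#
# The package ships NO vendor data: download the expected members'
# full-length 16S rRNA gene sequences from your mock's vendor or from a
# public repository, write the record->species map and the theoretical
# composition yourself, then point the paths below at those files.
# Flags given on the command line override values in this file.
#
# Usage:
#   mockqc check  --config custom_mock_template.yaml --out-dir results/
#   mockqc report --config custom_mock_template.yaml --out-dir results/

mock_name: my-8-species-mock

# --- input files (placeholders; replace with real paths) -------------------
asv_table: path/to/asv_table.tsv        # TSV: first column 'asv_sequence', one column per sample
reference: path/to/reference.fasta      # full-length 16S rRNA gene sequences of expected members
species_map: path/to/species_map.tsv    # TSV: record_id <TAB> species
theoretical: path/to/theoretical.tsv    # TSV: species <TAB> percent (must sum to 100)

# --- classifier parameters (defaults shown) --------------------------------
kmer_size: 8
bootstraps: 100
subsample_fraction: 0.125
confidence_threshold: 0.60
seed: 0
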