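"""Readers and writers for every on-disk format the tool touches.

All downstream modules work on in-memory domain objects; nothing else in
the package opens files. Formats are deliberately minimal and text-only:

* multi-record FASTA (wrapped lines allowed) for reference sequences;
* tab-separated tables (UTF-8, ``#`` comment lines ignored, mandatory
  header row) for the ASV count matrix, the record→species map, and all
  result tables.

The ASV table orientation is fixed: rows are ASVs (identified by their
DNA sequence, as produced by denoisers such as dada2), columns are
samples. The reader does not auto-detect orientation; a single documented
convention avoids silent transposition bugs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from mockqc.errors import ValidationError

# IUPAC nucleotide one-letter codes (references may carry ambiguity codes).
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
# Denoised ASVs are restricted to unambiguous bases plus N.
ASV_ALPHABET = frozenset("ACGTN")

ASV_TABLE_INDEX_COLUMN = "asv_sequence"


@dataclass(frozen=True)
class ReferenceRecord:
    """One expected mock member: a reference 16S sequence with its species label."""

    record_id: str
    species_label: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValidationError("reference record has an empty ID")
        if not self.species_label:
            raise ValidationError(
                f"reference record {self.record_id!r} has an empty species label"
            )
        seq = self.sequence.upper()
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise ValidationError(
                f"reference record {self.record_id!r} contains non-IUPAC "
                f"characters: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass
class AsvTable:
    """Counts of amplicon sequence variants (rows) across samples (columns).

    ASVs are identified by their DNA sequence string, not by opaque IDs,
    so that classification can operate on the row labels directly.
    """

    sample_ids: list[str]
    asv_sequences: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.asv_sequences = [str(a).upper() for a in self.asv_sequences]
        self.counts = np.asarray(self.counts)

        if len(self.sample_ids) < 1:
            raise ValidationError("ASV table needs at least one sample")
        if len(self.asv_sequences) < 1:
            raise ValidationError("ASV table needs at least one ASV")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicate sample IDs: {dupes}")
        if len(set(self.asv_sequences)) != len(self.asv_sequences):
            dupes = _duplicates(self.asv_sequences)
            raise ValidationError(
                f"duplicate ASV sequences (first 30 chars): "
                f"{[d[:30] for d in dupes]}"
            )
        for seq in self.asv_sequences:
            bad = set(seq) - ASV_ALPHABET
            if bad:
                raise ValidationError(
                    f"ASV sequence {seq[:30]!r}... contains characters outside "
                    f"{{A,C,G,T,N}}: {sorted(bad)}"
                )
        if self.counts.shape != (len(self.asv_sequences), len(self.sample_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.asv_sequences)} ASVs x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValidationError("ASV counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValidationError("ASV counts must be nonnegative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_sequences)

    def depths(self) -> np.ndarray:
        """Total read count per sample (column sums)."""
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.asv_sequences, name=ASV_TABLE_INDEX_COLUMN),
            columns=self.sample_ids,
        )


def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in items:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, SEQUENCE), ...]``.

    IDs are the header token up to the first whitespace; sequences are
    uppercased; record order is preserved. Rejects empty files, duplicate
    IDs and non-IUPAC characters, naming the offending record.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        seq = str(rec.seq).upper()
        if rid in seen:
            raise ValidationError(f"duplicate FASTA ID {rid!r} in {path}")
        seen.add(rid)
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise ValidationError(
                f"FASTA record {rid!r} in {path} contains non-IUPAC "
                f"characters: {sorted(bad)}"
            )
        if not seq:
            raise ValidationError(f"FASTA record {rid!r} in {path} has an empty sequence")
        records.append((rid, seq))
    if not records:
        raise ValidationError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike, width: int = 70) -> None:
    """Write ``(id, sequence)`` pairs as wrapped FASTA."""
    with open(path, "w", encoding="utf-8") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV tables


def _read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    if not Path(path).exists():
        raise ValidationError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, header=0)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty table: {path}") from None
    return df


def read_asv_table(path: str | os.PathLike) -> AsvTable:
    """Read an ASV count table (TSV, first column ``asv_sequence``)."""
    df = _read_tsv(path)
    if df.columns[0] != ASV_TABLE_INDEX_COLUMN:
        raise ValidationError(
            f"{path}: first column must be named {ASV_TABLE_INDEX_COLUMN!r}, "
            f"got {df.columns[0]!r}"
        )
    sample_ids = list(df.columns[1:])
    if not sample_ids:
        raise ValidationError(f"{path}: no sample columns")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(f"{path}: duplicate sample columns: {_duplicates(sample_ids)}")
    asv_sequences = [str(s) for s in df[ASV_TABLE_INDEX_COLUMN]]
    counts = np.empty((len(asv_sequences), len(sample_ids)), dtype=np.int64)
    for j, col in enumerate(sample_ids):
        for i, cell in enumerate(df[col]):
            try:
                value = int(str(cell))
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: non-integer count {cell!r} in column {col!r}, "
                    f"row {i + 1}"
                ) from None
            if value < 0:
                raise ValidationError(
                    f"{path}: negative count {value} in column {col!r}, row {i + 1}"
                )
            counts[i, j] = value
    return AsvTable(sample_ids=sample_ids, asv_sequences=asv_sequences, counts=counts)


def write_asv_table(table: AsvTable, path: str | os.PathLike) -> None:
    table.to_dataframe().to_csv(path, sep="\t")


def read_species_map(path: str | os.PathLike) -> dict[str, str]:
    """Read the 2-column ``record_id<TAB>species`` map."""
    df = _read_tsv(path)
    expected = ["record_id", "species"]
    if list(df.columns[:2]) != expected:
        raise ValidationError(
            f"{path}: species map must have header 'record_id\\tspecies', "
            f"got {list(df.columns)}"
        )
    mapping: dict[str, str] = {}
    for i, row in df.iterrows():
        rid = row["record_id"]
        species = row["species"]
        if pd.isna(rid) or not str(rid):
            raise ValidationError(f"{path}: empty record_id in row {i + 1}")
        if pd.isna(species) or not str(species).strip():
            raise ValidationError(f"{path}: empty species for record {rid!r}")
        if rid in mapping:
            raise ValidationError(f"{path}: duplicate record_id {rid!r}")
        mapping[str(rid)] = str(species)
    if not mapping:
        raise ValidationError(f"{path}: species map has no rows")
    return mapping


def write_species_map(mapping: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("record_id\tspecies\n")
        for rid, species in mapping.items():
            fh.write(f"{rid}\t{species}\n")


# ---------------------------------------------------------------------------
# Result tables

FLOAT_FMT = "%.6f"


def write_tsv_outputs(assignments, profiles, results, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write the three result tables to ``out_dir``.

    * ``asv_assignments.tsv`` — asv_sequence, species, confidence;
    * ``species_profiles.tsv`` — species × samples percent matrix;
    * ``correlation_table.tsv`` — sample, rho, n_taxa, unknown_percent.

    Numbers are rendered with 6 decimal places; an undefined rho is
    written as ``NA``. Empty inputs yield header-only files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "assignments": out / "asv_assignments.tsv",
        "profiles": out / "species_profiles.tsv",
        "correlations": out / "correlation_table.tsv",
    }

    with open(paths["assignments"], "w", encoding="utf-8") as fh:
        fh.write("asv_sequence\tspecies\tconfidence\n")
        for a in assignments:
            fh.write(f"{a.asv_sequence}\t{a.species_label}\t{a.confidence:.6f}\n")

    with open(paths["profiles"], "w", encoding="utf-8") as fh:
        if profiles:
            labels = list(profiles[0].abundances)
            fh.write("species\t" + "\t".join(p.sample_id for p in profiles) + "\n")
            for label in labels:
                row = "\t".join(f"{p.abundances[label]:.6f}" for p in profiles)
                fh.write(f"{label}\t{row}\n")
        else:
            fh.write("species\n")

    with open(paths["correlations"], "w", encoding="utf-8") as fh:
        fh.write("sample\trho\tn_taxa\tunknown_percent\n")
        for r in results:
            rho = "NA" if r.rho is None else f"{r.rho:.6f}"
            fh.write(f"{r.sample_id}\t{rho}\t{r.n_taxa}\t{r.unknown_percent:.6f}\n")

    return paths


def read_species_profiles(path: str | os.PathLike) -> pd.DataFrame:
    """Read back ``species_profiles.tsv`` as a species × samples DataFrame."""
    df = _read_tsv(path)
    if df.columns[0] != "species":
        raise ValidationError(f"{path}: first column must be 'species'")
    df = df.set_index("species")
    return df.astype(float)
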