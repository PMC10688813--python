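"""Ground-truth objects of the workflow.

Two inputs define what a mock-community sample *should* look like:

* the **training set** — the expected members' full-length 16S rRNA gene
  sequences with species labels, indexed by k-mer content for the
  classifier; and
* the **theoretical composition** — the vendor- or designer-specified
  expected percent of each member.

The package ships no vendor data: sequences and percentages are supplied
by the user as FASTA + TSV (a template config is included under
``config/``), and tests use fully synthetic panels.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

from mockqc.errors import ValidationError
from mockqc.io_formats import ReferenceRecord, _read_tsv

DEFAULT_K = 8
_K_RANGE = (4, 12)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iter_kmers(sequence: str, k: int) -> Iterable[str]:
    """Yield every k-mer of ``sequence`` composed only of A/C/G/T.

    Windows containing N or any ambiguity code are skipped (a common
    artifact of denoiser output); ambiguity codes are never expanded.
    """
    seq = sequence.upper()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if all(c in "ACGT" for c in w):
            yield w


def distinct_kmers(sequence: str, k: int) -> list[str]:
    """Sorted distinct A/C/G/T k-mers of ``sequence``."""
    return sorted(set(iter_kmers(sequence, k)))


@dataclass
class TrainingSet:
    """Expected mock members with a per-species k-mer presence index.

    ``kmer_index`` maps each species label to the set of distinct k-mers
    occurring in any of its reference records (forward strand, unless the
    set was built with ``both_strands=True``).
    """

    records: list[ReferenceRecord]
    species_labels: list[str]
    k: int
    kmer_index: dict[str, frozenset[str]]
    record_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len(self.species_labels)


def build_training_set(
    records: Iterable[ReferenceRecord],
    k: int = DEFAULT_K,
    both_strands: bool = False,
) -> TrainingSet:
    """Build the taxonomic training set from expected-member sequences.

    Requires at least two distinct species (a comparison against a
    single-species mock is meaningless) and every sequence to be at least
    ``2 k`` long. Species labels are held in lexicographic order, which
    also fixes classifier tie-breaking. With ``both_strands=True`` each
    species' index additionally contains the reverse-complement k-mers of
    its records, for ASV tables whose orientation is not guaranteed.
    """
    records = list(records)
    if not (_K_RANGE[0] <= k <= _K_RANGE[1]):
        raise ValidationError(f"word size k must be in [{_K_RANGE[0]}, {_K_RANGE[1]}], got {k}")
    if not records:
        raise ValidationError("no reference records supplied")
    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate record IDs in reference set")
    species = sorted({r.species_label for r in records})
    if len(species) < 2:
        raise ValidationError(
            f"training set needs at least 2 species, got {len(species)} "
            f"({species[0]!r})" if species else "training set needs at least 2 species"
        )
    for r in records:
        if len(r.sequence) < 2 * k:
            raise ValidationError(
                f"reference record {r.record_id!r} is shorter than 2k = {2 * k} bases"
            )

    index: dict[str, set[str]] = {s: set() for s in species}
    counts: dict[str, int] = {s: 0 for s in species}
    for r in records:
        kmers = set(iter_kmers(r.sequence, k))
        if both_strands:
            kmers |= set(iter_kmers(reverse_complement(r.sequence), k))
        index[r.species_label] |= kmers
        counts[r.species_label] += 1

    return TrainingSet(
        records=records,
        species_labels=species,
        k=k,
        kmer_index={s: frozenset(v) for s, v in index.items()},
        record_counts=counts,
    )


def load_reference_records(
    fasta_path: str | os.PathLike, species_map_path: str | os.PathLike
) -> list[ReferenceRecord]:
    """Join a reference FASTA with its record→species map."""
    from mockqc.io_formats import read_fasta, read_species_map

    seqs = read_fasta(fasta_path)
    mapping = read_species_map(species_map_path)
    missing = [rid for rid, _ in seqs if rid not in mapping]
    if missing:
        raise ValidationError(
            f"species map is missing entries for FASTA records: {missing}"
        )
    return [ReferenceRecord(rid, mapping[rid], seq) for rid, seq in seqs]


@dataclass(frozen=True)
class TheoreticalComposition:
    """Expected percent of each mock member; the comparison baseline.

    Percents must be positive and sum to exactly 100 (within 1e-6); they
    are never renormalized — an off-sum table is treated as a
    configuration mistake and rejected.
    """

    mock_name: str
    expected: dict[str, float]

    def __post_init__(self) -> None:
        if not self.expected:
            raise ValidationError("theoretical composition is empty")
        for label, pct in self.expected.items():
            if not label:
                raise ValidationError("theoretical composition has an empty species label")
            if not pct > 0:
                raise ValidationError(
                    f"theoretical percent for {label!r} must be positive, got {pct}"
                )
        total = sum(self.expected.values())
        if abs(total - 100.0) > 1e-6:
            raise ValidationError(
                f"theoretical percents must sum to 100, got {total!r}"
            )

    @property
    def species(self) -> list[str]:
        """Species labels in table order."""
        return list(self.expected)

    @property
    def percents(self) -> list[float]:
        return list(self.expected.values())


def read_theoretical_composition(
    path: str | os.PathLike, mock_name: str = "mock"
) -> TheoreticalComposition:
    """Read the 2-column ``species<TAB>percent`` table."""
    df = _read_tsv(path)
    expected_cols = ["species", "percent"]
    if list(df.columns[:2]) != expected_cols:
        raise ValidationError(
            f"{path}: theoretical table must have header 'species\\tpercent', "
            f"got {list(df.columns)}"
        )
    comp: dict[str, float] = {}
    for i, row in df.iterrows():
        label = row["species"]
        if label is None or not str(label).strip():
            raise ValidationError(f"{path}: empty species label in row {i + 1}")
        label = str(label)
        if label in comp:
            raise ValidationError(f"{path}: duplicate species {label!r}")
        try:
            pct = float(row["percent"])
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path}: non-numeric percent {row['percent']!r} for {label!r}"
            ) from None
        comp[label] = pct
    return TheoreticalComposition(mock_name=mock_name, expected=comp)


def write_theoretical_composition(
    tc: TheoreticalComposition, path: str | os.PathLike
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("species\tpercent\n")
        for label, pct in tc.expected.items():
            fh.write(f"{label}\t{pct:g}\n")


class ConcordanceReport(NamedTuple):
    """Label-set differences between training set and theoretical table."""

    only_in_training: list[str]
    only_in_theoretical: list[str]

    @property
    def training_subset_of_theoretical(self) -> bool:
        return not self.only_in_training


def check_label_concordance(
    ts: TrainingSet, tc: TheoreticalComposition
) -> ConcordanceReport:
    """Report species present in one label set but not the other.

    The pipeline refuses to proceed when the training set contains labels
    absent from the theoretical table (those calls could never be
    compared); the reverse — an expected species with no reference — is
    tolerated with a warning, since that species simply can never be
    observed.
    """
    train = set(ts.species_labels)
    theo = set(tc.species)
    return ConcordanceReport(
        only_in_training=sorted(train - theo),
        only_in_theoretical=sorted(theo - train),
    )
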