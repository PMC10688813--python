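"""Fully synthetic mock communities for testing and demonstration.

Generates the three inputs the pipeline needs — a reference panel with
species labels, a theoretical composition, and an ASV count table — with
no external downloads. The default configuration emulates an 8-species
bacterial DNA standard (ZymoBIOMICS D6300-style) subjected to a D0–D8
three-fold dilution series, in which progressively diluted input biomass
inflates the relative contribution of contaminant reads.

Design choices that make ground truth unambiguous:

* panel sequences are i.i.d. uniform-random DNA with pairwise k-mer-set
  Jaccard similarity enforced below a small ceiling, so species are
  cleanly separable by a k-mer classifier;
* contaminant sequences are constructed to share *no* k-mer with the
  panel, so every contaminant read is a true ``Unknown``;
* ASV variants differ from their reference by substitutions only (no
  indels), keeping lengths fixed and classification k-mer based.

All generation is deterministic under ``rng_seed``; independent
substreams are spawned per stage so changing, say, the number of
variants never perturbs the panel itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from mockqc.errors import ValidationError
from mockqc.io_formats import AsvTable, ReferenceRecord, write_asv_table, write_fasta, write_species_map
from mockqc.reference import DEFAULT_K, TheoreticalComposition, iter_kmers, write_theoretical_composition

_BASES = np.array(list("ACGT"))

DILUTION_LABELS = [f"D{i}" for i in range(9)]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic mock-community generator.

    ``seq_length`` defaults to 1500 nt (full-length 16S-like);
    ``asv_error_rate`` is a per-base substitution probability for the
    dada2-style variant sequences; ``contamination_rate`` is the
    probability mass routed to contaminant ASVs in a single sample (the
    dilution series overrides it per sample with an increasing schedule
    from ``dilution_c0`` at D0 to ``dilution_c8`` at D8).
    """

    n_species: int = 8
    seq_length: int = 1500
    n_samples: int = 3
    depth: int = 100_000
    n_variants_per_species: int = 3
    asv_error_rate: float = 0.02
    contamination_rate: float = 0.0
    n_contaminants: int = 12
    k: int = DEFAULT_K
    max_jaccard: float = 0.05
    dilution_c0: float = 0.01
    dilution_c8: float = 0.6
    exact_counts: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValidationError(f"n_species must be >= 2, got {self.n_species}")
        if self.depth < 1:
            raise ValidationError(f"depth must be >= 1, got {self.depth}")
        if self.seq_length < 2 * self.k:
            raise ValidationError(
                f"seq_length must be >= 2k = {2 * self.k}, got {self.seq_length}"
            )
        for name in ("asv_error_rate", "contamination_rate", "dilution_c0", "dilution_c8"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if self.asv_error_rate >= 0.1:
            raise ValidationError(
                f"asv_error_rate must be < 0.1, got {self.asv_error_rate}"
            )
        if self.n_variants_per_species < 1:
            raise ValidationError("n_variants_per_species must be >= 1")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.n_contaminants < 1:
            raise ValidationError("n_contaminants must be >= 1")


def _substreams(cfg: SimulationConfig, n: int = 5) -> list[np.random.Generator]:
    children = np.random.SeedSequence(cfg.rng_seed).spawn(n)
    return [np.random.default_rng(s) for s in children]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    return frozenset(iter_kmers(seq, k))


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def species_label(i: int) -> str:
    return f"Species_{i + 1:02d}"


def _draw_percents(rng: np.random.Generator, n: int) -> list[float]:
    """Random percents on a 0.1 grid: exact sum 100, every value >= 1,
    pairwise separation of at least 1 point (for panels small enough to
    allow it; the floor shrinks automatically beyond ~13 species).

    The separation floor keeps the expected abundance ranking
    unambiguous: at typical sequencing depths multinomial noise moves a
    percent by well under one point, so a rank swap between species is a
    signal of real bias, not sampling jitter.

    Construction (all arithmetic in integer tenths, so the sum is exact
    by construction): sorted values are a base ladder
    ``1 + sep * i`` plus nondecreasing random extras that consume the
    remaining mass, then the sorted values are assigned to species in
    random order.
    """
    if n < 2:
        raise ValidationError(f"need at least 2 species, got {n}")
    total = 1000  # tenths of a percent
    n_pairs = n * (n - 1) // 2
    # Largest feasible separation (in tenths) up to the 1-point target.
    sep = min(10, (total - 10 * n) // n_pairs)
    if sep < 1:
        raise ValidationError(f"cannot place {n} distinct percents >= 1 summing to 100")
    base = 10 + sep * np.arange(n)  # sorted ladder, in tenths
    remaining = total - int(base.sum())

    # Nondecreasing extras keep the sorted gaps >= sep.
    raw = np.sort(rng.random(n))
    extras = np.floor(raw / raw.sum() * remaining).astype(np.int64) if remaining else np.zeros(n, np.int64)
    shortfall = remaining - int(extras.sum())
    extras[n - shortfall :] += 1  # top up the largest extras; order preserved
    tenths = base + extras

    assert tenths.sum() == total and (np.diff(tenths) >= sep).all()
    order = rng.permutation(n)
    return [float(tenths[i]) / 10.0 for i in order]


def generate_reference_panel(
    cfg: SimulationConfig,
) -> tuple[list[ReferenceRecord], TheoreticalComposition]:
    """Synthetic reference panel + theoretical composition.

    Sequences are regenerated until every pair's k-mer Jaccard similarity
    is below ``cfg.max_jaccard``, guaranteeing classifier separability.
    """
    rng_seq, rng_pct = _substreams(cfg, 2)
    sequences: list[str] = []
    kmer_sets: list[frozenset[str]] = []
    for _ in range(cfg.n_species):
        for attempt in range(100):
            seq = _random_sequence(rng_seq, cfg.seq_length)
            ks = _kmer_set(seq, cfg.k)
            if all(_jaccard(ks, other) < cfg.max_jaccard for other in kmer_sets):
                sequences.append(seq)
                kmer_sets.append(ks)
                break
        else:
            raise ValidationError(
                "could not generate k-mer-separable panel sequences; "
                "seq_length is too short for this k"
            )

    records = [
        ReferenceRecord(f"ref{i + 1:02d}", species_label(i), seq)
        for i, seq in enumerate(sequences)
    ]
    percents = _draw_percents(rng_pct, cfg.n_species)
    tc = TheoreticalComposition(
        mock_name="synthetic-mock",
        expected={species_label(i): percents[i] for i in range(cfg.n_species)},
    )
    return records, tc


def generate_asv_variants(
    panel: list[ReferenceRecord], cfg: SimulationConfig
) -> list[tuple[str, str]]:
    """dada2-style ASV variants: each reference plus substitution-mutated
    copies, all unique. With ``asv_error_rate == 0`` mutation cannot
    produce new sequences, so the output deduplicates to one exact copy
    per species."""
    _, _, rng = _substreams(cfg, 3)
    variants: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in panel:
        if rec.sequence not in seen:
            variants.append((rec.sequence, rec.species_label))
            seen.add(rec.sequence)
        if cfg.asv_error_rate == 0.0:
            continue
        for _ in range(cfg.n_variants_per_species - 1):
            for attempt in range(50):
                mutated = _mutate(rng, rec.sequence, cfg.asv_error_rate)
                if mutated not in seen:
                    variants.append((mutated, rec.species_label))
                    seen.add(mutated)
                    break
            else:
                raise ValidationError(
                    f"could not generate a unique variant of {rec.record_id!r}"
                )
    return variants


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def generate_contaminant_pool(
    panel: list[ReferenceRecord], cfg: SimulationConfig
) -> list[str]:
    """Random sequences sharing no k-mer with the panel.

    Built base by base, only ever extending with a base whose new k-mer
    is absent from the panel's combined index; a dead end restarts the
    sequence. Disjointness makes contaminant reads unambiguous ground
    truth for the ``Unknown`` fraction.
    """
    _, _, _, rng = _substreams(cfg, 4)
    forbidden: set[str] = set()
    for rec in panel:
        forbidden |= set(iter_kmers(rec.sequence, cfg.k))
    pool: list[str] = []
    seen: set[str] = set()
    for _ in range(cfg.n_contaminants):
        for attempt in range(500):
            seq = _disjoint_sequence(rng, cfg.seq_length, cfg.k, forbidden)
            if seq is not None and seq not in seen:
                pool.append(seq)
                seen.add(seq)
                break
        else:
            raise ValidationError(
                "could not generate contaminants k-mer-disjoint from the panel"
            )
    return pool


def _disjoint_sequence(
    rng: np.random.Generator, length: int, k: int, forbidden: set[str]
) -> str | None:
    """One attempt at a sequence whose every k-mer avoids ``forbidden``."""
    for _ in range(200):
        start = _random_sequence(rng, k)
        if start not in forbidden:
            break
    else:
        return None
    chars = list(start)
    while len(chars) < length:
        tail = "".join(chars[-(k - 1) :])
        options = [b for b in _BASES[rng.permutation(4)] if tail + b not in forbidden]
        if not options:
            return None  # dead end; caller restarts
        chars.append(options[0])
    return "".join(chars)


def simulate_sample(
    variants: list[tuple[str, str]],
    contaminants: list[str],
    tc: TheoreticalComposition,
    depth: int,
    contamination_rate: float,
    rng: np.random.Generator,
    exact_counts: bool = False,
) -> np.ndarray:
    """One sample's read counts over ``variants + contaminants``.

    Read mass is allocated by a single multinomial draw of size
    ``depth``: variant *i* of species *s* has probability
    ``(1 - c) * (theoretical_s / 100) / n_variants_of_s`` and the
    contaminant pool shares probability ``c`` equally. With
    ``exact_counts`` the multinomial is replaced by ``round(depth * p)``
    — a noise-free surface for end-to-end identity checks.
    """
    n_var: dict[str, int] = {}
    for _, label in variants:
        n_var[label] = n_var.get(label, 0) + 1
    c = contamination_rate
    probs = np.empty(len(variants) + len(contaminants))
    for i, (_, label) in enumerate(variants):
        probs[i] = (1.0 - c) * (tc.expected[label] / 100.0) / n_var[label]
    if contaminants:
        probs[len(variants) :] = c / len(contaminants)
    elif c > 0:
        raise ValidationError("contamination_rate > 0 but contaminant pool is empty")
    if exact_counts:
        return np.rint(depth * probs).astype(np.int64)
    return rng.multinomial(depth, probs / probs.sum())


def dilution_schedule(cfg: SimulationConfig) -> list[float]:
    """Strictly increasing contamination rates c_i = 1 - (1 - c0) * g**i,
    with g chosen so that c8 hits ``cfg.dilution_c8``."""
    c0, c8 = cfg.dilution_c0, cfg.dilution_c8
    if not c8 > c0:
        raise ValidationError(f"dilution_c8 ({c8}) must exceed dilution_c0 ({c0})")
    g = ((1.0 - c8) / (1.0 - c0)) ** (1.0 / 8.0)
    return [1.0 - (1.0 - c0) * g**i for i in range(9)]


def simulate_dilution_series(
    panel: list[ReferenceRecord],
    tc: TheoreticalComposition,
    variants: list[tuple[str, str]],
    cfg: SimulationConfig,
) -> AsvTable:
    """Nine samples D0–D8 with the increasing contamination schedule and
    constant depth, sharing one ASV row set."""
    contaminants = generate_contaminant_pool(panel, cfg)
    schedule = dilution_schedule(cfg)
    _, _, _, _, rng = _substreams(cfg, 5)
    columns = [
        simulate_sample(
            variants, contaminants, tc, cfg.depth, c, rng, exact_counts=cfg.exact_counts
        )
        for c in schedule
    ]
    sequences = [seq for seq, _ in variants] + contaminants
    return AsvTable(
        sample_ids=list(DILUTION_LABELS),
        asv_sequences=sequences,
        counts=np.column_stack(columns),
    )


def simulate_constant_table(
    panel: list[ReferenceRecord],
    tc: TheoreticalComposition,
    variants: list[tuple[str, str]],
    cfg: SimulationConfig,
) -> AsvTable:
    """``cfg.n_samples`` replicate samples, all at ``cfg.contamination_rate``."""
    contaminants = (
        generate_contaminant_pool(panel, cfg) if cfg.contamination_rate > 0 else []
    )
    _, _, _, _, rng = _substreams(cfg, 5)
    columns = [
        simulate_sample(
            variants,
            contaminants,
            tc,
            cfg.depth,
            cfg.contamination_rate,
            rng,
            exact_counts=cfg.exact_counts,
        )
        for _ in range(cfg.n_samples)
    ]
    sequences = [seq for seq, _ in variants] + contaminants
    return AsvTable(
        sample_ids=[f"S{i + 1}" for i in range(cfg.n_samples)],
        asv_sequences=sequences,
        counts=np.column_stack(columns),
    )


@dataclass
class SyntheticDataset:
    """The full bundle the generator emits."""

    panel: list[ReferenceRecord]
    theoretical: TheoreticalComposition
    variants: list[tuple[str, str]] = field(repr=False)
    asv_table: AsvTable = field(repr=False)


def simulate_dataset(cfg: SimulationConfig, dilution_series: bool = True) -> SyntheticDataset:
    """Panel + composition + variants + ASV table in one call."""
    panel, tc = generate_reference_panel(cfg)
    variants = generate_asv_variants(panel, cfg)
    if dilution_series:
        table = simulate_dilution_series(panel, tc, variants, cfg)
    else:
        table = simulate_constant_table(panel, tc, variants, cfg)
    return SyntheticDataset(panel=panel, theoretical=tc, variants=variants, asv_table=table)


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write reference.fasta, species_map.tsv, theoretical.tsv, asv_table.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out / "reference.fasta",
        "species_map": out / "species_map.tsv",
        "theoretical": out / "theoretical.tsv",
        "asv_table": out / "asv_table.tsv",
    }
    write_fasta([(r.record_id, r.sequence) for r in ds.panel], paths["reference"])
    write_species_map({r.record_id: r.species_label for r in ds.panel}, paths["species_map"])
    write_theoretical_composition(ds.theoretical, paths["theoretical"])
    write_asv_table(ds.asv_table, paths["asv_table"])
    return paths
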