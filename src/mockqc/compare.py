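"""Species-level aggregation and comparison against the theoretical mix.

ASV counts are summed per species call, converted to percent relative
abundance per sample, and each sample's observed profile is compared to
the theoretical composition with Spearman's rank correlation. Reads whose
ASV failed classification carry the ``Unknown`` label; their percent is
reported separately as a contamination/artifact diagnostic and is
*excluded* from the correlation vector (the theoretical table has no
Unknown entry, and padding it with a zero would inflate rho).

Spearman's rho is computed as the Pearson correlation of midranks
(average ranks for ties) rather than the 6*sum(d^2) shortcut, because
mock profiles routinely contain ties — typically zeros for dropped-out
members. When either rank vector is constant the statistic is undefined
and reported as ``None``, never as a silently propagated NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mockqc.classifier import UNKNOWN_LABEL, TaxonomicAssignment
from mockqc.errors import ValidationError
from mockqc.io_formats import AsvTable
from mockqc.reference import TheoreticalComposition

logger = logging.getLogger(__name__)

__all__ = [
    "UNKNOWN_LABEL",
    "SpeciesProfile",
    "ComparisonResult",
    "aggregate_to_species",
    "to_relative_abundance",
    "spearman_rho",
    "compare_to_theoretical",
]


@dataclass(frozen=True)
class SpeciesProfile:
    """Percent relative abundance of each expected species (plus Unknown)
    in one sample. Percents sum to 100; unobserved species appear as 0."""

    sample_id: str
    abundances: dict[str, float]

    def __post_init__(self) -> None:
        for label, pct in self.abundances.items():
            if pct < 0:
                raise ValidationError(
                    f"negative abundance {pct} for {label!r} in sample {self.sample_id!r}"
                )
        total = sum(self.abundances.values())
        if abs(total - 100.0) > 1e-9:
            raise ValidationError(
                f"abundances in sample {self.sample_id!r} sum to {total!r}, not 100"
            )
        if UNKNOWN_LABEL not in self.abundances:
            raise ValidationError(f"profile {self.sample_id!r} lacks an {UNKNOWN_LABEL!r} entry")

    @property
    def unknown_percent(self) -> float:
        return self.abundances[UNKNOWN_LABEL]


@dataclass(frozen=True)
class ComparisonResult:
    """Per-sample agreement with the theoretical composition."""

    sample_id: str
    rho: float | None
    n_taxa: int
    unknown_percent: float


def aggregate_to_species(
    tbl: AsvTable,
    assignments: list[TaxonomicAssignment],
    tc: TheoreticalComposition,
) -> pd.DataFrame:
    """Sum ASV counts per species call.

    Returns a (species × samples) integer DataFrame whose row order is
    the theoretical table's species order with ``Unknown`` last. Calls to
    species absent from the theoretical table are folded into ``Unknown``
    — by definition they were not expected — with a logged warning.
    """
    if len(assignments) != tbl.n_asvs:
        raise ValidationError(
            f"{len(assignments)} assignments for {tbl.n_asvs} ASVs"
        )
    order = tc.species + [UNKNOWN_LABEL]
    known = set(tc.species)
    counts = pd.DataFrame(0, index=order, columns=tbl.sample_ids, dtype=np.int64)
    folded: set[str] = set()
    for i, a in enumerate(assignments):
        label = a.species_label
        if label != UNKNOWN_LABEL and label not in known:
            folded.add(label)
            label = UNKNOWN_LABEL
        counts.loc[label] += tbl.counts[i]
    if folded:
        logger.warning(
            "species not in the theoretical table folded into %r: %s",
            UNKNOWN_LABEL,
            sorted(folded),
        )
    return counts


def to_relative_abundance(species_counts: pd.DataFrame) -> list[SpeciesProfile]:
    """Convert per-sample species counts to percent profiles.

    Zero-depth samples are excluded with a logged warning rather than
    aborting the run; all other samples proceed.
    """
    profiles: list[SpeciesProfile] = []
    for sample_id in species_counts.columns:
        col = species_counts[sample_id].to_numpy(dtype=float)
        depth = col.sum()
        if depth <= 0:
            logger.warning("sample %r has zero depth; excluded from profiles", sample_id)
            continue
        pct = 100.0 * col / depth
        profiles.append(
            SpeciesProfile(
                sample_id=str(sample_id),
                abundances=dict(zip(species_counts.index, pct)),
            )
        )
    return profiles


def spearman_rho(x, y) -> float | None:
    """Spearman's rank correlation via midranks + Pearson.

    Returns ``None`` (the undefined marker) when either midrank vector is
    constant, i.e. all values tied. Requires n >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"vectors must be 1-D of equal length, got {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValidationError(f"need at least 3 observations for rho, got {x.size}")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = np.sqrt((sx**2).sum() * (sy**2).sum())
    if denom == 0.0:
        return None
    return float((sx * sy).sum() / denom)


def compare_to_theoretical(
    profiles: list[SpeciesProfile], tc: TheoreticalComposition
) -> list[ComparisonResult]:
    """The per-sample correlation table.

    For each sample the observed vector runs over the theoretical species
    only — Unknown mass is excluded and reported alongside. The observed
    vector is not renormalized after exclusion: Spearman is rank-based,
    so renormalization would be a no-op.
    """
    if len(tc.species) < 3:
        raise ValidationError(
            f"need at least 3 theoretical species for rho, got {len(tc.species)}"
        )
    results = []
    theoretical = np.array(tc.percents, dtype=float)
    for p in profiles:
        observed = np.array([p.abundances.get(s, 0.0) for s in tc.species])
        results.append(
            ComparisonResult(
                sample_id=p.sample_id,
                rho=spearman_rho(observed, theoretical),
                n_taxa=len(tc.species),
                unknown_percent=p.unknown_percent,
            )
        )
    return results
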