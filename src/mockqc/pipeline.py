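"""End-to-end check: classify → aggregate → compare.

Thin orchestration used by both the CLI and the acceptance script; all
substance lives in the classifier and compare modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from mockqc.classifier import ClassifierParams, TaxonomicAssignment, classify_table
from mockqc.compare import (
    ComparisonResult,
    SpeciesProfile,
    aggregate_to_species,
    compare_to_theoretical,
    to_relative_abundance,
)
from mockqc.errors import ValidationError
from mockqc.io_formats import AsvTable
from mockqc.reference import (
    TheoreticalComposition,
    TrainingSet,
    check_label_concordance,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything the check stage produces, ready for writing/plotting."""

    assignments: list[TaxonomicAssignment]
    species_counts: pd.DataFrame
    profiles: list[SpeciesProfile]
    comparisons: list[ComparisonResult]


def run_check(
    tbl: AsvTable,
    ts: TrainingSet,
    tc: TheoreticalComposition,
    params: ClassifierParams,
) -> PipelineResult:
    """Classify an ASV table and compare every sample to the theoretical mix.

    Refuses to run when the training set contains species absent from the
    theoretical table (their calls could never be compared); the reverse
    — an expected species with no reference sequence — only warns, since
    that species simply can never be observed.
    """
    report = check_label_concordance(ts, tc)
    if report.only_in_training:
        raise ValidationError(
            "training-set species missing from the theoretical table: "
            f"{report.only_in_training}; theoretical-only species: "
            f"{report.only_in_theoretical}"
        )
    if report.only_in_theoretical:
        logger.warning(
            "theoretical species with no reference sequence (can never be observed): %s",
            report.only_in_theoretical,
        )

    assignments = classify_table(tbl, ts, params)
    species_counts = aggregate_to_species(tbl, assignments, tc)
    profiles = to_relative_abundance(species_counts)
    comparisons = compare_to_theoretical(profiles, tc)
    return PipelineResult(
        assignments=assignments,
        species_counts=species_counts,
        profiles=profiles,
        comparisons=comparisons,
    )
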