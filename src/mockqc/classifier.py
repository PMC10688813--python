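"""Word-presence naive-Bayes classifier with bootstrap confidence.

Each ASV is assigned to one of the mock's expected species, or to the
sentinel ``"Unknown"``, in the style of RDP-like k-mer classifiers:

1. extract the ASV's distinct A/C/G/T k-mers;
2. if none of them occurs in any species' index, the call is
   ``("Unknown", 0.0)`` unconditionally — without this guard the all-tie
   case would elect a spuriously confident lexicographic winner;
3. otherwise run ``n_bootstraps`` rounds, each drawing
   ``ceil(subsample_fraction * n_kmers)`` k-mers with replacement,
   scoring every species by the naive-Bayes log-likelihood below, and
   voting for the arg-max (ties go to the lexicographically smallest
   label);
4. confidence is the plurality vote fraction; calls below
   ``confidence_threshold`` are demoted to ``"Unknown"`` (keeping their
   confidence value).

The per-species score of a query k-mer multiset Q is

    score(s) = sum over distinct w in Q of log P(w | s)
    P(w | s) = (m_s(w) + p_w) / (M_s + 1)

with m_s(w) = 1 if w occurs in species s' index else 0, M_s = 1, and the
word prior p_w = (n_w + 0.5) / (N + 1), where n_w is the number of
species containing w and N the number of species. This is word-presence
naive Bayes: each species is summarized by the *set* of words its
references contain, and priors downweight words shared by many species.

Randomness is confined to the bootstrap subsampling. Each ASV gets its
own RNG substream keyed by ``(rng_seed, asv_index)``, so results do not
depend on the order in which ASVs are processed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from mockqc.errors import ValidationError
from mockqc.io_formats import AsvTable
from mockqc.reference import DEFAULT_K, TrainingSet, distinct_kmers

logger = logging.getLogger(__name__)

UNKNOWN_LABEL = "Unknown"


@dataclass(frozen=True)
class TaxonomicAssignment:
    """Species call for one ASV, with bootstrap confidence in [0, 1]."""

    asv_sequence: str
    species_label: str
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(f"confidence must be in [0,1], got {self.confidence}")
        if self.confidence == 0.0 and self.species_label != UNKNOWN_LABEL:
            raise ValidationError("zero confidence is only permitted for 'Unknown'")

    @property
    def is_unknown(self) -> bool:
        return self.species_label == UNKNOWN_LABEL


@dataclass(frozen=True)
class ClassifierParams:
    """Tunables of the bootstrap naive-Bayes classifier.

    Defaults follow the conventions of the RDP family: word size 8,
    100 bootstrap rounds each drawing one eighth of the query's distinct
    k-mers, and a 0.60 confidence threshold below which calls become
    ``Unknown``.
    """

    k: int = DEFAULT_K
    n_bootstraps: int = 100
    subsample_fraction: float = 0.125
    confidence_threshold: float = 0.60
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstraps < 1:
            raise ValidationError(f"n_bootstraps must be >= 1, got {self.n_bootstraps}")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValidationError(
                f"subsample_fraction must be in (0,1], got {self.subsample_fraction}"
            )
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValidationError(
                f"confidence_threshold must be in [0,1], got {self.confidence_threshold}"
            )


def score_species(query_kmers, ts: TrainingSet) -> dict[str, float]:
    """Naive-Bayes log-score of every species for a query k-mer multiset.

    Only the distinct words of the query contribute (word *presence*, not
    abundance). Returns ``{species_label: log-score}`` over all training
    species, in lexicographic label order.
    """
    words = sorted(set(query_kmers))
    if not words:
        raise ValidationError("query k-mer set is empty")
    n_species = ts.n_species
    scores = {s: 0.0 for s in ts.species_labels}
    for w in words:
        n_w = sum(1 for s in ts.species_labels if w in ts.kmer_index[s])
        p_w = (n_w + 0.5) / (n_species + 1)
        for s in ts.species_labels:
            m = 1.0 if w in ts.kmer_index[s] else 0.0
            scores[s] += math.log((m + p_w) / 2.0)
    return scores


def _presence_matrix(words: list[str], ts: TrainingSet) -> np.ndarray:
    """Boolean (n_words, n_species) presence of each word in each index."""
    mat = np.zeros((len(words), ts.n_species), dtype=bool)
    for j, s in enumerate(ts.species_labels):
        idx = ts.kmer_index[s]
        for i, w in enumerate(words):
            if w in idx:
                mat[i, j] = True
    return mat


def classify_asv(
    asv: str,
    ts: TrainingSet,
    params: ClassifierParams,
    asv_index: int = 0,
) -> TaxonomicAssignment:
    """Classify one ASV sequence against the training set.

    ``asv_index`` keys this ASV's RNG substream together with
    ``params.rng_seed``; callers classifying a whole table pass the row
    index so per-ASV results are independent of processing order.
    """
    asv = asv.upper()
    if params.k != ts.k:
        raise ValidationError(
            f"classifier word size ({params.k}) does not match training set ({ts.k})"
        )
    words = distinct_kmers(asv, ts.k)
    if not words:
        logger.warning(
            "ASV %r... is shorter than k=%d or has no A/C/G/T k-mers; calling Unknown",
            asv[:30],
            ts.k,
        )
        return TaxonomicAssignment(asv, UNKNOWN_LABEL, 0.0)

    presence = _presence_matrix(words, ts)
    if not presence.any():
        # Zero shared evidence: never bootstrap, never elect a winner.
        return TaxonomicAssignment(asv, UNKNOWN_LABEL, 0.0)

    n_species = ts.n_species
    n_w = presence.sum(axis=1)
    p_w = (n_w + 0.5) / (n_species + 1)
    # log P(w|s) for every (word, species); bootstrap rounds sum rows.
    log_p = np.log((presence + p_w[:, None]) / 2.0)

    n_words = len(words)
    m = math.ceil(params.subsample_fraction * n_words)
    rng = np.random.default_rng([params.rng_seed, asv_index])
    votes = np.zeros(n_species, dtype=np.int64)
    for _ in range(params.n_bootstraps):
        draw = rng.integers(0, n_words, size=m)
        rows = np.unique(draw)
        scores = log_p[rows].sum(axis=0)
        # argmax returns the first maximal index; labels are sorted, so
        # ties resolve to the lexicographically smallest species.
        votes[int(np.argmax(scores))] += 1

    winner = int(np.argmax(votes))
    confidence = votes[winner] / params.n_bootstraps
    label = ts.species_labels[winner]
    if confidence < params.confidence_threshold:
        return TaxonomicAssignment(asv, UNKNOWN_LABEL, float(confidence))
    return TaxonomicAssignment(asv, label, float(confidence))


def classify_table(
    tbl: AsvTable, ts: TrainingSet, params: ClassifierParams
) -> list[TaxonomicAssignment]:
    """Classify every ASV of a table, in row order.

    Fully deterministic given ``params.rng_seed``: ASV *i* always uses
    the substream keyed by ``(rng_seed, i)``.
    """
    return [
        classify_asv(seq, ts, params, asv_index=i)
        for i, seq in enumerate(tbl.asv_sequences)
    ]
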