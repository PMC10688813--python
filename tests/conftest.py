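import numpy as np
import pytest

from mockqc.classifier import ClassifierParams
from mockqc.io_formats import ReferenceRecord
from mockqc.reference import build_training_set
from mockqc.synthdata import SimulationConfig, generate_reference_panel


@pytest.fixture(scope="session")
def small_cfg():
    """Small, fast synthetic configuration for unit tests."""
    return SimulationConfig(
        n_species=4,
        seq_length=300,
        depth=10_000,
        n_variants_per_species=2,
        asv_error_rate=0.02,
        n_contaminants=4,
        rng_seed=123,
    )


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return generate_reference_panel(small_cfg)


@pytest.fixture(scope="session")
def small_training_set(small_panel):
    records, _ = small_panel
    return build_training_set(records, k=8)


@pytest.fixture
def default_params():
    return ClassifierParams(rng_seed=11)


@pytest.fixture
def toy_records():
    """Two k-mer-disjoint species over k=4, tiny enough to reason about."""
    return [
        ReferenceRecord("r1", "Alpha", "ACGTACGTACGT"),
        ReferenceRecord("r2", "Beta", "CCCCGGGGCCCCGGGG"),
    ]


def brute_force_spearman(x, y):
    """Independent midrank + Pearson oracle, written with explicit loops
    and no ranking library."""

    def midranks(v):
        n = len(v)
        ranks = [0.0] * n
        for i in range(n):
            less = sum(1 for u in v if u < v[i])
            equal = sum(1 for u in v if u == v[i])
            ranks[i] = less + (equal + 1) / 2.0
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    if vx == 0 or vy == 0:
        return None
    return cov / (vx * vy) ** 0.5


def brute_force_scores(query_kmers, ts):
    """Independent evaluation of the word-presence naive-Bayes formula,
    straight from sets and math.log."""
    import math

    words = set(query_kmers)
    n_species = len(ts.species_labels)
    out = {}
    for s in ts.species_labels:
        total = 0.0
        for w in words:
            n_w = sum(1 for t in ts.species_labels if w in ts.kmer_index[t])
            p_w = (n_w + 0.5) / (n_species + 1)
            m = 1.0 if w in ts.kmer_index[s] else 0.0
            total += math.log((m + p_w) / 2.0)
        out[s] = total
    return out
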