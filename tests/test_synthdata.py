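"""Synthetic mock-community generator: determinism, separability,
dilution schedule, and sampling behavior."""

import numpy as np
import pytest

from mockqc.errors import ValidationError
from mockqc.reference import iter_kmers
from mockqc.synthdata import (
    DILUTION_LABELS,
    SimulationConfig,
    dilution_schedule,
    generate_asv_variants,
    generate_contaminant_pool,
    generate_reference_panel,
    simulate_constant_table,
    simulate_dilution_series,
    simulate_sample,
)


def _kmer_set(seq, k=8):
    return set(iter_kmers(seq, k))


class TestReferencePanel:
    def test_deterministic_under_seed(self, small_cfg):
        a_records, a_tc = generate_reference_panel(small_cfg)
        b_records, b_tc = generate_reference_panel(small_cfg)
        assert [(r.record_id, r.sequence) for r in a_records] == [
            (r.record_id, r.sequence) for r in b_records
        ]
        assert a_tc.expected == b_tc.expected

    def test_percents_sum_exactly_100_distinct_and_separated(self):
        for seed in range(10):
            cfg = SimulationConfig(n_species=8, seq_length=300, rng_seed=seed)
            _, tc = generate_reference_panel(cfg)
            vals = tc.percents
            assert sum(vals) == pytest.approx(100.0, abs=1e-9)
            assert len(set(vals)) == len(vals)
            assert min(vals) >= 1.0
            assert min(np.diff(sorted(vals))) >= 1.0 - 1e-9

    def test_pairwise_kmer_jaccard_below_ceiling(self, small_cfg, small_panel):
        records, _ = small_panel
        sets = [_kmer_set(r.sequence, small_cfg.k) for r in records]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                jac = len(sets[i] & sets[j]) / len(sets[i] | sets[j])
                assert jac < small_cfg.max_jaccard

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            SimulationConfig(n_species=1)
        with pytest.raises(ValidationError):
            SimulationConfig(asv_error_rate=0.5)
        with pytest.raises(ValidationError):
            SimulationConfig(seq_length=10)
        with pytest.raises(ValidationError):
            SimulationConfig(contamination_rate=1.5)


class TestAsvVariants:
    def test_zero_error_rate_deduplicates_to_references(self, small_panel):
        records, _ = small_panel
        cfg = SimulationConfig(
            n_species=4, seq_length=300, asv_error_rate=0.0, rng_seed=123
        )
        variants = generate_asv_variants(records, cfg)
        assert len(variants) == len(records)
        assert {seq for seq, _ in variants} == {r.sequence for r in records}

    def test_substitution_count_matches_binomial_mean(self):
        """error_rate * length substitutions expected per mutated copy;
        check the empirical mean over many seeds against the binomial
        mean with a generous band."""
        length, rate = 1000, 0.02
        totals, n_copies = 0, 0
        for seed in range(30):
            cfg = SimulationConfig(
                n_species=2,
                seq_length=length,
                n_variants_per_species=2,
                asv_error_rate=rate,
                rng_seed=seed,
            )
            records, _ = generate_reference_panel(cfg)
            by_id = {r.species_label: r.sequence for r in records}
            for seq, label in generate_asv_variants(records, cfg):
                ref = by_id[label]
                if seq != ref:
                    totals += sum(a != b for a, b in zip(seq, ref))
                    n_copies += 1
        mean = totals / n_copies
        expected = length * rate  # 20
        assert abs(mean - expected) < 3.0

    def test_all_variants_unique(self, small_cfg, small_panel):
        records, _ = small_panel
        variants = generate_asv_variants(records, small_cfg)
        seqs = [s for s, _ in variants]
        assert len(seqs) == len(set(seqs))
        assert len(variants) == small_cfg.n_species * small_cfg.n_variants_per_species


class TestContaminants:
    def test_pool_is_kmer_disjoint_from_panel(self, small_cfg, small_panel):
        records, _ = small_panel
        pool = generate_contaminant_pool(records, small_cfg)
        assert len(pool) == small_cfg.n_contaminants
        panel_kmers = set()
        for r in records:
            panel_kmers |= _kmer_set(r.sequence, small_cfg.k)
        for seq in pool:
            assert not (_kmer_set(seq, small_cfg.k) & panel_kmers)
            assert len(seq) == small_cfg.seq_length


class TestSimulateSample:
    def test_zero_contamination_puts_no_reads_on_contaminants(self, small_panel, small_cfg):
        records, tc = small_panel
        variants = generate_asv_variants(records, small_cfg)
        pool = generate_contaminant_pool(records, small_cfg)
        rng = np.random.default_rng(0)
        col = simulate_sample(variants, pool, tc, 10_000, 0.0, rng)
        assert col[len(variants):].sum() == 0
        assert col.sum() == 10_000

    def test_full_contamination_puts_all_reads_on_contaminants(self, small_panel, small_cfg):
        records, tc = small_panel
        variants = generate_asv_variants(records, small_cfg)
        pool = generate_contaminant_pool(records, small_cfg)
        rng = np.random.default_rng(0)
        col = simulate_sample(variants, pool, tc, 10_000, 1.0, rng)
        assert col[: len(variants)].sum() == 0

    def test_exact_counts_are_deterministic_rounding(self, small_panel, small_cfg):
        records, tc = small_panel
        cfg0 = SimulationConfig(
            n_species=4, seq_length=300, asv_error_rate=0.0, rng_seed=123
        )
        variants = generate_asv_variants(records, cfg0)  # one per species
        rng = np.random.default_rng(0)
        depth = 100_000
        col = simulate_sample(variants, [], tc, depth, 0.0, rng, exact_counts=True)
        for i, (_, label) in enumerate(variants):
            assert col[i] == round(depth * tc.expected[label] / 100.0)

    def test_contaminated_mass_concentrates_near_rate(self, small_panel, small_cfg):
        """Binomial concentration: at depth 1e5 the contaminant read
        fraction stays within a few points of c = 0.3."""
        records, tc = small_panel
        variants = generate_asv_variants(records, small_cfg)
        pool = generate_contaminant_pool(records, small_cfg)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            col = simulate_sample(variants, pool, tc, 100_000, 0.3, rng)
            frac = 100.0 * col[len(variants):].sum() / col.sum()
            assert 25.0 <= frac <= 35.0


class TestDilutionSeries:
    def test_schedule_strictly_increasing_with_stated_endpoints(self):
        cfg = SimulationConfig(rng_seed=0)
        sched = dilution_schedule(cfg)
        assert len(sched) == 9
        assert all(b > a for a, b in zip(sched, sched[1:]))
        assert sched[0] == pytest.approx(0.01, abs=1e-12)
        assert sched[8] == pytest.approx(0.6, abs=1e-12)

    def test_nine_samples_named_d0_to_d8(self, small_panel):
        records, tc = small_panel
        cfg = SimulationConfig(
            n_species=4, seq_length=300, depth=5_000, n_contaminants=4, rng_seed=123
        )
        variants = generate_asv_variants(records, cfg)
        tbl = simulate_dilution_series(records, tc, variants, cfg)
        assert tbl.sample_ids == DILUTION_LABELS == [f"D{i}" for i in range(9)]
        assert tbl.counts.shape[1] == 9
        assert (tbl.depths() == 5_000).all()

    def test_constant_table_has_requested_samples(self, small_panel):
        records, tc = small_panel
        cfg = SimulationConfig(
            n_species=4, seq_length=300, n_samples=5, depth=5_000,
            asv_error_rate=0.0, rng_seed=123,
        )
        variants = generate_asv_variants(records, cfg)
        tbl = simulate_constant_table(records, tc, variants, cfg)
        assert tbl.sample_ids == ["S1", "S2", "S3", "S4", "S5"]

    def test_series_deterministic_under_seed(self, small_panel):
        records, tc = small_panel
        cfg = SimulationConfig(
            n_species=4, seq_length=300, depth=5_000, n_contaminants=4, rng_seed=9
        )
        variants = generate_asv_variants(records, cfg)
        a = simulate_dilution_series(records, tc, variants, cfg)
        b = simulate_dilution_series(records, tc, variants, cfg)
        assert a.asv_sequences == b.asv_sequences
        assert np.array_equal(a.counts, b.counts)
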