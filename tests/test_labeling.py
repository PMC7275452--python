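"""Resampling, the exact rank-sum step, MSNH arithmetic, and the full filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vansip import pipeline
from vansip.errors import (
    DegenerateInputError,
    DomainError,
    InsufficientReplicationError,
    PairingError,
)
from vansip.labeling import (
    DEFAULT_RESAMPLING_DEPTH,
    OtuTable,
    absolute_abundance,
    apply_label_filter,
    compute_msnh,
    exact_ranksum_p,
    heavy_enrichment_test,
    qpcr_weight,
    resample_column,
    resample_table,
)
from vansip.simulate import SimulationConfig, default_community, simulate_dataset


class TestResampling:
    def test_output_sums_to_depth(self, rng):
        counts = rng.integers(0, 5000, size=200)
        out = resample_column(counts, DEFAULT_RESAMPLING_DEPTH, 1)
        assert out.sum() == DEFAULT_RESAMPLING_DEPTH

    def test_single_taxon_column(self):
        assert resample_column(np.array([5, 0, 0]), 3, 0).tolist() == [3, 0, 0]

    def test_seed_determinism(self):
        counts = np.array([100, 100])
        a = resample_column(counts, 50, 7)
        b = resample_column(counts, 50, 7)
        assert np.array_equal(a, b)

    def test_all_zero_column_rejected(self):
        with pytest.raises(DegenerateInputError):
            resample_column(np.zeros(3, dtype=int), 10, 0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_without_replacement_preserves_zeros(self, seed):
        counts = np.array([40, 0, 60, 0, 100])
        out = resample_column(counts, 50, seed)
        assert out.sum() == 50
        assert out[1] == 0 and out[3] == 0
        assert np.all(out <= counts)  # subsample of the observed reads

    def test_shallow_columns_use_replacement_and_are_flagged(self):
        table = OtuTable(
            ["a", "b"],
            np.array([[5, 500], [5, 500]]),
            [("s", 1), ("s", 2)],
            np.array([10.0, 10.0]),
        )
        resampled, shallow = resample_table(table, depth=100, seed=0)
        assert shallow == [("s", 1)]
        assert resampled.counts.sum(axis=0).tolist() == [100, 100]


class TestQpcrWeight:
    def test_copy_scaling(self):
        table = OtuTable(
            ["a", "b"], np.array([[10, 10], [10, 10]]), [("s", 1), ("s", 2)],
            np.array([1000.0, 0.0]),
        )
        scaled = qpcr_weight(table)
        assert scaled[:, 0].tolist() == [500.0, 500.0]
        assert scaled[:, 1].tolist() == [0.0, 0.0]

    def test_linearity_in_copies(self):
        table = OtuTable(
            ["a", "b"], np.array([[3, 3], [7, 7]]), [("s", 1), ("s", 2)],
            np.array([100.0, 10_000.0]),
        )
        scaled = qpcr_weight(table)
        assert scaled[:, 1] == pytest.approx(scaled[:, 0] * 100)


class TestExactRankSum:
    def brute_force_p(self, x, y):
        """Independent oracle: enumerate all rank assignments directly."""
        from itertools import combinations

        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        n1, n = len(x), len(pooled)
        w_obs = ranks[:n1].sum()
        mu = n1 * (n + 1) / 2
        ws = [sum(ranks[list(c)]) for c in combinations(range(n), n1)]
        return np.mean([abs(w - mu) >= abs(w_obs - mu) - 1e-12 for w in ws])

    def test_complete_separation_3v3(self):
        p, passed = heavy_enrichment_test([4, 5, 6], [1, 2, 3])
        assert p == pytest.approx(0.10)
        assert passed

    def test_one_overlap_3v3(self):
        # one discordant pair: the ¹²C maximum exceeds the smallest ¹³C value
        p, passed = heavy_enrichment_test([3, 5, 6], [1, 2, 4])
        assert p == pytest.approx(0.20)
        assert not passed

    def test_identical_groups(self):
        p, passed = heavy_enrichment_test([2, 2, 2], [2, 2, 2])
        assert p == 1.0
        assert not passed

    def test_matches_scipy_on_tie_free_data(self, rng):
        for _ in range(25):
            x = rng.normal(size=4)
            y = rng.normal(size=5)
            expected = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="exact"
            ).pvalue
            assert exact_ranksum_p(x, y) == pytest.approx(expected)

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(10):
            x = rng.integers(0, 4, size=3).astype(float)
            y = rng.integers(0, 4, size=4).astype(float)
            assert exact_ranksum_p(x, y) == pytest.approx(self.brute_force_p(x, y))

    def test_insufficient_replication(self):
        with pytest.raises(InsufficientReplicationError):
            exact_ranksum_p([1.0], [1.0, 2.0])

    def test_permutation_t_switch(self, rng):
        from vansip.labeling import heavy_enrichment_test, permutation_t_p

        # complete separation, 3 v 3: the only as-extreme splits are the two
        # group assignments themselves -> p = 2/20
        p, passed = heavy_enrichment_test(
            [10.0, 11.0, 12.0], [1.0, 2.0, 3.0], statistic="t_permutation"
        )
        assert p == pytest.approx(0.10)
        assert passed
        # identical groups: every split equally extreme
        assert permutation_t_p([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0


class TestMsnh:
    @pytest.mark.parametrize(
        "h13, h12, expected",
        [(0.30, 0.05, 0.25), (0.42, 0.42, 0.0), (0.00, 0.10, -0.10)],
    )
    def test_subtraction(self, h13, h12, expected):
        assert compute_msnh(h13, h12) == pytest.approx(expected)

    def test_rejects_non_fractions(self):
        with pytest.raises(DomainError):
            compute_msnh(1.2, 0.0)


class TestAbsoluteAbundance:
    def test_reported_scale(self):
        # 90.8% of (1.0 ± 0.3) x 10^6 labeled copies/g -> 9.1 x 10^5
        assert absolute_abundance(0.908, 1.0e6) == pytest.approx(9.1e5, rel=0.005)

    def test_identities(self):
        assert absolute_abundance(0.0, 5e6) == 0.0
        assert absolute_abundance(1.0, 3.3e4) == pytest.approx(3.3e4)


class TestLabelFilter:
    def test_truth_set_recovered_without_false_positives(
        self, demo_dataset, demo_peaks
    ):
        samples, table, truth = demo_dataset
        frame = pipeline.call_decomposers(
            table, demo_peaks, samples, "control", seed=1
        )
        called = set(frame.index[frame["is_decomposer"]])
        labeled = set(truth.index[truth["labeled"]])
        assert called  # strong labeling: the filter finds decomposers
        assert called <= labeled  # every call is in the truth set

    def test_otu_absent_from_heavy_fractions_fails_step1(
        self, demo_dataset, demo_peaks
    ):
        samples, table, truth = demo_dataset
        results = apply_label_filter(table, demo_peaks, samples, "control")
        by_id = {r.otu_id: r for r in results}
        rel = table.relative_abundance()
        heavy_cols = [
            j
            for s in samples
            if s.treatment == "control" and s.isotope in ("C13", "C12")
            for j in table.columns_for(
                s.sample_id, demo_peaks[s.sample_id].heavy_indices
            )
        ]
        absent = [
            otu
            for i, otu in enumerate(table.otu_ids)
            if rel[i, heavy_cols].sum() == 0
        ]
        assert absent, "fixture should contain OTUs absent from heavy fractions"
        for otu in absent:
            assert not by_id[otu].passed_step1
            assert not by_id[otu].is_decomposer

    def test_msnh_ratio_threshold_arithmetic(self, demo_dataset, demo_peaks):
        samples, table, _ = demo_dataset
        results = apply_label_filter(
            table, demo_peaks, samples, "control", msnh_ratio_min=0.20
        )
        for r in results:
            if np.isfinite(r.msnh_ratio):
                assert r.passed_step3 == (r.msnh_ratio >= 0.20)
                assert r.msnh_ratio <= 1 + 1e-9
            assert -1 <= r.msnh <= 1
            assert r.is_decomposer == (r.passed_step1 and r.passed_step3)

    def test_unpaired_sample_raises(self, demo_dataset, demo_peaks):
        samples, table, _ = demo_dataset
        without_c12 = [
            s
            for s in samples
            if not (s.treatment == "control" and s.isotope == "C12" and s.replicate == 2)
        ]
        with pytest.raises(PairingError):
            apply_label_filter(table, demo_peaks, without_c12, "control")

    def test_monotone_in_labeling_strength(self):
        """More label never means fewer truth-labeled calls (ensemble mean)."""
        means = []
        for af in (0.1, 0.3, 0.9):
            hits = []
            for rep in range(8):
                taxa = default_community(atom_fraction_label=af, seed=100 + rep)
                cfg = SimulationConfig(seed=200 + rep)
                samples, table, truth = simulate_dataset(
                    taxa, cfg, treatments=("control",)
                )
                peaks = pipeline.assign_peaks(samples)
                frame = pipeline.call_decomposers(
                    table, peaks, samples, "control", resample_depth=None
                )
                called = set(frame.index[frame["is_decomposer"]])
                labeled = set(truth.index[truth["labeled"]])
                hits.append(len(called & labeled))
            means.append(np.mean(hits))
        assert means[0] <= means[1] <= means[2]
        assert means[2] > means[0]  # labeling strength matters at all
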