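"""Differential expression: QC gate, normalizations, moderated test, BH, filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from netprio.diffexpr import (RnaQcRecord, bh_adjust, compute_fpkm, de_analysis,
                              filter_degs, log_cpm, moderated_ttest, qc_gate)
from netprio.errors import ValidationError
from netprio.synthdata import SimConfig, group_labels, simulate_counts


def bh_stepup_bruteforce(p):
    """Independent brute-force Benjamini–Hochberg step-up rule."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for pos, idx in enumerate(order):
        adj[idx] = min(1.0, min(p[order[j]] * m / (j + 1) for j in range(pos, m)))
    return adj


class TestQcGate:
    @pytest.mark.parametrize("rine,ratio,dv200,ok,failed", [
        (9.3, 2.4, 85.0, True, []),            # healthy sample
        (7.0, 2.01, 70.1, True, []),           # boundary: RINe inclusive, others strict
        (6.9, 2.5, 90.0, False, ["RINe"]),
        (9.0, 2.0, 90.0, False, ["28S/18S"]),  # ratio threshold is strict
        (9.0, 2.5, 70.0, False, ["DV200"]),
        (5.0, 1.0, 50.0, False, ["RINe", "28S/18S", "DV200"]),
    ])
    def test_gate_and_failure_enumeration(self, rine, ratio, dv200, ok, failed):
        passed, failures = qc_gate(RnaQcRecord(rine, ratio, dv200))
        assert passed is ok
        assert failures == failed

    def test_missing_field_is_a_validation_error(self):
        with pytest.raises(ValidationError):
            RnaQcRecord(float("nan"), 2.4, 85.0)


class TestFpkm:
    @pytest.mark.parametrize("count,lib,length,expected", [
        (100, 1e6, 1000, 100.0),
        (0, 1e6, 1000, 0.0),
        (50, 2e6, 500, 50.0),
    ])
    def test_formula(self, count, lib, length, expected):
        assert compute_fpkm([count], [length], [lib])[0] == pytest.approx(expected)

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValidationError, match="library"):
            compute_fpkm([1], [100], [0])


class TestLogCpm:
    def test_count_mapping_to_one_cpm_gives_zero(self):
        # (count + prior) / (lib + 2 prior) == 1e-6  =>  log2(1) == 0
        prior = 0.5
        lib = 1e9
        count = 1e-6 * (lib + 2 * prior) - prior
        assert log_cpm([count], [lib], prior)[0] == pytest.approx(0.0)

    def test_zero_count_small_library(self):
        assert log_cpm([0], [999_999], 0.5)[0] == pytest.approx(-1.0)

    def test_monotone_in_count(self):
        values = log_cpm(np.array([0, 1, 5, 100]), np.full(4, 1e6), 0.5)
        assert np.all(np.diff(values) > 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError, match="non-negative"):
            log_cpm([-1], [1e6], 0.5)


class TestModeratedTtest:
    def test_reduces_to_pooled_t_on_textbook_example(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        res = moderated_ttest(mat, ["control"] * 3 + ["treated"] * 3, prior_df=0)
        assert res["log2fc"].iloc[0] == pytest.approx(3.0)
        assert res["t"].iloc[0] == pytest.approx(3.6742, abs=1e-4)
        assert res["p"].iloc[0] == pytest.approx(0.0213, abs=1e-4)

    def test_identical_group_means_give_null_result(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0, 3.0, 2.0, 1.0]])
        res = moderated_ttest(mat, ["control"] * 3 + ["treated"] * 3, prior_df=0)
        assert res["t"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_prior_df_zero_equals_classical_pooled_t(self):
        rng = np.random.default_rng(42)
        mat = rng.normal(size=(100, 8))
        labels = ["control"] * 4 + ["treated"] * 4
        res = moderated_ttest(mat, labels, prior_df=0)
        t_ref, p_ref = stats.ttest_ind(mat[:, 4:], mat[:, :4], axis=1, equal_var=True)
        np.testing.assert_allclose(res["t"], t_ref, atol=1e-10)
        np.testing.assert_allclose(res["p"], p_ref, atol=1e-10)

    def test_huge_prior_df_behaves_like_known_variance_z_test(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(size=(200, 6))
        labels = ["control"] * 3 + ["treated"] * 3
        res = moderated_ttest(mat, labels, prior_df=1e9, prior_var=1.0)
        lfc = mat[:, 3:].mean(axis=1) - mat[:, :3].mean(axis=1)
        z = lfc / np.sqrt(1.0 * (2.0 / 3.0))
        p_z = 2 * stats.norm.sf(np.abs(z))
        np.testing.assert_allclose(res["t"], z, rtol=1e-6)
        np.testing.assert_allclose(res["p"], p_z, rtol=1e-4)

    def test_constant_gene_with_no_prior_is_flagged(self):
        mat = pd.DataFrame([[2.0] * 6])
        res = moderated_ttest(mat, ["control"] * 3 + ["treated"] * 3, prior_df=0)
        assert bool(res["degenerate"].iloc[0])
        assert res["p"].iloc[0] == 1.0

    def test_single_sample_group_rejected(self):
        with pytest.raises(ValidationError, match="2 samples"):
            moderated_ttest(np.zeros((3, 3)), ["control", "treated", "treated"])


class TestBhAdjust:
    @pytest.mark.parametrize("p,expected", [
        ([0.03], [0.03]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.5], [0.01, 0.5]),
    ])
    def test_hand_enumerated_cases(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    def test_exhaustive_grid_up_to_length_four(self):
        """Equality with the step-up oracle on every sorted p-multiset
        (0.05 grid); permutation equivariance is covered separately."""
        from itertools import combinations_with_replacement
        grid = np.round(np.arange(1, 21) * 0.05, 10)
        for m in range(1, 5):
            for combo in combinations_with_replacement(grid, m):
                p = np.array(combo)
                np.testing.assert_allclose(bh_adjust(p), bh_stepup_bruteforce(p),
                                           atol=1e-12)

    def test_sampled_grid_lengths_five_to_eight(self):
        rng = np.random.default_rng(2024)
        grid = np.round(np.arange(1, 21) * 0.05, 10)
        for m in range(5, 9):
            for _ in range(2000):
                p = rng.choice(grid, size=m)
                np.testing.assert_allclose(bh_adjust(p), bh_stepup_bruteforce(p),
                                           atol=1e-12)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance_and_range(self, p, rnd):
        p = np.asarray(p)
        adjusted = bh_adjust(p)
        assert np.all((adjusted >= 0) & (adjusted <= 1))
        perm = np.arange(len(p))
        rnd.shuffle(perm)
        np.testing.assert_allclose(bh_adjust(p[perm]), adjusted[perm], atol=1e-12)


class TestFilterDegs:
    def make(self, rows):
        return pd.DataFrame(rows, columns=["log2fc", "fdr"],
                            index=[f"g{i}" for i in range(len(rows))])

    def test_boundary_semantics(self):
        records = self.make([(0.5, 0.049), (0.49, 0.001), (-0.5, 0.05), (-0.6, 0.01)])
        up, down = filter_degs(records)
        assert up == {"g0"}          # |lfc| inclusive, fdr strict
        assert down == {"g3"}        # g2 rejected: fdr not < 0.05

    def test_up_and_down_sets_disjoint(self):
        rng = np.random.default_rng(1)
        records = self.make(list(zip(rng.normal(0, 1, 200), rng.uniform(0, 1, 200))))
        up, down = filter_degs(records)
        assert up.isdisjoint(down)


def test_planted_genes_recovered_at_pilot_settings():
    """DE stage on the simulated truth: sensitivity >= 0.7, empirical FDR <= 0.10."""
    cfg = SimConfig(n_genes=2000, frac_de=0.05, lfc_magnitude=1.5, seed=7)
    counts, lengths, truth = simulate_counts(cfg)
    result = de_analysis(counts, lengths, group_labels(cfg))
    called = set(result.index[result["de_flag"] != "ns"])
    tp = len(called & truth.de_gene_ids)
    assert tp / len(truth.de_gene_ids) >= 0.7
    assert (len(called) - tp) / max(len(called), 1) <= 0.10
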