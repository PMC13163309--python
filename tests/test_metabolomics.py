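"""PLS-DA/VIP against independent oracles, univariate stats, selection, dedup."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from netprio.errors import ValidationError
from netprio.metabolomics import (dedup_features, fit_plsda, fold_change,
                                  metabolomics_analysis, select_metabolites,
                                  univariate_test, vip_scores)
from netprio.synthdata import SimConfig, simulate_metabolite_table


def sklearn_vip_oracle(X_samples, y, n_components):
    """VIP computed from sklearn's independently fitted PLS model."""
    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(X_samples, y)
    W = pls.x_weights_
    T = pls.x_scores_
    q = pls.y_loadings_.ravel()
    ssy = np.array([(q[a] ** 2) * (T[:, a] @ T[:, a]) for a in range(n_components)])
    p = X_samples.shape[1]
    return np.sqrt(p * (W ** 2) @ ssy / ssy.sum())


def toy_data(seed=0, n=8, p=4):
    rng = np.random.default_rng(seed)
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1][:n])
    X = rng.normal(size=(p, n)) + np.outer(rng.uniform(0.5, 2.0, p), y)
    return X, np.array(["a"] * (n // 2) + ["b"] * (n // 2))


class TestFitPlsda:
    def test_single_feature_weight_is_unit(self):
        X, labels = toy_data(p=1)
        model = fit_plsda(X, labels, n_components=1)
        np.testing.assert_allclose(np.abs(model.x_weights), [[1.0]])

    def test_first_weight_matches_covariance_direction(self):
        # noiseless separable 2-feature toy: w1 proportional to X'y
        y = np.array([0.0, 0, 0, 1, 1, 1])
        X = np.vstack([3 * y + 1, -2 * y + 5])  # features x samples, no noise
        X_noise = X + np.array([[1e-9], [2e-9]]) * np.arange(6)  # break exact rank-1
        model = fit_plsda(X_noise, ["a"] * 3 + ["b"] * 3, n_components=1, scale="none")
        xc = (X_noise - X_noise.mean(axis=1, keepdims=True)).T
        w_expected = xc.T @ (y - y.mean())
        w_expected /= np.linalg.norm(w_expected)
        got = model.x_weights[:, 0]
        np.testing.assert_allclose(np.abs(got @ w_expected), 1.0, atol=1e-8)

    def test_deterministic_fit(self):
        X, labels = toy_data(3)
        a = fit_plsda(X, labels, 2)
        b = fit_plsda(X, labels, 2)
        np.testing.assert_array_equal(a.x_weights, b.x_weights)

    def test_too_many_components_rejected(self):
        X, labels = toy_data()
        with pytest.raises(ValidationError, match="n_components"):
            fit_plsda(X, labels, n_components=50)

    def test_constant_feature_dropped_with_warning(self, caplog):
        X, labels = toy_data()
        X[2] = 7.0
        with caplog.at_level("WARNING"):
            model = fit_plsda(X, labels, 1)
        assert model.n_features == 3
        assert "constant" in caplog.text


class TestVip:
    def test_single_feature_vip_is_one(self):
        X, labels = toy_data(p=1)
        model = fit_plsda(X, labels, 1)
        assert vip_scores(model).iloc[0] == pytest.approx(1.0)

    def test_mean_squared_vip_is_one_for_any_fit(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(rng.integers(3, 12), 10))
            labels = ["a"] * 5 + ["b"] * 5
            model = fit_plsda(X, labels, n_components=2)
            vip = vip_scores(model)
            assert (vip ** 2).mean() == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_independent_library_fit(self, seed):
        """VIP from our NIPALS fit equals VIP derived from sklearn's PLS."""
        X, labels = toy_data(seed)
        model = fit_plsda(X, labels, n_components=2)
        vip = vip_scores(model).to_numpy()
        y = (np.asarray(labels) == "b").astype(float)
        expected = sklearn_vip_oracle(X.T, y, 2)
        np.testing.assert_allclose(vip, expected, atol=1e-8)


class TestFoldChange:
    def test_simple_ratio(self):
        X = pd.DataFrame([[2.0, 2, 2, 4, 4, 4]], index=["f"])
        fc = fold_change(X, ["control"] * 3 + ["treated"] * 3)
        assert fc["f"] == pytest.approx(2.0)

    def test_identical_groups_give_unity(self):
        X = np.array([[5.0, 5, 5, 5, 5, 5]])
        assert fold_change(X, ["a"] * 3 + ["b"] * 3)[0] == pytest.approx(1.0)

    def test_recovers_planted_multiplicative_effect(self):
        cfg = SimConfig(seed=8, n_features_metab=300, metab_effect=5.0)
        table, truth = simulate_metabolite_table(cfg)
        X = table.drop(columns=["mz", "rt"])
        fc = fold_change(X, ["control"] * 3 + ["treated"] * 3)
        planted = fc[sorted(truth.discriminant_feature_ids)]
        assert planted.median() == pytest.approx(5.0, rel=0.25)


class TestUnivariate:
    def test_identical_groups_give_p_one(self):
        X = np.array([[4.0, 4, 4, 4, 4, 4]])
        res = univariate_test(X, ["a"] * 3 + ["b"] * 3)
        assert res["p"].iloc[0] == 1.0
        assert bool(res["degenerate"].iloc[0])

    def test_matches_welch_oracle_on_logged_values(self):
        # feed 2^x so the internal log2 recovers the textbook values
        logged = np.array([[1.0, 2, 3, 4, 5, 6]])
        res = univariate_test(2.0 ** logged, ["a"] * 3 + ["b"] * 3)
        _, p_ref = stats.ttest_ind([4, 5, 6], [1, 2, 3], equal_var=False)
        assert res["p"].iloc[0] == pytest.approx(p_ref, abs=1e-10)


class TestSelection:
    def frame(self, vip, p, fdr, fc):
        return pd.DataFrame({"vip": [vip], "p": [p], "fdr": [fdr], "fc": [fc]})

    @pytest.mark.parametrize("vip,p,fdr,fc,kept", [
        (1.6, 0.01, 0.03, 2.5, True),
        (1.5, 0.01, 0.03, 2.5, False),   # VIP threshold strict
        (2.0, 0.01, 0.03, 2.0, False),   # FC threshold strict
        (2.0, 0.05, 0.03, 2.5, False),
        (2.0, 0.01, 0.05, 2.5, False),
    ])
    def test_threshold_boundaries(self, vip, p, fdr, fc, kept):
        out = select_metabolites(self.frame(vip, p, fdr, fc))
        assert (len(out) == 1) is kept

    def test_two_sided_option_admits_depleted_features(self):
        features = self.frame(2.0, 0.01, 0.01, 0.3)
        assert len(select_metabolites(features)) == 0
        assert len(select_metabolites(features, two_sided_fc=True)) == 1

    def test_tightening_any_threshold_never_adds_features(self):
        rng = np.random.default_rng(5)
        features = pd.DataFrame({
            "vip": rng.uniform(0, 4, 200), "p": rng.uniform(0, 0.2, 200),
            "fdr": rng.uniform(0, 0.2, 200), "fc": rng.uniform(0.1, 6, 200)})
        base = set(select_metabolites(features).index)
        assert set(select_metabolites(features, vip_threshold=2.0).index) <= base
        assert set(select_metabolites(features, p_threshold=0.01).index) <= base
        assert set(select_metabolites(features, fdr_threshold=0.01).index) <= base
        assert set(select_metabolites(features, fc_threshold=3.0).index) <= base

    def test_missing_statistic_rejected(self):
        with pytest.raises(ValidationError, match="vip"):
            select_metabolites(pd.DataFrame({"p": [0.01], "fdr": [0.01], "fc": [3.0]}))


class TestDedup:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["mz", "rt", "mean_intensity"],
                            index=[f"f{i}" for i in range(len(rows))])

    def test_identical_ions_keep_the_brighter(self):
        out = dedup_features(self.frame([(500.0, 3.0, 10.0), (500.0, 3.0, 99.0)]))
        assert list(out.index) == ["f1"]

    def test_within_five_ppm_merged(self):
        # (0.0024 / 500) * 1e6 = 4.8 ppm
        out = dedup_features(self.frame([(500.0000, 3.0, 1.0), (500.0024, 3.0, 2.0)]))
        assert len(out) == 1

    def test_fifty_ppm_apart_not_merged(self):
        out = dedup_features(self.frame([(500.000, 3.0, 1.0), (500.025, 3.0, 2.0)]))
        assert len(out) == 2

    def test_retention_time_gate(self):
        out = dedup_features(self.frame([(500.0, 3.0, 1.0), (500.0005, 4.5, 2.0)]))
        assert len(out) == 2


def test_planted_discriminant_features_recovered_at_defaults():
    """Full-stage recovery on the simulated truth: sensitivity >= 0.7."""
    cfg = SimConfig(seed=7)
    table, truth = simulate_metabolite_table(cfg)
    result = metabolomics_analysis(table)
    selected = set(result.index[result["selected"]])
    tp = len(selected & truth.discriminant_feature_ids)
    assert tp / len(truth.discriminant_feature_ids) >= 0.7
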