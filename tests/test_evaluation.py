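import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qsmart.evaluation import (compare_models, evaluate,
                               interaction_analysis, multithreshold_roc,
                               perturb_effect, ppi_edge_impacts, score)
from qsmart.model import (PyramidNetRegressor, QsmartModelSpec, forward,
                          network_spec_from)


class TestScore:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        r2, rmse = score(y, y)
        assert r2 == 1.0 and rmse == 0.0

    def test_mean_predictor_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        r2, _ = score(np.full(4, y.mean()), y)
        assert r2 == pytest.approx(0.0)

    def test_four_point_manual_arithmetic(self):
        pred = np.array([1.0, 2.0, 2.0, 4.0])
        act = np.array([1.0, 1.0, 3.0, 5.0])
        rss = float(np.sum((act - pred) ** 2))   # 0+1+1+1 = 3
        tss = float(np.sum((act - act.mean()) ** 2))
        r2, rmse = score(pred, act)
        assert r2 == pytest.approx(1 - rss / tss)
        assert rmse == pytest.approx(np.sqrt(rss / 4))

    def test_constant_actuals_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            score(np.array([1.0, 2.0]), np.array([3.0, 3.0]))


class TestMultithresholdRoc:
    def test_perfect_ranker_gets_auc_one_everywhere(self, rng):
        actual = rng.uniform(-6, 4, 500)
        aucs, mean_auc, skipped = multithreshold_roc(actual, actual)
        assert skipped == []
        assert all(a == 1.0 for a in aucs.values())
        assert mean_auc == 1.0

    def test_random_predictions_near_half(self, rng):
        actual = rng.uniform(-6, 4, 2000)
        predicted = rng.normal(size=2000)
        _, mean_auc, _ = multithreshold_roc(predicted, actual)
        assert mean_auc == pytest.approx(0.5, abs=0.05)

    def test_degenerate_threshold_skipped(self, rng):
        actual = rng.uniform(0, 5, 100)  # nothing below -4
        _, _, skipped = multithreshold_roc(actual, actual,
                                           thresholds=(-4.0, 2.5))
        assert skipped == [-4.0]

    def test_auc_invariant_to_monotone_score_transform(self, rng):
        actual = rng.uniform(-6, 4, 300)
        pred = actual + rng.normal(0, 1.0, 300)
        a1, m1, _ = multithreshold_roc(pred, actual)
        a2, m2, _ = multithreshold_roc(np.exp(pred / 2), actual)
        assert m1 == pytest.approx(m2, abs=1e-12)

    def test_matches_brute_force_pair_counting(self, rng):
        actual = rng.normal(0, 2, 40)
        pred = actual + rng.normal(0, 1.5, 40)
        t = 0.0
        labels = actual < t
        s = -pred
        pos, neg = s[labels], s[~labels]
        wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
        expected = wins / (len(pos) * len(neg))
        aucs, _, _ = multithreshold_roc(pred, actual, thresholds=(t,))
        assert aucs[t] == pytest.approx(expected)


class TestPerturbEffect:
    def _linear(self):
        return QsmartModelSpec(
            feature_names=["From_Sanger", "GO_A_X_GO_B"], intercept=2.0,
            coefficients={"From_Sanger": -0.65, "GO_A_X_GO_B": 0.45})

    def test_linear_delta_equals_coefficient_exactly(self, rng):
        spec = self._linear()
        data = pd.DataFrame({"From_Sanger": rng.binomial(1, 0.5, 50).astype(float),
                             "GO_A_X_GO_B": rng.poisson(1, 50).astype(float)})
        for f, coef in spec.coefficients.items():
            eff = perturb_effect(spec, f, data)
            assert eff.delta == pytest.approx(coef, rel=1e-15)

    def test_absent_feature_rejected(self):
        with pytest.raises(ValueError, match="not in model"):
            perturb_effect(self._linear(), "nope",
                           pd.DataFrame({"From_Sanger": [1.0],
                                         "GO_A_X_GO_B": [0.0]}))

    def test_network_delta_matches_finite_difference(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(300, 2)), columns=["u", "v"])
        y = np.tanh(X["u"].to_numpy()) + rng.normal(0, 0.05, 300)
        est = PyramidNetRegressor(max_iter=80, cv=3, random_state=8).fit(X, y)
        spec = network_spec_from(est)
        eff = perturb_effect(spec, "u", X, view="network")
        bumped = X.copy()
        bumped["u"] += 1.0
        expected = est.predict(bumped).mean() - est.predict(X).mean()
        assert eff.delta == pytest.approx(expected, rel=1e-10)

    def test_zero_weight_network_has_zero_delta(self):
        spec = QsmartModelSpec(
            feature_names=["u"],
            network={"layers": [([[0.0]], [0.0]), ([[0.0]], [0.7])],
                     "x_mean": [0.0], "x_scale": [1.0],
                     "y_mean": 0.0, "y_scale": 1.0})
        data = pd.DataFrame({"u": [1.0, 2.0]})
        eff = perturb_effect(spec, "u", data, view="network")
        assert eff.delta == 0.0


class TestInteractionAnalysis:
    def test_planted_crossing_interaction_detected(self, rng):
        n = 400
        bit = rng.binomial(1, 0.5, n).astype(float)
        res = rng.choice([0.0, 1.0, 2.0], n)
        y = 0.2 * bit + 0.1 * res - 1.5 * bit * res + rng.normal(0, 0.5, n)
        f, p, cells = interaction_analysis(y, bit, res)
        assert p < 0.01
        # non-parallel: the bit effect differs by residue sign
        by = cells.set_index(["fingerprint_bit", "residue_sign"])
        gap_pos = (by.loc[(1, ">0"), "mean_response"]
                   - by.loc[(0, ">0"), "mean_response"])
        gap_zero = (by.loc[(1, "<=0"), "mean_response"]
                    - by.loc[(0, "<=0"), "mean_response"])
        assert abs(gap_pos - gap_zero) > 0.5

    def test_additive_fixture_parallel_means(self, rng):
        n = 2000
        bit = rng.binomial(1, 0.5, n).astype(float)
        res = rng.choice([0.0, 1.0, 2.0], n)
        y = 1.0 * bit + 0.8 * res + rng.normal(0, 0.3, n)
        f, p, cells = interaction_analysis(y, bit, res)
        by = cells.set_index(["fingerprint_bit", "residue_sign"])
        gap_pos = (by.loc[(1, ">0"), "mean_response"]
                   - by.loc[(0, ">0"), "mean_response"])
        gap_zero = (by.loc[(1, "<=0"), "mean_response"]
                    - by.loc[(0, "<=0"), "mean_response"])
        assert abs(gap_pos - gap_zero) < 0.15

    def test_matches_term_ftest(self, rng):
        from qsmart.interactions import ftest_term
        n = 100
        bit = rng.binomial(1, 0.5, n).astype(float)
        res = rng.normal(size=n)
        y = bit * res + rng.normal(0, 1, n)
        f1, p1, _ = interaction_analysis(y, bit, res)
        f2, p2 = ftest_term(y, bit * res, bit, res)
        assert f1 == f2 and p1 == p2


class TestPpiEdgeImpacts:
    def _model(self, coef):
        return QsmartModelSpec(
            feature_names=["EXP_MAP4K4_X_EXP_TP53"], intercept=2.7,
            coefficients={"EXP_MAP4K4_X_EXP_TP53": coef})

    def test_linear_edge_delta_and_class(self, rng):
        data = pd.DataFrame({"EXP_MAP4K4_X_EXP_TP53":
                             np.exp(rng.normal(0, 0.5, 20))})
        table = ppi_edge_impacts(self._model(-0.089), data)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["gene_a"] == "MAP4K4" and row["gene_b"] == "TP53"
        assert row["delta"] == pytest.approx(-0.089)
        assert row["sign_class"] == "negative"

    def test_zero_coefficient_is_weak(self, rng):
        data = pd.DataFrame({"EXP_MAP4K4_X_EXP_TP53": [1.0, 2.0]})
        table = ppi_edge_impacts(self._model(0.0), data)
        assert "weak" in table["sign_class"].iloc[0]

    def test_row_count_equals_ppi_terms(self, rng):
        spec = QsmartModelSpec(
            feature_names=["EXP_A_X_EXP_B", "EXP_C_X_EXP_D", "From_Sanger"],
            intercept=0.0,
            coefficients={"EXP_A_X_EXP_B": 0.2, "EXP_C_X_EXP_D": -0.01,
                          "From_Sanger": 1.0})
        data = pd.DataFrame({
            "EXP_A_X_EXP_B": rng.uniform(1, 2, 10),
            "EXP_C_X_EXP_D": rng.uniform(1, 2, 10),
            "From_Sanger": rng.binomial(1, 0.5, 10).astype(float)})
        assert len(ppi_edge_impacts(spec, data)) == 2

    def test_no_ppi_terms_rejected(self):
        spec = QsmartModelSpec(feature_names=["x"], intercept=0.0,
                               coefficients={"x": 1.0})
        with pytest.raises(ValueError, match="no PPI"):
            ppi_edge_impacts(spec, pd.DataFrame({"x": [1.0]}))


class TestCompareModels:
    def test_identical_vectors_give_p_one(self):
        a = np.linspace(0.5, 0.9, 10)
        assert compare_models(a, a.copy()) == 1.0

    def test_uniform_improvement_23_pairs(self, rng):
        b = rng.uniform(0.5, 0.9, 23)
        a = b + 0.1
        p = compare_models(a, b)
        assert p < 0.01
        # independent check: exact signed-rank statistic for all-positive
        expected = stats.wilcoxon(a, b, alternative="two-sided").pvalue
        assert p == pytest.approx(expected)

    def test_two_sided_symmetry(self, rng):
        a = rng.uniform(0.5, 0.9, 12)
        b = a + rng.normal(0, 0.05, 12)
        assert compare_models(a, b) == pytest.approx(compare_models(b, a))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            compare_models(np.ones(3), np.zeros(3))


class TestEvaluate:
    def test_report_fields_and_group_breakdown(self, rng):
        actual = rng.uniform(-6, 4, 300)
        pred = actual + rng.normal(0, 0.5, 300)
        groups = np.repeat(["g1", "g2", "g3"], 100)
        rep = evaluate(pred, actual, groups=groups)
        assert 0 <= rep.mean_auc <= 1
        assert rep.rmse >= 0
        assert set(rep.per_group) == {"g1", "g2", "g3"}
        assert sum(v["n"] for v in rep.per_group.values()) == 300
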