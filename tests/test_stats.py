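"""Statistical operations against closed-form, brute-force and library oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tumorvol as tv
from tumorvol.stats import icc_band


def brute_force_auc(scores, labels) -> float:
    """Mann-Whitney AUC by explicit pair enumeration (ties count half)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestCorrelate:
    def test_exact_linearity(self):
        x = np.arange(10.0)
        r, p = tv.correlate(x, 2 * x + 1, "pearson")
        assert r == pytest.approx(1.0)

    def test_monotone_nonlinearity(self):
        x = np.array([-3.0, -1.0, 0.5, 2.0, 4.0])
        rho, _ = tv.correlate(x, x**3, "spearman")
        r, _ = tv.correlate(x, x**3, "pearson")
        assert rho == pytest.approx(1.0)
        assert r < 1.0

    def test_spearman_matches_rank_difference_formula(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = rng.normal(size=12)  # continuous: no ties
        rho, _ = tv.correlate(x, y, "spearman")
        dx = np.argsort(np.argsort(x)) + 1.0
        dy = np.argsort(np.argsort(y)) + 1.0
        n = len(x)
        closed = 1 - 6 * np.sum((dx - dy) ** 2) / (n * (n**2 - 1))
        assert rho == pytest.approx(closed, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(tv.DegenerateStatisticError):
            tv.correlate([1, 1, 1], [1, 2, 3], "pearson")


class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(23), np.zeros(99)]
        fit = tv.fit_logistic(np.empty((122, 0)), y, names=[])
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(np.log(23 / 99), abs=1e-6)

    def test_two_by_two_odds_ratio_is_cross_product(self):
        y = np.r_[np.ones(9), np.zeros(22), np.ones(14), np.zeros(77)]
        x = np.r_[np.zeros(31), np.ones(91)]
        fit = tv.fit_logistic(x[:, None], y, names=["cn_pos"])
        assert 1.0 / fit.odds_ratios[1] == pytest.approx((9 * 77) / (22 * 14), abs=1e-6)

    def test_perfect_separation_flagged(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.copy()
        fit = tv.fit_logistic(x[:, None], y)
        assert not fit.converged
        assert fit.diagnostic
        assert np.isnan(fit.coefficients).all()

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        X = np.column_stack([x, x])
        y = (x + rng.normal(size=30) > 0).astype(float)
        with pytest.raises(tv.ParameterError):
            tv.fit_logistic(X, y)

    def test_or_equals_exp_coef_and_ci_ordered(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 3))
        y = rng.binomial(1, 1 / (1 + np.exp(-(X[:, 0] - 0.5 * X[:, 1]))))
        fit = tv.fit_logistic(X, y)
        assert np.allclose(fit.odds_ratios, np.exp(fit.coefficients))
        assert (fit.ci_lower < fit.ci_upper).all()


class TestVif:
    def test_orthogonal_predictors(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=64)
        b = rng.normal(size=64)
        b -= a * (a @ b) / (a @ a)  # exactly orthogonal, both centered enough
        out = tv.vif(np.column_stack([a, b]))
        assert np.allclose(out["vif"], 1.0, atol=0.05)

    def test_duplicated_predictor_infinite(self):
        x = np.random.default_rng(3).normal(size=40)
        out = tv.vif(np.column_stack([x, x]))
        assert np.isinf(out["vif"]).all()
        assert (out["flag"] == "extreme").all()

    def test_known_correlation_closed_form(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=5000)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.normal(size=5000)
        out = tv.vif(np.column_stack([a, b]), names=["a", "b"])
        r, _ = tv.correlate(a, b, "pearson")
        assert out.loc["a", "vif"] == pytest.approx(1 / (1 - r**2), rel=1e-9)
        assert out.loc["a", "vif"] == pytest.approx(1 / (1 - 0.64), rel=0.1)
        assert out.loc["a", "flag"] == "high"


class TestRoc:
    def test_four_point_example(self):
        assert tv.roc([1, 3, 2, 4], [0, 0, 1, 1], "as_is").auc == pytest.approx(0.75)

    def test_all_ties_half(self):
        assert tv.roc([5, 5, 5, 5], [0, 1, 0, 1], "as_is").auc == pytest.approx(0.5)

    def test_perfect_separation_one(self):
        assert tv.roc([0, 1, 10, 11], [0, 0, 1, 1], "as_is").auc == pytest.approx(1.0)

    def test_auto_orientation_flips_negative_scores(self):
        scores = np.array([10.0, 8.0, 3.0, 1.0])
        labels = np.array([0, 0, 1, 1])
        curve = tv.roc(scores, labels, "auto")
        assert curve.flipped and curve.auc == pytest.approx(1.0)

    def test_one_class_rejected(self):
        with pytest.raises(tv.ParameterError):
            tv.roc([1, 2, 3], [1, 1, 1])

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(10, 120))
    def test_matches_brute_force_pair_counting(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 8, n).astype(float)  # many ties
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0], labels[1] = 0, 1
        auc = tv.roc(scores, labels, "as_is").auc
        assert auc == pytest.approx(brute_force_auc(scores, labels), rel=1e-12)

    def test_reversal_maps_auc_to_complement(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        a = tv.roc(scores, labels, "as_is").auc
        b = tv.roc(-scores, labels, "as_is").auc
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestDeLong:
    def test_score_against_itself(self):
        labels = np.r_[np.ones(10), np.zeros(15)]
        s = np.random.default_rng(7).normal(size=25)
        out = tv.delong_compare(s, s, labels, "as_is")
        assert out.auc_difference == 0.0 and out.p == 1.0

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(8)
        labels = np.r_[np.ones(12), np.zeros(20)]
        a, b = rng.normal(size=32), rng.normal(size=32)
        ab = tv.delong_compare(a, b, labels, "as_is")
        ba = tv.delong_compare(b, a, labels, "as_is")
        assert ab.auc_difference == pytest.approx(-ba.auc_difference)
        assert ab.p == pytest.approx(ba.p)

    def test_variance_positive_and_p_in_unit_interval(self):
        rng = np.random.default_rng(9)
        labels = np.r_[np.ones(20), np.zeros(30)]
        base = np.r_[rng.normal(1, 1, 20), rng.normal(0, 1, 30)]
        a = base + rng.normal(0, 0.5, 50)
        b = base + rng.normal(0, 0.5, 50)
        out = tv.delong_compare(a, b, labels, "as_is")
        assert out.variance > 0 and 0 <= out.p <= 1


class TestIcc:
    def test_identical_readers_perfect_agreement(self):
        rng = np.random.default_rng(10)
        col = rng.normal(size=20)
        value, band = tv.icc(np.column_stack([col, col, col]))
        assert value == pytest.approx(1.0)
        assert band == "excellent"

    def test_band_boundaries(self):
        assert icc_band(0.76) == "excellent"
        assert icc_band(0.60) == "good"
        assert icc_band(0.40) == "fair"
        assert icc_band(0.10) == "poor"

    def test_independent_readers_near_zero(self):
        rng = np.random.default_rng(11)
        value, _ = tv.icc(rng.normal(size=(500, 3)))
        assert abs(value) < 0.1

    def test_matches_pingouin_two_way_random(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(12)
        subject = rng.normal(size=30)
        ratings = np.column_stack(
            [subject + rng.normal(0, 0.4, 30) + off for off in (0.0, 0.3, -0.2)]
        )
        value, _ = tv.icc(ratings)
        long = pd.DataFrame(
            {
                "case": np.repeat(np.arange(30), 3),
                "reader": np.tile(np.arange(3), 30),
                "score": ratings.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(long, targets="case", raters="reader", ratings="score")
        icc2 = ref.loc[ref["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
        assert value == pytest.approx(float(icc2), rel=1e-6)

    def test_constant_matrix_rejected(self):
        with pytest.raises(tv.DegenerateStatisticError):
            tv.icc(np.ones((10, 3)))
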