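"""Logistic risk models, IRLS fitting, ROC/AUC/Youden against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbscreen import (
    auc,
    fit_logistic,
    predict,
    roc_curve,
    select_candidates,
    youden_cutoff,
)
from hbscreen.risk_models import DegenerateInputError, MissingRatioError


def pairs_auc(scores, labels):
    """All-pairs Mann-Whitney proportion, ties counted half (oracle)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_youden(scores, labels):
    """Exhaustive threshold scan with the sensitivity-favoring tie-break (oracle).

    Uses exact rational arithmetic so genuine J ties are recognized as ties.
    """
    from fractions import Fraction

    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    n_pos, n_neg = int(np.sum(y == 1)), int(np.sum(y == 0))
    best = None
    for t in sorted(set(s)) + [np.inf]:
        called = s >= t
        sens = Fraction(int(np.sum(called & (y == 1))), n_pos)
        spec = Fraction(int(np.sum(~called & (y == 0))), n_neg)
        key = (sens + spec - 1, sens, -t)
        if best is None or key > best[0]:
            best = (key, t, float(sens + spec - 1), float(sens), float(spec))
    return best[1:]


class TestPredict:
    def test_printed_alpha_formula_at_zero_ratios(self, p_alpha_model):
        expected = 1.0 / (1.0 + math.exp(-1.771))
        got = predict(p_alpha_model, {"zT8_bT2": 0.0, "aT1_bT1": 0.0})
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.8546, abs=5e-5)

    def test_printed_beta_formula_at_zero_ratios(self, p_beta_model):
        expected = 1.0 / (1.0 + math.exp(13.195))
        got = predict(p_beta_model, {"dT2_bT2": 0.0, "aT3_bT1": 0.0})
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.86e-6, rel=1e-3)

    def test_saturation_without_overflow(self, p_alpha_model, p_beta_model):
        low = predict(p_alpha_model, {"zT8_bT2": 0.0, "aT1_bT1": 1000.0})
        assert 0.0 <= low < 1e-300
        high = predict(p_beta_model, {"dT2_bT2": 1000.0, "aT3_bT1": 0.0})
        assert high == 1.0

    def test_missing_ratio_propagates(self, p_alpha_model):
        with pytest.raises(MissingRatioError):
            predict(p_alpha_model, {"zT8_bT2": 0.0})

    @given(st.floats(min_value=0, max_value=0.2), st.floats(min_value=0.01, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_each_ratio(self, z, delta):
        from hbscreen import default_p_alpha, default_p_beta

        pa, pb = default_p_alpha(), default_p_beta()
        # P(alpha) strictly decreasing in aT1_bT1 (coefficient -1.030)
        assert predict(pa, {"zT8_bT2": z, "aT1_bT1": 1.0}) > predict(
            pa, {"zT8_bT2": z, "aT1_bT1": 1.0 + delta})
        # P(beta) strictly increasing in dT2_bT2 (coefficient +105.132)
        assert predict(pb, {"dT2_bT2": z, "aT3_bT1": 1.0}) < predict(
            pb, {"dT2_bT2": z + delta, "aT3_bT1": 1.0})


class TestFitLogistic:
    def test_intercept_only_symmetric(self):
        X = np.zeros((40, 1))
        y = np.array([0, 1] * 20)
        fit = fit_logistic(X, y)
        assert fit.converged
        assert fit.model.intercept == pytest.approx(0.0, abs=1e-6)

    def test_two_by_two_slope_equals_log_odds_ratio(self):
        # x=1: 30 positive / 10 negative; x=0: 12 positive / 48 negative
        x = [1] * 40 + [0] * 60
        y = [1] * 30 + [0] * 10 + [1] * 12 + [0] * 48
        fit = fit_logistic(np.array(x)[:, None], y, feature_names=["x"])
        log_or = math.log((30 * 48) / (10 * 12))
        assert fit.converged
        assert fit.model.coefficients["x"] == pytest.approx(log_or, rel=1e-6)
        assert fit.model.intercept == pytest.approx(math.log(12 / 48), rel=1e-6)

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 2))
        eta = 0.5 + 1.2 * X[:, 0] - 0.7 * X[:, 1]
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = fit_logistic(X, y, feature_names=["a", "b"])
        ref = statsmodels.Logit(y, statsmodels.add_constant(X)).fit(disp=0)
        assert fit.model.intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.model.coefficients["a"] == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.model.coefficients["b"] == pytest.approx(ref.params[2], abs=1e-6)
        assert fit.standard_errors["a"] == pytest.approx(ref.bse[1], rel=1e-4)

    def test_single_class_degenerate(self):
        with pytest.raises(DegenerateInputError):
            fit_logistic(np.ones((10, 1)), np.ones(10))

    def test_complete_separation_flagged(self):
        X = np.concatenate([np.linspace(0, 1, 20), np.linspace(2, 3, 20)])[:, None]
        y = np.array([0] * 20 + [1] * 20)
        fit = fit_logistic(X, y)
        assert fit.separation_flag

    def test_deterministic(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(80, 2))
        y = (rng.random(80) < 0.5).astype(int)
        f1 = fit_logistic(X, y)
        f2 = fit_logistic(X, y)
        assert f1.model == f2.model


class TestROC:
    def test_toy_set_matches_exhaustive_enumeration(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.8, 0.05]
        labels = [0, 0, 1, 1, 1, 0]
        curve = roc_curve(scores, labels)
        for t, sens, spec in zip(curve.thresholds, curve.sensitivity, curve.specificity):
            called = np.asarray(scores) >= t
            y = np.asarray(labels)
            assert sens == pytest.approx(np.sum(called & (y == 1)) / 3)
            assert spec == pytest.approx(np.sum(~called & (y == 0)) / 3)

    def test_sensitivity_non_increasing_and_endpoints(self):
        rng = np.random.default_rng(5)
        curve = roc_curve(rng.normal(size=50), rng.integers(0, 2, 50))
        assert np.all(np.diff(curve.sensitivity) <= 1e-12)
        assert curve.sensitivity[0] == 1.0   # lowest threshold calls everyone
        assert curve.sensitivity[-1] == 0.0  # +inf threshold calls no one

    def test_perfect_separation_hits_corner(self):
        curve = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert np.any((curve.sensitivity == 1.0) & (curve.specificity == 1.0))

    def test_single_class_degenerate(self):
        with pytest.raises(DegenerateInputError):
            roc_curve([1.0, 2.0], [1, 1])


class TestAUC:
    def test_perfect_and_all_ties(self):
        assert auc(roc_curve([1, 2, 3, 4], [0, 0, 1, 1])) == pytest.approx(1.0)
        assert auc(roc_curve([5, 5, 5, 5], [0, 1, 0, 1])) == pytest.approx(0.5)

    def test_mann_whitney_oracle_toy(self):
        scores = [0.2, 0.9, 0.4, 0.4, 0.6, 0.1, 0.7, 0.3]
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        assert auc(roc_curve(scores, labels)) == pytest.approx(pairs_auc(scores, labels))

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        if y.sum() in (0, 30):
            return
        a1 = auc(roc_curve(s, y))
        a2 = auc(roc_curve(np.exp(2.0 * s) + 5.0, y))
        assert a2 == pytest.approx(a1, abs=1e-12)


class TestSelectCandidates:
    def test_label_equal_ratio_selected_noise_excluded(self):
        rng = np.random.default_rng(17)
        labels = rng.integers(0, 2, 400)
        table = {
            "perfect": labels.astype(float),
            "noise": rng.normal(size=400),
            "inverted": 1.0 - labels.astype(float),  # orientation-corrected
        }
        selected = select_candidates(table, labels)
        assert selected["perfect"] == pytest.approx(1.0)
        assert selected["inverted"] == pytest.approx(1.0)
        assert "noise" not in selected

    def test_empty_result_is_valid(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 200)
        assert select_candidates({"x": rng.normal(size=200)}, labels) == {}


class TestYouden:
    def test_perfect_separation(self):
        cutoff, j, sens, spec = youden_cutoff(roc_curve([1, 2, 8, 9], [0, 0, 1, 1]))
        assert j == pytest.approx(1.0)
        assert sens == spec == 1.0
        assert cutoff == 8.0  # lower of the tied J-maximizing thresholds

    def test_brute_force_oracle_toy(self):
        scores = [0.2, 0.9, 0.4, 0.4, 0.6, 0.1, 0.7, 0.3, 0.55]
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 1]
        got = youden_cutoff(roc_curve(scores, labels))
        expected = brute_force_youden(scores, labels)
        assert got == pytest.approx(expected)

    def test_uninformative_scores_give_small_j(self):
        rng = np.random.default_rng(23)
        s = rng.normal(size=2000)
        y = rng.integers(0, 2, 2000)
        _, j, _, _ = youden_cutoff(roc_curve(s, y))
        assert j < 0.1
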