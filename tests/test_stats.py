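"""Prognostic statistics: DeLong AUC against the pairwise-concordance
oracle, FPR-0 cutoffs against exhaustive scans, exact binomial CIs against
tail inversion, and the logistic screening/selection machinery."""

import math

import numpy as np
import pandas as pd
import pytest

from neuroadc import (
    ConfusionCounts,
    InputError,
    PredictorSeries,
    auc_delong,
    classify_auc_band,
    clopper_pearson,
    combined_model_roc,
    cutoff_at_full_specificity,
    delong_paired_test,
    diagnostic_metrics,
    fit_multivariable_backward,
    univariable_screen,
)
from neuroadc.stats import HIGHER_IS_POOR, LOWER_IS_POOR


def pairwise_auc(pos, neg):
    """O(n^2) concordance oracle: mean of I(pos>neg) + 0.5*I(tie)."""
    pos, neg = np.asarray(pos)[:, None], np.asarray(neg)[None, :]
    return float(np.mean((pos > neg) + 0.5 * (pos == neg)))


def exhaustive_fpr0_scan(x, y):
    """Oracle: scan every threshold position for max TP subject to FP=0,
    calling positive when score > c."""
    candidates = np.concatenate([[-np.inf], np.sort(np.unique(x))])
    best_tp, best_c = -1, None
    for c in candidates:
        fp = np.count_nonzero(x[~y] > c)
        tp = np.count_nonzero(x[y] > c)
        if fp == 0 and tp > best_tp:
            best_tp, best_c = tp, c
    return best_tp, best_c


# ----------------------------------------------------------------- AUC

def test_auc_perfect_separation():
    s = PredictorSeries([1, 2, 3, 10, 11, 12], HIGHER_IS_POOR)
    y = ["good"] * 3 + ["poor"] * 3
    auc, se, ci = auc_delong(s, y)
    assert auc == 1.0 and se == 0.0 and ci == (1.0, 1.0)


def test_auc_all_tied_is_half():
    s = PredictorSeries([5.0] * 8, HIGHER_IS_POOR)
    auc, _, _ = auc_delong(s, ["good"] * 4 + ["poor"] * 4)
    assert auc == pytest.approx(0.5)


@pytest.mark.parametrize("seed", range(10))
def test_auc_matches_pairwise_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 31))
    m = int(rng.integers(6, 31))
    # ~half the instances have heavy ties
    vals = rng.integers(0, 8, n + m) if seed % 2 else rng.normal(size=n + m)
    y = np.array([True] * n + [False] * m)
    auc, _, _ = auc_delong(PredictorSeries(vals, HIGHER_IS_POOR), y)
    assert auc == pytest.approx(pairwise_auc(vals[:n], vals[n:]), abs=1e-12)


def test_auc_orientation_flip(rng):
    vals = rng.normal(size=40)
    y = rng.random(40) < 0.5
    y[0], y[1] = True, False
    a1, _, _ = auc_delong(PredictorSeries(vals, HIGHER_IS_POOR), y)
    a2, _, _ = auc_delong(PredictorSeries(vals, LOWER_IS_POOR), y)
    assert a1 + a2 == pytest.approx(1.0)


def test_auc_single_class_rejected():
    with pytest.raises(InputError):
        auc_delong(PredictorSeries([1, 2, 3], HIGHER_IS_POOR), ["poor"] * 3)


# ------------------------------------------------------------ FPR-0 cutoff

def test_cutoff_midpoint_convention():
    s = PredictorSeries([1, 2, 3, 4, 5, 6], HIGHER_IS_POOR)
    y = ["good"] * 3 + ["poor"] * 3
    res = cutoff_at_full_specificity(s, y)
    assert res.cutoff == pytest.approx(3.5)
    assert res.operator == ">"
    assert (res.confusion.tp, res.confusion.fp, res.confusion.tn, res.confusion.fn) == (3, 0, 3, 0)
    assert not res.degenerate


def test_cutoff_degenerate_when_good_tops_ranking():
    s = PredictorSeries([1, 2, 6, 3, 4, 5], HIGHER_IS_POOR)
    y = ["good"] * 3 + ["poor"] * 3
    res = cutoff_at_full_specificity(s, y)
    assert res.degenerate
    assert res.confusion.tp == 0 and res.confusion.fp == 0
    assert res.confusion.tn == 3 and res.confusion.fn == 3


def test_cutoff_lower_is_poor_orientation():
    # poor patients have LOW values; reported cutoff is '<' on the raw scale
    s = PredictorSeries([700, 720, 800, 810, 820], LOWER_IS_POOR)
    y = ["poor", "poor", "good", "good", "good"]
    res = cutoff_at_full_specificity(s, y)
    assert res.operator == "<"
    assert res.cutoff == pytest.approx(760.0)
    assert res.confusion.tp == 2 and res.confusion.fp == 0


@pytest.mark.parametrize("seed", range(10))
def test_cutoff_matches_exhaustive_scan(seed):
    rng = np.random.default_rng(100 + seed)
    n = 50
    y = np.zeros(n, dtype=bool)
    y[: n // 2] = True
    x = rng.normal(y.astype(float), 1.2)
    if seed % 3 == 0:
        x = np.round(x, 1)  # inject ties
    res = cutoff_at_full_specificity(PredictorSeries(x, HIGHER_IS_POOR), y)
    best_tp, _ = exhaustive_fpr0_scan(x, y)
    assert res.confusion.tp == best_tp
    assert res.confusion.fp == 0
    # applying the reported cutoff reproduces the reported confusion
    assert np.count_nonzero(x[y] > res.cutoff) == res.confusion.tp


def test_cutoff_confusion_totals(tiny_cohort, rng):
    y = rng.random(30) < 0.5
    y[0], y[1] = True, False
    x = rng.normal(size=30)
    res = cutoff_at_full_specificity(PredictorSeries(x, HIGHER_IS_POOR), y)
    assert res.confusion.tp + res.confusion.fn == int(y.sum())
    assert res.confusion.tn + res.confusion.fp == int((~y).sum())


# ------------------------------------------------ diagnostic metrics & CIs

@pytest.mark.parametrize(
    "counts, sens, spec, npv",
    [
        ((38, 0, 57, 36), 51, 100, 61),
        ((23, 0, 57, 51), 31, 100, 53),
        ((12, 0, 57, 62), 16, 100, 48),
    ],
)
def test_diagnostic_metrics_from_confusion_counts(counts, sens, spec, npv):
    m = diagnostic_metrics(ConfusionCounts(*counts))
    assert round(m["sensitivity"].estimate) == sens
    assert round(m["specificity"].estimate) == spec
    assert round(m["npv"].estimate) == npv
    assert m["ppv"].estimate == pytest.approx(100.0)  # FP = 0
    for metric in m.values():
        assert metric.ci_low <= metric.estimate <= metric.ci_high


def test_diagnostic_metrics_zero_denominator_absent():
    m = diagnostic_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
    assert m["sensitivity"] is None and m["ppv"] is None
    assert m["specificity"].estimate == pytest.approx(100.0)


def test_diagnostic_metrics_negative_counts_rejected():
    with pytest.raises(InputError):
        diagnostic_metrics(ConfusionCounts(-1, 0, 5, 5))


def test_clopper_pearson_boundary_cases():
    lo, hi = clopper_pearson(0, 10)
    assert lo == 0.0 and 0 < hi < 1
    lo, hi = clopper_pearson(57, 57)
    assert hi == 1.0
    assert lo == pytest.approx(0.025 ** (1 / 57))


def test_clopper_pearson_matches_binomial_tail_inversion():
    """Oracle: invert the explicitly summed binomial tails by bisection."""
    x, n, alpha = 38, 74, 0.05

    def upper_tail(p):  # P(X >= x)
        return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(x, n + 1))

    def lower_tail(p):  # P(X <= x)
        return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(0, x + 1))

    def bisect(f, target, lo=1e-9, hi=1 - 1e-9):
        for _ in range(60):
            mid = (lo + hi) / 2
            if f(mid) < target:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lo_oracle = bisect(upper_tail, alpha / 2)
    hi_oracle = bisect(lambda p: -lower_tail(p), -alpha / 2)
    lo, hi = clopper_pearson(x, n)
    assert lo == pytest.approx(lo_oracle, abs=1e-6)
    assert hi == pytest.approx(hi_oracle, abs=1e-6)


def test_clopper_pearson_invalid_counts():
    with pytest.raises(InputError):
        clopper_pearson(5, 4)


# ------------------------------------------------------- paired DeLong

def test_delong_identity_gives_p_one(rng):
    x = rng.normal(size=40)
    y = rng.random(40) < 0.5
    y[0], y[1] = True, False
    s = PredictorSeries(x, HIGHER_IS_POOR)
    cmp_ = delong_paired_test(s, PredictorSeries(x.copy(), HIGHER_IS_POOR), y)
    assert cmp_.auc_difference == 0.0 and cmp_.p_value == 1.0


def test_delong_rank_invariance(rng):
    x = rng.normal(size=60)
    y = rng.random(60) < 0.4
    y[0], y[1] = True, False
    a = PredictorSeries(x, HIGHER_IS_POOR)
    b = PredictorSeries(np.exp(2 * x) + 3, HIGHER_IS_POOR)  # strictly monotone
    cmp_ = delong_paired_test(a, b, y)
    assert cmp_.auc_a == pytest.approx(cmp_.auc_b)
    assert cmp_.auc_difference == pytest.approx(0.0)


def test_delong_detects_clear_difference(rng):
    n = 300
    y = np.arange(n) < n // 2
    signal = y.astype(float)
    strong = 1.5 * signal + rng.normal(size=n)
    weak = 0.2 * signal + rng.normal(size=n)
    cmp_ = delong_paired_test(
        PredictorSeries(strong, HIGHER_IS_POOR), PredictorSeries(weak, HIGHER_IS_POOR), y
    )
    assert cmp_.auc_a > cmp_.auc_b
    assert cmp_.p_value < 0.01


# ----------------------------------------------------------- AUC bands

@pytest.mark.parametrize(
    "auc, band",
    [
        (0.69, "poor"), (0.50, "poor"), (0.70, "fair"), (0.79, "fair"),
        (0.80, "good"), (0.83, "good"), (0.89, "good"),
        (0.90, "excellent"), (1.0, "excellent"), (0.40, "below-chance"),
    ],
)
def test_auc_band_classification(auc, band):
    assert classify_auc_band(auc) == band


# ------------------------------------------------- logistic machinery

def _outcome_frame(rng, n=120):
    y = rng.random(n) < 0.5
    y[0], y[1] = True, False
    return y


def test_constant_covariate_flagged_never_selected(rng):
    y = _outcome_frame(rng)
    df = pd.DataFrame({"flat": np.ones(len(y)), "x": rng.normal(size=len(y))})
    selected, flags = univariable_screen(df, y)
    assert flags.get("flat") == "constant"
    assert "flat" not in selected


def test_perfectly_separating_covariate_flagged(rng):
    y = _outcome_frame(rng)
    df = pd.DataFrame({"oracle": y.astype(float)})
    selected, flags = univariable_screen(df, y)
    assert flags.get("oracle") == "separation"
    assert "oracle" not in selected


def test_univariable_screen_type_one_rate(rng):
    """A covariate with true log-OR 0 should pass the P<0.1 screen at
    roughly the nominal 10% rate across simulations."""
    hits = 0
    n_sim = 200
    for _ in range(n_sim):
        y = rng.random(80) < 0.5
        if y.all() or not y.any():
            continue
        df = pd.DataFrame({"noise": rng.normal(size=80)})
        selected, _ = univariable_screen(df, y)
        hits += "noise" in selected
    rate = hits / n_sim
    tol = 3.5 * math.sqrt(0.1 * 0.9 / n_sim)
    assert abs(rate - 0.1) < tol


def test_backward_retains_single_significant_covariate(rng):
    n = 200
    y = rng.random(n) < 0.5
    y[0], y[1] = True, False
    x = y + 0.8 * rng.normal(size=n)
    model = fit_multivariable_backward(pd.DataFrame({"x": x}), y)
    assert model.terms == ["x"]
    assert model.odds_ratios["x"] == pytest.approx(
        math.exp(model.coefficients["x"])
    )
    lo, hi = model.or_ci["x"]
    assert lo < model.odds_ratios["x"] < hi


def test_backward_pure_noise_reaches_intercept_only(rng):
    n = 150
    y = rng.random(n) < 0.5
    y[0], y[1] = True, False
    df = pd.DataFrame({f"n{i}": rng.normal(size=n) for i in range(3)})
    # alpha_out=1e-6 forces every noise term out; must not fail
    model = fit_multivariable_backward(df, y, alpha_out=1e-6)
    assert model.terms == []
    assert len(model.eliminated) == 3
    assert len(model.linear_predictor) == n


def test_backward_recovers_strong_predictors():
    """Two strong predictors (log-OR 1.2) among three noise ones: retained
    in >= 95% of 100 simulated cohorts of n=400."""
    kept = 0
    n_sim = 100
    for seed in range(n_sim):
        rng = np.random.default_rng(7000 + seed)
        n = 400
        X = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(5)})
        eta = -0.2 + 1.2 * X.x0 + 1.2 * X.x1
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        model = fit_multivariable_backward(X, y)
        kept += {"x0", "x1"} <= set(model.terms)
    assert kept >= 95


def test_backward_is_deterministic(rng):
    n = 200
    y = rng.random(n) < 0.5
    y[0], y[1] = True, False
    df = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(4)})
    df["x0"] += y
    m1 = fit_multivariable_backward(df, y)
    m2 = fit_multivariable_backward(df.copy(), y)
    assert m1.terms == m2.terms and m1.eliminated == m2.eliminated
    np.testing.assert_array_equal(m1.linear_predictor, m2.linear_predictor)


def test_combined_model_single_covariate_auc_matches_raw(rng):
    n = 150
    y = rng.random(n) < 0.5
    y[0], y[1] = True, False
    x = y + rng.normal(size=n)
    model = fit_multivariable_backward(pd.DataFrame({"x": x}), y)
    roc = combined_model_roc(model, y)
    raw_auc, _, _ = auc_delong(PredictorSeries(x, HIGHER_IS_POOR), y)
    # linear predictor is a monotone transform of x
    assert roc.auc == pytest.approx(raw_auc)


def test_intercept_only_model_auc_half(rng):
    n = 60
    y = rng.random(n) < 0.5
    y[0], y[1] = True, False
    df = pd.DataFrame({"noise": rng.normal(size=n)})
    model = fit_multivariable_backward(df, y, alpha_out=1e-9)
    roc = combined_model_roc(model, y)
    assert roc.auc == pytest.approx(0.5)
    assert roc.cutoff.degenerate
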