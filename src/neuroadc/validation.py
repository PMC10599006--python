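"""Simulation-based validation drivers.

The study-scale quantities that depend on patient-level data (AUCs,
cutoff values, odds ratios) cannot be reproduced without that data, so the
statistical machinery is validated by construction instead: oracle
equivalence on random instances, bootstrap cross-checks of the paired AUC
test, calibration recovery on the synthetic cohort, and empirical coverage
of the exact binomial intervals.  These drivers are shared by the test
suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import norm, rankdata

from .adc import compute_metrics
from .cohort import CohortConfig, generate_cohort, covariate_table
from .stats import (
    HIGHER_IS_POOR,
    PredictorSeries,
    auc_delong,
    delong_paired_test,
)


def _auc_rows(scores: np.ndarray, m: int) -> np.ndarray:
    """Row-wise Mann-Whitney AUC for a (B, m+n) score matrix whose first m
    columns are cases; average ranks make ties count 1/2."""
    n = scores.shape[1] - m
    ranks = rankdata(scores, axis=1)
    return (ranks[:, :m].sum(axis=1) - m * (m + 1) / 2) / (m * n)


def stratified_bootstrap_auc_test(
    a: np.ndarray,
    b: np.ndarray,
    y: np.ndarray,
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
    level: float = 0.95,
) -> tuple[bool, tuple[float, float]]:
    """Percentile-bootstrap test of AUC(a) - AUC(b) = 0 with resampling
    stratified by outcome.  Returns (reject, CI of the difference)."""
    rng = rng or np.random.default_rng()
    y = np.asarray(y, dtype=bool)
    pos, neg = np.flatnonzero(y), np.flatnonzero(~y)
    m, n = len(pos), len(neg)
    pos_idx = pos[rng.integers(m, size=(n_boot, m))]
    neg_idx = neg[rng.integers(n, size=(n_boot, n))]
    idx = np.concatenate([pos_idx, neg_idx], axis=1)
    diffs = _auc_rows(a[idx], m) - _auc_rows(b[idx], m)
    # z-test with the bootstrap SE: same statistic and reference law as
    # the analytic test, variance estimated by resampling instead
    full = np.concatenate([a[np.concatenate([pos, neg])][None, :],
                           b[np.concatenate([pos, neg])][None, :]])
    observed = float(_auc_rows(full[:1], m)[0] - _auc_rows(full[1:], m)[0])
    se = float(diffs.std(ddof=1))
    alpha = 1.0 - level
    crit = norm.ppf(1 - alpha / 2)
    lo, hi = observed - crit * se, observed + crit * se
    return bool(lo > 0 or hi < 0), (float(lo), float(hi))


def simulate_paired_scores(
    seed: int, n: int = 500, alternative: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two correlated predictor scores on the same patients.

    Both scores share a patient-level latent severity plus independent
    measurement noise; under the null both carry the same outcome signal
    (equal true AUCs), under the alternative score b carries none beyond
    the shared latent, giving a genuine AUC gap at n=500.
    """
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=bool)
    y[: n // 2] = True
    latent = rng.normal(size=n)
    shift = y.astype(float)
    a = latent + 1.0 * shift + 0.8 * rng.normal(size=n)
    b_shift = 1.0 if not alternative else 0.35
    b = latent + b_shift * shift + 0.8 * rng.normal(size=n)
    return a, b, y


def delong_vs_bootstrap_agreement(
    seeds, n: int = 500, n_boot: int = 2000, alpha: float = 0.05
) -> dict:
    """Accept/reject agreement between the paired DeLong test and the
    stratified-bootstrap test over a seed grid; half the seeds are null
    designs, half alternatives."""
    seeds = list(seeds)
    agree, decisions = 0, []
    for i, seed in enumerate(seeds):
        alternative = i >= len(seeds) // 2
        a, b, y = simulate_paired_scores(seed, n=n, alternative=alternative)
        cmp_ = delong_paired_test(
            PredictorSeries(a, HIGHER_IS_POOR, "a"),
            PredictorSeries(b, HIGHER_IS_POOR, "b"),
            y,
        )
        delong_reject = cmp_.p_value < alpha
        boot_reject, _ = stratified_bootstrap_auc_test(
            a, b, y, n_boot=n_boot, rng=np.random.default_rng(seed + 1_000_003)
        )
        agree += delong_reject == boot_reject
        decisions.append(
            {"seed": seed, "alternative": alternative,
             "delong_p": cmp_.p_value, "delong_reject": delong_reject,
             "bootstrap_reject": boot_reject}
        )
    return {"n_seeds": len(seeds), "n_agree": agree,
            "agreement": agree / len(seeds), "decisions": decisions}


def clopper_pearson_coverage(
    ns=(10, 50, 100), ps=(0.1, 0.5, 0.9), reps: int = 2000,
    level: float = 0.95, seed: int = 0,
) -> dict:
    """Empirical coverage of the exact two-sided binomial interval on an
    (n, p) grid.  Exact intervals are conservative, so every cell should
    cover at least the nominal level up to Monte-Carlo error."""
    rng = np.random.default_rng(seed)
    alpha = 1.0 - level
    cells = {}
    for n in ns:
        for p in ps:
            x = rng.binomial(n, p, size=reps)
            lo = np.where(x == 0, 0.0, beta_dist.ppf(alpha / 2, x, n - x + 1))
            hi = np.where(x == n, 1.0, beta_dist.ppf(1 - alpha / 2, x + 1, n - x))
            cells[(n, p)] = float(np.mean((lo <= p) & (p <= hi)))
    return {"cells": cells, "min_coverage": min(cells.values())}


def cohort_recovery(
    n_patients: int = 200,
    seed: int | None = None,
    volume_shape: tuple[int, int, int] = (32, 32, 24),
) -> dict:
    """Default-calibration recovery run on a synthetic cohort.

    Computes per-patient imaging metrics, group medians of mean
    whole-brain ADC, per-patient monotonicity of the threshold sweep, the
    single-predictor AUCs for PLR absence / NSE / mean ADC, and the AUC of
    their combined logistic model.
    """
    from .stats import LOWER_IS_POOR, combined_model_roc, fit_multivariable_backward

    kwargs = dict(n_patients=n_patients, volume_shape=volume_shape)
    if seed is not None:
        kwargs["seed"] = seed
    config = CohortConfig(**kwargs)
    cohort = generate_cohort(config)
    table = covariate_table(cohort)
    metrics = [compute_metrics(p.volume) for p in cohort]
    table["mean_whole_brain_adc"] = [m.mean_whole_brain_adc for m in metrics]
    monotone = all(
        np.all(np.diff(list(m.percent_below.values())) >= -1e-12) for m in metrics
    )
    med = table.groupby("outcome")["mean_whole_brain_adc"].median()
    y = table["outcome"].to_numpy()
    aucs = {
        "plr_absent": auc_delong(
            PredictorSeries(1 - table["plr_present"], HIGHER_IS_POOR, "plr_absent"), y
        )[0],
        "nse_ng_ml": auc_delong(
            PredictorSeries(table["nse_ng_ml"], HIGHER_IS_POOR, "nse"), y
        )[0],
        "mean_whole_brain_adc": auc_delong(
            PredictorSeries(table["mean_whole_brain_adc"], LOWER_IS_POOR, "adc"), y
        )[0],
    }
    X = pd.DataFrame(
        {
            "plr_absent": 1 - table["plr_present"],
            "nse_ng_ml": table["nse_ng_ml"],
            "mean_whole_brain_adc": table["mean_whole_brain_adc"],
        }
    )
    model = fit_multivariable_backward(X, y, alpha_out=0.05)
    combined_auc = combined_model_roc(model, y).auc
    return {
        "config": config,
        "n_good": int((table["outcome"] == "good").sum()),
        "n_poor": int((table["outcome"] == "poor").sum()),
        "median_good": float(med["good"]),
        "median_poor": float(med["poor"]),
        "sweep_monotone": bool(monotone),
        "single_aucs": aucs,
        "combined_terms": model.terms,
        "combined_auc": float(combined_auc),
    }
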