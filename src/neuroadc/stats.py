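"""Prognostic statistics for dichotomised neurological outcome.

Implements the ROC machinery used to score predictors of poor outcome
(CPC 3-5) against good outcome (CPC 1-2):

* AUC with the DeLong placement-value variance and a normal-approximation
  confidence interval;
* the FPR-0 operating point: the cutoff achieving 100% specificity on the
  data while maximising sensitivity;
* diagnostic metrics (sensitivity, specificity, PPV, NPV) with exact
  two-sided Clopper-Pearson confidence intervals;
* the paired DeLong test comparing two correlated AUCs;
* univariable screening (Wald p < 0.1 by default) followed by
  backward-elimination multivariable logistic regression, whose per-patient
  linear predictor is itself scored by ROC as a combined model.

Conventions: predictors carry an explicit direction ('higher-is-poor' or
'lower-is-poor'); internally every series is oriented so larger values
indicate poor outcome.  AUC ties count 1/2.  Cutoffs are placed at the
midpoint between adjacent distinct observed values and reported with the
orientation symbol ('>' for higher-is-poor, '<' for lower-is-poor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import beta as beta_dist
from scipy.stats import norm, rankdata

from .adc import InputError

HIGHER_IS_POOR = "higher-is-poor"
LOWER_IS_POOR = "lower-is-poor"

AUC_BANDS = (
    (0.90, "excellent"),
    (0.80, "good"),
    (0.70, "fair"),
    (0.50, "poor"),
)


class SeparationError(RuntimeError):
    """Raised when a logistic fit is degenerate due to perfect separation."""


class DegeneracyError(RuntimeError):
    """Raised on a numerically degenerate variance in the paired AUC test."""


@dataclass
class PredictorSeries:
    """One candidate predictor: a value per patient plus its orientation."""

    values: np.ndarray
    direction: str = HIGHER_IS_POOR
    name: str = "predictor"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise InputError(f"predictor {self.name!r} contains non-finite values")
        if self.direction not in (HIGHER_IS_POOR, LOWER_IS_POOR):
            raise InputError(f"unknown direction {self.direction!r}")

    def oriented(self) -> np.ndarray:
        """Values oriented so larger = more likely poor outcome."""
        return self.values if self.direction == HIGHER_IS_POOR else -self.values


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_poor(self) -> int:
        return self.tp + self.fn

    @property
    def n_good(self) -> int:
        return self.tn + self.fp


@dataclass
class MetricWithCI:
    """A percentage in [0, 100] with its exact two-sided 95% CI."""

    estimate: float
    ci_low: float
    ci_high: float


@dataclass
class CutoffResult:
    cutoff: float
    operator: str  # '>' (higher-is-poor) or '<' (lower-is-poor)
    confusion: ConfusionCounts
    degenerate: bool = False  # True when no FPR-0 cutoff yields TP > 0

    @property
    def label(self) -> str:
        return f"{self.operator}{self.cutoff:g}"


@dataclass
class ROCAnalysis:
    """One report row: AUC (DeLong), FPR-0 cutoff, confusion counts and
    diagnostic metrics with exact CIs."""

    name: str
    auc: float
    auc_se: float
    auc_ci: tuple[float, float]
    cutoff: CutoffResult
    metrics: dict[str, MetricWithCI | None]
    band: str = ""


@dataclass
class DeLongComparison:
    auc_a: float
    auc_b: float
    auc_difference: float
    z_statistic: float
    p_value: float


@dataclass
class LogisticModel:
    """A fitted (possibly backward-selected) logistic model for poor outcome."""

    terms: list[str]
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    odds_ratios: dict[str, float]
    or_ci: dict[str, tuple[float, float]]
    linear_predictor: np.ndarray
    eliminated: list[str] = field(default_factory=list)


# --------------------------------------------------------------------- AUC


def _validate_outcomes(outcomes) -> np.ndarray:
    """Outcome labels -> boolean array (True = poor). Accepts 'good'/'poor'
    strings or 0/1 indicators."""
    arr = np.asarray(outcomes)
    if arr.dtype.kind in "UOS":
        y = np.asarray([str(v).lower() == "poor" for v in arr])
    else:
        y = arr.astype(float).astype(bool)
    if y.sum() == 0 or (~y).sum() == 0:
        raise InputError("both outcome groups must be non-empty")
    return y


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values.

    V10[i] is the fraction of controls that case i outranks (ties 1/2);
    V01[j] the fraction of cases that outrank control j, subtracted from 1.
    mean(V10) == mean(V01) == AUC.
    """
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    v10 = (all_ranks[:m] - rankdata(pos)) / n
    v01 = 1.0 - (all_ranks[m:] - rankdata(neg)) / m
    return v10, v01


def auc_delong(series: PredictorSeries, outcomes) -> tuple[float, float, tuple[float, float]]:
    """AUC as the Mann-Whitney concordance probability, with the DeLong
    standard error and a 1.96-SE normal CI truncated to [0, 1]."""
    y = _validate_outcomes(outcomes)
    x = series.oriented()
    if len(x) != len(y):
        raise InputError("series length must match outcome vector")
    v10, v01 = _placements(x[y], x[~y])
    auc = float(v10.mean())
    m, n = len(v10), len(v01)
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    return auc, se, ci


def delong_paired_test(
    series_a: PredictorSeries, series_b: PredictorSeries, outcomes
) -> DeLongComparison:
    """Paired z-test on the difference of two correlated AUCs measured on
    the same patients, using the DeLong covariance of placement values."""
    y = _validate_outcomes(outcomes)
    xa, xb = series_a.oriented(), series_b.oriented()
    if len(xa) != len(y) or len(xb) != len(y):
        raise InputError("both series must be measured on the same patients")
    v10a, v01a = _placements(xa[y], xa[~y])
    v10b, v01b = _placements(xb[y], xb[~y])
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    diff = auc_a - auc_b
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    s = s10 / m + s01 / n
    var_diff = float(s[0, 0] + s[1, 1] - 2.0 * s[0, 1])
    if var_diff <= 0:
        if abs(diff) < 1e-12:
            return DeLongComparison(auc_a, auc_b, 0.0, 0.0, 1.0)
        raise DegeneracyError(
            "zero variance of the AUC difference with a non-zero difference"
        )
    z = diff / math.sqrt(var_diff)
    p = float(2.0 * norm.sf(abs(z)))
    return DeLongComparison(auc_a, auc_b, diff, z, max(p, np.finfo(float).tiny))


# ------------------------------------------------------------ FPR-0 cutoff


def cutoff_at_full_specificity(series: PredictorSeries, outcomes) -> CutoffResult:
    """The operating point with zero false positives and maximal sensitivity.

    A patient is called positive (poor) when the oriented score strictly
    exceeds the internal threshold.  FP = 0 forces the threshold to at
    least the largest good-outcome score; sensitivity is then maximal at
    exactly that value, and the reported cutoff is the midpoint between it
    and the next distinct observed value above (the least extreme
    FPR-0 cutoff).  If no observed value exceeds the good-group maximum the
    result is degenerate: sensitivity 0, flagged, not an error.
    """
    y = _validate_outcomes(outcomes)
    x = series.oriented()
    if len(x) != len(y):
        raise InputError("series length must match outcome vector")
    pos, neg = x[y], x[~y]
    max_good = neg.max()
    tp = int(np.count_nonzero(pos > max_good))
    above = x[x > max_good]
    if tp == 0:
        internal = float(x.max())
        degenerate = True
    else:
        internal = float((max_good + above.min()) / 2.0)
        degenerate = False
    confusion = ConfusionCounts(
        tp=tp,
        fp=int(np.count_nonzero(neg > internal)),
        tn=int(np.count_nonzero(neg <= internal)),
        fn=int(np.count_nonzero(pos <= internal)),
    )
    if series.direction == HIGHER_IS_POOR:
        return CutoffResult(internal, ">", confusion, degenerate)
    return CutoffResult(-internal, "<", confusion, degenerate)


# --------------------------------------------------- exact binomial CIs


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided binomial confidence interval, as
    beta-distribution quantiles.  Lower bound 0 at x=0; upper bound 1 at
    x=n."""
    if trials <= 0 or not 0 <= successes <= trials:
        raise InputError(f"invalid counts: {successes}/{trials}")
    if not 0.0 < level < 1.0:
        raise InputError(f"level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(beta_dist.ppf(alpha / 2, successes, trials - successes + 1))
    hi = 1.0 if successes == trials else float(
        beta_dist.ppf(1 - alpha / 2, successes + 1, trials - successes)
    )
    return lo, hi


def _metric(successes: int, trials: int, level: float) -> MetricWithCI | None:
    if trials == 0:
        return None
    lo, hi = clopper_pearson(successes, trials, level)
    return MetricWithCI(100.0 * successes / trials, 100.0 * lo, 100.0 * hi)


def diagnostic_metrics(
    confusion: ConfusionCounts, level: float = 0.95
) -> dict[str, MetricWithCI | None]:
    """Sensitivity, specificity, PPV and NPV (percent) with exact two-sided
    Clopper-Pearson CIs.  A metric whose denominator is zero is reported as
    absent (None), not as 0."""
    c = confusion
    if min(c.tp, c.fp, c.tn, c.fn) < 0:
        raise InputError("confusion counts must be non-negative")
    return {
        "sensitivity": _metric(c.tp, c.tp + c.fn, level),
        "specificity": _metric(c.tn, c.tn + c.fp, level),
        "ppv": _metric(c.tp, c.tp + c.fp, level),
        "npv": _metric(c.tn, c.tn + c.fn, level),
    }


def classify_auc_band(auc: float) -> str:
    """Discriminative-performance band: poor 0.50-0.69, fair 0.70-0.79,
    good 0.80-0.89, excellent 0.90-1.00; below 0.50 is 'below-chance'."""
    if not 0.0 <= auc <= 1.0:
        raise InputError(f"AUC must be in [0, 1], got {auc}")
    if auc < 0.50:
        return "below-chance"
    for edge, label in AUC_BANDS:
        if auc >= edge:
            return label
    return "poor"


def analyze_predictor(series: PredictorSeries, outcomes, level: float = 0.95) -> ROCAnalysis:
    """Full single-predictor report row: DeLong AUC + FPR-0 cutoff +
    diagnostic metrics with exact CIs."""
    auc, se, ci = auc_delong(series, outcomes)
    cut = cutoff_at_full_specificity(series, outcomes)
    return ROCAnalysis(
        name=series.name,
        auc=auc,
        auc_se=se,
        auc_ci=ci,
        cutoff=cut,
        metrics=diagnostic_metrics(cut.confusion, level),
        band=classify_auc_band(auc),
    )


# --------------------------------------------------- logistic modelling


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    model = sm.Logit(y.astype(float), X)
    try:
        with np.errstate(all="ignore"):
            res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError et al.
        raise SeparationError(str(exc)) from exc
    if not res.mle_retvals.get("converged", True):
        raise SeparationError("logistic fit did not converge")
    # huge slope coefficients / non-finite SEs are the practical signature
    # of separation (the intercept is excluded: covariates far from zero,
    # e.g. ADC in raw units, legitimately produce large intercepts)
    slopes = res.params.drop("const", errors="ignore")
    if np.any(np.abs(slopes.values) > 50) or np.any(~np.isfinite(res.bse.values)):
        raise SeparationError("degenerate logistic fit (quasi-separation)")
    return res


def univariable_screen(
    covariates: pd.DataFrame, outcomes, alpha_in: float = 0.1
) -> tuple[list[str], dict[str, str]]:
    """Screen candidate predictors with single-covariate logistic fits.

    Returns the names with Wald p < ``alpha_in`` plus a flag map for
    variables that could not be screened honestly: 'constant' (zero
    information) or 'separation' (perfect/quasi-separation — no finite
    Wald p exists, so the variable is flagged rather than ranked).
    """
    y = _validate_outcomes(outcomes).astype(float)
    selected: list[str] = []
    flags: dict[str, str] = {}
    for name in covariates.columns:
        x = covariates[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise InputError(f"covariate {name!r} contains non-finite values")
        if np.ptp(x) == 0:
            flags[name] = "constant"
            continue
        X = sm.add_constant(pd.DataFrame({name: x}))
        try:
            res = _fit_logit(y, X)
        except SeparationError:
            flags[name] = "separation"
            continue
        if float(res.pvalues[name]) < alpha_in:
            selected.append(name)
    return selected, flags


def fit_multivariable_backward(
    covariates: pd.DataFrame, outcomes, alpha_out: float = 0.05
) -> LogisticModel:
    """Backward-elimination multivariable logistic regression.

    Starting from all candidate covariates, iteratively drops the term with
    the largest Wald p >= ``alpha_out`` and refits, until every remaining
    term is significant at ``alpha_out`` (the intercept is never dropped).
    An all-noise candidate set legitimately ends intercept-only.  Ties in p
    are broken by column order (first listed dropped), so the procedure is
    deterministic.
    """
    y = _validate_outcomes(outcomes).astype(float)
    if len(covariates) != len(y):
        raise InputError("covariate rows must match outcome vector")
    if len(y) <= covariates.shape[1]:
        raise InputError("need more patients than candidate covariates")
    terms = list(covariates.columns)
    eliminated: list[str] = []
    while True:
        X = sm.add_constant(covariates[terms], has_constant="add")
        res = _fit_logit(y, X)
        if terms:
            pvals = res.pvalues[terms]
            worst = pvals.idxmax()
            if float(pvals[worst]) >= alpha_out:
                terms.remove(worst)
                eliminated.append(worst)
                continue
        break
    params = res.params
    bse = res.bse
    ci = res.conf_int()
    return LogisticModel(
        terms=terms,
        coefficients={k: float(params[k]) for k in params.index},
        standard_errors={k: float(bse[k]) for k in bse.index},
        p_values={k: float(res.pvalues[k]) for k in params.index},
        odds_ratios={k: float(np.exp(params[k])) for k in terms},
        or_ci={k: (float(np.exp(ci.loc[k, 0])), float(np.exp(ci.loc[k, 1]))) for k in terms},
        linear_predictor=np.asarray(res.fittedvalues, dtype=float),
        eliminated=eliminated,
    )


def combined_model_roc(model: LogisticModel, outcomes, name: str = "combined") -> ROCAnalysis:
    """Score a fitted model's per-patient linear predictor as a
    higher-is-poor predictor series (AUC, FPR-0 cutoff, metrics)."""
    series = PredictorSeries(model.linear_predictor, HIGHER_IS_POOR, name)
    return analyze_predictor(series, outcomes)
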