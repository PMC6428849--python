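"""Diagnostic performance evaluation and study-design calculations.

Classification at the score >= 0 rule yields a confusion table from which
sensitivity, specificity, PPV, NPV and accuracy are computed with Wilson
score 95% intervals (Clopper-Pearson available).  Threshold-free
separation is the Mann-Whitney AUC with a DeLong interval.  Odds ratios
for index positivity, optionally age- and sex-adjusted, come from logistic
regression.  The two-sample normal-approximation formula gives the
per-group sample size for a target effect, SD, alpha and power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PerformanceReport",
    "PowerSpec",
    "EvaluationError",
    "SeparationError",
    "evaluate",
    "auc",
    "adjusted_odds_ratio",
    "required_sample_size",
]


class EvaluationError(ValueError):
    pass


class SeparationError(RuntimeError):
    """Logistic regression failed to converge (complete separation)."""


@dataclass(frozen=True)
class PowerSpec:
    """Two-sample design assumptions: minimum detectable log2 difference,
    representative SD, two-sided alpha, and power."""

    effect: float = 0.5
    sd: float = 1.0
    alpha: float = 0.05
    power: float = 0.85

    def __post_init__(self) -> None:
        if not self.effect > 0:
            raise EvaluationError("effect must be > 0")
        if not self.sd > 0:
            raise EvaluationError("sd must be > 0")
        if not 0 < self.alpha < 1:
            raise EvaluationError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise EvaluationError("power must be in (0, 1)")


@dataclass
class PerformanceReport:
    """Confusion counts and diagnostic metrics, each with a 95% CI."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    auc: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]
    accuracy_ci: tuple[float, float]
    auc_ci: tuple[float, float]
    ci_method: str = "wilson"
    auc_ci_method: str = "delong"

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity, "specificity_ci": list(self.specificity_ci),
            "ppv": self.ppv, "ppv_ci": list(self.ppv_ci),
            "npv": self.npv, "npv_ci": list(self.npv_ci),
            "accuracy": self.accuracy, "accuracy_ci": list(self.accuracy_ci),
            "auc": self.auc, "auc_ci": list(self.auc_ci),
            "ci_method": self.ci_method, "auc_ci_method": self.auc_ci_method,
        }


def _proportion_ci(k: int, n: int, method: str) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    sm_method = {"wilson": "wilson", "clopper-pearson": "beta"}[method]
    lo, hi = proportion_confint(k, n, alpha=0.05, method=sm_method)
    return (float(lo), float(hi))


def auc(scores, labels) -> tuple[float, tuple[float, float]]:
    """Mann-Whitney AUC (ties get half credit) with a DeLong 95% CI."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise EvaluationError("both classes must be present to compute AUC")
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    tz = stats.rankdata(np.concatenate([pos, neg]))
    value = float(tz[:m].sum() / (m * n) - (m + 1) / (2 * n))
    # DeLong structural components
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    half = 1.959963984540054 * math.sqrt(var)
    ci = (max(0.0, value - half), min(1.0, value + half))
    return value, ci


def evaluate(scores, labels, ci_method: str = "wilson") -> PerformanceReport:
    """Diagnostic performance at the score >= 0 rule.

    ``labels`` codes the positive (sarcoma) class as 1.  Proportion CIs use
    the Wilson score interval by default (``ci_method="clopper-pearson"``
    for the exact interval); the AUC interval is DeLong's.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(s) != len(y):
        raise EvaluationError("scores and labels differ in length")
    if len(np.unique(y)) < 2:
        raise EvaluationError("both label classes must be present")
    positive = s >= 0
    tp = int(np.sum(positive & (y == 1)))
    fp = int(np.sum(positive & (y == 0)))
    tn = int(np.sum(~positive & (y == 0)))
    fn = int(np.sum(~positive & (y == 1)))

    def ratio(k: int, n: int) -> float:
        return k / n if n else float("nan")

    auc_value, auc_ci = auc(s, y)
    return PerformanceReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        accuracy=(tp + tn) / len(y),
        auc=auc_value,
        sensitivity_ci=_proportion_ci(tp, tp + fn, ci_method),
        specificity_ci=_proportion_ci(tn, tn + fp, ci_method),
        ppv_ci=_proportion_ci(tp, tp + fp, ci_method),
        npv_ci=_proportion_ci(tn, tn + fn, ci_method),
        accuracy_ci=_proportion_ci(tp + tn, len(y), ci_method),
        auc_ci=auc_ci,
        ci_method=ci_method,
    )


def adjusted_odds_ratio(positive, labels, age=None, sex=None) -> dict:
    """Odds ratio of disease for index positivity by logistic regression.

    Returns ``{"univariate": (OR, (lo, hi))}`` and, when age/sex are given,
    an ``"adjusted"`` entry from the model with both covariates (sex coded
    M=1).  Wald 95% intervals.  Complete separation raises
    :class:`SeparationError`.
    """
    import statsmodels.api as sm

    pos = np.asarray(positive, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise EvaluationError("both outcome classes must be present")

    def fit(Xcols: list[np.ndarray]) -> tuple[float, tuple[float, float]]:
        X = sm.add_constant(np.column_stack(Xcols))
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=50)
        except Exception as exc:  # PerfectSeparationError and numerical failures
            raise SeparationError(f"logistic fit failed: {exc}") from exc
        coefs = np.asarray(res.params, dtype=float)
        if not res.mle_retvals.get("converged", True) or np.max(np.abs(coefs)) > 20:
            raise SeparationError("logistic regression did not converge (separation suspected)")
        beta = coefs[1]
        se = float(np.asarray(res.bse)[1])
        half = 1.959963984540054 * se
        return math.exp(beta), (math.exp(beta - half), math.exp(beta + half))

    out = {"univariate": fit([pos])}
    if age is not None and sex is not None:
        age_arr = np.asarray(age, dtype=float)
        sex_arr = np.asarray([1.0 if s == "M" else 0.0 for s in sex])
        out["adjusted"] = fit([pos, age_arr, sex_arr])
    return out


def required_sample_size(spec: PowerSpec = PowerSpec(), method: str = "normal") -> int:
    """Participants required per group for a two-sample comparison.

    ``method="normal"`` uses n = ceil(2 (z_{1−α/2} + z_{power})² (sd/effect)²);
    ``method="t"`` iterates the same formula with t quantiles at 2n−2
    degrees of freedom (one unit more conservative for the default design).
    """
    z_alpha = stats.norm.ppf(1 - spec.alpha / 2)
    z_beta = stats.norm.ppf(spec.power)
    ratio2 = (spec.sd / spec.effect) ** 2
    n = math.ceil(2 * (z_alpha + z_beta) ** 2 * ratio2)
    if method == "normal":
        return n
    if method != "t":
        raise EvaluationError("method must be 'normal' or 't'")
    for _ in range(100):
        df = max(2 * n - 2, 1)
        t_alpha = stats.t.ppf(1 - spec.alpha / 2, df)
        t_beta = stats.t.ppf(spec.power, df)
        n_new = math.ceil(2 * (t_alpha + t_beta) ** 2 * ratio2)
        if n_new == n:
            return n
        n = n_new
    return n
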