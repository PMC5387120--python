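"""Publication-bias diagnostics: Egger regression, Begg rank correlation, funnel data.

Egger's test regresses the standardized effect (log OR / SE) on precision
(1 / SE) by unweighted ordinary least squares; a non-zero intercept signals
funnel-plot asymmetry and the test is a two-sided t test on the intercept
with n - 2 residual degrees of freedom.

Begg's test is the Kendall rank correlation between the variance-stabilized
standardized deviates of the effects and their variances, using the normal
approximation z = S / sqrt(n(n-1)(2n+5)/18) without a continuity correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .pooling import EffectEstimate, pool_random_dl

__all__ = [
    "EggerResult",
    "BeggResult",
    "BiasTestResult",
    "FunnelPoint",
    "InsufficientStudiesError",
    "egger_test",
    "begg_test",
    "bias_tests",
    "funnel_data",
]


class InsufficientStudiesError(ValueError):
    """Too few studies for the requested bias diagnostic."""


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    se: float
    t: float
    df: int
    p_value: float


@dataclass(frozen=True)
class BeggResult:
    s: float        # Kendall score: concordant minus discordant pairs
    var_s: float    # n(n-1)(2n+5)/18
    z: float
    p_value: float
    n_ties: int = 0


@dataclass(frozen=True)
class BiasTestResult:
    egger: Optional[EggerResult]
    begg: Optional[BeggResult]


@dataclass(frozen=True)
class FunnelPoint:
    study_id: str
    or_point: float
    log_or: float
    se: float


def egger_test(effects: Sequence[EffectEstimate]) -> EggerResult:
    """Egger's regression test for funnel-plot asymmetry.

    OLS of y_i = theta_i / se_i on x_i = 1 / se_i; returns the intercept,
    its standard error at n - 2 residual df, the t statistic and the
    two-sided t-distribution p-value.  Requires n >= 3 and varying precision.
    """
    n = len(effects)
    if n < 3:
        raise InsufficientStudiesError(f"Egger test needs >= 3 studies, got {n}")
    se = np.array([e.se for e in effects])
    x = 1.0 / se
    y = np.array([e.log_or for e in effects]) / se
    if np.ptp(x) == 0:
        raise ValueError("Egger test: all precisions equal, regression design degenerate")
    design = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    df = n - 2
    s2 = float(resid @ resid) / df
    intercept = float(beta[0])
    scale = float(np.mean(y * y)) + 1.0
    if s2 <= 1e-12 * scale:
        # exact fit: a limiting case with no residual scatter.  A zero
        # intercept then carries no evidence of bias (t = 0, p = 1); a
        # non-zero one is infinitely strong evidence.
        if abs(intercept) <= 1e-8 * math.sqrt(scale):
            return EggerResult(intercept=0.0, se=0.0, t=0.0, df=df, p_value=1.0)
        return EggerResult(intercept=intercept, se=0.0, t=math.inf, df=df, p_value=0.0)
    cov = s2 * np.linalg.inv(design.T @ design)
    se_int = math.sqrt(float(cov[0, 0]))
    t = intercept / se_int
    p = float(2.0 * stats.t.sf(abs(t), df))
    return EggerResult(intercept=intercept, se=se_int, t=t, df=df, p_value=p)


def begg_test(effects: Sequence[EffectEstimate]) -> BeggResult:
    """Begg-Mazumdar rank-correlation test.

    Standardized deviates t_i = (theta_i - theta_bar) / sqrt(var_i - 1/Sum w)
    use the fixed-effect pooled mean; S counts concordant minus discordant
    pairs between the ranks of t_i and of var_i.  No continuity correction
    is applied to z.  Ties contribute zero to S and leave the variance
    unadjusted (a warning is emitted when ties are present).
    """
    n = len(effects)
    if n < 2:
        raise InsufficientStudiesError(f"Begg test needs >= 2 studies, got {n}")
    theta = np.array([e.log_or for e in effects])
    v = np.array([e.var for e in effects])
    w = 1.0 / v
    sw = w.sum()
    mu = (w * theta).sum() / sw
    cond = v - 1.0 / sw
    if np.any(cond <= 0):
        warnings.warn("Begg test: var_i <= 1/sum(w) for some study; "
                      "clamping the conditional variance to a small positive value",
                      RuntimeWarning, stacklevel=2)
        cond = np.maximum(cond, 1e-12)
    t_star = (theta - mu) / np.sqrt(cond)
    s = 0.0
    n_ties = 0
    for i in range(n):
        for j in range(i + 1, n):
            prod = np.sign(t_star[j] - t_star[i]) * np.sign(v[j] - v[i])
            if prod == 0:
                n_ties += 1
            s += prod
    if n_ties:
        warnings.warn(f"Begg test: {n_ties} tied pair(s); ties contribute 0 to S "
                      "and the variance is not adjusted", RuntimeWarning, stacklevel=2)
    var_s = n * (n - 1) * (2 * n + 5) / 18.0
    z = s / math.sqrt(var_s)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return BeggResult(s=float(s), var_s=var_s, z=z, p_value=p, n_ties=n_ties)


def bias_tests(effects: Sequence[EffectEstimate]) -> BiasTestResult:
    """Run both diagnostics, omitting whichever the study count cannot support."""
    egger = egger_test(effects) if len(effects) >= 3 else None
    begg = begg_test(effects) if len(effects) >= 2 else None
    return BiasTestResult(egger=egger, begg=begg)


def funnel_data(effects: Sequence[EffectEstimate]) -> tuple[list[FunnelPoint], Optional[float]]:
    """Per-study (OR, SE) funnel-plot coordinates plus the pooled reference OR.

    Returns plot-ready data only; no rendering.  The reference line is the
    default DL pooled odds ratio, or None for empty input.
    """
    points = [FunnelPoint(study_id=e.study_id, or_point=e.or_point,
                          log_or=e.log_or, se=e.se) for e in effects]
    ref = pool_random_dl(effects).pooled_or if effects else None
    return points, ref
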