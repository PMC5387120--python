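"""Per-study odds-ratio effects and fixed/random-effects pooling.

Effect sizes are Woolf log odds ratios: for a 2x2 table (a, b, c, d),
``log OR = ln(ad/bc)`` with large-sample variance ``1/a + 1/b + 1/c + 1/d``.
Pooling is inverse-variance fixed effect or DerSimonian-Laird (DL)
random effects, with Cochran's Q and the I-squared statistic quantifying
between-study heterogeneity.

The package default is DL random effects for every comparison, with the
method-of-moments tau-squared truncated at zero — when Q <= df the random-
effects fit collapses exactly onto the fixed-effect one, so a single rule
covers both the homogeneous and heterogeneous regimes.  The classical
decision rule (fixed effect when the Q test's p-value exceeds 0.10) is
available through :func:`select_model` as an explicit mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .tables import FourfoldTable

__all__ = [
    "Z_975",
    "Model",
    "HeterogeneityBand",
    "EffectEstimate",
    "PooledResult",
    "Heterogeneity",
    "DegenerateTableError",
    "woolf_effect",
    "pool_fixed_iv",
    "pool_random_dl",
    "pool",
    "heterogeneity",
    "select_model",
]

Z_975 = 1.959964  # 97.5% standard-normal quantile used for all 95% CIs


class DegenerateTableError(ValueError):
    """All four cells of a 2x2 table are zero: no effect is estimable."""


class Model(str, Enum):
    FIXED_IV = "fixed_iv"
    RANDOM_DL = "random_dl"


class HeterogeneityBand(str, Enum):
    """I-squared bands: <25% low, 25-75% moderate, >75% high inconsistency."""

    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


@dataclass(frozen=True)
class EffectEstimate:
    """One study's log odds ratio with its variance and 95% CI."""

    study_id: str
    log_or: float
    var: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if not self.var > 0:
            raise ValueError(f"{self.study_id}: variance must be positive, got {self.var}")

    @property
    def se(self) -> float:
        return math.sqrt(self.var)

    @property
    def or_point(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci_low(self) -> float:
        return math.exp(self.log_or - Z_975 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.log_or + Z_975 * self.se)


@dataclass(frozen=True)
class Heterogeneity:
    """Cochran's Q with its chi-square p-value and the I-squared statistic."""

    q: float
    df: int
    p_q: float
    i_squared: float
    band: Optional[HeterogeneityBand]  # None when < 2 studies

    @property
    def meaningful(self) -> bool:
        return self.band is not None


@dataclass(frozen=True)
class PooledResult:
    """A pooled comparison: effect, test, heterogeneity and per-study weights."""

    model: Model
    n_studies: int
    pooled_log_or: float
    pooled_se: float
    q: float
    df: int
    p_q: float
    i_squared: float
    tau_squared: float
    weights: tuple[tuple[str, float], ...]  # (study_id, normalized weight)

    @property
    def pooled_or(self) -> float:
        return math.exp(self.pooled_log_or)

    @property
    def ci_low(self) -> float:
        return math.exp(self.pooled_log_or - Z_975 * self.pooled_se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.pooled_log_or + Z_975 * self.pooled_se)

    @property
    def z(self) -> float:
        return self.pooled_log_or / self.pooled_se

    @property
    def p_value(self) -> float:
        return 2.0 * float(stats.norm.sf(abs(self.z)))

    @property
    def heterogeneity(self) -> Heterogeneity:
        return Heterogeneity(q=self.q, df=self.df, p_q=self.p_q,
                             i_squared=self.i_squared, band=_band(self.i_squared)
                             if self.n_studies >= 2 else None)


def woolf_effect(table: FourfoldTable, correction: float = 0.5,
                 study_id: str = "") -> EffectEstimate:
    """Woolf log odds ratio with reciprocal-sum variance for one 2x2 table.

    If any cell is zero, ``correction`` (default 0.5) is added to all four
    cells before computing, and the estimate is flagged ``corrected``.
    """
    if table.degenerate:
        raise DegenerateTableError(
            f"{study_id or 'table'}: all four cells are zero, odds ratio undefined")
    a, b, c, d = (float(x) for x in table.cells())
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + correction, b + correction, c + correction, d + correction
    log_or = math.log((a * d) / (b * c))
    var = 1 / a + 1 / b + 1 / c + 1 / d
    return EffectEstimate(study_id=study_id, log_or=log_or, var=var, corrected=corrected)


def _band(i_squared: float) -> HeterogeneityBand:
    if i_squared < 25.0:
        return HeterogeneityBand.LOW
    if i_squared <= 75.0:
        return HeterogeneityBand.MODERATE
    return HeterogeneityBand.HIGH


def _fixed_pass(effects: Sequence[EffectEstimate]):
    theta = np.array([e.log_or for e in effects])
    v = np.array([e.var for e in effects])
    w = 1.0 / v
    sw = w.sum()
    mu = float((w * theta).sum() / sw)
    q = float((w * (theta - mu) ** 2).sum())
    df = len(effects) - 1
    return theta, v, w, sw, mu, q, df


def heterogeneity(effects: Sequence[EffectEstimate]) -> Heterogeneity:
    """Cochran's Q from fixed inverse-variance weights, its p-value and I².

    With fewer than two studies the test is undefined: Q = 0, p = 1, and the
    band is flagged as None.
    """
    if len(effects) < 2:
        return Heterogeneity(q=0.0, df=0, p_q=1.0, i_squared=0.0, band=None)
    _, _, _, _, _, q, df = _fixed_pass(effects)
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return Heterogeneity(q=q, df=df, p_q=p_q, i_squared=i2, band=_band(i2))


def pool_fixed_iv(effects: Sequence[EffectEstimate]) -> PooledResult:
    """Inverse-variance fixed-effect pooling (tau-squared fixed at zero)."""
    if not effects:
        raise ValueError("pool_fixed_iv: need at least one effect")
    theta, v, w, sw, mu, q, df = _fixed_pass(effects)
    het = heterogeneity(effects)
    weights = tuple((e.study_id, float(wi / sw)) for e, wi in zip(effects, w))
    return PooledResult(model=Model.FIXED_IV, n_studies=len(effects),
                        pooled_log_or=mu, pooled_se=float(1.0 / math.sqrt(sw)),
                        q=het.q, df=het.df, p_q=het.p_q, i_squared=het.i_squared,
                        tau_squared=0.0, weights=weights)


def pool_random_dl(effects: Sequence[EffectEstimate]) -> PooledResult:
    """DerSimonian-Laird random-effects pooling.

    tau² = max(0, (Q - df) / C) with C = Σw - Σw²/Σw from the fixed-effect
    pass; random-effects weights are 1/(varᵢ + tau²).  Q, p_Q and I² are
    reported from the fixed-weight pass, as is conventional.
    """
    if not effects:
        raise ValueError("pool_random_dl: need at least one effect")
    theta, v, w, sw, mu, q, df = _fixed_pass(effects)
    het = heterogeneity(effects)
    if df > 0:
        c = sw - (w ** 2).sum() / sw
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    else:
        tau2 = 0.0
    w_star = 1.0 / (v + tau2)
    sw_star = w_star.sum()
    mu_star = float((w_star * theta).sum() / sw_star)
    weights = tuple((e.study_id, float(wi / sw_star)) for e, wi in zip(effects, w_star))
    return PooledResult(model=Model.RANDOM_DL, n_studies=len(effects),
                        pooled_log_or=mu_star, pooled_se=float(1.0 / math.sqrt(sw_star)),
                        q=het.q, df=het.df, p_q=het.p_q, i_squared=het.i_squared,
                        tau_squared=float(tau2), weights=weights)


def select_model(p_q: float, threshold: float = 0.10) -> Model:
    """Classical model choice: fixed effect iff the Q test's p exceeds 0.10.

    At the boundary (p_q == threshold) the random-effects model is used.
    """
    if not 0.0 <= p_q <= 1.0:
        raise ValueError(f"p_q must be a probability, got {p_q}")
    return Model.FIXED_IV if p_q > threshold else Model.RANDOM_DL


def pool(effects: Sequence[EffectEstimate], model: str = "dl_default",
         threshold: float = 0.10) -> PooledResult:
    """Pool under the package-default DL model or the rule-based mode.

    ``model="dl_default"`` always uses DerSimonian-Laird (the package
    default); ``model="rule_based"`` applies :func:`select_model` to the Q
    test's p-value first.
    """
    if model == "dl_default":
        return pool_random_dl(effects)
    if model == "rule_based":
        het = heterogeneity(effects)
        chosen = select_model(het.p_q, threshold)
        return (pool_fixed_iv if chosen is Model.FIXED_IV else pool_random_dl)(effects)
    raise ValueError(f"unknown model mode {model!r}")
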