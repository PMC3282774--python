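"""Meta-analytic pooling of per-study odds ratios.

Fixed-effects pooling uses the Mantel-Haenszel estimator on the 2x2 tables,

    OR_MH = sum(a_i * d_i / n_i) / sum(b_i * c_i / n_i),

with the Robins-Breslow-Greenland variance for its log.  Inverse-variance
fixed pooling and DerSimonian-Laird random-effects pooling operate on the
per-study log odds ratios; the between-study variance tau^2 is the usual
method-of-moments truncation max(0, (Q - df) / C).  Heterogeneity is
Cochran's Q with inverse-variance weights, summarised as I^2 = max(0,
(Q - df)/Q) * 100.

Model selection follows the common two-step convention: fixed effects when
the Q test is non-significant at a threshold (default p > 0.10), random
effects otherwise.  The pooled effect is tested with a two-sided Z test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .association import EffectEstimate, GeneticModel, TwoByTwo, Z_95, study_odds_ratio

__all__ = [
    "HeterogeneityResult",
    "PooledResult",
    "mh_pool",
    "iv_pool",
    "dl_pool",
    "cochran_q",
    "pool_with_selection",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its chi-square p, I^2 (%) and DL tau^2."""

    Q: float
    df: int
    p_Q: float
    I2: float
    tau2: float


@dataclass(frozen=True)
class PooledResult:
    """Pooled odds ratio for one genetic model in one stratum.

    ``het`` is None for single-study strata, where heterogeneity is not
    defined and the "pooled" result is just that study's estimate.
    """

    model: GeneticModel
    stratum: str
    k: int
    method: str  # "MH-fixed", "IV-fixed" or "DL-random"
    or_: float
    ci_low: float
    ci_high: float
    log_or: float
    se: float
    z: float
    p_assoc: float
    het: HeterogeneityResult | None


def _finish(log_or: float, se: float) -> tuple[float, float, float, float, float]:
    z = log_or / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return math.exp(log_or), math.exp(log_or - Z_95 * se), math.exp(log_or + Z_95 * se), z, p


def mh_pool(tables: Sequence[TwoByTwo]) -> tuple[float, float]:
    """Mantel-Haenszel pooled log-OR and its Robins-Breslow-Greenland SE.

    For a single table this reduces to the study's own odds ratio with its
    Woolf standard error.
    """
    if len(tables) == 0:
        raise ValueError("mh_pool needs at least one table")
    if len(tables) == 1:
        est = study_odds_ratio(tables[0])
        return est.log_or, est.se
    a = np.array([t.a for t in tables], dtype=float)
    b = np.array([t.b for t in tables], dtype=float)
    c = np.array([t.c for t in tables], dtype=float)
    d = np.array([t.d for t in tables], dtype=float)
    n = a + b + c + d
    R = float(np.sum(a * d / n))
    S = float(np.sum(b * c / n))
    if R == 0.0 or S == 0.0:
        raise ValueError("Mantel-Haenszel pool undefined: no discordant counts")
    log_or = math.log(R / S)
    # RBG variance of log(OR_MH)
    P = (a + d) / n
    Q = (b + c) / n
    var = (
        float(np.sum(P * a * d / n)) / (2 * R * R)
        + float(np.sum(P * b * c / n + Q * a * d / n)) / (2 * R * S)
        + float(np.sum(Q * b * c / n)) / (2 * S * S)
    )
    return log_or, math.sqrt(var)


def iv_pool(effects: Sequence[EffectEstimate]) -> tuple[float, float]:
    """Inverse-variance fixed-effects pooled log-OR and SE."""
    if len(effects) == 0:
        raise ValueError("iv_pool needs at least one effect")
    log_ors = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    sw = float(np.sum(w))
    return float(np.sum(w * log_ors) / sw), 1.0 / math.sqrt(sw)


def cochran_q(effects: Sequence[EffectEstimate]) -> HeterogeneityResult:
    """Cochran's Q about the IV fixed-effects pool, with I^2 and DL tau^2.

    Requires k >= 2 (heterogeneity is undefined for a single study).
    """
    k = len(effects)
    if k < 2:
        raise ValueError("heterogeneity requires at least two studies")
    log_ors = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    mu = float(np.sum(w * log_ors) / np.sum(w))
    Q = float(np.sum(w * (log_ors - mu) ** 2))
    df = k - 1
    p_Q = float(stats.chi2.sf(Q, df))
    I2 = 0.0 if Q <= df else (Q - df) / Q * 100.0
    C = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (Q - df) / C) if C > 0 else 0.0
    return HeterogeneityResult(Q=Q, df=df, p_Q=p_Q, I2=I2, tau2=tau2)


def dl_pool(effects: Sequence[EffectEstimate]) -> tuple[float, float, float]:
    """DerSimonian-Laird random-effects pooled log-OR, SE and tau^2.

    With tau^2 truncated at zero (Q <= df) the result coincides with the
    inverse-variance fixed-effects pool.
    """
    if len(effects) < 2:
        raise ValueError("random-effects pooling requires at least two studies")
    tau2 = cochran_q(effects).tau2
    log_ors = np.array([e.log_or for e in effects])
    w = np.array([1.0 / (e.se**2 + tau2) for e in effects])
    sw = float(np.sum(w))
    return float(np.sum(w * log_ors) / sw), 1.0 / math.sqrt(sw), tau2


def pool_with_selection(
    tables: Sequence[TwoByTwo],
    effects: Sequence[EffectEstimate],
    model: GeneticModel,
    stratum: str = "Total",
    q_threshold: float = 0.10,
    fixed_estimator: str = "MH",
) -> PooledResult:
    """Pool one stratum, choosing fixed vs random effects by the Q test.

    Fixed effects (Mantel-Haenszel by default, inverse-variance optionally)
    when the heterogeneity p exceeds ``q_threshold`` or only one study is
    available; DerSimonian-Laird random effects otherwise.
    """
    k = len(tables)
    if k == 0:
        raise ValueError("empty stratum")
    if k != len(effects):
        raise ValueError("tables and effects must be parallel")
    if fixed_estimator not in ("MH", "IV"):
        raise ValueError(f"unknown fixed estimator {fixed_estimator!r}")

    het = cochran_q(effects) if k >= 2 else None
    use_random = het is not None and het.p_Q <= q_threshold
    if use_random:
        log_or, se, _ = dl_pool(effects)
        method = "DL-random"
    elif fixed_estimator == "MH":
        log_or, se = mh_pool(tables)
        method = "MH-fixed"
    else:
        log_or, se = iv_pool(effects)
        method = "IV-fixed"
    or_, lo, hi, z, p = _finish(log_or, se)
    return PooledResult(
        model=model,
        stratum=stratum,
        k=k,
        method=method,
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        log_or=log_or,
        se=se,
        z=z,
        p_assoc=p,
        het=het,
    )
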