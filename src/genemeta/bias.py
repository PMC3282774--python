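"""Publication-bias tests and familywise multiplicity adjustment.

Begg's test rank-correlates the variance-standardised effect deviates

    t_i = (log_or_i - pooled) / sqrt(se_i^2 - se_pooled^2)

with the effect variances se_i^2 (Kendall score S = concordant minus
discordant pairs), and refers the continuity-corrected statistic
(|S| - 1) / sqrt(Var S) to the standard normal.  Egger's test regresses each
study's standard normal deviate log_or_i / se_i on its precision 1 / se_i by
ordinary least squares and tests the intercept with a t(k-2) distribution: a
nonzero intercept indicates funnel-plot asymmetry.

Familywise correction over the genetic-model tests uses the Holm step-down
procedure (with plain Bonferroni available for comparison).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import EffectEstimate, GeneticModel

__all__ = [
    "BiasTestResult",
    "AdjustedPvalues",
    "begg_test",
    "egger_test",
    "holm_adjust",
    "bonferroni_adjust",
    "funnel_data",
]

MIN_BIAS_STUDIES = 3


@dataclass(frozen=True)
class BiasTestResult:
    """Outcome of one publication-bias test on one model's study set.

    ``statistic`` is the continuity-corrected normal z for Begg and the
    intercept t for Egger; ``p`` is NaN when k < 3 studies make the test
    non-computable.
    """

    test: str  # "Begg" or "Egger"
    model: GeneticModel
    k: int
    statistic: float
    p: float
    intercept: float | None = None  # Egger only

    @property
    def computable(self) -> bool:
        return not math.isnan(self.p)


@dataclass(frozen=True)
class AdjustedPvalues:
    """Raw and familywise-adjusted p-values, in the original input order."""

    raw: tuple[float, ...]
    method: str  # "holm" or "bonferroni"
    adjusted: tuple[float, ...]
    alpha: float = 0.1

    def significant(self) -> tuple[bool, ...]:
        return tuple(p <= self.alpha for p in self.adjusted)


def _check_pvalues(raw: Sequence[float]) -> np.ndarray:
    p = np.asarray(raw, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("need a non-empty 1-D vector of p-values")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def begg_test(
    effects: Sequence[EffectEstimate],
    pooled_log_or: float,
    pooled_se: float,
    model: GeneticModel | None = None,
) -> BiasTestResult:
    """Begg-Mazumdar rank correlation test for small-study effects.

    Var(S) uses the tie-adjusted Kendall formula; with no ties it is
    k(k-1)(2k+5)/18.  The two-sided p comes from the continuity-corrected
    normal approximation, z = (|S| - 1)/sqrt(Var S) for |S| >= 1 and 0
    otherwise.  Fewer than three studies yield a non-computable result
    (p = NaN) rather than an error.
    """
    k = len(effects)
    model = model if model is not None else (effects[0].model if k else GeneticModel.HOM)
    if k < MIN_BIAS_STUDIES:
        return BiasTestResult("Begg", model, k, float("nan"), float("nan"))
    v = np.array([e.se**2 for e in effects])
    var_diff = v - pooled_se**2
    # the pooled variance is never larger than a single study's, up to rounding
    var_diff = np.maximum(var_diff, np.finfo(float).tiny)
    t = (np.array([e.log_or for e in effects]) - pooled_log_or) / np.sqrt(var_diff)

    S = 0
    for i, j in itertools.combinations(range(k), 2):
        S += int(np.sign(t[j] - t[i]) * np.sign(v[j] - v[i]))

    def tie_term(x: np.ndarray) -> tuple[float, float, float]:
        _, counts = np.unique(x, return_counts=True)
        ties = counts[counts > 1].astype(float)
        return (
            float(np.sum(ties * (ties - 1) * (2 * ties + 5))),
            float(np.sum(ties * (ties - 1))),
            float(np.sum(ties * (ties - 1) * (ties - 2))),
        )

    vt1, vt2, vt3 = tie_term(t)
    vu1, vu2, vu3 = tie_term(v)
    var_s = (k * (k - 1) * (2 * k + 5) - vt1 - vu1) / 18.0
    if vt2 and vu2:
        var_s += vt3 * vu3 / (9.0 * k * (k - 1) * (k - 2)) + vt2 * vu2 / (
            2.0 * k * (k - 1)
        )
    z = (abs(S) - 1) / math.sqrt(var_s) if abs(S) >= 1 else 0.0
    p = 2.0 * float(stats.norm.sf(z))
    return BiasTestResult("Begg", model, k, z, min(p, 1.0))


def egger_test(
    effects: Sequence[EffectEstimate], model: GeneticModel | None = None
) -> BiasTestResult:
    """Egger weighted-regression test for funnel-plot asymmetry.

    OLS of the standard normal deviate on precision; the intercept t
    statistic is referred to Student's t with k - 2 df (two-sided).
    """
    k = len(effects)
    model = model if model is not None else (effects[0].model if k else GeneticModel.HOM)
    if k < MIN_BIAS_STUDIES:
        return BiasTestResult("Egger", model, k, float("nan"), float("nan"), None)
    precision = np.array([1.0 / e.se for e in effects])
    snd = np.array([e.log_or / e.se for e in effects])
    if np.ptp(precision) == 0:
        raise ValueError("all precisions identical: Egger design matrix is singular")
    fit = stats.linregress(precision, snd)
    if fit.intercept_stderr == 0.0:
        # exact linear fit: the intercept is known without error
        t_stat = 0.0 if fit.intercept == 0.0 else math.inf * math.copysign(1, fit.intercept)
    else:
        t_stat = fit.intercept / fit.intercept_stderr
    p = 2.0 * float(stats.t.sf(abs(t_stat), k - 2))
    return BiasTestResult("Egger", model, k, float(t_stat), p, float(fit.intercept))


def holm_adjust(raw: Sequence[float], alpha: float = 0.1) -> AdjustedPvalues:
    """Holm step-down (step-down Bonferroni) familywise adjustment.

    Sorting the m raw p-values ascending, adjusted_(i) = max_{j<=i}
    min(1, (m - j + 1) * p_(j)); results are mapped back to input order.
    Controls the familywise error rate and is uniformly no more conservative
    than plain Bonferroni.
    """
    p = _check_pvalues(raw)
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = np.minimum(1.0, (m - np.arange(m)) * p[order])
    stepped = np.maximum.accumulate(stepped)
    adjusted = np.empty(m)
    adjusted[order] = stepped
    return AdjustedPvalues(tuple(map(float, p)), "holm", tuple(map(float, adjusted)), alpha)


def bonferroni_adjust(raw: Sequence[float], alpha: float = 0.1) -> AdjustedPvalues:
    """Plain Bonferroni adjustment: min(1, m * p) elementwise."""
    p = _check_pvalues(raw)
    adjusted = np.minimum(1.0, p.size * p)
    return AdjustedPvalues(
        tuple(map(float, p)), "bonferroni", tuple(map(float, adjusted)), alpha
    )


def funnel_data(
    effects: Sequence[EffectEstimate],
    pooled_log_or: float,
    pooled_se: float,
) -> pd.DataFrame:
    """Per-study funnel-plot coordinates: log-OR, SE, precision, SND, deviate.

    Enough to redraw a funnel or Egger regression plot externally.
    """
    rows = []
    for e in effects:
        var_diff = max(e.se**2 - pooled_se**2, np.finfo(float).tiny)
        rows.append(
            {
                "study_id": e.study_id,
                "log_or": e.log_or,
                "se": e.se,
                "precision": 1.0 / e.se,
                "snd": e.log_or / e.se,
                "std_deviate": (e.log_or - pooled_log_or) / math.sqrt(var_diff),
            }
        )
    return pd.DataFrame(rows)
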