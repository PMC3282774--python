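"""Per-study association statistics: HWE testing, genetic-model contrasts, odds ratios.

For a biallelic SNP with genotypes GG / GC / CC, four standard genetic models
collapse the 3x2 genotype-by-status table into a 2x2 exposure table:

========  ======================  =====================
model     exposed                 reference
========  ======================  =====================
HET       GC                      GG   (CC rows dropped)
HOM       CC                      GG   (GC rows dropped)
DOM       GC + CC                 GG
REC       CC                      GG + GC
========  ======================  =====================

Per-study effects are odds ratios with Woolf (log-scale) standard errors; the
Haldane-Anscombe 0.5 continuity correction is applied only when a cell is zero.
Hardy-Weinberg equilibrium in controls is tested with the plain Pearson
chi-square on the three genotype classes (1 df, no Yates correction).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from scipy import stats

from .studies import GenotypeCounts

__all__ = [
    "GeneticModel",
    "TwoByTwo",
    "HweResult",
    "EffectEstimate",
    "allele_frequency_c",
    "hwe_test",
    "collapse",
    "study_odds_ratio",
    "UndefinedEffectError",
    "Z_95",
]

#: two-sided 95% normal quantile, fixed for every confidence interval
Z_95 = 1.959963984540054


class UndefinedEffectError(ValueError):
    """Raised when an odds ratio cannot be estimated from a 2x2 table."""


class GeneticModel(str, enum.Enum):
    """The four genotype contrasts of a biallelic case-control analysis."""

    HET = "HET"  # GC vs GG (co-dominant, heterozygote)
    HOM = "HOM"  # CC vs GG (co-dominant, homozygote)
    DOM = "DOM"  # GC+CC vs GG (dominant)
    REC = "REC"  # CC vs GC+GG (recessive)

    @property
    def description(self) -> str:
        return {
            GeneticModel.HET: "GC vs GG",
            GeneticModel.HOM: "CC vs GG",
            GeneticModel.DOM: "GC+CC vs GG",
            GeneticModel.REC: "CC vs GC+GG",
        }[self]


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 exposure table: (a, b) = exposed/reference cases, (c, d) = controls."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be non-negative")
        if self.n < 1:
            raise ValueError("2x2 table must contain at least one observation")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def corrected(self) -> "TwoByTwo":
        """The table with 0.5 added to every cell (Haldane-Anscombe)."""
        return TwoByTwo(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


@dataclass(frozen=True)
class HweResult:
    """Hardy-Weinberg chi-square test of one arm's genotype counts."""

    allele_freq_C: float
    chi2: float
    df: int
    p: float

    @property
    def violates(self) -> bool:
        """True at the conventional 0.05 disequilibrium level."""
        return self.p < 0.05


@dataclass(frozen=True)
class EffectEstimate:
    """One study's odds ratio under one genetic model, on the log scale."""

    study_id: str
    model: GeneticModel
    log_or: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    corrected: bool = False

    @property
    def variance(self) -> float:
        return self.se**2


def allele_frequency_c(counts: GenotypeCounts) -> float:
    """Frequency of the variant (C) allele: (2*n_CC + n_GC) / (2*N)."""
    n = counts.total()
    if n < 1:
        raise ValueError("cannot compute allele frequency of an empty arm")
    return (2 * counts.n_CC + counts.n_GC) / (2 * n)


def hwe_test(counts: GenotypeCounts) -> HweResult:
    """Pearson chi-square test of Hardy-Weinberg proportions (1 df).

    Expected counts are N*p^2, 2*N*p*q, N*q^2 with q the variant-allele
    frequency estimated from the same counts; chi2 sums (obs-exp)^2/exp over
    the three genotype classes.  Monomorphic input gives chi2 = 0, p = 1
    (observed equals expected by construction).
    """
    n = counts.total()
    if n < 1:
        raise ValueError("cannot test HWE on an empty arm")
    q = allele_frequency_c(counts)
    p = 1.0 - q
    if q == 0.0 or q == 1.0:
        return HweResult(allele_freq_C=q, chi2=0.0, df=1, p=1.0)
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    observed = counts.as_tuple()
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return HweResult(allele_freq_C=q, chi2=chi2, df=1, p=float(stats.chi2.sf(chi2, 1)))


def collapse(
    cases: GenotypeCounts, controls: GenotypeCounts, model: GeneticModel
) -> TwoByTwo:
    """Collapse genotype counts to the 2x2 table of one genetic model.

    HET and HOM drop the excluded genotype class (rows are removed, never
    merged), so their tables may contain fewer subjects than the study.
    """
    model = GeneticModel(model)
    if model is GeneticModel.HET:
        return TwoByTwo(cases.n_GC, cases.n_GG, controls.n_GC, controls.n_GG)
    if model is GeneticModel.HOM:
        return TwoByTwo(cases.n_CC, cases.n_GG, controls.n_CC, controls.n_GG)
    if model is GeneticModel.DOM:
        return TwoByTwo(
            cases.n_GC + cases.n_CC, cases.n_GG, controls.n_GC + controls.n_CC, controls.n_GG
        )
    return TwoByTwo(
        cases.n_CC, cases.n_GG + cases.n_GC, controls.n_CC, controls.n_GG + controls.n_GC
    )


def study_odds_ratio(
    table: TwoByTwo,
    study_id: str = "",
    model: GeneticModel = GeneticModel.HOM,
    continuity_correction: bool = True,
) -> EffectEstimate:
    """Odds ratio (a*d)/(b*c) with Woolf SE sqrt(1/a + 1/b + 1/c + 1/d).

    When any cell is zero and ``continuity_correction`` is on, 0.5 is added
    to all four cells first and the estimate is flagged ``corrected``.  A
    table with an empty row or column (both exposed or both reference cells
    zero) carries no information about the odds ratio and raises
    :class:`UndefinedEffectError`.
    """
    if (table.a == 0 and table.c == 0) or (table.b == 0 and table.d == 0):
        raise UndefinedEffectError(
            f"study {study_id or '<unnamed>'}: empty exposure column, odds ratio undefined"
        )
    was_corrected = False
    t = table
    if t.has_zero_cell():
        if not continuity_correction:
            raise UndefinedEffectError(
                f"study {study_id or '<unnamed>'}: zero cell and continuity correction disabled"
            )
        t = t.corrected()
        was_corrected = True
    log_or = math.log((t.a * t.d) / (t.b * t.c))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return EffectEstimate(
        study_id=study_id,
        model=model,
        log_or=log_or,
        se=se,
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        corrected=was_corrected,
    )
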