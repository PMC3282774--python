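"""Synthetic case-control genotype studies with known truth.

The generator emulates the structure of a published genetic-association
meta-analysis input table: per study, control genotypes are multinomial
under Hardy-Weinberg proportions at a chosen variant-allele frequency
(optionally distorted by an inbreeding-style coefficient f, giving
probabilities p^2 + fpq, 2pq(1-f), q^2 + fpq), and case genotypes follow the
standard retrospective-sampling construction: a logistic disease model with
per-genotype odds ratios (OR_het, OR_hom) versus the GG reference tilts the
control genotype distribution,

    P(g | case)  propto  P(g | control) * OR_g * exp(eps_g),

renormalised, where eps ~ Normal(0, tau^2) per study injects between-study
heterogeneity on the log-OR scale (tau = 0 gives a common fixed effect).

Random streams are derived from (seed, study_index) so that adding studies
to a scenario never perturbs the ones already generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .association import GeneticModel
from .pipeline import MetaConfig, run_meta
from .studies import GenotypeCounts, StudyRecord, StudyTable

__all__ = ["SimScenario", "simulate_study", "simulate_table", "run_sim_study", "SimSummary"]


@dataclass(frozen=True)
class SimScenario:
    """Truth and design of a simulated meta-analysis.

    Defaults mirror a realistic European-ancestry scenario for rs2910164:
    four studies, control C-allele frequency 0.27, a purely recessive effect
    of OR_hom = 1.3, per-study sample sizes matching the four European
    case-control studies of the motivating dataset, and no between-study
    heterogeneity.
    """

    k_studies: int = 4
    allele_freq_C: float = 0.27
    or_het: float = 1.0
    or_hom: float = 1.3
    n_cases: tuple[int, ...] = (88, 754, 805, 1130)
    n_controls: tuple[int, ...] = (155, 1243, 904, 596)
    tau: float = 0.0
    hwe_disequilibrium: float = 0.0
    ethnicity: str = "Simulated"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_studies < 1:
            raise ValueError("k_studies must be >= 1")
        if not 0.0 < self.allele_freq_C < 1.0:
            raise ValueError("allele_freq_C must lie in (0, 1)")
        if self.or_het <= 0 or self.or_hom <= 0:
            raise ValueError("per-genotype odds ratios must be positive")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        self.control_probs()  # validates the disequilibrium-adjusted simplex

    def size_for(self, study_index: int) -> tuple[int, int]:
        nc = self.n_cases[study_index % len(self.n_cases)]
        nn = self.n_controls[study_index % len(self.n_controls)]
        return nc, nn

    def control_probs(self) -> np.ndarray:
        """Genotype probabilities (GG, GC, CC) in controls.

        With inbreeding-style coefficient f: p^2 + fpq, 2pq(1-f), q^2 + fpq.
        """
        q = self.allele_freq_C
        p = 1.0 - q
        f = self.hwe_disequilibrium
        probs = np.array([p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q])
        if np.any(probs < 0) or np.any(probs > 1) or not math.isclose(probs.sum(), 1.0):
            raise ValueError(
                f"disequilibrium coefficient {f} gives an invalid genotype simplex {probs}"
            )
        return probs


def _rng_for(scenario: SimScenario, study_index: int, replicate: int = 0) -> np.random.Generator:
    # independent stream per (seed, replicate, study); adding studies or
    # replicates never disturbs earlier ones
    return np.random.default_rng(
        np.random.SeedSequence(entropy=scenario.seed, spawn_key=(replicate, study_index))
    )


def simulate_study(
    scenario: SimScenario, study_index: int, replicate: int = 0
) -> StudyRecord:
    """Draw one case-control study's genotype counts.

    Deterministic given (scenario.seed, replicate, study_index).
    """
    rng = _rng_for(scenario, study_index, replicate)
    ctrl_probs = scenario.control_probs()
    if scenario.tau > 0:
        eps_het, eps_hom = rng.normal(0.0, scenario.tau, size=2)
    else:
        eps_het = eps_hom = 0.0
    tilt = np.array(
        [1.0, scenario.or_het * math.exp(eps_het), scenario.or_hom * math.exp(eps_hom)]
    )
    case_probs = ctrl_probs * tilt
    case_probs /= case_probs.sum()
    n_cases, n_controls = scenario.size_for(study_index)
    case_draw = rng.multinomial(n_cases, case_probs)
    ctrl_draw = rng.multinomial(n_controls, ctrl_probs)
    return StudyRecord(
        study_id=f"sim{replicate:04d}-{study_index:02d}",
        first_author="Synthetic",
        year=2024,
        country="Simulated",
        ethnicity=scenario.ethnicity,
        genotyping_method="simulation",
        cases=GenotypeCounts(*map(int, case_draw)),
        controls=GenotypeCounts(*map(int, ctrl_draw)),
    )


def simulate_table(scenario: SimScenario, replicate: int = 0) -> StudyTable:
    """A full k-study table for one replicate of the scenario."""
    return StudyTable(
        [simulate_study(scenario, i, replicate) for i in range(scenario.k_studies)]
    )


@dataclass
class SimSummary:
    """Operating characteristics of the pipeline over simulation replicates.

    All per-model dictionaries are keyed by genetic-model label.  Monte-Carlo
    standard errors accompany rates and means when n_reps > 1.
    """

    scenario: SimScenario
    n_reps: int
    alpha: float
    rejection_rate: dict[str, float]
    rejection_mc_se: dict[str, float]
    mean_pooled_log_or: dict[str, float]
    mean_bias_log_or: dict[str, float]
    bias_mc_se: dict[str, float]
    ci_coverage: dict[str, float]
    coverage_mc_se: dict[str, float]
    true_log_or: dict[str, float]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "model": list(self.rejection_rate),
                "rejection_rate": list(self.rejection_rate.values()),
                "rejection_mc_se": list(self.rejection_mc_se.values()),
                "mean_pooled_log_or": list(self.mean_pooled_log_or.values()),
                "true_log_or": list(self.true_log_or.values()),
                "mean_bias_log_or": list(self.mean_bias_log_or.values()),
                "bias_mc_se": list(self.bias_mc_se.values()),
                "ci_coverage": list(self.ci_coverage.values()),
                "coverage_mc_se": list(self.coverage_mc_se.values()),
            }
        )


def true_marginal_log_or(scenario: SimScenario, model: GeneticModel) -> float:
    """Population 2x2 log odds ratio implied by the scenario for one model.

    Computed from the exact case/control genotype probabilities at tau = 0
    (for tau > 0 this is the log-OR at the centre of the random-effects
    distribution, by symmetry of the Gaussian perturbation on the log scale).
    """
    ctrl = scenario.control_probs()
    case = ctrl * np.array([1.0, scenario.or_het, scenario.or_hom])
    case = case / case.sum()
    gg, gc, cc = 0, 1, 2
    pairs = {
        GeneticModel.HET: (case[gc], case[gg], ctrl[gc], ctrl[gg]),
        GeneticModel.HOM: (case[cc], case[gg], ctrl[cc], ctrl[gg]),
        GeneticModel.DOM: (case[gc] + case[cc], case[gg], ctrl[gc] + ctrl[cc], ctrl[gg]),
        GeneticModel.REC: (case[cc], case[gg] + case[gc], ctrl[cc], ctrl[gg] + ctrl[gc]),
    }
    a, b, c, d = pairs[GeneticModel(model)]
    return math.log((a * d) / (b * c))


def run_sim_study(
    scenario: SimScenario,
    n_reps: int,
    alpha: float = 0.05,
    config: MetaConfig | None = None,
) -> SimSummary:
    """Repeatedly simulate and analyse; report rejection, bias and coverage.

    Each replicate draws ``scenario.k_studies`` studies, runs the full
    pipeline (:func:`genemeta.pipeline.run_meta`), and records, per genetic
    model on the overall stratum: whether the Z-test rejects at ``alpha``,
    the pooled log-OR, and whether the 95% CI covers the true marginal OR.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    config = config or MetaConfig()
    models = [m.value for m in GeneticModel]
    truth = {m: true_marginal_log_or(scenario, GeneticModel(m)) for m in models}
    rejections = {m: np.zeros(n_reps, dtype=bool) for m in models}
    covered = {m: np.zeros(n_reps, dtype=bool) for m in models}
    pooled_log = {m: np.zeros(n_reps) for m in models}
    for rep in range(n_reps):
        table = simulate_table(scenario, replicate=rep)
        report = run_meta(table, config)
        for m in models:
            res = report.results[(m, "Total")]
            rejections[m][rep] = res.p_assoc < alpha
            pooled_log[m][rep] = res.log_or
            covered[m][rep] = res.ci_low <= math.exp(truth[m]) <= res.ci_high

    def rate_se(x: np.ndarray) -> float:
        r = float(np.mean(x))
        return math.sqrt(r * (1 - r) / n_reps) if n_reps > 1 else float("nan")

    return SimSummary(
        scenario=scenario,
        n_reps=n_reps,
        alpha=alpha,
        rejection_rate={m: float(np.mean(rejections[m])) for m in models},
        rejection_mc_se={m: rate_se(rejections[m]) for m in models},
        mean_pooled_log_or={m: float(np.mean(pooled_log[m])) for m in models},
        mean_bias_log_or={m: float(np.mean(pooled_log[m]) - truth[m]) for m in models},
        bias_mc_se={
            m: float(np.std(pooled_log[m], ddof=1) / math.sqrt(n_reps))
            if n_reps > 1
            else float("nan")
            for m in models
        },
        ci_coverage={m: float(np.mean(covered[m])) for m in models},
        coverage_mc_se={m: rate_se(covered[m]) for m in models},
        true_log_or=truth,
    )
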