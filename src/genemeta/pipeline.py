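"""Orchestration of the full meta-analysis and report export.

:func:`run_meta` takes a study table and configuration and produces a
:class:`MetaReport`: per-study Hardy-Weinberg summaries, pooled odds ratios
for every genetic model in the overall stratum and each subgroup, publication
bias tests per model on the overall stratum, and familywise-adjusted
association p-values within each stratum.  The report serialises to JSON
(full precision, schema-versioned) and to TSV tables shaped like the
characteristics and quantitative-synthesis tables of a typical
genetic-association meta-analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .association import (
    EffectEstimate,
    GeneticModel,
    HweResult,
    collapse,
    hwe_test,
    study_odds_ratio,
)
from .bias import (
    AdjustedPvalues,
    BiasTestResult,
    begg_test,
    bonferroni_adjust,
    egger_test,
    funnel_data,
    holm_adjust,
)
from .pooling import PooledResult, mh_pool, pool_with_selection
from .studies import StudyRecord, StudyTable

__all__ = ["MetaConfig", "MetaReport", "run_meta", "export_report"]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1
MODEL_ORDER = (GeneticModel.HET, GeneticModel.HOM, GeneticModel.DOM, GeneticModel.REC)
OVERALL = "Total"


@dataclass(frozen=True)
class MetaConfig:
    """Analysis configuration; defaults match the conventional thresholds.

    q_threshold
        Heterogeneity significance level for the fixed/random switch.
    hwe_alpha
        Level at which a control arm is flagged as violating HWE.
    fwe_alpha
        Familywise threshold applied to adjusted p-values.
    exclude_hwe_violations
        Sensitivity switch: drop studies whose controls violate HWE.
    fixed_estimator
        "MH" (Mantel-Haenszel) or "IV" (inverse-variance) fixed effects.
    multiplicity_method
        "holm", "bonferroni" or "both".
    """

    q_threshold: float = 0.10
    hwe_alpha: float = 0.05
    ci_level: float = 0.95
    fwe_alpha: float = 0.1
    subgroup_field: str = "ethnicity"
    exclude_hwe_violations: bool = False
    fixed_estimator: str = "MH"
    multiplicity_method: str = "both"
    continuity_correction: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("q_threshold", "hwe_alpha", "ci_level", "fwe_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.fixed_estimator not in ("MH", "IV"):
            raise ValueError("fixed_estimator must be 'MH' or 'IV'")
        if self.multiplicity_method not in ("holm", "bonferroni", "both"):
            raise ValueError("multiplicity_method must be 'holm', 'bonferroni' or 'both'")


@dataclass
class StudySummary:
    """Per-study metadata echo plus the control-arm HWE test."""

    record: StudyRecord
    hwe: HweResult
    hwe_flagged: bool
    excluded: bool


@dataclass
class MetaReport:
    """Complete machine-readable result of one meta-analysis run."""

    study_summaries: list[StudySummary]
    results: dict[tuple[str, str], PooledResult]  # (model, stratum) -> pooled
    effects: dict[tuple[str, str], list[EffectEstimate]]
    bias: dict[str, dict[str, BiasTestResult]]  # model -> {"Begg":…, "Egger":…}
    multiplicity: dict[str, dict[str, AdjustedPvalues]]  # stratum -> method -> adj
    strata: list[str]
    provenance: dict

    def to_dict(self) -> dict:
        """JSON-ready nested dict at full precision (deterministic ordering)."""

        def pooled(p: PooledResult) -> dict:
            d = {
                "model": p.model.value,
                "stratum": p.stratum,
                "k": p.k,
                "method": p.method,
                "or": p.or_,
                "ci_low": p.ci_low,
                "ci_high": p.ci_high,
                "log_or": p.log_or,
                "se": p.se,
                "z": p.z,
                "p_assoc": p.p_assoc,
            }
            d["het"] = (
                None
                if p.het is None
                else {
                    "Q": p.het.Q,
                    "df": p.het.df,
                    "p_Q": p.het.p_Q,
                    "I2": p.het.I2,
                    "tau2": p.het.tau2,
                }
            )
            return d

        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "studies": [
                {
                    "study_id": s.record.study_id,
                    "author": s.record.first_author,
                    "year": s.record.year,
                    "country": s.record.country,
                    "ethnicity": s.record.ethnicity,
                    "method": s.record.genotyping_method,
                    "n_cases": s.record.cases.total(),
                    "n_controls": s.record.controls.total(),
                    "allele_freq_C_controls": s.hwe.allele_freq_C,
                    "hwe_chi2": s.hwe.chi2,
                    "hwe_p": s.hwe.p,
                    "hwe_flagged": s.hwe_flagged,
                    "excluded": s.excluded,
                }
                for s in self.study_summaries
            ],
            "results": [pooled(self.results[k]) for k in sorted(self.results)],
            "effects": {
                f"{m}|{s}": [
                    {
                        "study_id": e.study_id,
                        "log_or": e.log_or,
                        "se": e.se,
                        "or": e.or_,
                        "ci_low": e.ci_low,
                        "ci_high": e.ci_high,
                        "corrected": e.corrected,
                    }
                    for e in self.effects[(m, s)]
                ]
                for m, s in sorted(self.effects)
            },
            "bias": {
                model: {
                    name: {
                        "test": b.test,
                        "k": b.k,
                        "statistic": None if math.isnan(b.statistic) else b.statistic,
                        "p": None if math.isnan(b.p) else b.p,
                        "intercept": b.intercept,
                    }
                    for name, b in sorted(tests.items())
                }
                for model, tests in sorted(self.bias.items())
            },
            "multiplicity": {
                stratum: {
                    method: {
                        "models": [m.value for m in MODEL_ORDER],
                        "raw": list(adj.raw),
                        "adjusted": list(adj.adjusted),
                        "alpha": adj.alpha,
                    }
                    for method, adj in sorted(adjs.items())
                }
                for stratum, adjs in sorted(self.multiplicity.items())
            },
            "strata": self.strata,
            "provenance": self.provenance,
        }


def _input_digest(table: StudyTable) -> str:
    csv = table.to_frame().to_csv(index=False)
    return hashlib.sha256(csv.encode()).hexdigest()


def run_meta(table: StudyTable, config: MetaConfig | None = None) -> MetaReport:
    """Run the complete meta-analysis over all genetic models and strata.

    Strata are the overall pool plus each level of ``config.subgroup_field``.
    Publication-bias tests run per model on the overall stratum (they need
    the full study set); multiplicity adjustment is applied to the four
    association p-values within each stratum.  Deterministic given
    (table, config).
    """
    config = config or MetaConfig()
    if len(table) == 0:
        raise ValueError("empty study table")

    warnings: list[str] = []
    summaries: list[StudySummary] = []
    kept: list[StudyRecord] = []
    for rec in table:
        hwe = hwe_test(rec.controls)
        flagged = hwe.p < config.hwe_alpha
        excluded = flagged and config.exclude_hwe_violations
        summaries.append(StudySummary(rec, hwe, flagged, excluded))
        if excluded:
            warnings.append(f"study {rec.study_id} excluded: control HWE p={hwe.p:.3g}")
        else:
            kept.append(rec)
    if not kept:
        raise ValueError("no studies remain after HWE exclusion")
    analysis = StudyTable(kept)

    strata: dict[str, StudyTable] = {OVERALL: analysis}
    strata.update(analysis.stratify(config.subgroup_field))

    results: dict[tuple[str, str], PooledResult] = {}
    effects_map: dict[tuple[str, str], list[EffectEstimate]] = {}
    for model in MODEL_ORDER:
        for stratum, sub in strata.items():
            if len(sub) == 0:  # pragma: no cover - stratify never yields empties
                warnings.append(f"stratum {stratum} empty; omitted")
                continue
            tables, effects = [], []
            for rec in sub:
                t = collapse(rec.cases, rec.controls, model)
                tables.append(t)
                effects.append(
                    study_odds_ratio(
                        t,
                        study_id=rec.study_id,
                        model=model,
                        continuity_correction=config.continuity_correction,
                    )
                )
            pooled = pool_with_selection(
                tables,
                effects,
                model=model,
                stratum=stratum,
                q_threshold=config.q_threshold,
                fixed_estimator=config.fixed_estimator,
            )
            results[(model.value, stratum)] = pooled
            effects_map[(model.value, stratum)] = effects
            logger.info(
                "%s / %s: k=%d %s OR=%.3f (%.3f-%.3f)",
                model.value,
                stratum,
                pooled.k,
                pooled.method,
                pooled.or_,
                pooled.ci_low,
                pooled.ci_high,
            )

    bias: dict[str, dict[str, BiasTestResult]] = {}
    for model in MODEL_ORDER:
        effects = effects_map[(model.value, OVERALL)]
        tables = [
            collapse(rec.cases, rec.controls, model) for rec in strata[OVERALL]
        ]
        pooled_log_or, pooled_se = mh_pool(tables)
        bias[model.value] = {
            "Begg": begg_test(effects, pooled_log_or, pooled_se, model),
            "Egger": egger_test(effects, model),
        }

    multiplicity: dict[str, dict[str, AdjustedPvalues]] = {}
    methods = (
        ("holm", "bonferroni")
        if config.multiplicity_method == "both"
        else (config.multiplicity_method,)
    )
    for stratum in strata:
        raw = [results[(m.value, stratum)].p_assoc for m in MODEL_ORDER]
        adjusters = {"holm": holm_adjust, "bonferroni": bonferroni_adjust}
        multiplicity[stratum] = {
            m: adjusters[m](raw, alpha=config.fwe_alpha) for m in methods
        }

    provenance = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "input_digest": _input_digest(table),
        "n_studies_input": len(table),
        "n_studies_analysed": len(analysis),
        "warnings": warnings,
    }
    return MetaReport(
        study_summaries=summaries,
        results=results,
        effects=effects_map,
        bias=bias,
        multiplicity=multiplicity,
        strata=list(strata),
        provenance=provenance,
    )


def _fmt(x: float, nd: int = 2) -> str:
    return f"{x:.{nd}f}"


def _table1_frame(report: MetaReport) -> pd.DataFrame:
    rows = []
    for s in report.study_summaries:
        r = s.record
        rows.append(
            {
                "study_id": r.study_id,
                "author": r.first_author,
                "year": r.year,
                "country": r.country,
                "ethnicity": r.ethnicity,
                "method": r.genotyping_method,
                "sample_size": f"{r.cases.total()}/{r.controls.total()}",
                "case_GG": r.cases.n_GG,
                "case_GC": r.cases.n_GC,
                "case_CC": r.cases.n_CC,
                "ctrl_GG": r.controls.n_GG,
                "ctrl_GC": r.controls.n_GC,
                "ctrl_CC": r.controls.n_CC,
                "P_HWE": _fmt(s.hwe.p, 3),
                "excluded": s.excluded,
            }
        )
    return pd.DataFrame(rows)


def _table2_frame(report: MetaReport) -> pd.DataFrame:
    rows = []
    for stratum in report.strata:
        row: dict[str, object] = {"stratum": stratum}
        for model in MODEL_ORDER:
            p = report.results.get((model.value, stratum))
            if p is None:
                continue
            row["k"] = p.k
            row[f"{model.value}_OR_CI"] = (
                f"{_fmt(p.or_)} ({_fmt(p.ci_low)}-{_fmt(p.ci_high)})"
            )
            row[f"{model.value}_pQ"] = _fmt(p.het.p_Q, 3) if p.het else "__"
        rows.append(row)
    return pd.DataFrame(rows)


def _forest_frame(report: MetaReport, model: GeneticModel) -> pd.DataFrame:
    effects = report.effects[(model.value, OVERALL)]
    weights = [1.0 / e.se**2 for e in effects]
    total_w = sum(weights)
    rows = [
        {
            "study_id": e.study_id,
            "OR": e.or_,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "weight_pct": 100.0 * w / total_w,
        }
        for e, w in zip(effects, weights)
    ]
    pooled = report.results[(model.value, OVERALL)]
    rows.append(
        {
            "study_id": f"Pooled ({pooled.method})",
            "OR": pooled.or_,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame(rows)


def export_report(
    report: MetaReport, out_dir: str | Path, formats: tuple[str, ...] = ("json", "tsv")
) -> list[Path]:
    """Write the report to disk; returns the list of files written.

    ``json`` writes the full-precision machine-readable report.  ``tsv``
    writes the study-characteristics table (with HWE p), the pooled-results
    table (OR, CI and heterogeneity p per model x stratum), one forest-data
    TSV per genetic model, and funnel-plot coordinates per model.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "json" in formats:
        path = out / "report.json"
        path.write_text(json.dumps(report.to_dict(), indent=1, sort_keys=False) + "\n")
        written.append(path)
    if "tsv" in formats:
        t1 = out / "studies_hwe.tsv"
        _table1_frame(report).to_csv(t1, sep="\t", index=False)
        written.append(t1)
        t2 = out / "pooled_results.tsv"
        _table2_frame(report).to_csv(t2, sep="\t", index=False)
        written.append(t2)
        for model in MODEL_ORDER:
            if (model.value, OVERALL) not in report.results:
                continue
            f = out / f"forest_{model.value}.tsv"
            _forest_frame(report, model).to_csv(f, sep="\t", index=False)
            written.append(f)
            effects = report.effects[(model.value, OVERALL)]
            if len(effects) >= 2:
                pooled = report.results[(model.value, OVERALL)]
                fd = out / f"funnel_{model.value}.tsv"
                funnel_data(effects, pooled.log_or, pooled.se).to_csv(
                    fd, sep="\t", index=False
                )
                written.append(fd)
    return written
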