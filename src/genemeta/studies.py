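"""Study data model and CSV I/O for case-control genotype tables.

A *study* is one case-control comparison with genotype counts for the three
classes of a biallelic SNP (here rs2910164 G>C: GG, GC, CC; G is the
reference/major allele, C the variant).  The packaged fixture
``table1_rs2910164_bc.csv`` carries the six breast-cancer case-control
studies whose counts drive every number this package reproduces.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "GenotypeCounts",
    "StudyRecord",
    "StudyTable",
    "ValidationFinding",
    "DEFAULT_SCHEMA",
    "load_studies",
    "validate_studies",
    "write_studies",
    "paper_fixture",
    "fixture_path",
]

#: Default CSV column names, mirroring the characteristics table one-to-one.
DEFAULT_SCHEMA: Mapping[str, str] = {
    "study_id": "study_id",
    "author": "author",
    "year": "year",
    "country": "country",
    "ethnicity": "ethnicity",
    "method": "method",
    "case_GG": "case_GG",
    "case_GC": "case_GC",
    "case_CC": "case_CC",
    "ctrl_GG": "ctrl_GG",
    "ctrl_GC": "ctrl_GC",
    "ctrl_CC": "ctrl_CC",
}

_FIXTURE_NAME = "table1_rs2910164_bc.csv"


class SchemaError(ValueError):
    """A required column is missing from the input file."""


class StudyValidationError(ValueError):
    """A study field fails validation on load."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one arm (cases or controls) of a study.

    Attributes
    ----------
    n_GG : int
        Major-allele homozygotes.
    n_GC : int
        Heterozygotes.
    n_CC : int
        Variant-allele homozygotes.
    """

    n_GG: int
    n_GC: int
    n_CC: int

    def __post_init__(self) -> None:
        for name in ("n_GG", "n_GC", "n_CC"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise StudyValidationError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise StudyValidationError(f"{name} must be non-negative, got {v}")

    def total(self) -> int:
        return self.n_GG + self.n_GC + self.n_CC

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_GG, self.n_GC, self.n_CC)


@dataclass(frozen=True)
class StudyRecord:
    """One case-control study: genotype counts plus bibliographic metadata."""

    study_id: str
    first_author: str
    year: int
    country: str
    ethnicity: str
    genotyping_method: str
    cases: GenotypeCounts
    controls: GenotypeCounts

    def __post_init__(self) -> None:
        if not self.study_id:
            raise StudyValidationError("study_id must be non-empty")


@dataclass
class StudyTable:
    """An ordered collection of studies with unique identifiers.

    Order is preserved for reporting; it has no statistical effect.
    """

    records: list[StudyRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.study_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise StudyValidationError(f"duplicate study_id values: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    def subset(self, study_ids: Iterable[str]) -> "StudyTable":
        keep = set(study_ids)
        return StudyTable([r for r in self.records if r.study_id in keep])

    def stratify(self, field_name: str = "ethnicity") -> dict[str, "StudyTable"]:
        """Split into subgroups by a metadata field, preserving record order."""
        groups: dict[str, list[StudyRecord]] = {}
        for r in self.records:
            groups.setdefault(getattr(r, field_name), []).append(r)
        return {k: StudyTable(v) for k, v in groups.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "study_id": r.study_id,
                    "author": r.first_author,
                    "year": r.year,
                    "country": r.country,
                    "ethnicity": r.ethnicity,
                    "method": r.genotyping_method,
                    "case_GG": r.cases.n_GG,
                    "case_GC": r.cases.n_GC,
                    "case_CC": r.cases.n_CC,
                    "ctrl_GG": r.controls.n_GG,
                    "ctrl_GC": r.controls.n_GC,
                    "ctrl_CC": r.controls.n_CC,
                }
            )
        return pd.DataFrame(rows, columns=list(DEFAULT_SCHEMA))


@dataclass(frozen=True)
class ValidationFinding:
    """One validation problem: which study, which field, which rule."""

    study_id: str
    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.study_id}: {self.field}: {self.rule}"


def _parse_count(value: object, study: str, column: str) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise StudyValidationError(
            f"study {study!r}, column {column!r}: {value!r} is not a number"
        ) from None
    if f != int(f):
        raise StudyValidationError(
            f"study {study!r}, column {column!r}: count {value!r} is not an integer"
        )
    n = int(f)
    if n < 0:
        raise StudyValidationError(
            f"study {study!r}, column {column!r}: count {n} is negative"
        )
    return n


def load_studies(
    path: str | Path | io.IOBase,
    schema: Mapping[str, str] | None = None,
) -> StudyTable:
    """Read a study table from CSV.

    Parameters
    ----------
    path
        CSV file (UTF-8, header row required) or an open text buffer.
    schema
        Optional mapping from the canonical field names in
        :data:`DEFAULT_SCHEMA` to the column names actually used in the file.

    Returns
    -------
    StudyTable
        One :class:`StudyRecord` per data row.  Percentage columns, if any,
        are ignored: counts are the sufficient statistic.

    Raises
    ------
    SchemaError
        If a required column is missing.
    StudyValidationError
        If a count fails to parse as a non-negative integer, or study
        identifiers are duplicated.
    """
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    records = []
    for _, row in df.iterrows():
        sid = str(row[cols["study_id"]])
        counts = {
            k: _parse_count(row[cols[k]], sid, cols[k])
            for k in ("case_GG", "case_GC", "case_CC", "ctrl_GG", "ctrl_GC", "ctrl_CC")
        }
        records.append(
            StudyRecord(
                study_id=sid,
                first_author=str(row[cols["author"]]),
                year=int(row[cols["year"]]),
                country=str(row[cols["country"]]),
                ethnicity=str(row[cols["ethnicity"]]),
                genotyping_method=str(row[cols["method"]]),
                cases=GenotypeCounts(counts["case_GG"], counts["case_GC"], counts["case_CC"]),
                controls=GenotypeCounts(counts["ctrl_GG"], counts["ctrl_GC"], counts["ctrl_CC"]),
            )
        )
    return StudyTable(records)


def validate_studies(table: StudyTable) -> list[ValidationFinding]:
    """Check a study table for per-record problems.

    Findings are returned, never raised; an empty list means the table is
    clean.  Checked rules: non-empty arms, non-negative counts (in case a
    record was constructed by bypassing the dataclass validation, e.g. via
    ``object.__setattr__``), non-empty ethnicity label.
    """
    findings: list[ValidationFinding] = []
    for r in table:
        for arm_name, arm in (("cases", r.cases), ("controls", r.controls)):
            for geno in ("n_GG", "n_GC", "n_CC"):
                if getattr(arm, geno) < 0:
                    findings.append(
                        ValidationFinding(r.study_id, f"{arm_name}.{geno}", "negative count")
                    )
            if arm.total() <= 0:
                findings.append(
                    ValidationFinding(r.study_id, arm_name, f"empty {arm_name[:-1]} arm")
                )
        if not r.ethnicity.strip():
            findings.append(ValidationFinding(r.study_id, "ethnicity", "empty subgroup label"))
    return findings


def write_studies(table: StudyTable, path: str | Path | io.IOBase) -> None:
    """Write a study table to CSV in the default schema (lossless round-trip)."""
    table.to_frame().to_csv(path, index=False)


def fixture_path() -> Path:
    """Filesystem path of the packaged six-study rs2910164 fixture CSV."""
    return Path(str(resources.files("genemeta.data") / _FIXTURE_NAME))


def paper_fixture() -> StudyTable:
    """The six published breast-cancer case-control studies of rs2910164.

    4225 cases and 4469 controls across four European, one Asian and one
    mixed-population study.
    """
    return load_studies(fixture_path())
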