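"""Per-study summary tables: schema, validation, TSV/CSV round-trip.

The unit of input is one association study of a biallelic risk variant:
a case-control arm pair with risk-allele frequencies (and optionally
genotype counts), and/or a set of parent-offspring trios with
transmitted/untransmitted risk-allele counts.  A :class:`StudyTable` is
an ordered, validated collection of such records.

The packaged fixture ``kcnj11_t2d_table1.tsv`` transcribes the published
48-study KCNJ11 E23K (rs5219) / type 2 diabetes table: 47 case-control
studies (56,349 cases, 81,800 controls) and two family studies totalling
483 trios.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import pandas as pd

__all__ = [
    "Design",
    "StudyRecord",
    "StudyTable",
    "StudyTableError",
    "TableSummary",
    "COLUMNS",
    "MANDATORY_COLUMNS",
    "read_study_table",
    "write_study_table",
    "summarize_table",
    "load_table1",
]

#: tolerance between a reported allele frequency and the frequency
#: implied by genotype counts, (het + 2*hom)/(2N)
GENOTYPE_MAF_TOL = 0.005


class Design(str, enum.Enum):
    """Study design: case-control, trio-based, or both arms present."""

    POPULATION = "population"
    FAMILY = "family"
    BOTH = "both"

    def has_case_control(self) -> bool:
        return self in (Design.POPULATION, Design.BOTH)

    def has_trios(self) -> bool:
        return self in (Design.FAMILY, Design.BOTH)


class StudyTableError(ValueError):
    """Schema, parse or validation failure for a study table."""


GenotypeCounts = tuple[int, int, int]  # (EE, EK, KK): non-risk hom, het, risk hom


@dataclass(frozen=True)
class StudyRecord:
    """One study row: arm sizes, allele frequencies, optional genotype,
    trio and covariate data."""

    study_id: str
    year: int
    ethnicity: str
    design: Design
    n_cases: int = 0
    n_controls: int = 0
    maf_cases: Optional[float] = None
    maf_controls: Optional[float] = None
    genotype_counts_cases: Optional[GenotypeCounts] = None
    genotype_counts_controls: Optional[GenotypeCounts] = None
    n_trios: Optional[int] = None
    transmitted: Optional[int] = None
    untransmitted: Optional[int] = None
    bmi_cases: Optional[float] = None
    bmi_controls: Optional[float] = None
    age_cases: Optional[float] = None
    age_controls: Optional[float] = None
    pct_male_cases: Optional[float] = None
    pct_male_controls: Optional[float] = None
    hwe_p: Optional[str] = None

    def validation_errors(self) -> list[str]:
        """All invariant violations for this record (empty list if valid)."""
        errs: list[str] = []
        if not self.study_id:
            errs.append("study_id is empty")
        if self.n_cases < 0 or self.n_controls < 0:
            errs.append("arm sizes must be non-negative")
        if self.design.has_case_control() and (self.n_cases <= 0 or self.n_controls <= 0):
            errs.append(
                f"design={self.design.value} requires positive case and control arms"
            )
        for name in ("maf_cases", "maf_controls"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                errs.append(f"{name}={v} outside [0, 1]")
        for arm, counts, n, maf in (
            ("cases", self.genotype_counts_cases, self.n_cases, self.maf_cases),
            ("controls", self.genotype_counts_controls, self.n_controls, self.maf_controls),
        ):
            if counts is None:
                continue
            if any(c < 0 for c in counts):
                errs.append(f"negative genotype count in {arm}")
                continue
            if sum(counts) != n:
                errs.append(
                    f"genotype counts in {arm} sum to {sum(counts)}, arm size is {n}"
                )
            elif maf is not None and n > 0:
                implied = (counts[1] + 2 * counts[2]) / (2 * n)
                if abs(implied - maf) > GENOTYPE_MAF_TOL:
                    errs.append(
                        f"genotype-implied frequency {implied:.4f} in {arm} "
                        f"disagrees with reported {maf:.4f}"
                    )
        if self.design.has_trios():
            if not self.n_trios or self.n_trios <= 0:
                errs.append(f"design={self.design.value} requires n_trios > 0")
        if (self.transmitted is None) != (self.untransmitted is None):
            errs.append("transmitted/untransmitted must be present together")
        for name in ("n_trios", "transmitted", "untransmitted"):
            v = getattr(self, name)
            if v is not None and v < 0:
                errs.append(f"{name} must be non-negative")
        return errs


@dataclass
class StudyTable:
    """Ordered collection of validated study records."""

    records: list[StudyRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise StudyTableError("study table must contain at least one record")
        seen: set[str] = set()
        for rec in self.records:
            if rec.study_id in seen:
                raise StudyTableError(f"duplicate study_id {rec.study_id!r}")
            seen.add(rec.study_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def case_control_records(self) -> list[StudyRecord]:
        """Records contributing a case-control arm (population or both)."""
        return [r for r in self.records if r.design.has_case_control()]

    def family_records(self) -> list[StudyRecord]:
        """Records contributing trios (family or both)."""
        return [r for r in self.records if r.design.has_trios()]

    def get(self, study_id: str) -> StudyRecord:
        for rec in self.records:
            if rec.study_id == study_id:
                return rec
        raise KeyError(study_id)


@dataclass(frozen=True)
class TableSummary:
    total_cases: int
    total_controls: int
    total_trios: int
    studies_per_ethnicity: dict[str, int]
    k: int


# TSV schema: genotype triples and trio columns are flattened.
MANDATORY_COLUMNS = (
    "study_id", "year", "ethnicity", "design", "n_cases", "n_controls",
)
OPTIONAL_COLUMNS = (
    "maf_cases", "maf_controls",
    "ee_cases", "ek_cases", "kk_cases",
    "ee_controls", "ek_controls", "kk_controls",
    "n_trios", "transmitted", "untransmitted",
    "bmi_cases", "bmi_controls", "age_cases", "age_controls",
    "pct_male_cases", "pct_male_controls", "hwe_p",
)
COLUMNS = MANDATORY_COLUMNS + OPTIONAL_COLUMNS

_NA_STRINGS = {"", "NA", "na", "NaN", "nan", "None"}


def _cell(df_row: pd.Series, col: str) -> Optional[str]:
    if col not in df_row.index:
        return None
    v = df_row[col]
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    s = str(v).strip()
    return None if s in _NA_STRINGS else s


def _parse_int(s: Optional[str], col: str, row: int) -> Optional[int]:
    if s is None:
        return None
    try:
        f = float(s)
        if f != int(f):
            raise ValueError
        return int(f)
    except ValueError:
        raise StudyTableError(
            f"row {row}: non-integer value {s!r} in column {col!r}"
        ) from None


def _parse_float(s: Optional[str], col: str, row: int) -> Optional[float]:
    if s is None:
        return None
    try:
        return float(s)
    except ValueError:
        raise StudyTableError(
            f"row {row}: non-numeric value {s!r} in column {col!r}"
        ) from None


def _triple(row: pd.Series, cols: tuple[str, str, str], idx: int) -> Optional[GenotypeCounts]:
    vals = [_parse_int(_cell(row, c), c, idx) for c in cols]
    if all(v is None for v in vals):
        return None
    if any(v is None for v in vals):
        raise StudyTableError(
            f"row {idx}: genotype counts {cols} must be all present or all absent"
        )
    return (vals[0], vals[1], vals[2])  # type: ignore[return-value]


def read_study_table(path, dialect: str = "tsv", provenance: str = "") -> StudyTable:
    """Read and validate a study table from a TSV or CSV file.

    Every row is parsed into a :class:`StudyRecord`; invariant violations
    are collected and raised together with 1-based data-row indices.
    Empty cells and ``NA`` both denote a missing optional value.
    """
    if dialect not in ("tsv", "csv"):
        raise StudyTableError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise StudyTableError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[StudyRecord] = []
    problems: list[str] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        sid = _cell(row, "study_id") or ""
        design_s = _cell(row, "design") or ""
        try:
            design = Design(design_s)
        except ValueError:
            problems.append(f"row {i}: unknown design {design_s!r}")
            continue
        try:
            rec = StudyRecord(
                study_id=sid,
                year=_parse_int(_cell(row, "year"), "year", i) or 0,
                ethnicity=_cell(row, "ethnicity") or "",
                design=design,
                n_cases=_parse_int(_cell(row, "n_cases"), "n_cases", i) or 0,
                n_controls=_parse_int(_cell(row, "n_controls"), "n_controls", i) or 0,
                maf_cases=_parse_float(_cell(row, "maf_cases"), "maf_cases", i),
                maf_controls=_parse_float(_cell(row, "maf_controls"), "maf_controls", i),
                genotype_counts_cases=_triple(row, ("ee_cases", "ek_cases", "kk_cases"), i),
                genotype_counts_controls=_triple(
                    row, ("ee_controls", "ek_controls", "kk_controls"), i
                ),
                n_trios=_parse_int(_cell(row, "n_trios"), "n_trios", i),
                transmitted=_parse_int(_cell(row, "transmitted"), "transmitted", i),
                untransmitted=_parse_int(_cell(row, "untransmitted"), "untransmitted", i),
                bmi_cases=_parse_float(_cell(row, "bmi_cases"), "bmi_cases", i),
                bmi_controls=_parse_float(_cell(row, "bmi_controls"), "bmi_controls", i),
                age_cases=_parse_float(_cell(row, "age_cases"), "age_cases", i),
                age_controls=_parse_float(_cell(row, "age_controls"), "age_controls", i),
                pct_male_cases=_parse_float(_cell(row, "pct_male_cases"), "pct_male_cases", i),
                pct_male_controls=_parse_float(
                    _cell(row, "pct_male_controls"), "pct_male_controls", i
                ),
                hwe_p=_cell(row, "hwe_p"),
            )
        except StudyTableError as exc:
            problems.append(str(exc))
            continue
        errs = rec.validation_errors()
        if errs:
            problems.extend(f"row {i} ({sid}): {e}" for e in errs)
        else:
            records.append(rec)
    if problems:
        raise StudyTableError("invalid study table:\n  " + "\n  ".join(problems))
    return StudyTable(records=records, provenance=provenance or str(path))


def _format_cell(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)
    if isinstance(v, Design):
        return v.value
    return str(v)


def write_study_table(table: StudyTable, path, dialect: str = "tsv") -> None:
    """Write a study table; ``read_study_table`` round-trips it exactly."""
    if dialect not in ("tsv", "csv"):
        raise StudyTableError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    sep = "\t" if dialect == "tsv" else ","
    rows = []
    for rec in table.records:
        gc = rec.genotype_counts_cases or (None, None, None)
        gn = rec.genotype_counts_controls or (None, None, None)
        rows.append({
            "study_id": rec.study_id, "year": rec.year,
            "ethnicity": rec.ethnicity, "design": rec.design,
            "n_cases": rec.n_cases, "n_controls": rec.n_controls,
            "maf_cases": rec.maf_cases, "maf_controls": rec.maf_controls,
            "ee_cases": gc[0], "ek_cases": gc[1], "kk_cases": gc[2],
            "ee_controls": gn[0], "ek_controls": gn[1], "kk_controls": gn[2],
            "n_trios": rec.n_trios, "transmitted": rec.transmitted,
            "untransmitted": rec.untransmitted,
            "bmi_cases": rec.bmi_cases, "bmi_controls": rec.bmi_controls,
            "age_cases": rec.age_cases, "age_controls": rec.age_controls,
            "pct_male_cases": rec.pct_male_cases,
            "pct_male_controls": rec.pct_male_controls,
            "hwe_p": rec.hwe_p,
        })
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    df = df.map(_format_cell)
    df.to_csv(path, sep=sep, index=False, encoding="utf-8")


def summarize_table(table: StudyTable) -> TableSummary:
    """Column totals: cases/controls over case-control arms, trios over
    family arms, and study counts per ethnicity label."""
    cc = table.case_control_records()
    fam = table.family_records()
    eth: dict[str, int] = {}
    for rec in table.records:
        eth[rec.ethnicity] = eth.get(rec.ethnicity, 0) + 1
    return TableSummary(
        total_cases=sum(r.n_cases for r in cc),
        total_controls=sum(r.n_controls for r in cc),
        total_trios=sum(r.n_trios or 0 for r in fam),
        studies_per_ethnicity=eth,
        k=len(table),
    )


def load_table1() -> StudyTable:
    """The packaged 48-study KCNJ11 E23K / T2D fixture table."""
    ref = resources.files("snpmeta.data").joinpath("kcnj11_t2d_table1.tsv")
    with resources.as_file(ref) as p:
        return read_study_table(p, dialect="tsv", provenance="kcnj11_t2d_table1")
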