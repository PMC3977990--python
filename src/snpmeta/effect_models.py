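"""Per-study effect sizes: 2x2 tables, Woolf log odds ratios, HWE test.

Genetic-model contrasts for a biallelic variant with non-risk allele E
and risk allele K:

=============  =======================================
allele         K vs E allele counts (2 per individual)
heterozygous   EK vs EE individuals
homozygous     KK vs EE individuals
dominant       EK+KK vs EE individuals
recessive      KK vs EE+EK individuals
=============  =======================================

The log odds ratio is ``ln(ad/bc)`` with Woolf variance
``1/a + 1/b + 1/c + 1/d``.  When any cell is zero, the
Haldane-Anscombe correction adds 0.5 to all four cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from .study_io import Design, StudyRecord, StudyTable

__all__ = [
    "MODELS",
    "ContingencyTable",
    "EffectEstimate",
    "allele_table_from_maf",
    "genotype_table",
    "log_odds_ratio",
    "hwe_chi2",
    "allele_estimates",
    "genotype_estimates",
]

#: genetic models computable from a 2x2 table (tdt is handled separately)
MODELS = ("allele", "heterozygous", "homozygous", "dominant", "recessive")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 exposure-by-status counts.

    ``a``/``b``: exposed/unexposed among cases; ``c``/``d``: the same
    among controls.  Cells are floats because the zero-cell correction
    adds 0.5 to every cell.
    """

    a: float
    b: float
    c: float
    d: float
    correction_applied: bool = False

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.a + self.b <= 0 or self.c + self.d <= 0:
            raise ValueError("each arm must contain observations")


@dataclass(frozen=True)
class EffectEstimate:
    """Per-study log odds ratio with its (Woolf) variance."""

    study_id: str
    model: str
    log_or: float
    variance: float
    design: Design = Design.POPULATION

    def __post_init__(self) -> None:
        if not (self.variance > 0 and math.isfinite(self.variance)):
            raise ValueError(f"variance must be positive and finite, got {self.variance}")
        if not math.isfinite(self.log_or):
            raise ValueError("log_or must be finite")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _maybe_correct(a: float, b: float, c: float, d: float) -> ContingencyTable:
    if min(a, b, c, d) == 0:
        return ContingencyTable(a + 0.5, b + 0.5, c + 0.5, d + 0.5, correction_applied=True)
    return ContingencyTable(a, b, c, d)


def allele_table_from_maf(
    n_cases: int, n_controls: int, maf_cases: float, maf_controls: float
) -> ContingencyTable:
    """Reconstruct the allele-contrast 2x2 table from arm sizes and
    risk-allele frequencies.

    Risk-allele counts are the nearest integer (half away from zero) of
    ``2*N*frequency`` per arm; the complementary cell absorbs the
    remainder so each arm contributes exactly ``2*N`` alleles.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("both arms must be non-empty")
    for f in (maf_cases, maf_controls):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"allele frequency {f} outside [0, 1]")
    a = _round_half_away(2 * n_cases * maf_cases)
    b = 2 * n_cases - a
    c = _round_half_away(2 * n_controls * maf_controls)
    d = 2 * n_controls - c
    return _maybe_correct(a, b, c, d)


def genotype_table(record: StudyRecord, model: str) -> ContingencyTable:
    """2x2 table for a genotype-based model from a study's genotype counts.

    Raises ``ValueError`` naming the study when genotype counts are absent.
    """
    if model not in ("heterozygous", "homozygous", "dominant", "recessive", "allele"):
        raise ValueError(f"unknown model {model!r}")
    gc = record.genotype_counts_cases
    gn = record.genotype_counts_controls
    if gc is None or gn is None:
        raise ValueError(
            f"model {model!r} unavailable for study {record.study_id!r}: "
            "genotype counts absent"
        )
    (ee1, ek1, kk1), (ee0, ek0, kk0) = gc, gn
    if model == "heterozygous":
        cells = (ek1, ee1, ek0, ee0)
    elif model == "homozygous":
        cells = (kk1, ee1, kk0, ee0)
    elif model == "dominant":
        cells = (ek1 + kk1, ee1, ek0 + kk0, ee0)
    elif model == "recessive":
        cells = (kk1, ee1 + ek1, kk0, ee0 + ek0)
    else:  # allele contrast straight from genotype counts
        cells = (ek1 + 2 * kk1, ek1 + 2 * ee1, ek0 + 2 * kk0, ek0 + 2 * ee0)
    return _maybe_correct(*map(float, cells))


def log_odds_ratio(
    table: ContingencyTable,
    study_id: str = "",
    model: str = "allele",
    design: Design = Design.POPULATION,
) -> EffectEstimate:
    """Log odds ratio ``ln(ad/bc)`` with Woolf variance ``Σ 1/cell``."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) <= 0:
        raise ValueError("all cells must be positive (apply the 0.5 correction first)")
    return EffectEstimate(
        study_id=study_id,
        model=model,
        log_or=math.log((a * d) / (b * c)),
        variance=1 / a + 1 / b + 1 / c + 1 / d,
        design=design,
    )


def hwe_chi2(genotypes: Sequence[int]) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit test for Hardy-Weinberg equilibrium.

    ``genotypes`` is the (EE, EK, KK) count triple for one arm.  Expected
    counts are ``N*(q^2, 2pq, p^2)`` at the sample allele frequency
    ``p = (EK + 2*KK)/(2N)``.  A monomorphic sample fits HWE trivially:
    (0, 1) is returned.
    """
    ee, ek, kk = genotypes
    if min(ee, ek, kk) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = ee + ek + kk
    if n <= 0:
        raise ValueError("at least one genotyped individual required")
    p = (ek + 2 * kk) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 0.0, 1.0
    q = 1.0 - p
    expected = (n * q * q, 2 * n * p * q, n * p * p)
    chi2 = sum((o - e) ** 2 / e for o, e in zip((ee, ek, kk), expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def allele_estimates(
    table: StudyTable, designs: Optional[Sequence[Design]] = None
) -> list[EffectEstimate]:
    """Allele-contrast estimates for every record with a case-control arm
    and reported frequencies in both arms.

    Family-only rows are skipped (no case-control counts); a ``both``
    design contributes its case-control arm.
    """
    out: list[EffectEstimate] = []
    for rec in table.records:
        if not rec.design.has_case_control():
            continue
        if designs is not None and rec.design not in designs:
            continue
        if rec.maf_cases is None or rec.maf_controls is None:
            continue
        t = allele_table_from_maf(rec.n_cases, rec.n_controls, rec.maf_cases, rec.maf_controls)
        out.append(log_odds_ratio(t, study_id=rec.study_id, model="allele", design=rec.design))
    return out


def genotype_estimates(table: StudyTable, model: str) -> list[EffectEstimate]:
    """Genotype-model estimates for every record carrying genotype counts."""
    out: list[EffectEstimate] = []
    for rec in table.records:
        if not rec.design.has_case_control():
            continue
        if rec.genotype_counts_cases is None or rec.genotype_counts_controls is None:
            continue
        t = genotype_table(rec, model)
        out.append(log_odds_ratio(t, study_id=rec.study_id, model=model, design=rec.design))
    return out
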