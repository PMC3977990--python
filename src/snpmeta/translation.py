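"""Translational quantities: attributable risk, power, allele frequencies.

* Population attributable risk of a risk allele with odds ratio ``OR``
  and population frequency ``f``: ``PAR = (OR − 1)/OR × f``.
* Sample size for a two-sided two-proportion test on allele counts
  (2 alleles per individual, case:control allocation r):
  ``p1 = p0·OR / (1 − p0 + p0·OR)`` and the required risk-allele sample
  per case group is ``m = (z_{1−α/2} + z_{1−β})²·(p1 q1 + p0 q0 / r) /
  (p1 − p0)²`` alleles, i.e. ``⌈m/2⌉`` individuals.
* Descriptive control-allele-frequency summaries weighted by control
  arm size, with a between-study weighted standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .study_io import StudyTable

__all__ = [
    "PowerSpec",
    "PowerResult",
    "FrequencySummary",
    "par",
    "sample_size_for_power",
    "control_freq_summary",
]


def par(or_: float, raf: float) -> float:
    """Population attributable risk ``(OR − 1)/OR × raf``.

    Negative for protective alleles (``OR < 1``).
    """
    if or_ <= 0:
        raise ValueError("odds ratio must be positive")
    if not 0.0 <= raf <= 1.0:
        raise ValueError("risk allele frequency must lie in [0, 1]")
    return (or_ - 1.0) / or_ * raf


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a per-allele case-control power calculation."""

    p0: float                 # control risk-allele frequency
    or_per_allele: float
    alpha: float = 0.05       # two-sided
    power: float = 0.80
    allocation: float = 1.0   # controls per case

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must lie in (0, 1)")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must lie strictly in (0, 1)")
        if self.or_per_allele <= 0:
            raise ValueError("odds ratio must be positive")
        if self.or_per_allele == 1.0:
            raise ValueError("or_per_allele = 1 requires an infinite sample")
        if self.allocation <= 0:
            raise ValueError("allocation ratio must be positive")


@dataclass(frozen=True)
class PowerResult:
    n_cases: int              # individuals
    n_controls: int
    n_rounded: int            # cases, rounded to the nearest hundred
    p1: float                 # implied case risk-allele frequency


def sample_size_for_power(spec: PowerSpec) -> PowerResult:
    """Individuals per group for a two-sided allele-contrast test."""
    p0, r = spec.p0, spec.allocation
    odds1 = p0 / (1.0 - p0) * spec.or_per_allele
    p1 = odds1 / (1.0 + odds1)
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0) + stats.norm.ppf(spec.power)
    m_alleles = z**2 * (p1 * (1 - p1) + p0 * (1 - p0) / r) / (p1 - p0) ** 2
    n_cases = math.ceil(m_alleles / 2.0)
    n_controls = math.ceil(r * m_alleles / 2.0)
    return PowerResult(
        n_cases=n_cases,
        n_controls=n_controls,
        n_rounded=int(round(n_cases / 100.0)) * 100,
        p1=float(p1),
    )


@dataclass(frozen=True)
class FrequencySummary:
    mean: float               # control-sample-size weighted
    minimum: float
    maximum: float
    ci_low: float
    ci_high: float
    k: int


def control_freq_summary(
    table: StudyTable, ethnicity: Optional[str] = None
) -> FrequencySummary:
    """Control risk-allele frequency summary over (optionally filtered)
    studies.

    The mean weights each study by its control arm size.  The CI is
    descriptive: weighted between-study standard deviation divided by
    ``√k``, times the normal 0.975 quantile.
    """
    recs = [
        r for r in table.case_control_records()
        if r.maf_controls is not None
        and (ethnicity is None or r.ethnicity == ethnicity)
    ]
    if not recs:
        raise ValueError(
            f"no case-control study with a control frequency matches "
            f"ethnicity={ethnicity!r}"
        )
    f = np.array([r.maf_controls for r in recs])
    n = np.array([r.n_controls for r in recs], dtype=float)
    mean = float(np.sum(n * f) / np.sum(n))
    k = len(recs)
    if k > 1:
        var_w = float(np.sum(n * (f - mean) ** 2) / np.sum(n)) * k / (k - 1)
        se = math.sqrt(var_w / k)
    else:
        se = 0.0
    z = float(stats.norm.ppf(0.975))
    return FrequencySummary(
        mean=mean, minimum=float(f.min()), maximum=float(f.max()),
        ci_low=mean - z * se, ci_high=mean + z * se, k=k,
    )
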