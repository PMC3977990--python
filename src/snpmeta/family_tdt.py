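"""Family-based (trio) effect sizes and cross-design combination.

The transmission disequilibrium test compares risk alleles transmitted
(``T``) versus not transmitted (``U``) from heterozygous parents to
affected offspring; under the null each is transmitted with probability
one half, so ``OR_TDT = T/U`` with ``var(ln OR) = 1/T + 1/U``.  Because
transmissions are internal to families, the TDT is robust to population
stratification.

Case-control and trio estimates are combined in two stages: each design
is pooled by DerSimonian-Laird separately, and the two design-level
estimates are then combined by inverse variance; a 1-df Q statistic
tests cross-design consistency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from .effect_models import EffectEstimate
from .pooling import PooledResult, Z_95, pool_dl
from .study_io import Design, StudyTable

__all__ = [
    "TdtCounts",
    "DesignCombination",
    "tdt_effect",
    "tdt_estimates",
    "pool_tdt",
    "combine_designs",
]


@dataclass(frozen=True)
class TdtCounts:
    """Transmitted/untransmitted risk-allele counts for one trio study."""

    study_id: str
    transmitted: int
    untransmitted: int

    def __post_init__(self) -> None:
        if self.transmitted < 0 or self.untransmitted < 0:
            raise ValueError("transmission counts must be non-negative")
        if self.transmitted + self.untransmitted == 0:
            raise ValueError("at least one informative transmission required")


def tdt_effect(counts: TdtCounts) -> EffectEstimate:
    """TDT log odds ratio ``ln(T/U)`` with variance ``1/T + 1/U``.

    If either count is zero, 0.5 is added to both (Haldane correction).
    """
    t, u = float(counts.transmitted), float(counts.untransmitted)
    if t == 0 or u == 0:
        t, u = t + 0.5, u + 0.5
    return EffectEstimate(
        study_id=counts.study_id,
        model="tdt",
        log_or=math.log(t / u),
        variance=1.0 / t + 1.0 / u,
        design=Design.FAMILY,
    )


def tdt_estimates(table: StudyTable) -> list[EffectEstimate]:
    """TDT estimates for every record with transmission counts."""
    out = []
    for rec in table.family_records():
        if rec.transmitted is None or rec.untransmitted is None:
            continue
        out.append(tdt_effect(TdtCounts(rec.study_id, rec.transmitted, rec.untransmitted)))
    return out


def pool_tdt(counts: Sequence[TdtCounts]) -> PooledResult:
    """DerSimonian-Laird pool of TDT effect sizes."""
    return pool_dl([tdt_effect(c) for c in counts])


@dataclass(frozen=True)
class DesignCombination:
    """Two-stage combination of case-control and family-based evidence."""

    combined: PooledResult
    case_control: Optional[PooledResult]
    tdt: Optional[PooledResult]
    q_design: float      # NaN when only one design is present
    p_design: float


def _inverse_variance_combine(parts: list[PooledResult], k_total: int) -> PooledResult:
    W = [1.0 / p.se**2 for p in parts]
    theta = [p.pooled_log_or for p in parts]
    sw = sum(W)
    pooled = sum(w * t for w, t in zip(W, theta)) / sw
    se = sw**-0.5
    z = pooled / se
    q = sum(w * (t - pooled) ** 2 for w, t in zip(W, theta))
    df = len(parts) - 1
    return PooledResult(
        k=k_total, pooled_log_or=pooled, se=se,
        ci_low=math.exp(pooled - Z_95 * se), ci_high=math.exp(pooled + Z_95 * se),
        z=z, p_z=float(2 * stats.norm.sf(abs(z))),
        Q=q, df=df, p_q=float(stats.chi2.sf(q, df)) if df > 0 else 1.0,
        tau2=0.0, i2=0.0, method="two-stage",
    )


def combine_designs(
    cc_estimates: Sequence[EffectEstimate],
    tdt_estimates: Sequence[EffectEstimate],
) -> DesignCombination:
    """Combine case-control and TDT estimates across designs.

    Each non-empty design is pooled by DL; the design-level estimates are
    combined by inverse variance.  ``q_design`` (1 df) tests whether the
    two designs estimate the same effect.  If one list is empty the other
    design's pool is returned with ``q_design = NaN`` and a warning.
    """
    if not cc_estimates and not tdt_estimates:
        raise ValueError("at least one design must contribute estimates")
    cc = pool_dl(cc_estimates) if cc_estimates else None
    td = pool_dl(tdt_estimates) if tdt_estimates else None
    if cc is None or td is None:
        only = cc if cc is not None else td
        warnings.warn(
            "only one design present: cross-design Q is undefined", stacklevel=2
        )
        return DesignCombination(
            combined=only, case_control=cc, tdt=td,
            q_design=math.nan, p_design=math.nan,
        )
    combined = _inverse_variance_combine([cc, td], k_total=cc.k + td.k)
    return DesignCombination(
        combined=combined, case_control=cc, tdt=td,
        q_design=combined.Q, p_design=combined.p_q,
    )
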