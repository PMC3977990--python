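"""Inverse-variance pooling: fixed effect, DerSimonian-Laird random
effects, heterogeneity decomposition, subgroups, leave-one-out.

Given per-study log odds ratios ``y_i`` with variances ``v_i``:

fixed effect
    weights ``w_i = 1/v_i``; pooled ``θ̂ = Σw_i y_i / Σw_i``;
    ``se = (Σw_i)^(-1/2)``; Cochran's ``Q = Σw_i (y_i − θ̂)²`` on
    ``k−1`` df; ``I² = max(0, (Q − df)/Q)``.

DerSimonian-Laird
    moments estimate ``τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))`` from
    the fixed-effect weights, then inverse-variance pooling with
    ``w*_i = 1/(v_i + τ²)``.

Confidence intervals use the normal 0.975 quantile (1.959964...),
reported on the odds-ratio scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .effect_models import EffectEstimate

__all__ = [
    "Z_95",
    "PooledResult",
    "SubgroupResult",
    "pool_fixed",
    "pool_dl",
    "pool_subgroups",
    "leave_one_out",
]

Z_95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class PooledResult:
    """Pooled log odds ratio with heterogeneity decomposition."""

    k: int
    pooled_log_or: float
    se: float
    ci_low: float        # OR scale
    ci_high: float       # OR scale
    z: float
    p_z: float
    Q: float
    df: int
    p_q: float
    tau2: float
    i2: float
    method: str          # "fixed" or "dl"

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.pooled_log_or)


@dataclass(frozen=True)
class SubgroupResult:
    """Stratified pooling with a between-subgroup heterogeneity test.

    ``q_between`` compares the subgroup-level pooled estimates by
    inverse-variance weighting (``W_g = 1/se_g²``) against their weighted
    mean, referred to a chi-square on ``levels − 1`` df.
    """

    variable: str
    levels: dict[str, PooledResult]
    q_between: float
    df_between: int
    p_between: float


def _arrays(estimates: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    if not estimates:
        raise ValueError("at least one estimate is required")
    y = np.array([e.log_or for e in estimates], dtype=float)
    v = np.array([e.variance for e in estimates], dtype=float)
    if np.any(v <= 0):
        raise ValueError("all variances must be positive")
    return y, v


def _assemble(y: np.ndarray, v: np.ndarray, tau2: float, method: str) -> PooledResult:
    k = y.size
    w_fixed = 1.0 / v
    pooled_f = float(np.sum(w_fixed * y) / np.sum(w_fixed))
    Q = float(np.sum(w_fixed * (y - pooled_f) ** 2))
    df = k - 1
    p_q = float(stats.chi2.sf(Q, df)) if df > 0 else 1.0
    i2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0

    w = 1.0 / (v + tau2)
    pooled = float(np.sum(w * y) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = pooled / se
    p_z = float(2 * stats.norm.sf(abs(z)))
    return PooledResult(
        k=k, pooled_log_or=pooled, se=se,
        ci_low=math.exp(pooled - Z_95 * se), ci_high=math.exp(pooled + Z_95 * se),
        z=z, p_z=p_z, Q=Q, df=df, p_q=p_q, tau2=tau2, i2=i2, method=method,
    )


def pool_fixed(estimates: Sequence[EffectEstimate]) -> PooledResult:
    """Fixed-effect (inverse-variance) pooled estimate with Cochran's Q."""
    y, v = _arrays(estimates)
    return _assemble(y, v, tau2=0.0, method="fixed")


def dl_tau2(y: np.ndarray, v: np.ndarray) -> float:
    """DerSimonian-Laird moments estimate of the between-study variance."""
    if y.size < 2:
        return 0.0
    w = 1.0 / v
    sw = np.sum(w)
    pooled = np.sum(w * y) / sw
    Q = np.sum(w * (y - pooled) ** 2)
    denom = sw - np.sum(w**2) / sw
    if denom <= 0:
        return 0.0
    return float(max(0.0, (Q - (y.size - 1)) / denom))


def pool_dl(estimates: Sequence[EffectEstimate]) -> PooledResult:
    """DerSimonian-Laird random-effects pooled estimate.

    With a single study the result degrades to the fixed effect (a
    warning is emitted); when ``Q ≤ k−1`` the moments estimate truncates
    to ``τ² = 0`` and the result coincides with :func:`pool_fixed`.
    """
    y, v = _arrays(estimates)
    if y.size == 1:
        warnings.warn("single study: falling back to fixed-effect pooling", stacklevel=2)
        return _assemble(y, v, tau2=0.0, method="dl")
    return _assemble(y, v, tau2=dl_tau2(y, v), method="dl")


def pool_subgroups(
    estimates: Sequence[EffectEstimate],
    labels: Mapping[str, Optional[str]],
    method: str = "dl",
) -> SubgroupResult:
    """Stratified pooling over the levels of a study-level variable.

    ``labels`` maps each study_id to its level; ``None`` excludes the
    study from the stratification.  Levels appear in first-seen input
    order; empty levels are dropped with a warning.
    """
    pool = pool_dl if method == "dl" else pool_fixed
    groups: dict[str, list[EffectEstimate]] = {}
    for est in estimates:
        if est.study_id not in labels:
            raise ValueError(f"study {est.study_id!r} missing from the label map")
        level = labels[est.study_id]
        if level is None:
            continue
        groups.setdefault(str(level), []).append(est)
    groups = {g: ests for g, ests in groups.items() if ests}
    if len(groups) < 2:
        raise ValueError("subgroup analysis requires at least two non-empty levels")
    results = {g: pool(ests) for g, ests in groups.items()}

    W = np.array([1.0 / r.se**2 for r in results.values()])
    theta = np.array([r.pooled_log_or for r in results.values()])
    theta_bar = np.sum(W * theta) / np.sum(W)
    q_between = float(np.sum(W * (theta - theta_bar) ** 2))
    df_between = len(results) - 1
    p_between = float(stats.chi2.sf(q_between, df_between))
    return SubgroupResult(
        variable="", levels=results,
        q_between=q_between, df_between=df_between, p_between=p_between,
    )


def leave_one_out(
    estimates: Sequence[EffectEstimate], method: str = "dl"
) -> list[tuple[str, PooledResult]]:
    """Re-pool ``k`` times, excluding one study each time (input order)."""
    if len(estimates) < 3:
        raise ValueError("leave-one-out requires at least 3 studies")
    pool = pool_dl if method == "dl" else pool_fixed
    out = []
    for i, excluded in enumerate(estimates):
        rest = [e for j, e in enumerate(estimates) if j != i]
        out.append((excluded.study_id, pool(rest)))
    return out
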