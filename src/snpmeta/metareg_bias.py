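"""Heterogeneity explanation and small-study bias diagnostics.

Meta-regression relates study-level log odds ratios to study-level
moderators (ethnicity, sample size, mean BMI, ...).  The between-study
variance is estimated by the method of moments on the weighted
regression residuals — the regression analogue of DerSimonian-Laird —
and the fraction of heterogeneity a moderator explains is
``1 − τ²_residual / τ²_null`` relative to the intercept-only model.

Egger's test regresses the standardized effect ``z_i = y_i/√v_i`` on
precision ``1/√v_i`` by ordinary least squares; an intercept away from
zero indicates that small (imprecise) studies report systematically
different effects, the signature of publication bias.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .effect_models import EffectEstimate
from .pooling import Z_95, pool_fixed

__all__ = [
    "MetaRegressionResult",
    "EggerResult",
    "meta_regress",
    "egger_test",
    "funnel_coordinates",
]


@dataclass(frozen=True)
class MetaRegressionResult:
    """Weighted least-squares fit with moments between-study variance."""

    names: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    tau2_residual: float
    tau2_null: float
    prop_explained: float
    k_used: int
    n_dropped: int

    def coefficient(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def p_value(self, name: str) -> float:
        return float(self.p_values[self.names.index(name)])


@dataclass(frozen=True)
class EggerResult:
    """Egger regression of standardized effect on precision."""

    intercept: float
    intercept_se: float
    t: float
    p: float           # two-sided, t distribution with k-2 df
    slope: float
    k: int


def _design_matrix(
    covariates: Union[pd.DataFrame, Mapping[str, Sequence]], k: int
) -> pd.DataFrame:
    df = pd.DataFrame(covariates)
    if df.shape[1] == 0:
        return pd.DataFrame(index=range(k))  # intercept-only design
    if len(df) != k:
        raise ValueError(f"covariates have {len(df)} rows for {k} estimates")
    cols = {}
    for name in df.columns:
        col = df[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = list(pd.unique(col.dropna()))
            for lev in levels[1:]:  # first-seen level is the reference
                cols[f"{name}[{lev}]"] = (col == lev).astype(float).where(col.notna())
        else:
            cols[name] = col.astype(float)
    return pd.DataFrame(cols, index=df.index)


def _mom_tau2(y, v, X) -> float:
    """Method-of-moments residual between-study variance for a WLS fit."""
    k, p = X.shape
    w = 1.0 / v
    XtW = X.T * w
    beta = np.linalg.solve(XtW @ X, XtW @ y)
    resid = y - X @ beta
    q_e = float(np.sum(w * resid**2))
    # tr(P) with P = W - W X (X'WX)^-1 X'W
    denom = float(np.sum(w) - np.trace(np.linalg.inv(XtW @ X) @ ((X.T * w**2) @ X)))
    if denom <= 0:
        return 0.0
    return max(0.0, (q_e - (k - p)) / denom)


def meta_regress(
    estimates: Sequence[EffectEstimate],
    covariates: Union[pd.DataFrame, Mapping[str, Sequence]],
) -> MetaRegressionResult:
    """Random-effects meta-regression of log odds ratios on moderators.

    Covariate rows align positionally with ``estimates``.  Categorical
    columns are dummy-coded against the first level in input order; rows
    with any missing covariate are dropped (count reported).  The
    residual ``τ²`` comes from the moments estimator on fixed-effect
    weighted residuals (one iteration), after which coefficients and
    standard errors come from WLS with weights ``1/(v_i + τ²)``;
    coefficient p-values use the standard normal.
    """
    if not estimates:
        raise ValueError("at least one estimate is required")
    y_all = np.array([e.log_or for e in estimates])
    v_all = np.array([e.variance for e in estimates])
    Xdf = _design_matrix(covariates, len(estimates))

    keep = ~Xdf.isna().any(axis=1).to_numpy()
    n_dropped = int((~keep).sum())
    y, v = y_all[keep], v_all[keep]
    X = np.column_stack([np.ones(keep.sum()), Xdf.to_numpy(dtype=float)[keep]])
    names = ("intercept",) + tuple(Xdf.columns)
    k, p = X.shape
    if k < p + 2:
        raise ValueError(f"need at least {p + 2} studies for {p} parameters, have {k}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(
            "design matrix is rank deficient; collinear columns among: "
            + ", ".join(names)
        )

    tau2_res = _mom_tau2(y, v, X)
    tau2_null = _mom_tau2(y, v, np.ones((k, 1)))

    w = 1.0 / (v + tau2_res)
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    beta = cov @ (XtW @ y)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))

    if tau2_null > 0:
        prop = min(1.0, max(0.0, 1.0 - tau2_res / tau2_null))
    else:
        prop = 0.0
    return MetaRegressionResult(
        names=names, coefficients=beta, standard_errors=se, p_values=pvals,
        tau2_residual=tau2_res, tau2_null=tau2_null, prop_explained=prop,
        k_used=k, n_dropped=n_dropped,
    )


def egger_test(estimates: Sequence[EffectEstimate]) -> EggerResult:
    """Egger's small-study-effect test (classical unweighted OLS form)."""
    if len(estimates) < 3:
        raise ValueError("Egger's test requires at least 3 studies")
    se_i = np.array([e.se for e in estimates])
    y = np.array([e.log_or for e in estimates])
    z = y / se_i
    x = 1.0 / se_i
    k = len(estimates)
    if np.allclose(x, x[0]):
        # degenerate design: intercept and slope are not separable; report
        # the mean standardized effect as the intercept with zero slope
        warnings.warn(
            "all precisions equal: Egger intercept and slope are not "
            "separable", stacklevel=2,
        )
        intercept = float(np.mean(z))
        se_int = float(np.std(z, ddof=1) / np.sqrt(k)) if k > 1 else float("inf")
        t = intercept / se_int if se_int > 0 else 0.0
        return EggerResult(
            intercept=intercept, intercept_se=se_int, t=float(t),
            p=float(2 * stats.t.sf(abs(t), df=k - 2)), slope=0.0, k=k,
        )
    fit = stats.linregress(x, z)
    t = fit.intercept / fit.intercept_stderr
    p = float(2 * stats.t.sf(abs(t), df=k - 2))
    return EggerResult(
        intercept=float(fit.intercept), intercept_se=float(fit.intercept_stderr),
        t=float(t), p=p, slope=float(fit.slope), k=k,
    )


def funnel_coordinates(
    estimates: Sequence[EffectEstimate], n_boundary: int = 50
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Funnel-plot coordinates: per-study (log OR, se) points plus the
    pseudo-95% funnel boundary around the fixed-effect pool.

    No graphics are produced; the two frames can be fed to any plotting
    front end.
    """
    if not estimates:
        raise ValueError("at least one estimate is required")
    points = pd.DataFrame({
        "study_id": [e.study_id for e in estimates],
        "log_or": [e.log_or for e in estimates],
        "se": [e.se for e in estimates],
    })
    center = pool_fixed(estimates).pooled_log_or
    se_max = points["se"].max()
    ses = np.linspace(0.0, se_max, n_boundary)
    boundary = pd.DataFrame({
        "se": ses,
        "center": center,
        "low": center - Z_95 * ses,
        "high": center + Z_95 * ses,
    })
    return points, boundary
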