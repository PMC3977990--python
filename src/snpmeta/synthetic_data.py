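"""Synthetic study collections with known truth.

Emulates the statistical world the pooling pipeline assumes: each study
draws a true log odds ratio from ``Normal(mu, tau2)``, a control
risk-allele frequency from a beta distribution, arm sizes log-uniformly,
and observed allele (or Hardy-Weinberg genotype) counts by binomial or
multinomial sampling.  Family studies emit transmitted/untransmitted
counts from heterozygous-parent transmissions.  Everything is driven by
one seed with counter-indexed per-study substreams, so a table is
byte-reproducible and individual studies keep their draws under
reordering.

Defaults mirror the 48-study case-control world the fixture table comes
from: ``mu = log 1.12``, modest heterogeneity ``tau2 = 0.02``, control
frequencies around 0.375, and per-arm sizes between 100 and 5000.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .study_io import Design, StudyRecord, StudyTable

__all__ = ["SimulationConfig", "simulate_studies", "simulate_with_covariate"]

_MAX_ATTEMPTS = 200


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; ``seed`` is mandatory for reproducibility."""

    seed: int
    k_studies: int = 48
    mu: float = math.log(1.12)
    tau2: float = 0.02
    raf_alpha: float = 15.0
    raf_beta: float = 25.0
    n_min: int = 100
    n_max: int = 5000
    genotype_mode: bool = False
    k_trios: int = 0
    trios_min: int = 100
    trios_max: int = 350
    selection_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.k_studies < 0 or self.k_trios < 0 or self.k_studies + self.k_trios == 0:
            raise ValueError("need at least one study")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if self.raf_alpha <= 0 or self.raf_beta <= 0:
            raise ValueError("beta-distribution parameters must be positive")
        mean_raf = self.raf_alpha / (self.raf_alpha + self.raf_beta)
        if not 0.0 < mean_raf < 1.0:
            raise ValueError("mean control frequency must lie in (0, 1)")
        if self.n_min < 20 or self.n_max < self.n_min:
            raise ValueError("need n_max >= n_min >= 20")
        if self.k_trios > 0 and not (0 < self.trios_min <= self.trios_max):
            raise ValueError("need trios_max >= trios_min > 0")
        if not 0.0 <= self.selection_bias < 1.0:
            raise ValueError("selection_bias must lie in [0, 1)")


def _study_rng(seed: int, index: int, attempt: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(index, attempt))
    )


def _log_uniform_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def _draw_theta_p0(rng: np.random.Generator, cfg: SimulationConfig, theta: Optional[float]):
    if theta is None:
        theta = cfg.mu + math.sqrt(cfg.tau2) * rng.standard_normal()
    p0 = float(np.clip(rng.beta(cfg.raf_alpha, cfg.raf_beta), 0.02, 0.98))
    return theta, p0


def _case_frequency(p0: float, theta: float) -> float:
    odds = p0 / (1.0 - p0) * math.exp(theta)
    return odds / (1.0 + odds)


def _cc_study(
    rng: np.random.Generator, cfg: SimulationConfig, study_id: str,
    theta: Optional[float],
) -> StudyRecord:
    theta, p0 = _draw_theta_p0(rng, cfg, theta)
    p1 = _case_frequency(p0, theta)
    n1 = _log_uniform_int(rng, cfg.n_min, cfg.n_max)
    n0 = _log_uniform_int(rng, cfg.n_min, cfg.n_max)
    if cfg.genotype_mode:
        or_ = math.exp(theta)
        q0 = 1.0 - p0
        hwe = np.array([q0 * q0, 2 * p0 * q0, p0 * p0])
        # multiplicative per-allele model: genotype risks 1 : OR : OR^2
        case_p = hwe * np.array([1.0, or_, or_ * or_])
        case_p /= case_p.sum()
        g0 = rng.multinomial(n0, hwe)
        g1 = rng.multinomial(n1, case_p)
        maf1 = (g1[1] + 2 * g1[2]) / (2 * n1)
        maf0 = (g0[1] + 2 * g0[2]) / (2 * n0)
        geno1, geno0 = tuple(int(x) for x in g1), tuple(int(x) for x in g0)
    else:
        maf1 = rng.binomial(2 * n1, p1) / (2 * n1)
        maf0 = rng.binomial(2 * n0, p0) / (2 * n0)
        geno1 = geno0 = None
    return StudyRecord(
        study_id=study_id, year=0, ethnicity="synthetic",
        design=Design.POPULATION, n_cases=n1, n_controls=n0,
        maf_cases=float(maf1), maf_controls=float(maf0),
        genotype_counts_cases=geno1, genotype_counts_controls=geno0,
    )


def _suppressed(rng: np.random.Generator, cfg: SimulationConfig, rec: StudyRecord) -> bool:
    """Publication-selection rule: small studies with unremarkable results
    vanish with probability ``selection_bias``."""
    if cfg.selection_bias == 0.0:
        return False
    from .effect_models import allele_table_from_maf, log_odds_ratio

    t = allele_table_from_maf(rec.n_cases, rec.n_controls, rec.maf_cases, rec.maf_controls)
    est = log_odds_ratio(t, study_id=rec.study_id)
    z = abs(est.log_or) / est.se
    small = rec.n_cases + rec.n_controls < 2 * math.sqrt(cfg.n_min * cfg.n_max)
    return small and z < 1.96 and rng.uniform() < cfg.selection_bias


def _trio_study(
    rng: np.random.Generator, cfg: SimulationConfig, study_id: str
) -> Optional[StudyRecord]:
    theta, p0 = _draw_theta_p0(rng, cfg, None)
    n_trios = int(rng.integers(cfg.trios_min, cfg.trios_max + 1))
    # heterozygous parents among 2*n_trios, each transmitting once
    h = int(rng.binomial(2 * n_trios, 2 * p0 * (1 - p0)))
    if h == 0:
        return None
    or_ = math.exp(theta)
    t = int(rng.binomial(h, or_ / (1.0 + or_)))
    return StudyRecord(
        study_id=study_id, year=0, ethnicity="synthetic", design=Design.FAMILY,
        n_trios=n_trios, transmitted=t, untransmitted=h - t,
    )


def _simulate(cfg: SimulationConfig, thetas: Optional[np.ndarray]) -> StudyTable:
    records: list[StudyRecord] = []
    for i in range(cfg.k_studies):
        theta_i = None if thetas is None else float(thetas[i])
        for attempt in range(_MAX_ATTEMPTS):
            rng = _study_rng(cfg.seed, i, attempt)
            rec = _cc_study(rng, cfg, f"study_{i:04d}", theta_i)
            if not _suppressed(rng, cfg, rec):
                break
        else:  # pragma: no cover - requires selection_bias ~ 1
            raise RuntimeError(f"study {i}: no study survived selection")
        records.append(rec)
    for j in range(cfg.k_trios):
        for attempt in range(_MAX_ATTEMPTS):
            rng = _study_rng(cfg.seed, cfg.k_studies + j, attempt)
            rec = _trio_study(rng, cfg, f"trio_{j:04d}")
            if rec is not None:
                break
        else:  # pragma: no cover - needs degenerate frequencies
            raise RuntimeError(f"trio study {j}: no informative transmissions")
        records.append(rec)
    return StudyTable(records=records, provenance=f"simulated(seed={cfg.seed})")


def simulate_studies(config: SimulationConfig) -> StudyTable:
    """Generate a study collection under the configured truth.

    Identical configs produce byte-identical tables; per-study substreams
    are indexed by study counter, so study ``i`` keeps its draws when
    ``k_studies`` changes.
    """
    return _simulate(config, thetas=None)


def simulate_with_covariate(
    config: SimulationConfig,
    cov_fraction_of_tau2: float,
    beta_cov: Optional[float] = None,
) -> tuple[StudyTable, np.ndarray]:
    """Generate studies whose true effects depend on a study-level
    covariate.

    A standard-normal covariate ``x_i`` shifts the true effect:
    ``θ_i = mu + β x_i + Normal(0, (1 − fraction)·tau2)`` with
    ``β² = fraction · tau2`` unless ``beta_cov`` overrides β.  Returns
    the table together with the covariate vector (case-control studies
    only; ``k_trios`` is ignored here).
    """
    if not 0.0 <= cov_fraction_of_tau2 <= 1.0:
        raise ValueError("cov_fraction_of_tau2 must lie in [0, 1]")
    if beta_cov is None:
        beta_cov = math.sqrt(cov_fraction_of_tau2 * config.tau2)
        resid_var = (1.0 - cov_fraction_of_tau2) * config.tau2
    else:
        resid_var = max(0.0, config.tau2 - beta_cov**2)
    cfg = replace(config, k_trios=0)
    rng = _study_rng(cfg.seed, 0, _MAX_ATTEMPTS)  # stream disjoint from studies'
    x = rng.standard_normal(cfg.k_studies)
    thetas = cfg.mu + beta_cov * x + math.sqrt(resid_var) * rng.standard_normal(cfg.k_studies)
    return _simulate(cfg, thetas=thetas), x
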