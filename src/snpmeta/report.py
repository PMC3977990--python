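"""Full-pipeline analysis report: one call runs every stage that the
input table supports and collects the results in a serializable object.

Sections that the data cannot support (genotype models without genotype
counts, BMI strata without BMI columns, ...) are marked
``"unavailable: <reason>"`` rather than dropped, so a report always has
the same shape.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import pandas as pd

from .effect_models import EffectEstimate, allele_estimates, genotype_estimates
from .family_tdt import DesignCombination, combine_designs, tdt_estimates
from .metareg_bias import EggerResult, egger_test, funnel_coordinates
from .pooling import (
    PooledResult,
    SubgroupResult,
    leave_one_out,
    pool_dl,
    pool_fixed,
    pool_subgroups,
)
from .study_io import StudyTable
from .translation import (
    FrequencySummary,
    PowerSpec,
    control_freq_summary,
    par,
    sample_size_for_power,
)

__all__ = ["AnalysisReport", "run_full_analysis", "write_report"]

#: ethnicity labels treated as strata; anything else (e.g. the fixture's
#: "Chinese" row) is excluded from the ethnicity stratification unless
#: remapped explicitly via ``map_ethnicity``.
ETHNIC_LEVELS = ("Caucasian", "East Asian", "Indian", "Other")

GENOTYPE_MODELS = ("heterozygous", "homozygous", "dominant", "recessive")

Section = Union[PooledResult, SubgroupResult, EggerResult, str]


@dataclass
class AnalysisReport:
    """Everything the pipeline computed, or why a section is unavailable."""

    overall: dict[str, Union[PooledResult, str]]
    subgroups: dict[str, Union[SubgroupResult, str]]
    sensitivity: Union[list[tuple[str, PooledResult]], str]
    egger: Union[EggerResult, str]
    funnel_points: Union[pd.DataFrame, str]
    funnel_boundary: Union[pd.DataFrame, str]
    combined_designs: Union[DesignCombination, str]
    freq_summaries: dict[str, Union[FrequencySummary, str]]
    par_table: dict[str, float]
    power_table: dict[str, dict[str, float]]
    provenance: dict[str, Any] = field(default_factory=dict)


def _size_label(n_cases: int, threshold: int = 1000) -> str:
    return "Large" if n_cases >= threshold else "Small"


def _bmi_label(bmi: Optional[float]) -> Optional[str]:
    if bmi is None:
        return None
    if bmi < 25:
        return "<25"
    if bmi <= 30:
        return "25-30"
    return ">30"


def run_full_analysis(
    table: StudyTable,
    method: str = "dl",
    map_ethnicity: Optional[dict[str, str]] = None,
    size_threshold: int = 1000,
) -> AnalysisReport:
    """Run the complete meta-analysis a study table supports.

    ``map_ethnicity`` remaps nonstandard ethnicity labels onto strata
    (e.g. ``{"Chinese": "East Asian"}``); unmapped nonstandard labels
    are excluded from the ethnicity stratification.  The sample-size
    stratification splits at ``size_threshold`` cases.
    """
    pool = pool_dl if method == "dl" else pool_fixed
    remap = map_ethnicity or {}
    by_id = {r.study_id: r for r in table.records}

    overall: dict[str, Union[PooledResult, str]] = {}
    allele = allele_estimates(table)
    overall["allele"] = pool(allele) if allele else "unavailable: no usable frequencies"
    for model in GENOTYPE_MODELS:
        ests = genotype_estimates(table, model)
        overall[model] = pool(ests) if ests else "unavailable: no genotype counts"

    subgroups: dict[str, Union[SubgroupResult, str]] = {}
    if allele:
        eth_labels = {}
        for e in allele:
            raw = by_id[e.study_id].ethnicity
            raw = remap.get(raw, raw)
            eth_labels[e.study_id] = raw if raw in ETHNIC_LEVELS else None
        try:
            sg = pool_subgroups(allele, eth_labels, method=method)
            subgroups["ethnicity"] = dataclasses.replace(sg, variable="ethnicity")
        except ValueError as exc:
            subgroups["ethnicity"] = f"unavailable: {exc}"

        size_labels = {
            e.study_id: _size_label(by_id[e.study_id].n_cases, size_threshold)
            for e in allele
        }
        try:
            sg = pool_subgroups(allele, size_labels, method=method)
            subgroups["sample_size"] = dataclasses.replace(sg, variable="sample_size")
        except ValueError as exc:
            subgroups["sample_size"] = f"unavailable: {exc}"

        bmi_labels = {
            e.study_id: _bmi_label(by_id[e.study_id].bmi_cases) for e in allele
        }
        if all(v is None for v in bmi_labels.values()):
            subgroups["bmi"] = "unavailable: no per-study mean BMI of cases"
        else:
            try:
                sg = pool_subgroups(allele, bmi_labels, method=method)
                subgroups["bmi"] = dataclasses.replace(sg, variable="bmi")
            except ValueError as exc:
                subgroups["bmi"] = f"unavailable: {exc}"
    else:
        subgroups["ethnicity"] = subgroups["sample_size"] = subgroups["bmi"] = (
            "unavailable: no allele-contrast estimates"
        )

    sensitivity: Union[list[tuple[str, PooledResult]], str]
    if len(allele) >= 3:
        sensitivity = leave_one_out(allele, method=method)
    else:
        sensitivity = "unavailable: fewer than 3 allele-contrast estimates"

    if len(allele) >= 3:
        egger: Union[EggerResult, str] = egger_test(allele)
    else:
        egger = "unavailable: fewer than 3 studies"
    if allele:
        pts, bound = funnel_coordinates(allele)
        funnel_points: Union[pd.DataFrame, str] = pts
        funnel_boundary: Union[pd.DataFrame, str] = bound
    else:
        funnel_points = funnel_boundary = "unavailable: no estimates"

    tdt = tdt_estimates(table)
    if allele and tdt:
        combined: Union[DesignCombination, str] = combine_designs(allele, tdt)
    elif tdt and not allele:
        combined = "unavailable: no case-control estimates to combine"
    else:
        combined = "unavailable: no trio transmission counts"

    freq: dict[str, Union[FrequencySummary, str]] = {}
    try:
        freq["all"] = control_freq_summary(table)
    except ValueError as exc:
        freq["all"] = f"unavailable: {exc}"
    for level in ETHNIC_LEVELS:
        try:
            freq[level] = control_freq_summary(table, ethnicity=level)
        except ValueError:
            freq[level] = "unavailable: no studies at this level"

    par_table: dict[str, float] = {}
    power_table: dict[str, dict[str, float]] = {}
    if isinstance(overall["allele"], PooledResult):
        if isinstance(freq["all"], FrequencySummary):
            par_table["all"] = par(overall["allele"].odds_ratio, freq["all"].mean)
    if isinstance(subgroups.get("ethnicity"), SubgroupResult):
        for level, res in subgroups["ethnicity"].levels.items():
            fs = freq.get(level)
            if not isinstance(fs, FrequencySummary):
                continue
            par_table[level] = par(res.odds_ratio, fs.mean)
            if res.odds_ratio != 1.0:
                pw = sample_size_for_power(
                    PowerSpec(p0=round(fs.mean, 2), or_per_allele=round(res.odds_ratio, 2))
                )
                power_table[level] = {
                    "p0": round(fs.mean, 2),
                    "or": round(res.odds_ratio, 2),
                    "n_per_group": pw.n_cases,
                    "n_rounded": pw.n_rounded,
                }

    from snpmeta import __version__

    return AnalysisReport(
        overall=overall, subgroups=subgroups, sensitivity=sensitivity,
        egger=egger, funnel_points=funnel_points, funnel_boundary=funnel_boundary,
        combined_designs=combined, freq_summaries=freq,
        par_table=par_table, power_table=power_table,
        provenance={
            "input": table.provenance,
            "method": method,
            "k": len(table),
            "package_version": __version__,
            "schema_version": 1,
        },
    )


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def _pooled_row(name: str, r: PooledResult) -> dict:
    return {
        "section": name, "k": r.k,
        "or": round(r.odds_ratio, 2),
        "ci_low": round(r.ci_low, 2), "ci_high": round(r.ci_high, 2),
        "p_z": r.p_z, "p_q": r.p_q, "tau2": r.tau2, "i2": r.i2,
        "log_or_full": r.pooled_log_or, "se_full": r.se, "method": r.method,
    }


def write_report(report: AnalysisReport, path, format: str = "json") -> list[Path]:
    """Serialize a report.

    ``json`` writes one schema-versioned document; ``tsv_bundle`` writes
    one TSV per section into the directory ``path``.  Presentation
    columns round ORs/CIs to 2 decimals alongside full-precision columns.
    Returns the paths written.
    """
    path = Path(path)
    if format == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_jsonable(report), fh, indent=1, allow_nan=False, default=str)
        return [path]
    if format != "tsv_bundle":
        raise ValueError(f"unknown format {format!r}; use 'json' or 'tsv_bundle'")

    path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    rows = [
        _pooled_row(model, r)
        for model, r in report.overall.items() if isinstance(r, PooledResult)
    ]
    for var, sg in report.subgroups.items():
        if isinstance(sg, SubgroupResult):
            rows += [_pooled_row(f"{var}:{lev}", r) for lev, r in sg.levels.items()]
    if rows:
        p = path / "pooled.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        written.append(p)

    if isinstance(report.sensitivity, list):
        p = path / "sensitivity.tsv"
        pd.DataFrame(
            [_pooled_row(sid, r) for sid, r in report.sensitivity]
        ).to_csv(p, sep="\t", index=False)
        written.append(p)

    if isinstance(report.funnel_points, pd.DataFrame):
        p = path / "funnel_points.tsv"
        report.funnel_points.to_csv(p, sep="\t", index=False)
        written.append(p)
        p = path / "funnel_boundary.tsv"
        report.funnel_boundary.to_csv(p, sep="\t", index=False)
        written.append(p)

    misc = {
        "egger": report.egger, "combined_designs": report.combined_designs,
        "freq_summaries": report.freq_summaries, "par": report.par_table,
        "power": report.power_table, "provenance": report.provenance,
    }
    p = path / "summary.json"
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(misc), fh, indent=1, allow_nan=False, default=str)
    written.append(p)
    return written
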