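"""Table readers/writers, run configuration and pipeline orchestration.

All tables are delimited text (comma by default, tab auto-detected), UTF-8,
with "." as the decimal separator; locale comma decimals are rejected
explicitly because silently mis-parsed European exports are the dominant
failure mode for this data shape.  Writers emit columns in a fixed,
documented order; readers accept any column order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .errors import ConfigurationError, TableFormatError
from .dosimetry import (
    EXPOSURE_COLUMNS,
    SCENARIOS,
    compare_predicted_vs_measured,
    predict_levels,
    predict_totals,
)
from .allocation import contribution_percentages, summarize_contributions
from .probabilistic import fit_from_percentiles, run_monte_carlo
from .risk import SELECTIVE_METABOLITE, risk_assessment
from .substances import Registry, canonical_metabolite, derive_hbm_gv, load_default_registry
from .synthetic import GeneratorConfig, generate_hbm_table, generate_primo_table

__all__ = [
    "read_diet_exposures",
    "write_diet_exposures",
    "read_hbm_aggregates",
    "write_hbm_aggregates",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

HBM_COLUMNS = ["country", "age_group", "metabolite_id", "percentile", "value", "unit"]
_ACCEPTED_UNITS = {"ug/L", "µg/L", "μg/L"}


def _read_delimited(path) -> pd.DataFrame:
    # sep=None + python engine sniffs comma vs tab
    return pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)


def _parse_number(raw: str, column: str, line: int, errors: list) -> float | None:
    text = str(raw).strip()
    if "," in text:
        errors.append((line, f"{column}: comma decimal separator in {text!r}; use '.'"))
        return None
    try:
        return float(text)
    except ValueError:
        errors.append((line, f"{column}: non-numeric value {text!r}"))
        return None


def read_diet_exposures(path, skip_invalid: bool = False) -> pd.DataFrame:
    """Read and validate a dietary %ADI record table.

    Row-level failures are collected with their 1-based file line numbers;
    the run aborts on any failure unless *skip_invalid* is set, in which
    case offending rows are dropped and logged.
    """
    df = _read_delimited(path)
    missing = [c for c in EXPOSURE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")

    errors: list[tuple[int, str]] = []
    rows = []
    for idx, rec in df.iterrows():
        line = idx + 2  # header is line 1
        year = _parse_number(rec["year"], "year", line, errors)
        pct = _parse_number(rec["percent_adi"], "percent_adi", line, errors)
        scenario = str(rec["scenario"]).strip()
        if scenario not in SCENARIOS:
            errors.append((line, f"scenario: {scenario!r} not in {SCENARIOS}"))
            continue
        if year is None or pct is None:
            continue
        if pct < 0:
            errors.append((line, f"percent_adi: negative value {pct}"))
            continue
        rows.append((str(rec["diet_id"]).strip(), str(rec["diet_label"]).strip(),
                     int(year), str(rec["substance"]).strip(), scenario, pct))

    if errors and not skip_invalid:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in errors[:10])
        raise TableFormatError(f"{path}: {len(errors)} invalid rows ({detail})", row_errors=errors)
    for ln, msg in errors:
        logger.warning("%s line %d dropped: %s", path, ln, msg)
    return pd.DataFrame(rows, columns=EXPOSURE_COLUMNS)


def write_diet_exposures(records: pd.DataFrame, path) -> None:
    records[EXPOSURE_COLUMNS].to_csv(path, index=False)


def read_hbm_aggregates(path, skip_invalid: bool = False) -> pd.DataFrame:
    """Read an aggregated urinary percentile table (long format).

    Units must be ug/L ("µg/L" accepted as an alias).  Percentile
    monotonicity is enforced per (country, age_group, metabolite): violating
    groups are rejected with a message (dropped when *skip_invalid*).
    """
    df = _read_delimited(path)
    missing = [c for c in HBM_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")

    errors: list[tuple[int, str]] = []
    rows = []
    for idx, rec in df.iterrows():
        line = idx + 2
        unit = str(rec["unit"]).strip()
        if unit not in _ACCEPTED_UNITS:
            errors.append((line, f"unit: {unit!r} not recognised; expected ug/L"))
            continue
        rank = _parse_number(rec["percentile"], "percentile", line, errors)
        value = _parse_number(rec["value"], "value", line, errors)
        if rank is None or value is None:
            continue
        if value < 0:
            errors.append((line, f"value: negative concentration {value}"))
            continue
        try:
            met = canonical_metabolite(rec["metabolite_id"])
        except Exception:
            errors.append((line, f"metabolite_id: unknown {rec['metabolite_id']!r}"))
            continue
        rows.append((str(rec["country"]).strip(), str(rec["age_group"]).strip(),
                     met, rank, value, "ug/L"))
    out = pd.DataFrame(rows, columns=HBM_COLUMNS)

    keep = []
    for key, grp in out.groupby(["country", "age_group", "metabolite_id"]):
        grp = grp.sort_values("percentile")
        if grp["value"].is_monotonic_increasing:
            keep.append(grp)
        else:
            errors.append((-1, f"group {key}: percentile values not non-decreasing; group rejected"))
    out = pd.concat(keep, ignore_index=True) if keep else pd.DataFrame(columns=HBM_COLUMNS)

    if errors and not skip_invalid:
        detail = "; ".join(f"line {ln}: {msg}" if ln > 0 else msg for ln, msg in errors[:10])
        raise TableFormatError(f"{path}: {len(errors)} problems ({detail})", row_errors=errors)
    for ln, msg in errors:
        logger.warning("%s: %s", path, msg)
    return out


def write_hbm_aggregates(hbm: pd.DataFrame, path) -> None:
    hbm[HBM_COLUMNS].to_csv(path, index=False)


class RunConfig(BaseModel):
    """Everything needed to reproduce one pipeline run."""

    model_config = ConfigDict(frozen=True)

    exposure_path: str | None = None
    hbm_path: str | None = None
    registry_path: str | None = None
    output_dir: str = "pyrethrisk_out"
    scenario: Literal["lower", "middle", "upper"] = "middle"
    adi_choice: Literal["primo", "current"] = "current"
    allocation_ranks: tuple[int, ...] = (10, 50, 90)
    seed: int = 0
    skip_invalid: bool = False
    monte_carlo: bool = False
    mc_iterations: int = Field(default=10_000, ge=1)
    mc_threshold: float = 1.0
    mc_renormalize: bool = False
    mc_metabolite: str = "3PBA"
    mc_group: tuple[str, str] | None = None  # (country, age_group); default: first available


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute predict -> allocate -> attribute -> risk (-> Monte Carlo).

    Inputs are read from the configured paths; when a path is absent the
    corresponding table is simulated from the generator defaults with the
    run seed, so a bare config is a self-contained smoke run.  All stage
    outputs are written to ``output_dir`` as CSV along with a JSON run
    summary holding seeds, input hashes, a registry hash and row counts.
    Returns the summary dict.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = load_default_registry(config.registry_path)
    summary: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "scenario": config.scenario,
        "adi_choice": config.adi_choice,
        "registry_sha256": hashlib.sha256(registry.to_yaml().encode()).hexdigest(),
        "inputs": {},
        "warnings": [],
        "row_counts": {},
    }

    gen_config = GeneratorConfig(seed=config.seed)
    if config.exposure_path:
        records = read_diet_exposures(config.exposure_path, config.skip_invalid)
        summary["inputs"]["exposures"] = {"path": str(config.exposure_path),
                                          "sha256": _sha256(config.exposure_path)}
    else:
        records, _truth = generate_primo_table(gen_config, registry)
        summary["inputs"]["exposures"] = {"simulated": True, "seed": config.seed}
    if config.hbm_path:
        hbm = read_hbm_aggregates(config.hbm_path, config.skip_invalid)
        summary["inputs"]["hbm"] = {"path": str(config.hbm_path),
                                    "sha256": _sha256(config.hbm_path)}
    else:
        hbm = generate_hbm_table(gen_config, registry)
        summary["inputs"]["hbm"] = {"simulated": True, "seed": config.seed + 1}

    levels = predict_levels(records, registry)
    totals = predict_totals(levels)
    contrib = contribution_percentages(levels, registry)
    summ = summarize_contributions(contrib, ranks=config.allocation_ranks)
    comparison = compare_predicted_vs_measured(totals, hbm)
    risk_tables = risk_assessment(
        hbm, summ, registry, scenario=config.scenario, adi_choice=config.adi_choice
    )

    outputs = {
        "predicted_levels": levels,
        "predicted_totals": totals,
        "contributions_long": contrib,
        "contribution_summary": summ,
        "comparison": comparison,
        "hq_per_substance": risk_tables["per_substance"],
        "hq_cumulative": risk_tables["cumulative"],
        "hq_combined": risk_tables["combined"],
    }

    if config.monte_carlo:
        mc_summary = _pipeline_monte_carlo(config, registry, hbm, summ)
        summary["monte_carlo"] = mc_summary

    for name, df in outputs.items():
        df.to_csv(out / f"{name}.csv", index=False)
        summary["row_counts"][name] = int(len(df))

    with open(out / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _pipeline_monte_carlo(config: RunConfig, registry: Registry, hbm, summ) -> dict:
    met = canonical_metabolite(config.mc_metabolite)
    sub_hbm = hbm[hbm["metabolite_id"] == met]
    if sub_hbm.empty:
        raise ConfigurationError(f"no measured data for metabolite {met}")
    if config.mc_group:
        country, age = config.mc_group
    else:
        first = sub_hbm.iloc[0]
        country, age = first["country"], first["age_group"]
    grp = sub_hbm[(sub_hbm["country"] == country) & (sub_hbm["age_group"] == age)]
    anchors = [(r, v) for r, v in zip(grp["percentile"], grp["value"]) if r in (5, 50, 95)]
    level_dist = fit_from_percentiles(anchors)

    cell = summ[(summ["metabolite_id"] == met) & (summ["age_class"] == age)
                & (summ["scenario"] == config.scenario)]
    contribution_dists, hbm_gvs = {}, {}
    group = registry.group(age)
    for rec in cell.itertuples(index=False):
        contribution_dists[rec.substance] = fit_from_percentiles(
            [(10, rec.p10), (50, rec.p50), (90, rec.p90)]
        )
        hbm_gvs[rec.substance] = derive_hbm_gv(
            registry.substance(rec.substance), met, group, config.adi_choice
        )
    result = run_monte_carlo(
        level_dist, contribution_dists, hbm_gvs,
        n=config.mc_iterations, seed=config.seed,
        threshold=config.mc_threshold, renormalize=config.mc_renormalize,
    )
    return {
        "metabolite": met,
        "country": country,
        "age_group": age,
        "level_family": level_dist.family,
        "contribution_families": {s: d.family for s, d in contribution_dists.items()},
        "n_iterations": result.n_iterations,
        "exceedance": result.exceedance,
        "threshold": result.threshold,
        "total_mean_hq": result.total_summary.mean,
        "total_p95_hq": result.total_summary.percentiles[95.0],
    }
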