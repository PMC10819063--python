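"""Allocation of shared urinary metabolites to individual pyrethroids.

Several pyrethroids excrete the same urinary biomarker (DCCA from
cyfluthrin, cypermethrin and permethrin; CFMP from lambda-cyhalothrin and
bifenthrin; 3-PBA from four substances), so a measured metabolite level
cannot be attributed to one parent directly.  This module computes, from the
forward dosimetry predictions, each substance's percent contribution to the
total predicted level of its metabolites, summarises the contributions as
percentiles across diets and years, applies the percentages to measured
levels, and converts attributed mass levels into parent molar equivalents
for the cross-metabolite consistency check.

Percentiles use the inclusive linear-interpolation convention (the
spreadsheet PERCENTILE.INC rule, numpy's ``"linear"``), which preserves the
two-contributor complementarity identity p_q(A) + p_{100-q}(B) = 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError, UndefinedFitError
from .substances import MetaboliteLink, Registry

__all__ = [
    "contribution_percentages",
    "summarize_contributions",
    "attribute_measured_level",
    "molar_parent_equivalent",
    "cross_metabolite_regression",
    "RegressionResult",
]

logger = logging.getLogger(__name__)

CELL_KEYS = ["metabolite_id", "diet_id", "year", "scenario"]


def contribution_percentages(
    levels: pd.DataFrame,
    registry: Registry | None = None,
) -> pd.DataFrame:
    """Percent contribution of each substance within each metabolite cell.

    A cell is one (metabolite, diet, year, scenario) combination;
    ``percent = 100 * substance level / cell total``.  Cells whose total is
    zero yield missing percents (NaN) and are excluded from percentile
    summaries downstream.

    When *registry* is given, substances that excrete a metabolite but have
    no record in a cell (no quantified residues in the food data) are
    completed as explicit 0% contributions rather than left missing.
    """
    if (levels["concentration"] < 0).any():
        raise ConfigurationError("negative predicted concentrations in levels table")
    df = levels.copy()

    if registry is not None:
        completed = []
        for met, met_df in df.groupby("metabolite_id"):
            producers = [s.name for s in registry.producers(met)]
            cells = met_df[CELL_KEYS + ["diet_label", "age_class"]].drop_duplicates(CELL_KEYS)
            full = cells.merge(pd.DataFrame({"substance": producers}), how="cross")
            met_full = full.merge(
                met_df, on=CELL_KEYS + ["diet_label", "age_class", "substance"], how="left"
            )
            met_full["concentration"] = met_full["concentration"].fillna(0.0)
            completed.append(met_full)
        df = pd.concat(completed, ignore_index=True)

    totals = df.groupby(CELL_KEYS)["concentration"].transform("sum")
    with np.errstate(invalid="ignore"):
        df["percent"] = np.where(totals > 0, 100.0 * df["concentration"] / totals, np.nan)
    n_empty = int(df.loc[totals == 0, CELL_KEYS].drop_duplicates().shape[0])
    if n_empty:
        logger.warning("%d metabolite cells have zero total prediction; percents set missing", n_empty)
    cols = CELL_KEYS + ["diet_label", "age_class", "substance", "concentration", "percent"]
    return df[cols].sort_values(CELL_KEYS + ["substance"], ignore_index=True)


def summarize_contributions(
    contributions: pd.DataFrame,
    ranks: Sequence[float] = (10, 50, 90),
) -> pd.DataFrame:
    """Percentile summary of contribution percents, pooled over diets and years.

    One output row per (metabolite, substance, age_class, scenario) with one
    column per requested rank (``p10``, ``p50``, ...).  Missing percents
    (zero-total cells) are excluded; cells that are empty after exclusion are
    dropped with a warning.
    """
    rank_cols = [f"p{int(r)}" for r in ranks]
    rows = []
    keys = ["metabolite_id", "substance", "age_class", "scenario"]
    for key, grp in contributions.groupby(keys):
        vals = grp["percent"].dropna().to_numpy()
        if vals.size == 0:
            logger.warning("empty contribution cell %s; omitted from summary", key)
            continue
        pct = np.percentile(vals, list(ranks), method="linear")
        rows.append((*key, *pct))
    out = pd.DataFrame(rows, columns=keys + rank_cols)
    return out.sort_values(keys, ignore_index=True)


def attribute_measured_level(level: float, percent: float) -> float:
    """Share of a measured urinary level attributable to one substance (ug/L)."""
    if not 0 <= percent <= 100:
        raise ConfigurationError(f"percent must be in [0, 100], got {percent}")
    if level < 0:
        raise ConfigurationError(f"level must be >= 0, got {level}")
    return level * percent / 100.0


def molar_parent_equivalent(level: float, percent: float, link: MetaboliteLink) -> float:
    """Parent-compound molar equivalent of an attributed metabolite level.

    ``(level * percent/100) / MW_metabolite / Fue`` in umol parent per L
    urine: the attributed mass concentration is converted to moles of
    metabolite and inflated by the excretion fraction to moles of parent
    that must have been ingested per litre excreted.
    """
    if link.fue <= 0:
        raise ZeroDivisionError(
            "Fue must be positive to back-calculate parent equivalents; "
            "check the metabolite link parameters"
        )
    return attribute_measured_level(level, percent) / link.mw_metabolite / link.fue


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def cross_metabolite_regression(
    generic_based: Iterable[float],
    selective_based: Iterable[float],
) -> RegressionResult:
    """OLS of selective-metabolite-based estimates on generic (3-PBA) based ones.

    Both inputs are parent molar equivalents for the same (population group,
    substance) pairs, estimated once through the substance's selective
    metabolite (DCCA or CFMP) and once through the generic 3-PBA pathway.
    When the generic pathway's assumed Fue understates the true excretion by
    a factor k, the expected slope is 1/k (an assumed Fue of 0.09 against a
    true 0.45 gives slope 0.2).
    """
    x = np.asarray(list(generic_based), dtype=float)
    y = np.asarray(list(selective_based), dtype=float)
    if x.size != y.size or x.size < 3:
        raise UndefinedFitError(f"need >= 3 paired points, got {x.size} and {y.size}")
    if np.ptp(x) == 0:
        raise UndefinedFitError("predictor has zero variance; fit undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        n=int(x.size),
    )
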