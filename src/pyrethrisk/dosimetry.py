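"""Forward dosimetry: from dietary %ADI records to predicted urinary levels.

The inputs are deterministic intake-model outputs (EFSA PRIMo shaped): one
row per (diet, year, substance, censoring scenario) holding chronic dietary
exposure expressed as a percentage of the ADI.  The three scenarios encode
the treatment of residues below the limit of quantification — lower (no
residue), middle (LOQ/2) and upper (LOQ).

Prediction chain, all units explicit:

    dose [mg/kg bw/day]  = percent_adi * ADI / 100
    level [ug/L urine]   = dose * Fue * (MW_met / MW_parent) * 1000 / U

Equivalently, when a guidance value HBM-GV for the same ADI exists,
``level = HBM-GV * percent_adi / 100``; both paths agree to floating
precision and the test suite asserts it.

Dietary predictions use the ADI vintage in force when the %ADI values were
computed (``adi_choice="primo"``); risk characterisation elsewhere uses the
current vintage.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UnknownSubstanceError
from .substances import PopulationGroup, Registry, SubstanceParams, canonical_metabolite

__all__ = [
    "SCENARIOS",
    "DEFAULT_CHILD_TOKENS",
    "classify_diet",
    "exposure_from_percent_adi",
    "predict_metabolite_level",
    "predict_via_hbm_gv",
    "predict_levels",
    "predict_totals",
    "compare_predicted_vs_measured",
]

logger = logging.getLogger(__name__)

SCENARIOS = ("lower", "middle", "upper")

#: Diet labels containing any of these tokens (case-insensitive) are treated
#: as children's diets; everything else — including "general" — as adult.
DEFAULT_CHILD_TOKENS = ("infant", "toddler", "child")

#: Column order of the exposure-record table.
EXPOSURE_COLUMNS = ["diet_id", "diet_label", "year", "substance", "scenario", "percent_adi"]

#: Column order of per-substance prediction tables.
LEVEL_COLUMNS = [
    "diet_id", "diet_label", "year", "scenario", "age_class",
    "substance", "metabolite_id", "concentration",
]


def classify_diet(diet_label: str, child_tokens: Iterable[str] = DEFAULT_CHILD_TOKENS) -> str:
    """Assign a diet label to the adult or child population group.

    Token match is case-insensitive substring search, so "children" and
    "Toddler" both classify as child while "DE general" stays adult.
    """
    if not str(diet_label).strip():
        raise ConfigurationError("diet_label must be non-empty")
    label = str(diet_label).lower()
    return "child" if any(tok.lower() in label for tok in child_tokens) else "adult"


def exposure_from_percent_adi(percent_adi: float, adi: float) -> float:
    """Convert a %ADI risk estimate into a dose in mg/kg bw/day."""
    if adi <= 0:
        raise ConfigurationError(f"adi must be positive, got {adi}")
    if percent_adi < 0:
        raise ConfigurationError(f"percent_adi must be >= 0, got {percent_adi}")
    return percent_adi * adi / 100.0


def predict_metabolite_level(
    dose: float,
    substance: SubstanceParams,
    metabolite_id: str,
    group: PopulationGroup,
) -> float:
    """Urinary metabolite concentration (ug/L) at a steady daily *dose* (mg/kg bw/day)."""
    if dose < 0:
        raise ConfigurationError(f"dose must be >= 0, got {dose}")
    link = substance.link(metabolite_id)
    return dose * link.fue * (link.mw_metabolite / substance.mw_parent) * 1000.0 / group.urinary_excretion


def predict_via_hbm_gv(percent_adi: float, hbm_gv: float) -> float:
    """Shortcut prediction through an existing guidance value.

    The guidance value is the level expected at 100 %ADI, so the prediction
    is a simple rescaling.
    """
    if hbm_gv < 0:
        raise ConfigurationError(f"hbm_gv must be >= 0, got {hbm_gv}")
    if percent_adi < 0:
        raise ConfigurationError(f"percent_adi must be >= 0, got {percent_adi}")
    return hbm_gv * percent_adi / 100.0


def _check_records(records: pd.DataFrame) -> None:
    missing = [c for c in EXPOSURE_COLUMNS if c not in records.columns]
    if missing:
        raise ConfigurationError(f"exposure records missing columns: {missing}")
    if (records["percent_adi"] < 0).any():
        bad = records.index[records["percent_adi"] < 0].tolist()[:5]
        raise ConfigurationError(f"negative percent_adi at rows {bad}")
    bad_scen = set(records["scenario"]) - set(SCENARIOS)
    if bad_scen:
        raise ConfigurationError(f"unknown scenarios {sorted(bad_scen)}; expected {SCENARIOS}")


def predict_levels(
    records: pd.DataFrame,
    registry: Registry,
    adi_choice: str = "primo",
    skip_unknown: bool = False,
    child_tokens: Iterable[str] = DEFAULT_CHILD_TOKENS,
) -> pd.DataFrame:
    """Per-substance, per-metabolite predicted urinary levels.

    One output row per (input record x metabolite link of its substance),
    with the diet's age class attached.  Unknown substances abort the run
    with a listing unless ``skip_unknown`` is set.
    """
    _check_records(records)
    known = set(registry.substance_names)
    unknown = sorted(set(records["substance"]) - known)
    if unknown:
        if not skip_unknown:
            raise UnknownSubstanceError(f"unknown substances in records: {unknown}")
        logger.warning("skipping %d records with unknown substances: %s",
                       int(records["substance"].isin(unknown).sum()), unknown)
        records = records[~records["substance"].isin(unknown)]

    rows = []
    for rec in records.itertuples(index=False):
        substance = registry.substance(rec.substance)
        age_class = classify_diet(rec.diet_label, child_tokens)
        group = registry.group(age_class)
        dose = exposure_from_percent_adi(rec.percent_adi, substance.adi(adi_choice))
        for link in substance.metabolites:
            conc = predict_metabolite_level(dose, substance, link.metabolite_id, group)
            rows.append((rec.diet_id, rec.diet_label, rec.year, rec.scenario, age_class,
                         substance.name, link.metabolite_id, conc))
    return pd.DataFrame(rows, columns=LEVEL_COLUMNS)


def predict_totals(
    levels_or_records: pd.DataFrame,
    registry: Registry | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Total predicted level per (diet, year, scenario, metabolite).

    Accepts either a per-substance level table from :func:`predict_levels`
    or raw exposure records (then *registry* is required and predictions are
    computed first).  Totals sum the contributions of every substance
    excreting the same metabolite.
    """
    if "concentration" not in levels_or_records.columns:
        if registry is None:
            raise ConfigurationError("registry required when passing raw exposure records")
        levels = predict_levels(levels_or_records, registry, **kwargs)
    else:
        levels = levels_or_records
    keys = ["diet_id", "diet_label", "year", "scenario", "age_class", "metabolite_id"]
    totals = levels.groupby(keys, as_index=False)["concentration"].sum()
    return totals.sort_values(keys, ignore_index=True)


def compare_predicted_vs_measured(
    totals: pd.DataFrame,
    hbm: pd.DataFrame,
) -> pd.DataFrame:
    """Pair predicted per-diet distributions with measured percentile curves.

    For each metabolite and age class shared by both inputs the output holds,
    in long format, (a) the empirical distribution of predicted per-diet
    totals for each censoring scenario, at Hazen plotting positions
    ``100 * (i - 0.5) / n``, and (b) the measured percentile curve of each
    population group.  Columns: metabolite_id, age_class, source
    ("predicted"/"measured"), series (scenario or country), rank, value.
    No statistical test is attached; the table is meant for overlay plots
    and tabular inspection.
    """
    needed = {"country", "age_group", "metabolite_id", "percentile", "value"}
    missing = needed - set(hbm.columns)
    if missing:
        raise ConfigurationError(f"hbm table missing columns: {sorted(missing)}")

    shared = sorted(set(totals["metabolite_id"]) & set(hbm["metabolite_id"]))
    if not shared:
        logger.warning("no shared metabolites between predictions and measurements")
        return pd.DataFrame(
            columns=["metabolite_id", "age_class", "source", "series", "rank", "value"]
        )

    out = []
    for met in shared:
        for age in sorted(set(totals["age_class"]) & set(hbm["age_group"])):
            pred = totals[(totals["metabolite_id"] == met) & (totals["age_class"] == age)]
            for scenario, grp in pred.groupby("scenario"):
                values = np.sort(grp["concentration"].to_numpy())
                n = len(values)
                ranks = 100.0 * (np.arange(1, n + 1) - 0.5) / n
                for r, v in zip(ranks, values):
                    out.append((met, age, "predicted", scenario, r, v))
            meas = hbm[(hbm["metabolite_id"] == met) & (hbm["age_group"] == age)]
            for country, grp in meas.groupby("country"):
                grp = grp.sort_values("percentile")
                for r, v in zip(grp["percentile"], grp["value"]):
                    out.append((met, age, "measured", country, float(r), float(v)))
    return pd.DataFrame(
        out, columns=["metabolite_id", "age_class", "source", "series", "rank", "value"]
    )
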