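"""Synthetic dietary-exposure and biomonitoring tables with known ground truth.

Real inputs for this workflow are (a) deterministic intake-model outputs —
one %ADI figure per (diet, year, substance, LOQ-censoring scenario) — and
(b) aggregated urinary biomarker tables — percentile concentrations per
country and age group.  Neither can be bundled, so this module generates
both shapes from a fully specified generating process, keeping the truth
(doses, contribution shares, population medians) alongside so that every
pipeline stage can be validated by parameter recovery.

Generating process
------------------
* True chronic dose per (diet, year, substance): ``mean_dose`` times two
  mean-one lognormal factors — a factor shared by all substances within a
  (diet, year) cell (``sigma_diet_shared``; diets differ in how much
  residue-bearing produce they contain overall) and a substance-specific
  factor (``sigma_diet_substance``; residue levels vary by crop and use
  pattern).  Total inter-diet log-SD is the root-sum-square (0.5 at the
  defaults).  Contribution shares are scale-free, so only the
  substance-specific component perturbs them; keeping it moderate makes
  the median share an essentially unbiased estimand of the analytic share.
* LOQ censoring at the aggregate level: a fraction ``loq_censor_fraction``
  of the residue mass is below the LOQ; the lower / middle / upper bounds
  replace that mass with 0, half, or all of it, giving ordered %ADI values.
* Urinary tables: the population median level of each metabolite is the
  forward-dosimetry prediction at the mean doses using the *generation*
  excretion fractions (``true_fue`` overrides allow deliberately
  misspecified analyses); percentiles follow a lognormal around the median
  with geometric SD ``population_gsd``.  Synthetic "countries" are
  replicate groups whose medians carry an inter-country factor drawn
  log-uniformly on ``[1/country_spread, country_spread]`` — a finite panel
  of national populations covers its range fairly evenly, and a log-uniform
  draw reproduces that span without the rare extreme groups an iid
  lognormal would inject — plus optional multiplicative measurement noise.

Default doses are chosen so that exposure sits well below the ADI for every
substance and the implied contribution shares resemble a European food
basket (cypermethrin dominating DCCA and 3-PBA, lambda-cyhalothrin
dominating CFMP); see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import ConfigurationError
from .substances import Registry, canonical_metabolite, load_default_registry
from .dosimetry import EXPOSURE_COLUMNS

__all__ = ["GeneratorConfig", "GroundTruth", "generate_primo_table", "generate_hbm_table"]

#: mg/kg bw/day.  The dose RATIOS set the contribution shares (chosen to
#: resemble a European food basket); the absolute scale is set so that
#: predicted urinary medians sit at the sub-ug/L levels European
#: biomonitoring reports and combined hazard quotients stay below 1 even
#: for highly exposed groups.  See docs/methods.md.
DEFAULT_MEAN_DOSES = {
    "cyfluthrin": 2.5e-5,
    "cypermethrin": 1.0e-4,
    "permethrin": 2.5e-5,
    "deltamethrin": 7.5e-5,
    "lambda-cyhalothrin": 5.0e-5,
    "bifenthrin": 2.5e-5,
}

_CHILD_LABELS = ("toddler", "child", "infant")


class GeneratorConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_diets: int = Field(default=36, ge=1)
    years: tuple[int, ...] = (2016, 2017, 2018, 2019, 2020)
    mean_doses: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_MEAN_DOSES))
    sigma_diet_shared: float = Field(
        default=0.4, ge=0, description="lognormal sigma of the diet factor common to all substances"
    )
    sigma_diet_substance: float = Field(
        default=0.3, ge=0, description="lognormal sigma of the substance-specific diet factor"
    )
    loq_censor_fraction: float | dict[str, float] = 0.3
    true_fue: dict[str, float] = Field(
        default_factory=dict,
        description="generation-side Fue override per metabolite id; empty = analysis values",
    )
    population_gsd: float = Field(default=2.0, ge=1.0, description="geometric SD of urinary levels")
    percentile_grid: tuple[float, ...] = (5, 10, 25, 50, 75, 90, 95)
    n_countries: int = Field(default=8, ge=1)
    country_spread: float = Field(
        default=3.0, ge=1.0,
        description="inter-country median factors are log-uniform on [1/spread, spread]",
    )
    measurement_cv: float = Field(default=0.0, ge=0, description="multiplicative noise CV on reported levels")
    child_fraction: float = Field(default=0.25, ge=0, le=1)
    seed: int = 0

    @field_validator("mean_doses")
    @classmethod
    def _doses_nonneg(cls, v):
        for name, dose in v.items():
            if dose < 0:
                raise ValueError(f"mean dose for {name} must be >= 0, got {dose}")
        return v

    @field_validator("true_fue", mode="before")
    @classmethod
    def _canon_fue(cls, v):
        return {canonical_metabolite(k): val for k, val in (v or {}).items()}

    @model_validator(mode="after")
    def _fractions(self):
        fracs = (self.loq_censor_fraction.values()
                 if isinstance(self.loq_censor_fraction, dict)
                 else [self.loq_censor_fraction])
        for f in fracs:
            if not 0 <= f <= 1:
                raise ValueError(f"loq_censor_fraction must be in [0, 1], got {f}")
        for met, fue in self.true_fue.items():
            if not 0 < fue <= 1:
                raise ValueError(f"true_fue[{met}] must be in (0, 1], got {fue}")
        return self

    def censor_fraction(self, substance: str) -> float:
        if isinstance(self.loq_censor_fraction, dict):
            return self.loq_censor_fraction.get(substance, 0.0)
        return self.loq_censor_fraction

    def generation_fue(self, registry: Registry, substance: str, metabolite_id: str) -> float:
        """Fue used on the generation side (override if present, else the registry value)."""
        if metabolite_id in self.true_fue:
            return self.true_fue[metabolite_id]
        return registry.substance(substance).link(metabolite_id).fue


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually used; the recovery targets for tests."""

    doses: pd.DataFrame            # diet_id, diet_label, year, substance, dose
    shares: pd.DataFrame           # metabolite_id, age_class, substance, share (sums to 1 per cell)
    median_levels: pd.DataFrame    # age_class, metabolite_id, median (ug/L)


def _diet_labels(config: GeneratorConfig) -> list[str]:
    n_child = round(config.n_diets * config.child_fraction)
    labels = []
    for i in range(config.n_diets):
        if i < n_child:
            labels.append(f"SYN-{i + 1:02d} {_CHILD_LABELS[i % len(_CHILD_LABELS)]}")
        else:
            labels.append(f"SYN-{i + 1:02d} general")
    return labels


def _analytic_shares(config: GeneratorConfig, registry: Registry) -> pd.DataFrame:
    rows = []
    mets = sorted({m for s in registry.substances for m in s.metabolite_ids})
    for met in mets:
        producers = [s for s in registry.producers(met) if s.name in config.mean_doses]
        weights = {
            s.name: config.mean_doses[s.name]
            * config.generation_fue(registry, s.name, met)
            * s.link(met).mw_metabolite / s.mw_parent
            for s in producers
        }
        total = sum(weights.values())
        if total == 0:
            continue
        for age in ("adult", "child"):
            for name, w in weights.items():
                rows.append((met, age, name, w / total))
    return pd.DataFrame(rows, columns=["metabolite_id", "age_class", "substance", "share"])


def generate_primo_table(
    config: GeneratorConfig,
    registry: Registry | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Dietary %ADI records in intake-model shape, plus the generating truth.

    Deterministic given ``config.seed``.  Records carry all three censoring
    scenarios with ``lower <= middle <= upper`` by construction; %ADI is
    computed against each substance's intake-era ADI.
    """
    registry = registry or load_default_registry()
    unknown = set(config.mean_doses) - set(registry.substance_names)
    if unknown:
        raise ConfigurationError(f"mean_doses name unknown substances: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    labels = _diet_labels(config)
    substances = sorted(config.mean_doses)

    records, dose_rows = [], []
    for d, label in enumerate(labels):
        diet_id = f"D{d + 1:02d}"
        for year in config.years:
            shared = rng.lognormal(-config.sigma_diet_shared**2 / 2, config.sigma_diet_shared)
            for name in substances:
                sub = registry.substance(name)
                mean_dose = config.mean_doses[name]
                idio = rng.lognormal(-config.sigma_diet_substance**2 / 2, config.sigma_diet_substance)
                dose = mean_dose * shared * idio
                dose_rows.append((diet_id, label, year, name, dose))
                f = config.censor_fraction(name)
                for scenario, kept in (("lower", 1 - f), ("middle", 1 - f / 2), ("upper", 1.0)):
                    pct = 100.0 * dose * kept / sub.adi_primo
                    records.append((diet_id, label, year, name, scenario, pct))

    records_df = pd.DataFrame(records, columns=EXPOSURE_COLUMNS)
    truth = GroundTruth(
        doses=pd.DataFrame(dose_rows, columns=["diet_id", "diet_label", "year", "substance", "dose"]),
        shares=_analytic_shares(config, registry),
        median_levels=_median_levels(config, registry),
    )
    return records_df, truth


def _median_levels(config: GeneratorConfig, registry: Registry) -> pd.DataFrame:
    rows = []
    mets = sorted({m for s in registry.substances for m in s.metabolite_ids})
    for age in ("adult", "child"):
        u = registry.group(age).urinary_excretion
        for met in mets:
            level = 0.0
            for s in registry.producers(met):
                if s.name not in config.mean_doses:
                    continue
                link = s.link(met)
                fue = config.generation_fue(registry, s.name, met)
                level += config.mean_doses[s.name] * fue * link.mw_metabolite / s.mw_parent * 1000.0 / u
            rows.append((age, met, level))
    return pd.DataFrame(rows, columns=["age_class", "metabolite_id", "median"])


def generate_hbm_table(
    config: GeneratorConfig,
    registry: Registry | None = None,
    ground_truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Aggregated urinary percentile tables for synthetic countries.

    Long format: country, age_group, metabolite_id, percentile, value, unit.
    Percentiles within each group are monotone by construction
    (``value = median * GSD ** z(rank)``).  Uses a generator seeded with
    ``config.seed + 1`` so dietary and urinary noise streams are distinct
    but jointly reproducible.
    """
    registry = registry or load_default_registry()
    medians = (ground_truth.median_levels if ground_truth is not None
               else _median_levels(config, registry))
    rng = np.random.default_rng(config.seed + 1)
    from scipy.stats import norm

    z = norm.ppf(np.array(config.percentile_grid) / 100.0)
    rows = []
    log_spread = np.log(config.country_spread)
    for i in range(config.n_countries):
        country = f"SYN-C{i + 1:02d}"
        country_factor = float(np.exp(rng.uniform(-log_spread, log_spread)))
        for rec in medians.itertuples(index=False):
            if rec.median <= 0:
                continue
            noise = (1.0 + config.measurement_cv * rng.standard_normal()
                     if config.measurement_cv > 0 else 1.0)
            noise = max(noise, 0.05)  # keep reported levels positive
            center = rec.median * country_factor * noise
            values = center * config.population_gsd ** z
            for rank, value in zip(config.percentile_grid, values):
                rows.append((country, rec.age_class, rec.metabolite_id, float(rank), float(value), "ug/L"))
    return pd.DataFrame(rows, columns=["country", "age_group", "metabolite_id", "percentile", "value", "unit"])
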