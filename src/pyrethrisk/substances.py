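"""Parameter registry for pyrethroid active substances and their urinary metabolites.

Each pyrethroid is described by its molecular weight, two Acceptable Daily
Intake (ADI) vintages, and one or two metabolite links.  A link carries the
metabolite's molecular weight and its molar urinary excretion fraction
``Fue`` (moles of metabolite excreted in urine per mole of parent ingested).

Two ADI vintages are kept because the European assessments this package
mirrors used the ADI in force at the time of the dietary-intake (PRIMo)
estimations for forward dosimetry, while the most recent ADI is used for the
risk characterisation.  Permethrin is the substance whose ADI changed most
consequentially (0.05 -> 0.01 mg/kg bw/day).

The human-biomonitoring guidance value (HBM-GV Gen Pop) for a metabolite is
the urinary concentration expected at steady dietary exposure equal to the
ADI:

    HBM-GV = ADI * Fue * (MW_metabolite / MW_parent) * 1000 / U   [ug/L]

where ``U`` is the body-weight-adjusted daily urinary excretion in
L/kg bw/day.  The default ``U`` values (0.0299 adult, 0.0197 child) are
calibrated so that permethrin at ADI 0.01 yields guidance values of 64 and
97 ug DCCA/L; they are configuration defaults, not measured constants (see
docs/methods.md).
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Literal, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ConfigurationError, NoSuchLinkError, UnknownMetaboliteError, UnknownSubstanceError

__all__ = [
    "METABOLITES",
    "MetaboliteLink",
    "SubstanceParams",
    "PopulationGroup",
    "Registry",
    "canonical_metabolite",
    "load_default_registry",
    "derive_hbm_gv",
]

#: Canonical urinary biomarker identifiers.
METABOLITES = ("DCCA", "DBCA", "CFMP", "3PBA", "F3PBA")

# Aliases are matched after uppercasing and stripping "-", "_" and spaces.
# CFMP is also written CLF3CA (or CIF3CA in OCR'd sources); the fluorinated
# phenoxybenzoic acid appears as 4-FPBA, F-3-PBA, 4-F-3-PBA.
_ALIASES = {
    "DCCA": "DCCA",
    "DBCA": "DBCA",
    "CFMP": "CFMP",
    "CLF3CA": "CFMP",
    "CIF3CA": "CFMP",
    "3PBA": "3PBA",
    "PBA": "3PBA",
    "F3PBA": "F3PBA",
    "4FPBA": "F3PBA",
    "4F3PBA": "F3PBA",
    "FPBA": "F3PBA",
}

AgeClass = Literal["adult", "child"]
AdiChoice = Literal["primo", "current"]


def canonical_metabolite(name: str) -> str:
    """Resolve a metabolite name or alias to its canonical identifier.

    Raises
    ------
    UnknownMetaboliteError
        If the name does not match any known biomarker.
    """
    key = str(name).upper().replace("-", "").replace("_", "").replace(" ", "")
    try:
        return _ALIASES[key]
    except KeyError:
        raise UnknownMetaboliteError(
            f"unknown metabolite {name!r}; expected one of {METABOLITES} or an alias"
        ) from None


class MetaboliteLink(BaseModel):
    """One parent-to-metabolite excretion pathway."""

    model_config = ConfigDict(frozen=True)

    metabolite_id: str
    mw_metabolite: float = Field(gt=0, description="metabolite molecular weight, g/mol")
    fue: float = Field(gt=0, le=1, description="molar urinary excretion fraction")

    @field_validator("metabolite_id", mode="before")
    @classmethod
    def _canonical(cls, v):
        return canonical_metabolite(v)


class SubstanceParams(BaseModel):
    """Parameters for one pyrethroid active substance."""

    model_config = ConfigDict(frozen=True)

    name: str
    mw_parent: float = Field(gt=0, description="parent molecular weight, g/mol")
    adi_primo: float = Field(gt=0, description="ADI used for the intake estimations, mg/kg bw/day")
    adi_current: float = Field(gt=0, description="most recent ADI, used for risk, mg/kg bw/day")
    metabolites: tuple[MetaboliteLink, ...] = Field(min_length=1, max_length=2)

    def adi(self, choice: AdiChoice = "current") -> float:
        if choice == "primo":
            return self.adi_primo
        if choice == "current":
            return self.adi_current
        raise ConfigurationError(f"adi_choice must be 'primo' or 'current', got {choice!r}")

    @property
    def metabolite_ids(self) -> tuple[str, ...]:
        return tuple(link.metabolite_id for link in self.metabolites)

    def link(self, metabolite_id: str) -> MetaboliteLink:
        """Return the excretion link for *metabolite_id*.

        Raises :class:`NoSuchLinkError` if this substance does not produce it.
        """
        met = canonical_metabolite(metabolite_id)
        for candidate in self.metabolites:
            if candidate.metabolite_id == met:
                return candidate
        raise NoSuchLinkError(f"{self.name} does not excrete {met} (has {self.metabolite_ids})")


class PopulationGroup(BaseModel):
    """Age class with its body-weight-adjusted daily urinary excretion."""

    model_config = ConfigDict(frozen=True)

    age_class: AgeClass
    urinary_excretion: float = Field(gt=0, description="L urine per kg bw per day")


class Registry(BaseModel):
    """Immutable collection of substance parameters and population groups."""

    model_config = ConfigDict(frozen=True)

    substances: tuple[SubstanceParams, ...]
    groups: tuple[PopulationGroup, ...]

    def substance(self, name: str) -> SubstanceParams:
        for s in self.substances:
            if s.name == name:
                return s
        raise UnknownSubstanceError(
            f"unknown substance {name!r}; registry has {sorted(self.substance_names)}"
        )

    @property
    def substance_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.substances)

    def group(self, age_class: str) -> PopulationGroup:
        for g in self.groups:
            if g.age_class == age_class:
                return g
        raise ConfigurationError(f"no population group {age_class!r}")

    def producers(self, metabolite_id: str) -> tuple[SubstanceParams, ...]:
        """All substances excreting *metabolite_id*, in registry order."""
        met = canonical_metabolite(metabolite_id)
        return tuple(s for s in self.substances if met in s.metabolite_ids)

    # -- serialisation -----------------------------------------------------

    @classmethod
    def from_dict(cls, data: Mapping) -> "Registry":
        try:
            substances = tuple(
                SubstanceParams(
                    name=entry["name"],
                    mw_parent=entry["mw"],
                    adi_primo=entry["adi_primo"],
                    adi_current=entry["adi_current"],
                    metabolites=tuple(
                        MetaboliteLink(
                            metabolite_id=m["id"], mw_metabolite=m["mw"], fue=m["fue"]
                        )
                        for m in entry["metabolites"]
                    ),
                )
                for entry in data["substances"]
            )
            groups = tuple(
                PopulationGroup(age_class=k, urinary_excretion=v["urinary_excretion"])
                for k, v in data["population_groups"].items()
            )
        except KeyError as exc:
            raise ConfigurationError(f"registry config missing key: {exc}") from exc
        return cls(substances=substances, groups=groups)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "population_groups": {
                g.age_class: {"urinary_excretion": g.urinary_excretion} for g in self.groups
            },
            "substances": [
                {
                    "name": s.name,
                    "mw": s.mw_parent,
                    "adi_primo": s.adi_primo,
                    "adi_current": s.adi_current,
                    "metabolites": [
                        {"id": m.metabolite_id, "mw": m.mw_metabolite, "fue": m.fue}
                        for m in s.metabolites
                    ],
                }
                for s in self.substances
            ],
        }

    @classmethod
    def from_yaml(cls, text: str) -> "Registry":
        return cls.from_dict(yaml.safe_load(text))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def load_default_registry(path: str | None = None, overrides: Mapping | None = None) -> Registry:
    """Load the packaged default parameter table, optionally from *path*.

    ``overrides`` is a nested mapping merged over the file contents before
    validation, e.g. ``{"population_groups": {"adult": {"urinary_excretion":
    0.03}}}``.  Any out-of-range value raises a validation error naming the
    offending field.
    """
    if path is None:
        text = resources.files("pyrethrisk.data").joinpath("default_parameters.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    data = yaml.safe_load(text)
    if overrides:
        data = _deep_merge(data, overrides)
    return Registry.from_dict(data)


def _deep_merge(base, extra):
    if isinstance(base, dict) and isinstance(extra, dict):
        merged = dict(base)
        for k, v in extra.items():
            merged[k] = _deep_merge(base.get(k), v) if k in base else v
        return merged
    if isinstance(base, list) and isinstance(extra, list):
        # substance entry lists merge by name; other lists (metabolites) replace
        if all(isinstance(e, dict) and "name" in e for e in base + extra):
            by_name = {e["name"]: e for e in base}
            for item in extra:
                if item["name"] in by_name:
                    by_name[item["name"]] = _deep_merge(by_name[item["name"]], item)
                else:
                    by_name[item["name"]] = item
            return list(by_name.values())
        return extra
    return extra


def derive_hbm_gv(
    substance: SubstanceParams,
    metabolite_id: str,
    group: PopulationGroup,
    adi_choice: AdiChoice = "current",
) -> float:
    """Human-biomonitoring guidance value in ug metabolite per L urine.

    Evaluates the forward dosimetry equation at a dose equal to the chosen
    ADI.  The value is returned unrounded; guidance values are conventionally
    displayed rounded to the nearest integer.
    """
    link = substance.link(metabolite_id)
    adi = substance.adi(adi_choice)
    return adi * link.fue * (link.mw_metabolite / substance.mw_parent) * 1000.0 / group.urinary_excretion
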