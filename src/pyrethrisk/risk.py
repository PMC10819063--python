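"""Hazard quotients and cumulative/combined risk against HBM-GV Gen Pop.

A hazard quotient (HQ) is an attributed urinary metabolite level divided by
the corresponding human-biomonitoring guidance value; values below 1 mean
the biomarker level sits below the concentration expected at the ADI.
Substances sharing a metabolite are aggregated by simple HQ summation
(cumulative HQ per metabolite).  The total combined risk across all
pyrethroids sums, for each substance, the HQ from its most selective
metabolite — the generic 3-PBA pathway is excluded because its conservative
excretion fraction inflates HQs — with each substance counted exactly once:

    deltamethrin -> DBCA, cyfluthrin -> F3PBA, cypermethrin -> DCCA,
    permethrin -> DCCA, lambda-cyhalothrin -> CFMP, bifenthrin -> CFMP

Cyfluthrin still contributes its DCCA share to the DCCA cumulative HQ; only
the combined total restricts it to F3PBA to avoid double counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigurationError
from .substances import Registry, derive_hbm_gv
from .allocation import attribute_measured_level

__all__ = [
    "SELECTIVE_METABOLITE",
    "HQResult",
    "CombinedRisk",
    "hazard_quotient",
    "cumulative_hq",
    "combined_total",
    "risk_assessment",
]

logger = logging.getLogger(__name__)

#: Most selective measurable metabolite per substance; never 3-PBA.
SELECTIVE_METABOLITE: Mapping[str, str] = {
    "deltamethrin": "DBCA",
    "cyfluthrin": "F3PBA",
    "cypermethrin": "DCCA",
    "permethrin": "DCCA",
    "lambda-cyhalothrin": "CFMP",
    "bifenthrin": "CFMP",
}


@dataclass(frozen=True)
class HQResult:
    country: str
    age_group: str
    percentile_rank: float
    substance: str
    metabolite_id: str
    hq: float

    def __post_init__(self):
        if self.hq < 0:
            raise ConfigurationError(f"hq must be >= 0, got {self.hq}")

    @property
    def group_key(self):
        return (self.country, self.age_group, self.percentile_rank)


@dataclass(frozen=True)
class CombinedRisk:
    country: str
    age_group: str
    percentile_rank: float
    total_hq: float
    components: tuple[HQResult, ...] = field(default_factory=tuple)


def hazard_quotient(attributed_level: float, hbm_gv: float) -> float:
    """Dimensionless ratio of an attributed level (ug/L) to its guidance value."""
    if hbm_gv <= 0:
        raise ConfigurationError(f"hbm_gv must be positive, got {hbm_gv}")
    if attributed_level < 0:
        raise ConfigurationError(f"attributed_level must be >= 0, got {attributed_level}")
    return attributed_level / hbm_gv


def cumulative_hq(metabolite_id: str, hqs: Iterable[HQResult]) -> float:
    """Sum of per-substance HQs sharing one metabolite within one population cell."""
    hqs = list(hqs)
    if not hqs:
        logger.warning("cumulative HQ over empty set for %s; returning 0", metabolite_id)
        return 0.0
    groups = {h.group_key for h in hqs}
    mets = {h.metabolite_id for h in hqs}
    if len(groups) > 1 or mets != {metabolite_id}:
        raise ConfigurationError(
            f"cumulative HQ requires a single (country, age_group, percentile, metabolite) "
            f"cell; got groups {groups} and metabolites {mets}"
        )
    return sum(h.hq for h in hqs)


def combined_total(
    country: str,
    age_group: str,
    percentile_rank: float,
    hq_results: Iterable[HQResult],
    selective_map: Mapping[str, str] = SELECTIVE_METABOLITE,
) -> CombinedRisk:
    """Total combined pyrethroid risk from the most selective metabolites.

    Picks, for every substance in *selective_map*, the HQ computed from its
    selective metabolite in the given population cell; substances with no
    matching HQ are omitted with a log message.  3-PBA-based HQs are never
    selected.
    """
    pool = [
        h for h in hq_results
        if h.group_key == (country, age_group, percentile_rank)
    ]
    components = []
    for substance, met in selective_map.items():
        match = [h for h in pool if h.substance == substance and h.metabolite_id == met]
        if not match:
            logger.info("no %s HQ via %s for (%s, %s, p%s); omitted",
                        substance, met, country, age_group, percentile_rank)
            continue
        if len(match) > 1:
            raise ConfigurationError(f"duplicate HQ entries for {substance}/{met}")
        components.append(match[0])
    return CombinedRisk(
        country=country,
        age_group=age_group,
        percentile_rank=percentile_rank,
        total_hq=sum(c.hq for c in components),
        components=tuple(components),
    )


def risk_assessment(
    hbm: pd.DataFrame,
    contribution_summary: pd.DataFrame,
    registry: Registry,
    scenario: str = "middle",
    allocation_rank: int = 50,
    adi_choice: str = "current",
) -> dict[str, pd.DataFrame]:
    """Deterministic risk tables from measured levels and allocation summaries.

    Pairs every measured percentile level with the allocation median
    (``allocation_rank``, default p50) of the chosen censoring scenario,
    attributes the level to each contributing substance, and divides by the
    substance's guidance value for the matching age class.  Returns three
    tables: ``per_substance`` HQ rows, ``cumulative`` per-metabolite sums,
    and ``combined`` totals over the selective-metabolite map.
    """
    col = f"p{allocation_rank}"
    summ = contribution_summary[contribution_summary["scenario"] == scenario]
    if col not in summ.columns:
        raise ConfigurationError(f"allocation summary lacks column {col}")

    hq_rows: list[HQResult] = []
    for rec in hbm.itertuples(index=False):
        group = registry.group(rec.age_group)
        cell = summ[
            (summ["metabolite_id"] == rec.metabolite_id)
            & (summ["age_class"] == rec.age_group)
        ]
        for alloc in cell.itertuples(index=False):
            substance = registry.substance(alloc.substance)
            attributed = attribute_measured_level(rec.value, getattr(alloc, col))
            gv = derive_hbm_gv(substance, rec.metabolite_id, group, adi_choice)
            hq_rows.append(HQResult(
                country=rec.country, age_group=rec.age_group,
                percentile_rank=float(rec.percentile), substance=substance.name,
                metabolite_id=rec.metabolite_id,
                hq=hazard_quotient(attributed, gv),
            ))
        # single-source metabolites carry no allocation rows: 100% pass-through
        if cell.empty:
            producers = registry.producers(rec.metabolite_id)
            if len(producers) == 1:
                substance = producers[0]
                gv = derive_hbm_gv(substance, rec.metabolite_id, group, adi_choice)
                hq_rows.append(HQResult(
                    country=rec.country, age_group=rec.age_group,
                    percentile_rank=float(rec.percentile), substance=substance.name,
                    metabolite_id=rec.metabolite_id,
                    hq=hazard_quotient(float(rec.value), gv),
                ))

    per_substance = pd.DataFrame(
        [(h.country, h.age_group, h.percentile_rank, h.substance, h.metabolite_id, h.hq)
         for h in hq_rows],
        columns=["country", "age_group", "percentile_rank", "substance", "metabolite_id", "hq"],
    )

    cum = (
        per_substance
        .groupby(["country", "age_group", "percentile_rank", "metabolite_id"], as_index=False)["hq"]
        .sum()
        .rename(columns={"hq": "cumulative_hq"})
    )

    combined_rows = []
    cells = per_substance[["country", "age_group", "percentile_rank"]].drop_duplicates()
    for cell_rec in cells.itertuples(index=False):
        cr = combined_total(cell_rec.country, cell_rec.age_group, cell_rec.percentile_rank, hq_rows)
        combined_rows.append((cr.country, cr.age_group, cr.percentile_rank, cr.total_hq,
                              len(cr.components)))
    combined = pd.DataFrame(
        combined_rows,
        columns=["country", "age_group", "percentile_rank", "total_hq", "n_components"],
    )
    return {"per_substance": per_substance, "cumulative": cum, "combined": combined}
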