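"""Sustainability indicators of a solved farm or system.

Four indicators summarize each run: GWP per kg beef carcass, net human-edible
protein (HEP) efficiency, work time per kg carcass and farm profit, plus the
stocking rate (livestock units per hectare of permanent grassland) used as
the explanatory variable of the sensitivity analysis.

Net HEP efficiency is the human-edible protein in the beef produced divided by
the human-edible protein in the feed used to produce that beef; a value above
one means the system adds protein to human nutrition. Rations made of grass
and by-products have an edible-protein input of zero, in which case the
indicator is reported as the +infinity sentinel. On dairy farms, feed eaten by
the milk-producing herd is attributed to beef by the same economic allocation
share as the emissions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from beeflca.fixtures import FarmConfig
from beeflca.herd import production_outputs
from beeflca.optimizer import OptimizationSolution

__all__ = [
    "IndicatorSet",
    "hep_components",
    "total_labor_minutes",
    "net_hep_efficiency",
    "work_time_per_kg",
    "farm_profit",
    "stocking_rate",
    "EDIBLE_PROTEIN_PER_KG_CARCASS",
]

# kg human-edible protein per kg carcass: ~19% crude protein of carcass tissue,
# of which ~3/4 in cuts consumed by humans (configurable default).
EDIBLE_PROTEIN_PER_KG_CARCASS = 0.14

WT_TASKS = ("feeding", "caretaking", "pasture", "fieldwork", "admin")


@dataclass
class IndicatorSet:
    """Indicator bundle for one (farm or system, scenario, draw)."""

    gwp_per_kg_carcass: float  # kg CO2eq / kg carcass
    net_hep_efficiency: float  # dimensionless; may be math.inf
    work_time_per_kg: float  # min / kg carcass
    work_time_breakdown: dict = field(default_factory=dict)
    farm_profit: float = 0.0  # EUR/yr, farm of interest
    stocking_rate: float = 0.0  # LU / ha permanent grassland

    def __post_init__(self) -> None:
        for name in ("gwp_per_kg_carcass", "work_time_per_kg", "stocking_rate"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.net_hep_efficiency < 0:
            raise ValueError("net_hep_efficiency must be >= 0 (may be inf)")

    def to_dict(self) -> dict:
        d = {
            "gwp_per_kg_carcass": self.gwp_per_kg_carcass,
            "net_hep_efficiency": self.net_hep_efficiency,
            "work_time_per_kg": self.work_time_per_kg,
            "farm_profit": self.farm_profit,
            "stocking_rate": self.stocking_rate,
        }
        d.update({f"wt_{k}": v for k, v in self.work_time_breakdown.items()})
        return d


def _dairy_labels(config: FarmConfig) -> set:
    """Classes whose feed belongs to the milk enterprise (allocated share)."""
    return {
        label
        for label, ac in config.herd_spec.classes.items()
        if (ac.mature and ac.milk_sold) or (label == "repl_heifer" and
            any(c.milk_sold for c in config.herd_spec.classes.values()))
    }


def hep_components(
    solution: OptimizationSolution,
    beef_allocation: float = 1.0,
    edible_protein_per_kg_carcass: float = EDIBLE_PROTEIN_PER_KG_CARCASS,
) -> tuple[float, float]:
    """(edible protein out in beef, edible protein in feed), kg/yr.

    Feed eaten by dairy classes counts only with the beef allocation share;
    beef-dedicated classes count fully.
    """
    model = solution.model
    config = model.config
    products = production_outputs(solution.state, config.herd_spec.classes)
    protein_out = float(products["carcass_kg"].sum()) * edible_protein_per_kg_carcass

    dairy = _dairy_labels(config)
    protein_in = 0.0
    for _, row in solution.ration.iterrows():
        props = model.feed_keys[row["feed_key"]]
        edible = row["kg_dm"] * props["cp"] / 1000.0 * props["hep"]
        protein_in += edible * (beef_allocation if row["animal_class"] in dairy else 1.0)
    return protein_out, protein_in


def net_hep_efficiency(
    solution: OptimizationSolution,
    beef_allocation: float = 1.0,
    edible_protein_per_kg_carcass: float = EDIBLE_PROTEIN_PER_KG_CARCASS,
) -> float:
    """Human-edible protein out (beef) over human-edible protein in (feed).

    Zero edible-protein input (all-grass and by-product rations) returns the
    +infinity sentinel: such a system adds protein to human nutrition without
    consuming any.
    """
    protein_out, protein_in = hep_components(
        solution, beef_allocation, edible_protein_per_kg_carcass
    )
    if protein_in <= 0:
        return math.inf
    return protein_out / protein_in


def work_time_per_kg(solution: OptimizationSolution) -> tuple[float, dict]:
    """Work time per kg carcass (min/kg) with a per-task breakdown.

    Tasks: herd feeding (per LU-month), caretaking incl. milking and calving,
    pasture management (per ha, already +10 % under FRG), fieldwork (per ha)
    and administration. The breakdown sums exactly to the total.
    """
    model = solution.model
    config = model.config
    lab = config.labor
    state = solution.state
    classes = config.herd_spec.classes

    lu = sum(state.stock(l) * classes[l].lu_coefficient for l in state.counts.index)
    feeding = lu * 12.0 * lab.feeding_h_per_lu_month
    heads = sum(state.stock(l) for l in state.counts.index)
    caretaking = heads * lab.caretaking_h_per_head_yr
    caretaking += sum(
        state.stock(l) * lab.milking_h_per_cow_yr
        for l in state.counts.index
        if classes[l].mature and classes[l].milk_sold
    )
    caretaking += state.calvings * lab.calving_h_per_calving

    pasture = fieldwork = 0.0
    crop_labor = {c.name: c.field_labor for c in config.crop_activities}
    for act in config.grassland_activities:
        ha = solution.activity_levels.get(act.name, 0.0)
        if act.is_grazing:
            pasture += ha * act.pasture_labor
        else:
            fieldwork += ha * act.pasture_labor
    for name, h_per_ha in crop_labor.items():
        fieldwork += solution.activity_levels.get(name, 0.0) * h_per_ha
    admin = lab.admin_h_fixed

    products = production_outputs(state, classes)
    carcass = float(products["carcass_kg"].sum())
    if carcass <= 0:
        raise ValueError("work time per kg is undefined without carcass output")
    breakdown = {
        "feeding": feeding * 60.0 / carcass,
        "caretaking": caretaking * 60.0 / carcass,
        "pasture": pasture * 60.0 / carcass,
        "fieldwork": fieldwork * 60.0 / carcass,
        "admin": admin * 60.0 / carcass,
    }
    return sum(breakdown.values()), breakdown


def total_labor_minutes(solution: OptimizationSolution) -> float:
    """Total farm work time, minutes/yr (for embodied-labor transfer)."""
    per_kg, _ = work_time_per_kg(solution)
    products = production_outputs(solution.state, solution.model.config.herd_spec.classes)
    return per_kg * float(products["carcass_kg"].sum())


def farm_profit(solution: OptimizationSolution) -> tuple[float, dict]:
    """Profit recomputed from primal values, with its decomposition.

    The total equals the LP objective (identity check, <=1e-6 relative); the
    lines follow the farm's revenue and cost streams: beef, milk, live
    animals and crops sold, subsidies, minus feed and fertilizer purchases,
    animal purchases, activity variable costs and fixed depreciation.
    """
    model = solution.model
    config = model.config
    h = solution.herd_scale
    rev = {k: v * h for k, v in model.revenue_unit.items()}
    rev["milk_sales"] = solution.sales.get("milk", 0.0) * 1000.0 * config.price_table.get("milk", 0.0)
    rev["decoupled_subsidy"] = config.subsidy_decoupled
    crop_by_name = {c.name: c for c in config.crop_activities}
    crop_sales = activity_costs = 0.0
    for name, ha in solution.activity_levels.items():
        if name in crop_by_name:
            crop = crop_by_name[name]
            activity_costs -= ha * crop.input_costs
            if crop.sale_commodity and not crop.produces_feed:
                crop_sales += ha * crop.crop_yield * config.price_table[crop.sale_commodity]
    for act in config.grassland_activities:
        activity_costs -= solution.activity_levels.get(act.name, 0.0) * act.variable_cost
    for commodity, t in solution.sales.items():
        if commodity != "milk":
            crop_sales += t * config.price_table[commodity]
    rev["crop_sales"] = crop_sales
    rev["activity_variable_costs"] = activity_costs
    rev["feed_purchases"] = -sum(
        t * config.feed_catalogue[name].price for name, t in solution.purchases.items()
    )
    rev["fertilizer_purchases"] = -solution.fertilizer_n * config.price_table.get("mineral_n", 1.1)
    rev["fixed_costs"] = -config.fixed_costs
    return sum(rev.values()), rev


def stocking_rate(solution_or_state, config: FarmConfig | None = None) -> float:
    """Livestock units per hectare of permanent grassland."""
    if isinstance(solution_or_state, OptimizationSolution):
        state = solution_or_state.state
        config = solution_or_state.model.config
    else:
        state = solution_or_state
    if config.permanent_grassland <= 0:
        raise ValueError("stocking rate requires permanent grassland > 0")
    classes = config.herd_spec.classes
    lu = sum(state.stock(l) * classes[l].lu_coefficient for l in state.counts.index)
    return lu / config.permanent_grassland
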