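"""Cradle-to-farm-gate greenhouse-gas inventory and GWP characterization.

Sources covered per farm-year:

* enteric CH4 — tier-2 form: CH4 = GE intake x Ym / 55.65 MJ/kg, with gross
  energy taken as a fixed energy density of ration dry matter (default
  18.45 MJ/kg DM). At equal energy supplied, a denser (higher-ME) ration means
  less DM eaten and therefore less methane;
* manure CH4 and manure-management N2O — linear in stable excreta N with
  distinct factor sets for solid and liquid systems;
* soil N2O — direct N2O from applied manure and mineral N and from pasture
  excreta, plus optional indirect N2O via volatilization and leaching;
* energy CO2 — diesel burned in field work and animal transport between farms;
* upstream CO2eq — provision of purchased feed, mineral fertilizer and
  cropping inputs/services, from the configuration's emission-factor tables.

Characterization multiplies gas masses by configurable GWP factors (defaults
CH4 34, N2O 298 kg CO2eq/kg). Economic allocation splits a dairy farm's
burden between milk and beef by value shares; where no market price exists
the optimizer's shadow price stands in. For multi-farm systems, emissions
embodied in transferred animals are expressed per kg live weight and carried
into the downstream farm's account so that the chain total is conserved
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields

from typing import Mapping

import pandas as pd

from beeflca.fixtures import EmissionParams, FarmConfig
from beeflca.herd import N_PER_CP, production_outputs
from beeflca.optimizer import MONTHS, OptimizationSolution

__all__ = [
    "EmissionInventory",
    "TransferRecord",
    "enteric_methane",
    "manure_and_soil_emissions",
    "upstream_emissions",
    "characterize_gwp",
    "allocate_milk_beef",
    "transfer_embodied",
    "system_gwp_per_kg_carcass",
    "nitrogen_flows",
    "compute_inventory",
]

N2O_PER_N = 44.0 / 28.0


@dataclass
class EmissionInventory:
    """Per-source gas masses of one farm-year (kg of each gas)."""

    enteric_ch4: float = 0.0
    manure_ch4: float = 0.0
    manure_n2o: float = 0.0
    soil_n2o: float = 0.0
    energy_co2: float = 0.0
    upstream_co2eq: float = 0.0
    embodied_co2eq: float = 0.0  # carried in with transferred animals
    allocation_applied: float = 1.0

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if f.name != "allocation_applied" and getattr(self, f.name) < 0:
                raise ValueError(f"negative emission mass {f.name}")
        if not 0.0 < self.allocation_applied <= 1.0:
            raise ValueError("allocation_applied must be in (0,1]")

    def __add__(self, other: "EmissionInventory") -> "EmissionInventory":
        if self.allocation_applied != other.allocation_applied:
            raise ValueError("cannot add inventories with different allocations applied")
        kwargs = {
            f.name: getattr(self, f.name) + getattr(other, f.name)
            for f in dc_fields(self)
            if f.name != "allocation_applied"
        }
        return EmissionInventory(allocation_applied=self.allocation_applied, **kwargs)

    def by_source(self, params: EmissionParams) -> dict:
        """Characterized kg CO2eq per source category."""
        return {
            "enteric_ch4": self.enteric_ch4 * params.gwp_ch4,
            "manure_ch4": self.manure_ch4 * params.gwp_ch4,
            "manure_n2o": self.manure_n2o * params.gwp_n2o,
            "soil_n2o": self.soil_n2o * params.gwp_n2o,
            "energy_co2": self.energy_co2 * params.gwp_co2,
            "upstream": self.upstream_co2eq,
            "embodied_in_animals": self.embodied_co2eq,
        }

    def allocated(self, share: float) -> "EmissionInventory":
        """Inventory with an economic allocation share applied to all sources."""
        if not 0.0 < share <= 1.0:
            raise ValueError("allocation share must be in (0,1]")
        kwargs = {
            f.name: getattr(self, f.name) * share
            for f in dc_fields(self)
            if f.name != "allocation_applied"
        }
        return EmissionInventory(allocation_applied=self.allocation_applied * share, **kwargs)


@dataclass(frozen=True)
class TransferRecord:
    """Burden embodied in animals transferred between farms of a system."""

    kg_liveweight_transferred: float
    embodied_ef: float  # kg CO2eq / kg live weight
    embodied_labor: float  # min / kg live weight

    def __post_init__(self) -> None:
        if self.kg_liveweight_transferred <= 0:
            raise ValueError("transfer requires positive live weight")
        if self.embodied_ef < 0 or self.embodied_labor < 0:
            raise ValueError("embodied values must be >= 0")


def enteric_methane(ration: Mapping[str, float], params: EmissionParams | None = None) -> float:
    """Enteric CH4 (kg) from a ration given as kg DM per feed.

    Linear in intake: CH4 = sum(DM) x GE density x Ym / 55.65.
    """
    params = params or EmissionParams()
    dm = 0.0
    for key, kg in ration.items():
        if kg < 0:
            raise ValueError(f"negative ration entry {key}")
        if math.isnan(kg):
            raise ValueError(f"missing intake for {key}")
        dm += kg
    return dm * params.ge_density * params.ym / params.ch4_energy


def manure_and_soil_emissions(
    stable_n: float,
    pasture_n: float,
    mineral_n: float,
    manure_system: str,
    params: EmissionParams | None = None,
) -> dict:
    """Manure CH4, manure-management N2O and soil N2O (kg of each gas).

    ``stable_n`` is excreted in housing (managed, then field-applied after
    storage losses), ``pasture_n`` deposited on pasture, ``mineral_n``
    purchased fertilizer N. Linear in all N flows; solid and liquid systems
    use distinct factor sets.
    """
    params = params or EmissionParams()
    if min(stable_n, pasture_n, mineral_n) < 0:
        raise ValueError("N flows must be >= 0")
    if manure_system not in params.ef_n2o_mms:
        raise ValueError(f"unknown manure system {manure_system!r}")
    applied_manure_n = stable_n * params.manure_n_availability
    manure_ch4 = stable_n * params.manure_ch4_per_kg_n[manure_system]
    manure_n2o = stable_n * params.ef_n2o_mms[manure_system] * N2O_PER_N
    direct = (applied_manure_n + mineral_n) * params.ef_n2o_applied + (
        pasture_n * params.ef_n2o_pasture
    )
    indirect = 0.0
    if params.indirect_n2o:
        volatilized = (
            stable_n * params.frac_gas_manure + mineral_n * params.frac_gas_mineral
        )
        leached = (applied_manure_n + pasture_n + mineral_n) * params.frac_leach
        indirect = volatilized * params.ef_n2o_volat + leached * params.ef_n2o_leach
    soil_n2o = (direct + indirect) * N2O_PER_N
    return {"manure_ch4": manure_ch4, "manure_n2o": manure_n2o, "soil_n2o": soil_n2o}


def upstream_emissions(
    purchases: Mapping[str, float],
    ef_table: Mapping[str, float],
) -> float:
    """kg CO2eq from purchased inputs: sum of quantity x emission factor.

    ``purchases`` and ``ef_table`` must use the same units per item. A missing
    emission factor is an error, never silently zero.
    """
    total = 0.0
    for item, qty in purchases.items():
        if qty < 0:
            raise ValueError(f"negative purchase quantity for {item!r}")
        if item not in ef_table:
            raise KeyError(f"no emission factor for purchased item {item!r}")
        total += qty * ef_table[item]
    return total


def characterize_gwp(inventory: EmissionInventory, params: EmissionParams | None = None) -> float:
    """Characterized GWP of an inventory, kg CO2eq (exact linear combination)."""
    params = params or EmissionParams()
    return float(sum(inventory.by_source(params).values()))


def allocate_milk_beef(beef_value: float, milk_value: float) -> tuple[float, float]:
    """Economic allocation shares (beef_share, milk_share); they sum to 1.

    Values may come from market revenues or, absent a market price, from the
    optimizer's shadow price times the quantity produced.
    """
    if beef_value < 0 or milk_value < 0:
        raise ValueError("product values must be >= 0")
    total = beef_value + milk_value
    if total <= 0:
        raise ValueError("economic allocation requires at least one valued product")
    beef_share = beef_value / total
    return beef_share, 1.0 - beef_share


def nitrogen_flows(solution: OptimizationSolution) -> dict:
    """Stable and pasture excreta N (kg/yr) implied by the solved rations."""
    model = solution.model
    rho = model.config.requirement_params.n_retention_fraction
    stable_n = pasture_n = 0.0
    for _, row in solution.ration.iterrows():
        props = model.feed_keys[row["feed_key"]]
        n_out = row["kg_dm"] * props["cp"] / 1000.0 * N_PER_CP * (1.0 - rho)
        if props["grazed"]:
            pasture_n += n_out
        else:
            stable_n += n_out
    return {"stable_n": stable_n, "pasture_n": pasture_n, "mineral_n": solution.fertilizer_n}


def compute_inventory(
    solution: OptimizationSolution,
    embodied_in: TransferRecord | None = None,
) -> EmissionInventory:
    """Full farm inventory from a solved farm-year.

    ``embodied_in`` carries the upstream burden of animals transferred into
    this farm (breeder-to-fattener chains).
    """
    if solution.status != "optimal":
        raise ValueError("inventory requires an optimal solution")
    model = solution.model
    config = model.config
    ep = config.emission_params

    enteric = enteric_methane(
        {i: r for i, r in enumerate(solution.ration["kg_dm"].tolist())}, ep
    )
    nflows = nitrogen_flows(solution)
    manure = manure_and_soil_emissions(
        nflows["stable_n"], nflows["pasture_n"], nflows["mineral_n"],
        config.manure_system, ep,
    )

    # upstream: purchased feeds (t fresh), mineral N (kg), cropping inputs (ha)
    purchases = dict(solution.purchases)
    ef_table = {name: f.upstream_ef for name, f in config.feed_catalogue.items()}
    upstream = upstream_emissions(purchases, ef_table)
    upstream += nflows["mineral_n"] * ep.ef_mineral_n_upstream
    crop_by_name = {c.name: c for c in config.crop_activities}
    field_hours = 0.0
    for act_name, ha in solution.activity_levels.items():
        if act_name in crop_by_name:
            crop = crop_by_name[act_name]
            upstream += ha * crop.upstream_ef
            field_hours += ha * crop.field_labor
    for act in config.grassland_activities:
        ha = solution.activity_levels.get(act.name, 0.0)
        if not act.is_grazing:
            field_hours += ha * act.pasture_labor  # mechanized harvest

    energy = field_hours * ep.diesel_l_per_field_hour * ep.ef_diesel_co2
    embodied = 0.0
    state = solution.state
    kg_in = 0.0
    for label in state.counts.index:
        ac = config.herd_spec.classes[label]
        kg_in += float(state.annual.loc[label, "purchased"]) * ac.entry_weight
    energy += kg_in * ep.transport_co2_per_kg_lw
    if embodied_in is not None:
        embodied = embodied_in.embodied_ef * embodied_in.kg_liveweight_transferred

    return EmissionInventory(
        enteric_ch4=enteric,
        manure_ch4=manure["manure_ch4"],
        manure_n2o=manure["manure_n2o"],
        soil_n2o=manure["soil_n2o"],
        energy_co2=energy,
        upstream_co2eq=upstream,
        embodied_co2eq=embodied,
    )


def transfer_embodied(
    solution: OptimizationSolution,
    inventory: EmissionInventory,
    total_labor_minutes: float = 0.0,
    beef_allocation: float = 1.0,
) -> TransferRecord:
    """Burden embodied in the animals a breeder transfers downstream.

    The breeder's beef-allocated GWP is split across its animal outputs by
    economic value; the share attributable to transferred animals, divided by
    the kg live weight transferred, becomes the downstream emission factor.
    Labor is treated symmetrically. The chain conserves totals exactly:
    downstream(own + embodied) + breeder retained = breeder + downstream own.
    """
    model = solution.model
    config = model.config
    state = solution.state
    products = production_outputs(state, config.herd_spec.classes)
    kg_transferred = float(products["live_kg_transferred"].sum())
    if kg_transferred <= 0:
        raise ValueError(f"{config.farm_id}: no animals transferred")
    value_transferred = value_total = 0.0
    for label, row in products.iterrows():
        ac = config.herd_spec.classes[label]
        if row["carcass_kg"] > 0:
            value_total += row["carcass_kg"] * config.price_table[ac.price_key]
        if row["live_kg_sold"] > 0:
            value_total += row["live_kg_sold"] * config.price_table[ac.price_key]
        if row["live_kg_transferred"] > 0:
            v = row["live_kg_transferred"] * config.price_table[ac.price_key]
            value_total += v
            value_transferred += v
    share = value_transferred / value_total
    gwp = characterize_gwp(inventory, config.emission_params) * beef_allocation
    return TransferRecord(
        kg_liveweight_transferred=kg_transferred,
        embodied_ef=gwp * share / kg_transferred,
        embodied_labor=total_labor_minutes * beef_allocation * share / kg_transferred,
    )


def system_gwp_per_kg_carcass(farm_results: list[dict]) -> float:
    """System-level GWP per kg beef carcass.

    ``farm_results`` holds one dict per farm with keys ``gwp`` (beef-allocated
    kg CO2eq, own emissions only) and ``carcass_kg`` (kg carcass sold by the
    farm: culled cows, heifers, finished bulls — transferred live animals do
    not count toward the functional unit).
    """
    total_gwp = sum(r["gwp"] for r in farm_results)
    total_carcass = sum(r["carcass_kg"] for r in farm_results)
    if total_carcass <= 0:
        raise ValueError("system produced no carcass")
    return total_gwp / total_carcass
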