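"""Scenario transforms: fast rotational grazing (FRG) and system redesign (SR).

The FRG transform is purely additive: every farm with permanent grassland
gains the FRG grassland activity, and whether, where and for which animals it
is used is left to the profit optimization. Because the baseline solution
stays feasible, FRG profit can never fall below baseline profit.

The SR transforms restructure each system around crossbreeding and sexed
semen:

* **BE-SR** — the specialized fattener is removed; the suckler breeder becomes
  a growing-fattening farm using its repurposed stables; a 70-cow Holstein
  dairy farm is added that breeds replacements with female-sexed Holstein
  semen and Belgian Blue x Holstein male calves otherwise. Calves transfer at
  3 weeks of age for EUR 200 and are finished at 19 months, 330 kg carcass
  (55 % carcass yield), EUR 3.4/kg.
* **FR-IT-SR** — the Italian fattener is removed and finishing moves to the
  French farm; Charolais cows are bred to Angus, bulls slaughtered at
  14 months, 300 kg carcass, EUR 4.18/kg (incl. a EUR 0.4/kg premium).
* **GE-SR** — sexed semen limits purebred heifer calves to the renewal need;
  the other cows produce Belgian Blue x Holstein males finished at 21 months,
  413 kg carcass, EUR 3.8/kg.

The FRG option carries over into the SR scenarios.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace as dc_replace

from beeflca.feeds import build_feed_table
from beeflca.grass import generate_grass_profiles
from beeflca.herd import AnimalClass, HerdSpec
from beeflca.fixtures import FarmConfig, EmissionParams

__all__ = ["CrossbredSpec", "RedesignSpec", "ScenarioSpec", "scenario_spec", "apply_scenario"]


@dataclass(frozen=True)
class CrossbredSpec:
    """Crossbred fattening animal introduced by a redesign."""

    label: str
    sire: str
    dam: str
    slaughter_age_months: float
    carcass_weight: float  # kg
    carcass_yield: float
    price_eur_per_kg: float  # carcass price incl. any premium
    premium_eur_per_kg: float = 0.0
    entry_age_months: float = 0.0
    entry_weight: float = 42.0
    grazes: bool = False
    fiber_floor: float = 0.25

    def __post_init__(self) -> None:
        if self.price_eur_per_kg <= 0:
            raise ValueError("crossbred price must be > 0")

    @property
    def exit_weight(self) -> float:
        return self.carcass_weight / self.carcass_yield

    def to_animal_class(self, price_key: str) -> AnimalClass:
        return AnimalClass(
            label=self.label,
            breed_or_cross=f"{self.sire} x {self.dam}",
            entry_age=self.entry_age_months,
            exit_age=self.slaughter_age_months,
            entry_weight=self.entry_weight,
            exit_weight=self.exit_weight,
            carcass_yield=self.carcass_yield,
            lu_coefficient=0.6,
            grazes=self.grazes,
            fiber_floor=self.fiber_floor,
            sale="carcass",
            price_key=price_key,
        )


@dataclass(frozen=True)
class RedesignSpec:
    removed_farms: tuple = ()
    crossbred: CrossbredSpec | None = None
    sexed_semen: bool = False
    add_dairy_supplier: bool = False
    dairy_cows: float = 0.0
    calf_transfer_age_weeks: float = 0.0
    calf_transfer_price: float = 0.0  # EUR/head


@dataclass(frozen=True)
class ScenarioSpec:
    scenario_id: str  # base | FRG | SR
    frg_enabled: bool = False
    redesign: RedesignSpec | None = None

    def __post_init__(self) -> None:
        if (self.scenario_id == "SR") != (self.redesign is not None):
            raise ValueError("redesign parameters are present iff the scenario is SR")


_SR_SPECS: dict[str, RedesignSpec] = {
    "BE": RedesignSpec(
        removed_farms=("BE-F",),
        crossbred=CrossbredSpec(
            label="crossbred_bull", sire="Belgian Blue", dam="Holstein",
            slaughter_age_months=19.0, carcass_weight=330.0, carcass_yield=0.55,
            price_eur_per_kg=3.4, entry_age_months=0.75, entry_weight=50.0,
            grazes=True, fiber_floor=0.35,
        ),
        sexed_semen=True, add_dairy_supplier=True, dairy_cows=70.0,
        calf_transfer_age_weeks=3.0, calf_transfer_price=200.0,
    ),
    "FR-IT": RedesignSpec(
        removed_farms=("FR-IT-F",),
        crossbred=CrossbredSpec(
            label="angus_bull", sire="Angus", dam="Charolais",
            slaughter_age_months=14.0, carcass_weight=300.0, carcass_yield=0.57,
            price_eur_per_kg=4.18, premium_eur_per_kg=0.4,
            entry_age_months=0.0, entry_weight=45.0, grazes=True, fiber_floor=0.45,
        ),
    ),
    "GE": RedesignSpec(
        crossbred=CrossbredSpec(
            label="crossbred_bull", sire="Belgian Blue", dam="Holstein",
            slaughter_age_months=21.0, carcass_weight=413.0, carcass_yield=0.57,
            price_eur_per_kg=3.8,
        ),
        sexed_semen=True,
    ),
}


def scenario_spec(system_id: str, scenario: str) -> ScenarioSpec:
    """Predefined scenario specification for a system."""
    if scenario == "base":
        return ScenarioSpec("base")
    if scenario == "FRG":
        return ScenarioSpec("FRG", frg_enabled=True)
    if scenario == "SR":
        if system_id not in _SR_SPECS:
            raise ValueError(f"no redesign defined for system {system_id!r}")
        return ScenarioSpec("SR", frg_enabled=True, redesign=_SR_SPECS[system_id])
    raise ValueError(f"unknown scenario {scenario!r}")


def _add_frg(farm: FarmConfig, seed: int) -> None:
    if farm.permanent_grassland > 0:
        have = {a.management for a in farm.grassland_activities}
        if "fast_rotational_grazing" not in have:
            farm.grassland_activities.append(
                generate_grass_profiles(farm.system_id, "fast_rotational_grazing", seed)
            )


def _holstein_dairy_classes(calf_exit_age: float, crossbred_calf: bool) -> dict[str, AnimalClass]:
    male_label = "crossbred_calf_male" if crossbred_calf else "calf_male"
    breed = "Belgian Blue x Holstein" if crossbred_calf else "Holstein"
    return {
        "dairy_cow": AnimalClass(
            label="dairy_cow", breed_or_cross="Holstein", entry_age=27, exit_age=39,
            entry_weight=650, exit_weight=650, carcass_yield=0.45, lu_coefficient=1.0,
            milk_yield=8500, milk_sold=True, grazes=True, fiber_floor=0.45,
            dmi_factor=1.7, mature=True, sale="carcass", price_key="carcass:cull_cow",
        ),
        male_label: AnimalClass(
            label=male_label, breed_or_cross=breed, entry_age=0, exit_age=calf_exit_age,
            entry_weight=42, exit_weight=50, carcass_yield=0.50, lu_coefficient=0.2,
            grazes=False, fiber_floor=0.0,
            sale="transfer" if crossbred_calf else "live",
            price_key=f"live:{male_label}",
        ),
        "surplus_calf_female": AnimalClass(
            label="surplus_calf_female", breed_or_cross="Holstein", entry_age=0, exit_age=0.75,
            entry_weight=42, exit_weight=55, carcass_yield=0.50, lu_coefficient=0.2,
            grazes=False, fiber_floor=0.0, sale="live", price_key="live:surplus_calf_female",
        ),
        "repl_heifer": AnimalClass(
            label="repl_heifer", breed_or_cross="Holstein", entry_age=0, exit_age=27,
            entry_weight=42, exit_weight=620, carcass_yield=0.45, lu_coefficient=0.6,
            grazes=True, fiber_floor=0.55, sale="none",
        ),
    }


def _be_sr_farms(farms: list[FarmConfig], rd: RedesignSpec, seed: int) -> list[FarmConfig]:
    breeder = next(f for f in farms if f.farm_id == "BE-B")
    calf_age_months = rd.calf_transfer_age_weeks / 52.0 * 12.0
    cb = rd.crossbred

    # dairy supplier: fixed Holstein herd, sexed semen, sells crossbred male
    # calves at the transfer age; modelled minimally (the growing-fattening
    # farm is the farm of interest)
    weaning, replacement = 0.90, 0.30
    supplier = FarmConfig(
        farm_id="BE-D", system_id="BE", scenario="SR",
        arable_land=20.0, permanent_grassland=30.0,
        stable_capacity={"dairy_cow": rd.dairy_cows, "repl_heifer": 55.0},
        herd_spec=HerdSpec(
            kind="dairy_supplier", n_units=rd.dairy_cows,
            classes=_holstein_dairy_classes(calf_age_months, crossbred_calf=True),
            weaning_rate=weaning, replacement_rate=replacement,
            female_sexed_share=replacement / weaning, breed="Holstein",
        ),
        crop_activities=[],
        grassland_activities=[
            generate_grass_profiles("BE", "continuous_grazing", seed),
            generate_grass_profiles("BE", "cut_silage", seed),
            generate_grass_profiles("BE", "cut_hay", seed),
        ],
        feed_catalogue=build_feed_table(),
        price_table={
            "carcass:cull_cow": 2.4, "milk": 0.35,
            "live:crossbred_calf_male": rd.calf_transfer_price / 50.0,  # EUR 200 per 50 kg calf
            "live:surplus_calf_female": 2.5, "mineral_n": 1.1,
        },
        subsidy_decoupled=50.0 * 270.0, manure_system="liquid", fixed_costs=55000.0,
    )
    _add_frg(supplier, seed)

    # the breeder becomes a growing-fattening farm on repurposed stables
    gf = breeder.copy()
    gf.scenario = "SR"
    gf.herd_spec = HerdSpec(
        kind="growing_fattening", n_units=300.0,
        classes={cb.label: cb.to_animal_class(f"carcass:{cb.label}")},
        breed=f"{cb.sire} x {cb.dam}",
    )
    # ~300 bull places per year in the repurposed suckler stables
    gf.stable_capacity = {cb.label: 300.0 * (cb.slaughter_age_months - cb.entry_age_months) / 12.0}
    gf.calf_purchase_price = rd.calf_transfer_price
    gf.price_table = {
        k: v for k, v in gf.price_table.items() if not k.startswith(("carcass:", "live:"))
    }
    gf.price_table[f"carcass:{cb.label}"] = cb.price_eur_per_kg
    gf.farm_of_interest = True
    _add_frg(gf, seed)
    return [supplier, gf]


def _fr_sr_farms(farms: list[FarmConfig], rd: RedesignSpec, seed: int) -> list[FarmConfig]:
    farm = next(f for f in farms if f.farm_id == "FR-IT-B").copy()
    farm.scenario = "SR"
    cb = rd.crossbred
    classes = dict(farm.herd_spec.classes)
    del classes["weanling_male"]
    classes[cb.label] = cb.to_animal_class(f"carcass:{cb.label}")
    farm.herd_spec = dc_replace(farm.herd_spec, classes=classes)
    farm.price_table = dict(farm.price_table)
    farm.price_table.pop("live:weanling_male", None)
    farm.price_table[f"carcass:{cb.label}"] = cb.price_eur_per_kg
    farm.stable_capacity = dict(farm.stable_capacity)
    farm.stable_capacity[cb.label] = 60.0
    _add_frg(farm, seed)
    return [farm]


def _ge_sr_farms(farms: list[FarmConfig], rd: RedesignSpec, seed: int) -> list[FarmConfig]:
    farm = farms[0].copy()
    farm.scenario = "SR"
    cb = rd.crossbred
    classes = dict(farm.herd_spec.classes)
    del classes["fattening_bull"]
    classes[cb.label] = cb.to_animal_class(f"carcass:{cb.label}")
    spec = farm.herd_spec
    farm.herd_spec = dc_replace(
        spec,
        classes=classes,
        female_sexed_share=spec.replacement_rate / spec.weaning_rate,
    )
    farm.price_table = dict(farm.price_table)
    farm.price_table.pop("carcass:bull", None)
    farm.price_table[f"carcass:{cb.label}"] = cb.price_eur_per_kg
    farm.stable_capacity = dict(farm.stable_capacity)
    farm.stable_capacity.pop("fattening_bull", None)
    farm.stable_capacity[cb.label] = 130.0
    _add_frg(farm, seed)
    return [farm]


def apply_scenario(
    farms: list[FarmConfig], spec: ScenarioSpec, seed: int = 0
) -> list[FarmConfig]:
    """Transform baseline fixtures according to a scenario specification.

    The baseline scenario is the identity transform (deep copy); FRG is
    additive; SR restructures the farm chain per system.
    """
    farms = [f.copy() for f in farms]
    if spec.scenario_id == "base":
        return farms
    if spec.scenario_id == "FRG":
        for farm in farms:
            farm.scenario = "FRG"
            _add_frg(farm, seed)
        return farms
    if spec.scenario_id == "SR":
        system = farms[0].system_id
        farms = [f for f in farms if f.farm_id not in spec.redesign.removed_farms]
        if system == "BE":
            return _be_sr_farms(farms, spec.redesign, seed)
        if system == "FR-IT":
            return _fr_sr_farms(farms, spec.redesign, seed)
        if system == "GE":
            return _ge_sr_farms(farms, spec.redesign, seed)
        raise ValueError(f"no redesign transform for system {system!r}")
    raise ValueError(f"unknown scenario {spec.scenario_id!r}")
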