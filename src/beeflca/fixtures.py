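"""Synthetic farm fixtures for the three studied beef production systems.

Three systems, each in three scenarios (base, FRG, SR):

* **BE** — a Belgian Blue suckler breeder (155 cows, 54 ha arable, 64 ha
  permanent grassland, cash crops) selling 78 weaned males per year to a
  specialized indoor fattener;
* **FR-IT** — a Charolais/Salers suckler farm in the Massif Central (79 cows,
  96 ha grassland) shipping 38 weanlings per year to an Italian indoor
  fattener (33 ha arable);
* **GE** — an integrated North-Rhine-Westphalian dairy/cash-crop farm
  (130 Holstein cows, 198 ha arable, 27 ha grassland) fattening its own
  male calves (56 bulls/yr).

Herd sizes, land endowments and animals sold per year are study parameters;
weaning rates are derived from them (males sold = cows x weaning rate / 2).
Prices, feed composition defaults, labor and emission factors not printed in
the study are plausible 2017-era defaults (provenance: assumed) and are all
carried on the configuration objects, never hard-coded in downstream logic.
Upstream emission factors are a small synthetic table standing in for a full
LCI database, so absolute GWP levels are internally consistent but not
comparable with inventories built on commercial databases.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

from beeflca.feeds import FeedStuff, build_feed_table
from beeflca.grass import GrasslandActivity, generate_grass_profiles
from beeflca.herd import AnimalClass, HerdSpec, RequirementParams

__all__ = [
    "CropActivity",
    "LaborCoefficients",
    "EmissionParams",
    "FarmConfig",
    "build_system_fixture",
    "SYSTEMS",
    "SCENARIOS",
]

SYSTEMS = ("BE", "FR-IT", "GE")
SCENARIOS = ("base", "FRG", "SR")


@dataclass(frozen=True)
class CropActivity:
    """One hectare-year of an arable cropping activity."""

    name: str
    crop_yield: float  # t fresh product / ha
    use: str  # cash | fodder
    input_costs: float  # EUR/ha (seed, fertilizer purchase excluded: N is balanced explicitly)
    field_labor: float  # h/ha
    nutrient_removal: float  # kg N/ha removed in harvested product
    upstream_ef: float  # kg CO2eq/ha for inputs & services (seed, pesticides, machinery provision)
    produces_feed: str | None = None  # feed commodity if harvest can be fed
    sale_commodity: str | None = None  # price-table key if harvest can be sold

    def __post_init__(self) -> None:
        if self.crop_yield <= 0:
            raise ValueError(f"{self.name}: yield must be > 0")
        if self.use not in ("cash", "fodder"):
            raise ValueError(f"{self.name}: use must be cash or fodder")


@dataclass(frozen=True)
class LaborCoefficients:
    """Work-time coefficients by task (hours)."""

    feeding_h_per_lu_month: float = 0.5
    caretaking_h_per_head_yr: float = 6.0
    milking_h_per_cow_yr: float = 35.0  # only milk-sold cow classes
    calving_h_per_calving: float = 2.0
    admin_h_fixed: float = 250.0  # management & administration per farm-year


@dataclass(frozen=True)
class EmissionParams:
    """Configurable emission factors and characterization factors.

    Defaults follow IPCC-style tier-2 forms (enteric CH4 from gross-energy
    intake with a methane conversion factor Ym; N2O from applied, deposited
    and managed nitrogen) and a GWP100 characterization of CH4 34 and N2O 298
    kg CO2eq/kg. Manure-management factors distinguish solid and liquid
    systems. All values are configuration.
    """

    ym: float = 0.065  # fraction of GE intake emitted as enteric CH4
    ge_density: float = 18.45  # MJ gross energy per kg DM
    ch4_energy: float = 55.65  # MJ per kg CH4
    gwp_ch4: float = 34.0
    gwp_n2o: float = 298.0
    gwp_co2: float = 1.0
    ef_n2o_applied: float = 0.01  # kg N2O-N per kg N applied to soil
    ef_n2o_pasture: float = 0.02  # kg N2O-N per kg N excreted on pasture
    ef_n2o_mms: dict = field(
        default_factory=lambda: {"solid": 0.005, "liquid": 0.001}
    )  # manure management, per kg stable N
    manure_ch4_per_kg_n: dict = field(
        default_factory=lambda: {"solid": 0.08, "liquid": 0.35}
    )  # kg CH4 per kg stable N (synthetic stand-in factors)
    indirect_n2o: bool = True
    frac_gas_manure: float = 0.20  # volatilized share of managed/applied manure N
    frac_gas_mineral: float = 0.10
    ef_n2o_volat: float = 0.01
    frac_leach: float = 0.24
    ef_n2o_leach: float = 0.0075
    manure_n_availability: float = 0.85  # stable N available for fertilization after losses
    diesel_l_per_field_hour: float = 8.0
    ef_diesel_co2: float = 2.65  # kg CO2 per litre burned
    ef_mineral_n_upstream: float = 5.6  # kg CO2eq per kg N provision
    transport_co2_per_kg_lw: float = 0.0  # animal transport into this farm


@dataclass
class FarmConfig:
    """Complete declarative description of one farm."""

    farm_id: str
    system_id: str
    scenario: str
    arable_land: float  # ha
    permanent_grassland: float  # ha
    stable_capacity: dict  # animal places by animal class label
    herd_spec: HerdSpec
    crop_activities: list  # list[CropActivity]
    grassland_activities: list  # list[GrasslandActivity]
    feed_catalogue: dict  # name -> FeedStuff
    price_table: dict  # commodity -> EUR/unit
    subsidy_decoupled: float  # EUR/yr
    labor: LaborCoefficients = field(default_factory=LaborCoefficients)
    requirement_params: RequirementParams = field(default_factory=RequirementParams)
    emission_params: EmissionParams = field(default_factory=EmissionParams)
    manure_system: str = "solid"  # solid | liquid
    herd_other_cost_per_lu_yr: float = 120.0  # vet, bedding, insurance
    fixed_costs: float = 0.0  # depreciation of structures & machinery, EUR/yr
    calf_purchase_price: float = 0.0  # EUR/head entering a fattening herd
    farm_of_interest: bool = False
    n_application_cap: float | None = None  # optional kg N/ha ceiling, off by default

    def __post_init__(self) -> None:
        if self.arable_land < 0 or self.permanent_grassland < 0:
            raise ValueError("land areas must be >= 0")
        if any(v < 0 for v in self.stable_capacity.values()):
            raise ValueError("stable capacity must be >= 0")
        if self.manure_system not in ("solid", "liquid"):
            raise ValueError("manure_system must be solid or liquid")
        self.validate_prices()

    def validate_prices(self) -> None:
        """Every tradable commodity must be priced."""
        missing = []
        for label, ac in self.herd_spec.classes.items():
            if ac.sale in ("carcass", "live", "transfer"):
                key = ac.price_key or f"{'carcass' if ac.sale == 'carcass' else 'live'}:{label}"
                if key not in self.price_table:
                    missing.append(key)
            if ac.milk_sold and "milk" not in self.price_table:
                missing.append("milk")
        for crop in self.crop_activities:
            if crop.sale_commodity and crop.sale_commodity not in self.price_table:
                missing.append(crop.sale_commodity)
        if missing:
            raise ValueError(f"{self.farm_id}: missing prices for {sorted(set(missing))}")

    def copy(self) -> "FarmConfig":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Animal class catalogues (weights in kg, ages in months)
# ---------------------------------------------------------------------------


def _be_breeder_classes() -> dict[str, AnimalClass]:
    return {
        "suckler_cow": AnimalClass(
            label="suckler_cow", breed_or_cross="Belgian Blue", entry_age=36, exit_age=48,
            entry_weight=700, exit_weight=700, carcass_yield=0.58, lu_coefficient=1.0,
            milk_yield=2300, milk_sold=False, coupled_subsidy=160.0, grazes=True,
            fiber_floor=0.60, mature=True, sale="carcass", price_key="carcass:cull_cow",
        ),
        "weanling_male": AnimalClass(
            label="weanling_male", breed_or_cross="Belgian Blue", entry_age=0, exit_age=8,
            entry_weight=50, exit_weight=320, carcass_yield=0.60, lu_coefficient=0.4,
            grazes=True, fiber_floor=0.40, sale="transfer", price_key="live:weanling_male",
        ),
        "weanling_female": AnimalClass(
            label="weanling_female", breed_or_cross="Belgian Blue", entry_age=0, exit_age=8,
            entry_weight=50, exit_weight=300, carcass_yield=0.60, lu_coefficient=0.4,
            grazes=True, fiber_floor=0.40, sale="live", price_key="live:weanling_female",
        ),
        "repl_heifer": AnimalClass(
            label="repl_heifer", breed_or_cross="Belgian Blue", entry_age=0, exit_age=36,
            entry_weight=50, exit_weight=650, carcass_yield=0.58, lu_coefficient=0.6,
            grazes=True, fiber_floor=0.55, sale="none",
        ),
    }


def _be_fattener_classes() -> dict[str, AnimalClass]:
    return {
        "fattening_bull": AnimalClass(
            label="fattening_bull", breed_or_cross="Belgian Blue", entry_age=8, exit_age=20,
            entry_weight=320, exit_weight=740, carcass_yield=0.65, lu_coefficient=0.6,
            grazes=False, fiber_floor=0.25, sale="carcass", price_key="carcass:bull",
        ),
    }


def _fr_breeder_classes() -> dict[str, AnimalClass]:
    return {
        "suckler_cow": AnimalClass(
            label="suckler_cow", breed_or_cross="Charolais/Salers", entry_age=36, exit_age=48,
            entry_weight=750, exit_weight=750, carcass_yield=0.55, lu_coefficient=1.0,
            milk_yield=2000, milk_sold=False, coupled_subsidy=180.0, grazes=True,
            fiber_floor=0.60, mature=True, sale="carcass", price_key="carcass:cull_cow",
        ),
        "weanling_male": AnimalClass(
            label="weanling_male", breed_or_cross="Charolais", entry_age=0, exit_age=8,
            entry_weight=45, exit_weight=300, carcass_yield=0.58, lu_coefficient=0.4,
            grazes=True, fiber_floor=0.45, sale="transfer", price_key="live:weanling_male",
        ),
        "weanling_female": AnimalClass(
            label="weanling_female", breed_or_cross="Charolais", entry_age=0, exit_age=8,
            entry_weight=45, exit_weight=280, carcass_yield=0.58, lu_coefficient=0.4,
            grazes=True, fiber_floor=0.45, sale="live", price_key="live:weanling_female",
        ),
        "repl_heifer": AnimalClass(
            label="repl_heifer", breed_or_cross="Charolais/Salers", entry_age=0, exit_age=36,
            entry_weight=45, exit_weight=700, carcass_yield=0.55, lu_coefficient=0.6,
            grazes=True, fiber_floor=0.55, sale="none",
        ),
    }


def _it_fattener_classes() -> dict[str, AnimalClass]:
    return {
        "fattening_bull": AnimalClass(
            label="fattening_bull", breed_or_cross="Charolais", entry_age=8, exit_age=17,
            entry_weight=300, exit_weight=495, carcass_yield=0.58, lu_coefficient=0.6,
            grazes=False, fiber_floor=0.25, sale="carcass", price_key="carcass:bull",
        ),
    }


def _ge_classes() -> dict[str, AnimalClass]:
    return {
        "dairy_cow": AnimalClass(
            label="dairy_cow", breed_or_cross="Holstein", entry_age=27, exit_age=39,
            entry_weight=650, exit_weight=650, carcass_yield=0.45, lu_coefficient=1.0,
            milk_yield=8500, milk_sold=True, grazes=True, fiber_floor=0.45,
            dmi_factor=1.7, mature=True, sale="carcass", price_key="carcass:cull_cow",
        ),
        "fattening_bull": AnimalClass(
            label="fattening_bull", breed_or_cross="Holstein", entry_age=0, exit_age=19,
            entry_weight=42, exit_weight=640, carcass_yield=0.52, lu_coefficient=0.5,
            grazes=False, fiber_floor=0.25, sale="carcass", price_key="carcass:bull",
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


# ---------------------------------------------------------------------------
# Crop catalogues
# ---------------------------------------------------------------------------


def _crop(name, y, use, costs, labor, n, ef, feed=None, sale=None) -> CropActivity:
    return CropActivity(
        name=name, crop_yield=y, use=use, input_costs=costs, field_labor=labor,
        nutrient_removal=n, upstream_ef=ef, produces_feed=feed, sale_commodity=sale,
    )


def _be_crops() -> list[CropActivity]:
    return [
        _crop("wheat", 8.5, "cash", 620.0, 9.0, 180.0, 420.0, feed="wheat", sale="wheat_grain"),
        _crop("barley", 7.5, "cash", 560.0, 8.5, 150.0, 380.0, feed="barley", sale="barley_grain"),
        _crop("sugar_beet", 80.0, "cash", 1250.0, 14.0, 160.0, 600.0, sale="sugar_beet"),
        _crop("maize_silage", 45.0, "fodder", 700.0, 10.0, 180.0, 480.0, feed="maize_silage"),
    ]


def _ge_crops() -> list[CropActivity]:
    return [
        _crop("wheat", 8.0, "cash", 600.0, 9.0, 170.0, 420.0, feed="wheat", sale="wheat_grain"),
        _crop("barley", 7.2, "cash", 540.0, 8.5, 145.0, 380.0, feed="barley", sale="barley_grain"),
        _crop("rapeseed", 4.0, "cash", 580.0, 8.0, 140.0, 450.0, sale="rapeseed"),
        _crop("sugar_beet", 78.0, "cash", 1250.0, 14.0, 160.0, 600.0, sale="sugar_beet"),
        _crop("maize_silage", 48.0, "fodder", 700.0, 10.0, 185.0, 480.0, feed="maize_silage"),
    ]


def _it_crops() -> list[CropActivity]:
    return [
        _crop("maize_silage", 55.0, "fodder", 760.0, 10.0, 200.0, 520.0, feed="maize_silage"),
    ]


_CROP_PRICES = {
    "wheat_grain": 165.0,
    "barley_grain": 150.0,
    "sugar_beet": 28.0,
    "rapeseed": 380.0,
}


def _grassland_set(system_id: str, seed: int, frg: bool) -> list[GrasslandActivity]:
    acts = [
        generate_grass_profiles(system_id, "continuous_grazing", seed),
        generate_grass_profiles(system_id, "cut_silage", seed),
        generate_grass_profiles(system_id, "cut_hay", seed),
    ]
    if frg:
        acts.append(generate_grass_profiles(system_id, "fast_rotational_grazing", seed))
    return acts


# ---------------------------------------------------------------------------
# Baseline farms
# ---------------------------------------------------------------------------


def _base_farms(system_id: str, seed: int) -> list[FarmConfig]:
    feeds = build_feed_table()
    if system_id == "BE":
        breeder = FarmConfig(
            farm_id="BE-B", system_id="BE", scenario="base",
            arable_land=54.0, permanent_grassland=64.0,
            stable_capacity={"suckler_cow": 155.0, "repl_heifer": 120.0},
            herd_spec=HerdSpec(
                kind="suckler_breeder", n_units=155.0, classes=_be_breeder_classes(),
                weaning_rate=2.0 * 78.0 / 155.0, replacement_rate=0.25, breed="Belgian Blue",
            ),
            crop_activities=_be_crops(),
            grassland_activities=_grassland_set("BE", seed, frg=False),
            feed_catalogue=feeds,
            price_table={
                **_CROP_PRICES,
                "carcass:cull_cow": 2.9, "live:weanling_male": 3.4,
                "live:weanling_female": 2.9, "mineral_n": 1.1,
            },
            subsidy_decoupled=(54.0 + 64.0) * 270.0,
            manure_system="solid", fixed_costs=60000.0, farm_of_interest=True,
        )
        fattener = FarmConfig(
            farm_id="BE-F", system_id="BE", scenario="base",
            arable_land=0.0, permanent_grassland=0.0,
            stable_capacity={"fattening_bull": 120.0},
            herd_spec=HerdSpec(
                kind="fattener", n_units=120.0, classes=_be_fattener_classes(),
                breed="Belgian Blue",
            ),
            crop_activities=[], grassland_activities=[],
            feed_catalogue=feeds,
            price_table={"carcass:bull": 4.05, "live:weanling_purchase": 3.4, "mineral_n": 1.1},
            subsidy_decoupled=0.0, manure_system="solid", fixed_costs=30000.0,
            emission_params=EmissionParams(transport_co2_per_kg_lw=0.06),
        )
        return [breeder, fattener]

    if system_id == "FR-IT":
        breeder = FarmConfig(
            farm_id="FR-IT-B", system_id="FR-IT", scenario="base",
            arable_land=0.0, permanent_grassland=96.0,
            stable_capacity={"suckler_cow": 79.0, "repl_heifer": 70.0},
            herd_spec=HerdSpec(
                kind="suckler_breeder", n_units=79.0, classes=_fr_breeder_classes(),
                weaning_rate=2.0 * 38.0 / 79.0, replacement_rate=0.28, breed="Charolais/Salers",
            ),
            crop_activities=[],
            grassland_activities=_grassland_set("FR-IT", seed, frg=False),
            feed_catalogue=feeds,
            price_table={
                "carcass:cull_cow": 3.0, "live:weanling_male": 2.85,
                "live:weanling_female": 2.5, "mineral_n": 1.1,
            },
            subsidy_decoupled=96.0 * 250.0,
            manure_system="solid", fixed_costs=45000.0, farm_of_interest=True,
        )
        fattener = FarmConfig(
            farm_id="FR-IT-F", system_id="FR-IT", scenario="base",
            arable_land=33.0, permanent_grassland=0.0,
            stable_capacity={"fattening_bull": 175.0},
            herd_spec=HerdSpec(
                kind="fattener", n_units=227.0, classes=_it_fattener_classes(),
                breed="Charolais",
            ),
            crop_activities=_it_crops(), grassland_activities=[],
            feed_catalogue=feeds,
            price_table={
                "carcass:bull": 3.9, "live:weanling_purchase": 2.85, "mineral_n": 1.1,
            },
            subsidy_decoupled=33.0 * 250.0, manure_system="solid", fixed_costs=35000.0,
            emission_params=EmissionParams(transport_co2_per_kg_lw=0.15),
        )
        return [breeder, fattener]

    if system_id == "GE":
        farm = FarmConfig(
            farm_id="GE", system_id="GE", scenario="base",
            arable_land=198.0, permanent_grassland=27.0,
            stable_capacity={"dairy_cow": 130.0, "fattening_bull": 95.0, "repl_heifer": 95.0},
            herd_spec=HerdSpec(
                kind="dairy_integrated", n_units=130.0, classes=_ge_classes(),
                weaning_rate=2.0 * 56.0 / 130.0, replacement_rate=0.30, breed="Holstein",
            ),
            crop_activities=_ge_crops(),
            grassland_activities=_grassland_set("GE", seed, frg=False),
            feed_catalogue=feeds,
            price_table={
                **_CROP_PRICES,
                "carcass:cull_cow": 2.4, "carcass:bull": 3.3,
                "live:surplus_calf_female": 3.0, "milk": 0.35, "mineral_n": 1.1,
            },
            subsidy_decoupled=(198.0 + 27.0) * 270.0,
            manure_system="liquid", fixed_costs=120000.0, farm_of_interest=True,
        )
        return [farm]

    raise ValueError(f"unknown system {system_id!r}")


def build_system_fixture(
    system_id: str, scenario: str = "base", seed: int = 0
) -> list[FarmConfig]:
    """All farms of one system under one scenario.

    Deterministic for a fixed seed. ``base`` returns the baseline farms;
    ``FRG`` adds the fast-rotational-grazing activity to every farm with
    permanent grassland (its adoption is left to the optimizer); ``SR``
    applies the system-redesign transform (crossbreeding, sexed semen and the
    restructured farm chain).
    """
    if system_id not in SYSTEMS:
        raise ValueError(f"unknown system {system_id!r}; expected one of {SYSTEMS}")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    farms = _base_farms(system_id, seed)
    if scenario == "base":
        return farms
    from beeflca.scenarios import scenario_spec, apply_scenario

    return apply_scenario(farms, scenario_spec(system_id, scenario), seed=seed)
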