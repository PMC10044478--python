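"""Monthly herd demographics, animal requirements, products and excreta.

The herd is modelled as a steady state over one calendar year with calvings
spread uniformly across months, so per-class head counts are constant monthly
stocks and flows (births, purchases, sales, transfers) are annual rates split
evenly over twelve months. Animal numbers are continuous, as is standard in
linear-programming farm models; this keeps every quantity derived here (feed
requirements, products, excreta) exactly linear in herd size.

Requirement functions are simple documented linear-in-weight forms

    ME (MJ/d)  = me_base + me_per_kg_lw * LW + me_per_kg_gain * ADG + me_per_kg_milk * milk
    CP (g/d)   = cp_base + cp_per_kg_lw * LW + cp_per_kg_gain * ADG + cp_per_kg_milk * milk
    DMI (kg/d) = (dmi_base + dmi_per_kg_lw * LW) * dmi_factor

with all coefficients configurable through :class:`RequirementParams`. Nitrogen
retention is modelled as a fixed fraction of nitrogen intake, so the excreta
mass balance (intake = retention + excretion) closes exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AnimalClass",
    "HerdSpec",
    "HerdState",
    "RequirementVector",
    "RequirementParams",
    "ExcretaNitrogen",
    "cohort_progression",
    "animal_requirements",
    "class_monthly_requirements",
    "production_outputs",
    "excreta_nitrogen",
    "DAYS_PER_MONTH",
]

DAYS_PER_MONTH = 365.0 / 12.0
N_PER_CP = 1.0 / 6.25  # kg N per kg crude protein


@dataclass(frozen=True)
class AnimalClass:
    """One animal category with a linear live-weight trajectory.

    ``entry_age``/``exit_age`` are months of age; mature classes (cows) set
    ``mature=True`` and keep a constant live weight. ``sale`` states how exits
    leave the farm: ``carcass`` (slaughter sale), ``live`` (live sale, e.g.
    weanlings or surplus calves), ``transfer`` (live transfer to the next farm
    of the same system) or ``none`` (kept, i.e. replacements entering the cow
    herd).
    """

    label: str
    breed_or_cross: str
    entry_age: float  # months
    exit_age: float  # months
    entry_weight: float  # kg live weight
    exit_weight: float  # kg
    carcass_yield: float  # dimensionless (0,1)
    lu_coefficient: float  # livestock units per head
    milk_yield: float = 0.0  # kg milk per head per year (dairy: sold; suckler: suckled)
    milk_sold: bool = False
    coupled_subsidy: float = 0.0  # EUR per head per year
    grazes: bool = True
    housed: bool = True  # occupies a stable place (winter housing)
    fiber_floor: float = 0.40  # min share of ration DM from forage
    dmi_factor: float = 1.0
    mature: bool = False
    sale: str = "none"
    price_key: str | None = None  # entry in the farm price table

    def __post_init__(self) -> None:
        if not self.mature and self.exit_age <= self.entry_age:
            raise ValueError(f"{self.label}: exit_age must exceed entry_age")
        if not 0.0 < self.carcass_yield < 1.0:
            raise ValueError(f"{self.label}: carcass_yield must be in (0,1)")
        if not self.mature and self.exit_weight < self.entry_weight:
            raise ValueError(f"{self.label}: weights must be non-decreasing")

    @property
    def duration_months(self) -> float:
        return 12.0 if self.mature else self.exit_age - self.entry_age

    def live_weight(self, month_of_age: float) -> float:
        """Live weight (kg) at a month of age, linear between entry and exit."""
        if self.mature:
            return self.exit_weight
        if not self.entry_age <= month_of_age <= self.exit_age:
            raise ValueError(
                f"{self.label}: age {month_of_age} outside [{self.entry_age}, {self.exit_age}]"
            )
        frac = (month_of_age - self.entry_age) / self.duration_months
        return self.entry_weight + frac * (self.exit_weight - self.entry_weight)

    def live_weight_trajectory(self) -> list[float]:
        """kg by integer month of age from entry to exit."""
        if self.mature:
            return [self.exit_weight] * 12
        months = np.arange(self.entry_age, self.exit_age + 1e-9)
        return [self.live_weight(float(m)) for m in months]

    @property
    def daily_gain(self) -> float:
        """kg/day averaged over the class duration."""
        if self.mature:
            return 0.0
        return (self.exit_weight - self.entry_weight) / (self.duration_months * DAYS_PER_MONTH)

    @property
    def carcass_weight(self) -> float:
        """kg carcass at exit."""
        return self.exit_weight * self.carcass_yield

    def resized(self, exit_age: float) -> "AnimalClass":
        """Copy with a new slaughter age; the growth rate is preserved, so the
        exit weight (and carcass weight) move with the fattening duration."""
        if self.mature:
            return self
        new_exit_w = self.entry_weight + self.daily_gain * DAYS_PER_MONTH * (
            exit_age - self.entry_age
        )
        return replace(self, exit_age=exit_age, exit_weight=new_exit_w)


@dataclass(frozen=True)
class RequirementVector:
    """Per-head, per-month nutrient requirements and intake limits."""

    me_requirement: float  # MJ/month
    cp_requirement: float  # g/month
    dm_intake_capacity: float  # kg DM/month
    fiber_floor: float  # min forage share of ration DM


@dataclass(frozen=True)
class RequirementParams:
    """Coefficients of the linear requirement functions (all configurable)."""

    me_base: float = 1.4  # MJ/d
    me_per_kg_lw: float = 0.105  # MJ/d per kg LW
    me_per_kg_gain: float = 25.0  # MJ per kg gain
    me_per_kg_milk: float = 5.3  # MJ per kg milk
    cp_base: float = 60.0  # g/d
    cp_per_kg_lw: float = 0.50  # g/d per kg LW
    cp_per_kg_gain: float = 280.0  # g per kg gain
    cp_per_kg_milk: float = 82.0  # g per kg milk
    dmi_base: float = 1.8  # kg DM/d
    dmi_per_kg_lw: float = 0.0185  # kg DM/d per kg LW
    n_retention_fraction: float = 0.10  # share of N intake retained in products


def animal_requirements(
    animal: AnimalClass, month_of_age: float, params: RequirementParams | None = None
) -> RequirementVector:
    """Requirements of one head of ``animal`` during one month of age."""
    params = params or RequirementParams()
    lw = animal.live_weight(month_of_age)
    gain = animal.daily_gain
    milk_per_day = animal.milk_yield / 365.0
    me_day = (
        params.me_base
        + params.me_per_kg_lw * lw
        + params.me_per_kg_gain * gain
        + params.me_per_kg_milk * milk_per_day
    )
    cp_day = (
        params.cp_base
        + params.cp_per_kg_lw * lw
        + params.cp_per_kg_gain * gain
        + params.cp_per_kg_milk * milk_per_day
    )
    dmi_day = (params.dmi_base + params.dmi_per_kg_lw * lw) * animal.dmi_factor
    return RequirementVector(
        me_requirement=me_day * DAYS_PER_MONTH,
        cp_requirement=cp_day * DAYS_PER_MONTH,
        dm_intake_capacity=dmi_day * DAYS_PER_MONTH,
        fiber_floor=animal.fiber_floor,
    )


def class_mean_requirements(
    animal: AnimalClass, params: RequirementParams | None = None
) -> RequirementVector:
    """Average per-head monthly requirements over a uniform age mix.

    With calvings spread uniformly, a class holds equal numbers of every age
    month between entry and exit; requirements are linear in live weight, so
    the mean equals the requirement at the mid-age.
    """
    mid = animal.entry_age if animal.mature else 0.5 * (animal.entry_age + animal.exit_age)
    return animal_requirements(animal, mid, params)


@dataclass(frozen=True)
class HerdSpec:
    """Declarative description of a farm's breeding or fattening herd."""

    kind: str  # suckler_breeder | fattener | dairy_integrated | dairy_supplier | growing_fattening
    n_units: float  # cows (breeding herds) or animals started per year (fatteners)
    classes: dict[str, AnimalClass]
    weaning_rate: float = 0.95  # calves weaned per cow per year
    replacement_rate: float = 0.25  # share of the cow herd replaced per year
    female_sexed_share: float | None = None  # share of calves born as replacement females
    breed: str = ""

    _KINDS = (
        "suckler_breeder",
        "fattener",
        "dairy_integrated",
        "dairy_supplier",
        "growing_fattening",
    )

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown herd kind {self.kind!r}")
        if not 0.0 <= self.replacement_rate <= 1.0:
            raise ValueError("replacement_rate must be in [0,1]")
        if self.n_units < 0:
            raise ValueError("herd size must be >= 0")


@dataclass
class HerdState:
    """Steady-state herd for one year.

    ``counts`` is a (class x month) table of head stocks; ``flows`` holds the
    annual entries and exits per class (each spread uniformly over months);
    ``annual`` details where exits go (sold for slaughter, sold live,
    transferred, kept as replacement) and where entries come from (born,
    purchased).
    """

    counts: pd.DataFrame  # index: class label, columns: 1..12
    annual: pd.DataFrame  # index: class label, columns: born, purchased, entries, sold_carcass, sold_live, transferred_out, kept_replacement
    milk_sold_kg: float
    calvings: float
    n_units: float

    MONTHS = list(range(1, 13))

    def monthly_entries(self, label: str) -> float:
        return float(self.annual.loc[label, "entries"]) / 12.0

    def monthly_exits(self, label: str) -> float:
        row = self.annual.loc[label]
        return float(
            row["sold_carcass"] + row["sold_live"] + row["transferred_out"] + row["kept_replacement"]
        ) / 12.0

    def flow_balance_residual(self) -> float:
        """Max |count(m+1) - count(m) - entries + exits| across classes/months.

        With uniform flows and steady stocks the residual is exactly the
        entries-exits mismatch; it must be ~0 for a valid steady state.
        """
        res = 0.0
        for label in self.counts.index:
            res = max(res, abs(self.monthly_entries(label) - self.monthly_exits(label)))
            row = self.counts.loc[label].to_numpy()
            res = max(res, float(np.max(np.abs(np.diff(np.r_[row, row[0]])))))
        return res

    def scale(self, factor: float) -> "HerdState":
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        return HerdState(
            counts=self.counts * factor,
            annual=self.annual * factor,
            milk_sold_kg=self.milk_sold_kg * factor,
            calvings=self.calvings * factor,
            n_units=self.n_units * factor,
        )

    def stock(self, label: str) -> float:
        return float(self.counts.loc[label].mean())


_ANNUAL_COLS = [
    "born",
    "purchased",
    "entries",
    "sold_carcass",
    "sold_live",
    "transferred_out",
    "kept_replacement",
]


def _empty_annual(labels) -> pd.DataFrame:
    return pd.DataFrame(0.0, index=list(labels), columns=_ANNUAL_COLS)


def cohort_progression(herd_spec: HerdSpec, scenario: str | None = None) -> HerdState:
    """Derive the steady-state monthly herd from a herd specification.

    Flow balance holds exactly by construction; culled cows equal the
    replacement rate times the cow stock; under sexed semen
    (``female_sexed_share``) the male/female calf split follows the stated
    share instead of 50/50.
    """
    spec = herd_spec
    classes = spec.classes
    n = spec.n_units
    labels = list(classes)
    annual = _empty_annual(labels)
    stocks = {label: 0.0 for label in labels}
    milk_sold = 0.0
    calvings = 0.0

    def months_on_farm(label: str) -> float:
        return classes[label].duration_months

    if spec.kind in ("suckler_breeder", "dairy_integrated", "dairy_supplier"):
        cow_label = next(l for l in labels if classes[l].mature)
        cow = classes[cow_label]
        w, rho = spec.weaning_rate, spec.replacement_rate
        calves = n * w
        calvings = calves
        if spec.female_sexed_share is not None:
            female_calves = calves * spec.female_sexed_share
        else:
            female_calves = calves / 2.0
        male_calves = calves - female_calves
        replacements = rho * n
        if replacements > female_calves + 1e-9:
            raise ValueError(
                "infeasible demography: replacement need "
                f"{replacements:.2f}/yr exceeds female calf supply {female_calves:.2f}/yr"
            )
        stocks[cow_label] = n
        annual.loc[cow_label, "entries"] = replacements
        annual.loc[cow_label, "sold_carcass"] = replacements  # culled cows

        heifer_label = next((l for l in labels if "heifer" in l), None)
        if heifer_label is not None:
            annual.loc[heifer_label, ["born", "entries", "kept_replacement"]] = replacements
            stocks[heifer_label] = replacements * months_on_farm(heifer_label) / 12.0

        for label in labels:
            ac = classes[label]
            if label in (cow_label, heifer_label):
                continue
            is_male = "female" not in label and ("male" in label or "bull" in label)
            flow = male_calves if is_male else female_calves - replacements
            if flow < -1e-9:
                raise ValueError(f"negative flow for class {label}")
            flow = max(flow, 0.0)
            annual.loc[label, ["born", "entries"]] = flow
            stocks[label] = flow * months_on_farm(label) / 12.0
            annual.loc[label, {"carcass": "sold_carcass", "live": "sold_live",
                               "transfer": "transferred_out", "none": "kept_replacement"}[ac.sale]] = flow
        if cow.milk_sold:
            milk_sold = n * cow.milk_yield

    elif spec.kind in ("fattener", "growing_fattening"):
        for label in labels:
            ac = classes[label]
            annual.loc[label, ["purchased", "entries"]] = n
            stocks[label] = n * months_on_farm(label) / 12.0
            annual.loc[label, "sold_carcass" if ac.sale in ("carcass", "none") else "sold_live"] = n
    else:  # pragma: no cover - guarded in HerdSpec
        raise ValueError(f"unknown herd kind {spec.kind!r}")

    counts = pd.DataFrame(
        {m: pd.Series(stocks) for m in HerdState.MONTHS}, index=labels
    )
    return HerdState(
        counts=counts,
        annual=annual,
        milk_sold_kg=milk_sold,
        calvings=calvings,
        n_units=n,
    )


def class_monthly_requirements(
    state: HerdState,
    classes: Mapping[str, AnimalClass],
    params: RequirementParams | None = None,
) -> pd.DataFrame:
    """Aggregate requirements of the whole herd, per class and calendar month.

    Returns a DataFrame indexed by (class, month) with columns ``me`` (MJ),
    ``cp`` (g), ``dmi_cap`` (kg DM) and ``fiber_floor``.
    """
    rows = []
    for label in state.counts.index:
        ac = classes[label]
        per_head = class_mean_requirements(ac, params)
        for m in HerdState.MONTHS:
            stock = float(state.counts.loc[label, m])
            rows.append(
                {
                    "animal_class": label,
                    "month": m,
                    "me": per_head.me_requirement * stock,
                    "cp": per_head.cp_requirement * stock,
                    "dmi_cap": per_head.dm_intake_capacity * stock,
                    "fiber_floor": per_head.fiber_floor,
                }
            )
    return pd.DataFrame(rows).set_index(["animal_class", "month"])


def production_outputs(
    state: HerdState, classes: Mapping[str, AnimalClass]
) -> pd.DataFrame:
    """Annual product table per animal class.

    carcass kg = heads sold for slaughter x live weight at exit x carcass
    yield; live sales and transfers are reported in kg live weight.
    """
    rows = []
    for label in state.counts.index:
        ac = classes[label]
        a = state.annual.loc[label]
        exit_lw = ac.exit_weight
        rows.append(
            {
                "animal_class": label,
                "heads_sold": float(a["sold_carcass"] + a["sold_live"] + a["transferred_out"]),
                "carcass_kg": float(a["sold_carcass"]) * exit_lw * ac.carcass_yield,
                "live_kg_sold": float(a["sold_live"]) * exit_lw,
                "live_kg_transferred": float(a["transferred_out"]) * exit_lw,
                "milk_kg": state.milk_sold_kg if (ac.mature and ac.milk_sold) else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("animal_class")


@dataclass(frozen=True)
class ExcretaNitrogen:
    """kg N per month, split between pasture and stable."""

    total: float
    pasture: float
    stable: float


def excreta_nitrogen(
    ration: Mapping[str, float],
    cp_density: Mapping[str, float],
    grazed: Mapping[str, bool],
    retention_fraction: float = RequirementParams.n_retention_fraction,
) -> ExcretaNitrogen:
    """Nitrogen excreted from a ration (kg N), by mass balance.

    ``ration`` maps feed keys to kg DM eaten in the month, ``cp_density`` to
    g CP/kg DM and ``grazed`` flags feeds eaten on pasture. N excreted equals
    N intake minus N retained (a fixed fraction of intake), and the pasture /
    stable split attributes each feed's excreted N to where it was eaten — the
    linear monthly-ration equivalent of a grazing-day split.
    """
    if not 0.0 <= retention_fraction < 1.0:
        raise ValueError("retention_fraction must be in [0,1)")
    total = pasture = 0.0
    for key, kg_dm in ration.items():
        if kg_dm < 0:
            raise ValueError(f"negative ration entry for {key}")
        n_in = kg_dm * cp_density[key] / 1000.0 * N_PER_CP  # kg N
        n_out = n_in * (1.0 - retention_fraction)
        total += n_out
        if grazed.get(key, False):
            pasture += n_out
    return ExcretaNitrogen(total=total, pasture=pasture, stable=total - pasture)
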