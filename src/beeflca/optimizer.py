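"""Profit-maximizing farm linear program.

One LP per farm and year: choose the herd scale, cropping and grassland areas,
monthly rations per animal class, feed purchases and sales, and mineral-N
purchases, maximizing profit subject to

* land balances for arable land and permanent grassland,
* stable-capacity limits per animal class,
* per-class, per-month feed balances in dry matter intake capacity,
  metabolizable energy and crude protein, with a structural-fiber floor,
* grazed grass usable only in its month of growth (no carry-over) while
  conserved forage and concentrates pool over the year,
* a nitrogen balance: nutrient removal of crops and grassland must be covered
  by recycled stable manure N, pasture excreta N and purchased mineral N.

Animal numbers and areas are continuous (standard LP farm-model practice), so
dual values of every named balance are well defined and exposed for economic
allocation. Supplementary feeding on pasture is allowed: grazing classes may
receive conserved feed and concentrates in grazing months.

The LP is solved with HiGHS via :func:`scipy.optimize.linprog`. Duals are
reported as the derivative of the *maximal profit* with respect to the
constraint right-hand side (so a binding resource has a non-negative dual).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from beeflca.fixtures import FarmConfig
from beeflca.herd import (
    HerdState,
    class_monthly_requirements,
    cohort_progression,
    N_PER_CP,
)

__all__ = [
    "LinearProgram",
    "LPResult",
    "FarmModel",
    "OptimizationSolution",
    "build_model",
    "solve",
    "shadow_price",
]

MONTHS = list(range(1, 13))
SOLVER_TOL = 1e-8


class LinearProgram:
    """Small named-variable/named-constraint front end to ``linprog``.

    Maximization; all variables are non-negative unless bounds are given.
    Duals are normalized to d(max objective)/d(rhs).
    """

    def __init__(self) -> None:
        self.var_names: list[str] = []
        self._var_index: dict[str, int] = {}
        self.obj: list[float] = []
        self.bounds: list[tuple[float, float | None]] = []
        self.constraints: list[tuple[str, dict[str, float], str, float]] = []
        self.obj_constant: float = 0.0

    def add_var(self, name: str, obj: float = 0.0, lb: float = 0.0, ub: float | None = None) -> str:
        if name in self._var_index:
            raise ValueError(f"duplicate variable {name!r}")
        self._var_index[name] = len(self.var_names)
        self.var_names.append(name)
        self.obj.append(obj)
        self.bounds.append((lb, ub))
        return name

    def add_constraint(self, name: str, coeffs: Mapping[str, float], sense: str, rhs: float) -> None:
        if sense not in ("<=", ">=", "=="):
            raise ValueError(f"bad sense {sense!r}")
        for v in coeffs:
            if v not in self._var_index:
                raise ValueError(f"constraint {name!r} references unknown variable {v!r}")
        self.constraints.append((name, dict(coeffs), sense, rhs))

    def solve(self) -> "LPResult":
        n = len(self.var_names)
        c = -np.asarray(self.obj, dtype=float)  # maximize
        a_ub, b_ub, ub_names, ub_signs = [], [], [], []
        a_eq, b_eq, eq_names = [], [], []
        for name, coeffs, sense, rhs in self.constraints:
            row = np.zeros(n)
            for v, coef in coeffs.items():
                row[self._var_index[v]] += coef
            if sense == "==":
                a_eq.append(row)
                b_eq.append(rhs)
                eq_names.append(name)
            elif sense == "<=":
                a_ub.append(row)
                b_ub.append(rhs)
                ub_names.append(name)
                ub_signs.append(1.0)
            else:  # >=  ->  -row <= -rhs
                a_ub.append(-row)
                b_ub.append(-rhs)
                ub_names.append(name)
                ub_signs.append(-1.0)
        res = linprog(
            c,
            A_ub=np.array(a_ub) if a_ub else None,
            b_ub=np.array(b_ub) if b_ub else None,
            A_eq=np.array(a_eq) if a_eq else None,
            b_eq=np.array(b_eq) if b_eq else None,
            bounds=self.bounds,
            method="highs",
        )
        status = {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(res.status, "failed")
        values = duals = None
        objective = float("nan")
        if status == "optimal":
            values = {v: float(x) for v, x in zip(self.var_names, res.x)}
            objective = -float(res.fun) + self.obj_constant
            duals = {}
            if a_ub:
                for name, sign, marg in zip(ub_names, ub_signs, res.ineqlin.marginals):
                    # d(max obj)/d(rhs as written); >= rows were negated twice
                    duals[name] = float(-marg * sign)
            if a_eq:
                for name, marg in zip(eq_names, res.eqlin.marginals):
                    duals[name] = float(-marg)
        return LPResult(status=status, objective=objective, values=values, duals=duals,
                        message=str(res.message))


@dataclass
class LPResult:
    status: str
    objective: float
    values: dict | None
    duals: dict | None
    message: str = ""


@dataclass
class FarmModel:
    """Assembled LP plus the templates needed to interpret its solution."""

    config: FarmConfig
    lp: LinearProgram
    unit_state: HerdState  # herd state per unit of the herd variable
    unit_requirements: pd.DataFrame
    feed_keys: dict  # feed key -> dict(me, cp, fill, forage, grazed, feed_name)
    revenue_unit: dict  # per-unit-herd revenue/cost lines (EUR per herd unit)


@dataclass
class OptimizationSolution:
    """Primal/dual summary of one solved farm-year."""

    status: str
    objective: float  # EUR/yr incl. fixed terms
    herd_scale: float
    activity_levels: dict  # activity name -> ha
    ration: pd.DataFrame  # columns feed_key, animal_class, month, kg_dm
    purchases: dict  # feed -> t fresh; plus mineral_n kg
    sales: dict  # commodity -> t
    fertilizer_n: float  # kg mineral N bought
    duals: dict
    model: FarmModel | None = None
    message: str = ""

    @property
    def state(self) -> HerdState:
        return self.model.unit_state.scale(self.herd_scale)


def _feed_key_table(config: FarmConfig) -> dict:
    """All feedable commodities: catalogue feeds plus per-activity grazed grass."""
    keys = {}
    for name, f in config.feed_catalogue.items():
        if name == "grazed_grass":
            continue  # grazing enters through activity-specific keys
        keys[name] = dict(
            me=f.me_density, cp=f.cp_density, fill=f.fill_value,
            forage=f.is_forage, grazed=False, feed_name=name,
            hep=f.human_edible_protein_fraction,
        )
    base_grass = config.feed_catalogue.get("grazed_grass")
    for act in config.grassland_activities:
        if act.is_grazing:
            me = max(act.monthly_me_density)
            cp = max(act.monthly_cp_density)
            keys[f"graze:{act.name}"] = dict(
                me=me, cp=cp,
                fill=base_grass.fill_value if base_grass else 1.0,
                forage=True, grazed=True, feed_name="grazed_grass",
                hep=base_grass.human_edible_protein_fraction if base_grass else 0.0,
            )
    return keys


def _unit_revenue_lines(config: FarmConfig, unit_state: HerdState) -> dict:
    """EUR per unit of the herd variable, by revenue/cost line."""
    spec = config.herd_spec
    lines = {
        "beef_sales": 0.0, "live_animal_sales": 0.0, "milk_sales": 0.0,
        "coupled_subsidy": 0.0, "animal_purchases": 0.0, "herd_variable_costs": 0.0,
    }
    for label, ac in spec.classes.items():
        a = unit_state.annual.loc[label]
        if ac.sale == "carcass" and a["sold_carcass"] > 0:
            lines["beef_sales"] += (
                a["sold_carcass"] * ac.carcass_weight * config.price_table[ac.price_key]
            )
        if ac.sale in ("live", "transfer"):
            heads = a["sold_live"] + a["transferred_out"]
            if heads > 0:
                lines["live_animal_sales"] += heads * ac.exit_weight * config.price_table[ac.price_key]
        stock = unit_state.stock(label)
        lines["coupled_subsidy"] += stock * ac.coupled_subsidy
        lines["herd_variable_costs"] -= stock * ac.lu_coefficient * config.herd_other_cost_per_lu_yr
        purchased = a["purchased"]
        if purchased > 0:
            if spec.kind == "fattener":
                lines["animal_purchases"] -= (
                    purchased * ac.entry_weight * config.price_table["live:weanling_purchase"]
                )
            else:  # growing_fattening: calves at a per-head transfer price
                lines["animal_purchases"] -= purchased * config.calf_purchase_price
    # milk is sold through an explicit balance so its shadow price is exposed;
    # its revenue therefore does NOT appear here
    return lines


def build_model(config: FarmConfig, state: HerdState | None = None) -> FarmModel:
    """Assemble the farm LP from a configuration.

    ``state`` defaults to the steady-state herd of ``config.herd_spec``; it is
    normalized per unit of herd size, and the LP chooses the scale.
    """
    spec = config.herd_spec
    nominal = spec.n_units
    if state is None:
        state = cohort_progression(spec)
    unit_state = state.scale(1.0 / nominal) if nominal > 0 else state
    unit_req = class_monthly_requirements(unit_state, spec.classes, config.requirement_params)
    feed_keys = _feed_key_table(config)
    rev = _unit_revenue_lines(config, unit_state)

    lp = LinearProgram()
    lp.obj_constant = config.subsidy_decoupled - config.fixed_costs

    lp.add_var("herd", obj=sum(rev.values()))

    for crop in config.crop_activities:
        obj = -crop.input_costs
        if crop.sale_commodity and not crop.produces_feed:
            obj += crop.crop_yield * config.price_table[crop.sale_commodity]
        lp.add_var(f"area:{crop.name}", obj=obj)
    for act in config.grassland_activities:
        lp.add_var(f"area:{act.name}", obj=-act.variable_cost)

    classes = spec.classes
    class_labels = [l for l in unit_state.counts.index if unit_state.stock(l) > 0]
    for fkey, props in feed_keys.items():
        for label in class_labels:
            if props["grazed"] and not classes[label].grazes:
                continue
            for m in MONTHS:
                lp.add_var(f"feed:{fkey}:{label}:{m}")

    for name, f in config.feed_catalogue.items():
        if f.purchasable:
            lp.add_var(f"buy:{name}", obj=-f.price, ub=f.max_purchase_t)
    for crop in config.crop_activities:
        if crop.sale_commodity and crop.produces_feed:
            lp.add_var(f"sell:{crop.sale_commodity}", obj=config.price_table[crop.sale_commodity])
    lp.add_var("buy_mineral_n", obj=-config.price_table.get("mineral_n", 1.1))

    milk_unit = unit_state.milk_sold_kg
    if milk_unit > 0:
        lp.add_var("sell_milk", obj=config.price_table["milk"])
        lp.add_constraint("milkbal", {"sell_milk": 1.0, "herd": -milk_unit}, "<=", 0.0)

    # land
    if config.crop_activities:
        lp.add_constraint(
            "land:arable",
            {f"area:{c.name}": 1.0 for c in config.crop_activities},
            "<=", config.arable_land,
        )
    if config.grassland_activities:
        lp.add_constraint(
            "land:grassland",
            {f"area:{a.name}": 1.0 for a in config.grassland_activities},
            "<=", config.permanent_grassland,
        )

    # stable places
    for label, cap in config.stable_capacity.items():
        if label in classes and unit_state.stock(label) > 0:
            lp.add_constraint(
                f"stable:{label}", {"herd": unit_state.stock(label)}, "<=", cap
            )

    # feed balances: conserved/concentrate commodities pool annually
    for name, f in config.feed_catalogue.items():
        if name == "grazed_grass":
            continue
        coeffs: dict[str, float] = {}
        for label in class_labels:
            for m in MONTHS:
                v = f"feed:{name}:{label}:{m}"
                if v in lp._var_index:
                    coeffs[v] = 1.0
        if f.purchasable:
            coeffs[f"buy:{name}"] = -1000.0 * f.dm_fraction  # t fresh -> kg DM
        for crop in config.crop_activities:
            if crop.produces_feed == name:
                coeffs[f"area:{crop.name}"] = coeffs.get(f"area:{crop.name}", 0.0) - (
                    crop.crop_yield * 1000.0 * f.dm_fraction
                )
                if crop.sale_commodity:
                    coeffs[f"sell:{crop.sale_commodity}"] = 1000.0 * f.dm_fraction
        for act in config.grassland_activities:
            if act.produces_feed == name:
                coeffs[f"area:{act.name}"] = coeffs.get(f"area:{act.name}", 0.0) - (
                    act.annual_dm * 1000.0
                )
        if coeffs:
            lp.add_constraint(f"feedbal:{name}", coeffs, "<=", 0.0)

    # grazed grass: month of growth only, no carry-over
    for act in config.grassland_activities:
        if not act.is_grazing:
            continue
        fkey = f"graze:{act.name}"
        for m in MONTHS:
            coeffs = {}
            for label in class_labels:
                v = f"feed:{fkey}:{label}:{m}"
                if v in lp._var_index:
                    coeffs[v] = 1.0
            if not coeffs:
                continue
            coeffs[f"area:{act.name}"] = -act.monthly_dm_yield[m - 1] * 1000.0
            lp.add_constraint(f"graze:{act.name}:{m}", coeffs, "<=", 0.0)

    # nutrition per class and month
    for label in class_labels:
        for m in MONTHS:
            req = unit_req.loc[(label, m)]
            me_c, cp_c, dmi_c, fib_c = {}, {}, {}, {}
            for fkey, props in feed_keys.items():
                v = f"feed:{fkey}:{label}:{m}"
                if v not in lp._var_index:
                    continue
                me_c[v] = props["me"]
                cp_c[v] = props["cp"]
                dmi_c[v] = props["fill"]
                fib_c[v] = (1.0 if props["forage"] else 0.0) - req["fiber_floor"]
            me_c["herd"] = -req["me"]
            cp_c["herd"] = -req["cp"]
            dmi_c["herd"] = -req["dmi_cap"]
            lp.add_constraint(f"me:{label}:{m}", me_c, ">=", 0.0)
            lp.add_constraint(f"cp:{label}:{m}", cp_c, ">=", 0.0)
            lp.add_constraint(f"dmi:{label}:{m}", dmi_c, "<=", 0.0)
            if req["fiber_floor"] > 0:
                lp.add_constraint(f"fiber:{label}:{m}", fib_c, ">=", 0.0)

    # nitrogen balance: removal covered by recycled stable N, pasture N, mineral N
    ep = config.emission_params
    rho = config.requirement_params.n_retention_fraction
    ncoeffs: dict[str, float] = {}
    for crop in config.crop_activities:
        ncoeffs[f"area:{crop.name}"] = crop.nutrient_removal
    for act in config.grassland_activities:
        # removal proportional to N in harvested/grazed DM
        ncoeffs[f"area:{act.name}"] = act.annual_cp * 1000.0 * N_PER_CP
    for fkey, props in feed_keys.items():
        n_excreted = props["cp"] / 1000.0 * N_PER_CP * (1.0 - rho)
        credit = n_excreted if props["grazed"] else n_excreted * ep.manure_n_availability
        for label in class_labels:
            for m in MONTHS:
                v = f"feed:{fkey}:{label}:{m}"
                if v in lp._var_index:
                    ncoeffs[v] = -credit
    ncoeffs["buy_mineral_n"] = -1.0
    lp.add_constraint("nbal", ncoeffs, "<=", 0.0)

    if config.n_application_cap is not None:
        area_total = config.arable_land + config.permanent_grassland
        cap_coeffs = {k: -v for k, v in ncoeffs.items() if k.startswith("feed:")}
        cap_coeffs["buy_mineral_n"] = 1.0
        lp.add_constraint("ncap", cap_coeffs, "<=", config.n_application_cap * area_total)

    return FarmModel(
        config=config, lp=lp, unit_state=unit_state, unit_requirements=unit_req,
        feed_keys=feed_keys, revenue_unit=rev,
    )


def solve(model: FarmModel) -> OptimizationSolution:
    """Solve the farm LP and unpack the solution."""
    res = model.lp.solve()
    if res.status != "optimal":
        message = res.message
        if res.status == "infeasible":
            bad = diagnose_infeasibility(model)
            message = f"infeasible constraint groups: {bad}" if bad else message
        return OptimizationSolution(
            status=res.status, objective=float("nan"), herd_scale=0.0,
            activity_levels={}, ration=pd.DataFrame(), purchases={}, sales={},
            fertilizer_n=0.0, duals={}, model=model, message=message,
        )
    vals = res.values
    rows = []
    for name, x in vals.items():
        if name.startswith("feed:") and x > 1e-9:
            head, label, m = name.rsplit(":", 2)  # feed keys may contain ':'
            fkey = head[len("feed:"):]
            rows.append({"feed_key": fkey, "animal_class": label, "month": int(m), "kg_dm": x})
    ration = pd.DataFrame(rows, columns=["feed_key", "animal_class", "month", "kg_dm"])
    purchases = {
        name.split(":", 1)[1]: v for name, v in vals.items()
        if name.startswith("buy:") and v > 1e-9
    }
    sales = {
        name.split(":", 1)[1]: v for name, v in vals.items()
        if name.startswith("sell:") and v > 1e-9
    }
    if vals.get("sell_milk", 0.0) > 1e-9:
        sales["milk"] = vals["sell_milk"] / 1000.0  # t
    activities = {
        name.split(":", 1)[1]: v for name, v in vals.items() if name.startswith("area:")
    }
    return OptimizationSolution(
        status="optimal", objective=res.objective, herd_scale=vals["herd"],
        activity_levels=activities, ration=ration, purchases=purchases,
        sales=sales, fertilizer_n=vals.get("buy_mineral_n", 0.0),
        duals=res.duals, model=model,
    )


def diagnose_infeasibility(model: FarmModel) -> list[str]:
    """Identify constraint groups needing elastic relaxation for feasibility."""
    lp = model.lp
    elastic = LinearProgram()
    elastic.var_names = list(lp.var_names)
    elastic._var_index = dict(lp._var_index)
    elastic.obj = [0.0] * len(lp.obj)
    elastic.bounds = list(lp.bounds)
    slack_groups: dict[str, str] = {}
    for name, coeffs, sense, rhs in lp.constraints:
        group = name.split(":", 1)[0]
        coeffs = dict(coeffs)
        slack = f"__slack:{name}"
        elastic.add_var(slack, obj=-1.0)
        coeffs[slack] = -1.0 if sense in ("<=", "==") else 1.0
        elastic.constraints.append((name, coeffs, sense, rhs))
        slack_groups[slack] = group
    res = elastic.solve()
    if res.status != "optimal" or res.values is None:
        return []
    groups = sorted(
        {slack_groups[v] for v, x in res.values.items() if v.startswith("__slack:") and x > 1e-6}
    )
    return groups


def shadow_price(solution: OptimizationSolution, commodity: str) -> float:
    """Dual value of a commodity balance (EUR per unit of the balance).

    Feed commodities return EUR/kg DM from their annual balance; ``milk``
    returns EUR/kg from the milk balance. Used by economic allocation when no
    exogenous market price exists.
    """
    if solution.status != "optimal":
        raise ValueError("shadow prices require an optimal solution")
    for key in (commodity, f"feedbal:{commodity}", "milkbal" if commodity == "milk" else None):
        if key and key in solution.duals:
            return solution.duals[key]
    raise KeyError(f"no balance constraint for commodity {commodity!r}")
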