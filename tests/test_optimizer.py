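"""Farm LP correctness: oracles, duality, identities and properties."""

import numpy as np
import pytest

from lp_oracle import random_bounded_lp, vertex_enumeration_max

from beeflca.fixtures import build_system_fixture
from beeflca.optimizer import LinearProgram, build_model, shadow_price, solve


class TestLinearProgramAgainstEnumeration:
    def test_random_small_lps_match_vertex_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(120):
            c, a, b, lb, ub = random_bounded_lp(rng)
            lp = LinearProgram()
            for j in range(c.size):
                lp.add_var(f"x{j}", obj=float(c[j]), lb=float(lb[j]), ub=float(ub[j]))
            for i in range(a.shape[0]):
                lp.add_constraint(
                    f"c{i}", {f"x{j}": float(a[i, j]) for j in range(c.size)}, "<=", float(b[i])
                )
            res = lp.solve()
            oracle = vertex_enumeration_max(c, a, b, lb, ub)
            assert res.status == "optimal"
            assert res.objective == pytest.approx(oracle, abs=1e-8)

    def test_hand_solved_dual(self):
        # max 3x + 2y s.t. x + y <= 4, x <= 2: optimum (2,2)=10;
        # dual of the first constraint is 2, of the second 1 (manual simplex)
        lp = LinearProgram()
        lp.add_var("x", obj=3.0)
        lp.add_var("y", obj=2.0)
        lp.add_constraint("sum", {"x": 1.0, "y": 1.0}, "<=", 4.0)
        lp.add_constraint("capx", {"x": 1.0}, "<=", 2.0)
        res = lp.solve()
        assert res.objective == pytest.approx(10.0)
        assert res.duals["sum"] == pytest.approx(2.0)
        assert res.duals["capx"] == pytest.approx(1.0)

    def test_ge_and_eq_dual_signs(self):
        # min-cost style: max -x s.t. x >= 3  ->  x*=3, d(obj)/d(rhs) = -1
        lp = LinearProgram()
        lp.add_var("x", obj=-1.0)
        lp.add_constraint("floor", {"x": 1.0}, ">=", 3.0)
        res = lp.solve()
        assert res.objective == pytest.approx(-3.0)
        assert res.duals["floor"] == pytest.approx(-1.0)


class TestFarmModel:
    def test_subsidy_only_closed_form(self, be_base_farms):
        # no animals, single cash crop of margin m on A ha:
        # profit = m*A + decoupled subsidy - fixed costs, with m net of the
        # mineral N that must be bought to cover the crop's nutrient removal
        farm = be_base_farms[0].copy()
        farm.stable_capacity = {k: 0.0 for k in farm.stable_capacity}  # no animals
        keep = [c for c in farm.crop_activities if c.name == "sugar_beet"]
        farm.crop_activities = keep
        farm.grassland_activities = []
        farm.permanent_grassland = 0.0
        sol = solve(build_model(farm))
        assert sol.status == "optimal"
        beet = keep[0]
        margin = (
            beet.crop_yield * farm.price_table["sugar_beet"]
            - beet.input_costs
            - beet.nutrient_removal * farm.price_table["mineral_n"]
        )
        expected = margin * farm.arable_land + farm.subsidy_decoupled - farm.fixed_costs
        assert sol.objective == pytest.approx(expected, rel=1e-9)
        assert sol.herd_scale == pytest.approx(0.0, abs=1e-9)

    def test_bound_feed_balance_dual_equals_market_price(self):
        # BE fattener buys all feed; if maize silage purchase is active, the
        # dual of its balance equals the purchase price per kg DM (LP duality)
        farms = build_system_fixture("BE", "base", seed=0)
        fat = farms[1]
        sol = solve(build_model(fat))
        assert sol.status == "optimal"
        feeds = fat.feed_catalogue
        for name, t in sol.purchases.items():
            if t > 1e-6 and feeds[name].max_purchase_t is None:
                price_per_kg_dm = feeds[name].price / (1000.0 * feeds[name].dm_fraction)
                assert shadow_price(sol, name) == pytest.approx(price_per_kg_dm, rel=1e-6)
                break
        else:
            pytest.fail("no unconstrained purchased feed found")

    def test_milk_shadow_price_positive_and_equals_market(self, ge_base_result):
        sol = ge_base_result["farms"]["GE"]["solution"]
        milk_dual = shadow_price(sol, "milk")
        assert milk_dual == pytest.approx(sol.model.config.price_table["milk"], rel=1e-6)
        assert milk_dual > 0

    def test_baselines_feasible_all_systems(self):
        for system in ("BE", "FR-IT", "GE"):
            for farm in build_system_fixture(system, "base", seed=0):
                sol = solve(build_model(farm))
                assert sol.status == "optimal", f"{farm.farm_id}: {sol.message}"

    def test_yield_relaxation_never_decreases_profit(self, be_base_farms):
        # raising a grassland activity's yields relaxes the feasible set
        farm = be_base_farms[0]
        base = solve(build_model(farm)).objective
        richer = farm.copy()
        richer.grassland_activities = [
            a.scaled_yield(1.2) if a.is_grazing else a for a in richer.grassland_activities
        ]
        assert solve(build_model(richer)).objective >= base - 1e-6

    def test_price_scaling_scales_profit(self, be_base_farms):
        farm = be_base_farms[0].copy()
        k = 2.0
        farm.price_table = {c: p * k for c, p in farm.price_table.items()}
        farm.feed_catalogue = {
            n: f.__class__(**{**f.to_dict(), "price": f.price * k})
            for n, f in farm.feed_catalogue.items()
        }
        for attr in ("subsidy_decoupled", "fixed_costs", "herd_other_cost_per_lu_yr"):
            setattr(farm, attr, getattr(farm, attr) * k)
        farm.crop_activities = [
            c.__class__(**{**c.__dict__, "input_costs": c.input_costs * k})
            for c in farm.crop_activities
        ]
        farm.grassland_activities = [
            a.__class__(**{**a.to_dict(), "variable_cost": a.variable_cost * k})
            for a in farm.grassland_activities
        ]
        classes = {
            l: ac.__class__(**{**ac.__dict__, "coupled_subsidy": ac.coupled_subsidy * k})
            for l, ac in farm.herd_spec.classes.items()
        }
        from dataclasses import replace

        farm.herd_spec = replace(farm.herd_spec, classes=classes)
        base = solve(build_model(be_base_farms[0])).objective
        scaled = solve(build_model(farm)).objective
        assert scaled == pytest.approx(k * base, rel=1e-9)

    def test_infeasible_reports_constraint_group(self, be_base_farms):
        farm = be_base_farms[0].copy()
        # force herd but forbid all feed: nutrition becomes infeasible
        farm.grassland_activities = []
        farm.permanent_grassland = 0.0
        farm.crop_activities = []
        farm.arable_land = 0.0
        farm.feed_catalogue = {
            n: f.__class__(**{**f.to_dict(), "purchasable": False})
            for n, f in farm.feed_catalogue.items()
        }
        model = build_model(farm)
        model.lp.add_constraint("minherd", {"herd": 1.0}, ">=", 10.0)
        sol = solve(model)
        assert sol.status == "infeasible"
        assert "infeasible constraint groups" in sol.message

    def test_missing_price_raises_validation_error(self, be_base_farms):
        farm = be_base_farms[0].copy()
        farm.price_table = dict(farm.price_table)
        del farm.price_table["carcass:cull_cow"]
        with pytest.raises(ValueError, match="missing prices"):
            farm.validate_prices()
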