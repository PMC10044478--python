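"""Latin-Hypercube design, re-optimization per draw, HEP-stocking relation."""

import math

import numpy as np
import pandas as pd
import pytest

from beeflca.fixtures import build_system_fixture
from beeflca.sensitivity import (
    DEFAULT_RANGES,
    hep_vs_stocking,
    lhs_design,
    perturb_farm,
    run_sensitivity,
)


class TestDesign:
    def test_default_design_has_100_draws_over_stated_ranges(self):
        d = lhs_design(seed=0)
        assert d.n_draws == 100
        assert d.matrix.shape == (100, 3)
        assert d.parameters["stable_capacity"] == (0.8, 1.2)
        assert d.parameters["frg_yield"] == (0.9, 1.1)
        assert d.parameters["slaughter_age"] == (0.9, 1.1)

    @pytest.mark.parametrize("column", list(DEFAULT_RANGES))
    def test_one_sample_per_stratum(self, column):
        d = lhs_design(n_draws=100, seed=3)
        assert (d.stratum_counts(column) == 1).all()

    def test_seed_reproducibility_and_divergence(self):
        a = lhs_design(n_draws=20, seed=5).matrix
        b = lhs_design(n_draws=20, seed=5).matrix
        c = lhs_design(n_draws=20, seed=6).matrix
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_single_draw_inside_box(self):
        d = lhs_design(n_draws=1, seed=1)
        row = d.matrix.iloc[0]
        for name, (lo, hi) in DEFAULT_RANGES.items():
            assert lo <= row[name] <= hi

    def test_marginal_uniformity_large_n(self):
        from scipy import stats

        d = lhs_design(n_draws=400, seed=2)
        for name, (lo, hi) in DEFAULT_RANGES.items():
            u = (d.matrix[name] - lo) / (hi - lo)
            assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lhs_design(n_draws=0)
        with pytest.raises(ValueError):
            lhs_design(ranges={"x": (1.0, 1.0)})


class TestPerturbation:
    def test_slaughter_age_rounds_to_whole_months(self):
        farm = build_system_fixture("GE", "SR", seed=0)[0]
        p = perturb_farm(farm, pd.Series({"slaughter_age": 1.07}))
        bull = p.herd_spec.classes["crossbred_bull"]
        assert bull.exit_age == round(21 * 1.07)  # 22 months
        assert bull.exit_weight > farm.herd_spec.classes["crossbred_bull"].exit_weight

    def test_stable_and_frg_multipliers(self):
        farm = build_system_fixture("BE", "FRG", seed=0)[0]
        p = perturb_farm(farm, pd.Series({"stable_capacity": 0.8, "frg_yield": 1.1}))
        for k in farm.stable_capacity:
            assert p.stable_capacity[k] == pytest.approx(0.8 * farm.stable_capacity[k])
        frg = next(a for a in p.grassland_activities
                   if a.management == "fast_rotational_grazing")
        assert frg.annual_dm == pytest.approx(9.0 * 1.1)
        cg = next(a for a in p.grassland_activities if a.management == "continuous_grazing")
        assert cg.annual_dm == pytest.approx(8.0)  # baseline sward untouched


class TestRunSensitivity:
    def test_degenerate_design_gives_identical_rows(self):
        d = lhs_design(n_draws=3, seed=0)
        d.matrix.loc[:, :] = 1.0
        results = run_sensitivity("GE", "base", d, seed=0)
        assert len(results) == 3
        assert (results["status"] == "optimal").all()
        cols = ["farm_profit", "gwp_per_kg_carcass", "stocking_rate"]
        assert (results[cols].nunique() == 1).all()

    def test_single_draw_equals_direct_run(self):
        from beeflca.pipeline import evaluate_system

        d = lhs_design(n_draws=1, seed=4)
        results = run_sensitivity("GE", "base", d, seed=0)
        farms = [perturb_farm(f, d.matrix.iloc[0]) for f in
                 build_system_fixture("GE", "base", seed=0)]
        direct = evaluate_system(farms)["indicators"]
        assert results.iloc[0]["farm_profit"] == pytest.approx(direct.farm_profit, rel=1e-9)

    def test_reproducible_median_on_small_design(self):
        d = lhs_design(n_draws=10, seed=7)
        r1 = run_sensitivity("GE", "base", d, seed=0)
        r2 = run_sensitivity("GE", "base", d, seed=0)
        assert r1["farm_profit"].median() == r2["farm_profit"].median()


class TestHepVsStocking:
    def test_constant_hep_gives_undefined_correlation(self):
        df = pd.DataFrame({
            "status": ["optimal"] * 5,
            "stocking_rate": [1.0, 2.0, 3.0, 4.0, 5.0],
            "net_hep_efficiency": [0.5] * 5,
        })
        out = hep_vs_stocking(df)
        assert math.isnan(out["spearman_rho"])

    def test_synthetic_decreasing_series_gives_minus_one(self):
        df = pd.DataFrame({
            "status": ["optimal"] * 6,
            "stocking_rate": np.linspace(1, 4, 6),
            "net_hep_efficiency": np.linspace(2.0, 0.2, 6),
        })
        out = hep_vs_stocking(df)
        assert out["spearman_rho"] == pytest.approx(-1.0)

    def test_infeasible_rows_counted_not_dropped_silently(self):
        df = pd.DataFrame({
            "status": ["optimal", "optimal", "infeasible", "optimal"],
            "stocking_rate": [1.0, 2.0, float("nan"), 3.0],
            "net_hep_efficiency": [1.5, 1.0, float("nan"), 0.5],
        })
        out = hep_vs_stocking(df)
        assert out["n_infeasible"] == 1
        assert out["n_used"] == 3

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            hep_vs_stocking(pd.DataFrame({"stocking_rate": [1.0],
                                          "net_hep_efficiency": [1.0]}))

    def test_increasing_herd_at_fixed_grassland_gives_negative_correlation(self):
        # fixture family: scale the stable (herd) at fixed grassland; feed
        # pressure pushes human-edible concentrate into the ration
        from beeflca.pipeline import evaluate_system

        farms = build_system_fixture("BE", "base", seed=0)
        rows = []
        for cap in np.linspace(0.7, 1.3, 7):
            scaled = [perturb_farm(f, pd.Series({"stable_capacity": cap})) for f in farms]
            ind = evaluate_system(scaled)["indicators"]
            rows.append({
                "status": "optimal",
                "stocking_rate": ind.stocking_rate,
                "net_hep_efficiency": ind.net_hep_efficiency,
            })
        out = hep_vs_stocking(pd.DataFrame(rows))
        assert out["spearman_rho"] < 0
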