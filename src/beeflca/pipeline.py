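"""End-to-end orchestration: fixtures -> optimization -> inventory -> indicators.

``evaluate_system`` runs a whole system (one or two farms) for one scenario:
the upstream farm (suckler breeder or dairy supplier) is solved first; its
animal transfers cap the downstream fattening herd and carry an embodied
emission factor and embodied labor into the downstream account, so the chain
total is conserved exactly. System indicators use the functional unit of 1 kg
beef carcass at farm gate (culled cows, heifers and finished bulls).

``run_pipeline`` writes fixtures, solutions, inventories, indicators and a
run manifest to disk; ``report`` aggregates finished runs into per-source GWP
and work-time breakdown tables plus scenario-vs-baseline deltas. Reruns with
identical manifest inputs reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

import beeflca
from beeflca.emissions import (
    TransferRecord,
    allocate_milk_beef,
    characterize_gwp,
    compute_inventory,
    system_gwp_per_kg_carcass,
)
from beeflca.fixtures import FarmConfig, build_system_fixture
from beeflca.herd import production_outputs
from beeflca.indicators import (
    IndicatorSet,
    farm_profit,
    hep_components,
    net_hep_efficiency,
    stocking_rate,
    total_labor_minutes,
    work_time_per_kg,
)
from beeflca.optimizer import build_model, solve

__all__ = ["evaluate_farm", "evaluate_system", "run_pipeline", "report", "RunManifest"]

log = logging.getLogger("beeflca")

_UPSTREAM_KINDS = ("suckler_breeder", "dairy_supplier", "dairy_integrated")
_DOWNSTREAM_KINDS = ("fattener", "growing_fattening")


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    system_id: str
    scenario: str
    seed: int
    version: str
    timestamp: str
    outputs: list = field(default_factory=list)
    status: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def evaluate_farm(
    farm: FarmConfig,
    embodied_in: TransferRecord | None = None,
    entry_cap: float | None = None,
) -> dict:
    """Solve one farm and compute its inventory, allocation and products.

    ``entry_cap`` limits animals entering per year (the upstream farm's
    transfer supply); ``embodied_in`` carries their embodied emissions.
    """
    model = build_model(farm)
    if entry_cap is not None:
        entries_per_unit = float(model.unit_state.annual["purchased"].sum())
        if entries_per_unit > 0:
            model.lp.add_constraint(
                "supply:animals", {"herd": entries_per_unit}, "<=", entry_cap
            )
    sol = solve(model)
    if sol.status != "optimal":
        raise ValueError(f"{farm.farm_id}: {sol.status} ({sol.message})")

    inventory = compute_inventory(sol, embodied_in=embodied_in)
    state = sol.state
    products = production_outputs(state, farm.herd_spec.classes)

    milk_kg = float(products["milk_kg"].sum())
    if milk_kg > 0:
        milk_value = milk_kg * farm.price_table["milk"]
        beef_value = 0.0
        for label, row in products.iterrows():
            ac = farm.herd_spec.classes[label]
            if ac.price_key and ac.price_key in farm.price_table:
                qty = row["carcass_kg"] + row["live_kg_sold"] + row["live_kg_transferred"]
                beef_value += qty * farm.price_table[ac.price_key]
        beef_share, milk_share = allocate_milk_beef(beef_value, milk_value)
    else:
        beef_share, milk_share = 1.0, 0.0

    labor_minutes = total_labor_minutes(sol)
    return {
        "farm": farm,
        "solution": sol,
        "inventory": inventory,
        "products": products,
        "beef_share": beef_share,
        "milk_share": milk_share,
        "gwp_total": characterize_gwp(inventory, farm.emission_params),
        "gwp_beef": characterize_gwp(inventory, farm.emission_params) * beef_share,
        "labor_minutes": labor_minutes,
        "labor_beef": labor_minutes * beef_share,
        "carcass_kg": float(products["carcass_kg"].sum()),
        "transferred_kg": float(products["live_kg_transferred"].sum()),
        "transferred_heads": float(
            sum(state.annual.loc[l, "transferred_out"] for l in state.counts.index)
        ),
    }


def evaluate_system(farms: list[FarmConfig]) -> dict:
    """Run all farms of a system, chaining transfers upstream to downstream."""
    upstream = [f for f in farms if f.herd_spec.kind in _UPSTREAM_KINDS]
    downstream = [f for f in farms if f.herd_spec.kind in _DOWNSTREAM_KINDS]
    if not upstream:
        raise ValueError("system has no breeding farm")

    results = {}
    transfer = None
    up_res = None
    for farm in upstream:
        res = evaluate_farm(farm)
        results[farm.farm_id] = res
        up_res = res
        if downstream and res["transferred_kg"] > 0:
            from beeflca.emissions import transfer_embodied

            transfer = transfer_embodied(
                res["solution"], res["inventory"],
                total_labor_minutes=res["labor_minutes"],
                beef_allocation=res["beef_share"],
            )
    for farm in downstream:
        res = evaluate_farm(
            farm,
            embodied_in=transfer,
            entry_cap=up_res["transferred_heads"] if up_res else None,
        )
        results[farm.farm_id] = res

    # functional unit: all carcass sold by the system's farms
    farm_terms = [
        {"gwp": r["gwp_beef"], "carcass_kg": r["carcass_kg"]} for r in results.values()
    ]
    gwp_kg = system_gwp_per_kg_carcass(farm_terms)
    carcass_total = sum(r["carcass_kg"] for r in results.values())
    wt_kg = sum(r["labor_beef"] for r in results.values()) / carcass_total

    protein_out = protein_in = 0.0
    for r in results.values():
        out_r, in_r = hep_components(r["solution"], r["beef_share"])
        protein_out += out_r
        protein_in += in_r
    hep = protein_out / protein_in if protein_in > 0 else math.inf

    foi = next((f for f in farms if f.farm_of_interest), farms[0])
    foi_res = results[foi.farm_id]
    profit, profit_lines = farm_profit(foi_res["solution"])
    sr = (
        stocking_rate(foi_res["solution"])
        if foi.permanent_grassland > 0
        else 0.0
    )
    wt_breakdown = work_time_per_kg(foi_res["solution"])[1]

    indicators = IndicatorSet(
        gwp_per_kg_carcass=gwp_kg,
        net_hep_efficiency=hep,
        work_time_per_kg=wt_kg,
        work_time_breakdown=wt_breakdown,
        farm_profit=profit,
        stocking_rate=sr,
    )
    return {
        "farms": results,
        "transfer": transfer,
        "indicators": indicators,
        "profit_lines": profit_lines,
        "system_carcass_kg": carcass_total,
        "farm_of_interest": foi.farm_id,
    }


def save_fixtures(farms: list[FarmConfig], out_dir: Path) -> list[str]:
    """Serialize farm configurations (YAML) and profile tables (CSV)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for farm in farms:
        path = out_dir / f"{farm.farm_id}.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(farm.to_dict(), fh, sort_keys=False)
        written.append(str(path))
        prof = pd.DataFrame(
            {a.name: a.monthly_dm_yield for a in farm.grassland_activities},
            index=pd.Index(range(1, 13), name="month"),
        )
        ppath = out_dir / f"{farm.farm_id}_grass_profiles.csv"
        prof.to_csv(ppath)
        written.append(str(ppath))
    feeds = farms[0].feed_catalogue
    fpath = out_dir / "feed_table.csv"
    pd.DataFrame([f.to_dict() for f in feeds.values()]).to_csv(fpath, index=False)
    written.append(str(fpath))
    return written


def run_pipeline(
    system_id: str, scenario: str, seed: int = 0, out_dir: str | Path = "results"
) -> dict:
    """Run one (system, scenario) end to end and persist all outputs."""
    out = Path(out_dir) / f"{system_id}_{scenario}"
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        system_id=system_id, scenario=scenario, seed=seed,
        version=beeflca.__version__,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    farms = build_system_fixture(system_id, scenario, seed=seed)
    manifest.outputs += save_fixtures(farms, out / "fixtures")
    result = evaluate_system(farms)
    manifest.status["optimization"] = "optimal"

    inv_rows = []
    for fid, r in result["farms"].items():
        row = {"farm_id": fid, "beef_share": r["beef_share"]}
        row.update(r["inventory"].by_source(r["farm"].emission_params))
        inv_rows.append(row)
    inv_path = out / "inventory.csv"
    pd.DataFrame(inv_rows).to_csv(inv_path, index=False)
    manifest.outputs.append(str(inv_path))

    ind = result["indicators"].to_dict()
    ind.update({"system": system_id, "scenario": scenario, "seed": seed})
    ind_path = out / "indicators.csv"
    pd.DataFrame([ind]).to_csv(ind_path, index=False)
    manifest.outputs.append(str(ind_path))

    profit_path = out / "profit_lines.json"
    profit_path.write_text(json.dumps(result["profit_lines"], indent=2, sort_keys=True))
    manifest.outputs.append(str(profit_path))

    (out / "manifest.json").write_text(manifest.to_json())
    log.info("pipeline %s/%s complete: %s", system_id, scenario, out)
    return result


def report(results_dir: str | Path) -> dict:
    """Aggregate finished runs: GWP source breakdown, WT breakdown, deltas."""
    results_dir = Path(results_dir)
    ind_files = sorted(results_dir.glob("*/indicators.csv"))
    inv_files = sorted(results_dir.glob("*/inventory.csv"))
    if not ind_files:
        raise FileNotFoundError(f"no completed runs under {results_dir}")
    indicators = pd.concat([pd.read_csv(f) for f in ind_files], ignore_index=True)
    inventories = pd.concat(
        [pd.read_csv(f).assign(run=f.parent.name) for f in inv_files], ignore_index=True
    )
    deltas = None
    base = indicators[indicators["scenario"] == "base"]
    if len(base):
        rows = []
        for _, row in indicators.iterrows():
            b = base[base["system"] == row["system"]]
            if row["scenario"] == "base" or b.empty:
                continue
            b = b.iloc[0]
            for col in ("gwp_per_kg_carcass", "net_hep_efficiency", "work_time_per_kg",
                        "farm_profit", "stocking_rate"):
                if b[col] and math.isfinite(b[col]) and math.isfinite(row[col]):
                    rows.append({
                        "system": row["system"], "scenario": row["scenario"],
                        "indicator": col, "baseline": b[col], "value": row[col],
                        "pct_change": 100.0 * (row[col] - b[col]) / abs(b[col]),
                    })
        deltas = pd.DataFrame(rows)
    return {"indicators": indicators, "inventories": inventories, "deltas": deltas}
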