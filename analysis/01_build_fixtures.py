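#!/usr/bin/env python
"""Generate and serialize the farm fixtures of all systems and scenarios.

Writes one directory per (system, scenario) under results/fixtures with farm
configurations (YAML), monthly grass profiles and the feed table (CSV), and
prints the fixture headline numbers: herd sizes, land endowments and the
annual grazing yields."""

from pathlib import Path

from beeflca.fixtures import SCENARIOS, SYSTEMS, build_system_fixture
from beeflca.pipeline import save_fixtures

SEED = 1
OUT = Path("results/fixtures")


def main() -> None:
    for system in SYSTEMS:
        for scenario in SCENARIOS:
            farms = build_system_fixture(system, scenario, seed=SEED)
            save_fixtures(farms, OUT / f"{system}_{scenario}")
            for farm in farms:
                grazing = [a for a in farm.grassland_activities if a.is_grazing]
                yields = ", ".join(f"{a.management}={a.annual_dm:.1f} t DM/ha" for a in grazing)
                print(
                    f"{system}/{scenario} {farm.farm_id}: {farm.herd_spec.kind}, "
                    f"{farm.herd_spec.n_units:g} herd units, "
                    f"{farm.arable_land:g} ha arable + {farm.permanent_grassland:g} ha grassland"
                    + (f" ({yields})" if yields else "")
                )
    print(f"\nfixtures written under {OUT}/")


if __name__ == "__main__":
    main()
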