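"""Feedstuff catalogue.

Composition values are per kg of dry matter (DM). ``human_edible_protein_fraction``
is the share of the feed's crude protein that could have been consumed directly
by humans; forages, grazed grass and by-products such as pressed sugar beet
pulp carry 0 by convention, cereal grains about 0.8, soybean meal about 0.65
(values in the range used by feed-food competition literature). All values are
configuration, not hard-coded into any downstream logic: every computation
reads them from the catalogue a :class:`~beeflca.fixtures.FarmConfig` carries.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

__all__ = ["FeedStuff", "build_feed_table"]


@dataclass(frozen=True)
class FeedStuff:
    """One purchasable or farm-grown feed commodity.

    Parameters
    ----------
    name : str
        Commodity label used in price tables, rations and balances.
    dm_fraction : float
        kg DM per kg fresh matter, in [0, 1].
    me_density : float
        Metabolizable energy, MJ ME per kg DM.
    cp_density : float
        Crude protein, g CP per kg DM.
    fill_value : float
        Intake-capacity units per kg DM (reference forage = 1; concentrates
        occupy less rumen fill per kg DM).
    human_edible_protein_fraction : float
        Share of CP directly consumable by humans, in [0, 1].
    price : float
        EUR per tonne fresh matter.
    upstream_ef : float
        Cradle-to-farm-gate emission factor of provision and transport,
        kg CO2eq per tonne fresh matter.
    is_forage : bool
        Counts toward the ration's structural-fiber floor.
    purchasable : bool
        Whether the optimizer may buy it on the market.
    max_purchase_t : float or None
        Annual purchase ceiling, t fresh (by-products such as pressed pulp
        are contract-limited regional supplies); None means unlimited.
    """

    name: str
    dm_fraction: float
    me_density: float
    cp_density: float
    fill_value: float
    human_edible_protein_fraction: float
    price: float
    upstream_ef: float
    is_forage: bool = False
    purchasable: bool = True
    max_purchase_t: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.dm_fraction <= 1.0:
            raise ValueError(f"{self.name}: dm_fraction must be in [0,1]")
        if not 0.0 <= self.human_edible_protein_fraction <= 1.0:
            raise ValueError(f"{self.name}: human_edible_protein_fraction must be in [0,1]")
        if self.me_density < 0 or self.cp_density < 0 or self.fill_value < 0:
            raise ValueError(f"{self.name}: densities must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def build_feed_table() -> dict[str, FeedStuff]:
    """Default feed catalogue covering the feeds the studied systems use.

    Returns a dict keyed by feed name. Grazed grass appears here as a generic
    entry; in the optimization, grass grazed from a specific pasture activity
    takes its ME/CP densities from that :class:`~beeflca.grass.GrasslandActivity`.
    Prices and upstream emission factors are plausible 2017-era defaults
    (provenance: assumed) and are meant to be overridden per farm where known.
    """
    feeds = [
        #         name              dm    ME    CP  fill  hep  EUR/t  EF    forage purch
        FeedStuff("grazed_grass", 0.18, 11.0, 200.0, 1.00, 0.0, 0.0, 0.0, True, False),
        FeedStuff("grass_silage", 0.35, 10.2, 160.0, 1.10, 0.0, 45.0, 35.0, True, True),
        FeedStuff("hay", 0.86, 8.8, 120.0, 1.20, 0.0, 120.0, 45.0, True, True),
        FeedStuff("maize_silage", 0.33, 10.8, 75.0, 1.00, 0.15, 38.0, 30.0, True, True),
        FeedStuff("wheat", 0.87, 13.3, 120.0, 0.40, 0.80, 165.0, 350.0, False, True),
        FeedStuff("barley", 0.87, 12.9, 115.0, 0.40, 0.80, 150.0, 330.0, False, True),
        FeedStuff("soymeal", 0.88, 13.2, 480.0, 0.40, 0.65, 360.0, 2500.0, False, True),
        FeedStuff("beet_pulp_pressed", 0.25, 11.8, 95.0, 0.80, 0.0, 28.0, 25.0, True, True,
                  max_purchase_t=400.0),
        FeedStuff("milk_replacer", 0.96, 16.0, 230.0, 0.20, 0.92, 2200.0, 1300.0, False, True),
    ]
    return {f.name: f for f in feeds}
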