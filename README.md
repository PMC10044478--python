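# beeflca

Farm-level bio-economic optimization and cradle-to-farm-gate greenhouse-gas
accounting for European beef production systems.

## The problem

Beef production is under pressure to cut its contribution to global warming
and its use of feed that people could eat directly. Two management
innovations are candidates: **fast rotational grazing** (FRG — paddocks
grazed 0.5–3 days, raising grass quantity and quality over continuous
grazing) and **system redesign** (SR — producing beef from dairy- or
early-maturing crossbred animals using sexed semen, instead of specialized
suckler herds). Whether they pay off depends on whole-farm economics: grass
only substitutes for maize silage and concentrates if the profit-maximizing
plan says so.

`beeflca` answers that question with a single-farm linear program coupled to
a GHG inventory and feed-food competition accounting, exercised on stylized
fixtures of three typical systems:

* **BE** — Belgian Blue suckler breeder (155 cows, 54 ha arable, 64 ha
  grassland) + indoor fattener;
* **FR-IT** — Charolais/Salers suckler farm in the Massif Central (79 cows,
  96 ha grassland) + Italian indoor fattener;
* **GE** — integrated German dairy/cash-crop farm (130 Holstein cows,
  198 ha arable, 27 ha grassland) fattening its own male calves.

## Model core

For each farm-year the package maximizes profit

```
max  Σ p_s q_s  −  Σ c_a x_a          (sales minus activity & purchase costs)
s.t. land, stable places, monthly feed balances (DM, ME, CP, intake
     capacity, fiber floor), grazed grass only in its growth month,
     N balance: crop+grass removal ≤ recycled manure N + pasture N + bought N
```

over continuous activity levels: cropping and grassland hectares, herd scale,
monthly rations per animal class, purchases and sales. Herd demographics are
a monthly steady state (births, replacement, culling, slaughter, transfers);
animal requirements are linear in live weight, so everything stays a pure LP
with well-defined duals (shadow prices), solved with HiGHS.

From the optimum the package computes the four sustainability indicators:

* **GWP/kg carcass** — tier-2 enteric CH₄ (GE intake × Ym / 55.65), manure
  CH₄/N₂O with solid/liquid factor sets, soil N₂O, field-energy CO₂ and
  upstream burdens, characterized with GWP100 (CH₄ 34, N₂O 298) and split
  between milk and beef by economic allocation (shadow prices where no market
  price exists). Emissions embodied in transferred animals move between farms
  as kg CO₂eq/kg live weight with exact chain conservation;
* **net HEP efficiency** — human-edible protein in beef ÷ human-edible
  protein in the feed used for beef (>1 = net protein gain for human
  nutrition);
* **work time/kg carcass** — feeding, caretaking, pasture management
  (+10 %/ha under FRG), fieldwork, administration;
* **farm profit** — identical, by construction, to the LP objective.

A Latin-Hypercube layer re-optimizes 100 draws over stable size (±20 %), FRG
yield (±10 %) and slaughter age (±10 %) and relates net HEP efficiency to the
stocking rate (LU/ha permanent grassland).

## Worked example

```sh
$ python analysis/02_run_baselines.py
system    profit EUR/yr  GWP kg/kg  net HEP  WT min/kg  LU/ha PG
BE              119,992      32.83     1.69       7.21      4.00
FR-IT            16,337      38.96     3.92      10.71      1.39
GE              446,189      10.05     1.76       3.85      8.41
```

Each row is one solved baseline system: the farm-of-interest profit, the
system GWP per kg carcass (beef-allocated, all farms of the chain), the net
human-edible protein efficiency, work time per kg carcass, and the stocking
rate. The dairy-integrated GE system has the lowest GWP per kg beef because
milk carries most of the herd's burden under economic allocation; the grass
rich FR-IT system has the highest net HEP efficiency per unit of edible feed
input. Absolute GWP levels rest on the package's synthetic emission-factor
table and are meant for scenario comparison, not for benchmarking against
inventories built on commercial LCI databases.

`analysis/03_scenario_effects.py` adds the FRG and SR scenarios and prints
percentage changes against each baseline; `analysis/04_sensitivity.py` runs
the 100-draw LHS per system and scenario and reports the Spearman rank
correlation between net HEP efficiency and stocking rate (negative in all
nine runs).

The same machinery is scriptable through the CLI:

```sh
beeflca run --system BE --scenario FRG --seed 1 --out results
beeflca sensitivity --system BE --scenario SR --n 100 --seed 7 --out results
```

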