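# Methods

## Scope and structure

`beeflca` is an analysis package: a library (`src/beeflca`) implementing a
single-farm profit-maximization model with monthly herd and feed accounting,
a cradle-to-farm-gate GHG inventory, feed-food competition and work-time
indicators, scenario transforms and a Latin-Hypercube sensitivity layer; and
numbered drivers (`analysis/`) that run the stylized Belgian, French–Italian
and German beef systems through it. Everything the drivers print is computed
at run time from the fixture configurations.

## Herd model

The herd is a steady state over one calendar year. Calvings are spread
uniformly over months, so per-class head counts are constant monthly stocks
and all flows (births, purchases, sales, transfers) are annual rates split
evenly across twelve months; monthly flow balance then holds exactly by
construction. Animal numbers are continuous, in the linear-programming
tradition: the model describes an average year, not individual animals, and
continuity keeps every derived quantity linear in herd size and all LP duals
well defined.

Weaning rates of the fixture herds are derived from the fixture systems'
printed statistics (males sold per year = cows × weaning rate / 2), giving
1.006 (BE), 0.962 (FR-IT) and 0.862 (GE) calves weaned per cow-year. The
Belgian value slightly above one is what the printed herd numbers imply for a
tightly managed Belgian Blue herd; it is carried as a fixture parameter, not
a biological claim.

Requirement functions are deliberately simple linear-in-weight forms,

    ME (MJ/d)  = 1.4 + 0.105·LW + 25·ADG + 5.3·milk
    CP (g/d)   = 60  + 0.50·LW  + 280·ADG + 82·milk
    DMI (kg/d) = (1.8 + 0.0185·LW) · intake factor

with every coefficient configurable (`RequirementParams`). They are not a
reimplementation of any specific feed-planning standard: published
requirement systems are nonlinear and far more detailed. The linear forms
keep the farm model a pure LP while preserving the properties the analysis
needs (monotonicity in weight, linearity in herd size, a meaningful intake
ceiling and a structural-fiber floor per class). Dairy cows carry an intake
factor of 1.7; without it a 650 kg cow could not physically eat a
28 kg-milk-day ration.

Nitrogen retention is a fixed fraction (default 0.10) of nitrogen intake, so
the excreta mass balance closes exactly: N excreted = (1 − ρ) × N intake. The
pasture/stable split attributes each feed's excreted N to where that feed was
eaten (grazed grass → pasture). In a monthly average-ration model this is the
linear equivalent of a grazing-day split and is what keeps the LP's nitrogen
balance a linear constraint.

## Farm LP

Decision variables: herd scale, hectares per cropping and grassland activity,
kg DM of each feed per animal class per month, feed purchases/sales, mineral
N purchase, milk sale. Constraints: arable and grassland area balances;
stable places per animal class; per-class-month metabolizable energy and
crude protein floors, dry-matter intake ceilings (feed-specific fill values)
and a minimum forage share; monthly balances for grazed grass (no carry-over)
and annual pools for conserved forage and concentrates; and a nitrogen
balance requiring crop and grassland nutrient removal to be covered by
recycled stable manure N (after a storage-loss factor), pasture excreta N and
purchased mineral N. An optional per-hectare N application cap exists but is
off by default. Labor is accounted for the work-time indicator but is not a
binding constraint.

Solved with HiGHS through `scipy.optimize.linprog` at default tolerances
(~1e-9 feasibility; the package asserts its identities at 1e-6 or tighter).
Duals are normalized to d(max profit)/d(rhs) and exposed by constraint name;
the milk balance is modelled explicitly so that milk always has a shadow
price even when it has a market price (in which case the two coincide).
Activity levels at the optimum may be non-unique (LP degeneracy); reported
results rest on the objective and on totals, not on a particular basis.

By-products are purchase-limited (pressed sugar-beet pulp: 400 t fresh/yr per
farm) because they are contract-limited regional supplies; without a limit
the LP substitutes pulp for every other feed and the feed-food competition
question disappears.

## Emissions and allocation

Enteric CH₄ uses the tier-2 form CH₄ = GE × Ym / 55.65 with gross energy
computed from ration dry matter at a fixed energy density (18.45 MJ GE/kg DM,
configurable) and Ym = 6.5 %. Computing GE from DM rather than from ME means
that a ration of higher energy density supplying the same ME produces less
methane — the grass-quality mechanism the FRG scenario is about. A tier-3
treatment of sward quality on the methane conversion factor itself is
deliberately not attempted.

Manure CH₄ and manure-management N₂O are linear in stable excreta N with
distinct solid (BE, FR-IT) and liquid (GE) factor sets; soil N₂O covers
applied manure and mineral N (EF 0.01), pasture deposition (EF 0.02) and
optional indirect volatilization/leaching pathways. Field energy CO₂ is
derived from fieldwork hours via a diesel-use factor; upstream burdens of
purchased feed, mineral N and cropping inputs come from the configuration's
emission-factor tables. Those upstream factors are a small synthetic table:
internally consistent, configurable, but **not** equivalent to a commercial
LCI database — absolute GWP levels are therefore comparable only within this
package. Characterization defaults are GWP100-style CH₄ 34 and N₂O 298.

Milk/beef allocation is economic (value shares; shadow prices where no market
price exists). For two-farm chains the breeder's beef-allocated GWP is split
over its animal outputs by economic value, and the share on transferred
animals becomes an emission factor per kg live weight in the fattener's
account; embodied work time moves symmetrically (the same allocation is used
for both, a deliberate symmetry choice). The chain conserves totals exactly
and the system indicator divides by all carcass sold (culled cows, heifers,
finished bulls — the functional unit), never counting live transfers as
product.

## Indicators

Net HEP efficiency = edible protein in carcass output ÷ edible protein in
feed input. Beef output uses a configurable 0.14 kg edible protein per kg
carcass (≈19 % crude protein of carcass tissue, ~3/4 of it in cuts consumed
by humans). Feed edible fractions sit on the feed table (cereals 0.8, soymeal
0.65, milk replacer 0.92, maize silage 0.15 for its grain share; grass,
conserved forage and by-products 0). A zero denominator (all-grass/by-product
systems) returns +infinity as a documented sentinel. On dairy farms the feed
of the milk-producing classes enters the denominator with the beef allocation
share, consistent with the emission allocation.

Work time sums feeding (per LU-month), caretaking/milking/calving (per head,
cow and calving), pasture management (per ha; FRG carries the +10 % premium),
fieldwork (per ha) and a fixed administration block, divided by carcass
output. Profit is recomputed from primal values line by line and must equal
the LP objective; this identity is asserted in the tests at 1e-6 relative.

## Scenarios

FRG adds the fast-rotational-grazing activity (annual DM 9.0/4.4/9.9 t/ha in
BE/FR-IT/GE versus 8.0/4.0/9.0 continuous; FRG CP totals 1.9/0.9/2.1 t/ha;
+37.5 EUR/ha, +10 % pasture labor) to every farm with grassland and leaves
adoption to the optimizer. Because it only adds options, FRG profit can never
fall below baseline — a property the tests exercise. The within-season
monthly split of the annual totals is a documented seasonal weight vector
(spring peak, autumn flush; grazing April–October in BE/GE, May–October in
the mountainous FR-IT site) with a small seeded jitter; annual totals are
preserved exactly under any seed.

SR restructures each system: BE replaces the suckler chain with a 70-cow
Holstein supplier (sexed semen; renewal share of female-sexed inseminations
set to replacement need) plus a growing-fattening farm on repurposed stables
(calves transferred at 3 weeks for EUR 200; bulls 19 months, 330 kg carcass
at 55 % yield, EUR 3.4/kg; coupled suckler subsidies leave with the cows);
FR-IT finishes Angus-cross bulls on the breeding farm (14 months, 300 kg,
EUR 4.18/kg incl. 0.4 premium); GE fattens Belgian Blue × Holstein bulls
(21 months, 413 kg, EUR 3.8/kg). The BE dairy supplier is modelled minimally
(fixed herd, calves as output) since the growing-fattening farm is the farm
of interest. The GE split between female-sexed and male-sexed inseminations
is not pinned by the study design and is exposed as a parameter (default:
renewal need).

## Sensitivity analysis

`scipy.stats.qmc.LatinHypercube` generates the seeded design; the default is
100 draws over stable capacity ×[0.8, 1.2], FRG yield ×[0.9, 1.1] and
slaughter age ×[0.9, 1.1], uniform and uncorrelated, one sample per stratum
per column. Slaughter-age multipliers are rounded to whole months (the
model's time grid); exit weight moves with the new duration at constant daily
gain. The FRG multiplier perturbs only the FRG sward, not the baseline sward
(configurable). Every draw re-solves all farms; infeasible draws are flagged
and counted, never dropped silently. The HEP–stocking-rate relation is
summarized by a Spearman rank correlation; a constant series is reported as
undefined rather than zero.

## Fixtures: what they emulate and what they do not

The fixture module reproduces the three systems' printed structure exactly
(herd sizes, land endowments, animals sold per year, grazing yield totals,
scenario parameters). Prices, feed composition, labor coefficients and
emission factors not printed anywhere are plausible 2017-era defaults flagged
as assumed, and all of them live in configuration objects. Consequently the
pipeline's *relative* scenario effects and all structural properties
(conservation laws, identities, directions, correlations) are meaningful,
while *absolute* profit and GWP levels are properties of the fixture defaults.
Weather-driven grass growth, multi-year dynamics, drought years, heterosis
genetics, health dynamics beyond flat rates, and acidification/eutrophication
midpoints are out of scope.

## Problem sizes and numerical choices

A farm LP has ~450 variables and ~220 constraints and solves in tens of
milliseconds; the full 3×3 run grid plus a 100-draw LHS per cell (900
re-optimizations) completes in about half a minute on one core, which is the
scale the analysis drivers and tests use. Degenerate inputs are handled
explicitly: zero herds give zero flows; zero carcass output makes per-kg
indicators an error rather than a division; infeasible LPs are diagnosed by
elastic relaxation and reported by constraint group; replacement demand
exceeding female calf supply is rejected as infeasible demography.
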