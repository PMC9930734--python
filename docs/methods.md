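# Methods

`cowcalfsim` is a stochastic, individual-animal simulator of a U.S.
commercial (Angus-type) beef cow–calf herd on a daily time step, plus an
exploratory-factor-analysis (EFA) pipeline for comparing its output with
field performance records. This note documents the model, its
assumptions, the parameters that matter, and the limits of what the test
suite demonstrates.

## Model overview

Each animal carries genetic potentials (GP) for mature weight (MW, kg at
BCS 5 and body-fat fraction 0.1889), peak lactation (PL, kg milk/d),
205-d weaning weight (WW, lb, steer base) and birth weight (BW, lb, bull
base). Each day, every animal's nutrient requirements, intake, growth,
body condition, reproductive state and health outcomes are updated, and
calendar-driven management rules (breeding exposure, pregnancy diagnosis,
weaning, culling, replacement, grazing turnout/removal) act on the herd.

### Genetics

Sire WW potential derives from a linear regression on sire MW
(`0.42·1400 + (MW_lb − 1400)·0.125`), sire BW from a regression on WW
(`0.037·(WW_base + WW_EBV_1992) + 54.202`), each plus a four-year moving
average of breed EBV trends (EBV = 2 × EPD; a sire serves four seasons
with first progeny at age two). Progeny potentials are normal draws
around the parental average (SDs: MW 25.4 kg, PL 1 kg, WW 22 lb, BW
3.76 lb). After each breeding season the conception cohort's traits are
adjusted so the sample correlations hit their targets exactly —
MW–PL +0.14, MW–WW +0.44, WW–BW +0.29, BW–gestation length +0.30 — by a
constructive blend (standardize, mix target·x with the scaled residual,
restore mean/SD) that leaves the anchor trait bit-identical. Phenotypic
birth weight is N(BW GP, 4.07 lb) minus a dam-age adjustment; heifer
calves weigh 94% (and carry 93% of the steer WW potential).

Pre-weaning growth potential: base ADG = (sexed, dam-age-adjusted WW GP −
BW GP)/205; the base weaning-weight potential is birth weight plus base
ADG times each calf's weaning age. Before day 80 calf gain is limited
only by energy intake; from day 80 daily gain is capped at the
straight-line rate needed to reach that potential, and calves can never
exceed it.

### Nutrition

Energy is the only nutrient modelled. Maintenance requirement is
`[0.0007·(20 − T) + 0.077]·CSBW^0.75` Mcal NEm (T = monthly mean °C) plus
lactation (0.72 Mcal/kg milk) and gestation (conceptus deposition from
the pre-drawn calf birth weight and gestation day, converted at 0.13 and
charged at km = 0.576). Milk follows a Wood-type curve scaled so that
yield equals PL·AF exactly at week 1/k (k = 0.1175; AF = 0.74/0.88/1.0
for 2-yr-olds/3-yr-olds/mature). Cows with PL < 7 kg/d have maintenance
reduced 12% (their calves 11%). Intake uses the NASEM-style equations:
metabolic-weight form with a gestation-day branch for cows, a
diet-density quadratic percent-of-body-weight form (capped) for weaned
young stock. Growth for animals ≤ 3 yr follows the allometric
empty-body-weight gain curve on NEg intake; mature cows convert NEm
surplus/deficit through BCS-specific Mcal-per-kg-of-body-change tables.
Body condition is scored 1–9: young animals by body-fat fraction (NRC
slope 0.037/score, anchored 0.1889 ↔ BCS 5), mature cows by weight
relative to mature BCS-5 weight (0.07/score), 3-yr-olds by the maximum of
both.

Nursing calves drink their dam's actual daily milk (0.55/0.33 Mcal
NEm/NEg per kg), milk-only through 50 d. The published pre-weaning
forage-intake form this component stands in for is not reproducible here,
so calf forage DMI is a pluggable function; the default ramps the
young-animal intake form in linearly from 50 to 140 d of age and lets
each kg of actual milk substitute for 0.12 kg DM of forage. Using the
actual (declining) daily milk rather than a static peak raises
late-lactation forage intake, which is the documented intent of the
modification; the original form's absolute offset (+0.65 kg/d) cannot be
verified without its published coefficients.

### Ration formulation and feeding policy

Off-grass, animals eat a 73% alfalfa / 19% wheat straw / 8% corn base
diet (1.20/0.64 Mcal NEm/NEg per kg DM); a 60% alfalfa / 40% corn
supplement (1.63/1.02) is available. For a thin cow (BCS < 5) in negative
energy balance the daily base/supplement mix minimizes feed cost subject
to NEm, NEg, minimum- and maximum-intake and base-availability
constraints (a two-variable linear program; infeasible days fall back to
a 60/40 base/supplement split of the day's intake). Over-conditioned
animals (BCS > 6) are restricted to 70% of the intake meeting NEm until
back at 6. Growing stock are fed ad libitum. On pasture (May 1–Oct 31,
spring-peaking bluestem forage densities), thin cows in deficit receive
supplement up to 20% of daily DMI, substituting kg-for-kg for forage.

Because the LP's gain requirement for a mature cow is zero, meeting
requirements alone would hold a thin cow at the BCS 4/5 boundary forever.
The feeding policy therefore adds a condition-recovery allowance for
mature cows below BCS 5 — supplementation targets maintenance plus
0.3 kg/d of shrunk-weight regain — implementing the management goal of
keeping post-weaning animals at BCS 5–6.

Forage supply is budgeted per season: production (kg DM/acre) is linear
in cumulative Jan–Aug precipitation and the prior season's percent of
forage remaining (defaults calibrated so a 612 kg pair on its 7.3-acre
allocation finishes an average season near 45% remaining); acreage scales
with metabolic weight indexed to a 612.25 kg cow; intake is inflated by
25% waste; the herd comes off grass early if remaining forage falls below
40%.

### Reproduction, health, management

Heifers reach first estrus at the later of a drawn age (N(300, 20) d) and
40% of mature weight. Postpartum interval is beta-PERT by parity and BCS
class (multiparous moderate cell 40/60/90 d; other cells within ±6 d;
dystocia adds a truncated-normal 10 ± 3 d). Estrous cycles are truncated
N(21, 0.75) on [18, 24] d. Each in-season estrus of an exposed,
non-pregnant female conceives with probability 0.65 (see calibration
below); gestation is truncated N(285, 5) on [260, 310], correlated +0.30
with calf birth weight within the cohort. Pregnancy carries a daily
abortion hazard (5·10⁻⁵); abortion before season end allows one rebreed,
abortion after the cull date culls the female that day. Dystocia risk is
drawn per iteration (mean 0.05; 0.08 for primiparous dams with calves
≥ 90 lb).

Health hazards are drawn once per iteration from truncated normals
(lower bound 0) and applied uniformly within category: calf morbidity
(once at most) by age class (≤ 3 d vs older) × dystocia; calf mortality
over the eight (age × dystocia × morbidity) cells; female mortality for
replacements vs the breeding herd. Defaults target ≈4.5–5% pre-weaning
calf mortality and ≈1.5%/yr cow mortality.

Management: 100 females exposed May 1–Jul 3; diagnosis Sep 1 (60 d after
season end); one herd-wide weaning date when the oldest calf turns 220 d;
at the later of weaning and diagnosis, opens and all 13-yr-olds are
culled and voluntary culls top each age group up to a 10% minimum;
replacement heifers are retained oldest-first to cover culls plus the
previous off-season's losses, with purchases (traits matching the raised
population) covering any shortfall at exposure. A dam losing her calf
between calving and the breeding season is culled that day. The calendar
is a fixed 365-day year with real month boundaries. Daily sub-steps run
nutrition → growth/BCS → reproduction → health → management; the order is
a design choice and only affects same-day edge cases.

Runs cover 1995–2018 with the first five years treated as burn-in and
excluded from reported output. Each iteration re-draws its health and
dystocia profiles; everything is reproducible from a single seed.

## Synthetic weather

The generator emulates Manhattan, KS climatology: monthly temperature
normals plus N(0, 1.5 °C) noise, monthly precipitation normals with 35%
multiplicative noise clipped at zero, and fixed seasonal forage nutrient
densities (1.48/0.90 Mcal NEm/NEg per kg DM Apr–Jun, 1.10/0.54 Jul–Aug,
0.71/0.18 otherwise). It reproduces the seasonal pattern and interannual
variation that drive the nutrition model, not actual historical weather;
real series can be supplied as CSV. Consequently, passing tests show the
model behaves correctly under realistic *statistical* conditions, not
that it reproduces any particular historical year.

## Calibrated stand-ins

Several parameter tables come from a supplementary source that is not
reproducible here; they are config entries with documented defaults, and
four of them were explicitly calibrated so the simulator meets its design
targets (≈93% of exposed females pregnant, stationary mean cow age
≈5.8 yr, ≈4.7% calf mortality, ≈1.1% pregnancy loss):

* **Conception probability per estrus = 0.65.** The design arithmetic
  (three opportunities in a 63-d season → 1 − 0.4³ ≈ 0.94) assumes every
  female cycles from the season's first weeks. In the realized
  calving-date equilibrium roughly one cow in ten calves late enough to
  get only one or two opportunities, so 0.60 yields ≈89–90% pregnant;
  0.65 — within the published per-estrus conception range — restores the
  design target.
* **PPI PERT cells** sit within ±6 d of the anchored multiparous-moderate
  (40, 60, 90) cell. Wider class spreads create a self-perpetuating
  late-calving tail.
* **Voluntary culling minimum 0.10 per age group**, giving total annual
  cow exits near 15% and a stationary mean cow age of ≈5.5–5.8 yr
  (closed-form geometric check).
* **Health hazard means** chosen so expected pre-weaning calf mortality
  is ≈4.7% of calves born.

Other stand-ins (EBV trend ramps, BIF dam-age adjustment tables, BCS
energy tables, diet prices, DMI cap, forage regression coefficients,
dormant-season forage DE) use conventional values documented in
`config_environment.py` and are replaceable from YAML.

A known artifact: the daily body-fat-gain equation accretes little fat at
moderate gain rates, so normally growing heifers read BCS 3–4 by the
young-animal fat method even when well fed. The only decision this feeds
is the PPI class at first calving, which the PPI calibration accounts
for.

## EFA validation pipeline

The pipeline standardizes the pooled (simulated + field) table, chooses
the factor count by Horn's parallel analysis (leading eigenvalues vs the
mean of random-data eigenvalues, stopping at the first failure), extracts
by iterated principal-axis factoring (SMC start values, eigenvalues
floored at zero, Heywood cases clamped and flagged, ≤ 100 iterations),
rotates obliquely by oblimin (gradient projection, γ = 0), and computes
regression-method (Thurstone) factor scores. Communalities are invariant
under the rotation to 10⁻⁸. Two-SD normal data ellipses per data source
are returned as (center, axis widths, angle) for plotting; published
loading-vector rescaling constants (2.85 individual, 2.5 herd) are a
plotting convention and not applied to stored loadings.

## Numerical choices

* The two-feed LP is solved exactly: `solve_ration` wraps HiGHS
  (`scipy.optimize.linprog`); the engine's inner loop enumerates
  constraint-boundary intersections of the two-variable program across
  all animals at once. Both satisfy the constraints to 10⁻⁹ and agree
  with a grid-search oracle.
* Correlation enforcement is exact (10⁻¹⁵-level) by construction;
  gestation lengths are clipped to [260, 310] afterwards, which can move
  the realized correlation by up to ~0.02.
* Mixed diets use blended NEm/NEg densities; maintenance is satisfied
  first and the remaining intake supplies gain.
* Degenerate guards: weights floored (30 kg adults, half birth weight for
  calves), fat clipped to [0, 0.45·CSBW], zero-SD draws return their
  mean, division guards at 10⁻⁹.
* Weaning ages, and hence growth caps, are fixed once the season's last
  calving has occurred; a calf reaching 80 d before that point is briefly
  uncapped (a few days at most).

## Problem sizes

Reported experiments use the study's full design — 100 exposed females,
24 years, 32 scenarios — at one iteration per scenario for the pooled
grid and 10 iterations for the reference-scenario trial; these sizes are
the package's validation defaults and complete in a few minutes on one
core. Monte-Carlo unit checks use 10⁴–10⁵ draws.

## Known limitations

Energy-only nutrition (no protein or minerals); no creep feed; no bulls,
twinning, AI or disease transmission; morbidity has no growth penalty;
purchased replacements are always available at matching genetics; a fixed
365-day calendar (no leap days); lactation is not limited by what the
calf actually drinks, and forage-intake competition between cows and
calves is not modelled beyond the shared forage budget. The pre-weaning
growth equations are extrapolated below the weights they were estimated
on, which the growth-potential cap partially masks; realized weaning
weights are therefore most trustworthy in relative (between-scenario)
terms.
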