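# Methods

## Scope and data model

`nutgeom` converts three field tables — food composition (% dry matter),
timed focal-animal feeding bouts, and intake-rate observations — plus unit
dry masses and body masses into per-focal-day intakes, geometric-framework
representations, and seasonal/group statistical summaries. Percentages are
stored on the 0–100 scale in all files and converted to fractions at
computation boundaries. A focal-day is keyed by (focal individual, date);
nocturnal feeding is assumed absent (focal animals are followed dawn to
dusk and re-found at the same sleeping sites).

## Food chemistry

Available protein is crude protein minus acid-detergent-insoluble crude
protein. Total non-structural carbohydrate is computed by difference from
100% dry matter; assay rounding can push the difference slightly below
zero, in which case it is clamped to 0 and a `NutrientWarning` is emitted
(an error would reject otherwise usable assays over rounding noise).
Energy density sums physiological fuel values (16.736 kJ/g protein and
carbohydrate, 37.656 kJ/g fat, 12.552 kJ/g fiber), crediting fiber only for
the digestible fractions of cellulose (ADF − lignin, digestibility 0.3911)
and hemicellulose (NDF − ADF, digestibility 0.5197). Concentrations enter
the sum as g/g, so a hypothetical pure-fat food returns exactly the fat
fuel value in kJ/g.

Two distinct balance conventions coexist deliberately and are exposed as
separately named quantities to prevent confusion:

* **AP:NPE** — non-protein energy *includes* digestible-fiber energy
  (dietary balance of a fiber-eating folivore);
* **RMT shares** — fiber energy is *excluded* and only protein, fat and
  TNC span the triangle (fiber typically contributes <10% of macronutrient
  energy in these diets, and a fourth axis would be needed otherwise).

For a zero-protein food the AP:NPE ratio is 0 under any fiber convention;
for positive-protein foods the ratio depends on the assumed ADF/lignin
split, which matters when comparing against rounded published per-food
values (they are generally not reproducible from rounded concentrations and
are treated as approximate cross-checks only).

**Substitution hierarchy** for foods eaten but not assayed: direct record →
unweighted mean of sampled congeners of the same plant part/stage → mean of
all sampled records of that part/stage; provenance is recorded on every
resolved record. Unassayed fat in young-leaf records is filled with the
young-leaf average fat before use. Ties between several congeners take an
unweighted mean (no abundance weighting is attempted).

## Intake estimation

Intake rates are pooled across individuals and sites as total units ÷ total
observed seconds (duration-weighted), which is robust to very short
observation intervals; interval-count and per-item-handling records pool
identically. A food with no rate records falls back to the pooled rate of
its plant-part code, mirroring the composition substitution, with a logged
warning. Conversion factors C_x default to 1.0 and are configurable per
food (published values for the two foods known to need them are not
available). Soil bouts are excluded from all nutritional sums but tallied
separately for auditing. Body masses use the individual's capture value;
individuals without one take their group mean (logged).

Day-level energy is accumulated food-by-food (mass × energy density), and
the day's AP:NPE uses the day's total protein kJ over total non-protein kJ;
both identities (energy = Σ food masses × densities = AP kJ + NPE kJ) hold
to 1e-9 relative tolerance by construction and are enforced in tests.
Periods 1–12 map to seasons as {1–2, 3–5, 6–8, 9–10, 11–12} → 1–5, with
seasons 1, 4, 5 flagged lean. Scaled intakes use a metabolic exponent of
0.762 for energy and 1 for protein. Requirement conversions use the protein
fuel value (e.g., 2.8 g·kg⁻¹·day⁻¹ at 5 kg → 234 kJ/day) and are rounded to
the nearest kJ for display; the oblique energy line 500·5^0.762 evaluates
to 1704.5 kJ (published figures sometimes print 1703 from a rounded
exponent term; we do not force agreement).

## Geometry

RMT coordinates are percent shares of fiber-free macronutrient energy;
carbohydrate isolines are the segments x + y = 100 − z. Ratio ↔ proportion
conversions are p/(1−p) and r/(1+r). Rails are least-squares through-origin
fits, slope = Σ(ap·npe)/Σ(ap²); by default rails are fitted to group ×
season mean intakes (per-day fitting is available). Because a through-origin
fit has mean perpendicular residual ≈ 0, a literal coefficient of variation
of residuals is ill-posed; `residual_spread` is therefore defined as
100 × SD(perpendicular deviations) ÷ mean distance of points from the
origin, a scale-free spread measure. Macronutrient shares and AP:NPE in the
descriptive tables are means of daily values (matching mean ± SD
presentation); coefficients of variation are computed on daily values.

## Mixed models

Daily values are averaged within individual × period (1–5 days per cell in
typical field data) to balance the design. The model for each intake
variable is `y ~ group * period` (both categorical) with a random intercept
per individual, fitted by REML via statsmodels MixedLM. The fruit/seed mass
proportion is arcsine-square-root transformed and available protein is
log-transformed (raw-scale fits of strongly right-skewed protein intakes
converge poorly); estimated marginal means are back-transformed for
reporting.

statsmodels provides no F-tests for categorical terms, so the package
computes marginal Wald F-tests: main effects are tested as equality of
marginal means averaged over the other factor (with an interaction present,
testing raw treatment-coded dummies would test differences at the reference
level only), and the interaction as its coefficients jointly zero.
Denominator degrees of freedom use a containment-style split: individuals −
groups for the group effect; residual within-individual dof for period and
interaction. This is an approximation (no Satterthwaite/Kenward-Roger), it
is flagged in every model report, and exact replication of fixed-effect
statistics from other software (with, e.g., per-period residual variances)
is explicitly out of scope. The per-period diagonal residual structure used
by some packages is not representable in MixedLM; the homoscedastic
residual + random intercept structure used here is stated in the report
notes. Pairwise group comparisons are unadjusted (LSD) t-tests on EMM
differences at α = 0.05, summarised as compact letter displays.

## Synthetic-data generator

The generator emulates the study design the analysis assumes: 5 groups on a
habitat-disturbance gradient (basal-area proxy in (0, 1]), 18 individuals
(5/4/3/2/4), 12 collection periods → 5 seasons, ~50 bouts and ~3 h feeding
per day, gamma bout durations (shape 2) and Poisson bout counts. Defaults
encode the conditions the analysis targets: dietary AP:NPE 0.105; lean-season
intake at 40% of the undisturbed abundant-season intake; abundant-season
frugivory of 0.60/0.62/0.39/0.22/0.64 across groups converging to 0.15 in
the lean season; an undisturbed abundant-season dry-mass intake of 450 g/day.

Two generator mechanisms deserve note:

* **Mass targets.** The lean-season daily-mass target is common to all
  groups (lean diets converge on the same fallback foods); each group's
  abundant-season target interpolates between that lean target and the
  undisturbed target by its disturbance score. The lean:abundant ratio
  therefore equals the configured multiplier exactly for an undisturbed
  group, and is larger for disturbed groups — the generator's encoding of
  "disturbed groups fail to realise the abundant-season lift".
* **Pool calibration.** Foods are split into fruit-like and leaf-like
  pools; within each pool crude protein is shifted uniformly (TNC
  recomputed by difference, foods clamped at feasibility bounds and the
  shift re-solved) until the pool's intake-flux-weighted AP:NPE equals the
  target. Any fruit/leaf time mix then yields the target ratio in
  expectation, so configured frugivory and configured nutrient balance are
  simultaneously satisfiable.

Every focal-day's expected intake vector is computed analytically by the
generator and exported; with noise disabled the generator emits one
deterministic bout per food with exact time shares and the pipeline
reproduces the truth to machine precision. All randomness flows from
`numpy.random.default_rng(seed)` (PCG64), reproducible across platforms.

What the generator does **not** emulate: phenology-driven food availability,
plant secondary metabolites or gut-capacity limits (scarcity is encoded
directly as intake multipliers), spatial ranging, demography, observer
error in bout segmentation, and integer-valued intake-rate counts (emitted
rate records are exact). Passing recovery tests therefore demonstrates the
pipeline's correctness and statistical power under the assumed structure,
not the field validity of that structure.

## Problem sizes and numerical choices

The default synthetic study (2 days per individual × period) yields 432
focal-days; parameter-recovery checks use 5 days per cell (1080 focal-days)
for the rail and lean:abundant ratio, and 100 replicates of the 18 × 12
individual-period table for mixed-model power (group contrast as in the
strong habitat gradient; detection at α = 0.01) and type-I error (all group
means equal; nominal 5% at α = 0.05). Tolerances: exact identities at 1e-9
to 1e-12 relative; Monte-Carlo recoveries at ±0.002 (rail ratio), ±0.03–0.04
(lean:abundant ratio). Through-origin fits require at least one positive
AP value; degenerate fits, zero-mass days (AP:NPE reported missing), zero
NPE foods, and out-of-range periods all raise typed errors.

## Known limitations

* F-test dof are containment approximations; p-values near a decision
  boundary should be re-checked in a dedicated mixed-model package.
* The substitution hierarchy averages without abundance weighting.
* Rate pooling ignores individual/site differences by design (pooled rates
  trade bias for variance, the established practice with sparse rate data).
* The replication loader maps spreadsheet columns by name fragments;
  unusual headers need an explicit `column_map`.
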