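# Methods

## Balance-sheet model

The package treats a region's food system as a nine-group balance
sheet. Each group *j* carries an edible-conversion factor CF_j ∈ (0,
1.5] (raw mass → edible mass; values above 1 are admitted for foods
whose reporting convention includes added water, though the defaults
stay ≤ 1), a caloric factor CalF_j > 0 (kcal per g edible mass), and
macronutrient energy shares EP_{j,q} ∈ [0, 1] for q ∈ {carbohydrate,
protein, fat}. Per-food caloric production is TCP_j = FP_j·CF_j·CalF_j;
the total and its plant/animal partition are straight sums. Nutrient
*mass* production divides the nutrient-allocated energy by the
Atwater-style coefficient: MNP_{j,q} = TCP_j·EP_{j,q}/ECF_q with ECF =
(4, 4, 9) kcal/g. Two modelling choices deserve note:

* **Per-food energy shares.** Nutrient production is computed from each
  food's own calories (TCP_j), not the regional total, so the per-food
  table is additive: MNP_q = Σ_j MNP_{j,q}. Any formulation multiplying
  the *total* TCP by a per-food share would make one food's nutrient
  output depend on every other food's harvest and break that
  additivity.
* **Energy → mass conversion.** Dividing (not multiplying) by ECF_q is
  what makes nutrient accounts reportable in kt next to B kcal calorie
  accounts, and is the only direction under which the packaged
  aggregate accounts are mutually consistent (3574.6 B kcal of demand
  against 506.3/122.9/126.4 kt of nutrients in 2020; multiplying would
  be off by roughly ECF² ≈ 16 on carbohydrate).

Σ_q EP_{j,q} may fall below 1 (fibre, organic acids); the validator
warns outside [0.9, 1]. Energy is therefore conserved as an inequality
Σ_q MNP_q·ECF_q ≤ TCP, with equality exactly when every food's shares
sum to 1 — a property test.

The demand side is the mirror image over a cohort-structured
population: TCD_j = Σ_a Pop_a·FI_{a,j}·CalF_j, with FI in g/person/year
(tables supplied in kg/person/year are converted on load), and
MND_{q,j} = TCD_j·NRGP_{q,j}/ECF_q. NRGP defaults to the production-side
EP matrix; a separate demand-side matrix can be supplied.

## Population and dietary structures

Cohorts are nine age stages × sex × residence (urban/rural). The nine
default stage labels (0-6, 7-10, 11-13, 14-17, 18-49, 50-64, 65-74,
75-79, 80+) follow the Chinese dietary-guideline banding convention;
they are labels, not logic — any nine stages shared between pyramid and
intake table work, and nothing in the accounting depends on the default.

Dietary structures: S0 is the arithmetic mean of supplied historical
intake tables (kept separate per residence when the tables are); S1 and
S2 adopt the guideline upper and lower bounds and are
residence-invariant. Structures may be *uniform* (age-invariant, the
form in which published per-capita consumption tables arrive) or
age-resolved; lookup resolves an `"all"` wildcard on either index
level. When S1 and S2 derive from the same guideline table, S1 ≥ S2
elementwise, which forces TCD(S1) ≥ TCD(S2) on any pyramid — both are
enforced as invariants.

## Gap statistics

Gap = (demand − production)/production × 100 at total-calorie,
per-nutrient, and per-food resolution. Published accounts include a
food whose production collapses to near zero (legumes, 0.2 kt in
2020), which makes the per-food percentage explode; batch reports
therefore flag entries with production at or below a configurable floor
(default 0) as `undefined`, retain the absolute shortfall, and omit the
percentage. Scalar calls raise instead.

Guideline deviations ((bound − consumption)/denominator × 100, and the
symmetric above-upper form) expose the denominator as an explicit
parameter because published deviation figures use both conventions:
the 2000-era percentages reproduce with the guideline bound as
denominator, while the 2020 legume figure (16.8 %) reproduces only with
consumption as denominator. Default is `guideline`; every report names
the convention. Display rounding is one decimal for percentages and
nearest integer for statistics conventionally quoted whole (fold
changes, peak shares); raw values are always retained in machine
output.

Two families of published nutrient-gap percentages (the 2020
protein/fat gaps under actual consumption and the lower-limit nutrient
gaps) are not reproducible from the published aggregate tables under
the gap definition above; they are treated as documented discrepancies
and no test or acceptance value depends on them. Likewise the published
future-gap ranges imply an S1/S2 ordering opposite to their
definitions; the definitions (S1 = upper, S2 = lower) are followed.

## Projection

Downscaling uses a constant per-cohort share: the mean of
regional/provincial ratios over the overlapping observed years, with
per-cohort Pearson correlation reported as fit quality (NaN when only
one year overlaps). This is the simplest model consistent with the
high published structure correlations (0.889–0.999); a share of 1
reduces downscaling to identity. The mean-of-ratios estimator carries a
Jensen bias of order share·cv² under multiplicative noise (~1.5e-4 at
cv = 0.02) — negligible against its sampling spread, and quantified in
the test suite.

Term windows are fixed inclusive ranges (basic 2011–2030, near
2021–2040, mid 2041–2060); a term pyramid is the per-cohort arithmetic
mean over its window. Future gaps compare projected demand against a
frozen baseline-year production account (default 2020), deliberately
isolating demand-side pressure: no future production capacity is
modelled. Scenario identifiers (SSP1-2.6, SSP2-4.5, SSP5-8.5) are
labels routing input trajectories; no climate forcing enters the
computation.

## Synthetic data

The generators emulate the study conditions: provincial pyramids at the
~26 M scale with exponential cohort growth (1.5 %/yr default), a
regional share of 0.41 (the study region's 2020 share of its
province), production levels at the magnitudes of the published 2020
accounts with per-food trends including a legume-style collapse
(−0.21/yr, reaching ~2 % of baseline over a 20-year series), and
guideline-scale intake tables with S2 drawn first and S1 = S2 × a
factor ≥ 1. Noise is multiplicative log-normal with mean one (cv 0.02
default), keeping all quantities positive; each generator has its own
stream seeded by a stable hash of (master seed, generator name), so
adding a generator never perturbs the others and identical
seed + config gives byte-identical output.

What the synthetic data does *not* emulate: autocorrelated yearbook
revision artifacts, migration shocks, policy-driven structural breaks,
or realistic cross-food covariance. Passing tests on synthetic data
therefore demonstrate the accounting, calibration, and reporting
machinery — linearity, conservation, dominance, parameter recovery —
not the empirical accuracy of any coefficient set on real regions.

## Coefficients and fixtures

The study-specific per-food coefficient values (CF, CalF, EP by food,
intake by age band) are not published in the available aggregate
tables; the shipped factor table is assembled from conventional Chinese
food-composition values and is explicitly marked `default`. All
reference statistics are computed from the *published aggregate
accounts* (packaged verbatim in `foodgap.uma_data`), so no default
coefficient can silently affect them. One transcription note: the 2000
production row is internally inconsistent in the source (plant + animal
= 2866.24 vs a printed total of 2866.94 B kcal); the fixture preserves
the printed values and the regression test documents the 0.7 B kcal
discrepancy, while 2010 and 2020 add exactly.

## Numerical choices

All computation is in canonical units (g, kcal); kt = 1e9 g and
B kcal = 1e9 kcal conversions happen only in the reporting layer.
Sums are plain float64 accumulation — at nine foods and ≤ 36 cohorts,
ordering effects are below 1e-12 relative and the tests' oracle
comparisons run at that tolerance. Zero-production foods stay in every
table (contributing zeros) so per-food statistics remain defined.
Degenerate inputs fail loudly: negative masses, zero populations, zero
baselines, and age-stage misalignment raise typed errors rather than
propagating NaN; the quality-protein share of an all-zero protein
account is NaN on the account (flagged) but an error when requested as
a scalar.

Problem sizes in the test and acceptance runs — 200-instance oracle
sweeps, 200-seed share recovery on 20-year × 36-cohort series, 50-year
projection examples — were chosen to give stable Monte-Carlo estimates
(share SE ≈ 2.5e-5 on the 200-seed mean) while keeping the whole suite
in the tens of seconds.

## Limitations

No seed/feed/industrial/reserve deductions on the production side (the
accounts measure maximum self-sufficiency capacity) and no waste or
loss adjustment on the demand side. Micronutrients are out of scope.
Future *production* is not modelled; future gaps are demand-side
pressure against frozen capacity. The constant-share downscaling
ignores differential regional ageing; a trend-share variant would be
the natural extension.
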