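# Methods

This note documents the models and procedures implemented in `dietprint`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic data do and do not establish.

## Diet-quality scoring

Each index component carries a **scoring standard**: a direction
(adequacy or moderation), a maximum point value, and two thresholds — the
intake amount awarded zero points and the amount awarded full points —
expressed on a component-specific basis. Scores interpolate linearly
between the thresholds and clamp outside them. Standards are data
(`src/dietprint/data/*.csv`), not code: swapping a table or a flag is how
variants (e.g. unmodified AHEI-2010) are produced, which is what the
sensitivity analysis requires.

**HEI-2015** (13 components, max 100) scores most components as densities
per 1000 kcal; added sugars and saturated fat are percent of energy
(4 kcal/g and 9 kcal/g conversions); the fatty-acid component is the
unsaturated:saturated ratio (full score at ≥ 2.5, zero at ≤ 1.2). When
saturated fat is exactly zero the ratio is degenerate: any unsaturated
intake saturates the component, none at all scores the floor.

**AHEI-2010** (10 components, max 100) is implemented without the trans-fat
component. Under the *modified* flag (default) absolute daily amounts are
rescaled by 1849/energy — 1849 kcal/d being the mean intake of the index's
source population — before scoring, and individuals younger than 18
receive 10 alcohol points for zero reported consumption and 0 otherwise.
Unmodified, amounts are scored raw and the adult alcohol rule applies to
everyone. The adult alcohol rule is a two-sided trapezoid: full credit in
the moderate band (0.5–1.5 drinks/d), declining linearly to zero at
2.5 drinks/d and toward zero intake, with exact abstainers receiving the
2.5-point partial credit recorded in the table. Two editable-table choices
replace data-dependent rules in the original index: the whole-grain
full-score threshold is fixed at 75 g/d for all (the original is
sex-specific: 75 g women / 90 g men, and the standard schema carries no
sex field), and sodium uses fixed thresholds (zero at 3.4 g/d, full at
1.1 g/d) in place of the original's sample deciles. Both are defaults in
an editable table, not constants in code.

**Population-ratio means.** The population mean score of a component is
the score of the population-level amount — weighted total intake over
weighted total energy, scaled to the component basis — not the weighted
mean of individual scores; clamping makes the two differ. Doubling all
weights changes nothing (ratio invariance).

**Quintiles** use the left-continuous inverse of the weighted ECDF at the
20/40/60/80th percentiles; ties at a cutpoint fall to the lower quintile.
Weighted quintiles are the default (unweighted is exposed); quintiles are
formed on the pooled sample. Records with non-positive energy are excluded
from scoring with a logged count by default (a strict policy errors).

## Commodity mapping and loss/waste accounting

Recipe tables distribute each food's grams over commodities by mass
fraction; fraction sums must be within 1e-6 of 1 per food and violations
abort rather than silently renormalizing. Foods missing from the recipe
table are dropped with a coverage report by default (this mirrors a
crosswalk that has not kept pace with new food codes); the report gives
the unmapped mass share against both the all-food and mapped-only
denominators, since which denominator the original analyses used is not
knowable from the outside.

The loss chain runs backward from observed consumed mass because intake is
observed and loss fractions are forward rates; the stage order is
retail → inedible → consumer waste, with the consumer-waste fraction
applied to *edible* purchased mass. The four category masses are additive
to Total Food Demand by construction at every aggregation scope.
Commodities with no loss profile get zero loss with a warning (policy
switchable to error). Masses are carried at full floating precision and
rounded only in reports.

## Design-based estimation

Weighted means are ratio estimators with Taylor-linearized variance under
the with-replacement between-PSU approximation: linearized scores are
totalled per PSU and the variance is the stratum-weighted between-PSU
scatter, Σ_h n_h/(n_h−1) Σ_j (S_hj − S̄_h)². Confidence intervals and
tests use t on (#PSUs − #strata) degrees of freedom, the convention of the
major survey packages. Strata with a single PSU abort variance estimation
(public-use survey files guarantee two). Trend tests regress the outcome
on the quintile index treated as a continuous 1–5 score in a
survey-weighted linear model with the sandwich (PSU-aggregated) covariance;
adjusted models append age (continuous) and a male indicator. Trend models
are fit at the individual level (quintile-summary fits are possible via
the same `design_wls` primitive). The modified-vs-original AHEI comparison
is a paired Wald test on individual-level score differences; an exactly
constant nonzero difference has zero linearized SE and is reported as
degenerate with a warning. No replicate-weight methods and no
multiple-testing adjustment are provided.

No design-based survey estimator was available among the installed
statistical libraries, so the linearized variance machinery is implemented
here directly; an ordinary WLS fit serves as an independent cross-check of
point estimates in the tests.

## The biophysical model

The model treats the country as a closed food system. Demand for
commodities flagged non-domestic is reapportioned within their food group
proportional to the remaining members' demand (equal split if all domestic
demand is zero; a group with demand and no domestic member is an error).
Plant commodities convert to primary crop mass by a processing conversion
that embeds pre-retail losses; animal commodities convert to carcass
weight and then to feed-crop and forage mass through a per-product feed
vector (life phases collapsed into one aggregate vector per product).
Retail- and consumer-level loss stages are structurally absent from the
model because losses enter as separate demand streams; re-applying them
inside the model would double count.

**Multi-use crops.** A crop serving several chains carries allocation
fractions summing to 1 over its users. Each chain's ledger entry records
its gross crop draw (demand divided by its fraction) and the allocated
share actually charged (gross × fraction = demanded mass), so shared crops
are never double-counted and total allocated mass equals total demanded
mass exactly. Land is requirement / (yield × utilization ×
double-crop factor); grazed categories use a forage-utilization scalar
(0.5–0.6 by default) so unused grazing land is not charged. Application
rates per land-use category turn land into fertilizer nutrients
(N + P₂O₅ + K₂O summed), pesticides, and irrigation water. The chain is
linear in demand, so stream footprints add to the total-demand footprint
(within 1e-6 relative; the property is tested). An optional
land-availability table produces a required-vs-available report with an
exceedance flag — no optimization.

**Monte Carlo.** Each replicate draws 50% of individuals without
replacement with probability proportional to survey weight (unweighted
draws are exposed; whether the original procedure respected weights is not
documented, and weighted draws are the design-consistent choice),
recomputes the weighted per-capita demand and the full chain, and scales
to the population (taken as the sum of survey weights). Intervals are
2.5/97.5 percentiles over 500 replicates by default (200 in the analysis
scripts); runs are deterministic under a fixed seed.

## Synthetic data: what it emulates and what it does not

The generator produces a stratified design (default 15 strata × 2 PSUs ×
40 individuals = 1200), log-normal weights (median ≈ 2.6 × 10⁵, log-SD
0.6, so the implied population is ≈ 3–4 × 10⁸ and weighted and unweighted
analyses diverge), energy ~ Normal(2100, 650) kcal floored at 400 with a
small PSU-level shift to induce intra-cluster correlation, and per-food
grams generated conditional on energy (whole-diet energy density between
0.8 and 2.5 kcal/g — the stated intake/energy consistency tolerance). A
latent healthfulness factor, scaled by the `gradient` parameter (default
0.6), raises adequacy densities, lowers moderation amounts, and tilts food
shares toward fruit/vegetable/nut commodities, creating the
diet-quality/intake correlation the trend analyses probe. Parameter tables
include a 10% unmapped-food share, loss fractions in LAFA-like ranges
(retail 3–12%, inedible up to 35% for produce and meat, consumer waste
15–45%), and at least one non-domestic commodity.

Passing tests on these data show the machinery is correct — mass is
conserved, estimators are calibrated, the model is linear — not that any
national point estimate is reproduced: real recall data have food codes,
episodic consumption, measurement error, and hundreds of commodities with
empirically estimated loss fractions that the generator does not imitate.
National-scale results additionally depend on the full parameter set
(crop-specific yields, feed budgets, survey-based application rates) for
which the generator substitutes plausible magnitudes.

## Numerical choices and problem sizes

Recipe-fraction tolerance 1e-6; category additivity 1e-6 g; allocation
conservation 1e-9 relative; quintile ties to the lower quintile; all-tied
scores collapse to quintile 1 with a warning. The calibration suite runs
the null trend test on 1000 replicates of 320 individuals (20 strata ×
2 PSUs × 8) and accepts a rejection rate within the 99% binomial band
around 0.05; recovery checks use one seeded population of 600 individuals
each. These sizes are the package's chosen test conditions and are fixed
in the tests.

## Known limitations

No greenhouse-gas, water-scarcity, or eutrophication indicators; no
spatial or production-system heterogeneity; no replicate-weight variance;
no trans-fat AHEI component; no nutrient computation from recipes (index
component amounts arrive with the recall table); livestock life phases
aggregated; a single utilization scalar per pasture category.
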