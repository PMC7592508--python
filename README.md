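# dietprint

Diet quality, food loss/waste mass accounting, and the agricultural
resources used to produce what a population demands.

## The scientific problem

Healthier diets are not automatically more sustainable. To examine the
link, one needs to connect three bodies of method that are usually kept
apart:

1. **Diet-quality indices** scored from 24-hour dietary recalls — the
   Healthy Eating Index 2015 (HEI-2015: 13 components, densities per
   1000 kcal, max 100) and a modified Alternative Healthy Eating Index
   2010 (AHEI-2010: 10 components, trans fat excluded, amounts
   energy-adjusted to a 1849 kcal/d reference, with a special alcohol rule
   for individuals under 18);
2. **Food loss and waste mass balance** — observed intake is *consumed*
   mass; dividing it back through commodity-specific consumer-waste,
   inedible, and retail-loss fractions recovers purchased mass and
   **Total Food Demand** (consumed + consumer waste + inedible + retail
   loss);
3. **A closed-food-system biophysical model** that converts demand into
   primary crop mass (processing conversions, livestock feed vectors,
   multi-use-crop allocation), crop mass into land by land-use category
   (yields, double-cropping, forage utilization), and land into fertilizer
   nutrients (N + P₂O₅ + K₂O), pesticides, and irrigation water via
   per-hectare application rates.

Estimation is design-based throughout: survey-weighted means with
stratified-cluster Taylor-linearized variance, weighted quintiles of diet
quality, linear trend tests across quintiles (optionally adjusted for age
and sex), and paired Wald tests for scoring-rule sensitivity analyses.
Uncertainty in the biophysical model comes from Monte Carlo resampling of
individuals without replacement.

The package is aimed at nutrition and food-system researchers who want a
tested, reproducible implementation of this chain that runs end-to-end on
synthetic survey data with the right statistical structure (stratified
two-PSU design, skewed weights, heterogeneous energy intake, commodity
loss fractions, a small crop/livestock parameter set) — no restricted
downloads required.

## The core quantities

For a commodity with consumer-waste fraction *w*, inedible fraction *i*,
and retail-loss fraction *r* (all in [0, 1)):

```
edible_purchased = consumed / (1 − w)
purchased        = edible_purchased / (1 − i)
total_demand     = purchased / (1 − r)
```

Component scores are piecewise-linear between a zero-score and a
full-score threshold (reverse for moderation components); population mean
scores use the population-ratio method — score the ratio of weighted total
intake to weighted total energy once, rather than averaging individual
scores. Design variance for a weighted mean uses between-PSU scatter of
linearized score totals, with t intervals on (#PSUs − #strata) degrees of
freedom.

## Worked example

Run the numbered analysis scripts from the repository root (each accepts
`--seed`; all computation lives in the package, the scripts only narrate):

```
$ python analysis/04_waste_accounting.py --seed 1
per-capita Total Food Demand: 1974 g/d
  retail loss       129 g (7% of total)
  inedible          188 g (10% of purchased)
  consumer waste    520 g (31% of edible)
  consumed         1137 g
loss and waste: 837 g = 42% of Total Food Demand
```

The synthetic population of 1200 individuals demands 1974 g of food per
person per day, of which 42% is never eaten — lost at retail, inedible, or
discarded by consumers. Feeding that demand through the biophysical model:

```
$ python analysis/06_foodprint.py --seed 1
resources to produce Total Food Demand (population scale, per year):
  land           112.6 million ha
  fertilizer     14074 million kg (N+P2O5+K2O)
  pesticides       264 million kg
  irrigation     135.8 billion m3
attribution of resource use (share of each resource):
  retail_loss     6-7%
  inedible        10-12%
  consumer_waste  24-30%
  consumed        53-59%
Monte Carlo land interval: 112.5 (110.5-114.6) million ha
```

Consumed food accounts for just over half of each resource; the rest is
attributable to food that was demanded but not eaten. `05_trend_tests.py`
prints the design-based confidence interval for Total Food Demand, trend
slopes across HEI-2015/AHEI-2010 quintiles, and the Wald test comparing
modified vs. original AHEI scoring. The same pipeline is available as a
CLI (`dietprint run-all --config cfg.yaml --seed 1`) or as library calls
(`dietprint.run_pipeline`).

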