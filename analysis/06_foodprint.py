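"""Run the closed-food-system model: land and input use for each loss/waste
stream, attribution shares, Monte Carlo intervals, and per-quintile totals."""

import pandas as pd

from _common import make_config, parse_seed
from dietprint import run_pipeline

seed = parse_seed(__doc__)
cfg = make_config(seed)
manifest = run_pipeline(cfg)  # all stages

tot = pd.read_csv(manifest["artifacts"]["footprint_total"], comment="#")
sums = tot.drop(columns="land_use_category").sum()
print("resources to produce Total Food Demand (population scale, per year):")
print(f"  land        {sums['land_ha']/1e6:8.1f} million ha")
print(f"  fertilizer  {sums['fertilizer_kg']/1e6:8.0f} million kg (N+P2O5+K2O)")
print(f"  pesticides  {sums['pesticide_kg']/1e6:8.0f} million kg")
print(f"  irrigation  {sums['irrigation_m3']/1e9:8.1f} billion m3")

shares = pd.read_csv(manifest["artifacts"]["attribution_shares"], comment="#", index_col=0)
print("attribution of resource use (share of each resource):")
for stream, row in shares.iterrows():
    rng = f"{100*row.min():.0f}-{100*row.max():.0f}%"
    print(f"  {stream:15s} {rng}")

mc = pd.read_csv(manifest["artifacts"]["footprint_mc"], comment="#")
land = mc[mc["resource"] == "land_ha"].iloc[0]
print(f"Monte Carlo land interval: {land['mean']/1e6:.1f} "
      f"({land['ci_low']/1e6:.1f}-{land['ci_high']/1e6:.1f}) million ha")

fq = pd.read_csv(manifest["artifacts"]["footprint_by_quintile"], comment="#")
for index, sub in fq.groupby("index"):
    q1 = sub[sub["quintile"] == 1]["land_ha"].iloc[0]
    q5 = sub[sub["quintile"] == 5]["land_ha"].iloc[0]
    print(f"{index}: land Q1 {q1/1e6:.1f} -> Q5 {q5/1e6:.1f} million ha")
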