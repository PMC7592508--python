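"""Back-calculate per-capita retail loss, inedible portions, consumer
waste, and Total Food Demand from consumed mass and loss fractions."""

import pandas as pd

from _common import make_config, parse_seed
from dietprint import run_pipeline

seed = parse_seed(__doc__)
cfg = make_config(seed)
manifest = run_pipeline(cfg, stages=["simulate", "map", "score", "account"])

pc = pd.read_csv(manifest["artifacts"]["per_capita_breakdown"], comment="#")
row = pc[pc["scope"] == "overall"].iloc[0]
total, purch, edible = row["total_demand"], row["purchased"], row["edible_purchased"]
print(f"per-capita Total Food Demand: {total:.0f} g/d")
print(f"  retail loss    {row['retail_loss']:6.0f} g ({100*row['retail_loss']/total:.0f}% of total)")
print(f"  inedible       {row['inedible']:6.0f} g ({100*row['inedible']/purch:.0f}% of purchased)")
print(f"  consumer waste {row['consumer_waste']:6.0f} g ({100*row['consumer_waste']/edible:.0f}% of edible)")
print(f"  consumed       {row['consumed']:6.0f} g")
lost = row["retail_loss"] + row["inedible"] + row["consumer_waste"]
print(f"loss and waste: {lost:.0f} g = {100*lost/total:.0f}% of Total Food Demand")
groups = pc[pc["scope"] != "overall"].sort_values("total_demand", ascending=False)
print("top food groups by demand: " + ", ".join(
    f"{r['scope']} {r['total_demand']:.0f} g" for _, r in groups.head(3).iterrows()))
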