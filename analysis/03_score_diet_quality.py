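"""Score HEI-2015 and modified AHEI-2010 and assign weighted quintiles.

Reports individual-mean and population-ratio total scores; the two differ
because component clamping makes scoring nonlinear, which is exactly why
the population-ratio method is used for population means.
"""

import pandas as pd

from _common import make_config, parse_seed
from dietprint import run_pipeline

seed = parse_seed(__doc__)
cfg = make_config(seed)
manifest = run_pipeline(cfg, stages=["simulate", "map", "score"])

for index in ("hei2015", "ahei2010"):
    sc = pd.read_csv(manifest["artifacts"][f"scores_{index}"], comment="#")
    pop = pd.read_csv(manifest["artifacts"][f"population_score_{index}"], comment="#")
    print(f"{index}: mean of individual totals {sc['total'].mean():.1f}, "
          f"population-ratio total {pop['total'].iloc[0]:.1f}")
    shares = sc.groupby("quintile")["total"].agg(["min", "max", "size"])
    print(f"  quintile score ranges: " + ", ".join(
        f"Q{q}: {r['min']:.0f}-{r['max']:.0f}" for q, r in shares.iterrows()))
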