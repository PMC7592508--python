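"""Generate the synthetic survey population and parameter tables.

Writes the recall table under results/ and reports the design layout and
the skew of the sampling weights (weighted analyses should diverge from
unweighted ones when weights are this heterogeneous).
"""

import pandas as pd

from _common import make_config, parse_seed
from dietprint import run_pipeline

seed = parse_seed(__doc__)
cfg = make_config(seed)
manifest = run_pipeline(cfg, stages=["simulate"])

rec = pd.read_csv(manifest["artifacts"]["recall"], comment="#")
print(f"simulated {len(rec)} individuals "
      f"({rec['stratum'].nunique()} strata x {rec['psu'].nunique()} PSUs/stratum)")
print(f"weights: mean {rec['weight'].mean():,.0f}, median {rec['weight'].median():,.0f} "
      f"(mean/median {rec['weight'].mean()/rec['weight'].median():.2f} — right-skewed)")
print(f"energy: mean {rec['energy_kcal'].mean():.0f} kcal/d, "
      f"sd {rec['energy_kcal'].std():.0f}")
print(f"tables in {cfg.output_dir}")
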