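"""Shared run configuration for the numbered analysis scripts.

The synthetic study conditions (15 strata x 2 PSUs x 40 individuals,
log-normal survey weights, 30 foods over 18 commodities with a 10%
unmapped-food share) are the package defaults; every script accepts
--seed so the whole analysis is reproducible end to end.
"""

import argparse

from dietprint import RunConfig


def make_config(seed: int = 1) -> RunConfig:
    return RunConfig(
        output_dir=f"results/run_seed{seed}",
        seed=seed,
        synthetic={},  # package-default design and population
        monte_carlo={"n_reps": 200, "draw_fraction": 0.5},
    )


def parse_seed(description: str) -> int:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    return parser.parse_args().seed
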