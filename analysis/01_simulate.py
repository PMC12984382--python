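#!/usr/bin/env python
"""Generate the default synthetic study dataset under results/data/."""

from omicsconcord.synthetic_data import SimConfig, simulate_all, write_outputs

SEED = 1

if __name__ == "__main__":
    cfg = SimConfig(rng_seed=SEED)
    paths = write_outputs(simulate_all(cfg), "results/data")
    for name, path in paths.items():
        print(f"{name}: {path}")
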