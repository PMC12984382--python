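#!/usr/bin/env python
"""Per-contrast differential CpG methylation from results/data/."""

from pathlib import Path

from omicsconcord.data_model import SampleTable, canonical_contrasts
from omicsconcord.methylation import MethylationTable, run_methylation

if __name__ == "__main__":
    out = Path("results/methylation")
    out.mkdir(parents=True, exist_ok=True)
    mt = MethylationTable.read_tsv("results/data/methylation.tsv")
    samples = SampleTable.read_tsv("results/data/samples.tsv")

    for contrast in canonical_contrasts():
        dm = run_methylation(mt, contrast, samples)
        dm.to_csv(out / f"dm_{contrast.name}.tsv", sep="\t", index=False)
        print(f"{contrast.name}: {int(dm['is_dm'].sum())} DM CpGs of {len(dm)} tested")
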