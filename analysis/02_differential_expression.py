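#!/usr/bin/env python
"""Per-contrast RNA and protein differential expression from results/data/."""

import json
from pathlib import Path

from omicsconcord.data_model import SampleTable, canonical_contrasts, read_matrix
from omicsconcord.de_protein import run_de_protein
from omicsconcord.de_rna import run_de_rna

if __name__ == "__main__":
    data = Path("results/data")
    out = Path("results/de")
    out.mkdir(parents=True, exist_ok=True)

    counts = read_matrix(data / "counts.tsv", "counts")
    intensities = read_matrix(data / "intensities.tsv", "intensities")
    samples = SampleTable.read_tsv(data / "samples.tsv")

    for contrast in canonical_contrasts():
        deg = run_de_rna(counts, samples, contrast)
        deg.to_csv(out / f"degs_{contrast.name}.tsv", sep="\t")
        dep, report = run_de_protein(intensities, samples, contrast)
        dep.to_csv(out / f"deps_{contrast.name}.tsv", sep="\t")
        print(
            f"{contrast.name}: {int((deg['status'] != 'NS').sum())} DEGs, "
            f"{int((dep['status'] != 'NS').sum())} DEPs"
        )
    (out / "filter_report.json").write_text(json.dumps(report.as_dict(), indent=2))
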