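#!/usr/bin/env python
"""Gene-protein pairing, regulatory-pattern classes and concordance tables."""

import json
from pathlib import Path

import pandas as pd

from omicsconcord.data_model import canonical_contrasts, read_gene_protein_map
from omicsconcord.integration import build_pairs, summarize_concordance

if __name__ == "__main__":
    de = Path("results/de")
    out = Path("results/integration")
    out.mkdir(parents=True, exist_ok=True)
    gp_map = read_gene_protein_map("results/data/map.tsv")

    summary = {}
    for contrast in canonical_contrasts():
        deg = pd.read_csv(de / f"degs_{contrast.name}.tsv", sep="\t", index_col=0)
        dep = pd.read_csv(de / f"deps_{contrast.name}.tsv", sep="\t", index_col=0)
        pairs = build_pairs(deg, dep, gp_map, contrast)
        pairs.to_csv(out / f"pairs_{contrast.name}.tsv", sep="\t", index=False)
        s = summarize_concordance(pairs)
        summary[contrast.name] = s.as_dict()
        d = s.as_dict()
        print(
            f"{contrast.name}: {s.n_concordant}/{s.n_pairs} concordant "
            f"({d['concordance_pct_display']}%), r={s.pearson_r:.3f}, "
            f"rho={s.spearman_rho:.3f}"
        )
    (out / "concordance.json").write_text(json.dumps(summary, indent=2))
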