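#!/usr/bin/env python
"""Ordered-query enrichment at both layers plus concordant-term lists."""

import json
from pathlib import Path

import pandas as pd

from omicsconcord.data_model import canonical_contrasts, read_gene_protein_map
from omicsconcord.enrichment import (
    concordant_terms,
    ordered_query_enrichment,
    rank_features,
    results_frame,
)
from omicsconcord.synthetic_data import SimConfig, simulate_annotations

SEED = 1

if __name__ == "__main__":
    de = Path("results/de")
    out = Path("results/enrichment")
    out.mkdir(parents=True, exist_ok=True)
    terms = simulate_annotations(SimConfig(rng_seed=SEED))
    gene_for = read_gene_protein_map("results/data/map.tsv").gene_for()

    concordant = {}
    for contrast in canonical_contrasts():
        deg = pd.read_csv(de / f"degs_{contrast.name}.tsv", sep="\t", index_col=0)
        dep = pd.read_csv(de / f"deps_{contrast.name}.tsv", sep="\t", index_col=0)
        dep["gene_id"] = [gene_for.get(p) for p in dep.index]
        dep = dep.dropna(subset=["gene_id"])
        dep = dep.reindex(dep["log2fc"].abs().sort_values(ascending=False).index)
        dep = dep.drop_duplicates("gene_id").set_index("gene_id")

        per_layer = {}
        for layer, res in (("rna", deg), ("prot", dep)):
            universe = set(res.index)
            n_de = int((res["status"] != "NS").sum())
            per_layer[layer] = []
            for direction in ("UP", "DOWN"):
                enr = ordered_query_enrichment(
                    rank_features(res, direction), universe, terms,
                    direction=direction, layer=layer.upper(),
                    de_prefix=n_de or None,
                )
                per_layer[layer] += enr
                results_frame(enr).to_csv(
                    out / f"enrichment_{contrast.name}_{layer}_{direction}.tsv",
                    sep="\t", index=False,
                )
        concordant[contrast.name] = concordant_terms(
            per_layer["rna"], per_layer["prot"]
        )
        print(f"{contrast.name}: concordant terms {concordant[contrast.name]}")
    (out / "concordant_terms.json").write_text(json.dumps(concordant, indent=2))
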