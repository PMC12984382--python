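#!/usr/bin/env python
"""PCA and clustering views of the RNA and protein matrices."""

from pathlib import Path

import numpy as np

from omicsconcord.data_model import read_gene_protein_map, read_matrix
from omicsconcord.exploratory import cluster_heatmap_order, pca

if __name__ == "__main__":
    out = Path("results/exploratory")
    out.mkdir(parents=True, exist_ok=True)

    counts = read_matrix("results/data/counts.tsv", "counts")
    mapped = sorted(set(read_gene_protein_map("results/data/map.tsv").gene_for()))
    rna_pca = pca(counts.values.loc[mapped], log_mode=True)
    rna_pca.scores.round(6).to_csv(out / "pca_rna_scores.tsv", sep="\t")
    print("RNA PCA variance (%):",
          ", ".join(f"{v:.1f}" for v in rna_pca.variance_explained_pct[:3]))

    intensities = read_matrix("results/data/intensities.tsv", "intensities")
    complete = intensities.values.dropna()
    prot_pca = pca(np.log2(complete))
    prot_pca.scores.round(6).to_csv(out / "pca_prot_scores.tsv", sep="\t")
    print("Protein PCA variance (%):",
          ", ".join(f"{v:.1f}" for v in prot_pca.variance_explained_pct[:3]))

    rows, cols = cluster_heatmap_order(np.log2(complete))
    (out / "heatmap_order.tsv").write_text(
        "rows\t" + "\t".join(map(str, rows)) + "\ncols\t" + "\t".join(map(str, cols)) + "\n"
    )
    print("heatmap column order:", ", ".join(cols))
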