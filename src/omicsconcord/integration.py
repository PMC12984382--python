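"""Gene-protein pair construction, regulatory-pattern classification and
concordance statistics.

Each mapped gene-protein pair tested at both omic layers in a contrast is
assigned one of six regulatory patterns:

* CONCORDANT_UP / CONCORDANT_DOWN - significant at both layers, same sign;
* DISCORDANT - significant at both layers, opposite signs;
* RNA_EXCLUSIVE / PROTEIN_EXCLUSIVE - significant at exactly one layer;
* NS - significant at neither.

"Concordant" requires significance at BOTH layers with matching sign;
directional agreement without dual significance lands in the exclusive
classes. Correlations (Pearson r, Spearman rho) are computed over the
log2 fold changes of ALL pairs, not only the significant ones, because the
pair universe of a contrast is what the summary characterises.

Proteins mapping many-to-one onto a gene each contribute their own pair
(no collapsing by default; a max-mean-intensity representative mode is
available behind a flag).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .data_model import Contrast, GeneProteinMap


class PairClass(str, Enum):
    CONCORDANT_UP = "CONCORDANT_UP"
    CONCORDANT_DOWN = "CONCORDANT_DOWN"
    DISCORDANT = "DISCORDANT"
    RNA_EXCLUSIVE = "RNA_EXCLUSIVE"
    PROTEIN_EXCLUSIVE = "PROTEIN_EXCLUSIVE"
    NS = "NS"


PAIR_CLASSES = [c.value for c in PairClass]


def classify_pair(
    rna_status: str, rna_log2fc: float, prot_status: str, prot_log2fc: float
) -> PairClass:
    """Map the two layers' statuses (and signs) onto a regulatory pattern.

    Raises if a status contradicts the sign of its log2FC, which would
    indicate an upstream thresholding bug.
    """
    for status, lfc, layer in (
        (rna_status, rna_log2fc, "RNA"),
        (prot_status, prot_log2fc, "protein"),
    ):
        if status not in ("UP", "DOWN", "NS"):
            raise ValueError(f"unknown status {status!r}")
        if status == "UP" and not lfc > 0:
            raise ValueError(f"{layer} status UP with log2fc {lfc}")
        if status == "DOWN" and not lfc < 0:
            raise ValueError(f"{layer} status DOWN with log2fc {lfc}")

    rna_sig = rna_status != "NS"
    prot_sig = prot_status != "NS"
    if not rna_sig and not prot_sig:
        return PairClass.NS
    if rna_sig and not prot_sig:
        return PairClass.RNA_EXCLUSIVE
    if prot_sig and not rna_sig:
        return PairClass.PROTEIN_EXCLUSIVE
    if rna_status == prot_status:
        return PairClass.CONCORDANT_UP if rna_status == "UP" else PairClass.CONCORDANT_DOWN
    return PairClass.DISCORDANT


def build_pairs(
    deg: pd.DataFrame,
    dep: pd.DataFrame,
    gp_map: GeneProteinMap,
    contrast: Contrast,
    collapse: bool = False,
    intensities: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per tested protein whose mapped gene was tested at RNA level.

    ``deg`` / ``dep`` are ContrastResult frames indexed by feature_id. With
    ``collapse=True`` a gene keeps only its max-mean-intensity protein
    (requires ``intensities``).
    """
    gene_for = gp_map.gene_for()
    rows = []
    for protein_id in dep.index:
        gene_id = gene_for.get(protein_id)
        if gene_id is None or gene_id not in deg.index:
            continue
        r, p = deg.loc[gene_id], dep.loc[protein_id]
        rows.append(
            {
                "gene_id": gene_id,
                "protein_id": protein_id,
                "rna_log2fc": r["log2fc"],
                "rna_pvalue": r["pvalue"],
                "rna_fdr": r["fdr"],
                "rna_status": r["status"],
                "prot_log2fc": p["log2fc"],
                "prot_pvalue": p["pvalue"],
                "prot_fdr": p["fdr"],
                "prot_status": p["status"],
            }
        )
    pairs = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "protein_id",
            "rna_log2fc", "rna_pvalue", "rna_fdr", "rna_status",
            "prot_log2fc", "prot_pvalue", "prot_fdr", "prot_status",
        ],
    )
    if pairs.empty:
        warnings.warn(f"{contrast.name}: no gene-protein pairs", stacklevel=2)
        pairs["pair_class"] = pd.Series(dtype=object)
        return pairs

    if collapse:
        if intensities is None:
            raise ValueError("collapse=True requires the intensity matrix")
        mean_int = intensities.mean(axis=1, skipna=True)
        pairs["_mi"] = pairs["protein_id"].map(mean_int)
        pairs = (
            pairs.sort_values(["gene_id", "_mi"], ascending=[True, False])
            .drop_duplicates("gene_id", keep="first")
            .drop(columns="_mi")
            .reset_index(drop=True)
        )

    pairs["pair_class"] = [
        classify_pair(r.rna_status, r.rna_log2fc, r.prot_status, r.prot_log2fc).value
        for r in pairs.itertuples()
    ]
    return pairs


def correlate(x, y) -> tuple[float, float]:
    """(Pearson r, Spearman rho); rho is Pearson on mid-ranks.

    A zero-variance vector makes the corresponding coefficient NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("correlate needs two equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("correlate needs length >= 2")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("MISSING values not allowed in correlate")

    def _pearson(a: np.ndarray, b: np.ndarray) -> float:
        if a.std() == 0 or b.std() == 0:
            return float("nan")
        a = a - a.mean()
        b = b - b.mean()
        return float((a @ b) / math.sqrt((a @ a) * (b @ b)))

    rx = pd.Series(x).rank(method="average").to_numpy()
    ry = pd.Series(y).rank(method="average").to_numpy()
    return _pearson(x, y), _pearson(rx, ry)


def format_pct(value: float) -> str:
    """Report view of a percentage: one decimal, two significant decimals
    below 0.1 (so 18.6 and 0.08 print as the study tables do)."""
    if value < 0.1:
        return f"{value:.2f}"
    return f"{value:.1f}"


@dataclass
class ConcordanceSummary:
    n_pairs: int
    n_concordant: int
    concordance_pct: float
    pearson_r: float
    spearman_rho: float
    class_counts: dict

    def as_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_concordant": self.n_concordant,
            "concordance_pct": self.concordance_pct,
            "concordance_pct_display": format_pct(self.concordance_pct),
            "pearson_r": self.pearson_r,
            "spearman_rho": self.spearman_rho,
            "class_counts": self.class_counts,
        }


def summarize_concordance(pairs: pd.DataFrame) -> ConcordanceSummary:
    """Concordant share and cross-layer log2FC correlations over all pairs."""
    n_pairs = len(pairs)
    counts = {c: 0 for c in PAIR_CLASSES}
    if n_pairs:
        counts.update(pairs["pair_class"].value_counts().to_dict())
    n_conc = counts["CONCORDANT_UP"] + counts["CONCORDANT_DOWN"]
    pct = 100.0 * n_conc / n_pairs if n_pairs else float("nan")
    if n_pairs >= 2:
        r, rho = correlate(pairs["rna_log2fc"], pairs["prot_log2fc"])
    else:
        r = rho = float("nan")
    return ConcordanceSummary(n_pairs, n_conc, pct, r, rho, counts)
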