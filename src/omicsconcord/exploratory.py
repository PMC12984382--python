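"""PCA and z-score hierarchical-clustering views of omics matrices.

PCA centres each feature across samples (no unit scaling by default: on
log-transformed count data the variance scale is meaningful) and runs an
SVD over the sample dimension; the percentage of variance explained by
component k is 100 * sigma_k^2 / sum(sigma^2). Constant features are
dropped with a warning. For methylation proportions a logit-transformed
convenience entry point is provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    variance_explained_pct: np.ndarray


def pca(x: pd.DataFrame, log_mode: bool = False, scale: bool = False) -> PCAResult:
    """PCA of a feature x sample matrix over the sample dimension.

    ``log_mode`` applies log2(x + 1) first (for count data); ``scale``
    additionally divides each centred feature by its standard deviation.
    """
    if x.shape[1] < 2:
        raise ValueError("PCA needs at least two samples")
    values = x.to_numpy(dtype=float)
    if log_mode:
        values = np.log2(values + 1.0)
    sd = values.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant feature(s)", stacklevel=2)
        values = values[~constant]
        sd = sd[~constant]
    features = x.index[~constant]

    centred = values - values.mean(axis=1, keepdims=True)
    if scale:
        centred = centred / sd[:, None]

    # rows = samples for the decomposition
    u, s, vt = np.linalg.svd(centred.T, full_matrices=False)
    var_pct = 100.0 * s**2 / np.sum(s**2)
    comp_names = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(u * s, index=x.columns, columns=comp_names)
    loadings = pd.DataFrame(vt.T, index=features, columns=comp_names)
    return PCAResult(scores, loadings, var_pct)


def pca_methylation(proportions: pd.DataFrame, eps: float = 0.01) -> PCAResult:
    """PCA on logit-transformed methylation proportions."""
    p = proportions.clip(lower=eps, upper=1 - eps)
    return pca(np.log2(p / (1 - p)), log_mode=False)


def zscore_rows(x: pd.DataFrame) -> pd.DataFrame:
    """Per-feature z-scores; zero-sd features become rows of zeros."""
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=0)
    z = x.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} zero-sd feature(s) z-scored to 0", stacklevel=2)
    return z


def cluster_heatmap_order(
    x: pd.DataFrame, linkage: str = "average"
) -> tuple[list, list]:
    """Row and column leaf orderings for a z-scored heatmap.

    Rows are z-scored before clustering; agglomerative clustering uses
    Euclidean distance with the requested linkage (average or complete).
    scipy's linkage is deterministic, so ties break by input order.
    """
    if linkage not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >=2 rows and >=2 columns")
    z = zscore_rows(x)
    row_link = hierarchy.linkage(pdist(z.to_numpy()), method=linkage)
    col_link = hierarchy.linkage(pdist(z.to_numpy().T), method=linkage)
    row_order = [x.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [x.columns[i] for i in hierarchy.leaves_list(col_link)]
    return row_order, col_order
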