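"""Negative-binomial differential expression on RNA-seq counts.

A deliberately self-contained NB Wald procedure: median-of-ratios size
factors, method-of-moments gene-wise dispersion shrunk toward a mean-
dispersion trend, and a per-gene NB GLM (log link, intercept + group
indicator) fitted by IRLS with the dispersion held fixed. No Cox-Reid
adjustment, LFC shrinkage, independent filtering or outlier handling is
applied; numerical parity with heavier NB frameworks is a non-goal.

A gene is called differentially expressed when |log2FC| >= 1 and the
Benjamini-Hochberg FDR is below 0.05; the BH family is the set of genes
tested in the contrast at hand (genes with nonzero counts in at least one
of its samples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import Contrast, CountMatrix, SampleTable

logger = logging.getLogger(__name__)

RNA_LFC_THRESHOLD = 1.0
RNA_FDR_THRESHOLD = 0.05

_DISPERSION_FLOOR = 1e-8
_MAX_IRLS_ITER = 100
_IRLS_TOL = 1e-8
_BETA_CAP = 30.0  # natural-log scale; caps divergent fits on all-zero groups


class DEError(ValueError):
    pass


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up FDR: q_(i) = min_{j>=i} (m/j) p_(j), clipped at 1.

    Order of the input is preserved in the output; ties share a value by
    construction of the running minimum.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise DEError("MISSING p-values must be excluded before BH")
    if (p < 0).any() or (p > 1).any():
        raise DEError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def size_factors_median_of_ratios(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled so their geometric mean is 1.

    The pseudo-reference is the per-gene geometric mean over samples,
    restricted to genes positive in every sample.
    """
    k = counts.values.to_numpy(dtype=float)
    if k.shape[1] < 2:
        raise DEError("need at least two samples for size factors")
    all_positive = (k > 0).all(axis=1)
    if not all_positive.any():
        raise DEError(
            "no gene has positive counts in every sample; "
            "pseudo-reference fallback is disabled"
        )
    kp = k[all_positive]
    log_geomean = np.log(kp).mean(axis=1)
    ratios = np.log(kp) - log_geomean[:, None]
    s = np.exp(np.median(ratios, axis=0))
    s = s / np.exp(np.log(s).mean())  # geomean(s) = 1 convention
    return pd.Series(s, index=counts.values.columns, name="size_factor")


@dataclass
class DispersionEstimate:
    """Per-gene NB dispersion: raw method-of-moments, trend and shrunk final."""

    raw: pd.Series
    trend: pd.Series
    final: pd.Series
    flagged_zero_mean: pd.Series  # genes whose dispersion fell back to the trend


def _fit_trend(alpha: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    """Fit alpha ~ a0 + a1/mu by least squares with one outlier-trimming pass."""
    use = alpha > 0
    if use.sum() < 2:
        # degenerate fixture: flat trend at the mean (or floor)
        level = float(alpha[use].mean()) if use.any() else _DISPERSION_FLOOR
        return max(level, _DISPERSION_FLOOR), 0.0
    x = 1.0 / mu[use]
    y = alpha[use]
    for _ in range(2):
        A = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        mad = np.median(np.abs(resid - np.median(resid)))
        if mad == 0:
            break
        keep = np.abs(resid) <= 3 * 1.4826 * mad
        if keep.all() or keep.sum() < 2:
            break
        x, y = x[keep], y[keep]
    a0, a1 = float(coef[0]), float(coef[1])
    return max(a0, _DISPERSION_FLOOR), max(a1, 0.0)


def estimate_dispersion(
    counts: CountMatrix, size_factors: pd.Series, samples: SampleTable
) -> DispersionEstimate:
    """Method-of-moments dispersion pooled within groups, shrunk to a trend.

    Raw estimate per gene: alpha = max(0, (s2 - mu) / mu^2) on size-factor
    normalised counts, with the variance pooled within groups. The trend is a
    robust two-parameter fit a0 + a1/mu; the final value is the geometric
    mean of raw and trend (weight 0.5 on the log scale), with zero-variance
    or zero-mean genes pulled fully to the trend.
    """
    norm = counts.values.to_numpy(dtype=float) / size_factors.reindex(
        counts.values.columns
    ).to_numpy()
    groups = samples.table.loc[counts.values.columns, "group"].to_numpy()
    uniq = pd.unique(groups)

    ss = np.zeros(norm.shape[0])
    df = 0
    for g in uniq:
        cols = groups == g
        n_g = int(cols.sum())
        if n_g < 2:
            continue
        sub = norm[:, cols]
        ss += sub.var(axis=1, ddof=1) * (n_g - 1)
        df += n_g - 1
    if df == 0:
        raise DEError("need >=2 replicates in at least one group")
    s2 = ss / df
    mu = norm.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, np.maximum(0.0, (s2 - mu) / np.maximum(mu, 1e-300) ** 2), 0.0)

    zero_mean = mu <= 0
    a0, a1 = _fit_trend(raw[~zero_mean], mu[~zero_mean])
    trend = np.full_like(mu, a0)
    trend[~zero_mean] = np.maximum(a0 + a1 / mu[~zero_mean], _DISPERSION_FLOOR)

    final = np.where(
        (raw <= _DISPERSION_FLOOR) | zero_mean,
        trend,
        np.exp(0.5 * np.log(np.maximum(raw, _DISPERSION_FLOOR)) + 0.5 * np.log(trend)),
    )
    final = np.maximum(final, _DISPERSION_FLOOR)

    idx = counts.values.index
    return DispersionEstimate(
        raw=pd.Series(raw, index=idx),
        trend=pd.Series(trend, index=idx),
        final=pd.Series(final, index=idx),
        flagged_zero_mean=pd.Series(zero_mean, index=idx),
    )


def _irls_two_group(
    y: np.ndarray, offset: np.ndarray, x: np.ndarray, alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised IRLS for per-gene NB GLMs sharing one 2-column design.

    y: genes x samples counts; offset: log size factors; x: group indicator
    (1 = numerator); alpha: per-gene dispersion. Returns (beta1, se1,
    converged). The design is intercept + indicator, so the weighted normal
    equations are closed-form 2x2 per gene.
    """
    n_genes, n_samples = y.shape
    # moment-based start
    mean1 = (y[:, x == 1] / np.exp(offset[x == 1])).mean(axis=1)
    mean0 = (y[:, x == 0] / np.exp(offset[x == 0])).mean(axis=1)
    b0 = np.log(np.maximum(mean0, 1e-8))
    b1 = np.log(np.maximum(mean1, 1e-8)) - b0

    converged = np.zeros(n_genes, dtype=bool)
    active = np.ones(n_genes, dtype=bool)
    for _ in range(_MAX_IRLS_ITER):
        eta = b0[:, None] + b1[:, None] * x[None, :] + offset[None, :]
        mu = np.exp(np.clip(eta, -700, 700))
        w = mu / (1.0 + alpha[:, None] * mu)  # NB working weights, fixed alpha
        z = (y - mu) / np.maximum(mu, 1e-300)

        sw = w.sum(axis=1)
        swx = (w * x[None, :]).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w * z * x[None, :]).sum(axis=1)
        det = sw * swx - swx * swx  # x binary: sum(w x^2) = sum(w x)
        det = np.where(det <= 0, np.nan, det)
        # solve [sw, swx; swx, swx] [d0, d1] = [swz, swxz]
        d1 = (sw * swxz - swx * swz) / det
        d0 = (swz - swx * d1) / sw

        step0 = np.where(active, d0, 0.0)
        step1 = np.where(active, d1, 0.0)
        b0 = np.clip(b0 + np.nan_to_num(step0), -_BETA_CAP, _BETA_CAP)
        b1 = np.clip(b1 + np.nan_to_num(step1), -_BETA_CAP, _BETA_CAP)

        moved = np.abs(np.nan_to_num(step0)) + np.abs(np.nan_to_num(step1))
        newly = active & (moved < _IRLS_TOL)
        converged |= newly
        active &= ~newly
        if not active.any():
            break

    eta = b0[:, None] + b1[:, None] * x[None, :] + offset[None, :]
    mu = np.exp(np.clip(eta, -700, 700))
    w = mu / (1.0 + alpha[:, None] * mu)
    sw = w.sum(axis=1)
    swx = (w * x[None, :]).sum(axis=1)
    det = sw * swx - swx * swx
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = sw / det  # (X'WX)^{-1}[1,1]
    se1 = np.sqrt(np.where(var_b1 > 0, var_b1, np.nan))
    return b1, se1, converged


def nb_wald_contrast(
    counts: CountMatrix,
    size_factors: pd.Series,
    dispersions: DispersionEstimate,
    contrast: Contrast,
    samples: SampleTable,
    lfc_threshold: float = RNA_LFC_THRESHOLD,
    fdr_threshold: float = RNA_FDR_THRESHOLD,
) -> pd.DataFrame:
    """Wald test of the group coefficient for one two-group contrast.

    Returns a DataFrame indexed by feature_id with columns log2fc, pvalue,
    fdr, status (UP/DOWN/NS). Genes with all-zero counts across the
    contrast's samples are excluded from testing and from the BH family.
    """
    from scipy import stats

    num_samples = samples.samples_in_group(contrast.numerator)
    den_samples = samples.samples_in_group(contrast.denominator)
    if len(num_samples) < 2 or len(den_samples) < 2:
        raise DEError(f"both groups of {contrast.name} need >=2 samples")
    cols = den_samples + num_samples
    x = np.array([0] * len(den_samples) + [1] * len(num_samples), dtype=float)

    sub = counts.values[cols].to_numpy(dtype=float)
    tested = sub.sum(axis=1) > 0
    y = sub[tested]
    alpha = dispersions.final.reindex(counts.values.index).to_numpy()[tested]
    offset = np.log(size_factors.reindex(cols).to_numpy())

    b1, se1, converged = _irls_two_group(y, offset, x, alpha)
    log2fc = b1 / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = b1 / se1
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue = np.where(converged & np.isfinite(pvalue), pvalue, np.nan)

    ok = ~np.isnan(pvalue)
    fdr = np.full(pvalue.shape, np.nan)
    if ok.any():
        fdr[ok] = benjamini_hochberg(pvalue[ok])

    status = np.full(pvalue.shape, "NS", dtype=object)
    sig = ok & (fdr < fdr_threshold)
    status[sig & (log2fc >= lfc_threshold)] = "UP"
    status[sig & (log2fc <= -lfc_threshold)] = "DOWN"

    n_nonconv = int((~converged).sum())
    if n_nonconv:
        logger.warning("%s: %d gene(s) did not converge", contrast.name, n_nonconv)

    idx = counts.values.index[tested]
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvalue, "fdr": fdr, "status": status}, index=idx
    ).rename_axis("feature_id")


def run_de_rna(
    counts: CountMatrix,
    samples: SampleTable,
    contrast: Contrast,
    lfc_threshold: float = RNA_LFC_THRESHOLD,
    fdr_threshold: float = RNA_FDR_THRESHOLD,
) -> pd.DataFrame:
    """Full RNA DE for one contrast: size factors, dispersion, NB Wald."""
    sf = size_factors_median_of_ratios(counts)
    cols = samples.samples_in_group(contrast.numerator) + samples.samples_in_group(
        contrast.denominator
    )
    sub = CountMatrix(counts.values[cols])
    sub_sf = sf[cols] / np.exp(np.log(sf[cols]).mean())
    disp = estimate_dispersion(sub, sub_sf, samples)
    return nb_wald_contrast(
        sub, sub_sf, disp, contrast, samples, lfc_threshold, fdr_threshold
    )
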