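"""Label-free proteomic filtering and moderated-t differential abundance.

Proteins are filtered (contaminants, <2 unique peptides, missing in more
than 30% of replicates — strict inequality), log2-transformed and
median-centred per sample, then tested per contrast with an empirical-Bayes
moderated t: per-protein available-case pooled variances are shrunk toward
a common prior whose degrees of freedom d0 and scale s0^2 are obtained by
closed-form moment matching on log s^2 (digamma/trigamma inversion).

A protein is a DEP when |log2FC| >= 0.5 and BH FDR < 0.05. The threshold is
applied symmetrically: the down direction uses log2FC <= -0.5.

Missing values are never imputed; with intensity-dependent (MNAR) dropout,
imputation would bias fold changes, so each protein is tested on its
available cases with its own degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .data_model import Contrast, IntensityMatrix, SampleTable
from .de_rna import benjamini_hochberg

logger = logging.getLogger(__name__)

PROT_LFC_THRESHOLD = 0.5
PROT_FDR_THRESHOLD = 0.05

_D0_CAP = 1e6  # treated as an effectively infinite prior


@dataclass
class FilterReport:
    n_input: int
    n_removed_contaminant: int
    n_removed_peptides: int
    n_removed_missingness: int
    n_retained: int

    def as_dict(self) -> dict:
        return asdict(self)


def filter_proteins(
    m: IntensityMatrix, max_missing_frac: float = 0.30, per_group: SampleTable | None = None
) -> tuple[IntensityMatrix, FilterReport]:
    """Apply the three retention rules with fixed report precedence.

    Removal reasons are attributed in the order contaminant -> unique
    peptides < 2 -> missing fraction > ``max_missing_frac`` (strict: a
    protein missing in exactly 30% of samples is retained). If ``per_group``
    is given, the missingness rule applies within every group instead of
    across all samples.
    """
    v = m.values
    contaminant = m.is_contaminant.reindex(v.index).fillna(False).astype(bool)
    few_peptides = m.unique_peptides.reindex(v.index) < 2

    if per_group is None:
        miss_frac = v.isna().mean(axis=1)
        too_missing = miss_frac > max_missing_frac
    else:
        groups = per_group.table.loc[v.columns, "group"]
        too_missing = pd.Series(False, index=v.index)
        for g in groups.unique():
            cols = groups.index[groups == g]
            too_missing |= v[cols].isna().mean(axis=1) > max_missing_frac

    removed_cont = contaminant
    removed_pept = ~removed_cont & few_peptides
    removed_miss = ~removed_cont & ~few_peptides & too_missing
    keep = ~(removed_cont | removed_pept | removed_miss)

    report = FilterReport(
        n_input=len(v),
        n_removed_contaminant=int(removed_cont.sum()),
        n_removed_peptides=int(removed_pept.sum()),
        n_removed_missingness=int(removed_miss.sum()),
        n_retained=int(keep.sum()),
    )
    filtered = IntensityMatrix(
        v.loc[keep].copy(),
        unique_peptides=m.unique_peptides.reindex(v.index)[keep],
        is_contaminant=contaminant[keep],
    )
    logger.info("protein filter: %s", report.as_dict())
    return filtered, report


def log_transform_normalize(m: IntensityMatrix) -> pd.DataFrame:
    """log2 intensities, median-centred per sample over present values."""
    logged = np.log2(m.values)
    medians = logged.median(axis=0, skipna=True)
    return logged - medians


def fit_ebayes_hyperparams(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match (d0, s0^2) to the scaled-chi-square model of variances.

    For s^2 ~ s0^2 * chi2_df / df scaled by a chi2_d0 prior, z = log s^2 has
    E[z] = log s0^2 + digamma(df/2) - log(df/2) - digamma(d0/2) + log(d0/2)
    and Var[z] = trigamma(df/2) + trigamma(d0/2). d0 comes from inverting
    the trigamma by Newton steps (tol 1e-8, capped at 1e6 ~ infinity).
    """
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return _D0_CAP, float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1.0
    z = np.log(s2[ok])
    dg = df[ok].astype(float)
    e = z - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    excess = np.var(e, ddof=1) - np.mean(special.polygamma(1, dg / 2.0))
    if excess <= 0:
        d0 = _D0_CAP
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        d0 = min(d0, _D0_CAP)
    s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def moderated_t_contrast(
    x: pd.DataFrame,
    contrast: Contrast,
    samples: SampleTable,
    lfc_threshold: float = PROT_LFC_THRESHOLD,
    fdr_threshold: float = PROT_FDR_THRESHOLD,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t for one two-group contrast.

    ``x`` is the log2, median-centred intensity matrix (NaN = missing).
    Available-case analysis: a protein needs >=2 present values in each
    group, otherwise it is excluded from this contrast and flagged in the
    log. Returns a DataFrame with log2fc, pvalue, fdr, status plus the
    diagnostic columns t_mod, df_total, n_num, n_den.
    """
    num_cols = [s for s in samples.samples_in_group(contrast.numerator) if s in x.columns]
    den_cols = [s for s in samples.samples_in_group(contrast.denominator) if s in x.columns]
    a = x[num_cols].to_numpy(dtype=float)
    b = x[den_cols].to_numpy(dtype=float)

    n1 = (~np.isnan(a)).sum(axis=1)
    n2 = (~np.isnan(b)).sum(axis=1)
    testable = (n1 >= 2) & (n2 >= 2)
    n_excluded = int((~testable).sum())
    if n_excluded:
        logger.info("%s: %d protein(s) excluded (<2 present per group)", contrast.name, n_excluded)
    if not testable.any():
        warnings.warn(f"{contrast.name}: all proteins excluded", stacklevel=2)
        return pd.DataFrame(
            columns=["log2fc", "pvalue", "fdr", "status", "t_mod", "df_total", "n_num", "n_den"]
        ).rename_axis("feature_id")

    a, b = a[testable], b[testable]
    n1, n2 = n1[testable], n2[testable]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean1 = np.nanmean(a, axis=1)
        mean2 = np.nanmean(b, axis=1)
        var1 = np.nanvar(a, axis=1, ddof=1)
        var2 = np.nanvar(b, axis=1, ddof=1)
    log2fc = mean1 - mean2
    dg = (n1 + n2 - 2).astype(float)
    s2 = ((n1 - 1) * np.nan_to_num(var1) + (n2 - 1) * np.nan_to_num(var2)) / dg

    d0, s0_sq = fit_ebayes_hyperparams(s2, dg)
    s2_post = (d0 * s0_sq + dg * s2) / (d0 + dg)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log2fc / se
    df_total = np.minimum(d0 + dg, _D0_CAP)
    pvalue = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    pvalue = np.where(np.isfinite(pvalue), pvalue, np.nan)

    ok = ~np.isnan(pvalue)
    fdr = np.full(pvalue.shape, np.nan)
    if ok.any():
        fdr[ok] = benjamini_hochberg(pvalue[ok])

    status = np.full(pvalue.shape, "NS", dtype=object)
    sig = ok & (fdr < fdr_threshold)
    status[sig & (log2fc >= lfc_threshold)] = "UP"
    status[sig & (log2fc <= -lfc_threshold)] = "DOWN"

    idx = x.index[testable]
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvalue,
            "fdr": fdr,
            "status": status,
            "t_mod": t_mod,
            "df_total": df_total,
            "n_num": n1,
            "n_den": n2,
        },
        index=idx,
    ).rename_axis("feature_id")


def run_de_protein(
    m: IntensityMatrix,
    samples: SampleTable,
    contrast: Contrast,
    lfc_threshold: float = PROT_LFC_THRESHOLD,
    fdr_threshold: float = PROT_FDR_THRESHOLD,
) -> tuple[pd.DataFrame, FilterReport]:
    """Filter, normalise and test one contrast; returns (results, report)."""
    filtered, report = filter_proteins(m)
    x = log_transform_normalize(filtered)
    res = moderated_t_contrast(x, contrast, samples, lfc_threshold, fdr_threshold)
    return res, report
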