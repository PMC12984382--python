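"""Per-CpG differential methylation and genomic-feature annotation.

CpGs are kept when total coverage exceeds 8 reads in every sample of both
contrast groups (strict >8) and the pooled methylation proportion is not
degenerate (0 or 1, i.e. no variability). Counts are then pooled within
group into a 2x2 table and tested with a two-sided Fisher's exact test;
BH across CpGs, with a CpG called differentially methylated at FDR < 0.01.

Pooling discards replicate-level overdispersion, which makes the call
anti-conservative when individuals vary beyond binomial noise; this
replicate-aware limitation is documented rather than modelled.

Feature contexts come from a gene model (GFF3 or BED12): promoter
[TSS-2000, TSS+500] in transcript orientation, then exon, first (5'-most)
intron, other intron, intergenic - resolved in that precedence when a
position hits several transcripts. The CpG's own strand is ignored; the
feature strand orients the promoter window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Contrast, DataModelError, SampleTable
from .de_rna import benjamini_hochberg

logger = logging.getLogger(__name__)

METH_COVERAGE_MIN = 8  # strict: keep t > 8
METH_FDR_THRESHOLD = 0.01
PROMOTER_UP = 2000
PROMOTER_DOWN = 500

FEATURE_PRECEDENCE = ("promoter", "exon", "first_intron", "other_intron", "intergenic")


@dataclass
class MethylationTable:
    """Per-CpG methylated (m) / total (t) read counts per sample.

    ``sites``: DataFrame with columns chrom, pos (1-based), strand.
    ``meth`` / ``total``: DataFrames (sites x samples), same index.
    """

    sites: pd.DataFrame
    meth: pd.DataFrame
    total: pd.DataFrame

    def __post_init__(self) -> None:
        key = self.sites[["chrom", "pos", "strand"]]
        if key.duplicated().any():
            raise DataModelError("duplicate CpG positions")
        m = self.meth.to_numpy()
        t = self.total.to_numpy()
        if (m < 0).any() or (m > t).any():
            raise DataModelError("need 0 <= methylated <= total per cell")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meth.columns)

    def subset(self, mask: np.ndarray) -> "MethylationTable":
        return MethylationTable(
            self.sites[mask].reset_index(drop=True),
            self.meth[mask].reset_index(drop=True),
            self.total[mask].reset_index(drop=True),
        )

    @classmethod
    def read_tsv(cls, path) -> "MethylationTable":
        """TSV layout: chrom, pos, strand, then <sample>_m / <sample>_t pairs."""
        df = pd.read_csv(path, sep="\t")
        sites = df[["chrom", "pos", "strand"]].copy()
        m_cols = [c for c in df.columns if c.endswith("_m")]
        samples = [c[:-2] for c in m_cols]
        meth = df[[f"{s}_m" for s in samples]].copy()
        meth.columns = samples
        total = df[[f"{s}_t" for s in samples]].copy()
        total.columns = samples
        return cls(sites, meth, total)

    def write_tsv(self, path) -> None:
        out = self.sites.copy()
        for s in self.sample_ids:
            out[f"{s}_m"] = self.meth[s]
            out[f"{s}_t"] = self.total[s]
        out.to_csv(path, sep="\t", index=False)


def filter_cpgs(
    mt: MethylationTable, contrast: Contrast, samples: SampleTable
) -> MethylationTable:
    """Coverage (>8 in every sample of both groups) and variability filter."""
    cols = samples.samples_in_group(contrast.numerator) + samples.samples_in_group(
        contrast.denominator
    )
    cols = [c for c in cols if c in mt.total.columns]
    t = mt.total[cols].to_numpy()
    m = mt.meth[cols].to_numpy()
    covered = (t > METH_COVERAGE_MIN).all(axis=1)
    pooled = m.sum(axis=1) / np.maximum(t.sum(axis=1), 1)
    variable = (pooled > 0) & (pooled < 1)
    keep = covered & variable
    logger.info(
        "%s: %d/%d CpGs pass coverage+variability", contrast.name, int(keep.sum()), len(keep)
    )
    return mt.subset(keep)


def dm_test(
    mt: MethylationTable,
    contrast: Contrast,
    samples: SampleTable,
    fdr_threshold: float = METH_FDR_THRESHOLD,
) -> pd.DataFrame:
    """Pooled-count Fisher's exact test per CpG.

    Returns a DataFrame with chrom, pos, strand, delta (proportion
    difference, numerator minus denominator), log2_ratio (group mean
    proportions with p-hat clamped away from 0/1 by 1/(T+1)), pvalue, fdr
    and is_dm.
    """
    g1 = [c for c in samples.samples_in_group(contrast.numerator) if c in mt.meth.columns]
    g2 = [c for c in samples.samples_in_group(contrast.denominator) if c in mt.meth.columns]
    m1 = mt.meth[g1].to_numpy().sum(axis=1)
    t1 = mt.total[g1].to_numpy().sum(axis=1)
    m2 = mt.meth[g2].to_numpy().sum(axis=1)
    t2 = mt.total[g2].to_numpy().sum(axis=1)
    u1, u2 = t1 - m1, t2 - m2

    pvals = np.ones(len(m1))
    for i in range(len(m1)):
        table = np.array([[m1[i], u1[i]], [m2[i], u2[i]]])
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            pvals[i] = 1.0  # degenerate margin
            continue
        pvals[i] = stats.fisher_exact(table, alternative="two-sided")[1]

    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(t1 > 0, m1 / np.maximum(t1, 1), np.nan)
        p2 = np.where(t2 > 0, m2 / np.maximum(t2, 1), np.nan)
    delta = p1 - p2
    big_t = t1 + t2
    lo = 1.0 / (big_t + 1.0)
    hi = big_t / (big_t + 1.0)
    p1c = np.clip(p1, lo, hi)
    p2c = np.clip(p2, lo, hi)
    log2_ratio = np.log2(p1c / p2c)

    fdr = benjamini_hochberg(pvals) if len(pvals) else np.array([])
    is_dm = fdr < fdr_threshold

    out = mt.sites[["chrom", "pos", "strand"]].copy()
    out["delta"] = delta
    out["log2_ratio"] = log2_ratio
    out["pvalue"] = pvals
    out["fdr"] = fdr
    out["is_dm"] = is_dm
    return out


# ---------------------------------------------------------------------------
# gene models and feature-context annotation


@dataclass
class Transcript:
    """One transcript span with exons, 1-based inclusive coordinates."""

    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    exons: list = field(default_factory=list)  # list of (start, end)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    def promoter(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.tss - PROMOTER_UP, self.tss + PROMOTER_DOWN
        return self.tss - PROMOTER_DOWN, self.tss + PROMOTER_UP

    def introns(self) -> list:
        """(start, end, is_first) with 'first' = 5'-most in transcript orientation."""
        exons = sorted(self.exons)
        gaps = [
            (exons[i][1] + 1, exons[i + 1][0] - 1)
            for i in range(len(exons) - 1)
            if exons[i + 1][0] - exons[i][1] > 1
        ]
        if not gaps:
            return []
        first_idx = 0 if self.strand == "+" else len(gaps) - 1
        return [(s, e, i == first_idx) for i, (s, e) in enumerate(gaps)]


def read_gff3(path) -> list[Transcript]:
    """Minimal GFF3 consumption: mRNA/transcript rows and their exons."""
    transcripts: dict[str, Transcript] = {}
    exon_rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise DataModelError("GFF3 row with fewer than 9 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype in ("mRNA", "transcript"):
                tid = attr.get("ID")
                if tid is None:
                    raise DataModelError("transcript row without ID attribute")
                transcripts[tid] = Transcript(tid, chrom, int(start), int(end), strand)
            elif ftype == "exon":
                exon_rows.append((attr.get("Parent"), int(start), int(end)))
    for parent, start, end in exon_rows:
        if parent in transcripts:
            transcripts[parent].exons.append((start, end))
    return list(transcripts.values())


def read_bed12(path) -> list[Transcript]:
    """BED12 gene model; 0-based half-open converted to 1-based inclusive."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise DataModelError("BED12 row with fewer than 12 columns")
            chrom, start0, end, name, _, strand = f[:6]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            tx_start = int(start0) + 1
            exons = [
                (tx_start + off, tx_start + off + size - 1)
                for off, size in zip(offsets, sizes)
            ]
            out.append(Transcript(name, chrom, tx_start, int(end), strand, exons))
    return out


def annotate_context(dm: pd.DataFrame, transcripts: list[Transcript]) -> pd.DataFrame:
    """Assign one feature context per CpG with fixed precedence.

    promoter > exon > first_intron > other_intron > intergenic across all
    transcripts overlapping the position. CpGs on chromosomes absent from
    the gene model are intergenic and flagged (``unannotated_chrom``).
    """
    by_chrom: dict[str, list[Transcript]] = {}
    for tx in transcripts:
        by_chrom.setdefault(tx.chrom, []).append(tx)

    rank = {name: i for i, name in enumerate(FEATURE_PRECEDENCE)}
    contexts, flags = [], []
    for chrom, pos in zip(dm["chrom"], dm["pos"]):
        txs = by_chrom.get(chrom)
        if txs is None:
            contexts.append("intergenic")
            flags.append(True)
            continue
        best = "intergenic"
        for tx in txs:
            ps, pe = tx.promoter()
            if ps <= pos <= pe and rank["promoter"] < rank[best]:
                best = "promoter"
            if tx.start <= pos <= tx.end:
                label = None
                if any(s <= pos <= e for s, e in tx.exons):
                    label = "exon"
                else:
                    for s, e, is_first in tx.introns():
                        if s <= pos <= e:
                            label = "first_intron" if is_first else "other_intron"
                            break
                if label and rank[label] < rank[best]:
                    best = label
        contexts.append(best)
        flags.append(False)
    out = dm.copy()
    out["feature_context"] = contexts
    out["unannotated_chrom"] = flags
    return out


def run_methylation(
    mt: MethylationTable,
    contrast: Contrast,
    samples: SampleTable,
    transcripts: list[Transcript] | None = None,
) -> pd.DataFrame:
    filtered = filter_cpgs(mt, contrast, samples)
    dm = dm_test(filtered, contrast, samples)
    if transcripts is not None:
        dm = annotate_context(dm, transcripts)
    return dm
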