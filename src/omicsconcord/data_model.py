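"""Domain types and TSV/GMT readers shared by every pipeline stage.

All matrices are features-in-rows, samples-in-columns. Feature identifiers are
opaque strings; no accession normalisation is attempted. Missing label-free
intensities are encoded as NaN in memory and as an empty cell or ``NA``
(case-insensitive) on disk; a literal ``0`` intensity is rejected because LFQ
intensities are strictly positive where observed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("F1F", "F1M", "wtF", "wtM")

#: sex / origin factors implied by each group label
GROUP_SEX = {"F1F": "F", "F1M": "M", "wtF": "F", "wtM": "M"}
GROUP_ORIGIN = {"F1F": "F1", "F1M": "F1", "wtF": "wt", "wtM": "wt"}

#: the four canonical two-group comparisons of the study design
CANONICAL_CONTRASTS = (
    ("F1F", "F1M"),
    ("F1F", "wtF"),
    ("F1M", "wtM"),
    ("wtF", "wtM"),
)

MISSING_TOKENS = {"", "na"}


class DataModelError(ValueError):
    """Raised on any structural violation of the input contracts."""


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison; log2FC > 0 means higher in the numerator group."""

    numerator: str
    denominator: str

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise DataModelError("contrast groups must be distinct")
        for g in (self.numerator, self.denominator):
            if g not in GROUPS:
                raise DataModelError(f"unknown group {g!r}; expected one of {GROUPS}")

    @property
    def name(self) -> str:
        return f"{self.numerator}_vs_{self.denominator}"

    @classmethod
    def parse(cls, text: str) -> "Contrast":
        """Parse 'F1F:F1M' or 'F1F_vs_F1M'."""
        sep = ":" if ":" in text else "_vs_"
        parts = text.split(sep)
        if len(parts) != 2:
            raise DataModelError(f"cannot parse contrast {text!r}")
        return cls(parts[0], parts[1])


def canonical_contrasts() -> list[Contrast]:
    return [Contrast(a, b) for a, b in CANONICAL_CONTRASTS]


@dataclass
class SampleTable:
    """Sample metadata: one row per sample with group, derived sex and origin."""

    table: pd.DataFrame  # index sample_id; columns group, sex, origin

    @classmethod
    def from_groups(cls, sample_ids: Iterable[str], groups: Iterable[str]) -> "SampleTable":
        sample_ids = list(sample_ids)
        groups = list(groups)
        if len(sample_ids) != len(set(sample_ids)):
            raise DataModelError("duplicate sample_id in sample table")
        bad = sorted(set(groups) - set(GROUPS))
        if bad:
            raise DataModelError(f"unknown group label(s) {bad}")
        df = pd.DataFrame(
            {
                "group": groups,
                "sex": [GROUP_SEX[g] for g in groups],
                "origin": [GROUP_ORIGIN[g] for g in groups],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        return cls(df)

    @classmethod
    def read_tsv(cls, path) -> "SampleTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"sample_id", "group"}.issubset(df.columns):
            raise DataModelError("sample table needs sample_id and group columns")
        return cls.from_groups(df["sample_id"], df["group"])

    def write_tsv(self, path) -> None:
        self.table.reset_index()[["sample_id", "group"]].to_csv(path, sep="\t", index=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise DataModelError(f"samples absent from sample table: {missing}")


@dataclass
class CountMatrix:
    """Integer RNA-seq read counts, genes x samples."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise DataModelError(f"duplicate feature_id(s): {dups[:5]}")
        if (v.to_numpy() < 0).any():
            raise DataModelError("negative count encountered")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def fpkm(self, lengths_kb: pd.Series) -> pd.DataFrame:
        """Derived FPKM view; raw counts remain the testing substrate."""
        per_million = self.values.sum(axis=0) / 1e6
        return self.values.div(per_million, axis=1).div(lengths_kb, axis=0)


@dataclass
class IntensityMatrix:
    """Label-free protein intensities (NaN = missing), proteins x samples."""

    values: pd.DataFrame
    unique_peptides: pd.Series = field(default=None)  # type: ignore[assignment]
    is_contaminant: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise DataModelError(f"duplicate feature_id(s): {dups[:5]}")
        arr = v.to_numpy(dtype=float)
        present = ~np.isnan(arr)
        if (arr[present] <= 0).any():
            raise DataModelError(
                "intensities must be strictly positive where present "
                "(zero intensity is invalid, not missing)"
            )
        if self.unique_peptides is None:
            self.unique_peptides = pd.Series(2, index=v.index, name="unique_peptides")
        if self.is_contaminant is None:
            self.is_contaminant = pd.Series(False, index=v.index, name="is_contaminant")
        if (self.unique_peptides < 0).any():
            raise DataModelError("unique_peptides must be >= 0")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneProteinMap:
    """protein_id -> gene_id correspondence; unique on protein_id."""

    table: pd.DataFrame  # columns protein_id, gene_id

    def __post_init__(self) -> None:
        t = self.table
        conflicts = t.groupby("protein_id")["gene_id"].nunique()
        bad = conflicts[conflicts > 1].index.tolist()
        if bad:
            raise DataModelError(f"protein_id mapped to multiple gene_ids: {bad[:5]}")
        self.table = t.drop_duplicates().reset_index(drop=True)

    @property
    def n_proteins(self) -> int:
        return self.table["protein_id"].nunique()

    @property
    def n_genes(self) -> int:
        return self.table["gene_id"].nunique()

    def gene_for(self) -> pd.Series:
        return self.table.set_index("protein_id")["gene_id"]

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class AnnotationSet:
    """One functional term (GO namespace or KEGG pathway) and its member genes."""

    term_id: str
    term_name: str
    namespace: str  # BP, MF, CC or KEGG
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise DataModelError(f"term {self.term_id} has no members")

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = "feature_id"
    return df


def read_matrix(path, kind: str):
    """Read a features x samples TSV as a CountMatrix or IntensityMatrix.

    The first column holds feature ids and the header row holds sample ids.
    For intensities the optional trailing columns ``unique_peptides`` and
    ``is_contaminant`` are recognised; an empty cell or ``NA`` is missing.
    """
    if kind not in ("counts", "intensities"):
        raise DataModelError(f"unknown matrix kind {kind!r}")
    raw = _read_table(path)

    peptides = contaminant = None
    if kind == "intensities":
        if "unique_peptides" in raw.columns:
            peptides = raw.pop("unique_peptides").astype(int)
        if "is_contaminant" in raw.columns:
            contaminant = raw.pop("is_contaminant").map(
                {"True": True, "False": False, "1": True, "0": False}
            )
            if contaminant.isna().any():
                raise DataModelError("is_contaminant must be boolean")

    stripped = raw.apply(lambda s: s.str.strip())
    is_missing = stripped.apply(lambda s: s.str.lower().isin(MISSING_TOKENS))
    parsed = stripped.apply(pd.to_numeric, errors="coerce")
    bad = parsed.isna() & ~is_missing
    if bad.to_numpy().any():
        fid = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[fid]][0]
        raise DataModelError(
            f"non-numeric cell at feature {fid!r}, sample {col!r}: {raw.loc[fid, col]!r}"
        )
    if kind == "counts" and is_missing.to_numpy().any():
        fid = is_missing.index[is_missing.any(axis=1)][0]
        col = is_missing.columns[is_missing.loc[fid]][0]
        raise DataModelError(f"missing cell not allowed in counts: {fid!r}/{col!r}")

    if kind == "counts":
        arr = parsed.to_numpy()
        if np.isnan(arr).any():
            raise DataModelError("missing values not allowed in count matrices")
        if not np.allclose(arr, np.round(arr)):
            raise DataModelError("counts must be integers")
        m = CountMatrix(parsed.round().astype(int))
    else:
        m = IntensityMatrix(parsed, unique_peptides=peptides, is_contaminant=contaminant)
    logger.info("read %s matrix: %d features x %d samples", kind, *parsed.shape)
    return m


def write_matrix(matrix, path, float_format: str = "%.6g") -> None:
    """Write a matrix in the canonical TSV layout (feature rows sorted)."""
    df = matrix.values.sort_index()
    if isinstance(matrix, IntensityMatrix):
        df = df.copy()
        out = df.astype(object)
        for col in out.columns:
            out[col] = [
                "NA" if pd.isna(x) else float_format % x for x in df[col]
            ]
        out["unique_peptides"] = matrix.unique_peptides.reindex(df.index).astype(int)
        out["is_contaminant"] = matrix.is_contaminant.reindex(df.index)
        out.to_csv(path, sep="\t", index_label="feature_id")
    else:
        df.to_csv(path, sep="\t", index_label="feature_id")


def read_gene_protein_map(path) -> GeneProteinMap:
    """Read a two-column (protein_id, gene_id) TSV; header auto-detected."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, header=None, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.empty:
        warnings.warn("gene-protein map file is empty", stacklevel=2)
        return GeneProteinMap(pd.DataFrame(columns=["protein_id", "gene_id"]))
    if df.shape[1] < 2:
        raise DataModelError("gene-protein map needs two tab-separated columns")
    df = df.iloc[:, :2]
    df.columns = ["protein_id", "gene_id"]
    first = tuple(df.iloc[0])
    if first in {("protein_id", "gene_id"), ("protein", "gene")}:
        df = df.iloc[1:]
    if df.empty:
        warnings.warn("gene-protein map has a header but no records", stacklevel=2)
    return GeneProteinMap(df.reset_index(drop=True))


def read_annotations(path) -> dict[str, AnnotationSet]:
    """Read a GMT-style annotation file: term_id TAB term_name TAB member...

    The term name may carry a ``namespace=BP|MF|CC|KEGG`` suffix after a pipe
    (``name|BP``); otherwise the namespace defaults to BP. Duplicate members
    within a line are deduplicated; singleton terms are retained but flagged.
    """
    sets: dict[str, AnnotationSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataModelError(f"GMT line {lineno}: fewer than 3 fields")
            term_id, term_name = fields[0], fields[1]
            if term_id in sets:
                raise DataModelError(f"GMT line {lineno}: duplicate term_id {term_id!r}")
            namespace = "BP"
            if "|" in term_name:
                term_name, ns = term_name.rsplit("|", 1)
                if ns in ("BP", "MF", "CC", "KEGG"):
                    namespace = ns
            members = frozenset(f for f in fields[2:] if f)
            ann = AnnotationSet(term_id, term_name, namespace, members)
            if ann.is_singleton:
                logger.info("singleton term retained: %s", term_id)
            sets[term_id] = ann
    return sets


def write_annotations(sets: dict[str, AnnotationSet], path) -> None:
    with open(path, "w") as fh:
        for term in sets.values():
            name = f"{term.term_name}|{term.namespace}"
            fh.write("\t".join([term.term_id, name, *sorted(term.members)]) + "\n")


def validate_samples(matrix, samples: SampleTable) -> None:
    """Every matrix column must map to exactly one sample-table row."""
    samples.require_samples(matrix.sample_ids)
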