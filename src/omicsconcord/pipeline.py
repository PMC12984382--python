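"""End-to-end orchestration: simulate (or load) -> per-contrast RNA and
protein differential expression -> gene-protein integration -> dual-omics
enrichment -> differential methylation -> exploratory views, with a
deterministic JSON manifest (file hashes, seed, per-stage summaries)."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    Contrast,
    SampleTable,
    canonical_contrasts,
    read_annotations,
    read_gene_protein_map,
    read_matrix,
)
from .de_protein import run_de_protein
from .de_rna import run_de_rna
from .enrichment import (
    concordant_terms,
    ordered_query_enrichment,
    rank_features,
    results_frame,
)
from .exploratory import pca
from .integration import build_pairs, summarize_concordance
from .methylation import MethylationTable, read_bed12, read_gff3, run_methylation
from .synthetic_data import SimConfig, simulate_all, simulate_annotations

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat configuration; every field has a CLI flag override."""

    outdir: str = "results/pipeline"
    seed: int = 1
    contrasts: list = field(default_factory=lambda: [c.name for c in canonical_contrasts()])
    rna_lfc: float = 1.0
    rna_fdr: float = 0.05
    prot_lfc: float = 0.5
    prot_fdr: float = 0.05
    meth_fdr: float = 0.01
    enrichment_alpha: float = 0.05
    simulate: dict | None = None  # SimConfig overrides; None = real-data mode
    inputs: dict | None = None  # paths: counts, samples, intensities, map, gmt, methylation, gff
    run_enrichment: bool = True
    run_methylation: bool = True

    def __post_init__(self) -> None:
        for name in ("rna_lfc", "rna_fdr", "prot_lfc", "prot_fdr", "meth_fdr", "enrichment_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.contrast_objs = [Contrast.parse(c) for c in self.contrasts]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(cfg: PipelineConfig) -> dict:
    if cfg.simulate is not None:
        sim_cfg = SimConfig(**{**cfg.simulate, "rng_seed": cfg.seed})
        data = simulate_all(sim_cfg)
        data["annotations"] = simulate_annotations(sim_cfg)
        data["transcripts"] = None
        return data
    paths = cfg.inputs or {}
    counts = read_matrix(paths["counts"], "counts")
    samples = SampleTable.read_tsv(paths["samples"])
    data = {
        "counts": counts,
        "rna_samples": samples,
        "intensities": read_matrix(paths["intensities"], "intensities"),
        "prot_samples": samples,
        "gene_protein_map": read_gene_protein_map(paths["map"]),
        "truth": None,
        "annotations": read_annotations(paths["gmt"]) if "gmt" in paths else None,
        "methylation": (
            MethylationTable.read_tsv(paths["methylation"]) if "methylation" in paths else None
        ),
        "meth_samples": samples,
        "transcripts": None,
    }
    if "gff" in paths:
        data["transcripts"] = read_gff3(paths["gff"])
    elif "bed" in paths:
        data["transcripts"] = read_bed12(paths["bed"])
    return data


def _enrich_layer(results, universe, terms, layer, alpha, de_count):
    out = {}
    for direction in ("UP", "DOWN"):
        ranked = rank_features(results, direction)
        out[direction] = ordered_query_enrichment(
            ranked, universe, terms, direction=direction, layer=layer,
            de_prefix=de_count if de_count else None,
        )
    return out


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage and write outputs + manifest under cfg.outdir.

    Returns the manifest dictionary. Any stage failure aborts with the
    stage name; the partial manifest is still written.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "contrasts": list(cfg.contrasts),
        "stages": {},
        "files": {},
    }
    stage = "load"
    try:
        data = _stage(manifest, stage, lambda: _load_inputs(cfg))
        gene_for = data["gene_protein_map"].gene_for()

        degs, deps, pair_frames = {}, {}, {}
        stage = "de_rna"

        def _de_rna():
            return {
                c.name: run_de_rna(
                    data["counts"], data["rna_samples"], c, cfg.rna_lfc, cfg.rna_fdr
                )
                for c in cfg.contrast_objs
            }

        degs = _stage(manifest, stage, _de_rna)
        manifest["stages"]["de_rna"]["deg_counts"] = {
            name: int((df["status"] != "NS").sum()) for name, df in degs.items()
        }

        stage = "de_protein"

        def _de_prot():
            out = {}
            for c in cfg.contrast_objs:
                res, report = run_de_protein(
                    data["intensities"], data["prot_samples"], c, cfg.prot_lfc, cfg.prot_fdr
                )
                out[c.name] = (res, report)
            return out

        dep_pairs = _stage(manifest, stage, _de_prot)
        deps = {k: v[0] for k, v in dep_pairs.items()}
        manifest["stages"]["de_protein"]["dep_counts"] = {
            name: int((df["status"] != "NS").sum()) for name, df in deps.items()
        }
        manifest["stages"]["de_protein"]["filter_report"] = next(
            iter(dep_pairs.values())
        )[1].as_dict()

        stage = "integration"

        def _integrate():
            out = {}
            for c in cfg.contrast_objs:
                pairs = build_pairs(degs[c.name], deps[c.name], data["gene_protein_map"], c)
                out[c.name] = pairs
            return out

        pair_frames = _stage(manifest, stage, _integrate)
        manifest["stages"]["integration"]["concordance"] = {
            name: summarize_concordance(pf).as_dict() for name, pf in pair_frames.items()
        }

        if cfg.run_enrichment and data.get("annotations"):
            stage = "enrichment"

            def _enrich():
                out = {}
                terms = data["annotations"]
                for c in cfg.contrast_objs:
                    deg = degs[c.name]
                    rna_universe = set(deg.index)
                    rna_res = _enrich_layer(
                        deg, rna_universe, terms, "RNA", cfg.enrichment_alpha,
                        int((deg["status"] != "NS").sum()),
                    )
                    dep = deps[c.name].copy()
                    dep["gene_id"] = [gene_for.get(p) for p in dep.index]
                    dep = dep.dropna(subset=["gene_id"])
                    # one gene per ranked slot: keep the most extreme protein
                    dep = dep.reindex(dep["log2fc"].abs().sort_values(ascending=False).index)
                    dep = dep.drop_duplicates("gene_id").set_index("gene_id")
                    prot_universe = set(dep.index)
                    prot_res = _enrich_layer(
                        dep, prot_universe, terms, "PROT", cfg.enrichment_alpha,
                        int((dep["status"] != "NS").sum()),
                    )
                    conc = concordant_terms(
                        rna_res["UP"] + rna_res["DOWN"],
                        prot_res["UP"] + prot_res["DOWN"],
                        cfg.enrichment_alpha,
                    )
                    out[c.name] = {"rna": rna_res, "prot": prot_res, "concordant": conc}
                return out

            enr = _stage(manifest, stage, _enrich)
            manifest["stages"]["enrichment"]["concordant_terms"] = {
                name: v["concordant"] for name, v in enr.items()
            }
        else:
            enr = {}

        if cfg.run_methylation and data.get("methylation") is not None:
            stage = "methylation"

            def _meth():
                out = {}
                for c in cfg.contrast_objs:
                    out[c.name] = run_methylation(
                        data["methylation"], c, data["meth_samples"], data.get("transcripts")
                    )
                return out

            dms = _stage(manifest, stage, _meth)
            manifest["stages"]["methylation"]["dm_counts"] = {
                name: int(df["is_dm"].sum()) for name, df in dms.items()
            }
        else:
            dms = {}

        stage = "exploratory"

        def _explore():
            mapped = [g for g in set(gene_for.values) if g in data["counts"].values.index]
            rna_pca = pca(data["counts"].values.loc[sorted(mapped)], log_mode=True)
            complete = data["intensities"].values.dropna()
            prot_pca = pca(np.log2(complete)) if len(complete) >= 2 else None
            return rna_pca, prot_pca

        rna_pca, prot_pca = _stage(manifest, stage, _explore)
        manifest["stages"]["exploratory"]["rna_pca_variance_pct"] = [
            round(float(v), 4) for v in rna_pca.variance_explained_pct[:2]
        ]
        if prot_pca is not None:
            manifest["stages"]["exploratory"]["prot_pca_variance_pct"] = [
                round(float(v), 4) for v in prot_pca.variance_explained_pct[:2]
            ]

        # ------------------------------------------------------------------
        stage = "write"
        for name, df in degs.items():
            df.to_csv(outdir / f"degs_{name}.tsv", sep="\t")
        for name, df in deps.items():
            df.to_csv(outdir / f"deps_{name}.tsv", sep="\t")
        for name, pf in pair_frames.items():
            pf.to_csv(outdir / f"pairs_{name}.tsv", sep="\t", index=False)
        for name, df in dms.items():
            df.to_csv(outdir / f"dm_{name}.tsv", sep="\t", index=False)
        for name, v in enr.items():
            for layer in ("rna", "prot"):
                for direction, results in v[layer].items():
                    results_frame(results).to_csv(
                        outdir / f"enrichment_{name}_{layer}_{direction}.tsv",
                        sep="\t",
                        index=False,
                    )
        rna_pca.scores.round(6).to_csv(outdir / "pca_rna_scores.tsv", sep="\t")
        if prot_pca is not None:
            prot_pca.scores.round(6).to_csv(outdir / "pca_prot_scores.tsv", sep="\t")

        for f in sorted(outdir.glob("*.tsv")):
            manifest["files"][f.name] = _sha256(f)
        manifest["status"] = "complete"
    except Exception as exc:  # partial manifest aids debugging
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage(manifest: dict, name: str, fn):
    t0 = time.perf_counter()
    result = fn()
    elapsed = time.perf_counter() - t0
    logger.info("stage=%s elapsed=%.2fs", name, elapsed)
    manifest["stages"][name] = {}
    return result
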