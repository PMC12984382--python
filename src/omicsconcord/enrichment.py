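"""Functional enrichment: classical over-representation and a rank-based
ordered-query scheme over log2FC-ordered feature lists.

The ordered-query scheme evaluates each term's hypergeometric tail at a
grid of list prefixes (10, 20, ..., up to 1000, plus the DE-threshold
prefix when supplied), takes the best prefix, and pays for the search with
a Bonferroni factor over the number of prefixes examined; BH is then
applied across terms within each namespace. UP and DOWN analyses run on the
descending and ascending orderings respectively.

The enrichment universe is the set of features tested in the relevant
layer and contrast - not the genome - to avoid spurious enrichment from
detection bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AnnotationSet
from .de_rna import benjamini_hochberg

PREFIX_STEP = 10
PREFIX_MAX = 1000


def hypergeometric_pvalue(k: int, n_universe: int, n_term: int, n_query: int) -> float:
    """Upper-tail P(X >= k) drawing n_query from a universe with n_term
    successes. k = 0 gives p = 1 under the k >= 0 convention."""
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, n_universe, n_term, n_query))


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    namespace: str
    direction: str  # UP or DOWN
    layer: str  # RNA or PROT
    count: int
    rich_factor: float
    pvalue: float
    adjusted_p: float = float("nan")


def _bh_within_namespace(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    by_ns: dict[str, list[EnrichmentResult]] = {}
    for r in results:
        by_ns.setdefault(r.namespace, []).append(r)
    for rs in by_ns.values():
        adj = benjamini_hochberg([r.pvalue for r in rs])
        for r, q in zip(rs, adj):
            r.adjusted_p = float(q)
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def hypergeometric_ora(
    query: set,
    universe: set,
    terms: dict[str, AnnotationSet],
    direction: str = "UP",
    layer: str = "RNA",
) -> list[EnrichmentResult]:
    """Classical over-representation by the upper hypergeometric tail.

    Term member sets are intersected with the universe; the query must be a
    subset of the universe.
    """
    if not query:
        return []
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    n_universe = len(universe)
    n_query = len(query)
    results = []
    for term in terms.values():
        members = term.members & universe
        if not members:
            continue
        k = len(query & members)
        p = hypergeometric_pvalue(k, n_universe, len(members), n_query)
        results.append(
            EnrichmentResult(
                term.term_id,
                term.term_name,
                term.namespace,
                direction,
                layer,
                count=k,
                rich_factor=k / len(members) if members else 0.0,
                pvalue=p,
            )
        )
    return _bh_within_namespace(results)


def prefix_grid(list_len: int, extra: int | None = None) -> list[int]:
    """Prefix cutoffs: 10, 20, ... up to min(list_len, 1000), plus the
    DE-threshold prefix when given; a list shorter than 10 uses itself."""
    top = min(list_len, PREFIX_MAX)
    grid = list(range(PREFIX_STEP, top + 1, PREFIX_STEP))
    if not grid:
        grid = [list_len]
    if extra is not None and 0 < extra <= list_len and extra not in grid:
        grid.append(extra)
    return sorted(set(grid))


def ordered_query_enrichment(
    ranked: list,
    universe: set,
    terms: dict[str, AnnotationSet],
    direction: str = "UP",
    layer: str = "RNA",
    de_prefix: int | None = None,
) -> list[EnrichmentResult]:
    """Rank-based enrichment over a log2FC-ordered feature list.

    ``ranked`` must already be ordered for the requested direction
    (descending log2FC for UP, ascending for DOWN) and be deduplicated.
    Per term: min over prefix cutoffs of the hypergeometric tail, times the
    number of cutoffs (Bonferroni over the prefix search), clipped at 1;
    count and rich factor are reported at the argmin prefix.
    """
    if len(ranked) != len(set(ranked)):
        raise ValueError("ranked list must be deduplicated")
    if not set(ranked) <= universe:
        raise ValueError("ranked list must be drawn from the universe")
    if not ranked:
        return []

    grid = prefix_grid(len(ranked), extra=de_prefix)
    n_universe = len(universe)
    n_grid = len(grid)
    rank_of = {f: i for i, f in enumerate(ranked)}

    results = []
    for term in terms.values():
        members = term.members & universe
        if not members:
            continue
        n_term = len(members)
        member_ranks = np.sort([rank_of[f] for f in members if f in rank_of])
        best_p, best_k, best_len = 1.0, 0, grid[0]
        for cutoff in grid:
            k = int(np.searchsorted(member_ranks, cutoff, side="left"))
            p = hypergeometric_pvalue(k, n_universe, n_term, cutoff)
            if p < best_p:
                best_p, best_k, best_len = p, k, cutoff
        results.append(
            EnrichmentResult(
                term.term_id,
                term.term_name,
                term.namespace,
                direction,
                layer,
                count=best_k,
                rich_factor=best_k / n_term,
                pvalue=min(1.0, best_p * n_grid),
            )
        )
    return _bh_within_namespace(results)


def rank_features(results: pd.DataFrame, direction: str) -> list:
    """Order tested features by log2FC: descending for UP, ascending DOWN.
    Ties break by feature id so orderings are deterministic."""
    ascending = direction == "DOWN"
    df = results.sort_index().sort_values("log2fc", ascending=ascending, kind="mergesort")
    return list(df.index)


def concordant_terms(
    rna: list[EnrichmentResult], prot: list[EnrichmentResult], alpha: float = 0.05
) -> dict[str, list[str]]:
    """Terms significant in the same direction at both layers.

    Returns {"UP": [...term ids...], "DOWN": [...]}.
    """
    def sig(results):
        return {
            (r.term_id, r.direction) for r in results if r.adjusted_p < alpha
        }

    both = sig(rna) & sig(prot)
    return {
        "UP": sorted(t for t, d in both if d == "UP"),
        "DOWN": sorted(t for t, d in both if d == "DOWN"),
    }
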