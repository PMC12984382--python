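"""Shared fixtures: small synthetic configurations and canonical tables."""

import numpy as np
import pandas as pd
import pytest

from omicsconcord.data_model import CountMatrix, IntensityMatrix, SampleTable
from omicsconcord.synthetic_data import SimConfig


@pytest.fixture
def small_cfg() -> SimConfig:
    """A scaled-down study design that keeps every stage fast."""
    return SimConfig(
        n_genes=400,
        n_mapped_proteins=120,
        n_cpgs=300,
        rng_seed=7,
    )


@pytest.fixture
def two_group_samples() -> SampleTable:
    ids = [f"F1F{i}" for i in range(5)] + [f"F1M{i}" for i in range(5)]
    return SampleTable.from_groups(ids, ["F1F"] * 5 + ["F1M"] * 5)


def nb_counts(rng, mu, dispersion, n_reps):
    """Negative-binomial draws, genes x replicates, around per-gene means."""
    mu = np.asarray(mu, dtype=float)
    if dispersion == 0:
        return rng.poisson(mu[:, None], size=(len(mu), n_reps))
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mu[:, None]), size=(len(mu), n_reps))


def count_matrix(values, sample_ids=None, gene_ids=None) -> CountMatrix:
    values = np.asarray(values)
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    gene_ids = gene_ids or [f"G{i}" for i in range(values.shape[0])]
    return CountMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))


def intensity_matrix(values, sample_ids=None, protein_ids=None, **kw) -> IntensityMatrix:
    values = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    protein_ids = protein_ids or [f"P{i}" for i in range(values.shape[0])]
    return IntensityMatrix(
        pd.DataFrame(values, index=protein_ids, columns=sample_ids), **kw
    )
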