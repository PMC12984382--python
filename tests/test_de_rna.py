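"""NB Wald RNA differential expression: BH, size factors, dispersion, Wald."""

import numpy as np
import pandas as pd
import pytest

from omicsconcord.data_model import Contrast, SampleTable
from omicsconcord.de_rna import (
    DEError,
    benjamini_hochberg,
    estimate_dispersion,
    nb_wald_contrast,
    run_de_rna,
    size_factors_median_of_ratios,
)

from conftest import count_matrix, nb_counts


def bh_bruteforce(p):
    """Independent step-up oracle: q_i = min over j with p_(j) >= p_i of
    min_{l >= j} p_(l) * m / l, computed by direct double loop."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos in range(m):
        i = order[rank_pos]
        best = 1.0
        for later in range(rank_pos, m):
            j = order[later]
            best = min(best, p[j] * m / (later + 1))
        q[i] = best
    return q


class TestBenjaminiHochberg:
    def test_single_pvalue_unchanged(self):
        assert benjamini_hochberg([0.03])[0] == pytest.approx(0.03)

    def test_uniform_grid_all_collapse_to_max(self):
        # p = (0.01, 0.02, ..., 0.05): p_(i) * 5/i = 0.05 for every i
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(q, 0.05)

    def test_all_ones(self):
        assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_order_preserved(self):
        p = np.array([0.9, 0.001, 0.5])
        q = benjamini_hochberg(p)
        assert q[1] == q.min()

    def test_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(1, 40))
            p = rng.uniform(size=n)
            if rng.random() < 0.3:  # inject ties
                p = np.round(p, 1)
            assert np.allclose(benjamini_hochberg(p), bh_bruteforce(p), atol=1e-12)

    def test_rejects_nan_and_out_of_range(self):
        with pytest.raises(DEError):
            benjamini_hochberg([0.1, np.nan])
        with pytest.raises(DEError):
            benjamini_hochberg([-0.1])
        with pytest.raises(DEError):
            benjamini_hochberg([1.1])

    def test_empty_input(self):
        assert benjamini_hochberg([]).size == 0


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = count_matrix([[10, 10], [4, 4], [7, 7]])
        assert np.allclose(size_factors_median_of_ratios(cm), 1.0)

    def test_doubled_sample(self):
        # every gene doubled in s1: factors (2^-1/2, 2^1/2) after geomean-1
        cm = count_matrix([[4, 8], [10, 20], [6, 12]])
        sf = size_factors_median_of_ratios(cm)
        assert np.allclose(sf, [2 ** -0.5, 2 ** 0.5])

    def test_three_sample_hand_example(self):
        # columns proportional to (1, 2, 1) -> factors (2^-1/3, 2^2/3, 2^-1/3)
        cm = count_matrix([[10, 20, 10], [4, 8, 4], [6, 12, 6], [8, 16, 8]])
        sf = size_factors_median_of_ratios(cm)
        assert np.allclose(sf, [2 ** (-1 / 3), 2 ** (2 / 3), 2 ** (-1 / 3)])
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0)

    def test_no_all_positive_gene_is_an_error(self):
        cm = count_matrix([[0, 5], [5, 0]])
        with pytest.raises(DEError, match="positive counts in every sample"):
            size_factors_median_of_ratios(cm)

    def test_single_sample_rejected(self):
        cm = count_matrix([[5], [3]])
        with pytest.raises(DEError, match="two samples"):
            size_factors_median_of_ratios(cm)


class TestDispersion:
    def _table(self, n):
        ids = [f"F1F{i}" for i in range(n)]
        return SampleTable.from_groups(ids, ["F1F"] * n)

    def test_poisson_data_near_zero_dispersion(self):
        rng = np.random.default_rng(42)
        mu = np.exp2(rng.uniform(2, 10, 2000))
        cm = count_matrix(rng.poisson(mu[:, None], size=(2000, 10)),
                          sample_ids=[f"F1F{i}" for i in range(10)])
        st = self._table(10)
        d = estimate_dispersion(cm, size_factors_median_of_ratios(cm), st)
        assert np.median(d.final) <= 0.05

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(42)
        mu = np.exp2(rng.uniform(2, 10, 2000))
        cm = count_matrix(nb_counts(rng, mu, 0.4, 10),
                          sample_ids=[f"F1F{i}" for i in range(10)])
        st = self._table(10)
        d = estimate_dispersion(cm, size_factors_median_of_ratios(cm), st)
        assert 0.3 <= np.median(d.final) <= 0.5

    def test_constant_gene_pulled_to_trend(self):
        rng = np.random.default_rng(1)
        mu = np.full(200, 100.0)
        counts = nb_counts(rng, mu, 0.2, 6)
        counts[0] = 50  # zero within-group variance
        cm = count_matrix(counts, sample_ids=[f"F1F{i}" for i in range(6)])
        st = self._table(6)
        d = estimate_dispersion(cm, size_factors_median_of_ratios(cm), st)
        assert d.raw.iloc[0] == 0.0
        assert d.final.iloc[0] == pytest.approx(d.trend.iloc[0])

    def test_variance_pooled_within_groups_not_across(self):
        # two groups with a huge mean shift but no within-group noise:
        # pooling across groups would report a large dispersion
        ids = [f"F1F{i}" for i in range(3)] + [f"F1M{i}" for i in range(3)]
        st = SampleTable.from_groups(ids, ["F1F"] * 3 + ["F1M"] * 3)
        cm = count_matrix(
            np.array([[100, 100, 100, 1000, 1000, 1000]] * 50), sample_ids=ids
        )
        d = estimate_dispersion(cm, pd.Series(1.0, index=ids), st)
        assert (d.raw == 0).all()

    def test_single_replicate_everywhere_is_an_error(self):
        ids = ["F1F1", "F1M1"]
        st = SampleTable.from_groups(ids, ["F1F", "F1M"])
        cm = count_matrix([[5, 9], [2, 3]], sample_ids=ids)
        with pytest.raises(DEError, match="replicates"):
            estimate_dispersion(cm, pd.Series(1.0, index=ids), st)


class TestNBWald:
    def _fixture(self, seed=5, n=2000, alpha=0.2, lfc=3.0, frac=0.1, reps=5):
        rng = np.random.default_rng(seed)
        mu0 = np.exp2(rng.uniform(2, 10, n))
        true_lfc = np.zeros(n)
        de_idx = rng.choice(n, int(frac * n), replace=False)
        true_lfc[de_idx] = rng.choice([-lfc, lfc], size=len(de_idx))
        ids = [f"F1F{i}" for i in range(reps)] + [f"F1M{i}" for i in range(reps)]
        st = SampleTable.from_groups(ids, ["F1F"] * reps + ["F1M"] * reps)
        muA = mu0 * np.exp2(true_lfc / 2)
        muB = mu0 * np.exp2(-true_lfc / 2)
        counts = np.hstack(
            [nb_counts(rng, muA, alpha, reps), nb_counts(rng, muB, alpha, reps)]
        )
        cm = count_matrix(counts, sample_ids=ids)
        return cm, st, pd.Series(true_lfc, index=cm.values.index)

    def test_exact_twofold_counts_give_lfc_one(self):
        ids = ["F1F1", "F1F2", "F1M1", "F1M2"]
        st = SampleTable.from_groups(ids, ["F1F", "F1F", "F1M", "F1M"])
        base = np.array([100, 400, 50, 800, 220])
        counts = np.column_stack([2 * base, 2 * base, base, base])
        cm = count_matrix(counts, sample_ids=ids)
        sf = pd.Series(1.0, index=ids)
        disp = estimate_dispersion(cm, sf, st)
        res = nb_wald_contrast(cm, sf, disp, Contrast("F1F", "F1M"), st)
        assert np.allclose(res["log2fc"], 1.0, atol=1e-6)

    def test_scale_invariance_of_log2fc(self):
        cm, st, _ = self._fixture(seed=3, n=200)
        c = Contrast("F1F", "F1M")
        res1 = run_de_rna(cm, st, c)
        cm2 = count_matrix(cm.values.to_numpy() * 2, sample_ids=cm.sample_ids)
        res2 = run_de_rna(cm2, st, c)
        # doubling all counts only tightens precision; effect sizes agree
        assert np.corrcoef(res1["log2fc"], res2["log2fc"])[0, 1] > 0.99

    def test_all_zero_genes_excluded_from_family(self):
        ids = ["F1F1", "F1F2", "F1M1", "F1M2"]
        st = SampleTable.from_groups(ids, ["F1F", "F1F", "F1M", "F1M"])
        counts = np.array([[5, 6, 7, 8], [0, 0, 0, 0], [9, 9, 9, 9]])
        cm = count_matrix(counts, sample_ids=ids)
        res = run_de_rna(cm, st, Contrast("F1F", "F1M"))
        assert "G1" not in res.index
        assert len(res) == 2

    def test_status_consistent_with_thresholds(self):
        cm, st, _ = self._fixture(seed=9, n=500)
        res = run_de_rna(cm, st, Contrast("F1F", "F1M"))
        up = res["status"] == "UP"
        down = res["status"] == "DOWN"
        assert (res.loc[up, "log2fc"] >= 1.0).all()
        assert (res.loc[up, "fdr"] < 0.05).all()
        assert (res.loc[down, "log2fc"] <= -1.0).all()
        assert (res.loc[down, "fdr"] < 0.05).all()
        ns = res["status"] == "NS"
        assert ((res.loc[ns, "log2fc"].abs() < 1.0) | (res.loc[ns, "fdr"] >= 0.05)).all()

    def test_contrast_sign_convention(self):
        # numerator higher -> positive log2FC
        cm, st, truth = self._fixture(seed=21, n=400, lfc=4.0)
        res = run_de_rna(cm, st, Contrast("F1F", "F1M"))
        strong_up = truth[truth > 0].index
        assert (res.loc[strong_up, "log2fc"] > 0).all()

    def test_too_few_replicates_rejected(self):
        ids = ["F1F1", "F1M1", "F1M2"]
        st = SampleTable.from_groups(ids, ["F1F", "F1M", "F1M"])
        cm = count_matrix([[5, 6, 7], [8, 9, 10]], sample_ids=ids)
        sf = pd.Series(1.0, index=ids)
        disp_st = SampleTable.from_groups(ids, ["F1F", "F1M", "F1M"])
        disp = estimate_dispersion(cm, sf, disp_st)
        with pytest.raises(DEError, match=">=2 samples"):
            nb_wald_contrast(cm, sf, disp, Contrast("F1F", "F1M"), st)

    def test_planted_recovery_sensitivity_and_fdr(self):
        cm, st, truth = self._fixture(seed=5)
        res = run_de_rna(cm, st, Contrast("F1F", "F1M"))
        called = res.index[res["status"] != "NS"]
        truly_de = set(truth.index[truth != 0])
        sensitivity = len(set(called) & truly_de) / len(truly_de)
        empirical_fdr = len(set(called) - truly_de) / max(len(called), 1)
        assert sensitivity >= 0.7
        assert empirical_fdr <= 0.10
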