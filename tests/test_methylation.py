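"""CpG filtering, pooled Fisher differential methylation, feature contexts."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from omicsconcord.data_model import Contrast, DataModelError, SampleTable
from omicsconcord.methylation import (
    FEATURE_PRECEDENCE,
    MethylationTable,
    Transcript,
    annotate_context,
    dm_test,
    filter_cpgs,
    read_bed12,
    read_gff3,
    run_methylation,
)


def fisher_two_sided_bruteforce(a, b, c, d):
    """Exact two-sided Fisher p by enumerating all tables with the observed
    margins and summing probabilities <= the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # x = top-left cell
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def make_table(meth, total, sample_ids, pos=None):
    meth = np.atleast_2d(meth)
    total = np.atleast_2d(total)
    n = meth.shape[0]
    sites = pd.DataFrame({
        "chrom": ["chr1"] * n,
        "pos": pos if pos is not None else np.arange(1, n + 1) * 100,
        "strand": ["+"] * n,
    })
    return MethylationTable(
        sites,
        pd.DataFrame(meth, columns=sample_ids),
        pd.DataFrame(total, columns=sample_ids),
    )


@pytest.fixture
def samples_2x3():
    ids = ["F1F1", "F1F2", "F1F3", "F1M1", "F1M2", "F1M3"]
    return ids, SampleTable.from_groups(ids, ["F1F"] * 3 + ["F1M"] * 3)


class TestMethylationTable:
    def test_meth_exceeding_total_rejected(self):
        with pytest.raises(DataModelError, match="methylated"):
            make_table([[5]], [[4]], ["s1"])

    def test_duplicate_position_rejected(self):
        with pytest.raises(DataModelError, match="duplicate"):
            make_table([[1], [1]], [[5], [5]], ["s1"], pos=[100, 100])

    def test_tsv_roundtrip(self, tmp_path, samples_2x3):
        ids, _ = samples_2x3
        mt = make_table(
            np.arange(12).reshape(2, 6), np.full((2, 6), 20), ids
        )
        p = tmp_path / "meth.tsv"
        mt.write_tsv(p)
        back = MethylationTable.read_tsv(p)
        pd.testing.assert_frame_equal(back.meth, mt.meth)
        pd.testing.assert_frame_equal(back.total, mt.total)
        pd.testing.assert_frame_equal(back.sites, mt.sites)


class TestFilterCpGs:
    def test_coverage_exactly_eight_removed(self, samples_2x3):
        ids, st = samples_2x3
        total = np.full((3, 6), 20)
        total[0, 2] = 8   # boundary: > 8 is required, so 8 fails
        total[1, 4] = 9   # passes
        meth = np.full((3, 6), 5)
        mt = make_table(meth, total, ids)
        kept = filter_cpgs(mt, Contrast("F1F", "F1M"), st)
        assert list(kept.sites["pos"]) == [200, 300]

    def test_fully_methylated_or_unmethylated_removed(self, samples_2x3):
        ids, st = samples_2x3
        total = np.full((3, 6), 20)
        meth = np.array([
            [20] * 6,  # pooled proportion 1 -> removed
            [0] * 6,   # pooled proportion 0 -> removed
            [10] * 6,
        ])
        mt = make_table(meth, total, ids)
        kept = filter_cpgs(mt, Contrast("F1F", "F1M"), st)
        assert list(kept.sites["pos"]) == [300]

    def test_only_contrast_samples_considered(self):
        ids = ["F1F1", "F1F2", "F1M1", "F1M2", "wtF1", "wtF2"]
        st = SampleTable.from_groups(ids, ["F1F"] * 2 + ["F1M"] * 2 + ["wtF"] * 2)
        total = np.full((1, 6), 20)
        total[0, 4] = 3  # low coverage only in wtF, outside the contrast
        mt = make_table([[10, 10, 10, 10, 2, 10]], total, ids)
        kept = filter_cpgs(mt, Contrast("F1F", "F1M"), st)
        assert len(kept.sites) == 1


class TestDMTest:
    def test_identical_groups_give_p_one_delta_zero(self, samples_2x3):
        ids, st = samples_2x3
        mt = make_table([[10] * 6], [[20] * 6], ids)
        res = dm_test(mt, Contrast("F1F", "F1M"), st)
        assert res["pvalue"].iloc[0] == pytest.approx(1.0)
        assert res["delta"].iloc[0] == pytest.approx(0.0)
        assert not res["is_dm"].iloc[0]

    def test_strong_difference_2x2_oracle(self, samples_2x3):
        ids, st = samples_2x3
        # pooled table (90, 10; 10, 90)
        mt = make_table([[30, 30, 30, 4, 3, 3]],
                        [[34, 33, 33, 34, 33, 33]], ids)
        res = dm_test(mt, Contrast("F1F", "F1M"), st)
        expected = fisher_two_sided_bruteforce(90, 10, 10, 90)
        assert res["pvalue"].iloc[0] == pytest.approx(expected, rel=1e-9)
        assert res["delta"].iloc[0] == pytest.approx(0.8)
        assert res["log2_ratio"].iloc[0] == pytest.approx(np.log2(0.9 / 0.1))

    def test_matches_bruteforce_on_random_tables(self, samples_2x3):
        ids, st = samples_2x3
        rng = np.random.default_rng(6)
        rows_m, rows_t, oracles = [], [], []
        for _ in range(100):
            # pooled totals per group <= 30 so the margin sum stays <= 60
            t1 = int(rng.integers(3, 31))
            t2 = int(rng.integers(3, 31))
            m1 = int(rng.integers(0, t1 + 1))
            m2 = int(rng.integers(0, t2 + 1))
            if min(m1 + m2, (t1 - m1) + (t2 - m2)) == 0:
                continue  # degenerate margin; covered by its own test
            # split the pooled counts over 3 replicates per group; allocate
            # methylated reads greedily so every cell keeps m <= t
            def split(m, t):
                a = t // 3
                tt = [a, a, t - 2 * a]
                mm, rest = [], m
                for cell in tt:
                    take = min(rest, cell)
                    mm.append(take)
                    rest -= take
                return mm, tt
            sm1, st1 = split(m1, t1)
            sm2, st2 = split(m2, t2)
            rows_m.append(sm1 + sm2)
            rows_t.append(st1 + st2)
            oracles.append(fisher_two_sided_bruteforce(m1, t1 - m1, m2, t2 - m2))
        mt = make_table(np.array(rows_m), np.array(rows_t), ids)
        res = dm_test(mt, Contrast("F1F", "F1M"), st)
        assert np.allclose(res["pvalue"], oracles, rtol=1e-9)

    def test_degenerate_margin_p_one(self, samples_2x3):
        ids, st = samples_2x3
        mt = make_table([[0] * 6], [[20] * 6], ids)  # no methylated reads at all
        res = dm_test(mt, Contrast("F1F", "F1M"), st)
        assert res["pvalue"].iloc[0] == 1.0

    def test_log2_ratio_clamped_for_extreme_proportions(self, samples_2x3):
        ids, st = samples_2x3
        mt = make_table([[20, 20, 20, 0, 0, 0]], [[20] * 6], ids)
        res = dm_test(mt, Contrast("F1F", "F1M"), st)
        assert np.isfinite(res["log2_ratio"].iloc[0])
        assert res["log2_ratio"].iloc[0] > 0


class TestGeneModels:
    GFF = (
        "##gff-version 3\n"
        "chr1\tsrc\tmRNA\t10000\t12000\t.\t+\t.\tID=tx1;Name=gene1\n"
        "chr1\tsrc\texon\t10000\t10400\t.\t+\t.\tParent=tx1\n"
        "chr1\tsrc\texon\t11000\t11300\t.\t+\t.\tParent=tx1\n"
        "chr1\tsrc\texon\t11800\t12000\t.\t+\t.\tParent=tx1\n"
        "chr1\tsrc\tmRNA\t30000\t32000\t.\t-\t.\tID=tx2\n"
        "chr1\tsrc\texon\t30000\t30500\t.\t-\t.\tParent=tx2\n"
        "chr1\tsrc\texon\t31500\t32000\t.\t-\t.\tParent=tx2\n"
    )

    def test_read_gff3(self, tmp_path):
        p = tmp_path / "model.gff3"
        p.write_text(self.GFF)
        txs = {t.transcript_id: t for t in read_gff3(p)}
        assert txs["tx1"].tss == 10000
        assert txs["tx2"].tss == 32000  # minus strand: TSS at the end
        assert len(txs["tx1"].exons) == 3

    def test_promoter_window_orientation(self):
        plus = Transcript("a", "chr1", 10000, 12000, "+")
        assert plus.promoter() == (8000, 10500)
        minus = Transcript("b", "chr1", 30000, 32000, "-")
        assert minus.promoter() == (31500, 34000)

    def test_first_intron_is_five_prime_most(self):
        plus = Transcript("a", "chr1", 100, 1000, "+",
                          exons=[(100, 200), (400, 500), (800, 1000)])
        introns = plus.introns()
        assert introns[0] == (201, 399, True)
        assert introns[1] == (501, 799, False)
        minus = Transcript("b", "chr1", 100, 1000, "-",
                           exons=[(100, 200), (400, 500), (800, 1000)])
        assert [(s, e, f) for s, e, f in minus.introns()] == [
            (201, 399, False), (501, 799, True)
        ]

    def test_read_bed12_coordinates(self, tmp_path):
        p = tmp_path / "model.bed"
        # 0-based half-open [99, 1000) with two exons
        p.write_text(
            "chr1\t99\t1000\ttxA\t0\t+\t99\t1000\t0\t2\t101,200\t0,701\n"
        )
        tx = read_bed12(p)[0]
        assert (tx.start, tx.end) == (100, 1000)
        assert tx.exons == [(100, 200), (801, 1000)]

    def test_gff_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("chr1\tsrc\tmRNA\t1\t10\n")
        with pytest.raises(DataModelError, match="9 columns"):
            read_gff3(p)


class TestAnnotateContext:
    def _dm(self, positions, chrom="chr1"):
        return pd.DataFrame({
            "chrom": [chrom] * len(positions),
            "pos": positions,
            "strand": ["+"] * len(positions),
        })

    def test_context_assignment_and_precedence(self, tmp_path):
        p = tmp_path / "model.gff3"
        p.write_text(TestGeneModels.GFF)
        txs = read_gff3(p)
        dm = self._dm([9000, 10200, 10700, 11500, 50000, 33000])
        out = annotate_context(dm, txs)
        assert list(out["feature_context"]) == [
            "promoter",      # within [8000, 10500] of tx1
            "promoter",      # inside exon 1 but promoter wins (<= 10500)
            "first_intron",  # gap (10401, 10999) of tx1
            "other_intron",  # gap (11301, 11799)
            "intergenic",
            "promoter",      # minus-strand promoter of tx2: [31500, 34000]
        ]
        assert not out["unannotated_chrom"].any()

    def test_exon_beats_intron_across_overlapping_transcripts(self):
        tx_exonic = Transcript("a", "chr1", 100, 1000, "+", exons=[(100, 1000)])
        tx_introny = Transcript("b", "chr1", 50, 2000, "+",
                                exons=[(50, 60), (1900, 2000)])
        # position 800 is past both promoter windows (they end at 600 / 550),
        # exonic in tx a and intronic in tx b: exon must win
        out = annotate_context(self._dm([800]), [tx_exonic, tx_introny])
        assert out["feature_context"].iloc[0] == "exon"

    def test_unannotated_chromosome_flagged(self):
        tx = Transcript("a", "chr1", 100, 1000, "+", exons=[(100, 1000)])
        out = annotate_context(self._dm([500], chrom="chr9"), [tx])
        assert out["feature_context"].iloc[0] == "intergenic"
        assert out["unannotated_chrom"].iloc[0]

    def test_every_cpg_gets_exactly_one_context(self):
        tx = Transcript("a", "chr1", 1000, 5000, "+",
                        exons=[(1000, 1500), (3000, 5000)])
        out = annotate_context(self._dm(list(range(1, 6001, 97))), [tx])
        assert out["feature_context"].isin(FEATURE_PRECEDENCE).all()


class TestRunMethylation:
    def test_null_calibration_at_fdr_threshold(self, samples_2x3):
        ids, st = samples_2x3
        rng = np.random.default_rng(20)
        n = 1500
        p = rng.beta(2, 2, size=n)
        total = rng.poisson(30, size=(n, 6)) + 9  # comfortably > 8
        meth = rng.binomial(total, p[:, None])
        mt = make_table(meth, total, ids, pos=np.arange(1, n + 1) * 10)
        res = run_methylation(mt, Contrast("F1F", "F1M"), st)
        # null data at FDR < 0.01: essentially nothing should be called
        mc = 3 * np.sqrt(0.01 * 0.99 / len(res))
        assert res["is_dm"].mean() <= 0.01 + mc

    def test_planted_shift_detected_with_direction(self, samples_2x3):
        ids, st = samples_2x3
        rng = np.random.default_rng(21)
        n = 300
        p1 = np.full(n, 0.5)
        p2 = np.full(n, 0.5)
        p1[:30] = 0.9  # F1F hypermethylated at the first 30 CpGs
        total = rng.poisson(40, size=(n, 6)) + 9
        meth = np.empty_like(total)
        meth[:, :3] = rng.binomial(total[:, :3], p1[:, None])
        meth[:, 3:] = rng.binomial(total[:, 3:], p2[:, None])
        mt = make_table(meth, total, ids, pos=np.arange(1, n + 1) * 10)
        res = run_methylation(mt, Contrast("F1F", "F1M"), st)
        planted = res["pos"] <= 300
        assert res.loc[planted, "is_dm"].mean() >= 0.9
        assert (res.loc[planted & res["is_dm"], "delta"] > 0).all()
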