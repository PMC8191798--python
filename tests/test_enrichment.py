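import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ubiprom.enrichment import (
    GeneModel,
    Loop,
    assign_gene_class,
    bh_fdr,
    bidirectional_pairs,
    both_class_permutation,
    center_within,
    chia_anchor_enrichment,
    chip_bound,
    fisher_exact,
    filter_genes,
    omim_filter,
    rank_window_fraction,
    read_bedpe_loops,
    read_gtf_genes,
    stapseq_compare,
    synteny_class,
    write_bedpe_loops,
)
from ubiprom.regions import GenomicInterval
from ubiprom.seqfeat import MotifSite
from ubiprom.ubiquity import CcreRecord


def _ccre(start, end, cls="PLS", ubi=False, chrom="c"):
    iv = GenomicInterval(chrom, start, end, "+", f"e{start}")
    return CcreRecord(iv, True, False, False, 100, ccre_class=cls, ubiquitous=ubi)


class TestGeneAssignment:
    def test_four_way_partition(self):
        ubi = [GenomicInterval("c", 100, 400)]
        non = [GenomicInterval("c", 1000, 1300)]
        genes = [
            GeneModel("g_ubi", "c", "+", tss_list=[200]),
            GeneModel("g_non", "c", "+", tss_list=[1100]),
            GeneModel("g_both", "c", "+", tss_list=[200, 1100]),
            GeneModel("g_none", "c", "+", tss_list=[5000]),
            GeneModel("g_offchrom", "x", "+", tss_list=[200]),
        ]
        out = assign_gene_class(ubi, non, genes)
        assert out == {
            "g_ubi": "ubi-only",
            "g_non": "nonubi-only",
            "g_both": "both",
            "g_none": "none",
            "g_offchrom": "none",
        }

    def test_classes_partition_gene_total(self, rng):
        ubi = [GenomicInterval("c", int(s), int(s) + 300)
               for s in rng.integers(0, 50_000, 20) * 10]
        non = [GenomicInterval("c", int(s), int(s) + 300)
               for s in rng.integers(50_000, 100_000, 20) * 10]
        genes = [
            GeneModel(f"g{i}", "c", "+",
                      tss_list=sorted(set(rng.integers(0, 1_000_000, 3).tolist())))
            for i in range(100)
        ]
        out = assign_gene_class(ubi, non, genes)
        assert len(out) == len(genes)
        assert set(out.values()) <= {"ubi-only", "nonubi-only", "both", "none"}

    def test_biotype_filter(self):
        genes = [
            GeneModel("a", "c", "+", "protein_coding", [1]),
            GeneModel("b", "c", "+", "pseudogene", [2]),
            GeneModel("d", "c", "+", "processed_pseudogene", [3]),
            GeneModel("e", "c", "+", "TEC", [4]),
        ]
        assert [g.gene_id for g in filter_genes(genes)] == ["a"]


class TestCenterWithin:
    @pytest.mark.parametrize("dist,expected", [(150, True), (200, True), (201, False)])
    def test_inclusive_boundary(self, dist, expected):
        ccre = _ccre(1000, 1300)  # center 1150
        assert center_within(ccre, 1150 + dist) is expected
        assert center_within(ccre, 1150 - dist) is expected


class TestBidirectional:
    def test_opposite_strand_within_gap(self):
        genes = [
            GeneModel("a", "c", "+", tss_list=[100]),
            GeneModel("b", "c", "-", tss_list=[900]),
            GeneModel("d", "c", "-", tss_list=[1200]),
            GeneModel("e", "c", "+", tss_list=[950]),
        ]
        pairs = bidirectional_pairs(genes, 1000)
        assert ("a", "b") in pairs
        assert ("a", "d") not in pairs  # gap 1100
        assert ("b", "e") in pairs
        assert all(x != y for x, y in pairs)

    def test_same_strand_never_paired(self):
        genes = [
            GeneModel("a", "c", "+", tss_list=[100]),
            GeneModel("b", "c", "+", tss_list=[200]),
        ]
        assert bidirectional_pairs(genes) == []


class TestBothClassPermutation:
    def test_exhaustive_two_gene_expectation(self):
        """2 genes x 2 TSSs, 2 labels: E[both] = 4/3 by enumerating all 6
        labelings; the permutation mean must agree within 3 SE."""
        genes = [
            GeneModel("g1", "c", "+", tss_list=[10, 20]),
            GeneModel("g2", "c", "+", tss_list=[30, 40]),
        ]
        n_perm = 10_000
        res = both_class_permutation(genes, 2, n_perm=n_perm, seed=3)
        exact = 4 / 3
        se = res.expected_sd / math.sqrt(n_perm)
        assert abs(res.expected_mean - exact) <= 3 * se

    def test_zero_labels_zero_statistic(self):
        genes = [GeneModel("g", "c", "+", tss_list=[1, 2, 3])]
        res = both_class_permutation(genes, 0, n_perm=50, seed=0)
        assert res.expected_mean == 0.0

    def test_excess_labels_rejected(self):
        genes = [GeneModel("g", "c", "+", tss_list=[1])]
        with pytest.raises(ValueError):
            both_class_permutation(genes, 5, n_perm=10, seed=0)

    def test_depleted_observation_small_p(self):
        genes = [GeneModel(f"g{i}", "c", "+", tss_list=[i * 10, i * 10 + 1])
                 for i in range(20)]
        res = both_class_permutation(genes, 20, n_perm=2000, seed=5, observed=0)
        assert res.empirical_p is not None
        assert res.empirical_p < 0.01


class TestFisherExact:
    def test_printed_disease_essential_overlap(self):
        """941 of 2718 Mendelian-disease genes are cell-essential among
        18 633 screened genes (5312 essential overall)."""
        odds, p = fisher_exact([[941, 1777], [4371, 11544]])
        assert p == pytest.approx(6.1e-14, rel=0.05)

    def test_exchangeable_table(self):
        assert fisher_exact([[1, 1], [1, 1]])[1] == pytest.approx(1.0)

    def test_diagonal_table(self):
        odds, p = fisher_exact([[3, 0], [0, 3]])
        assert p == pytest.approx(0.1)
        assert math.isinf(odds)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [0, 0]])

    def test_matches_exhaustive_enumeration_small_tables(self):
        """Minimum-likelihood two-sided p equals exhaustive hypergeometric
        enumeration (math.comb arithmetic) for every table with total <= 14,
        and a stratified sweep up to total 40."""

        def oracle(a, b, c, d):
            n, r1, c1 = a + b + c + d, a + b, a + c
            lo, hi = max(0, r1 + c1 - n), min(r1, c1)
            denom = math.comb(n, c1)
            probs = {
                k: math.comb(r1, k) * math.comb(n - r1, c1 - k) / denom
                for k in range(lo, hi + 1)
            }
            p_obs = probs[a]
            return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))

        for n in range(1, 15):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        _, p = fisher_exact([[a, b], [c, d]])
                        assert p == pytest.approx(oracle(a, b, c, d), abs=1e-9)

        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(15, 41))
            cuts = np.sort(rng.integers(0, n + 1, size=3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = n - a - b - c
            _, p = fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(oracle(a, b, c, d), abs=1e-9)

    def test_agrees_with_scipy(self, rng):
        for _ in range(50):
            t = rng.integers(0, 60, size=(2, 2))
            if t.sum() == 0:
                continue
            _, p = fisher_exact(t)
            assert p == pytest.approx(sps.fisher_exact(t)[1], rel=1e-8)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.04]).tolist() == [0.04]

    def test_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_q_at_least_p(self, rng):
        p = rng.random(30)
        assert (bh_fdr(p) >= p - 1e-12).all()


class TestRankWindows:
    def _genes(self, n, flag_top):
        genes, flags = [], {}
        for i in range(n):
            g = GeneModel(f"g{i:04d}", "c", "+", tss_list=[i])
            g.crispr_scores = {"s": float(i)}
            genes.append(g)
            flags[g.gene_id] = i < flag_top
        return genes, flags

    def test_window_count_and_partial(self):
        genes, flags = self._genes(1100, 0)
        df = rank_window_fraction(genes, flags, window=500)
        assert df["n_genes"].tolist() == [500, 500, 100]

    def test_saturated_flags(self):
        genes, flags = self._genes(1000, 1000)
        df = rank_window_fraction(genes, flags, window=500)
        assert (df["fraction"] == 1.0).all()

    def test_planted_concentration_decreases(self):
        genes, flags = self._genes(1500, 400)
        df = rank_window_fraction(genes, flags, window=500)
        fr = df["fraction"].tolist()
        assert fr[0] > fr[1] >= fr[2]


class TestChiaAnchors:
    def test_read_filter_and_overlap(self):
        ubi = [GenomicInterval("c", i * 10_000, i * 10_000 + 300, "+", f"u{i}")
               for i in range(20)]
        non = [GenomicInterval("c", 500_000 + i * 10_000, 500_000 + i * 10_000 + 300,
                               "+", f"n{i}") for i in range(20)]
        loops = [Loop(u, GenomicInterval("c", 900_000, 900_400), 5) for u in ubi]
        weak = [Loop(n, GenomicInterval("c", 900_000, 900_400), 3) for n in non]
        res = chia_anchor_enrichment(loops + weak, ubi, non)
        assert res.n_loops == 20  # 3-read loops excluded
        assert res.percent_ubi_anchored == 100.0
        assert res.percent_nonubi_anchored == 0.0
        assert res.fisher_p < 1e-6

    def test_single_bp_overlap_counts(self):
        region = [GenomicInterval("c", 1000, 1345, "+", "u0")]
        # the resized region keeps [1000,1345); anchor shares exactly 1 bp
        anchor = GenomicInterval("c", 1344, 1500)
        other = [GenomicInterval("c", 90_000, 90_345, "+", "n0")]
        loops = [Loop(anchor, GenomicInterval("c", 5_000_000, 5_000_100), 4)]
        res = chia_anchor_enrichment(loops, region, other, resize_width=345)
        assert res.percent_ubi_anchored == 100.0

    def test_empty_after_filter(self):
        loops = [Loop(GenomicInterval("c", 0, 10), GenomicInterval("c", 50, 60), 1)]
        with pytest.raises(ValueError):
            chia_anchor_enrichment(loops, [GenomicInterval("c", 0, 300)],
                                   [GenomicInterval("c", 400, 700)])

    def test_planted_loops_detected(self, rng):
        """Loops planted on the ubiquitous set yield a significant Fisher p
        at 200 regions per group."""
        ubi = [GenomicInterval("c", i * 5000, i * 5000 + 300, "+", f"u{i}")
               for i in range(200)]
        non = [GenomicInterval("c", 2_000_000 + i * 5000, 2_000_000 + i * 5000 + 300,
                               "+", f"n{i}") for i in range(200)]
        loops = [
            Loop(ubi[i], GenomicInterval("c", 8_000_000, 8_000_400), 6)
            for i in rng.choice(200, 120, replace=False)
        ]
        res = chia_anchor_enrichment(loops, ubi, non)
        assert res.fisher_p < 0.01

    def test_bedpe_round_trip(self, tmp_path):
        loops = [Loop(GenomicInterval("c", 0, 100), GenomicInterval("c", 500, 600), 7)]
        path = tmp_path / "l.bedpe"
        write_bedpe_loops(str(path), loops)
        assert read_bedpe_loops(str(path)) == loops


class TestChipBound:
    def test_half_overlap_and_motif_required(self):
        ccre = _ccre(1000, 1300)
        site = MotifSite(GenomicInterval("c", 1100, 1108), "+", 5.0, 1e-6)
        peak_half = GenomicInterval("c", 1250, 1350)  # width 100, overlap 50
        peak_less = GenomicInterval("c", 1251, 1351)  # overlap 49
        assert chip_bound(ccre, [peak_half], [site])
        assert not chip_bound(ccre, [peak_less], [site])
        assert not chip_bound(ccre, [peak_half], [])


class TestStapseq:
    def test_medians_and_identical_groups(self):
        signal = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]],
            index=["cfA", "cfB"],
            columns=["p1", "p2", "p3", "p4"],
        )
        groups = {"p1": "ubi", "p2": "nonubi", "p3": "ubi", "p4": "nonubi"}
        res = stapseq_compare(signal, groups)
        assert res.medians.loc["cfA", "ubi"] == 2.0  # median of 1, 3
        assert res.medians.loc["cfA", "nonubi"] == 3.0

    def test_null_ratios_one(self, rng):
        vals = rng.gamma(3, 2, size=(3, 40))
        signal = pd.DataFrame(np.vstack([vals, vals[0:1]]),
                              index=["a", "b", "c", "d"],
                              columns=[f"p{i}" for i in range(40)])
        groups = {f"p{i}": ("ubi" if i % 2 else "nonubi") for i in range(40)}
        # make the two groups share the same promoters' values by symmetry of
        # random assignment: only check that identical distributions give a
        # ratio near 1 for the duplicated cofactor pair
        res = stapseq_compare(signal, groups)
        assert res.ratios["a"] == res.ratios["d"]

    def test_perfectly_correlated_merge_first(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=30)
        signal = pd.DataFrame(
            [base, base * 2 + 1, rng.normal(size=30), rng.normal(size=30)],
            index=["x1", "x2", "y1", "y2"],
            columns=[f"p{i}" for i in range(30)],
        )
        groups = {f"p{i}": ("ubi" if i < 15 else "nonubi") for i in range(30)}
        res = stapseq_compare(signal, groups)
        assert set(res.merge_order[0]) == {"x1", "x2"}

    def test_planted_blocks_recovered(self):
        """Two planted cofactor blocks come out as the two top-level
        clusters."""
        from ubiprom.synthetic import SyntheticConfig, gen_aux

        aux = gen_aux(SyntheticConfig(seed=21, n_genes=50, n_elements=100))
        groups = {
            p: ("ubi" if i % 2 == 0 else "nonubi")
            for i, p in enumerate(aux.stapseq.columns)
        }
        res = stapseq_compare(aux.stapseq, groups)
        leaf_blocks = [aux.stapseq_blocks[cf] for cf in res.leaf_order]
        # block labels must be contiguous in the dendrogram leaf order
        assert leaf_blocks in ([0, 0, 0, 1, 1, 1], [1, 1, 1, 0, 0, 0])

    def test_zero_nonubi_median_flagged(self):
        signal = pd.DataFrame(
            [[1.0, 0.0], [1.0, 0.0]], index=["a", "b"], columns=["p1", "p2"]
        )
        res = stapseq_compare(signal, {"p1": "ubi", "p2": "nonubi"})
        assert res.infinite_ratio.all()
        assert np.isinf(res.ratios).all()


class TestSynteny:
    def _targets(self):
        return [
            _ccre(1000, 1400, "PLS", ubi=True),
            _ccre(5000, 5400, "PLS", ubi=False),
            _ccre(9000, 9400, "dELS"),
        ]

    def test_categories(self):
        src = GenomicInterval("h", 0, 100)
        lifted = [
            (src, GenomicInterval("c", 1100, 1500)),  # 75% on ubi PLS
            (src, GenomicInterval("c", 5100, 5500)),  # non-ubi PLS
            (src, GenomicInterval("c", 9100, 9500)),  # other class
            (src, GenomicInterval("c", 1340, 1440)),  # 60% overlap -> ubi
            (src, GenomicInterval("c", 1360, 1460)),  # 40% -> not a cCRE
            (src, None),
        ]
        out = synteny_class(lifted, self._targets())
        assert out == [
            "ubi-in-target",
            "nonubi-PLS-in-target",
            "other-cCRE",
            "ubi-in-target",
            "not-a-cCRE",
            "liftover-failed",
        ]

    def test_stable_under_target_reordering(self, rng):
        targets = self._targets()
        lifted = [(GenomicInterval("h", 0, 100),
                   GenomicInterval("c", int(s), int(s) + 200))
                  for s in rng.integers(500, 10_000, 30)]
        base = synteny_class(lifted, targets)
        for _ in range(5):
            perm = [targets[i] for i in rng.permutation(3)]
            assert synteny_class(lifted, perm) == base


class TestOmim:
    def test_bracket_and_brace_filtering(self):
        df = pd.DataFrame(
            {
                "gene": ["A", "A", "B", "C", "D"],
                "phenotype": [
                    "[Blood group, ABO]",
                    "Deafness, autosomal recessive",
                    "{Diabetes mellitus, susceptibility}",
                    "[Non-disease trait]",
                    "Myopathy, congenital",
                ],
            }
        )
        assert omim_filter(df) == {"A", "D"}


class TestGtf:
    def test_reader_merges_transcripts_and_filters(self, tmp_path):
        path = tmp_path / "g.gtf"
        path.write_text(
            'c\tx\ttranscript\t101\t600\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; gene_type "protein_coding";\n'
            'c\tx\ttranscript\t201\t700\t.\t+\t.\tgene_id "g1"; transcript_id "t2"; gene_type "protein_coding";\n'
            'c\tx\ttranscript\t901\t999\t.\t-\t.\tgene_id "g2"; transcript_id "t3"; gene_type "pseudogene";\n'
        )
        genes = read_gtf_genes(str(path))
        assert len(genes) == 1
        assert genes[0].gene_id == "g1"
        assert sorted(genes[0].tss_list) == [100, 200]  # 0-based 5' ends
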