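"""QC filtering, trend-test association, regions, concordance and motifs."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from florin import gwas
from florin.types import (
    AssociationResult,
    GeneFeature,
    GenotypeCalls,
    MotifHit,
    TranscriptSeq,
)


def calls_from(codes):
    codes = np.asarray(codes, dtype=np.int8)
    n_snps, n_acc = codes.shape
    snps = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, n_snps + 1) * 100,
                         "ref": "A", "alt": "G"})
    return GenotypeCalls(snps, codes, [f"a{i}" for i in range(n_acc)])


class TestQcFilter:
    def test_monomorphic_removed(self):
        calls = calls_from([[0] * 10, [0, 1] * 5])
        assert gwas.qc_filter(calls).n_snps == 1

    def test_boundaries_are_strict(self):
        # MAF exactly 0.05: 1 alt allele among 20 -> removed
        maf_edge = [1] + [0] * 9
        # missing rate exactly 0.2: 2 of 10 missing -> removed
        miss_edge = [-1, -1, 0, 1, 1, 0, 1, 0, 1, 0]
        keeper = [0, 1, 2, 1, 0, 1, 2, 0, 1, 2]
        calls = calls_from([maf_edge, miss_edge, keeper])
        kept = gwas.qc_filter(calls)
        assert kept.snps["pos"].tolist() == [300]

    def test_hand_computed_survivors(self):
        rows = [
            [0, 0, 0, 0, 0, 0, 0, 0, 0, 1],   # MAF 0.05 -> out
            [0, 0, 0, 0, 0, 0, 0, 0, 1, 1],   # MAF 0.10 -> in
            [2, 2, 2, 2, 2, 2, 2, 2, 2, 2],   # MAF 0    -> out
            [0, 1, 2, 0, 1, 2, 0, 1, 2, 0],   # MAF 0.45 -> in
            [-1, -1, -1, 0, 1, 2, 0, 1, 2, 0],  # missing 0.3 -> out
        ]
        kept = gwas.qc_filter(calls_from(rows))
        assert kept.snps["pos"].tolist() == [200, 400]

    def test_maf_uses_nonmissing_calls_only(self):
        row = [-1, 1, 1, 0, 0, 0, 0, 0, 0, 0]  # MAF = 2/18 > 0.05, missing 0.1
        assert gwas.qc_filter(calls_from([row])).n_snps == 1


class TestTrendTest:
    def test_perfect_separation_closed_form(self):
        # cases all alt-hom, controls all ref-hom: chi2 equals N
        codes = np.array([2] * 10 + [0] * 10)
        classes = np.array(["LF"] * 10 + ["NF"] * 10)
        r = gwas.trend_test(codes, classes)
        assert r.chi_square == pytest.approx(20.0)

    def test_identical_class_rows_are_null(self):
        codes = np.array([0, 1, 2] * 4)
        classes = np.array((["LF"] * 3 + ["NF"] * 3) * 2)
        r = gwas.trend_test(codes, classes)
        assert r.chi_square == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # 2x3 table: cases (1, 3, 6), controls (7, 2, 1)
        codes = np.array([0, 1, 1, 1, 2, 2, 2, 2, 2, 2,
                          0, 0, 0, 0, 0, 0, 0, 1, 1, 2])
        classes = np.array(["LF"] * 10 + ["NF"] * 10)
        r_i = np.array([1, 3, 6]); n_i = np.array([8, 5, 7]); s = np.array([0, 1, 2])
        N, R = 20, 10
        num = N * (s * r_i).sum() - R * (s * n_i).sum()
        den = R * (N - R) * (N * (s * s * n_i).sum() - (s * n_i).sum() ** 2)
        expected = N * num ** 2 / den
        r = gwas.trend_test(codes, classes)
        assert r.chi_square == pytest.approx(expected)
        assert r.p_value == pytest.approx(stats.chi2.sf(expected, 1))

    def test_constant_genotype_untestable(self):
        codes = np.array([1] * 20)
        classes = np.array(["LF"] * 10 + ["NF"] * 10)
        assert gwas.trend_test(codes, classes).untestable

    def test_missing_calls_dropped(self):
        codes = np.array([2] * 10 + [0] * 10 + [-1, -1])
        classes = np.array(["LF"] * 10 + ["NF"] * 12)
        assert gwas.trend_test(codes, classes).chi_square == pytest.approx(20.0)

    def test_too_few_per_class_rejected(self):
        with pytest.raises(ValueError, match="2 accessions"):
            gwas.trend_test(np.array([0, 1, 2]), np.array(["LF", "NF", "NF"]))

    def test_null_p_uniform(self):
        """Kolmogorov–Smirnov check on null p-values at alpha = 0.01."""
        rng = np.random.default_rng(17)
        classes = np.array(["LF"] * 23 + ["NF"] * 43)
        ps = []
        for _ in range(2000):
            q = rng.uniform(0.05, 0.5)
            r = gwas.trend_test(rng.binomial(2, q, size=66), classes)
            if not r.untestable:
                ps.append(r.p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBonferroni:
    def test_study_scale_two_decimals(self):
        value = gwas.bonferroni_threshold(0.05, 2_598_398)
        assert gwas.threshold_display(value) == 7.71

    def test_single_test_reduces_to_alpha(self):
        assert gwas.bonferroni_threshold(0.05, 1) == pytest.approx(-math.log10(0.05))

    def test_closed_form(self):
        assert gwas.bonferroni_threshold(0.01, 100) == pytest.approx(4.0)

    def test_monotone_in_m_and_alpha(self):
        ms = [1, 10, 1000, 10 ** 6]
        vals = [gwas.bonferroni_threshold(0.05, m) for m in ms]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert (gwas.bonferroni_threshold(0.01, 100)
                > gwas.bonferroni_threshold(0.05, 100))

    @pytest.mark.parametrize("alpha,m", [(0.0, 10), (1.0, 10), (0.05, 0)])
    def test_invalid_inputs_rejected(self, alpha, m):
        with pytest.raises(ValueError):
            gwas.bonferroni_threshold(alpha, m)


def assoc(pos, chrom="chr1", idx=0):
    return AssociationResult(idx, chrom, pos, 30.0, 1e-8, 8.0, significant=True)


class TestCandidateRegions:
    def test_no_snps_no_regions(self):
        assert gwas.candidate_regions([]) == []

    def test_single_snp_arithmetic(self):
        [r] = gwas.candidate_regions([assoc(50_000)])
        assert (r.start, r.end) == (40_000, 60_000)

    def test_clip_at_one(self):
        [r] = gwas.candidate_regions([assoc(4_000)])
        assert r.start == 1

    def test_close_snps_merge(self):
        [r] = gwas.candidate_regions([assoc(50_000), assoc(55_000, idx=1)])
        assert (r.start, r.end) == (40_000, 65_000)
        assert r.member_snps == [0, 1]

    def test_distant_snps_stay_separate_and_sorted(self):
        regions = gwas.candidate_regions([assoc(200_000, idx=1), assoc(50_000)])
        assert [(r.start, r.end) for r in regions] == [(40_000, 60_000),
                                                       (190_000, 210_000)]
        for a, b in zip(regions, regions[1:]):
            assert a.end < b.start

    def test_genes_attached_by_intersection(self):
        ann = [GeneFeature("in", "chr1", 59_000, 61_000, "+", "mRNA"),
               GeneFeature("out", "chr1", 80_000, 81_000, "+", "mRNA"),
               GeneFeature("offchrom", "chr2", 50_000, 50_500, "+", "mRNA")]
        [r] = gwas.candidate_regions([assoc(50_000)], ann)
        assert r.gene_ids == ["in"]


class TestConcordance:
    def test_perfect_separation(self):
        codes = np.array([2] * 23 + [0] * 43)
        classes = np.array(["LF"] * 23 + ["NF"] * 43)
        assert gwas.concordance(codes, classes) == 1.0

    def test_constant_genotype_gives_majority_fraction(self):
        codes = np.array([1] * 66)
        classes = np.array(["LF"] * 23 + ["NF"] * 43)
        assert gwas.concordance(codes, classes) == pytest.approx(43 / 66)

    def test_partial_concordance_fraction(self):
        # 60 of 66 concordant under the best ({0} vs {1,2}) dichotomy
        codes = np.array([2] * 20 + [0] * 3 + [0] * 40 + [2] * 3)
        classes = np.array(["LF"] * 23 + ["NF"] * 43)
        assert gwas.concordance(codes, classes) == pytest.approx(60 / 66)

    def test_matches_brute_force_over_dichotomies(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            codes = rng.integers(0, 3, size=30)
            classes = np.where(rng.random(30) < 0.4, "LF", "NF")
            best = 0.0
            for sides in [({0}, {1, 2}), ({0, 1}, {2}), ({0, 2}, {1})]:
                for lf_side in (0, 1):
                    members = sides[lf_side]
                    pred = np.where(np.isin(codes, list(members)), "LF", "NF")
                    best = max(best, float((pred == classes).mean()))
            assert gwas.concordance(codes, classes) == pytest.approx(best)


def brute_force_motif_scan(seq: str, motifs):
    comp = str.maketrans("ACGT", "TGCA")
    hits = []
    for motif in motifs:
        rc = motif.translate(comp)[::-1]
        for i in range(len(seq) - len(motif) + 1):
            window = seq[i:i + len(motif)]
            if window == motif:
                hits.append((i + 1, i + len(motif), "+", motif))
            if window == rc:
                hits.append((i + 1, i + len(motif), "-", motif))
    return sorted(hits)


class TestMotifScan:
    def test_absent_motif_empty(self):
        assert gwas.motif_scan(TranscriptSeq("p", "AAAA" * 10)) == []

    def test_planted_hit_coordinates(self):
        seq = TranscriptSeq("p", "A" * 10 + "TACGTG" + "A" * 10)
        [hit] = gwas.motif_scan(seq)
        assert (hit.start, hit.end, hit.strand) == (11, 16, "+")

    def test_reverse_complement_hit(self):
        seq = TranscriptSeq("p", "G" * 8 + "CACGTA" + "G" * 8)
        [hit] = gwas.motif_scan(seq)
        assert (hit.start, hit.strand) == (9, "-")

    def test_matches_brute_force_including_overlaps(self):
        rng = np.random.default_rng(29)
        seq = "".join(rng.choice(list("ACGT"), 4000))
        motifs = ("TACGTG", "CACGTG", "ATAT")
        got = sorted((h.start, h.end, h.strand, h.motif)
                     for h in gwas.motif_scan(TranscriptSeq("p", seq), motifs))
        assert got == brute_force_motif_scan(seq, motifs)


class TestSnpMotifDisruption:
    SEQ = TranscriptSeq("p", "A" * 10 + "TACGTG" + "A" * 10)

    def test_third_nucleotide_mutation_disrupts(self):
        hits = gwas.motif_scan(self.SEQ)
        [(hit, disrupted)] = gwas.snp_motif_disruption((13, "C", "T"), hits, self.SEQ)
        assert disrupted

    def test_snp_outside_hits_no_records(self):
        hits = gwas.motif_scan(self.SEQ)
        assert gwas.snp_motif_disruption((2, "A", "G"), hits, self.SEQ) == []

    def test_substitution_matching_another_motif_not_disrupted(self):
        motifs = ("TACGTG", "CACGTG")
        hits = gwas.motif_scan(self.SEQ, motifs)
        records = gwas.snp_motif_disruption((11, "T", "C"), hits, self.SEQ, motifs)
        plus = [d for h, d in records if h.strand == "+"]
        assert plus == [False]  # TACGTG -> CACGTG still in the set

    def test_minus_strand_hit_reevaluated_in_orientation(self):
        seq = TranscriptSeq("p", "G" * 8 + "CACGTA" + "G" * 8)
        hits = gwas.motif_scan(seq)
        # SNP at the motif's reverse-strand third nucleotide (seq position 12)
        [(hit, disrupted)] = gwas.snp_motif_disruption((12, "G", "A"), hits, seq)
        assert hit.strand == "-" and disrupted

    def test_ref_mismatch_rejected(self):
        hits = gwas.motif_scan(self.SEQ)
        with pytest.raises(ValueError, match="ref allele"):
            gwas.snp_motif_disruption((13, "G", "T"), hits, self.SEQ)
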