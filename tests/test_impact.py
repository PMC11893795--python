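"""Gene-impact decision table: worked examples and per-base oracle."""

import numpy as np
import pytest

import ppsv
from ppsv.impact import (
    CG,
    IED,
    INTERGENIC,
    INTRONIC,
    PARTIAL_EXON_DUP,
    PARTIAL_GENE_DUP,
    PLOF,
    PROMOTER,
    UTR,
    WHOLE_GENE_INV,
)
from ppsv.model import GeneModel, Region, RegionSet, SVRecord, SVType

from helpers_oracles import oracle_impact


def sv(svtype, pos1, pos2, chrom="chr1", chrom2=None, strands=None):
    chrom2 = chrom2 or chrom
    svlen = pos2 - pos1 if svtype in (SVType.DEL, SVType.DUP, SVType.INV) else None
    return SVRecord("sv", chrom, pos1, chrom2, pos2, svtype, svlen=svlen,
                    strands=strands)


def categories(annotations, gene_id):
    return [a.category for a in annotations if a.gene_id == gene_id]


class TestDecisionTable:
    def test_exon_deleting_del_is_plof(self, toy_genes):
        anns = ppsv.annotate_sv(sv(SVType.DEL, 11_900, 12_600), toy_genes)
        assert categories(anns, "gA") == [PLOF]

    def test_intronic_del(self, toy_genes):
        anns = ppsv.annotate_sv(sv(SVType.DEL, 12_600, 13_800), toy_genes)
        assert categories(anns, "gA") == [INTRONIC]

    def test_utr_only_del(self, toy_genes):
        # gA CDS starts at 10,250; deleting the first 100 exonic bases
        # removes 5' UTR sequence only
        anns = ppsv.annotate_sv(sv(SVType.DEL, 10_000, 10_150), toy_genes)
        assert categories(anns, "gA") == [UTR]

    def test_gene_spanning_dup_is_copy_gain(self, toy_genes):
        anns = ppsv.annotate_sv(sv(SVType.DUP, 9_000, 21_000), toy_genes)
        assert categories(anns, "gA") == [CG]

    def test_dup_containing_exon_with_intronic_breakpoints_is_ied(self, toy_genes):
        anns = ppsv.annotate_sv(sv(SVType.DUP, 13_000, 15_000), toy_genes)
        assert categories(anns, "gA") == [IED]

    def test_intragenic_dup_without_exon_is_partial_exon_dup(self, toy_genes):
        anns = ppsv.annotate_sv(sv(SVType.DUP, 12_600, 13_800), toy_genes)
        assert categories(anns, "gA") == [PARTIAL_EXON_DUP]

    def test_dup_with_both_breakpoints_in_exons_is_plof(self, toy_genes):
        anns = ppsv.annotate_sv(sv(SVType.DUP, 12_100, 14_100), toy_genes)
        assert categories(anns, "gA") == [PLOF]

    def test_dup_with_one_breakpoint_inside_is_partial_gene_dup(self, toy_genes):
        anns = ppsv.annotate_sv(sv(SVType.DUP, 15_000, 25_000), toy_genes)
        assert categories(anns, "gA") == [PARTIAL_GENE_DUP]

    def test_inv_containing_gene_with_outside_breakpoints(self, toy_genes):
        anns = ppsv.annotate_sv(
            sv(SVType.INV, 9_000, 21_000, strands=("+", "+")), toy_genes
        )
        assert categories(anns, "gA") == [WHOLE_GENE_INV]

    def test_inv_breakpoint_inside_gene_is_plof(self, toy_genes):
        anns = ppsv.annotate_sv(
            sv(SVType.INV, 13_000, 21_000, strands=("+", "+")), toy_genes
        )
        assert categories(anns, "gA") == [PLOF]

    def test_inv_within_single_intron_is_intronic(self, toy_genes):
        anns = ppsv.annotate_sv(
            sv(SVType.INV, 12_600, 13_800, strands=("+", "+")), toy_genes
        )
        assert categories(anns, "gA") == [INTRONIC]

    def test_tra_breakpoint_in_cds_span_is_plof(self, toy_genes):
        anns = ppsv.annotate_sv(
            sv(SVType.TRA, 13_000, 5_000, chrom2="chr9"), toy_genes
        )
        assert categories(anns, "gA") == [PLOF]

    def test_tra_intronic_breakpoint_configurable(self, toy_genes):
        anns = ppsv.annotate_sv(
            sv(SVType.TRA, 13_000, 5_000, chrom2="chr9"), toy_genes,
            tra_intronic_is_plof=False,
        )
        assert categories(anns, "gA") == [INTRONIC]

    def test_tra_utr_breakpoint(self, toy_genes):
        anns = ppsv.annotate_sv(
            sv(SVType.TRA, 10_100, 5_000, chrom2="chr9"), toy_genes
        )
        assert categories(anns, "gA") == [UTR]

    def test_intergenic_sv_gets_single_gene_free_annotation(self, toy_genes):
        (ann,) = ppsv.annotate_sv(sv(SVType.DEL, 25_000, 26_000), toy_genes)
        assert ann.category == INTERGENIC and ann.gene_id is None

    def test_promoter_only_overlap(self, toy_genes):
        # gA is + strand with TSS 10,000: promoter [9000, 9999]
        anns = ppsv.annotate_sv(sv(SVType.DEL, 9_200, 9_400), toy_genes)
        assert categories(anns, "gA") == [PROMOTER]

    def test_fusion_label_ordered_by_breakpoint(self, toy_genes):
        partner = GeneModel(
            gene_id="gC", gene_name="GC", canonical_transcript="gC.t1",
            chrom="chr9", strand="+", tx_start=4_000, tx_end=8_000,
            exons=[(4_000, 4_200), (7_800, 8_000)], canonical=True,
        )
        anns = ppsv.annotate_sv(
            sv(SVType.TRA, 13_000, 4_100, chrom2="chr9"), toy_genes + [partner]
        )
        fusions = {a.fusion for a in anns if a.gene_id in ("gA", "gC")}
        assert fusions == {"GA-GC"}

    def test_large_sv_restricted_to_breakpoint_genes(self, toy_genes):
        wide = GeneModel(
            gene_id="gW", gene_name="GW", canonical_transcript="gW.t1",
            chrom="chr1", strand="+", tx_start=500_000, tx_end=520_000,
            exons=[(500_000, 500_300)], canonical=True,
        )
        big = sv(SVType.DEL, 13_000, 1_600_000)
        anns = ppsv.annotate_sv(big, toy_genes + [wide])
        # gA contains a breakpoint; gB and gW are spanned without one
        assert categories(anns, "gA") == [PLOF]
        assert not categories(anns, "gB") and not categories(anns, "gW")

    def test_enhancer_hit_requires_breakpoint_inside(self, toy_genes):
        enhancers = RegionSet(
            "enhancers", [Region("chr1", 12_999, 13_050, "gA")]
        )
        hit = ppsv.annotate_sv(
            sv(SVType.DEL, 13_000, 14_200), toy_genes, enhancers=enhancers
        )
        spanned = ppsv.annotate_sv(
            sv(SVType.DEL, 11_900, 14_200), toy_genes, enhancers=enhancers
        )
        assert [a.enhancer_hit for a in hit if a.gene_id == "gA"] == [True]
        assert [a.enhancer_hit for a in spanned if a.gene_id == "gA"] == [False]


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(4))
    def test_decision_table_matches_per_base_oracle(self, seed, toy_genes):
        rng = np.random.default_rng(seed)
        annotator = ppsv.GenomeAnnotator(toy_genes)
        for _ in range(250):
            svtype = [SVType.DEL, SVType.DUP, SVType.INV, SVType.TRA][
                int(rng.integers(4))
            ]
            pos1 = int(rng.integers(5_000, 45_000))
            if svtype is SVType.TRA:
                record = sv(SVType.TRA, pos1, int(rng.integers(1, 50_000)),
                            chrom2="chr9")
            else:
                size = int(rng.integers(50, 20_000))
                strands = ("+", "+") if svtype is SVType.INV else None
                record = sv(svtype, pos1, pos1 + size, strands=strands)
            anns = {
                a.gene_id: a.category
                for a in annotator.annotate(record)
                if a.gene_id and a.category != PROMOTER
            }
            for gene in toy_genes:
                expected = oracle_impact(record, gene)
                assert anns.get(gene.gene_id) == expected, (record, gene.gene_id)

    def test_category_exclusive_per_gene_pair(self, toy_genes):
        rng = np.random.default_rng(99)
        annotator = ppsv.GenomeAnnotator(toy_genes)
        for _ in range(200):
            pos1 = int(rng.integers(5_000, 45_000))
            record = sv(SVType.DEL, pos1, pos1 + int(rng.integers(50, 15_000)))
            anns = annotator.annotate(record)
            gene_ids = [a.gene_id for a in anns if a.gene_id]
            assert len(gene_ids) == len(set(gene_ids))

    def test_enlarging_del_never_weakens_plof(self, toy_genes):
        annotator = ppsv.GenomeAnnotator(toy_genes)
        base = sv(SVType.DEL, 11_900, 12_600)
        assert categories(annotator.annotate(base), "gA") == [PLOF]
        for grow in (500, 2_000, 10_000):
            bigger = sv(SVType.DEL, 11_900 - grow, 12_600 + grow)
            assert categories(annotator.annotate(bigger), "gA") == [PLOF]


class TestPromoters:
    def test_plus_strand_window(self):
        g = GeneModel("g", "G", "g.t1", "chr1", "+", 5_000, 9_000,
                      exons=[(5_000, 5_100)])
        (region,) = ppsv.promoter_regions([g]).intervals
        assert (region.start1, region.end1) == (4_000, 4_999)

    def test_minus_strand_window_mirrors(self):
        g = GeneModel("g", "G", "g.t1", "chr1", "-", 1_000, 5_000,
                      exons=[(1_000, 1_100)])
        (region,) = ppsv.promoter_regions([g]).intervals
        assert (region.start1, region.end1) == (5_001, 6_000)

    def test_zero_window_is_empty(self):
        g = GeneModel("g", "G", "g.t1", "chr1", "+", 5_000, 9_000,
                      exons=[(5_000, 5_100)])
        assert len(ppsv.promoter_regions([g], window=0)) == 0


class TestCanonicalSelection:
    def _tx(self, tid, cds_len, tx_len, flagged=False):
        return GeneModel(
            "g", "G", tid, "chr1", "+", 1_000, 1_000 + tx_len - 1,
            exons=[(1_000, 1_000 + cds_len - 1)],
            cds_start=1_000, cds_end=1_000 + cds_len - 1, canonical=flagged,
        )

    def test_flagged_transcript_wins(self):
        ts = [self._tx("T1", 900, 5_000), self._tx("T2", 300, 2_000, flagged=True),
              self._tx("T3", 1_200, 9_000)]
        assert ppsv.pick_canonical(ts).canonical_transcript == "T2"

    def test_longest_cds_fallback(self):
        ts = [self._tx("T1", 900, 5_000), self._tx("T2", 1_200, 5_000)]
        assert ppsv.pick_canonical(ts).canonical_transcript == "T2"

    def test_full_tie_breaks_lexicographically(self):
        ts = [self._tx("T2", 900, 5_000), self._tx("T1", 900, 5_000)]
        assert ppsv.pick_canonical(ts).canonical_transcript == "T1"

    def test_no_transcripts_is_error(self):
        with pytest.raises(ValueError):
            ppsv.pick_canonical([])
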