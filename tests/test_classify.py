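"""Consensus scoring, cancer-gene relevance and the gene-role rule engine."""

import numpy as np
import pytest

import ppsv
from ppsv.classify import (
    CAUTIONARY,
    GeneSetCollection,
    NOT_CANDIDATE,
    PP_SV,
    ScorePanel,
    UNLIKELY,
    cancer_relevance,
    classify_final,
    consensus_candidate,
)
from ppsv.impact import CG, IED, PLOF, ImpactAnnotation
from ppsv.known import KnownSVEntry, match_known
from ppsv.model import SVRecord, SVType


def panel(sv_id="s", **scores):
    return ScorePanel(sv_id=sv_id, **scores)


class TestConsensus:
    def test_two_of_four_passes(self):
        candidate, n_passed, n_scored = consensus_candidate(
            panel(strvctvre=0.50, cadd_sv=12, postre=0.1, phenosv=0.1)
        )
        assert candidate and n_passed == 2 and n_scored == 4

    def test_all_just_below_thresholds(self):
        candidate, n_passed, _ = consensus_candidate(
            panel(strvctvre=0.36, cadd_sv=9.9, postre=0.79, phenosv=0.49)
        )
        assert not candidate and n_passed == 0

    def test_thresholds_are_inclusive(self):
        _, n_passed, _ = consensus_candidate(
            panel(strvctvre=0.37, cadd_sv=10, postre=0.8, phenosv=0.5)
        )
        assert n_passed == 4

    def test_translocation_scoreable_by_two_tools_only(self):
        candidate, n_passed, n_scored = consensus_candidate(
            panel(postre=0.9, phenosv=0.9)
        )
        assert candidate and n_passed == 2 and n_scored == 2

    def test_absent_scores_count_against_absolute_requirement(self):
        candidate, _, _ = consensus_candidate(panel(phenosv=0.9))
        assert not candidate

    def test_relative_counting_option(self):
        candidate, _, _ = consensus_candidate(
            panel(phenosv=0.9), min_pass_relative=True
        )
        assert candidate

    def test_negative_score_is_error(self):
        with pytest.raises(ValueError):
            consensus_candidate(panel(cadd_sv=-1))

    def test_raising_thresholds_never_grows_candidates(self):
        rng = np.random.default_rng(3)
        panels = [
            panel(f"s{i}", strvctvre=rng.uniform(0, 1), cadd_sv=rng.uniform(0, 30),
                  postre=rng.uniform(0, 1), phenosv=rng.uniform(0, 1))
            for i in range(200)
        ]
        base = {"strvctvre": 0.37, "cadd_sv": 10.0, "postre": 0.8, "phenosv": 0.5}
        base_set = {p.sv_id for p in panels if consensus_candidate(p, base)[0]}
        for tool in base:
            stricter = dict(base)
            stricter[tool] *= 1.5
            strict_set = {
                p.sv_id for p in panels if consensus_candidate(p, stricter)[0]
            }
            assert strict_set <= base_set
        # lowering min_pass never shrinks; requiring all four is far stricter
        relaxed = {p.sv_id for p in panels if consensus_candidate(p, base, min_pass=1)[0]}
        all_four = {p.sv_id for p in panels if consensus_candidate(p, base, min_pass=4)[0]}
        assert base_set <= relaxed
        assert len(all_four) < len(base_set)


class TestCancerRelevance:
    @pytest.fixture()
    def sets(self):
        return GeneSetCollection(
            hallmark={"G1", "G3"},
            oncogenic_signatures={"G2"},
            cancer_census={"G1", "G2"},
        )

    def test_gene_in_two_collections(self, sets):
        assert cancer_relevance(["G1"], sets)

    def test_gene_in_one_collection_fails(self, sets):
        assert not cancer_relevance(["G3"], sets)

    def test_fusion_union_vs_single_gene_reading(self, sets):
        genes = ["G3", "G2"]  # hallmark-only partner + oncogenic/census partner
        assert cancer_relevance(genes, sets, union=True)
        assert cancer_relevance(genes, sets, union=False)  # G2 alone covers 2
        assert cancer_relevance(["G3", "X"], sets, union=True) is False
        # a fusion of two single-collection genes differs between readings
        lopsided = GeneSetCollection(
            hallmark={"A"}, oncogenic_signatures={"B"}, cancer_census={"Z"}
        )
        assert cancer_relevance(["A", "B"], lopsided, union=True)
        assert not cancer_relevance(["A", "B"], lopsided, union=False)


def _loss_call(svtype, genes, roles, match=None, **kw):
    sv = SVRecord("s", "chr1", 1000, "chr1" if svtype is not SVType.TRA else "chr2",
                  2000, svtype)
    impacts = [
        ImpactAnnotation("s", g, PLOF, breakpoint_genes=list(genes)) for g in genes
    ]
    defaults = dict(candidate=True, rarity_ok=True, cancer_related=True)
    defaults.update(kw)
    return classify_final(sv, impacts, match, roles=roles, **defaults)


def _dosage_call(category, gene, roles, breakpoint_genes=(), **kw):
    sv = SVRecord("s", "chr1", 1000, "chr1", 2000, SVType.DUP)
    impacts = [
        ImpactAnnotation("s", gene, category, breakpoint_genes=list(breakpoint_genes))
    ]
    defaults = dict(candidate=True, rarity_ok=True, cancer_related=True)
    defaults.update(kw)
    return classify_final(sv, impacts, None, roles=roles, **defaults)


class TestRuleEngine:
    def test_tsg_loss_inversion_is_pp_sv(self):
        call = _loss_call(SVType.INV, ["MLH1"], {"MLH1": "TSG"})
        assert call.final_class == PP_SV and call.rule == "R2-tsg-loss"

    def test_tsg_oncogene_fusion_is_cautionary(self):
        call = _loss_call(
            SVType.TRA, ["PHC3", "PRKACA"],
            {"PHC3": "TSG", "PRKACA": "oncogene"},
        )
        assert call.final_class == CAUTIONARY

    def test_oncogene_loss_is_unlikely(self):
        call = _loss_call(SVType.INV, ["NSD3"], {"NSD3": "oncogene"})
        assert call.final_class == UNLIKELY

    def test_conflicting_role_is_cautionary(self):
        call = _loss_call(SVType.TRA, ["PKHD1"], {"PKHD1": "conflicting"})
        assert call.final_class == CAUTIONARY

    def test_tsg_with_unclear_partner_is_cautionary(self):
        call = _loss_call(
            SVType.TRA, ["KCTD3", "DST"], {"KCTD3": "unclear", "DST": "TSG"}
        )
        assert call.final_class == CAUTIONARY

    def test_two_tsg_fusion_is_pp_sv(self):
        call = _loss_call(SVType.TRA, ["AK8", "DST"], {"AK8": "TSG", "DST": "TSG"})
        assert call.final_class == PP_SV

    def test_all_unclear_is_unlikely(self):
        call = _loss_call(SVType.DEL, ["X"], {"X": "unclear"})
        assert call.final_class == UNLIKELY

    def test_copy_gain_of_oncogene_is_pp_sv(self):
        call = _dosage_call(CG, "COL4A2", {"COL4A2": "oncogene"})
        assert call.final_class == PP_SV and call.rule == "R3-oncogene-gain"

    def test_exon_dup_of_oncogene_is_pp_sv(self):
        call = _dosage_call(IED, "SLC2A5", {"SLC2A5": "oncogene"})
        assert call.final_class == PP_SV

    def test_copy_gain_with_cancer_breakpoint_genes_is_cautionary(self):
        call = _dosage_call(
            CG, "TTC27", {"BIRC6": "oncogene", "LTBP1": "TSG"},
            breakpoint_genes=["BIRC6", "LTBP1"],
        )
        assert call.final_class == CAUTIONARY

    def test_copy_gain_without_role_evidence_is_unlikely(self):
        call = _dosage_call(CG, "X", {})
        assert call.final_class == UNLIKELY

    def test_clinvar_pathogenic_match_overrides(self):
        entry = KnownSVEntry("e", "chr1", 1000, "chr1", 2000, SVType.DEL,
                             clinical_significance="likely_pathogenic")
        sv = SVRecord("s", "chr1", 1000, "chr1", 2000, SVType.DEL)
        match = match_known(sv, [entry])
        call = _loss_call(SVType.DEL, ["OCA2"], {}, match=match)
        assert call.final_class == PP_SV and call.clinvar_override
        assert call.rule == "R1"

    def test_gates_force_not_candidate(self):
        for gate in ("candidate", "rarity_ok", "cancer_related"):
            call = _loss_call(SVType.DEL, ["MLH1"], {"MLH1": "TSG"}, **{gate: False})
            assert call.final_class == NOT_CANDIDATE
        call = _loss_call(SVType.DEL, ["MLH1"], {"MLH1": "TSG"},
                          frequency_excluded=True)
        assert call.final_class == NOT_CANDIDATE
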