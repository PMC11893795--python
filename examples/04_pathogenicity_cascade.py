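"""The consensus pathogenicity cascade and gene-role rule engine.

A candidate must pass at least two of four impact-predictor thresholds
(StrVCTVRE >= 0.37, CADD-SV >= 10, POSTRE >= 0.8, PhenoSV >= 0.5), hit
genes in two of three cancer gene collections, be rare in both
ancestries, and finally earn its class from the curated roles of the
genes it disrupts.
"""

import ppsv
from ppsv.classify import GeneSetCollection, ScorePanel
from ppsv.impact import ImpactAnnotation
from ppsv.model import SVRecord, SVType

sets = GeneSetCollection(
    hallmark={"MLH1", "PRKACA"},
    oncogenic_signatures={"PRKACA"},
    cancer_census={"MLH1", "PHC3"},
)
roles = {"MLH1": "TSG", "PHC3": "TSG", "PRKACA": "oncogene"}

# an inversion disrupting a mismatch-repair tumour suppressor: scoreable
# only by the two tools that handle inversions
inv = SVRecord("inv1", "chr3", 37_000_362, "chr3", 39_352_689, SVType.INV,
               strands=("+", "+"))
panel = ScorePanel("inv1", postre=0.91, phenosv=0.82)
candidate, n_passed, n_scored = ppsv.consensus_candidate(panel)
print(f"inv1: {n_passed}/{n_scored} tools passed -> candidate={candidate}")
print(f"inv1 cancer-relevant: {ppsv.cancer_relevance(['MLH1'], sets)}")
call = ppsv.classify_final(
    inv, [ImpactAnnotation("inv1", "MLH1", "pLoF")], match=None,
    candidate=candidate, rarity_ok=True, roles=roles,
)
print(f"inv1 final class: {call.final_class} (rule {call.rule})")

# a translocation fusing a tumour suppressor with an oncogene: the
# conflicting role evidence earns only a cautionary call
tra = SVRecord("tra1", "chr3", 170_090_742, "chr19", 14_110_142, SVType.TRA)
impacts = [
    ImpactAnnotation("tra1", "PHC3", "pLoF", breakpoint_genes=["PHC3", "PRKACA"]),
    ImpactAnnotation("tra1", "PRKACA", "pLoF", breakpoint_genes=["PHC3", "PRKACA"]),
]
call = ppsv.classify_final(tra, impacts, match=None, candidate=True,
                           rarity_ok=True, roles=roles)
print(f"tra1 final class: {call.final_class} (rule {call.rule})")
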