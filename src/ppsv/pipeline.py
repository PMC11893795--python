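"""End-to-end orchestration of the prioritization cascade.

:func:`prioritize` takes a cohort-genotyped site list plus all the
annotation resources and runs the full cascade — genotype QC, allele
frequencies, rarity, gene impact, known-SV matching, score consensus,
cancer-gene relevance, the gene-role rule engine — returning per-SV
calls and a stage-by-stage funnel of counts.  The funnel is
non-increasing by construction, mirroring the workflow's triage figure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .classify import (
    CAUTIONARY,
    DEFAULT_THRESHOLDS,
    GeneSetCollection,
    PP_SV,
    PathogenicityCall,
    ScorePanel,
    cancer_relevance,
    classify_final,
    consensus_candidate,
)
from .genotypes import (
    CohortSite,
    FrequencyRecord,
    compute_frequencies,
    mask_genotypes,
    missingness_filter,
    site_filter,
)
from .impact import GenomeAnnotator, ImpactAnnotation
from .known import KnownSVEntry, MatchResult, match_known
from .model import GeneModel, RegionSet


@dataclass
class PipelineConfig:
    """Tunable thresholds of the cascade (defaults follow the workflow)."""

    min_pass_ratio: float = 0.5
    min_bnd_gq: int = 20
    max_missing: float = 0.2
    maf_rare: float = 0.01          # rarity gate, applied per ancestry
    maf_lowfreq_max: float = 0.05   # common-SV exclusion
    thresholds: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    min_pass: int = 2
    min_pass_relative: bool = False
    min_sets: int = 2
    cancer_sets_union: bool = True
    known_tolerance: int = 200
    max_known_af: float = 0.01
    rare_boundary_exclusive: bool = False
    tra_intronic_is_plof: bool = True


@dataclass
class PipelineResult:
    calls: dict[str, PathogenicityCall]
    frequencies: dict[str, FrequencyRecord]
    annotations: dict[str, list[ImpactAnnotation]]
    matches: dict[str, MatchResult]
    funnel: dict[str, int]

    def final_classes(self) -> dict[str, str]:
        return {sv_id: c.final_class for sv_id, c in self.calls.items()}

    def final_pp(self) -> dict[str, str]:
        """sv_id -> class for the final PP / cautionary call set."""
        return {
            sv_id: c.final_class
            for sv_id, c in self.calls.items()
            if c.final_class in (PP_SV, CAUTIONARY)
        }

    def calls_table(self) -> pd.DataFrame:
        rows = []
        for sv_id in sorted(self.calls):
            c = self.calls[sv_id]
            f = self.frequencies.get(sv_id)
            genes = sorted(
                {a.gene_id for a in self.annotations.get(sv_id, []) if a.gene_id}
            )
            rows.append(
                {
                    "sv_id": sv_id,
                    "genes": ",".join(genes),
                    "final_class": c.final_class,
                    "rule": c.rule,
                    "n_tools_passed": c.n_tools_passed,
                    "cancer_related": c.cancer_related,
                    "clinvar_override": c.clinvar_override,
                    "maf_afr": None if f is None else f.maf_afr,
                    "maf_eur": None if f is None else f.maf_eur,
                }
            )
        return pd.DataFrame(rows)


def _disrupted_genes(impacts: Sequence[ImpactAnnotation]) -> list[str]:
    """Genes feeding the cancer-relevance gate: functionally impacted
    genes plus genes disrupted at a breakpoint (dosage events and
    fusions implicate both)."""
    genes: dict[str, None] = {}
    for a in impacts:
        if a.is_disruptive and a.gene_id is not None:
            genes.setdefault(a.gene_id)
    for a in impacts:
        if a.is_disruptive:
            for g in a.breakpoint_genes:
                genes.setdefault(g)
    return list(genes)


def prioritize(
    sites: list[CohortSite],
    genes: Sequence[GeneModel],
    known_table: Sequence[KnownSVEntry],
    score_panels: Mapping[str, ScorePanel],
    gene_sets: GeneSetCollection,
    roles: Mapping[str, str],
    enhancers: Optional[RegionSet] = None,
    promoters: Optional[RegionSet] = None,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run the full prioritization cascade over a genotyped cohort."""
    cfg = config or PipelineConfig()
    funnel: dict[str, int] = {}
    funnel["genotyped_sites"] = len(sites)

    # genotype QC
    sites = site_filter(sites, cfg.min_pass_ratio)
    funnel["site_pass"] = len(sites)
    for site in sites:
        mask_genotypes(site, cfg.min_bnd_gq)
    sites = missingness_filter(sites, cfg.max_missing)
    frequencies = {
        s.sv.id: compute_frequencies(
            s, rare_boundary_exclusive=cfg.rare_boundary_exclusive
        )
        for s in sites
    }
    sites = [
        s
        for s in sites
        if not frequencies[s.sv.id].remove_af1 and not frequencies[s.sv.id].undefined
    ]
    funnel["high_confidence"] = len(sites)

    # common-SV exclusion
    sites = [
        s for s in sites
        if (frequencies[s.sv.id].maf_combined or 0.0) <= cfg.maf_lowfreq_max
    ]
    funnel["rare_lowfreq"] = len(sites)

    # gene impact
    annotator = GenomeAnnotator(
        genes, promoters, enhancers, tra_intronic_is_plof=cfg.tra_intronic_is_plof
    )
    annotations = {s.sv.id: annotator.annotate(s.sv) for s in sites}
    disruptive = [
        s for s in sites if any(a.is_disruptive for a in annotations[s.sv.id])
    ]
    funnel["gene_disruptive"] = len(disruptive)

    # known-SV matching and classification gates
    matches: dict[str, MatchResult] = {}
    calls: dict[str, PathogenicityCall] = {}
    n_candidates = n_cancer = n_rare = n_after_af = 0
    empty_panel = ScorePanel(sv_id="")
    for site in disruptive:
        sv = site.sv
        impacts = annotations[sv.id]
        match = match_known(sv, known_table, cfg.known_tolerance)
        matches[sv.id] = match
        panel = score_panels.get(sv.id, empty_panel)
        candidate, n_passed, n_scored = consensus_candidate(
            panel, cfg.thresholds, cfg.min_pass, cfg.min_pass_relative
        )
        n_candidates += candidate
        cancer = candidate and cancer_relevance(
            _disrupted_genes(impacts), gene_sets, cfg.min_sets, cfg.cancer_sets_union
        )
        n_cancer += cancer
        freq = frequencies[sv.id]
        rare = (freq.maf_afr or 0.0) <= cfg.maf_rare and (
            freq.maf_eur or 0.0
        ) <= cfg.maf_rare
        rarity_ok = cancer and rare
        n_rare += rarity_ok
        freq_excluded = (
            match.max_reported_af is not None
            and match.max_reported_af >= cfg.max_known_af
        )
        n_after_af += rarity_ok and not freq_excluded
        calls[sv.id] = classify_final(
            sv,
            impacts,
            match,
            candidate=candidate,
            rarity_ok=rare,
            cancer_related=cancer,
            roles=roles,
            n_tools_passed=n_passed,
            n_tools_scored=n_scored,
            frequency_excluded=freq_excluded,
        )
    funnel["score_candidates"] = n_candidates
    funnel["cancer_related"] = n_cancer
    funnel["rare_candidates"] = n_rare
    funnel["after_known_af_exclusion"] = n_after_af
    funnel["final_pp"] = sum(
        1 for c in calls.values() if c.final_class in (PP_SV, CAUTIONARY)
    )
    return PipelineResult(
        calls=calls,
        frequencies=frequencies,
        annotations=annotations,
        matches=matches,
        funnel=funnel,
    )
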