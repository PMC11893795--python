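"""Synthetic cohort generator with known ground truth.

Generates, from a seed and a configuration, every input the
prioritization pipeline consumes: per-sample dual-caller call sets (with
breakpoint jitter, dropped calls, false positives and non-PASS labels),
a cohort-genotyped multi-sample site list with GT/FT/GQ noise, toy gene
models and enhancers, a known-SV archive with planted clinical labels
(3 pathogenic / likely-pathogenic and 10 benign controls by default),
impact-score panels, cancer gene sets, a gene-role table, carrier depth
tracks and breakpoint read evidence, and tumour copy-number segments
with planted LOH states.

The genome is deliberately tiny — three 5-Mb chromosomes with 48
regularly spaced genes — so a full end-to-end run takes seconds.
Planted SVs are constructed to exercise every branch of the cascade:
true potentially pathogenic variants (rare, well-scored, cancer-gene,
loss-of-TSG or gain-of-oncogene), and decoys that each fail exactly one
gate (too common, benign scores, non-cancer gene, oncogene loss,
archived at appreciable population frequency).

Planted carrier genotypes are emitted clean (no FT/GQ/missingness noise
on the carriers themselves) so that the planted truth remains observable
in the emitted files; all other genotypes receive the configured noise.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import io as svio
from .allelics import (
    BreakpointEvidence,
    CNSegment,
    DepthTrack,
    LOH_CNG,
    LOH_CNL,
    LOH_CNN,
    LOH_NEG,
    write_cn_segments,
    write_depth_track,
)
from .classify import (
    CAUTIONARY,
    GeneSetCollection,
    NOT_CANDIDATE,
    NO_ROLE,
    PP_SV,
    ScorePanel,
    TSG,
    ONCOGENE,
    CONFLICTING,
    UNLIKELY,
    write_gene_roles,
    write_gmt,
    write_score_panels,
)
from .genotypes import CohortSite, Genotype, write_cohort_vcf
from .known import (
    BENIGN,
    KnownSVEntry,
    LIKELY_PATHOGENIC,
    NO_SIGNIFICANCE,
    PATHOGENIC,
    write_known_table,
)
from .model import GeneModel, Region, RegionSet, SVRecord, SVType


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class CallerNoise:
    """Noise model for the two per-sample SV callers."""

    jitter_sd: float = 20.0       # breakpoint jitter (bases, per caller)
    drop_rate_a: float = 0.03     # per-call miss rate, caller A
    drop_rate_b: float = 0.03
    nonpass_rate: float = 0.05    # chance a reported call is non-PASS
    fp_per_sample: float = 2.0    # Poisson mean of caller-private calls


@dataclass
class DepthModel:
    mean_coverage: float = 46.0   # matches deep WGS germline data
    breakpoint_support: float = 0.45  # altered-read fraction at INV/TRA breakpoints


@dataclass
class PlantedSV:
    """Specification of one planted SV with its expected fate."""

    name: str
    svtype: SVType
    category: str                      # target impact: pLoF / CG / IED
    role: str = NO_ROLE                # curated role of the primary gene
    sets: tuple[str, ...] = ()         # cancer collections holding the gene
    carriers_afr: int = 0
    carriers_eur: int = 0
    score_profile: str = "pathogenic"  # "pathogenic" (>=2 tools) or "benign" (<=1)
    clinvar: Optional[str] = None      # significance planted in the known table
    in_known: bool = False
    known_af: Optional[float] = None
    partner_role: Optional[str] = None  # TRA partner gene role (None: no partner gene)
    partner_sets: tuple[str, ...] = ()
    expected_final: str = NOT_CANDIDATE
    loh: str = LOH_NEG
    second_hit: Optional[str] = None

    @property
    def sv_id(self) -> str:
        return f"sv_{self.name}"


def default_planted() -> list[PlantedSV]:
    """The default planting plan: positives, single-gate decoys and the
    clinical-archive control fixtures (3 pathogenic/likely-pathogenic,
    10 benign)."""
    planted = [
        # -- true potentially pathogenic SVs -------------------------------
        PlantedSV("P_DEL_TSG", SVType.DEL, "pLoF", role=TSG,
                  sets=("hallmark", "census"), carriers_afr=2,
                  in_known=True, known_af=1e-4, expected_final=PP_SV,
                  loh=LOH_CNN, second_hit="CNL"),
        PlantedSV("P_INV_TSG", SVType.INV, "pLoF", role=TSG,
                  sets=("hallmark", "oncogenic"), carriers_afr=1,
                  expected_final=PP_SV, loh=LOH_NEG, second_hit="CNG"),
        PlantedSV("P_TRA_FUSION", SVType.TRA, "pLoF", role=TSG,
                  sets=("hallmark",), partner_role=ONCOGENE,
                  partner_sets=("census",), carriers_afr=1,
                  expected_final=CAUTIONARY),
        PlantedSV("P_DUP_CG_ONC", SVType.DUP, "CG", role=ONCOGENE,
                  sets=("oncogenic", "census"), carriers_eur=1,
                  expected_final=PP_SV),
        PlantedSV("P_DUP_IED_ONC", SVType.DUP, "IED", role=ONCOGENE,
                  sets=("hallmark", "census"), carriers_afr=2,
                  expected_final=PP_SV, loh=LOH_CNG),
        PlantedSV("P_TRA_CONFL", SVType.TRA, "pLoF", role=CONFLICTING,
                  sets=("hallmark", "census"), carriers_afr=2,
                  expected_final=CAUTIONARY),
        # -- clinical-archive pathogenic controls --------------------------
        PlantedSV("C_PATH_DEL", SVType.DEL, "pLoF", role=NO_ROLE,
                  sets=("hallmark", "census"), carriers_afr=1,
                  clinvar=PATHOGENIC, in_known=True, known_af=1e-4,
                  expected_final=PP_SV, loh=LOH_CNL),
        PlantedSV("C_LPATH_DEL", SVType.DEL, "pLoF", role=NO_ROLE,
                  sets=("oncogenic", "census"), carriers_afr=1,
                  clinvar=LIKELY_PATHOGENIC, in_known=True, known_af=2e-4,
                  expected_final=PP_SV),
        PlantedSV("C_LPATH_DUP", SVType.DUP, "IED", role=NO_ROLE,
                  sets=("hallmark", "oncogenic"), carriers_afr=2,
                  clinvar=LIKELY_PATHOGENIC, in_known=True, known_af=1e-4,
                  expected_final=PP_SV, loh=LOH_CNG, second_hit="CNL"),
        # -- decoys: each fails exactly one gate ---------------------------
        PlantedSV("D_COMMON", SVType.DEL, "pLoF", role=TSG,
                  sets=("hallmark", "census"), carriers_afr=27, carriers_eur=14,
                  expected_final=NOT_CANDIDATE),
        PlantedSV("D_BENIGN_SCORES", SVType.DEL, "pLoF", role=TSG,
                  sets=("hallmark", "census"), carriers_afr=1,
                  score_profile="benign", expected_final=NOT_CANDIDATE),
        PlantedSV("D_NONCANCER", SVType.DEL, "pLoF", role=TSG,
                  sets=("hallmark",), carriers_afr=1,
                  expected_final=NOT_CANDIDATE),
        PlantedSV("D_ONC_LOSS", SVType.DEL, "pLoF", role=ONCOGENE,
                  sets=("hallmark", "census"), carriers_afr=1,
                  expected_final=UNLIKELY),
        PlantedSV("D_KNOWN_FREQ", SVType.DEL, "pLoF", role=TSG,
                  sets=("hallmark", "census"), carriers_afr=1,
                  in_known=True, known_af=0.03, expected_final=NOT_CANDIDATE),
    ]
    # clinical-archive benign controls: archived benign, scored benign
    for i in range(10):
        planted.append(
            PlantedSV(f"B_BENIGN_{i:02d}", SVType.DEL, "pLoF", role=NO_ROLE,
                      sets=(), carriers_afr=1 + i % 2,
                      score_profile="benign", clinvar=BENIGN,
                      in_known=True, known_af=1e-4,
                      expected_final=NOT_CANDIDATE)
        )
    return planted


@dataclass
class SimulationConfig:
    seed: int = 0
    n_afr: int = 113
    n_eur: int = 57
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 5_000_000), ("chr2", 5_000_000), ("chr3", 5_000_000)
    )
    genes_per_chrom: int = 16
    n_background_svs: int = 400
    missing_rate: float = 0.01
    ft_fail_rate: float = 0.03
    gq_low_rate: float = 0.03
    caller_noise: CallerNoise = field(default_factory=CallerNoise)
    depth: DepthModel = field(default_factory=DepthModel)
    planted: list[PlantedSV] = field(default_factory=default_planted)

    def __post_init__(self) -> None:
        if self.n_afr < 1 or self.n_eur < 1:
            raise ValueError("cohort sizes must be >= 1")
        if self.caller_noise.jitter_sd < 0:
            raise ValueError("jitter sd must be >= 0")
        for p in self.planted:
            if p.carriers_afr > self.n_afr or p.carriers_eur > self.n_eur:
                raise ValueError(f"{p.name}: more carriers than samples")


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class PlantedTruth:
    name: str
    sv_id: str
    svtype: str
    category: str
    expected_candidate: bool
    expected_cancer_related: bool
    expected_rare: bool
    expected_final: str
    clinvar: Optional[str]
    carriers: list[str]
    true_maf_afr: float
    true_maf_eur: float
    true_vaf: float
    gene_id: str
    loh: str


@dataclass
class GroundTruth:
    planted: list[PlantedTruth]
    background_ids: list[str]

    def by_id(self) -> dict[str, PlantedTruth]:
        return {t.sv_id: t for t in self.planted}


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_GENE_SPAN = 30_000
_EXON_LEN = 200
_EXON_STEP = 4_000
_N_EXONS = 8

_SCORE_PATHOGENIC = {
    SVType.DEL: dict(strvctvre=0.62, cadd_sv=16.0, postre=0.88, phenosv=0.74),
    SVType.DUP: dict(strvctvre=0.55, cadd_sv=14.0, postre=0.85, phenosv=0.66),
    SVType.INV: dict(strvctvre=None, cadd_sv=None, postre=0.91, phenosv=0.81),
    SVType.TRA: dict(strvctvre=None, cadd_sv=None, postre=0.86, phenosv=0.72),
}
_SCORE_BENIGN = {
    SVType.DEL: dict(strvctvre=0.12, cadd_sv=11.0, postre=0.21, phenosv=0.08),
    SVType.DUP: dict(strvctvre=0.09, cadd_sv=2.5, postre=0.30, phenosv=0.12),
    SVType.INV: dict(strvctvre=None, cadd_sv=None, postre=0.33, phenosv=0.15),
    SVType.TRA: dict(strvctvre=None, cadd_sv=None, postre=0.18, phenosv=0.22),
}


def _make_genes(config: SimulationConfig) -> list[GeneModel]:
    genes = []
    for chrom, length in config.genome:
        spacing = length // (config.genes_per_chrom + 1)
        for i in range(config.genes_per_chrom):
            start = spacing * (i + 1)
            exons = [
                (start + k * _EXON_STEP, start + k * _EXON_STEP + _EXON_LEN - 1)
                for k in range(_N_EXONS)
            ]
            gid = f"{chrom}_g{i:02d}"
            genes.append(
                GeneModel(
                    gene_id=gid,
                    gene_name=gid.upper(),
                    canonical_transcript=f"{gid}.t1",
                    chrom=chrom,
                    strand="+" if i % 2 == 0 else "-",
                    tx_start=start,
                    tx_end=start + _GENE_SPAN - 1,
                    exons=exons,
                    cds_start=start + 100,          # exon 1 partly 5' UTR
                    cds_end=exons[-1][1] - 100,     # exon 8 partly 3' UTR
                    canonical=True,
                )
            )
    return genes


def _planted_coords(p: PlantedSV, gene: GeneModel, partner: Optional[GeneModel]) -> SVRecord:
    """Place a planted SV on its gene so it earns the target category."""
    s = gene.tx_start
    if p.svtype is SVType.DEL:
        # remove coding exons 3-4
        return SVRecord(p.sv_id, gene.chrom, s + 7_800, gene.chrom, s + 13_500,
                        SVType.DEL, svlen=5_700)
    if p.svtype is SVType.DUP and p.category == "CG":
        return SVRecord(p.sv_id, gene.chrom, gene.tx_start - 5_000, gene.chrom,
                        gene.tx_end + 5_000, SVType.DUP,
                        svlen=gene.tx_end + 5_000 - (gene.tx_start - 5_000))
    if p.svtype is SVType.DUP:  # IED: intronic breakpoints around exon 5
        return SVRecord(p.sv_id, gene.chrom, s + 13_000, gene.chrom, s + 17_500,
                        SVType.DUP, svlen=4_500)
    if p.svtype is SVType.INV:
        # intronic breakpoints, inverted segment spans exons 3-6
        return SVRecord(p.sv_id, gene.chrom, s + 5_000, gene.chrom, s + 25_000,
                        SVType.INV, svlen=20_000, strands=("+", "+"))
    if p.svtype is SVType.TRA:
        if partner is not None:
            chrom2, pos2 = partner.chrom, partner.tx_start + 10_100
        else:
            # partner breakpoint lands intergenic on another chromosome
            chrom2 = "chr1" if gene.chrom != "chr1" else "chr2"
            pos2 = 50_000
        if chrom2 == gene.chrom:
            raise ValueError(f"{p.name}: TRA partner on same chromosome")
        return SVRecord(p.sv_id, gene.chrom, s + 10_100, chrom2, pos2,
                        SVType.TRA, strands=("+", "-"))
    raise ValueError(f"{p.name}: unsupported planted type {p.svtype}")


@dataclass
class SyntheticCohort:
    """Everything the pipeline needs, plus the ground truth."""

    config: SimulationConfig
    samples: list[str]
    ancestry: dict[str, str]
    genes: list[GeneModel]
    enhancers: RegionSet
    sites: list[CohortSite]
    known_table: list[KnownSVEntry]
    score_panels: dict[str, ScorePanel]
    gene_sets: GeneSetCollection
    roles: dict[str, str]
    caller_calls: dict[str, tuple[list[SVRecord], list[SVRecord]]]
    depth_tracks: dict[tuple[str, str], list[DepthTrack]]
    evidence: dict[tuple[str, str], BreakpointEvidence]
    cn_segments: dict[str, list[CNSegment]]
    somatic_events: dict[str, list[tuple[str, str]]]
    truth: GroundTruth

    @property
    def afr_samples(self) -> list[str]:
        return [s for s in self.samples if self.ancestry[s] == "AFR"]

    @property
    def eur_samples(self) -> list[str]:
        return [s for s in self.samples if self.ancestry[s] == "EUR"]


def generate_cohort(
    config: Optional[SimulationConfig] = None,
    out_dir: Optional[str] = None,
    caller_vcf_samples: Optional[Sequence[str]] = None,
) -> SyntheticCohort:
    """Generate the full synthetic cohort; optionally write the file bundle.

    Everything derives from ``config.seed`` through one generator, so
    identical configurations yield identical cohorts (and byte-identical
    bundles).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)

    samples = [f"AFR{i:04d}" for i in range(config.n_afr)] + [
        f"EUR{i:04d}" for i in range(config.n_eur)
    ]
    ancestry = {s: s[:3] for s in samples}
    afr_idx = np.arange(config.n_afr)
    eur_idx = np.arange(config.n_afr, config.n_afr + config.n_eur)

    genes = _make_genes(config)
    enhancers = RegionSet(
        "enhancers",
        [
            Region(g.chrom, g.tx_start - 8_000, g.tx_start - 7_000, g.gene_id)
            for g in genes[:10]
        ],
    )

    # -- assign planted SVs to genes --------------------------------------
    chroms = [c for c, _ in config.genome]
    gene_pool = {c: [g for g in genes if g.chrom == c] for c in chroms}
    cursor = {c: 0 for c in chroms}

    def next_gene(chrom: str) -> GeneModel:
        g = gene_pool[chrom][cursor[chrom]]
        cursor[chrom] += 1
        return g

    planted_svs: list[tuple[PlantedSV, SVRecord, GeneModel, Optional[GeneModel]]] = []
    for k, p in enumerate(config.planted):
        chrom = chroms[k % len(chroms)]
        gene = next_gene(chrom)
        partner = None
        if p.svtype is SVType.TRA and p.partner_role is not None:
            partner = next_gene(chroms[(k + 1) % len(chroms)])
        sv = _planted_coords(p, gene, partner)
        planted_svs.append((p, sv, gene, partner))

    # -- roles and cancer gene sets ----------------------------------------
    roles = {}
    set_members: dict[str, set[str]] = {"hallmark": set(), "oncogenic": set(), "census": set()}
    for p, _, gene, partner in planted_svs:
        if p.role != NO_ROLE:
            roles[gene.gene_id] = p.role
        for sname in p.sets:
            set_members[sname].add(gene.gene_id)
        if partner is not None:
            if p.partner_role and p.partner_role != NO_ROLE:
                roles[partner.gene_id] = p.partner_role
            for sname in p.partner_sets:
                set_members[sname].add(partner.gene_id)
    # pad collections with decoy members so none is empty or trivially small
    filler = [g.gene_id for g in genes if g.gene_id not in roles][-6:]
    set_members["hallmark"].add(filler[0])
    set_members["oncogenic"].add(filler[1])
    set_members["census"].add(filler[2])
    gene_sets = GeneSetCollection(
        hallmark=frozenset(set_members["hallmark"]),
        oncogenic_signatures=frozenset(set_members["oncogenic"]),
        cancer_census=frozenset(set_members["census"]),
    )

    # -- background SVs -----------------------------------------------------
    background: list[tuple[SVRecord, float, float]] = []  # (sv, af_afr, af_eur)
    for i in range(config.n_background_svs):
        chrom, length = config.genome[int(rng.integers(len(config.genome)))]
        svtype = [SVType.DEL, SVType.DUP, SVType.INV][int(rng.integers(3))]
        size = int(rng.integers(500, 20_000))
        pos1 = int(rng.integers(10_000, length - size - 10_000))
        af_afr = float(rng.beta(0.5, 10))
        af_eur = 0.0 if rng.random() < 0.45 else af_afr * float(rng.uniform(0.4, 1.2))
        if rng.random() < 0.10:
            af_afr, af_eur = 0.0, max(af_eur, float(rng.beta(0.5, 10)))
        af_eur = min(af_eur, 0.95)
        strands = ("+", "+") if svtype is SVType.INV else None
        sv = SVRecord(f"bg{i:04d}", chrom, pos1, chrom, pos1 + size, svtype,
                      svlen=size, strands=strands)
        background.append((sv, af_afr, af_eur))
    # one fixed-difference site: the reference genome carries the minor allele
    ref_sv = SVRecord("bg_af1", chroms[0], 4_900_000, chroms[0], 4_901_000,
                      SVType.DEL, svlen=1_000)

    # -- genotypes ----------------------------------------------------------
    n = len(samples)

    def noisy_site(sv: SVRecord, gt_alt: np.ndarray, clean: np.ndarray) -> CohortSite:
        """Wrap an alt-allele-count vector into a CohortSite with FT/GQ noise.

        ``clean`` marks samples whose genotype must stay unperturbed
        (planted carriers)."""
        is_bnd = sv.svtype in (SVType.INV, SVType.TRA)
        genotypes = []
        for j in range(n):
            alt = int(gt_alt[j])
            gt = ("0/0", "0/1", "1/1")[alt]
            ft: Optional[str] = None
            gq = int(rng.integers(30, 100))
            if clean[j]:
                if not is_bnd:
                    ft = "PASS"
                genotypes.append(Genotype(gt=gt, ft=ft, gq=gq))
                continue
            if rng.random() < config.missing_rate:
                gt = None
            if is_bnd:
                if rng.random() < config.gq_low_rate:
                    gq = int(rng.integers(0, 20))
            else:
                ft = "LowQual" if rng.random() < config.ft_fail_rate else "PASS"
            genotypes.append(Genotype(gt=gt, ft=ft, gq=gq))
        return CohortSite(sv=sv, samples=samples, genotypes=genotypes,
                          ancestry=ancestry, pass_ratio=None)

    sites: list[CohortSite] = []
    truth_planted: list[PlantedTruth] = []
    carrier_map: dict[str, list[str]] = {}

    for p, sv, gene, partner in planted_svs:
        gt_alt = np.zeros(n, dtype=int)
        chosen = []
        if p.carriers_afr:
            chosen.extend(rng.choice(afr_idx, size=p.carriers_afr, replace=False))
        if p.carriers_eur:
            chosen.extend(rng.choice(eur_idx, size=p.carriers_eur, replace=False))
        for j in chosen:
            gt_alt[j] = 1  # heterozygous carriers
        clean = np.zeros(n, dtype=bool)
        clean[list(chosen)] = True
        sites.append(noisy_site(sv, gt_alt, clean))
        carriers = [samples[int(j)] for j in sorted(chosen)]
        carrier_map[sv.id] = carriers
        maf_afr = p.carriers_afr / (2 * config.n_afr)
        maf_eur = p.carriers_eur / (2 * config.n_eur)
        true_vaf = {SVType.DEL: 0.5, SVType.DUP: 1.0 / 3.0}.get(
            p.svtype, config.depth.breakpoint_support
        )
        expected_rare = max(maf_afr, maf_eur) <= 0.01
        expected_final = p.expected_final
        if expected_final in (PP_SV, CAUTIONARY) and not expected_rare:
            # smaller cohorts cannot realise a <=1% MAF; the truth must
            # reflect the rarity gate the pipeline will actually apply
            expected_final = NOT_CANDIDATE
        truth_planted.append(
            PlantedTruth(
                name=p.name, sv_id=p.sv_id, svtype=p.svtype.value,
                category=p.category,
                expected_candidate=p.score_profile == "pathogenic",
                expected_cancer_related=len(set(p.sets) | set(p.partner_sets)) >= 2,
                expected_rare=expected_rare,
                expected_final=expected_final,
                clinvar=p.clinvar,
                carriers=carriers,
                true_maf_afr=maf_afr,
                true_maf_eur=maf_eur,
                true_vaf=true_vaf,
                gene_id=gene.gene_id,
                loh=p.loh,
            )
        )

    no_clean = np.zeros(n, dtype=bool)
    for sv, af_afr, af_eur in background:
        gt_alt = np.concatenate(
            [rng.binomial(2, af_afr, size=config.n_afr),
             rng.binomial(2, af_eur, size=config.n_eur)]
        )
        sites.append(noisy_site(sv, gt_alt, no_clean))
    sites.append(noisy_site(ref_sv, np.full(n, 2, dtype=int), no_clean))

    # -- known-SV archive ---------------------------------------------------
    known_table: list[KnownSVEntry] = []
    for p, sv, _, _ in planted_svs:
        if not (p.in_known or p.clinvar):
            continue
        offset = int(rng.integers(-150, 151))
        afs = []
        if p.known_af is not None:
            afs.append(("popstudy", "ALL", p.known_af))
        known_table.append(
            KnownSVEntry(
                entry_id=f"k_{p.name}",
                chrom1=sv.chrom1, pos1=sv.pos1 + offset,
                chrom2=sv.chrom2, pos2=sv.pos2 + offset,
                svtype=sv.svtype,
                clinical_significance=p.clinvar or NO_SIGNIFICANCE,
                reported_afs=afs,
            )
        )
    # unrelated archive entries that must not match anything
    for i in range(20):
        chrom, length = config.genome[int(rng.integers(len(config.genome)))]
        pos = int(rng.integers(100_000, length - 120_000))
        size = int(rng.integers(5_000, 80_000))
        known_table.append(
            KnownSVEntry(
                entry_id=f"k_random_{i:02d}",
                chrom1=chrom, pos1=pos, chrom2=chrom, pos2=pos + size,
                svtype=SVType.DUP if i % 2 else SVType.DEL,
                reported_afs=[("popstudy", "ALL", float(rng.beta(1, 50)))],
            )
        )

    # -- score panels -------------------------------------------------------
    score_panels: dict[str, ScorePanel] = {}
    for p, sv, _, _ in planted_svs:
        base = (_SCORE_PATHOGENIC if p.score_profile == "pathogenic"
                else _SCORE_BENIGN)[sv.svtype]
        score_panels[sv.id] = ScorePanel(sv_id=sv.id, **base)
    for sv, _, _ in background:
        base = dict(_SCORE_BENIGN[sv.svtype])
        # occasional single-tool pass, never two
        if rng.random() < 0.15:
            base["phenosv"] = float(rng.uniform(0.5, 0.9))
        score_panels[sv.id] = ScorePanel(sv_id=sv.id, **base)
    score_panels[ref_sv.id] = ScorePanel(sv_id=ref_sv.id, **_SCORE_BENIGN[SVType.DEL])

    # -- per-sample caller call sets ---------------------------------------
    noise = config.caller_noise
    caller_calls: dict[str, tuple[list[SVRecord], list[SVRecord]]] = {}

    def jitter(pos: int) -> int:
        if noise.jitter_sd == 0:
            return pos
        return max(1, pos + int(round(rng.normal(0, noise.jitter_sd))))

    def make_call(sv: SVRecord, caller: str, idx: int) -> list[SVRecord]:
        filt = "MinQUAL" if rng.random() < noise.nonpass_rate else "PASS"
        p1, p2 = jitter(sv.pos1), jitter(sv.pos2)
        if sv.chrom1 == sv.chrom2 and p1 > p2:
            p1, p2 = p2, p1
        rid = f"{caller}_{idx:05d}"
        if caller == "B" and sv.svtype in (SVType.INV, SVType.TRA):
            strands = sv.strands or ("+", "+")
            a = SVRecord(f"{rid}a", sv.chrom1, p1, sv.chrom2, p2, SVType.BND,
                         strands=strands, filter=filt, caller="callerB",
                         mate_id=f"{rid}b")
            b = SVRecord(f"{rid}b", sv.chrom2, p2, sv.chrom1, p1, SVType.BND,
                         strands=strands[::-1], filter=filt, caller="callerB",
                         mate_id=f"{rid}a")
            return [a, b]
        svlen = (p2 - p1) if sv.svtype in (SVType.DEL, SVType.DUP, SVType.INV) else None
        return [SVRecord(rid, sv.chrom1, p1, sv.chrom2, p2, sv.svtype,
                         svlen=svlen, strands=sv.strands, filter=filt,
                         caller="callerA" if caller == "A" else "callerB")]

    for si, sample in enumerate(samples):
        calls_a: list[SVRecord] = []
        calls_b: list[SVRecord] = []
        idx = 0
        for site in sites:
            g = site.genotypes[si]
            if g.gt is None or "1" not in g.gt:
                continue
            sv = site.sv
            if rng.random() >= noise.drop_rate_a:
                calls_a.extend(make_call(sv, "A", idx))
            if rng.random() >= noise.drop_rate_b:
                calls_b.extend(make_call(sv, "B", idx))
            idx += 1
        for caller, calls in (("A", calls_a), ("B", calls_b)):
            for _ in range(rng.poisson(noise.fp_per_sample)):
                chrom, length = config.genome[int(rng.integers(len(config.genome)))]
                size = int(rng.integers(300, 5_000))
                pos = int(rng.integers(10_000, length - size - 10_000))
                calls.append(
                    SVRecord(f"{caller}_fp_{idx:05d}", chrom, pos, chrom,
                             pos + size, SVType.DEL, svlen=size,
                             filter="PASS",
                             caller="callerA" if caller == "A" else "callerB")
                )
                idx += 1
        caller_calls[sample] = (calls_a, calls_b)

    # -- depth tracks, breakpoint evidence, tumour copy number -------------
    cov = config.depth.mean_coverage
    depth_tracks: dict[tuple[str, str], list[DepthTrack]] = {}
    evidence: dict[tuple[str, str], BreakpointEvidence] = {}
    cn_segments: dict[str, list[CNSegment]] = {}
    somatic_events: dict[str, list[tuple[str, str]]] = {}
    loh_cn = {LOH_NEG: (1, 1), LOH_CNL: (1, 0), LOH_CNN: (2, 0), LOH_CNG: (3, 0)}

    for (p, sv, gene, partner), t in zip(planted_svs, truth_planted):
        if p.expected_final not in (PP_SV, CAUTIONARY):
            continue
        for sample in t.carriers:
            key = (sv.id, sample)
            if sv.svtype in (SVType.DEL, SVType.DUP):
                factor = 0.5 if sv.svtype is SVType.DEL else 1.5
                start = sv.pos1 - 10_500
                flank_len, region_len = sv.pos1 - start, sv.pos2 - sv.pos1 + 1
                tail_len = 10_500
                depths = np.concatenate([
                    rng.poisson(cov, size=flank_len),
                    rng.poisson(cov * factor, size=region_len),
                    rng.poisson(cov, size=tail_len),
                ]).astype(float)
                depth_tracks[key] = [DepthTrack(sv.chrom1, start, depths)]
            else:
                tracks = []
                for chrom, pos in sv.breakpoints():
                    depths = rng.poisson(cov, size=601).astype(float)
                    tracks.append(DepthTrack(chrom, pos - 300, depths))
                depth_tracks[key] = tracks
                altered = int(rng.binomial(int(round(cov)),
                                           config.depth.breakpoint_support))
                split = int(rng.binomial(altered, 0.4)) if altered else 0
                evidence[key] = BreakpointEvidence(
                    sv_id=sv.id, discordant_pairs=altered - split, split_reads=split
                )
        # tumour copy number for the first carrier
        if t.carriers:
            patient = t.carriers[0]
            major, minor = loh_cn[p.loh]
            segs = cn_segments.setdefault(patient, [])
            segs.append(CNSegment(gene.chrom, max(1, gene.tx_start - 50_000),
                                  gene.tx_end + 50_000, major, minor))
            if p.second_hit:
                somatic_events.setdefault(patient, []).append(
                    (gene.gene_id, p.second_hit)
                )

    truth = GroundTruth(
        planted=truth_planted,
        background_ids=[sv.id for sv, _, _ in background] + [ref_sv.id],
    )
    cohort = SyntheticCohort(
        config=config, samples=samples, ancestry=ancestry, genes=genes,
        enhancers=enhancers, sites=sites, known_table=known_table,
        score_panels=score_panels, gene_sets=gene_sets, roles=roles,
        caller_calls=caller_calls, depth_tracks=depth_tracks,
        evidence=evidence, cn_segments=cn_segments,
        somatic_events=somatic_events, truth=truth,
    )
    if out_dir is not None:
        write_bundle(cohort, out_dir, caller_vcf_samples=caller_vcf_samples)
    return cohort


# ---------------------------------------------------------------------------
# Ground-truth comparison
# ---------------------------------------------------------------------------

def truth_compare(
    final_classes: dict[str, str], truth: GroundTruth
) -> dict[str, dict[str, float]]:
    """Per-stage confusion metrics for a pipeline run against the truth.

    ``final_classes`` maps every classified sv_id to its final class
    (SVs dropped before classification may be absent; they count as
    negatives).  Planted SVs expected in the final call set
    (PP_SV / cautionary) are positives; planted decoys and background
    SVs are negatives.  Raises when a planted sv id is entirely unknown
    to the run's universe.
    """
    known_ids = set(final_classes)
    pos_classes = (PP_SV, CAUTIONARY)
    tp = fn = fp = tn = 0
    for t in truth.planted:
        got = final_classes.get(t.sv_id, NOT_CANDIDATE)
        if t.expected_final in pos_classes:
            if got in pos_classes:
                tp += 1
            else:
                fn += 1
        else:
            if got in pos_classes:
                fp += 1
            else:
                tn += 1
    for sv_id in truth.background_ids:
        if final_classes.get(sv_id) in pos_classes:
            fp += 1
        else:
            tn += 1
    if tp + fn == 0:
        raise ValueError("truth contains no expected positives")
    return {
        "final": {
            "tp": tp, "fn": fn, "fp": fp, "tn": tn,
            "sensitivity": tp / (tp + fn),
            "specificity": tn / (tn + fp) if (tn + fp) else 1.0,
        }
    }


# ---------------------------------------------------------------------------
# File bundle
# ---------------------------------------------------------------------------

def write_bundle(
    cohort: SyntheticCohort,
    out_dir: str,
    caller_vcf_samples: Optional[Sequence[str]] = None,
) -> None:
    """Write the cohort as the file formats the pipeline consumes.

    ``caller_vcf_samples`` restricts per-sample caller VCF output (the
    cohort VCF always covers everyone)."""
    os.makedirs(out_dir, exist_ok=True)
    write_cohort_vcf(cohort.sites, os.path.join(out_dir, "cohort.vcf"))
    svio.write_gene_models(cohort.genes, os.path.join(out_dir, "genes.tsv"))
    svio.write_region_bed(cohort.enhancers, os.path.join(out_dir, "enhancers.bed"))
    write_known_table(cohort.known_table, os.path.join(out_dir, "known_svs.tsv"))
    write_score_panels(
        [cohort.score_panels[k] for k in sorted(cohort.score_panels)],
        os.path.join(out_dir, "scores.tsv"),
    )
    write_gmt(
        {
            "HALLMARK": cohort.gene_sets.hallmark,
            "ONCOGENIC": cohort.gene_sets.oncogenic_signatures,
            "CENSUS": cohort.gene_sets.cancer_census,
        },
        os.path.join(out_dir, "genesets.gmt"),
    )
    write_gene_roles(cohort.roles, os.path.join(out_dir, "roles.tsv"))
    with open(os.path.join(out_dir, "patients.tsv"), "w") as fh:
        fh.write("sample_id\tancestry\n")
        for s in cohort.samples:
            fh.write(f"{s}\t{cohort.ancestry[s]}\n")

    caller_dir = os.path.join(out_dir, "callers")
    os.makedirs(caller_dir, exist_ok=True)
    wanted = cohort.samples if caller_vcf_samples is None else list(caller_vcf_samples)
    for sample in wanted:
        calls_a, calls_b = cohort.caller_calls[sample]
        simple_a, _ = svio.resolve_breakends(calls_a)
        simple_b, _ = svio.resolve_breakends(calls_b)
        svio.write_sv_vcf(simple_a, os.path.join(caller_dir, f"{sample}_a.vcf"))
        svio.write_sv_vcf(simple_b, os.path.join(caller_dir, f"{sample}_b.vcf"))

    depth_dir = os.path.join(out_dir, "depth")
    os.makedirs(depth_dir, exist_ok=True)
    for (sv_id, sample), tracks in sorted(cohort.depth_tracks.items()):
        path = os.path.join(depth_dir, f"{sv_id}__{sample}.tsv")
        for i, track in enumerate(tracks):
            write_depth_track(track, path, mode="w" if i == 0 else "a")
    with open(os.path.join(out_dir, "evidence.tsv"), "w") as fh:
        fh.write("sv_id\tsample\tdiscordant\tsplit\n")
        for (sv_id, sample), ev in sorted(cohort.evidence.items()):
            fh.write(f"{sv_id}\t{sample}\t{ev.discordant_pairs}\t{ev.split_reads}\n")
    cn_dir = os.path.join(out_dir, "cn")
    os.makedirs(cn_dir, exist_ok=True)
    for patient, segs in sorted(cohort.cn_segments.items()):
        write_cn_segments(segs, os.path.join(cn_dir, f"{patient}.tsv"))

    truth_dict = {
        "planted": [dataclasses.asdict(t) for t in cohort.truth.planted],
        "background_ids": cohort.truth.background_ids,
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth_dict, fh, indent=1, sort_keys=True)
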