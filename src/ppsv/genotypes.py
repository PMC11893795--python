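"""Cohort-level genotype quality control and allele-frequency estimation.

The genotyped multi-sample VCF carries, per sample, a genotype (GT), a
genotype filter tag (FT) and a genotype quality (GQ).  The QC cascade is

1. :func:`site_filter` — keep sites whose fraction of passing genotype
   calls (``PASS_ratio``) is at least 0.5 and whose site FILTER is PASS;
2. :func:`mask_genotypes` — set individual genotypes to missing when
   FT is not PASS, or, for breakend-derived sites (INV/TRA) where FT is
   unavailable, when GQ < 20;
3. :func:`missingness_filter` — drop sites with a genotype missingness
   rate above 20% in *either* ancestry group.

Allele frequencies are then computed from the surviving (high-quality,
non-missing) genotype calls only, per ancestry and overall; sites where
every retained genotype is homozygous-alternate (AF = 100%, i.e. the
reference genome carries the minor allele) are flagged for removal.

Minor-allele-frequency rarity classes: rare (MAF <= 1%), low-frequency
(1% < MAF <= 5%), common (MAF > 5%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pysam
from scipy import stats

from . import io as svio
from .model import SVRecord, SVType

#: Site types derived from breakends, for which callers emit no FT tag.
BND_DERIVED_TYPES = frozenset({SVType.INV, SVType.TRA})

AFR = "AFR"
EUR = "EUR"


@dataclass
class Genotype:
    """One sample's call at one site.

    ``gt`` is ``"0/0"``, ``"0/1"``, ``"1/1"`` (or ``"0"``/``"1"`` on
    haploid chromosomes), or None when missing; ``ft`` is the genotype
    filter tag (None when the caller emits none); ``gq`` the genotype
    quality (0-99) or None.
    """

    gt: Optional[str]
    ft: Optional[str] = None
    gq: Optional[int] = None

    def alt_alleles(self) -> int:
        if self.gt is None:
            return 0
        return sum(1 for a in self.gt.split("/") if a == "1")

    def n_alleles(self) -> int:
        if self.gt is None:
            return 0
        return len(self.gt.split("/"))


@dataclass
class CohortSite:
    """A genotyped SV site across the whole cohort."""

    sv: SVRecord
    samples: Sequence[str]
    genotypes: list[Genotype]
    ancestry: dict[str, str]
    pass_ratio: Optional[float] = None
    site_filter: str = "PASS"

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.genotypes):
            raise ValueError(
                f"{self.sv.id}: {len(self.genotypes)} genotypes for "
                f"{len(self.samples)} samples"
            )

    @property
    def is_bnd_derived(self) -> bool:
        return self.sv.svtype in BND_DERIVED_TYPES

    def computed_pass_ratio(self) -> float:
        """Fraction of passing genotype calls over all samples.

        Where FT is unavailable (breakend-derived sites) a genotype
        counts as passing when it is called with GQ >= 20.
        """
        n = len(self.genotypes)
        if n == 0:
            return 0.0
        if self.is_bnd_derived:
            ok = sum(
                1
                for g in self.genotypes
                if g.gt is not None and g.gq is not None and g.gq >= 20
            )
        else:
            ok = sum(1 for g in self.genotypes if g.ft == "PASS")
        return ok / n

    def missing_fraction(self, group: Optional[str] = None) -> float:
        idx = [
            i
            for i, s in enumerate(self.samples)
            if group is None or self.ancestry.get(s) == group
        ]
        if not idx:
            raise ValueError(f"{self.sv.id}: no samples in ancestry group {group}")
        return sum(1 for i in idx if self.genotypes[i].gt is None) / len(idx)


# ---------------------------------------------------------------------------
# QC cascade
# ---------------------------------------------------------------------------

def site_filter(
    sites: list[CohortSite], min_pass_ratio: float = 0.5
) -> list[CohortSite]:
    """Keep sites with PASS_ratio >= ``min_pass_ratio`` and site FILTER PASS.

    The passing-genotype fraction is recomputed from FT/GQ when the site
    annotation is absent.
    """
    kept = []
    for site in sites:
        ratio = site.pass_ratio
        if ratio is None:
            ratio = site.computed_pass_ratio()
            site.pass_ratio = ratio
        if site.site_filter == "PASS" and ratio >= min_pass_ratio:
            kept.append(site)
    return kept


def mask_genotypes(site: CohortSite, min_bnd_gq: int = 20) -> CohortSite:
    """Set low-quality genotypes to missing, in place.

    Non-breakend sites: genotypes whose FT is not PASS become missing.
    Breakend-derived (INV/TRA) sites, where FT is unavailable: genotypes
    with GQ < ``min_bnd_gq`` become missing.
    """
    for g in site.genotypes:
        if g.gt is None:
            continue
        if site.is_bnd_derived:
            if g.gq is None or g.gq < min_bnd_gq:
                g.gt = None
        elif g.ft != "PASS":
            g.gt = None
    return site


def missingness_filter(
    sites: list[CohortSite],
    max_missing: float = 0.2,
    groups: Sequence[str] = (AFR, EUR),
) -> list[CohortSite]:
    """Drop sites missing in more than ``max_missing`` of either ancestry."""
    kept = []
    for site in sites:
        if not site.ancestry:
            raise ValueError(f"{site.sv.id}: ancestry labels are required")
        if all(site.missing_fraction(g) <= max_missing for g in groups):
            kept.append(site)
    return kept


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

RARITY_RARE = "rare"
RARITY_LOW = "low_frequency"
RARITY_COMMON = "common"


def rarity_class(maf: Optional[float], rare_boundary_exclusive: bool = False) -> Optional[str]:
    """Map a minor allele frequency onto {rare, low_frequency, common}.

    ``rare_boundary_exclusive`` moves a MAF of exactly 1% into the
    low-frequency class (some reports label the boundary that way).
    """
    if maf is None:
        return None
    if maf < 0 or maf > 0.5:
        raise ValueError(f"MAF {maf} outside [0, 0.5]")
    rare = maf < 0.01 if rare_boundary_exclusive else maf <= 0.01
    if rare:
        return RARITY_RARE
    if maf <= 0.05:
        return RARITY_LOW
    return RARITY_COMMON


@dataclass
class FrequencyRecord:
    """Ancestry-stratified allele frequencies for one site."""

    sv_id: str
    af_overall: Optional[float]
    af_afr: Optional[float]
    af_eur: Optional[float]
    maf_afr: Optional[float]
    maf_eur: Optional[float]
    n_alleles_afr: int
    n_alleles_eur: int
    carriers_afr: int
    carriers_eur: int
    rarity_afr: Optional[str]
    rarity_eur: Optional[str]
    rarity_combined: Optional[str]
    remove_af1: bool = False
    undefined: bool = False

    @property
    def maf_combined(self) -> Optional[float]:
        """The larger of the two ancestry MAFs (rarity must hold in both)."""
        mafs = [m for m in (self.maf_afr, self.maf_eur) if m is not None]
        return max(mafs) if mafs else None


def _group_counts(
    site: CohortSite, group: Optional[str], haploid: bool
) -> tuple[int, int, int]:
    """(alt alleles, total non-missing alleles, carrier count) in a group."""
    alt = total = carriers = 0
    for sample, g in zip(site.samples, site.genotypes):
        if group is not None and site.ancestry.get(sample) != group:
            continue
        if g.gt is None:
            continue
        a = g.alt_alleles()
        n = 1 if haploid else g.n_alleles()
        if haploid:
            a = min(a, 1)
        alt += a
        total += n
        carriers += 1 if a > 0 else 0
    return alt, total, carriers


def compute_frequencies(
    site: CohortSite,
    haploid_chroms: frozenset[str] = frozenset({"chrX", "chrY", "X", "Y"}),
    rare_boundary_exclusive: bool = False,
) -> FrequencyRecord:
    """Allele frequencies from high-quality (non-missing) genotypes only.

    All patients in the workflow are male, so sites on the chromosomes in
    ``haploid_chroms`` are counted as one allele per sample.  Sites whose
    overall AF is 1.0 are flagged for removal (they mark reference-genome
    minor alleles, not cohort variation); sites with zero non-missing
    genotypes are flagged undefined.
    """
    haploid = site.sv.chrom1 in haploid_chroms

    def freq(alt: int, total: int) -> Optional[float]:
        return alt / total if total > 0 else None

    alt_a, tot_a, car_a = _group_counts(site, AFR, haploid)
    alt_e, tot_e, car_e = _group_counts(site, EUR, haploid)
    alt_o, tot_o = alt_a + alt_e, tot_a + tot_e

    af_afr, af_eur = freq(alt_a, tot_a), freq(alt_e, tot_e)
    af_overall = freq(alt_o, tot_o)

    def maf(af: Optional[float]) -> Optional[float]:
        return None if af is None else min(af, 1.0 - af)

    maf_afr, maf_eur = maf(af_afr), maf(af_eur)
    rarity = lambda m: rarity_class(m, rare_boundary_exclusive)
    rec = FrequencyRecord(
        sv_id=site.sv.id,
        af_overall=af_overall,
        af_afr=af_afr,
        af_eur=af_eur,
        maf_afr=maf_afr,
        maf_eur=maf_eur,
        n_alleles_afr=tot_a,
        n_alleles_eur=tot_e,
        carriers_afr=car_a,
        carriers_eur=car_e,
        rarity_afr=rarity(maf_afr),
        rarity_eur=rarity(maf_eur),
        rarity_combined=rarity(maf(af_overall)) if af_overall is not None else None,
        remove_af1=af_overall == 1.0,
        undefined=af_overall is None,
    )
    return rec


@dataclass
class RankSumResult:
    median_a: float
    range_a: tuple[float, float]
    median_b: float
    range_b: tuple[float, float]
    statistic: float
    p_value: float


def per_genome_sv_count_test(
    counts_afr: Sequence[int], counts_eur: Sequence[int]
) -> RankSumResult:
    """Compare per-genome SV counts between ancestries.

    Returns group medians and ranges plus a two-sided Wilcoxon rank-sum
    (Mann-Whitney U) p-value.
    """
    if len(counts_afr) < 2 or len(counts_eur) < 2:
        raise ValueError("each group needs at least two genomes")
    a = np.asarray(counts_afr, dtype=float)
    b = np.asarray(counts_eur, dtype=float)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return RankSumResult(
        median_a=float(np.median(a)),
        range_a=(float(a.min()), float(a.max())),
        median_b=float(np.median(b)),
        range_b=(float(b.min()), float(b.max())),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


# ---------------------------------------------------------------------------
# Multi-sample VCF I/O
# ---------------------------------------------------------------------------

_COHORT_HEADER_EXTRA = [
    '##INFO=<ID=PASS_RATIO,Number=1,Type=Float,Description="Fraction of passing genotype calls">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=FT,Number=1,Type=String,Description="Genotype filter">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
]


def read_cohort_vcf(path: str, ancestry: dict[str, str]) -> list[CohortSite]:
    """Read a cohort-genotyped multi-sample SV VCF into CohortSite objects.

    ``ancestry`` maps sample id to AFR/EUR.  The per-site passing
    fraction is taken from the ``PASS_RATIO`` INFO key when present.
    """
    sites: list[CohortSite] = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf.fetch():
            sv = svio._convert_record(rec, caller=None)
            genotypes = []
            for s in samples:
                call = rec.samples[s]
                gt_tuple = call.get("GT")
                if gt_tuple is None or all(a is None for a in gt_tuple):
                    gt = None
                else:
                    gt = "/".join(str(a) for a in gt_tuple)
                ft = call.get("FT")
                gq = call.get("GQ")
                genotypes.append(
                    Genotype(gt=gt, ft=ft, gq=None if gq is None else int(gq))
                )
            pr = rec.info.get("PASS_RATIO")
            sites.append(
                CohortSite(
                    sv=sv,
                    samples=samples,
                    genotypes=genotypes,
                    ancestry=ancestry,
                    pass_ratio=None if pr is None else float(pr),
                    site_filter="PASS" if sv.filter == "PASS" else sv.filter,
                )
            )
    return sites


def write_cohort_vcf(sites: list[CohortSite], path: str) -> None:
    """Write cohort sites as a multi-sample VCF with GT/FT/GQ fields."""
    if not sites:
        raise ValueError("no sites to write")
    samples = list(sites[0].samples)
    contigs = sorted({s.sv.chrom1 for s in sites} | {s.sv.chrom2 for s in sites})
    header = svio._build_header(contigs, extra=_COHORT_HEADER_EXTRA)
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for site in sites:
            sv = site.sv
            rec = out.new_record(
                contig=sv.chrom1,
                start=sv.pos1 - 1,
                alleles=("N", f"<{sv.svtype.value}>"),
                id=sv.id,
            )
            rec.info["SVTYPE"] = sv.svtype.value
            if sv.svtype is SVType.TRA:
                rec.info["CHR2"] = sv.chrom2
                rec.info["END2"] = sv.pos2
                rec.stop = sv.pos1  # END on the record's own chromosome
            else:
                rec.stop = sv.pos2
            if sv.svlen is not None:
                rec.info["SVLEN"] = sv.svlen
            if site.pass_ratio is not None:
                rec.info["PASS_RATIO"] = round(site.pass_ratio, 6)
            rec.filter.add("PASS" if site.site_filter == "PASS" else "MinQUAL")
            for s, g in zip(site.samples, site.genotypes):
                call = rec.samples[s]
                if g.gt is None:
                    call["GT"] = (None,)
                else:
                    call["GT"] = tuple(int(a) for a in g.gt.split("/"))
                if g.ft is not None:
                    call["FT"] = g.ft
                if g.gq is not None:
                    call["GQ"] = g.gq
            out.write(rec)
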