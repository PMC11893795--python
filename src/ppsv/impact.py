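"""Breakpoint-based gene-impact annotation of structural variants.

Each SV is compared against the canonical transcript of every gene it
touches and assigned exactly one impact category per (SV, gene) pair:

========== ==================================================================
pLoF       predicted loss of function: a DEL removing coding exon sequence,
           an INV/TRA breakpoint severing the transcript, or a DUP with
           both breakpoints inside exons of one gene
CG         copy gain: a DUP fully containing the gene, raising its dosage
IED        intragenic exon duplication: DUP internal to a gene and fully
           containing at least one exon
partial_gene_DUP / partial_exon_DUP / whole_gene_INV / UTR / promoter /
intronic / intergenic
                                      no clear direct coding effect
========== ==================================================================

Only pLoF, CG and IED count as *gene-disruptive* downstream — they act
through gene inactivation or increased dosage; the remaining categories
are annotated for completeness but excluded from pathogenicity
classification.

Two further rules mirror the short-read reality of SV calling: for SVs
spanning more than 1 Mb only genes containing a breakpoint are annotated
(large spans are poorly resolved by short reads), and an SV is flagged
enhancer-disruptive for a gene when at least one breakpoint falls inside
an enhancer linked to that gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .model import GeneModel, Region, RegionSet, SVRecord, SVType

# impact categories
PLOF = "pLoF"
CG = "CG"
IED = "IED"
PARTIAL_GENE_DUP = "partial_gene_DUP"
PARTIAL_EXON_DUP = "partial_exon_DUP"
WHOLE_GENE_INV = "whole_gene_INV"
UTR = "UTR"
PROMOTER = "promoter"
INTRONIC = "intronic"
INTERGENIC = "intergenic"

#: Categories with a direct functional impact (inactivation or dosage).
DISRUPTIVE_CATEGORIES = frozenset({PLOF, CG, IED})

#: Span above which only breakpoint-overlapped genes are annotated.
LARGE_SV_SPAN = 1_000_000


@dataclass
class ImpactAnnotation:
    """Impact of one SV on one gene (or on no gene, for intergenic SVs)."""

    sv_id: str
    gene_id: Optional[str]
    category: str
    enhancer_hit: bool = False
    #: genes (by id) that contain one of the SV's breakpoints
    breakpoint_genes: list[str] = field(default_factory=list)
    #: "GENE1-GENE2" fusion label for translocations joining two genes
    fusion: Optional[str] = None

    @property
    def is_disruptive(self) -> bool:
        return self.category in DISRUPTIVE_CATEGORIES


def promoter_regions(genes: Sequence[GeneModel], window: int = 1000) -> RegionSet:
    """Derive promoters: a 1 kb window upstream of each TSS, strand-aware.

    For a plus-strand gene with TSS t the promoter is [t-window, t-1]
    (1-based inclusive); for a minus-strand gene [t+1, t+window].
    A window of zero yields an empty set.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    regions = []
    if window > 0:
        for g in genes:
            if g.strand == "+":
                start1, end1 = g.tss - window, g.tss - 1
            else:
                start1, end1 = g.tss + 1, g.tss + window
            if end1 < 1:
                continue
            start1 = max(start1, 1)
            regions.append(Region(g.chrom, start1 - 1, end1, g.gene_id))
    return RegionSet(name="promoters", intervals=regions)


def pick_canonical(transcripts: Sequence[GeneModel]) -> GeneModel:
    """Select one representative transcript for a gene.

    The flagged canonical transcript wins; without a flag the longest
    CDS, then the longest transcript, then the lexicographically
    smallest transcript id.
    """
    if not transcripts:
        raise ValueError("gene has no transcripts")
    flagged = [t for t in transcripts if t.canonical]
    pool = flagged if flagged else list(transcripts)
    return min(
        pool,
        key=lambda t: (-t.cds_length(), -t.transcript_length(), t.canonical_transcript),
    )


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _contains_point(iv: tuple[int, int], pos1: int) -> bool:
    """Whether half-open interval ``iv`` contains a 1-based position."""
    return iv[0] < pos1 <= iv[1]


class GenomeAnnotator:
    """Pre-indexed gene/promoter/enhancer annotation engine.

    Build once per genome, then call :meth:`annotate` per SV.  The
    decision table is evaluated per (SV, gene), first match wins; see the
    module docstring for the categories.
    """

    def __init__(
        self,
        genes: Sequence[GeneModel],
        promoters: Optional[RegionSet] = None,
        enhancers: Optional[RegionSet] = None,
        tra_intronic_is_plof: bool = True,
    ) -> None:
        self.genes = {g.gene_id: g for g in genes}
        if promoters is None:
            promoters = promoter_regions(genes)
        self.promoters = promoters
        self.enhancers = enhancers or RegionSet("enhancers", [])
        self.tra_intronic_is_plof = tra_intronic_is_plof

        self._gene_tree: dict[str, IntervalTree] = {}
        for g in genes:
            lo, hi = g.tx_interval()
            self._gene_tree.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g.gene_id)
        self._prom_tree: dict[str, IntervalTree] = {}
        for r in self.promoters:
            self._prom_tree.setdefault(r.chrom, IntervalTree()).addi(
                r.start, r.end, r.linked_gene
            )
        self._enh_by_gene: dict[str, list[Region]] = {}
        for r in self.enhancers:
            if r.linked_gene is not None:
                self._enh_by_gene.setdefault(r.linked_gene, []).append(r)

    # -- lookups -----------------------------------------------------------

    def _genes_overlapping(self, chrom: str, lo: int, hi: int) -> set[str]:
        tree = self._gene_tree.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(lo, hi)}

    def _genes_at_point(self, chrom: str, pos1: int) -> set[str]:
        tree = self._gene_tree.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(pos1 - 1)}

    def _breakpoint_genes(self, sv: SVRecord) -> list[str]:
        found: dict[str, None] = {}
        for chrom, pos in sv.breakpoints():
            for gid in sorted(self._genes_at_point(chrom, pos)):
                found.setdefault(gid)
        return list(found)

    def _enhancer_hit(self, sv: SVRecord, gene_id: str) -> bool:
        for region in self._enh_by_gene.get(gene_id, ()):
            if any(region.contains(c, p) for c, p in sv.breakpoints()):
                return True
        return False

    def _promoter_genes(self, sv: SVRecord, breakpoints_only: bool = False) -> set[str]:
        hits: set[str] = set()
        if (
            sv.chrom1 == sv.chrom2
            and sv.svtype is not SVType.TRA
            and not breakpoints_only
        ):
            _, lo, hi = sv.span_interval()
            tree = self._prom_tree.get(sv.chrom1)
            if tree is not None:
                hits |= {iv.data for iv in tree.overlap(lo, hi)}
        else:
            for chrom, pos in sv.breakpoints():
                tree = self._prom_tree.get(chrom)
                if tree is not None:
                    hits |= {iv.data for iv in tree.at(pos - 1)}
        return hits

    # -- per-gene decision table -------------------------------------------

    def _categorize(self, sv: SVRecord, gene: GeneModel) -> Optional[str]:
        tx = gene.tx_interval()
        exons = gene.exon_intervals()
        cds = gene.cds_interval()
        bp_inside = [
            _contains_point(tx, pos)
            for chrom, pos in sv.breakpoints()
            if chrom == gene.chrom
        ]
        any_bp_inside = any(bp_inside)

        if sv.svtype is SVType.TRA:
            return self._categorize_tra(sv, gene)

        if sv.chrom1 != gene.chrom:
            return None
        _, lo, hi = sv.span_interval()
        sv_iv = (lo, hi)
        if _overlap(sv_iv, tx) == 0:
            return None

        if sv.svtype is SVType.INS:
            # insertions are retained for containment only: no coding
            # category beyond intronic placement
            return INTRONIC if any_bp_inside else None

        if sv.svtype is SVType.DEL:
            def coding_part(exon: tuple[int, int]) -> tuple[int, int]:
                if cds is None:
                    return exon
                return max(exon[0], cds[0]), min(exon[1], cds[1])

            removes_coding = any(
                _overlap(sv_iv, coding_part(e)) > 0 for e in exons
            )
            if removes_coding:
                return PLOF
            if any(_overlap(sv_iv, e) > 0 for e in exons):
                return UTR
            return INTRONIC

        if sv.svtype is SVType.DUP:
            contains_gene = lo <= tx[0] and hi >= tx[1]
            if contains_gene:
                return CG
            both_inside = len(bp_inside) == 2 and all(bp_inside)
            if both_inside:
                if any(lo <= e[0] and hi >= e[1] for e in exons):
                    return IED
                bp_in_exon = [
                    any(_contains_point(e, pos) for e in exons)
                    for chrom, pos in sv.breakpoints()
                ]
                if all(bp_in_exon):
                    return PLOF
                return PARTIAL_EXON_DUP
            if any_bp_inside:
                return PARTIAL_GENE_DUP
            return None

        if sv.svtype is SVType.INV:
            contains_gene = lo <= tx[0] and hi >= tx[1]
            if contains_gene and not any_bp_inside:
                return WHOLE_GENE_INV
            if any_bp_inside:
                inner = (max(lo, tx[0]), min(hi, tx[1]))
                if any(_overlap(inner, e) > 0 for e in exons):
                    return PLOF
                return INTRONIC
            return None

        raise ValueError(f"{sv.id}: cannot annotate svtype {sv.svtype}")

    def _categorize_tra(self, sv: SVRecord, gene: GeneModel) -> Optional[str]:
        """A translocation breakpoint inside the coding span severs the
        transcript; breakpoints upstream/downstream of the CDS within the
        transcript are UTR hits."""
        tx = gene.tx_interval()
        cds = gene.cds_interval() or tx
        exons = gene.exon_intervals()
        for chrom, pos in sv.breakpoints():
            if chrom != gene.chrom or not _contains_point(tx, pos):
                continue
            if _contains_point(cds, pos):
                if self.tra_intronic_is_plof:
                    return PLOF
                in_exon = any(_contains_point(e, pos) for e in exons)
                return PLOF if in_exon else INTRONIC
            return UTR
        return None

    # -- public entry point ------------------------------------------------

    def annotate(self, sv: SVRecord) -> list[ImpactAnnotation]:
        """Annotate one SV against every gene it touches.

        Returns at least one annotation; SVs hitting neither a gene nor a
        promoter yield a single intergenic row with no gene id.
        """
        if sv.svtype is SVType.BND:
            raise ValueError(f"{sv.id}: resolve breakends before annotation")

        bp_genes = self._breakpoint_genes(sv)
        large = sv.span is not None and sv.span > LARGE_SV_SPAN

        if sv.svtype is SVType.TRA or large:
            candidates = list(bp_genes)
        else:
            _, lo, hi = sv.span_interval()
            candidates = sorted(self._genes_overlapping(sv.chrom1, lo, hi))

        fusion = self._fusion_label(sv)
        annotations: list[ImpactAnnotation] = []
        for gid in candidates:
            category = self._categorize(sv, self.genes[gid])
            if category is None:
                continue
            annotations.append(
                ImpactAnnotation(
                    sv_id=sv.id,
                    gene_id=gid,
                    category=category,
                    enhancer_hit=self._enhancer_hit(sv, gid),
                    breakpoint_genes=list(bp_genes),
                    fusion=fusion,
                )
            )
        covered = {a.gene_id for a in annotations}
        for gid in sorted(self._promoter_genes(sv, breakpoints_only=large) - covered):
            annotations.append(
                ImpactAnnotation(
                    sv_id=sv.id,
                    gene_id=gid,
                    category=PROMOTER,
                    enhancer_hit=self._enhancer_hit(sv, gid),
                    breakpoint_genes=list(bp_genes),
                    fusion=fusion,
                )
            )
        if not annotations:
            annotations.append(
                ImpactAnnotation(
                    sv_id=sv.id,
                    gene_id=None,
                    category=INTERGENIC,
                    breakpoint_genes=list(bp_genes),
                )
            )
        return annotations

    def _fusion_label(self, sv: SVRecord) -> Optional[str]:
        """"GENE1-GENE2" when a TRA's breakpoints land in two different
        genes, ordered by breakpoint (chrom, pos)."""
        if sv.svtype is not SVType.TRA:
            return None
        partners = []
        for chrom, pos in sorted(sv.breakpoints()):
            hits = sorted(self._genes_at_point(chrom, pos))
            if hits:
                partners.append(self.genes[hits[0]].gene_name)
        if len(partners) == 2 and partners[0] != partners[1]:
            return f"{partners[0]}-{partners[1]}"
        return None


def annotate_sv(
    sv: SVRecord,
    genes: Sequence[GeneModel],
    promoters: Optional[RegionSet] = None,
    enhancers: Optional[RegionSet] = None,
    **kwargs,
) -> list[ImpactAnnotation]:
    """Convenience wrapper building a throw-away :class:`GenomeAnnotator`."""
    return GenomeAnnotator(genes, promoters, enhancers, **kwargs).annotate(sv)
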