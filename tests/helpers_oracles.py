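"""Independent brute-force oracles used to validate the fast paths.

Each oracle recomputes its answer from first principles (all-pairs scans
with repeated global-minimum selection, per-base membership sets) rather
than reusing the package's interval arithmetic.
"""

from __future__ import annotations

from ppsv.model import GeneModel, SVRecord, SVType


# ---------------------------------------------------------------------------
# Concordance / known-SV matching oracle: all-pairs + repeated global min
# ---------------------------------------------------------------------------

def _pair_distance(a: SVRecord, b) -> tuple[int, int] | None:
    """Distances between two same-type variants; b may be an SVRecord or a
    known-SV entry exposing chrom1/pos1/chrom2/pos2/svtype."""
    if a.svtype != SVType(b.svtype):
        return None
    anchors_a = [(a.chrom1, a.pos1), (a.chrom2, a.pos2)]
    anchors_b = [(b.chrom1, b.pos1), (b.chrom2, b.pos2)]
    if a.svtype is SVType.TRA:
        options = []
        for order in (anchors_b, anchors_b[::-1]):
            if anchors_a[0][0] == order[0][0] and anchors_a[1][0] == order[1][0]:
                options.append(
                    (abs(anchors_a[0][1] - order[0][1]),
                     abs(anchors_a[1][1] - order[1][1]))
                )
        if not options:
            return None
        return min(options, key=sum)
    if a.chrom1 != b.chrom1 or a.chrom2 != b.chrom2:
        return None
    return abs(a.pos1 - b.pos1), abs(a.pos2 - b.pos2)


def oracle_match_calls(set_a, set_b, tolerance=200, require_both_pass=False):
    """All-pairs greedy matching by repeated global-minimum selection.

    Returns the set of matched (id_a, id_b) pairs.
    """
    candidates = []
    for ia, a in enumerate(set_a):
        for ib, b in enumerate(set_b):
            ok_pass = (a.is_pass and b.is_pass) if require_both_pass else (
                a.is_pass or b.is_pass
            )
            if not ok_pass:
                continue
            d = _pair_distance(a, b)
            if d is None or d[0] > tolerance or d[1] > tolerance:
                continue
            candidates.append((ia, ib, d))
    matched = set()
    used_a, used_b = set(), set()
    while True:
        best = None
        for ia, ib, (d1, d2) in candidates:
            if ia in used_a or ib in used_b:
                continue
            key = (d1 + d2, set_a[ia].pos1, set_a[ia].id, set_b[ib].id)
            if best is None or key < best[0]:
                best = (key, ia, ib)
        if best is None:
            return matched
        _, ia, ib = best
        matched.add((set_a[ia].id, set_b[ib].id))
        used_a.add(ia)
        used_b.add(ib)


def oracle_match_known(sv: SVRecord, table, tolerance=200):
    """Best-entry selection by exhaustive scan; returns entry_id or None."""
    best = None
    for entry in table:
        d = _pair_distance(sv, entry)
        if d is None or d[0] > tolerance or d[1] > tolerance:
            continue
        key = (d[0] + d[1], entry.clinical_significance == "none", entry.entry_id)
        if best is None or key < best[0]:
            best = (key, entry.entry_id)
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# Gene-impact oracle: per-base membership sets
# ---------------------------------------------------------------------------

def oracle_impact(sv: SVRecord, gene: GeneModel, tra_intronic_is_plof=True):
    """Impact category of one SV on one gene, from explicit base sets.

    Mirrors the decision table but derives every overlap / containment
    from 1-based base-membership sets, catching off-by-one errors in the
    interval arithmetic.  Returns the category string or None.
    """
    gene_bases = set(range(gene.tx_start, gene.tx_end + 1))
    exon_bases = set()
    for s, e in gene.exons:
        exon_bases.update(range(s, e + 1))
    if gene.cds_start is not None:
        cds_span = set(range(gene.cds_start, gene.cds_end + 1))
    else:
        cds_span = set(gene_bases)
    coding_bases = exon_bases & cds_span

    breakpoints = [
        pos for chrom, pos in sv.breakpoints() if chrom == gene.chrom
    ]
    bp_inside = [pos in gene_bases for pos in breakpoints]

    if sv.svtype is SVType.TRA:
        for pos, inside in zip(breakpoints, bp_inside):
            if not inside:
                continue
            if pos in cds_span:
                if tra_intronic_is_plof or pos in exon_bases:
                    return "pLoF"
                return "intronic"
            return "UTR"
        return None

    sv_bases = set(range(sv.pos1, sv.pos2 + 1))
    if not (sv_bases & gene_bases):
        return None

    if sv.svtype is SVType.INS:
        return "intronic" if any(bp_inside) else None

    if sv.svtype is SVType.DEL:
        if sv_bases & coding_bases:
            return "pLoF"
        if sv_bases & exon_bases:
            return "UTR"
        return "intronic"

    if sv.svtype is SVType.DUP:
        if gene_bases <= sv_bases:
            return "CG"
        if len(bp_inside) == 2 and all(bp_inside):
            contains_exon = any(
                set(range(s, e + 1)) <= sv_bases for s, e in gene.exons
            )
            if contains_exon:
                return "IED"
            if all(pos in exon_bases for pos in breakpoints):
                return "pLoF"
            return "partial_exon_DUP"
        if any(bp_inside):
            return "partial_gene_DUP"
        return None

    if sv.svtype is SVType.INV:
        if gene_bases <= sv_bases and not any(bp_inside):
            return "whole_gene_INV"
        if any(bp_inside):
            if sv_bases & gene_bases & exon_bases:
                return "pLoF"
            return "intronic"
        return None

    raise AssertionError(f"unexpected type {sv.svtype}")
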