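"""Dual-caller concordance: the high-confidence per-sample SV set.

Two calls from different callers support the same variant when they have
the same SV type, the same chromosome anchors, both breakpoint positions
within a tolerance (default 200 bases) of each other, and at least one of
the two is a PASS call.  Matching is one-to-one and greedy by minimal
summed breakpoint distance, so the concordant set can serve directly as a
deduplicated site list for downstream genotyping.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

from .model import Caller, SVRecord, SVType


@dataclass
class ConcordanceResult:
    """Outcome of matching two call sets from one sample."""

    concordant: list[SVRecord] = field(default_factory=list)
    only_a: list[SVRecord] = field(default_factory=list)
    only_b: list[SVRecord] = field(default_factory=list)
    #: one (id_a, id_b, distance1, distance2) row per accepted match
    match_log: list[tuple[str, str, int, int]] = field(default_factory=list)


def _anchor_distances(a: SVRecord, b: SVRecord) -> tuple[int, int] | None:
    """Breakpoint distances between two same-type records, or None.

    TRA anchors are compared orderlessly: both pairings of the two
    (chrom, pos) anchors are tried and the closer valid one is used.
    """
    if a.svtype is SVType.TRA:
        best = None
        pairings = (
            ((a.chrom1, a.pos1, a.chrom2, a.pos2), (b.chrom1, b.pos1, b.chrom2, b.pos2)),
            ((a.chrom1, a.pos1, a.chrom2, a.pos2), (b.chrom2, b.pos2, b.chrom1, b.pos1)),
        )
        for (c1, p1, c2, p2), (d1, q1, d2, q2) in pairings:
            if c1 == d1 and c2 == d2:
                dist = (abs(p1 - q1), abs(p2 - q2))
                if best is None or sum(dist) < sum(best):
                    best = dist
        return best
    if a.chrom1 != b.chrom1:
        return None
    return abs(a.pos1 - b.pos1), abs(a.pos2 - b.pos2)


def match_calls(
    set_a: list[SVRecord],
    set_b: list[SVRecord],
    tolerance: int = 200,
    require_both_pass: bool = False,
) -> ConcordanceResult:
    """Intersect two caller call sets under the breakpoint-distance rule.

    Parameters
    ----------
    set_a, set_b:
        Call sets from the two callers for the same sample, with BND
        records already resolved to simple types.
    tolerance:
        Maximum distance (bases) allowed at *each* breakpoint.
    require_both_pass:
        When True, both members must be PASS; the default accepts a pair
        with at least one PASS call.

    Each record matches at most one partner.  Candidate pairs are ranked
    by summed breakpoint distance, ties broken by smaller first
    breakpoint position, then by the pair's identifiers.  The merged
    record keeps the callerA member's coordinates (the dialect consumed
    by the downstream genotyper).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")

    candidates: list[tuple[int, int, str, str, int, int, int, int]] = []
    for ia, a in enumerate(set_a):
        for ib, b in enumerate(set_b):
            if a.svtype is not b.svtype:
                continue
            if require_both_pass:
                if not (a.is_pass and b.is_pass):
                    continue
            elif not (a.is_pass or b.is_pass):
                continue
            dist = _anchor_distances(a, b)
            if dist is None:
                continue
            d1, d2 = dist
            if d1 <= tolerance and d2 <= tolerance:
                candidates.append((d1 + d2, a.pos1, a.id, b.id, ia, ib, d1, d2))

    candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    result = ConcordanceResult()
    for total, _pos, id_a, id_b, ia, ib, d1, d2 in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        merged = replace(set_a[ia], caller=Caller.MERGED, filter="PASS")
        result.concordant.append(merged)
        result.match_log.append((id_a, id_b, d1, d2))
    result.only_a = [r for i, r in enumerate(set_a) if i not in used_a]
    result.only_b = [r for i, r in enumerate(set_b) if i not in used_b]
    return result
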