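"""Variant allele fractions and tumour loss-of-heterozygosity calls.

The VAF of a germline SV is the fraction of sequencing evidence
supporting the variant allele — about 0.5 for a heterozygous carrier.

* DEL/DUP use read depth: the altered read count is the mean depth
  difference between the SV region and its +/-10 kb flanks; the total is
  the flank mean for a DEL and the region mean for a DUP.
* INV/TRA use breakpoint evidence: discordantly-aligned read pairs plus
  split reads (each read counted once) within +/-150 bases of the
  breakpoints, over the mean depth in those windows.  This can
  underestimate the true VAF, since a read showing both signals is
  counted once and some non-reference pairs still align properly.

Tumour LOH is called from purity/ploidy-adjusted allele-specific copy
number: a gene whose minor allele copy number is zero has LOH, subtyped
by the remaining major copy number — hemizygous loss (LOH_CNL, major 1),
copy-neutral (LOH_CNN, major 2) or amplification (LOH_CNG, major >= 3).
A somatic copy-number event on a germline-hit gene is a candidate
second hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import SVRecord, SVType

DEPTH_DEL = "depth_del"
DEPTH_DUP = "depth_dup"
BREAKPOINT_READS = "breakpoint_reads"

LOH_CNL = "LOH_CNL"
LOH_CNN = "LOH_CNN"
LOH_CNG = "LOH_CNG"
LOH_NEG = "LOH_neg"
LOH_UNDETERMINED = "undetermined"

#: ordering used to break coverage ties: prefer the more altered status
_LOH_SEVERITY = {LOH_UNDETERMINED: -1, LOH_NEG: 0, LOH_CNG: 1, LOH_CNN: 2, LOH_CNL: 3}


@dataclass
class DepthTrack:
    """Per-base read depth over one contiguous chromosome window."""

    chrom: str
    start: int  # 1-based position of depth[0]
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    @property
    def end(self) -> int:
        """Last covered 1-based position."""
        return self.start + len(self.depth) - 1

    def values(self, start1: int, end1: int) -> np.ndarray:
        """Per-base depths over a 1-based inclusive range (must be covered)."""
        if start1 < self.start or end1 > self.end or start1 > end1:
            raise ValueError(
                f"range {start1}-{end1} outside track "
                f"{self.chrom}:{self.start}-{self.end}"
            )
        off = start1 - self.start
        return self.depth[off : off + (end1 - start1 + 1)]

    def mean_depth(self, start1: int, end1: int) -> float:
        """Arithmetic mean depth including zero-depth bases."""
        return float(self.values(start1, end1).mean())


@dataclass
class BreakpointEvidence:
    """Read evidence at an SV's breakpoints, deduplicated per read."""

    sv_id: str
    discordant_pairs: int
    split_reads: int

    def __post_init__(self) -> None:
        if self.discordant_pairs < 0 or self.split_reads < 0:
            raise ValueError(f"{self.sv_id}: negative evidence counts")

    @property
    def altered_reads(self) -> int:
        return self.discordant_pairs + self.split_reads


@dataclass
class VAFEstimate:
    sv_id: str
    vaf: float
    altered: float
    total: float
    method: str
    #: breakpoint-evidence estimates may undercount the variant allele
    possibly_conservative: bool = False


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def vaf_depth(sv: SVRecord, track: DepthTrack, flank: int = 10_000) -> VAFEstimate:
    """Depth-based VAF for a DEL or DUP.

    DEL: (flank mean - region mean) / flank mean.
    DUP: (region mean - flank mean) / region mean.
    Both flanks are pooled into a single per-base mean; the result is
    clamped into [0, 1].
    """
    if sv.svtype not in (SVType.DEL, SVType.DUP):
        raise ValueError(f"{sv.id}: depth-based VAF applies to DEL/DUP only")
    region = track.values(sv.pos1, sv.pos2)
    flanks = np.concatenate(
        [
            track.values(max(track.start, sv.pos1 - flank), sv.pos1 - 1),
            track.values(sv.pos2 + 1, min(track.end, sv.pos2 + flank)),
        ]
    )
    mean_region = float(region.mean())
    mean_flank = float(flanks.mean())
    if sv.svtype is SVType.DEL:
        if mean_flank == 0:
            raise ValueError(f"{sv.id}: zero flank depth, VAF undefined")
        vaf = (mean_flank - mean_region) / mean_flank
        altered, total, method = mean_flank - mean_region, mean_flank, DEPTH_DEL
    else:
        if mean_region == 0:
            raise ValueError(f"{sv.id}: zero region depth, VAF undefined")
        vaf = (mean_region - mean_flank) / mean_region
        altered, total, method = mean_region - mean_flank, mean_region, DEPTH_DUP
    return VAFEstimate(
        sv_id=sv.id, vaf=_clamp01(vaf), altered=altered, total=total, method=method
    )


def vaf_breakpoint(
    sv: SVRecord,
    evidence: BreakpointEvidence,
    tracks: DepthTrack | Sequence[DepthTrack],
    window: int = 150,
) -> VAFEstimate:
    """Breakpoint-evidence VAF for an INV or TRA.

    The denominator is the mean per-base depth over the union of the
    +/-``window`` windows around both breakpoints (one track per
    chromosome for a TRA).
    """
    if sv.svtype not in (SVType.INV, SVType.TRA):
        raise ValueError(f"{sv.id}: breakpoint VAF applies to INV/TRA only")
    if isinstance(tracks, DepthTrack):
        tracks = [tracks]
    pooled: list[np.ndarray] = []
    for chrom, pos in sv.breakpoints():
        track = next((t for t in tracks if t.chrom == chrom and t.start <= pos <= t.end), None)
        if track is None:
            raise ValueError(f"{sv.id}: no depth track covers {chrom}:{pos}")
        pooled.append(
            track.values(max(track.start, pos - window), min(track.end, pos + window))
        )
    mean_depth = float(np.concatenate(pooled).mean())
    if mean_depth == 0:
        raise ValueError(f"{sv.id}: zero breakpoint depth, VAF undefined")
    altered = evidence.altered_reads
    return VAFEstimate(
        sv_id=sv.id,
        vaf=_clamp01(altered / mean_depth),
        altered=float(altered),
        total=mean_depth,
        method=BREAKPOINT_READS,
        possibly_conservative=True,
    )


@dataclass
class CNSegment:
    """Purity/ploidy-adjusted allele-specific copy-number segment."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    major_cn: int
    minor_cn: int
    adjusted: bool = True

    def __post_init__(self) -> None:
        if self.minor_cn < 0 or self.major_cn < self.minor_cn:
            raise ValueError(
                f"invalid allele copy numbers ({self.major_cn}, {self.minor_cn})"
            )

    def status(self) -> str:
        if self.minor_cn > 0:
            return LOH_NEG
        if self.major_cn <= 1:
            return LOH_CNL
        if self.major_cn == 2:
            return LOH_CNN
        return LOH_CNG


@dataclass
class LOHCall:
    gene_id: str
    status: str
    major_cn: Optional[int] = None
    minor_cn: Optional[int] = None


def classify_loh(
    gene_id: str,
    gene_region: tuple[str, int, int],
    segments: Sequence[CNSegment],
) -> LOHCall:
    """LOH status of a gene from the segment covering most of it.

    ``gene_region`` is (chrom, start, end), 1-based inclusive.  Ties on
    covered length prefer the more altered status (CNL > CNN > CNG >
    negative).  A gene covered by no segment is undetermined.
    """
    chrom, start, end = gene_region
    best: Optional[CNSegment] = None
    best_key = None
    for seg in segments:
        if seg.chrom != chrom:
            continue
        covered = min(seg.end, end) - max(seg.start, start) + 1
        if covered <= 0:
            continue
        key = (covered, _LOH_SEVERITY[seg.status()])
        if best_key is None or key > best_key:
            best_key = key
            best = seg
    if best is None:
        return LOHCall(gene_id=gene_id, status=LOH_UNDETERMINED)
    return LOHCall(
        gene_id=gene_id,
        status=best.status(),
        major_cn=best.major_cn,
        minor_cn=best.minor_cn,
    )


def second_hit(
    pp_sv_genes: Iterable[str],
    somatic_events: Sequence[tuple[str, str]],
) -> dict[str, list[str]]:
    """Somatic copy-number second hits on germline-hit genes.

    ``somatic_events`` are (gene, event-type) pairs, e.g. ("GENE1",
    "CNL").  Returns every queried gene mapped to its events in input
    order — an empty list means no second hit.
    """
    events_by_gene: dict[str, list[str]] = {}
    for gene, event in somatic_events:
        events_by_gene.setdefault(gene, []).append(event)
    return {g: list(events_by_gene.get(g, [])) for g in pp_sv_genes}


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_depth_tracks(path: str) -> list[DepthTrack]:
    """Read a three-column depth TSV (chrom, pos, depth) as emitted by a
    depth utility; each contiguous run of positions becomes one track."""
    df = pd.read_csv(path, sep="\t", names=["chrom", "pos", "depth"], dtype={"chrom": str})
    tracks = []
    for chrom, group in df.groupby("chrom", sort=True):
        pos = group["pos"].to_numpy()
        depth = group["depth"].to_numpy(dtype=float)
        order = np.argsort(pos)
        pos, depth = pos[order], depth[order]
        breaks = np.nonzero(np.diff(pos) != 1)[0] + 1
        for chunk_pos, chunk_depth in zip(np.split(pos, breaks), np.split(depth, breaks)):
            tracks.append(DepthTrack(chrom=str(chrom), start=int(chunk_pos[0]), depth=chunk_depth))
    return tracks


def write_depth_track(track: DepthTrack, path: str, mode: str = "w") -> None:
    with open(path, mode) as fh:
        for i, d in enumerate(track.depth):
            fh.write(f"{track.chrom}\t{track.start + i}\t{int(d)}\n")


def read_cn_segments(path: str) -> list[CNSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        CNSegment(
            chrom=r.chrom, start=int(r.start), end=int(r.end),
            major_cn=int(r.major_cn), minor_cn=int(r.minor_cn),
        )
        for r in df.itertuples(index=False)
    ]


def write_cn_segments(segments: Sequence[CNSegment], path: str) -> None:
    pd.DataFrame(
        [
            {"chrom": s.chrom, "start": s.start, "end": s.end,
             "major_cn": s.major_cn, "minor_cn": s.minor_cn}
            for s in segments
        ]
    ).to_csv(path, sep="\t", index=False)
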