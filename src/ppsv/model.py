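"""Core data model for germline structural variants (SVs).

Coordinates follow the VCF convention externally: 1-based, inclusive.
Every piece of interval arithmetic inside the package operates on 0-based
half-open intervals obtained through the ``*_interval`` helpers, so the
conversion between the two systems happens in exactly one place.

An SV is modelled as a single record with two breakpoint anchors
``(chrom1, pos1)`` and ``(chrom2, pos2)``.  Simple intra-chromosomal
events (DEL, DUP, INS, INV) have both anchors on one chromosome with
``pos1 <= pos2``; inter-chromosomal translocations (TRA) keep two
independent anchors and carry no length.  Unresolved breakends (BND)
reference their partner through ``mate_id`` and are resolved to simple
types by :func:`ppsv.io.classify_breakend_pair`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence


class SVType(str, enum.Enum):
    DEL = "DEL"
    DUP = "DUP"
    INS = "INS"
    INV = "INV"
    TRA = "TRA"
    BND = "BND"


class Caller(str, enum.Enum):
    CALLER_A = "callerA"
    CALLER_B = "callerB"
    MERGED = "merged"


#: Types whose two anchors live on the same chromosome.
INTRA_CHROM_TYPES = frozenset({SVType.DEL, SVType.DUP, SVType.INS, SVType.INV})

#: Types with a well-defined length equal to the breakpoint span.
SPAN_LENGTH_TYPES = frozenset({SVType.DEL, SVType.DUP, SVType.INV})


@dataclass
class SVRecord:
    """One structural variant (or one unresolved breakend).

    Parameters
    ----------
    id:
        Caller-assigned variant identifier; unique within one call set.
    chrom1, pos1:
        First breakpoint anchor (1-based).
    chrom2, pos2:
        Second breakpoint anchor (1-based).  Equals the first anchor's
        chromosome for intra-chromosomal types.
    svtype:
        One of DEL / DUP / INS / INV / TRA / BND.
    svlen:
        Event length in bases; ``pos2 - pos1`` for DEL/DUP/INV, the
        inserted length for INS, absent for TRA.
    strands:
        Junction orientation as an ordered ``(+|-, +|-)`` pair, when the
        caller reports it (breakend bracket notation or a STRANDS tag).
    filter:
        ``"PASS"`` or the caller's failure label.
    caller:
        Provenance: callerA, callerB or merged.
    mate_id:
        Partner breakend identifier (BND only).
    """

    id: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    svtype: SVType
    svlen: Optional[int] = None
    strands: Optional[tuple[str, str]] = None
    filter: str = "PASS"
    caller: Optional[Caller] = None
    mate_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.svtype = SVType(self.svtype)
        if self.caller is not None:
            self.caller = Caller(self.caller)
        if self.strands is not None:
            self.strands = tuple(self.strands)  # type: ignore[assignment]
            if len(self.strands) != 2 or any(s not in "+-" for s in self.strands):
                raise ValueError(f"{self.id}: invalid strands {self.strands!r}")
        if self.svtype in INTRA_CHROM_TYPES:
            if self.chrom1 != self.chrom2:
                raise ValueError(
                    f"{self.id}: {self.svtype.value} anchors on different "
                    f"chromosomes ({self.chrom1}, {self.chrom2})"
                )
            if self.pos1 > self.pos2:
                raise ValueError(f"{self.id}: pos1 {self.pos1} > pos2 {self.pos2}")
        if self.svtype is SVType.TRA and self.chrom1 == self.chrom2:
            raise ValueError(f"{self.id}: TRA requires two chromosomes")
        if self.svtype in SPAN_LENGTH_TYPES and self.svlen is not None:
            if self.svlen != self.pos2 - self.pos1:
                raise ValueError(
                    f"{self.id}: svlen {self.svlen} != pos2 - pos1 "
                    f"({self.pos2 - self.pos1})"
                )

    # -- derived geometry -------------------------------------------------

    @property
    def is_pass(self) -> bool:
        return self.filter == "PASS"

    @property
    def span(self) -> Optional[int]:
        """Breakpoint span in bases for intra-chromosomal events."""
        if self.chrom1 != self.chrom2:
            return None
        return self.pos2 - self.pos1

    def span_interval(self) -> tuple[str, int, int]:
        """0-based half-open interval covered by an intra-chromosomal SV."""
        if self.chrom1 != self.chrom2:
            raise ValueError(f"{self.id}: no single-chromosome span for TRA/BND")
        return self.chrom1, self.pos1 - 1, self.pos2

    def breakpoints(self) -> list[tuple[str, int]]:
        """The two breakpoint anchors as (chrom, 1-based position)."""
        return [(self.chrom1, self.pos1), (self.chrom2, self.pos2)]


@dataclass
class BreakendPair:
    """Two reciprocal BND records joined through their mate identifiers."""

    first: SVRecord
    second: SVRecord

    def __post_init__(self) -> None:
        for rec in (self.first, self.second):
            if rec.svtype is not SVType.BND:
                raise ValueError(f"{rec.id}: BreakendPair members must be BND")
        if (
            self.first.mate_id != self.second.id
            or self.second.mate_id != self.first.id
        ):
            raise ValueError(
                f"breakends {self.first.id}/{self.second.id} are not reciprocal"
            )


@dataclass
class GeneModel:
    """A gene reduced to its single canonical (or candidate) transcript.

    ``exons`` are 1-based inclusive, sorted and non-overlapping, and must
    lie within ``[tx_start, tx_end]``.  ``cds_start``/``cds_end`` bound
    the coding span when the transcript is coding.
    """

    gene_id: str
    gene_name: str
    canonical_transcript: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: Sequence[tuple[int, int]]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    canonical: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.tx_start > self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start > tx_end")
        self.exons = [tuple(e) for e in self.exons]
        prev_end = None
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"{self.gene_id}: exon start {start} > end {end}")
            if start < self.tx_start or end > self.tx_end:
                raise ValueError(f"{self.gene_id}: exon outside transcript bounds")
            if prev_end is not None and start <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = end
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.gene_id}: cds_start/cds_end must come together")

    # -- geometry helpers (0-based half-open) ------------------------------

    def tx_interval(self) -> tuple[int, int]:
        return self.tx_start - 1, self.tx_end

    def exon_intervals(self) -> list[tuple[int, int]]:
        return [(s - 1, e) for s, e in self.exons]

    def cds_interval(self) -> Optional[tuple[int, int]]:
        if self.cds_start is None:
            return None
        return self.cds_start - 1, self.cds_end

    @property
    def tss(self) -> int:
        """Transcription start site (1-based, strand-aware)."""
        return self.tx_start if self.strand == "+" else self.tx_end

    def cds_length(self) -> int:
        """Total coding bases, i.e. exon bases within the CDS span."""
        cds = self.cds_interval()
        if cds is None:
            return 0
        lo, hi = cds
        return sum(
            max(0, min(e, hi) - max(s, lo)) for s, e in self.exon_intervals()
        )

    def transcript_length(self) -> int:
        return self.tx_end - self.tx_start + 1


@dataclass
class Region:
    """One genomic interval (0-based half-open) optionally linked to a gene."""

    chrom: str
    start: int  # 0-based
    end: int    # half-open
    linked_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.chrom}:{self.start}-{self.end} is empty")

    @property
    def start1(self) -> int:
        """First covered base, 1-based inclusive."""
        return self.start + 1

    @property
    def end1(self) -> int:
        """Last covered base, 1-based inclusive."""
        return self.end

    def contains(self, chrom: str, pos1: int) -> bool:
        """Whether the region contains a 1-based position."""
        return chrom == self.chrom and self.start < pos1 <= self.end


@dataclass
class RegionSet:
    """A named collection of regions (promoters, enhancers, ...)."""

    name: str
    intervals: list[Region] = field(default_factory=list)

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)
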