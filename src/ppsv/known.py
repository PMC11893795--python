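"""Matching cohort SVs against a curated table of known structural variants.

The table emulates a public SV archive: each entry carries breakpoint
coordinates, an SV type, a clinical-significance label (when a clinical
interpretation exists) and allele frequencies reported by population
studies.  A cohort SV is *known* when an entry of the same type has both
breakpoints within 200 bases; known SVs already reported at appreciable
population frequency (reported AF >= 1%) are excluded from the rare
pathogenic-candidate cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .model import SVRecord, SVType

PATHOGENIC = "pathogenic"
LIKELY_PATHOGENIC = "likely_pathogenic"
UNCERTAIN = "uncertain"
BENIGN = "benign"
NO_SIGNIFICANCE = "none"

SIGNIFICANCES = (PATHOGENIC, LIKELY_PATHOGENIC, UNCERTAIN, BENIGN, NO_SIGNIFICANCE)


@dataclass
class KnownSVEntry:
    """One archived SV with its clinical label and reported frequencies."""

    entry_id: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    svtype: SVType
    clinical_significance: str = NO_SIGNIFICANCE
    #: (study, population label, allele frequency) triples
    reported_afs: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.svtype = SVType(self.svtype)
        if self.clinical_significance not in SIGNIFICANCES:
            raise ValueError(
                f"{self.entry_id}: unknown significance "
                f"{self.clinical_significance!r}"
            )
        for _, _, af in self.reported_afs:
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"{self.entry_id}: reported AF {af} outside [0,1]")

    @property
    def max_reported_af(self) -> Optional[float]:
        """Maximum AF over all studies/populations (conservative rarity)."""
        if not self.reported_afs:
            return None
        return max(af for _, _, af in self.reported_afs)


@dataclass
class MatchResult:
    sv_id: str
    status: str  # "known" | "unknown"
    matched_entry: Optional[str] = None
    significance: str = NO_SIGNIFICANCE
    max_reported_af: Optional[float] = None

    @property
    def is_known(self) -> bool:
        return self.status == "known"


def _entry_distances(
    sv: SVRecord, entry: KnownSVEntry
) -> Optional[tuple[int, int]]:
    if sv.svtype is not entry.svtype:
        return None
    if sv.svtype is SVType.TRA:
        best = None
        anchors = ((entry.chrom1, entry.pos1), (entry.chrom2, entry.pos2))
        for (ec1, ep1), (ec2, ep2) in (anchors, anchors[::-1]):
            if sv.chrom1 == ec1 and sv.chrom2 == ec2:
                dist = (abs(sv.pos1 - ep1), abs(sv.pos2 - ep2))
                if best is None or sum(dist) < sum(best):
                    best = dist
        return best
    if sv.chrom1 != entry.chrom1 or sv.chrom2 != entry.chrom2:
        return None
    return abs(sv.pos1 - entry.pos1), abs(sv.pos2 - entry.pos2)


def match_known(
    sv: SVRecord,
    table: Sequence[KnownSVEntry],
    tolerance: int = 200,
) -> MatchResult:
    """Match one cohort SV against the known-SV table.

    A match requires the same SV type, matching chromosome anchors and
    both breakpoint distances within ``tolerance``.  Among multiple
    matches the minimal summed distance wins; ties prefer entries with a
    clinical interpretation, then the smallest entry id — a total order,
    so matching is independent of table order.
    """
    best_key = None
    best_entry = None
    for entry in table:
        dist = _entry_distances(sv, entry)
        if dist is None or dist[0] > tolerance or dist[1] > tolerance:
            continue
        key = (
            dist[0] + dist[1],
            entry.clinical_significance == NO_SIGNIFICANCE,
            entry.entry_id,
        )
        if best_key is None or key < best_key:
            best_key = key
            best_entry = entry
    if best_entry is None:
        return MatchResult(sv_id=sv.id, status="unknown")
    return MatchResult(
        sv_id=sv.id,
        status="known",
        matched_entry=best_entry.entry_id,
        significance=best_entry.clinical_significance,
        max_reported_af=best_entry.max_reported_af,
    )


def frequency_exclusion(
    candidates: Sequence[MatchResult], max_known_af: float = 0.01
) -> tuple[list[MatchResult], list[MatchResult]]:
    """Split candidates into (kept, excluded) by reported population AF.

    Known SVs whose maximum reported AF reaches ``max_known_af`` are
    excluded (the threshold is inclusive: a variant already reported at
    1% is not rare).  Unknown SVs and known-but-rarer SVs are kept.
    """
    kept, excluded = [], []
    for m in candidates:
        if m.max_reported_af is not None and m.max_reported_af >= max_known_af:
            excluded.append(m)
        else:
            kept.append(m)
    return kept, excluded


# ---------------------------------------------------------------------------
# TSV I/O — one row per (entry, study/population AF observation)
# ---------------------------------------------------------------------------

_COLUMNS = [
    "entry_id", "chrom1", "pos1", "chrom2", "pos2", "svtype",
    "significance", "af_study", "af_population", "af",
]


def read_known_table(path: str) -> list[KnownSVEntry]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str})
    entries = []
    for entry_id, group in df.groupby("entry_id", sort=True):
        first = group.iloc[0]
        afs = [
            (str(r.af_study), str(r.af_population), float(r.af))
            for r in group.itertuples(index=False)
            if not pd.isna(r.af)
        ]
        entries.append(
            KnownSVEntry(
                entry_id=str(entry_id),
                chrom1=first.chrom1,
                pos1=int(first.pos1),
                chrom2=first.chrom2,
                pos2=int(first.pos2),
                svtype=SVType(first.svtype),
                clinical_significance=str(first.significance),
                reported_afs=afs,
            )
        )
    return entries


def write_known_table(entries: Sequence[KnownSVEntry], path: str) -> None:
    rows = []
    for e in entries:
        afs = e.reported_afs or [(None, None, None)]
        for study, pop, af in afs:
            rows.append(
                dict(
                    entry_id=e.entry_id, chrom1=e.chrom1, pos1=e.pos1,
                    chrom2=e.chrom2, pos2=e.pos2, svtype=e.svtype.value,
                    significance=e.clinical_significance,
                    af_study=study, af_population=pop, af=af,
                )
            )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)
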