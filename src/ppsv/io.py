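"""Readers and writers for the VCF dialects and tables the pipeline touches.

VCF access goes through :mod:`pysam`; the functions here only translate
between pysam records and the package's :class:`~ppsv.model.SVRecord`
dialect (INFO keys ``SVTYPE``, ``END``, ``SVLEN``, ``MATEID``, ``CHR2``,
``END2``, ``STRANDS``).  Breakend (BND) ALT bracket notation is parsed
into mate coordinates and junction orientation.

Record-level problems (e.g. a line without ``SVTYPE``) are collected and
reported, never fatal; an unreadable file raises immediately.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Optional

import pandas as pd
import pysam

from .model import (
    BreakendPair,
    Caller,
    GeneModel,
    Region,
    RegionSet,
    SPAN_LENGTH_TYPES,
    SVRecord,
    SVType,
)

log = logging.getLogger(__name__)

_BND_ALT = re.compile(
    r"^(?P<leadseq>[A-Za-z.*]*)"
    r"(?P<open>[\[\]])(?P<chrom>[^:\[\]]+):(?P<pos>\d+)(?P<close>[\[\]])"
    r"(?P<trailseq>[A-Za-z.*]*)$"
)


def _parse_bnd_alt(alt: str) -> Optional[tuple[str, int, tuple[str, str]]]:
    """Decode a breakend ALT string into (mate_chrom, mate_pos, strands).

    The four bracket layouts map onto junction orientations as::

        t[p[  -> (+,-)   deletion-type junction
        t]p]  -> (+,+)   inverted junction
        ]p]t  -> (-,+)   duplication-type junction
        [p[t  -> (-,-)   inverted junction
    """
    m = _BND_ALT.match(alt)
    if m is None:
        return None
    leading = bool(m.group("leadseq"))
    bracket = m.group("open")
    if leading and bracket == "[":
        strands = ("+", "-")
    elif leading and bracket == "]":
        strands = ("+", "+")
    elif not leading and bracket == "]":
        strands = ("-", "+")
    else:
        strands = ("-", "-")
    return m.group("chrom"), int(m.group("pos")), strands


def _filter_label(rec: pysam.VariantRecord) -> str:
    keys = list(rec.filter.keys())
    if not keys or keys == ["PASS"]:
        return "PASS"
    return ";".join(k for k in keys if k != "PASS") or "PASS"


def _scalar(value):
    if isinstance(value, tuple):
        return value[0]
    return value


def read_sv_vcf(
    path: str,
    caller_label: Caller | str | None = None,
    errors: Optional[list[tuple[int, str]]] = None,
) -> list[SVRecord]:
    """Read a single-sample SV VCF into :class:`SVRecord` objects.

    Non-BND lines become one record each; BND lines are returned
    unpaired with ``mate_id`` populated (resolve them afterwards with
    :func:`pair_breakends` / :func:`classify_breakend_pair`).

    Parameters
    ----------
    path:
        VCF 4.2 file with ``SVTYPE`` in INFO.
    caller_label:
        Provenance stamped on every record.
    errors:
        Optional list collecting ``(record_number, message)`` tuples for
        malformed records (1-based data-line ordinals); they are also
        logged as warnings.
    """
    caller = Caller(caller_label) if caller_label is not None else None
    records: list[SVRecord] = []
    with pysam.VariantFile(path) as vcf:
        for lineno, rec in enumerate(vcf.fetch(), start=1):
            try:
                sv = _convert_record(rec, caller)
            except ValueError as exc:
                msg = f"record {lineno} ({rec.chrom}:{rec.pos}): {exc}"
                log.warning("%s: %s", path, msg)
                if errors is not None:
                    errors.append((lineno, str(exc)))
                continue
            records.append(sv)
    return records


def _convert_record(rec: pysam.VariantRecord, caller: Optional[Caller]) -> SVRecord:
    info = rec.info
    if "SVTYPE" not in info:
        raise ValueError("missing SVTYPE")
    svtype = SVType(_scalar(info["SVTYPE"]))
    strands = None
    if "STRANDS" in info:
        s = str(_scalar(info["STRANDS"]))
        if len(s) == 2:
            strands = (s[0], s[1])
    rid = rec.id or f"{rec.chrom}:{rec.pos}:{svtype.value}"
    filt = _filter_label(rec)

    if svtype is SVType.BND:
        alt = rec.alts[0] if rec.alts else ""
        parsed = _parse_bnd_alt(alt)
        if parsed is None:
            raise ValueError(f"unparseable BND ALT {alt!r}")
        mate_chrom, mate_pos, alt_strands = parsed
        return SVRecord(
            id=rid,
            chrom1=rec.chrom,
            pos1=rec.pos,
            chrom2=mate_chrom,
            pos2=mate_pos,
            svtype=SVType.BND,
            strands=strands or alt_strands,
            filter=filt,
            caller=caller,
            mate_id=_scalar(info["MATEID"]) if "MATEID" in info else None,
        )

    if svtype is SVType.TRA:
        chrom2 = str(_scalar(info.get("CHR2")))
        pos2 = info.get("END2")
        if chrom2 == "None" or pos2 is None:
            raise ValueError("TRA record lacks CHR2/END2")
        return SVRecord(
            id=rid,
            chrom1=rec.chrom,
            pos1=rec.pos,
            chrom2=chrom2,
            pos2=int(_scalar(pos2)),
            svtype=SVType.TRA,
            strands=strands,
            filter=filt,
            caller=caller,
        )

    pos2 = rec.stop  # pysam exposes INFO END (1-based inclusive) as .stop
    svlen = None
    if "SVLEN" in info:
        svlen = abs(int(_scalar(info["SVLEN"])))
    if svtype is SVType.INS:
        pos2 = rec.pos
    elif svtype in SPAN_LENGTH_TYPES:
        svlen = pos2 - rec.pos
    return SVRecord(
        id=rid,
        chrom1=rec.chrom,
        pos1=rec.pos,
        chrom2=rec.chrom,
        pos2=pos2,
        svtype=svtype,
        svlen=svlen,
        strands=strands,
        filter=filt,
        caller=caller,
    )


_VCF_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">',
    '##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">',
    '##INFO=<ID=CHR2,Number=1,Type=String,Description="Chromosome of second breakpoint">',
    '##INFO=<ID=END2,Number=1,Type=Integer,Description="Position of second breakpoint">',
    '##INFO=<ID=STRANDS,Number=1,Type=String,Description="Junction orientation">',
    '##FILTER=<ID=MinQUAL,Description="Low quality call">',
]


def _build_header(contigs: Iterable[str], extra: Iterable[str] = ()) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for line in _VCF_HEADER_LINES:
        header.add_line(line)
    for line in extra:
        header.add_line(line)
    for contig in contigs:
        header.contigs.add(contig)
    return header


def _contigs_of(records: Iterable[SVRecord]) -> list[str]:
    seen: dict[str, None] = {}
    for rec in records:
        seen.setdefault(rec.chrom1)
        seen.setdefault(rec.chrom2)
    return sorted(seen)


def write_sv_vcf(records: list[SVRecord], path: str) -> None:
    """Write resolved SV records (no raw BND) as a VCF.

    TRA records are written as single lines carrying ``CHR2``/``END2``,
    which :func:`read_sv_vcf` understands, so a write/read round trip
    preserves coordinates, types and lengths.
    """
    header = _build_header(_contigs_of(records))
    with pysam.VariantFile(path, "w", header=header) as out:
        for sv in records:
            if sv.svtype is SVType.BND:
                raise ValueError(f"{sv.id}: resolve BND records before writing")
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
            if sv.strands is not None:
                rec.info["STRANDS"] = "".join(sv.strands)
            if sv.filter == "PASS":
                rec.filter.add("PASS")
            else:
                rec.filter.add("MinQUAL")
            out.write(rec)


def pair_breakends(
    records: list[SVRecord],
) -> tuple[list[BreakendPair], list[SVRecord]]:
    """Join reciprocally-referenced BND records into pairs.

    Returns ``(pairs, orphans)``; together they partition the input.
    Records whose mate reference is missing or asymmetric are orphans.
    """
    for rec in records:
        if rec.svtype is not SVType.BND:
            raise ValueError(f"{rec.id}: pair_breakends accepts BND records only")
    by_id = {rec.id: rec for rec in records}
    pairs: list[BreakendPair] = []
    orphans: list[SVRecord] = []
    used: set[str] = set()
    for rec in records:
        if rec.id in used:
            continue
        mate = by_id.get(rec.mate_id) if rec.mate_id else None
        if (
            mate is not None
            and mate.id not in used
            and mate.id != rec.id
            and mate.mate_id == rec.id
        ):
            pairs.append(BreakendPair(rec, mate))
            used.add(rec.id)
            used.add(mate.id)
        else:
            orphans.append(rec)
            used.add(rec.id)
            if mate is not None and mate.mate_id != rec.id:
                log.warning(
                    "asymmetric mate reference %s -> %s", rec.id, rec.mate_id
                )
    return pairs, orphans


def classify_breakend_pair(pair: BreakendPair) -> SVRecord:
    """Resolve a reciprocal breakend pair to a simple SV type.

    Different chromosomes give TRA.  Same-chromosome junctions are typed
    from the junction orientation: ``++``/``--`` (inverted) give INV,
    ``+-`` a deletion-type junction and ``-+`` a duplication-type one.
    """
    first, second = pair.first, pair.second
    if (first.chrom1, first.pos1) > (second.chrom1, second.pos1):
        first, second = second, first
    base_id = first.id.rsplit(":", 1)[0]
    filt = "PASS" if (first.is_pass and second.is_pass) else (
        first.filter if not first.is_pass else second.filter
    )
    if first.chrom1 != second.chrom1:
        return SVRecord(
            id=f"{base_id}:TRA",
            chrom1=first.chrom1,
            pos1=first.pos1,
            chrom2=second.chrom1,
            pos2=second.pos1,
            svtype=SVType.TRA,
            strands=first.strands,
            filter=filt,
            caller=first.caller,
        )
    strands = first.strands
    if strands is None:
        raise ValueError(f"{first.id}: same-chromosome pair without orientation")
    if strands[0] == strands[1]:
        svtype = SVType.INV
    elif strands == ("+", "-"):
        svtype = SVType.DEL
    else:
        svtype = SVType.DUP
    pos1, pos2 = first.pos1, second.pos1
    return SVRecord(
        id=f"{base_id}:{svtype.value}",
        chrom1=first.chrom1,
        pos1=pos1,
        chrom2=first.chrom1,
        pos2=pos2,
        svtype=svtype,
        svlen=pos2 - pos1,
        strands=strands,
        filter=filt,
        caller=first.caller,
    )


def resolve_breakends(records: list[SVRecord]) -> tuple[list[SVRecord], list[SVRecord]]:
    """Split a call set into resolved simple SVs and orphan breakends.

    Non-BND records pass through unchanged; reciprocal BND pairs are
    classified with :func:`classify_breakend_pair`.
    """
    simple = [r for r in records if r.svtype is not SVType.BND]
    bnds = [r for r in records if r.svtype is SVType.BND]
    pairs, orphans = pair_breakends(bnds)
    simple.extend(classify_breakend_pair(p) for p in pairs)
    return simple, orphans


# ---------------------------------------------------------------------------
# Tab-separated tables and BED region sets
# ---------------------------------------------------------------------------

def read_gene_models(path: str) -> list[GeneModel]:
    """Read gene models from the package's 8+-column TSV dialect.

    Columns: gene_id, gene_name, canonical_transcript, chrom, strand,
    tx_start, tx_end, exons (``start-end`` pairs joined by commas),
    optional cds_start, cds_end, canonical (0/1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    genes = []
    for row in df.itertuples(index=False):
        exons = [
            tuple(int(x) for x in chunk.split("-"))
            for chunk in str(row.exons).split(",")
        ]
        cds_start = getattr(row, "cds_start", None)
        cds_end = getattr(row, "cds_end", None)
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                gene_name=row.gene_name,
                canonical_transcript=row.canonical_transcript,
                chrom=row.chrom,
                strand=row.strand,
                tx_start=int(row.tx_start),
                tx_end=int(row.tx_end),
                exons=exons,
                cds_start=None if pd.isna(cds_start) else int(cds_start),
                cds_end=None if pd.isna(cds_end) else int(cds_end),
                canonical=bool(getattr(row, "canonical", False)),
            )
        )
    return genes


def write_gene_models(genes: list[GeneModel], path: str) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "gene_name": g.gene_name,
                "canonical_transcript": g.canonical_transcript,
                "chrom": g.chrom,
                "strand": g.strand,
                "tx_start": g.tx_start,
                "tx_end": g.tx_end,
                "exons": ",".join(f"{s}-{e}" for s, e in g.exons),
                "cds_start": g.cds_start,
                "cds_end": g.cds_end,
                "canonical": int(g.canonical),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_region_bed(path: str, name: str) -> RegionSet:
    """Read a BED-like file (chrom, start, end[, linked_gene]) into a RegionSet."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            gene = parts[3] if len(parts) > 3 else None
            regions.append(Region(parts[0], int(parts[1]), int(parts[2]), gene))
    return RegionSet(name=name, intervals=regions)


def write_region_bed(regions: RegionSet, path: str) -> None:
    with open(path, "w") as fh:
        for r in regions:
            gene = r.linked_gene or "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{gene}\n")
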