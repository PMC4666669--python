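"""BAM alignment access, SA/XA supplementary-tag parsing and clip signatures.

All coordinates in this package are 0-based, half-open.  SAM optional tags
(SA, XA) store 1-based positions; the shift to 0-based happens exactly once,
inside :func:`parse_tag_alignments`.  The shift back to 1-based happens
exactly once, in the VCF writer (:mod:`clipsv.vcfio`).
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Tuple

import pysam

log = logging.getLogger(__name__)

# CIGAR operations that consume the reference / the query.
_REF_OPS = set("MDN=X")
_QRY_OPS = set("MIS=X")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: sentinel MAPQ for XA entries, which carry no per-entry mapping quality.
XA_MAPQ_UNKNOWN = -1

LEFT = "left"
RIGHT = "right"


def parse_cigar(cigar: str) -> List[Tuple[str, int]]:
    """Parse a CIGAR string into a list of (op, length) tuples."""
    out = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if "".join(f"{n}{op}" for op, n in out) != cigar:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return out


def cigar_reference_span(cigar: List[Tuple[str, int]]) -> int:
    """Number of reference bases consumed by a CIGAR."""
    return sum(n for op, n in cigar if op in _REF_OPS)


def cigar_query_span(cigar: List[Tuple[str, int]]) -> int:
    """Number of query bases consumed (soft clips included, hard clips not)."""
    return sum(n for op, n in cigar if op in _QRY_OPS)


@dataclass(slots=True)
class TagAlignment:
    """One alignment reported in an SA (supplementary) or XA (alternative) tag."""

    chrom: str
    pos: int                      # 0-based leftmost reference position
    strand: str                   # '+' or '-'
    cigar: List[Tuple[str, int]]
    mapq: int                     # XA_MAPQ_UNKNOWN for XA entries
    nm: int

    @property
    def reference_span(self) -> int:
        return cigar_reference_span(self.cigar)

    @property
    def end(self) -> int:
        return self.pos + self.reference_span


@dataclass(slots=True)
class AlignedRead:
    """A mapped read with the fields the caller consumes.

    ``sa_raw``/``xa_raw`` keep the unparsed tag strings; ``sa_entries`` /
    ``xa_entries`` parse them on demand (most reads carry neither tag, and
    the detection scan touches millions of records).
    """

    query_name: str
    sample_id: str
    chrom: str
    pos: int
    mapq: int
    cigar: List[Tuple[str, int]]
    is_paired: bool = False
    is_proper_pair: bool = False
    is_reverse: bool = False
    mate_is_reverse: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False
    is_unmapped: bool = False
    mate_is_unmapped: bool = False
    seq: Optional[str] = None
    mate_chrom: Optional[str] = None
    mate_pos: int = -1
    tlen: int = 0
    is_read1: bool = True
    sa_raw: str = ""
    xa_raw: str = ""
    _sa: Optional[List[TagAlignment]] = field(default=None, repr=False)
    _xa: Optional[List[TagAlignment]] = field(default=None, repr=False)

    @property
    def reference_span(self) -> int:
        return cigar_reference_span(self.cigar)

    @property
    def reference_end(self) -> int:
        return self.pos + self.reference_span

    @property
    def is_primary(self) -> bool:
        return not (self.is_secondary or self.is_supplementary)

    @property
    def sa_entries(self) -> List[TagAlignment]:
        if self._sa is None:
            self._sa = parse_tag_alignments(self.sa_raw)
        return self._sa

    @property
    def xa_entries(self) -> List[TagAlignment]:
        if self._xa is None:
            self._xa = parse_tag_alignments(self.xa_raw)
        return self._xa


@dataclass(slots=True)
class ClipSignature:
    """A soft- or hard-clip boundary: the atomic unit of breakpoint evidence.

    ``break_pos`` is the reference coordinate of the clip boundary: the read
    start for a left clip, the read end (pos + reference span) for a right
    clip.  Hard clips contribute support but no sequence (``clip_seq`` empty).
    """

    chrom: str
    break_pos: int
    side: str                     # LEFT or RIGHT
    clip_seq: str
    clip_len: int
    read_ref: str
    is_primary: bool
    read: Optional[AlignedRead] = None


def parse_tag_alignments(tag_value: str) -> List[TagAlignment]:
    """Parse an SA- or XA-style tag into :class:`TagAlignment` entries.

    SA grammar:  ``chr,pos,strand,CIGAR,mapQ,NM;`` repeated.
    XA grammar:  ``chr,[+-]pos,CIGAR,NM;`` repeated (strand fused to pos; no
    per-entry MAPQ, recorded as :data:`XA_MAPQ_UNKNOWN`).

    Parsing is total: malformed entries are skipped with a warning, never
    raised on.  1-based tag positions are converted to 0-based.
    """
    entries: List[TagAlignment] = []
    if not tag_value:
        return entries
    for raw in tag_value.split(";"):
        if not raw:
            continue
        fields = raw.split(",")
        try:
            if len(fields) == 6:            # SA dialect
                chrom, pos_s, strand, cig, mapq_s, nm_s = fields
                if strand not in "+-":
                    raise ValueError("bad strand")
                pos = int(pos_s) - 1
                mapq = int(mapq_s)
                nm = int(nm_s)
            elif len(fields) == 4:          # XA dialect
                chrom, spos, cig, nm_s = fields
                strand = spos[0]
                if strand not in "+-":
                    raise ValueError("bad strand prefix")
                pos = int(spos[1:]) - 1
                mapq = XA_MAPQ_UNKNOWN
                nm = int(nm_s)
            else:
                raise ValueError("wrong field count")
            if pos < 0:
                raise ValueError("negative position")
            entries.append(TagAlignment(chrom, pos, strand, parse_cigar(cig), mapq, nm))
        except (ValueError, IndexError) as exc:
            log.warning("skipping malformed tag entry %r (%s)", raw, exc)
    return entries


def clip_signatures(read: AlignedRead) -> List[ClipSignature]:
    """Extract the 0, 1 or 2 clip signatures of a mapped read.

    A leading S/H op yields a left signature at ``read.pos``; a trailing S/H
    op yields a right signature at ``read.pos + reference_span``.  Soft clips
    carry the clipped bases; hard clips carry an empty sequence.
    """
    if read.is_unmapped or not read.cigar:
        return []
    sigs: List[ClipSignature] = []
    first_op, first_len = read.cigar[0]
    last_op, last_len = read.cigar[-1]
    if first_op in "SH":
        seq = ""
        if first_op == "S" and read.seq is not None:
            seq = read.seq[:first_len]
        sigs.append(ClipSignature(read.chrom, read.pos, LEFT, seq, first_len,
                                  read.query_name, read.is_primary, read))
    if len(read.cigar) > 1 and last_op in "SH":
        seq = ""
        if last_op == "S" and read.seq is not None:
            seq = read.seq[len(read.seq) - last_len:]
        sigs.append(ClipSignature(read.chrom, read.reference_end, RIGHT, seq,
                                  last_len, read.query_name, read.is_primary, read))
    return sigs


_CIGAR_OPS = "MIDNSHP=X"


def from_pysam(rec: pysam.AlignedSegment, sample_id: str,
               load_seq: bool = True) -> AlignedRead:
    """Convert a pysam record to an :class:`AlignedRead`."""
    cig = [(_CIGAR_OPS[op], n) for op, n in (rec.cigartuples or [])]
    return AlignedRead(
        query_name=rec.query_name or "",
        sample_id=sample_id,
        chrom=rec.reference_name or "",
        pos=rec.reference_start if rec.reference_start is not None else -1,
        mapq=rec.mapping_quality,
        cigar=cig,
        is_paired=rec.is_paired,
        is_proper_pair=rec.is_proper_pair,
        is_reverse=rec.is_reverse,
        mate_is_reverse=rec.mate_is_reverse if rec.is_paired else False,
        is_secondary=rec.is_secondary,
        is_supplementary=rec.is_supplementary,
        is_duplicate=rec.is_duplicate,
        is_unmapped=rec.is_unmapped,
        mate_is_unmapped=rec.mate_is_unmapped if rec.is_paired else False,
        seq=rec.query_sequence if load_seq else None,
        mate_chrom=rec.next_reference_name,
        mate_pos=rec.next_reference_start if rec.next_reference_start is not None else -1,
        tlen=rec.template_length,
        is_read1=rec.is_read1,
        sa_raw=rec.get_tag("SA") if rec.has_tag("SA") else "",
        xa_raw=rec.get_tag("XA") if rec.has_tag("XA") else "",
    )


def sample_map(bam: pysam.AlignmentFile, path: str) -> dict:
    """Map read-group ID -> sample name (SM), falling back to the file basename."""
    default = os.path.basename(path)
    for suffix in (".bam", ".sam", ".cram"):
        if default.endswith(suffix):
            default = default[: -len(suffix)]
    rg_map = {}
    for rg in (bam.header.to_dict().get("RG") or []):
        rg_map[rg.get("ID", "")] = rg.get("SM", default)
    rg_map[None] = default
    return rg_map


def _check_sorted(bam: pysam.AlignmentFile, path: str) -> None:
    hd = bam.header.to_dict().get("HD", {})
    so = hd.get("SO", "unknown")
    if so != "coordinate":
        raise ValueError(f"{path}: BAM is not coordinate-sorted (SO={so})")


def read_alignments(bam_path: str, region: Optional[str] = None,
                    load_seq: bool = True) -> Iterator[AlignedRead]:
    """Stream :class:`AlignedRead` records from a coordinate-sorted BAM.

    Unmapped and duplicate-flagged records are yielded with their flags set;
    filtering is the caller's responsibility.  ``region`` is a samtools-style
    ``chrom:start-end`` string (1-based inclusive, as samtools expects) or a
    bare contig name; region queries require an index.
    """
    try:
        bam = pysam.AlignmentFile(bam_path, "rb")
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot open BAM {bam_path}: {exc}") from exc
    with bam:
        _check_sorted(bam, bam_path)
        samples = sample_map(bam, bam_path)
        if region is not None:
            if not bam.has_index():
                raise ValueError(f"{bam_path}: region query requires a BAM index")
            it = bam.fetch(region=region)
        else:
            it = bam.fetch(until_eof=True)
        for rec in it:
            rg = rec.get_tag("RG") if rec.has_tag("RG") else None
            sid = samples.get(rg, samples[None])
            yield from_pysam(rec, sid, load_seq=load_seq)
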