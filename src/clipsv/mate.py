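"""Partner-breakpoint resolution: SA/XA endpoints, 10 bp clustering,
Smith-Waterman refinement of the clip consensus, and large-SV filters.

A clipped read stack marks one breakpoint precisely; the partner breakpoint
is recovered from the supplementary (SA) and alternative (XA) alignments of
the supporting reads.  Each tag alignment covers the clipped portion of its
read and soft-clips the anchored portion, so the partner junction is the tag
alignment's boundary adjacent to its larger clip.  Implied positions are
clustered on a 10 bp grid (half-up rounding), the best-supported cluster
wins, and the consensus sequence is locally re-aligned around the winner to
pin the partner to a single base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Protocol, Sequence, Tuple

from Bio import Align

from .bamio import RIGHT, TagAlignment
from .detect import BreakpointCandidate
from .variants import SVCall

#: intra-chromosomal spans above this trigger the extra mate-support filter.
LARGE_SV_SPAN = 1_000_000
#: minimum reads at the exact mate position for large/inter-chromosomal SVs.
LARGE_SV_MIN_MATE_SUPPORT = 2
#: candidates whose split reads hit more than this many chromosomes are dropped.
MAX_SPLIT_CHROMS = 3


@dataclass(slots=True)
class Endpoint:
    chrom: str
    pos: int
    precise: bool = True          # False for mate-pair fallback positions


@dataclass(slots=True)
class EndpointCluster:
    chrom: str
    rounded_pos: int              # multiple of 10
    member_positions: List[int] = field(default_factory=list)
    refined_pos: Optional[int] = None

    @property
    def support(self) -> int:
        return len(self.member_positions)

    def exact_support(self, pos: int) -> int:
        return sum(1 for p in self.member_positions if p == pos)

    def modal(self) -> Tuple[int, int]:
        """(position, count) of the best-agreed exact endpoint in the cluster."""
        counts: Dict[int, int] = {}
        for p in self.member_positions:
            counts[p] = counts.get(p, 0) + 1
        pos = min(p for p in counts if counts[p] == max(counts.values()))
        return pos, counts[pos]


@dataclass(slots=True)
class SWParams:
    """Local-alignment acceptance parameters for consensus refinement."""

    match: int = 2
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -1
    window: int = 200             # bp each side of the rounded cluster position
    min_coverage: float = 0.90    # of the consensus length
    min_identity: float = 0.80


class ReferenceAccessor(Protocol):
    """Indexed-FASTA contract: contig -> subsequence by 0-based half-open range."""

    def fetch(self, chrom: str, start: int, end: int) -> str: ...
    def length(self, chrom: str) -> int: ...


def _tag_junction(tag: TagAlignment) -> Optional[int]:
    """Partner junction implied by one tag alignment.

    The tag alignment covers the clipped piece of the read; its larger clip
    covers the anchored piece, so the junction is the boundary next to that
    clip.  Tag alignments without clips (e.g. full-length XA hits) carry no
    junction information and are skipped.
    """
    cig = tag.cigar
    lead = cig[0][1] if cig[0][0] in "SH" else 0
    trail = cig[-1][1] if len(cig) > 1 and cig[-1][0] in "SH" else 0
    if lead == 0 and trail == 0:
        return None
    return tag.pos if lead >= trail else tag.end


def candidate_endpoints(candidate: BreakpointCandidate,
                        read_length: int = 100) -> List[Endpoint]:
    """Implied partner positions from SA/XA tags of the supporting reads.

    When no tag carries a junction, discordant mate positions are appended
    as imprecise fallbacks (never SW-refined).
    """
    precise: List[Endpoint] = []
    fallback: List[Endpoint] = []
    for sig in candidate.signatures:
        read = sig.read
        if read is None:
            continue
        for tag in list(read.sa_entries) + list(read.xa_entries):
            pos = _tag_junction(tag)
            if pos is not None:
                precise.append(Endpoint(tag.chrom, pos, True))
        if read.is_paired and not read.mate_is_unmapped and read.mate_chrom:
            discordant = (read.mate_chrom != read.chrom
                          or abs(read.mate_pos - read.pos) > 10 * read_length)
            if discordant:
                fallback.append(Endpoint(read.mate_chrom, read.mate_pos, False))
    return precise if precise else fallback


def round_to_ten(pos: int) -> int:
    """Half-up rounding to the nearest multiple of 10."""
    return ((pos + 5) // 10) * 10


def cluster_endpoints(endpoints: Sequence[Endpoint]
                      ) -> Tuple[List[EndpointCluster], Optional[EndpointCluster]]:
    """Group endpoints on the 10 bp grid; winner = highest support.

    Ties break to the smallest (chrom, rounded_pos).  Empty input yields no
    winner; the call is then emitted as a single-breakpoint record.
    """
    groups: Dict[Tuple[str, int], EndpointCluster] = {}
    for ep in endpoints:
        key = (ep.chrom, round_to_ten(ep.pos))
        cl = groups.get(key)
        if cl is None:
            cl = groups[key] = EndpointCluster(key[0], key[1])
        cl.member_positions.append(ep.pos)
    clusters = sorted(groups.values(), key=lambda c: (c.chrom, c.rounded_pos))
    if not clusters:
        return [], None
    winner = max(clusters, key=lambda c: c.support)   # max() keeps first tie
    return clusters, winner


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


def _make_aligner(params: SWParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _best_local(aligner: Align.PairwiseAligner, ref: str, query: str):
    if not query or not ref:
        return None
    try:
        aln = aligner.align(ref, query)
    except (ValueError, OverflowError):
        return None
    if len(aln) == 0:
        return None
    return aln[0]


def refine_with_sw(consensus: str, reference: ReferenceAccessor,
                   cluster: EndpointCluster, side: str,
                   params: Optional[SWParams] = None) -> Optional[int]:
    """Refine a partner cluster to an exact base with local alignment.

    The consensus (and its reverse complement, for inversions) is aligned to
    the reference window around the rounded cluster position.  An alignment
    covering >= ``min_coverage`` of the consensus at >= ``min_identity``
    wins; its junction-proximal end on the reference is the refined position.
    ``side`` is the clip side of the *primary* breakpoint: a right clip reads
    into the partner locus, so its consensus starts at the partner junction
    on a forward match and ends there on a reverse-complement match (and the
    mirror rule for left clips).
    """
    params = params or SWParams()
    start = max(0, cluster.rounded_pos - params.window)
    end = min(reference.length(cluster.chrom), cluster.rounded_pos + params.window)
    if end <= start:
        return None
    window = reference.fetch(cluster.chrom, start, end).upper()
    aligner = _make_aligner(params)

    best = None
    for orient, query in (("+", consensus.upper()), ("-", _revcomp(consensus.upper()))):
        aln = _best_local(aligner, window, query)
        if aln is None:
            continue
        tblocks, qblocks = aln.aligned
        covered = sum(int(b - a) for a, b in qblocks)
        matches = 0
        for (ts, te), (qs, qe) in zip(tblocks, qblocks):
            matches += sum(1 for t, q in zip(window[ts:te], query[qs:qe]) if t == q)
        if covered < params.min_coverage * len(consensus):
            continue
        if matches < params.min_identity * len(consensus):
            continue
        # score floor: what an ungapped full-length alignment scores at the
        # minimum identity; heavily gap-stitched chance chains in the window
        # can reach the match-count thresholds but never this score
        if aln.score < params.match * len(consensus) * (2 * params.min_identity - 1):
            continue
        score = aln.score
        if best is None or score > best[0]:
            best = (score, orient, int(tblocks[0][0]), int(tblocks[-1][1]))
    if best is None:
        return None
    _, orient, tstart, tend = best
    forward = orient == "+"
    if (side == RIGHT) == forward:
        return start + tstart
    return start + tend


def apply_distance_filters(call: SVCall, n_split_chroms: int = 1
                           ) -> Tuple[bool, str]:
    """Large-SV / translocation filters.

    Inter-chromosomal calls and intra-chromosomal spans > 1 Mb need at least
    two reads at the exact (refined) mate position; candidates whose split
    reads map to more than three chromosomes are dropped as repeat-induced
    mapping noise.
    """
    if n_split_chroms > MAX_SPLIT_CHROMS:
        return False, "too_many_chroms"
    if call.mate is None:
        return True, "ok"
    inter = call.mate.chrom != call.chrom
    if inter or call.svlen > LARGE_SV_SPAN:
        if call.mate.support < LARGE_SV_MIN_MATE_SUPPORT:
            return False, "weak_distal_support"
    return True, "ok"
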