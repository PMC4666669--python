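"""Joint multi-sample breakpoint detection from clipped-read pileups.

Reads from every sample are pooled; soft- and hard-clip boundaries are hashed
by exact (chrom, position, side).  Positions where at least ``min_support``
primary reads share a clip boundary become breakpoint candidates.  The clipped
overhangs are then collapsed into a consensus sequence by anchor-aligned
column majority voting: the clips of one candidate all share a fixed anchor
(the breakpoint itself), so right clips are left-aligned at the anchor and
left clips are right-aligned, padded to the longest, and each column takes
the majority base.  Candidates whose consensus is shorter than 10 bp or whose
clip stack disagrees with the consensus in more than 50% of its characters
are discarded as likely mapping errors.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from .bamio import AlignedRead, ClipSignature, LEFT, clip_signatures

#: minimum primary clipped reads sharing a boundary to open a candidate.
DEFAULT_MIN_SUPPORT = 3
#: consensus sequences shorter than this are discarded.
MIN_CONSENSUS_LEN = 10
#: clip stacks with a mismatch fraction strictly above this are discarded.
MAX_MISMATCH_FRACTION = 0.5

ClipKey = Tuple[str, int, str]


@dataclass(slots=True)
class ConsensusResult:
    sequence: str
    n_input: int
    aligned_columns: int
    mismatch_fraction: float


@dataclass(slots=True)
class BreakpointCandidate:
    chrom: str
    pos: int
    side: str
    support: int                       # primary clipped reads (becomes SP)
    signatures: List[ClipSignature]
    consensus: Optional[ConsensusResult] = None


def build_clip_index(reads: Iterable[AlignedRead]) -> Dict[ClipKey, List[ClipSignature]]:
    """Hash clip boundaries of all (non-duplicate, mapped) reads by position.

    Duplicate-flagged and unmapped records are excluded -- duplicates are a
    classic source of false shared clip positions.  Secondary/supplementary
    records are retained with ``is_primary=False`` so they contribute split
    evidence without counting toward the support threshold.
    """
    index: Dict[ClipKey, List[ClipSignature]] = defaultdict(list)
    for read in reads:
        if read.is_unmapped or read.is_duplicate:
            continue
        for sig in clip_signatures(read):
            index[(sig.chrom, sig.break_pos, sig.side)].append(sig)
    return dict(index)


def find_candidates(index: Dict[ClipKey, List[ClipSignature]],
                    min_support: int = DEFAULT_MIN_SUPPORT) -> List[BreakpointCandidate]:
    """Candidates: keys with >= min_support primary signatures, sorted."""
    out: List[BreakpointCandidate] = []
    for (chrom, pos, side), sigs in index.items():
        n_primary = sum(1 for s in sigs if s.is_primary)
        if n_primary >= min_support:
            out.append(BreakpointCandidate(chrom, pos, side, n_primary, sigs))
    out.sort(key=lambda c: (c.chrom, c.pos, c.side))
    return out


def build_consensus(signatures: List[ClipSignature], side: str) -> ConsensusResult:
    """Column-majority consensus of the clipped overhangs sharing a boundary.

    Right clips run away from the anchor left-to-right and are left-aligned;
    left clips run toward the anchor and are right-aligned.  Ties break to
    the lexicographically smallest base for reproducibility.  Columns with
    fewer than 2 non-pad characters are trimmed from the consensus (a single
    read's overhang tail is not a consensus).
    """
    seqs = [s.clip_seq for s in signatures if s.clip_seq]
    if not seqs:
        return ConsensusResult("", len(signatures), 0, 0.0)
    width = max(len(s) for s in seqs)
    if side == LEFT:
        aligned = [s.rjust(width, "-") for s in seqs]
    else:
        aligned = [s.ljust(width, "-") for s in seqs]

    consensus_chars: List[str] = []
    keep_mask: List[bool] = []
    mismatches = 0
    total = 0
    for col in range(width):
        column = [s[col] for s in aligned if s[col] != "-"]
        counts = Counter(column)
        best = min((c for c in counts if counts[c] == max(counts.values()))) \
            if counts else "-"
        mismatches += sum(v for c, v in counts.items() if c != best)
        total += len(column)
        consensus_chars.append(best)
        keep_mask.append(len(column) >= 2)

    sequence = "".join(c for c, k in zip(consensus_chars, keep_mask) if k)
    frac = mismatches / total if total else 0.0
    return ConsensusResult(sequence, len(seqs), width, frac)


def filter_consensus(candidate: BreakpointCandidate) -> Tuple[bool, str]:
    """Apply the consensus length / divergence filters.

    Returns (keep, reason) with reason in {"ok", "too_short", "too_divergent"}.
    The divergence filter is a strict inequality: exactly 50% mismatches pass.
    """
    cons = candidate.consensus
    if cons is None:
        raise ValueError("candidate has no consensus")
    if len(cons.sequence) < MIN_CONSENSUS_LEN:
        return False, "too_short"
    if cons.mismatch_fraction > MAX_MISMATCH_FRACTION:
        return False, "too_divergent"
    return True, "ok"
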