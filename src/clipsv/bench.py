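"""Truth-interval benchmarking: sensitivity and FDR per class and size bin.

A call record is a true positive only when *both* of its breakpoints fall
inside (possibly different) slop-extended truth intervals of the same truth
SV.  Matching is greedy by call support, and one truth SV can be recalled by
at most one record: because the caller emits the 5' and 3' breakpoints as
independent records, the second record of a fully recovered SV is a
duplicate, not a false positive.  Records matching no truth SV count as
false positives individually.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import pandas as pd

from .simulate import TruthSV
from .variants import SVCall, UNKNOWN_CLASS

#: left-closed size strata, 50 bp to 1 Mb.
SIZE_BINS = ((50, 1_000), (1_000, 10_000), (10_000, 100_000), (100_000, 1_000_001))
SIZE_BIN_LABELS = ("50-1k", "1k-10k", "10k-100k", "100k-1M")

DEFAULT_TRUTH_PAD = 25
DEFAULT_SLOPS = (1, 5, 10, 25, 50, 100, 500)


def size_bin_label(size: int) -> str:
    for (lo, hi), label in zip(SIZE_BINS, SIZE_BIN_LABELS):
        if lo <= size < hi:
            return label
    return SIZE_BIN_LABELS[-1] if size >= SIZE_BINS[-1][0] else SIZE_BIN_LABELS[0]


@dataclass
class BenchmarkResult:
    """Per-stratum and overall TP/FP/FN counts at one slop setting."""

    slop: int
    rows: List[dict] = field(default_factory=list)
    tp: int = 0
    fp: int = 0
    fn: int = 0
    matched_sv_ids: Set[str] = field(default_factory=set)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def fdr(self) -> float:
        return self.fp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = self.rows + [{
            "class": "ALL", "size_bin": "ALL", "slop": self.slop,
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "sensitivity": round(self.sensitivity, 6),
            "fdr": round(self.fdr, 6)}]
        return pd.DataFrame(rows, columns=["class", "size_bin", "slop", "tp",
                                           "fp", "fn", "sensitivity", "fdr"])

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class _IntervalIndex:
    """chrom -> sorted (start, end, sv_id); membership by position."""

    def __init__(self) -> None:
        self._by_chrom: Dict[str, List[Tuple[int, int, str]]] = defaultdict(list)
        self._starts: Dict[str, List[int]] = {}

    def add(self, chrom: str, start: int, end: int, sv_id: str) -> None:
        self._by_chrom[chrom].append((start, end, sv_id))

    def freeze(self) -> None:
        for chrom, ivals in self._by_chrom.items():
            ivals.sort()
            self._starts[chrom] = [iv[0] for iv in ivals]

    def hits(self, chrom: str, pos: int, max_width: int) -> Set[str]:
        ivals = self._by_chrom.get(chrom)
        if not ivals:
            return set()
        starts = self._starts[chrom]
        lo = bisect.bisect_right(starts, pos)
        out = set()
        i = lo - 1
        while i >= 0 and pos - ivals[i][0] <= max_width:
            if ivals[i][0] <= pos <= ivals[i][1]:
                out.add(ivals[i][2])
            i -= 1
        return out


def _build_index(truth: Sequence[TruthSV], pad: int, slop: int) -> Tuple[_IntervalIndex, int]:
    index = _IntervalIndex()
    width = pad + slop
    for sv in truth:
        for chrom, pos in sv.breakpoints():
            index.add(chrom, pos - width, pos + width, sv.sv_id)
    index.freeze()
    return index, 2 * width + 1


def evaluate_calls(calls: Sequence[SVCall], truth: Sequence[TruthSV],
                   slop: int, pad: int = DEFAULT_TRUTH_PAD) -> BenchmarkResult:
    """Score a call set against truth intervals of ``pad`` bp extended by ``slop``.

    Truth strata come from the truth SV's class and size; unmatched call
    records are stratified by their own (possibly UNK) classification and
    span, so per-stratum FP columns are indicative while the overall row is
    exact.
    """
    if slop < 0:
        raise ValueError("slop must be >= 0")
    index, width = _build_index(truth, pad, slop)
    by_id = {sv.sv_id: sv for sv in truth}

    matched: Set[str] = set()
    fp_calls: List[SVCall] = []
    ordered = sorted(calls, key=lambda c: (-c.support, c.chrom, c.pos, c.side))
    for call in ordered:
        bps = call.breakpoints
        if len(bps) < 2:
            fp_calls.append(call)
            continue
        hit_sets = [index.hits(chrom, pos, width) for chrom, pos in bps]
        cands = sorted(set.intersection(*hit_sets))
        fresh = [sv for sv in cands if sv not in matched]
        if fresh:
            matched.add(fresh[0])
        elif not cands:
            fp_calls.append(call)
        # else: duplicate record of an already-recalled SV

    result = BenchmarkResult(slop=slop)
    strata: Dict[Tuple[str, str], Dict[str, int]] = defaultdict(
        lambda: {"tp": 0, "fp": 0, "fn": 0})
    for sv in truth:
        key = (sv.sv_class, size_bin_label(sv.size))
        if sv.sv_id in matched:
            strata[key]["tp"] += 1
            result.tp += 1
        else:
            strata[key]["fn"] += 1
            result.fn += 1
    for call in fp_calls:
        cls = call.wc if call.wc != UNKNOWN_CLASS else "UNK"
        label = size_bin_label(call.svlen) if call.svlen else "NA"
        strata[(cls, label)]["fp"] += 1
        result.fp += 1
    for (cls, label), counts in sorted(strata.items()):
        tp, fp, fn = counts["tp"], counts["fp"], counts["fn"]
        result.rows.append({
            "class": cls, "size_bin": label, "slop": slop,
            "tp": tp, "fp": fp, "fn": fn,
            "sensitivity": round(tp / (tp + fn), 6) if tp + fn else 0.0,
            "fdr": round(fp / (tp + fp), 6) if tp + fp else 0.0})
    result.matched_sv_ids = matched
    return result


def breakpoint_accuracy_curve(calls: Sequence[SVCall], truth: Sequence[TruthSV],
                              slops: Iterable[int] = DEFAULT_SLOPS
                              ) -> Dict[int, float]:
    """Sensitivity vs slop on raw breakpoints (no truth-interval padding)."""
    return {s: evaluate_calls(calls, truth, slop=s, pad=0).sensitivity
            for s in slops}


def load_truth_bed(path: str, return_pad: bool = False):
    """Reconstruct truth SVs from a 5-column truth-interval BED.

    Interval midpoints are the breakpoints; the SV size is the span between
    the two most distant same-chromosome breakpoints (0 when only one
    midpoint exists, e.g. a pure insertion point).  With ``return_pad`` the
    median interval half-width is returned too, so scoring can reproduce the
    BED's own confidence padding.
    """
    groups: Dict[str, List[Tuple[str, int, str]]] = defaultdict(list)
    widths: List[int] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            chrom, start, end = f[0], int(f[1]), int(f[2])
            widths.append(end - start)
            sv_id = f[3] if len(f) > 3 else f"{chrom}:{start}"
            cls = f[4] if len(f) > 4 else UNKNOWN_CLASS
            groups[sv_id].append((chrom, (start + end) // 2, cls))
    out = []
    for sv_id, bps in groups.items():
        cls = bps[0][2]
        by_chrom: Dict[str, List[int]] = defaultdict(list)
        for chrom, mid, _ in bps:
            by_chrom[chrom].append(mid)
        size = max((max(v) - min(v) for v in by_chrom.values()), default=0)
        chrom0, pos0, _ = bps[0]
        out.append(TruthSV(sv_id=sv_id, sv_class=cls, chrom=chrom0, start=pos0,
                           end=pos0 + size, size=size,
                           explicit_breakpoints=[(c, m) for c, m, _ in bps]))
    if return_pad:
        widths.sort()
        pad = widths[len(widths) // 2] // 2 if widths else 0
        return out, pad
    return out
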