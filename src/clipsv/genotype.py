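"""Bi-allelic SV genotyping from mapping-quality-weighted read evidence.

Each read overlapping a breakpoint is classified as reference or alternative
evidence: clips at the breakpoint, large internal indels spanning it,
discordant pairs and same-strand (inversion-signature) pairs are alternative;
clean spanning reads are reference.  The genotype likelihood is the standard
per-read mixture model used by short-read SNP genotypers, with the read's
mapping quality standing in for base quality: with error probability
``e = 10^(-mapq/10)`` (capped at 0.5 so MAPQ 0 is uninformative), a genotype
with ``g`` alternative copies explains an alt observation with probability
``(g/2)(1-e) + (1-g/2)e`` and symmetrically for reference observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

import numpy as np

from .bamio import AlignedRead
from .variants import GenotypeCall, SVCall

#: minimum internal I/D CIGAR length treated as breakpoint evidence.
MIN_INTERNAL_INDEL = 10
#: an individual needs this many alt reads for a site to survive joint calling.
JOINT_MIN_ALT_READS = 3

ALT_BASES = ("clipped_at_breakpoint", "internal_breakpoint",
             "discordant_pair", "same_strand_pair")


@dataclass(slots=True)
class ReadEvidence:
    read_ref: str
    allele: str                   # "ref" or "alt"
    mapq: int
    basis: str


@dataclass(slots=True)
class InsertStats:
    mu: float
    sigma: float

    @property
    def upper(self) -> float:
        return self.mu + 3.0 * self.sigma


def estimate_insert_stats(tlens: Iterable[int],
                          max_pairs: int = 100_000) -> InsertStats:
    """Robust (median/MAD) insert-size location and scale from proper pairs."""
    vals = []
    for t in tlens:
        if t > 0:
            vals.append(t)
            if len(vals) >= max_pairs:
                break
    if not vals:
        return InsertStats(400.0, 50.0)
    arr = np.asarray(vals, dtype=float)
    mu = float(np.median(arr))
    mad = float(np.median(np.abs(arr - mu)))
    sigma = 1.4826 * mad if mad > 0 else max(1.0, 0.1 * mu)
    return InsertStats(mu, sigma)


def _internal_indel_spans(read: AlignedRead, pos: int) -> bool:
    """True when a >=10 bp I/D CIGAR op sits at/over the breakpoint."""
    ref = read.pos
    for op, n in read.cigar:
        if op in "M=XN":
            ref += n
        elif op == "D":
            if n >= MIN_INTERNAL_INDEL and ref <= pos <= ref + n:
                return True
            ref += n
        elif op == "I":
            if n >= MIN_INTERNAL_INDEL and abs(ref - pos) <= 1:
                return True
    return False


def classify_read(read: AlignedRead, call: SVCall,
                  insert_stats: InsertStats) -> Optional[ReadEvidence]:
    """Classify one read as reference/alternative evidence for a call.

    A read is counted at most once; the strongest alternative basis wins
    (clip > internal indel > discordant pair > same-strand pair).  Reads that
    neither touch nor span a breakpoint return ``None``.
    """
    positions = [call.pos]
    if call.mate is not None and call.mate.chrom == read.chrom:
        positions.append(call.mate.pos)
    rstart, rend = read.pos, read.reference_end

    first_op = read.cigar[0][0] if read.cigar else ""
    last_op = read.cigar[-1][0] if read.cigar else ""
    clip_positions = []
    if first_op in "SH":
        clip_positions.append(rstart)
    if last_op in "SH" and len(read.cigar) > 1:
        clip_positions.append(rend)
    if any(cp in positions for cp in clip_positions):
        return ReadEvidence(read.query_name, "alt", read.mapq, "clipped_at_breakpoint")

    overlaps = any(rstart <= p < rend for p in positions)
    if overlaps and any(_internal_indel_spans(read, p) for p in positions):
        return ReadEvidence(read.query_name, "alt", read.mapq, "internal_breakpoint")

    if read.is_paired and not read.mate_is_unmapped:
        near = overlaps or any(abs(rstart - p) <= rend - rstart for p in positions)
        if near:
            inter = read.mate_chrom not in (None, read.chrom)
            if inter or abs(read.tlen) > insert_stats.upper:
                return ReadEvidence(read.query_name, "alt", read.mapq, "discordant_pair")
            if read.is_reverse == read.mate_is_reverse:
                return ReadEvidence(read.query_name, "alt", read.mapq, "same_strand_pair")

    if overlaps:
        return ReadEvidence(read.query_name, "ref", read.mapq, "reference_spanning")
    return None


def genotype_likelihoods(evidence: List[ReadEvidence]) -> GenotypeCall:
    """Bi-allelic genotype call from read evidence under a flat prior.

    Likelihoods are accumulated in log10 space and normalized so the best
    genotype has GL 0.  Empty evidence yields ``./.`` with GLs (0,0,0).
    """
    if not evidence:
        return GenotypeCall("./.", (0.0, 0.0, 0.0), 0, 0, 0)
    logl = np.zeros(3)
    alt_count = 0
    for ev in evidence:
        e = min(10.0 ** (-ev.mapq / 10.0), 0.5)
        p_alt_given_alt, p_alt_given_ref = 1.0 - e, e
        if ev.allele == "alt":
            alt_count += 1
            p_ref_allele, p_alt_allele = p_alt_given_ref, p_alt_given_alt
        else:
            p_ref_allele, p_alt_allele = 1.0 - p_alt_given_ref, 1.0 - p_alt_given_alt
        for g in range(3):
            p = (g / 2.0) * p_alt_allele + (1.0 - g / 2.0) * p_ref_allele
            logl[g] += math.log10(max(p, 1e-300))
    norm = logl - logl.max()
    g_best = int(np.argmax(norm))
    posts = 10.0 ** norm
    posts /= posts.sum()
    p_err = max(1.0 - posts[g_best], 1e-100)
    gq = int(min(99, round(-10.0 * math.log10(p_err))))
    gt = ("0/0", "0/1", "1/1")[g_best]
    return GenotypeCall(gt, tuple(float(x) for x in norm),
                        len(evidence), alt_count, gq)


def joint_site_filter(per_sample_alt_counts: Dict[str, int],
                      min_alt_reads: int = JOINT_MIN_ALT_READS) -> bool:
    """True when at least one individual has >= 3 alternative-allele reads.

    Guards joint calling against soft-clip start/stop positions randomly
    shared across individuals.
    """
    return any(v >= min_alt_reads for v in per_sample_alt_counts.values())
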