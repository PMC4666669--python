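"""Synthetic truth SVs and the alignment-level evidence they induce.

The generator builds a random reference genome, implants four classes of
structural variants (deletions, tandem duplications, inter-chromosomal
copy insertions, inversions) into per-sample diploid haplotypes, and emits a
coordinate-sorted, indexed BAM of paired-end reads *as an aligner would
report them*: fragments are tiled over each haplotype, each read's haplotype
interval is mapped through a piecewise segment map back to reference
coordinates, and reads crossing a junction become soft-clipped records whose
SA tag points at the partner locus (strand-flipped inside inversions,
mate-everted across tandem-duplication junctions, inter-chromosomal for
copy insertions).  Mapping imperfections of real pipelines are emulated:
substitution errors at a configurable rate, junction reads that the aligner
fails to clip cleanly (``clip_fraction``), split pieces too short to seed a
supplementary alignment (``sa_min_seed``), and a low rate of chimeric
artifact reads carrying spurious clipped tails.

Everything is deterministic per seed.  What the emulation does *not* model
(reference errors, mobile elements, base-quality profiles, true mapping
ambiguity in repeats) is discussed in the methods documentation.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .variants import SV_CLASSES

_COMP = str.maketrans("ACGTN", "TGCAN")

HET = "het"
HOM = "hom"

# SAM flag bits
_PAIRED, _PROPER, _REVERSE, _MREVERSE = 0x1, 0x2, 0x10, 0x20
_READ1, _READ2, _SUPPLEMENTARY = 0x40, 0x80, 0x800


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Study conditions for one simulation; the seed is mandatory."""

    seed: int
    n_chroms: int = 4
    chrom_length: int = 5_000_000
    n_svs_per_class: int = 100
    min_sv_size: int = 50
    max_sv_size: int = 1_000_000
    coverage: float = 50.0
    read_length: int = 100
    insert_mu: float = 400.0
    insert_sigma: float = 50.0
    base_error_rate: float = 0.001
    clip_fraction: float = 0.9       # junction reads the aligner clips cleanly
    chimera_rate: float = 2e-4       # reads with a spurious clipped tail
    chimera_pair_rate: float = 0.01  # ligation-artifact fragments (discordant pairs)
    low_mapq_noise: float = 0.01     # background reads with depressed MAPQ
    duplicate_rate: float = 0.03     # PCR duplicates (emitted duplicate-flagged)
    sa_min_seed: int = 20            # min split-piece length for an SA entry
    cnv_mapq: int = 10               # MAPQ for reads inside duplicated content
    max_match_extension: int = 25    # aligner match extension past a junction
    min_gap: int = 1_000             # spacing between implanted SVs
    edge_margin: int = 2_000         # SV-free zone at contig ends
    het_fraction: float = 0.5
    samples: Tuple[str, ...] = ("s1",)

    def chrom_names(self) -> List[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class TruthSV:
    """One implanted variant with its reference-coordinate breakpoints."""

    sv_id: str
    sv_class: str                    # DEL / DUP / INS / INV
    chrom: str
    start: int                       # 0-based; start == end for INS (acceptor)
    end: int
    size: int
    zygosity: Dict[str, str] = field(default_factory=dict)   # sample -> het/hom
    het_hap: Dict[str, int] = field(default_factory=dict)    # haplotype carrying a het
    donor_chrom: Optional[str] = None
    donor_start: Optional[int] = None
    donor_end: Optional[int] = None
    #: explicit breakpoint list for truth sets loaded from BED
    explicit_breakpoints: Optional[List[Tuple[str, int]]] = None

    def breakpoints(self) -> List[Tuple[str, int]]:
        if self.explicit_breakpoints is not None:
            return list(self.explicit_breakpoints)
        if self.sv_class == "INS":
            return [(self.chrom, self.start),
                    (self.donor_chrom, self.donor_start),
                    (self.donor_chrom, self.donor_end)]
        return [(self.chrom, self.start), (self.chrom, self.end)]

    def on_haplotype(self, sample: str, hap: int) -> bool:
        z = self.zygosity.get(sample)
        if z == HOM:
            return True
        if z == HET:
            return self.het_hap.get(sample, 0) == hap
        return False


# ---------------------------------------------------------------------------
# reference and truth-set generation
# ---------------------------------------------------------------------------

def generate_reference(config: SimConfig,
                       rng: Optional[np.random.Generator] = None) -> Dict[str, str]:
    """I.i.d. uniform-ACGT contigs; byte-identical per seed."""
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    bases = np.frombuffer(b"ACGT", dtype="S1")
    ref = {}
    for name in config.chrom_names():
        arr = bases[rng.integers(0, 4, config.chrom_length)]
        ref[name] = arr.tobytes().decode()
    return ref


def write_fasta(ref: Dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in ref.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    pysam.faidx(path)


class _Occupancy:
    """Per-contig reserved intervals with a minimum-gap overlap test."""

    def __init__(self, gap: int):
        self.gap = gap
        self.intervals: Dict[str, List[Tuple[int, int]]] = {}

    def free(self, chrom: str, start: int, end: int) -> bool:
        for s, e in self.intervals.get(chrom, ()):
            if start - self.gap < e and s < end + self.gap:
                return False
        return True

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self.intervals.setdefault(chrom, []).append((start, end))


def implant_svs(ref: Dict[str, str], config: SimConfig,
                rng: Optional[np.random.Generator] = None) -> List[TruthSV]:
    """Place non-overlapping truth SVs of the four classes.

    Sizes are drawn log-uniformly on [min_sv_size, max_sv_size]; when the
    genome fills up, the size cap for further draws is halved until a
    placement fits (the largest size stratum is therefore thinner on small
    genomes than the nominal law).  Classes are placed round-robin so every
    class samples the whole size range.  Zygosity is het or hom per sample
    with probability ``het_fraction``; hets land on a random haplotype.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    occ = _Occupancy(config.min_gap)
    chroms = config.chrom_names()
    truth: List[TruthSV] = []
    counter = 0

    def draw_size(cap: int) -> int:
        lo, hi = math.log(config.min_sv_size), math.log(max(cap, config.min_sv_size + 1))
        return int(round(math.exp(rng.uniform(lo, hi))))

    def place(span: int) -> Optional[Tuple[str, int]]:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        limit = len(ref[chrom]) - config.edge_margin - span
        if limit <= config.edge_margin:
            return None
        start = int(rng.integers(config.edge_margin, limit))
        if occ.free(chrom, start, start + span):
            return chrom, start
        return None

    for i in range(config.n_svs_per_class):
        for cls in SV_CLASSES:
            cap = min(config.max_sv_size, config.chrom_length // 4)
            placed = None
            for attempt in range(400):
                size = draw_size(cap)
                if cls == "INS":
                    spot = place(1)
                    if spot is None:
                        continue
                    donor = place(size)
                    # donors come from another contig when one exists
                    if donor is None or (len(chroms) > 1 and donor[0] == spot[0]):
                        continue
                    placed = (spot, donor, size)
                else:
                    spot = place(size)
                    if spot is not None:
                        placed = (spot, None, size)
                if placed is not None:
                    break
                if attempt % 40 == 39:
                    cap = max(config.min_sv_size * 2, cap // 2)
            if placed is None:
                raise ValueError(
                    f"genome too small for the requested SV load "
                    f"({config.n_svs_per_class} per class on "
                    f"{config.n_chroms}x{config.chrom_length} bp)")
            (chrom, start), donor, size = placed
            counter += 1
            sv = TruthSV(sv_id=f"sv{counter:04d}", sv_class=cls, chrom=chrom,
                         start=start,
                         end=start + (0 if cls == "INS" else size),
                         size=size)
            occ.reserve(chrom, sv.start, max(sv.end, sv.start + 1))
            if donor is not None:
                sv.donor_chrom, sv.donor_start = donor
                sv.donor_end = sv.donor_start + size
                occ.reserve(sv.donor_chrom, sv.donor_start, sv.donor_end)
            for sample in config.samples:
                het = rng.random() < config.het_fraction
                sv.zygosity[sample] = HET if het else HOM
                sv.het_hap[sample] = int(rng.integers(0, 2))
            truth.append(sv)
    truth.sort(key=lambda s: (s.chrom, s.start, s.sv_id))
    return truth


def write_truth_bed(truth: Sequence[TruthSV], path: str, pad: int = 25) -> None:
    """Truth intervals: pad bp up- and downstream of every breakpoint."""
    rows = []
    for sv in truth:
        for chrom, pos in sv.breakpoints():
            rows.append((chrom, max(0, pos - pad), pos + pad, sv.sv_id, sv.sv_class))
    rows.sort()
    with open(path, "w") as fh:
        for chrom, s, e, sid, cls in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{sid}\t{cls}\n")


def write_truth_table(truth: Sequence[TruthSV], path: str) -> None:
    """Full truth table (TSV) including size, class, donor and zygosity."""
    with open(path, "w") as fh:
        fh.write("sv_id\tclass\tchrom\tstart\tend\tsize\tdonor_chrom\t"
                 "donor_start\tdonor_end\tzygosity\n")
        for sv in truth:
            zyg = ",".join(f"{s}:{z}" for s, z in sorted(sv.zygosity.items()))
            fh.write(f"{sv.sv_id}\t{sv.sv_class}\t{sv.chrom}\t{sv.start}\t"
                     f"{sv.end}\t{sv.size}\t{sv.donor_chrom or '.'}\t"
                     f"{'.' if sv.donor_start is None else sv.donor_start}\t"
                     f"{'.' if sv.donor_end is None else sv.donor_end}\t{zyg}\n")


def read_truth_table(path: str) -> List[TruthSV]:
    out: List[TruthSV] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            zyg = {}
            if f[9]:
                for item in f[9].split(","):
                    s, z = item.split(":")
                    zyg[s] = z
            out.append(TruthSV(
                sv_id=f[0], sv_class=f[1], chrom=f[2], start=int(f[3]),
                end=int(f[4]), size=int(f[5]),
                zygosity=zyg,
                donor_chrom=None if f[6] == "." else f[6],
                donor_start=None if f[7] == "." else int(f[7]),
                donor_end=None if f[8] == "." else int(f[8])))
    return out


def write_truth_vcf(truth: Sequence[TruthSV], ref: Dict[str, str], path: str) -> None:
    lines = ["##fileformat=VCFv4.2", "##source=clipsv-simulate",
             '##INFO=<ID=END,Number=1,Type=Integer,Description="End">',
             '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">',
             '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV size">']
    for name, seq in ref.items():
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for sv in truth:
        lines.append(f"{sv.chrom}\t{sv.start + 1}\t{sv.sv_id}\tN\t<{sv.sv_class}>"
                     f"\t.\tPASS\tEND={sv.end + 1};SVTYPE={sv.sv_class};"
                     f"SVLEN={sv.size}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# haplotype segment maps
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class Segment:
    """One reference piece of a haplotype: hap [hap_start, hap_start+len)."""

    hap_start: int
    chrom: str
    r0: int
    r1: int
    strand: str                      # '+' or '-'

    @property
    def length(self) -> int:
        return self.r1 - self.r0


def haplotype_segments(ref: Dict[str, str], truth: Sequence[TruthSV],
                       sample: str, hap: int) -> Dict[str, List[Segment]]:
    """Piecewise map hap coordinates -> reference pieces, per carrier contig."""
    by_chrom: Dict[str, List[TruthSV]] = {c: [] for c in ref}
    for sv in truth:
        if sv.on_haplotype(sample, hap):
            by_chrom[sv.chrom].append(sv)
    maps: Dict[str, List[Segment]] = {}
    for chrom, svs in by_chrom.items():
        svs.sort(key=lambda s: s.start)
        segs: List[Segment] = []
        hap_pos = 0
        cursor = 0

        def emit(c: str, r0: int, r1: int, strand: str = "+") -> None:
            nonlocal hap_pos
            if r1 > r0:
                segs.append(Segment(hap_pos, c, r0, r1, strand))
                hap_pos += r1 - r0
        for sv in svs:
            emit(chrom, cursor, sv.start)
            cursor = sv.start
            if sv.sv_class == "DEL":
                cursor = sv.end
            elif sv.sv_class == "DUP":
                emit(chrom, sv.start, sv.end)
                emit(chrom, sv.start, sv.end)
                cursor = sv.end
            elif sv.sv_class == "INV":
                emit(chrom, sv.start, sv.end, "-")
                cursor = sv.end
            elif sv.sv_class == "INS":
                emit(sv.donor_chrom, sv.donor_start, sv.donor_end)
        emit(chrom, cursor, len(ref[chrom]))
        maps[chrom] = segs
    return maps


def haplotype_sequence(ref: Dict[str, str], segs: List[Segment]) -> str:
    parts = []
    for seg in segs:
        piece = ref[seg.chrom][seg.r0:seg.r1]
        parts.append(piece if seg.strand == "+" else _revcomp(piece))
    return "".join(parts)


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class _Placement:
    chrom: str
    pos: int
    cigar: str
    seq: str
    reverse: bool
    mapq: int = 60
    sa: str = ""
    xa: str = ""
    ref_end: int = 0


def _blocks(a: int, b: int, segs: List[Segment], seg_starts: np.ndarray):
    """Split hap interval [a, b) into per-segment blocks."""
    i = int(np.searchsorted(seg_starts, a, side="right")) - 1
    out = []
    x = a
    while x < b and i < len(segs):
        seg = segs[i]
        seg_end = seg.hap_start + seg.length
        y = min(b, seg_end)
        out.append((x - a, y - a, seg, x))
        x = y
        i += 1
    return out


def _sa_entry(p: _Placement) -> str:
    strand = "-" if p.reverse else "+"
    return f"{p.chrom},{p.pos + 1},{strand},{p.cigar},{p.mapq},0;"


class _ReadMapper:
    """Aligner emulation for one (sample, haplotype, contig).

    Mapping follows the score-maximizing behavior of a BWA-MEM-like aligner:
    the largest reference-colinear block anchors the read; alignment is
    extended base-by-base past the junction while the read happens to match
    the reference continuation (chance microhomology, so the reported clip
    boundary can sit a few bases off the molecular junction, identically for
    every read over that junction); small deletions are absorbed as internal
    D ops whenever the through-gap score beats the clipped score (overhang >
    deletion size + 1 under unit match / affine-gap scoring); remaining
    pieces become soft clips with SA entries when they are long enough to
    seed (``sa_min_seed``).  Reads whose primary block lies inside duplicated
    sample content (tandem-duplication spans, insertion donor copies) are
    reported at ``cnv_mapq``, mirroring the depressed mapping confidence of
    CNV loci.
    """

    def __init__(self, segs: List[Segment], ref: Dict[str, str],
                 config: SimConfig,
                 dup_content: Dict[str, List[Tuple[int, int, str, int]]]):
        self.segs = segs
        self.seg_starts = np.array([s.hap_start for s in segs])
        self.ref = ref
        self.config = config
        # chrom -> sorted (start, end, partner_chrom, partner_pos)
        self.dup_content = dup_content
        self._dup_starts = {c: [iv[0] for iv in ivs]
                            for c, ivs in dup_content.items()}

    def _in_dup_content(self, chrom: str, start: int, end: int):
        ivs = self.dup_content.get(chrom)
        if not ivs:
            return None
        import bisect as _bisect
        i = _bisect.bisect_right(self._dup_starts[chrom], start) - 1
        if i >= 0 and ivs[i][0] <= start and end <= ivs[i][1]:
            return ivs[i]
        return None

    def _extend(self, qs: int, qe: int, seg: Segment, hap_x: int,
                seq_hap: str) -> Tuple[int, int, int]:
        """Match-extension of a block into its clipped neighborhoods.

        Returns (qs, qe, ref_start) after extending while read bases match
        the reference continuation (up to ``max_match_extension`` per side).
        """
        cap = self.config.max_match_extension
        length = len(seq_hap)
        chrom_seq = self.ref[seg.chrom]
        if seg.strand == "+":
            pos = seg.r0 + (hap_x - seg.hap_start)
            end_ref = pos + (qe - qs)
            i = 0
            while (i < cap and qe + i < length and end_ref + i < len(chrom_seq)
                   and seq_hap[qe + i] == chrom_seq[end_ref + i]):
                i += 1
            qe += i
            j = 0
            while (j < cap and qs - 1 - j >= 0 and pos - 1 - j >= 0
                   and seq_hap[qs - 1 - j] == chrom_seq[pos - 1 - j]):
                j += 1
            return qs - j, qe, pos - j
        r_end = seg.r1 - (hap_x - seg.hap_start)
        r_start = r_end - (qe - qs)
        comp = _COMP
        i = 0
        while (i < cap and qe + i < length and r_start - 1 - i >= 0
               and seq_hap[qe + i] == chrom_seq[r_start - 1 - i].translate(comp)):
            i += 1
        qe += i
        r_start -= i
        j = 0
        while (j < cap and qs - 1 - j >= 0 and r_end + j < len(chrom_seq)
               and seq_hap[qs - 1 - j] == chrom_seq[r_end + j].translate(comp)):
            j += 1
        return qs - j, qe, r_start

    def _placement(self, qs: int, qe: int, seg: Segment, hap_x: int,
                   orient: str, seq_hap: str, extend: bool) -> _Placement:
        length = len(seq_hap)
        if extend:
            qs, qe, pos = self._extend(qs, qe, seg, hap_x, seq_hap)
        elif seg.strand == "+":
            pos = seg.r0 + (hap_x - seg.hap_start)
        else:
            pos = seg.r1 - (hap_x - seg.hap_start) - (qe - qs)
        span = qe - qs
        if seg.strand == "+":
            lead, trail = qs, length - qe
            reverse = orient == "-"
            seq = seq_hap
        else:
            lead, trail = length - qe, qs
            reverse = orient == "+"
            seq = _revcomp(seq_hap)
        cigar = (f"{lead}S" if lead else "") + f"{span}M" + \
                (f"{trail}S" if trail else "")
        mapq = 60
        hit = self._in_dup_content(seg.chrom, pos, pos + span)
        p = _Placement(seg.chrom, pos, cigar, seq, reverse, mapq,
                       ref_end=pos + span)
        if hit is not None:
            p.mapq = self.config.cnv_mapq
            if hit[2] is not None:
                strand = "-" if reverse else "+"
                p.xa = f"{hit[2]},{strand}{hit[3] + 1},{span}M,0;"
        return p

    def _try_absorb_deletion(self, blocks, orient: str, seq_hap: str
                             ) -> Optional[_Placement]:
        """Internal-D representation when the gap score beats clipping."""
        if len(blocks) != 2:
            return None
        (q0s, q0e, seg0, x0), (q1s, q1e, seg1, x1) = sorted(blocks,
                                                            key=lambda b: b[0])
        if seg0.chrom != seg1.chrom or seg0.strand != "+" or seg1.strand != "+":
            return None
        p0 = seg0.r0 + (x0 - seg0.hap_start)
        p1 = seg1.r0 + (x1 - seg1.hap_start)
        gap = p1 - (p0 + (q0e - q0s))
        if gap <= 0:
            return None
        minor = min(q0e - q0s, q1e - q1s)
        if minor <= gap + 1:
            return None
        length = len(seq_hap)
        cigar = f"{q0e - q0s}M{gap}D{q1e - q1s}M"
        return _Placement(seg0.chrom, p0, cigar, seq_hap, orient == "-", 60,
                          ref_end=p1 + (q1e - q1s))

    def map_read(self, a: int, b: int, orient: str, seq_hap: str,
                 clip_cleanly: bool
                 ) -> Optional[Tuple[_Placement, List[_Placement]]]:
        blocks = _blocks(a, b, self.segs, self.seg_starts)
        if not blocks:
            return None
        absorbed = self._try_absorb_deletion(blocks, orient, seq_hap)
        if absorbed is not None:
            return absorbed, []
        blocks.sort(key=lambda blk: blk[1] - blk[0], reverse=True)
        qs, qe, seg, hap_x = blocks[0]
        if qe - qs < self.config.sa_min_seed:
            return None                   # nothing the aligner could anchor
        primary = self._placement(qs, qe, seg, hap_x, orient, seq_hap, True)
        if len(blocks) == 1:
            return primary, []
        if not clip_cleanly:
            # aligner forced the whole read through the primary locus
            length = len(seq_hap)
            start_shift = qs if seg.strand == "+" else length - qe
            pos = max(0, primary.pos - start_shift)
            forced = replace(primary, pos=pos, cigar=f"{length}M", sa="",
                             ref_end=pos + length)
            return forced, []
        splits = []
        for bqs, bqe, bseg, bhap_x in blocks[1:]:
            if bqe - bqs >= self.config.sa_min_seed:
                splits.append(self._placement(bqs, bqe, bseg, bhap_x, orient,
                                              seq_hap, True))
        if splits:
            primary.sa = "".join(_sa_entry(s) for s in splits)
            back = _sa_entry(primary)
            for s in splits:
                s.sa = back
        return primary, splits


def _pair_flags(p1: _Placement, p2: _Placement, mu: float, sigma: float
                ) -> Tuple[int, int, int, int]:
    """(flag1, flag2, tlen1, tlen2) for the two primary placements."""
    f1 = _PAIRED | _READ1
    f2 = _PAIRED | _READ2
    if p1.reverse:
        f1 |= _REVERSE
        f2 |= _MREVERSE
    if p2.reverse:
        f2 |= _REVERSE
        f1 |= _MREVERSE
    t1 = t2 = 0
    if p1.chrom == p2.chrom:
        left = min(p1.pos, p2.pos)
        right = max(p1.ref_end, p2.ref_end)
        t = right - left
        if (p1.pos, p2.reverse) <= (p2.pos, p1.reverse):
            t1, t2 = t, -t
            leftmost, rightmost = p1, p2
        else:
            t1, t2 = -t, t
            leftmost, rightmost = p2, p1
        proper = (not leftmost.reverse and rightmost.reverse
                  and mu - 3 * sigma <= t <= mu + 3 * sigma)
        if proper:
            f1 |= _PROPER
            f2 |= _PROPER
    return f1, f2, t1, t2


def _sam_line(name: str, flag: int, p: _Placement, mate: _Placement,
              tlen: int, sample: str, supplementary: bool = False) -> str:
    rnext = "=" if mate.chrom == p.chrom else mate.chrom
    tags = f"RG:Z:{sample}"
    if p.sa:
        tags += f"\tSA:Z:{p.sa}"
    if p.xa:
        tags += f"\tXA:Z:{p.xa}"
    fl = flag | (_SUPPLEMENTARY if supplementary else 0)
    return (f"{name}\t{fl}\t{p.chrom}\t{p.pos + 1}\t{p.mapq}\t{p.cigar}\t"
            f"{rnext}\t{mate.pos + 1}\t{tlen}\t{p.seq}\t*\t{tags}")


_BASES = "ACGT"


def emit_alignments(ref: Dict[str, str], truth: Sequence[TruthSV],
                    config: SimConfig, out_bam: str,
                    rng: Optional[np.random.Generator] = None,
                    fastq_prefix: Optional[str] = None) -> str:
    """Write the sorted, indexed BAM of emulated alignments for all samples.

    Optionally also writes raw read pairs as ``{fastq_prefix}_1.fastq`` /
    ``_2.fastq`` for users who want a genuine aligner round trip.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    rl = config.read_length
    sam_path = out_bam + ".unsorted.sam"
    fq1 = fq2 = None
    if fastq_prefix:
        fq1 = open(fastq_prefix + "_1.fastq", "w")
        fq2 = open(fastq_prefix + "_2.fastq", "w")

    with open(sam_path, "w") as sam:
        sam.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in ref.items():
            sam.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for sample in config.samples:
            sam.write(f"@RG\tID:{sample}\tSM:{sample}\n")

        dup_content = _duplicated_content(truth)
        for sample in config.samples:
            for hap in (0, 1):
                seg_maps = haplotype_segments(ref, truth, sample, hap)
                for chrom in config.chrom_names():
                    segs = seg_maps[chrom]
                    _emit_chrom(sam, ref, segs, config, rng, sample, hap,
                                chrom, dup_content, fq1, fq2)
    if fq1:
        fq1.close()
        fq2.close()

    pysam.sort("-o", out_bam, sam_path)
    pysam.index(out_bam)
    os.remove(sam_path)
    return out_bam


def _duplicated_content(truth: Sequence[TruthSV]
                        ) -> Dict[str, List[Tuple[int, int, Optional[str], int]]]:
    """Reference spans present in >1 copy in some sample genome."""
    out: Dict[str, List[Tuple[int, int, Optional[str], int]]] = {}
    for sv in truth:
        if sv.sv_class == "DUP":
            out.setdefault(sv.chrom, []).append((sv.start, sv.end, None, 0))
        elif sv.sv_class == "INS":
            out.setdefault(sv.donor_chrom, []).append(
                (sv.donor_start, sv.donor_end, sv.chrom, sv.start))
    for ivs in out.values():
        ivs.sort()
    return out


def _emit_chrom(sam, ref, segs: List[Segment], config: SimConfig, rng,
                sample: str, hap: int, chrom: str, dup_content,
                fq1, fq2) -> None:
    rl = config.read_length
    hap_len = sum(s.length for s in segs)
    if hap_len < 3 * rl:
        return
    n_frags = int(config.coverage / 2.0 * hap_len / (2.0 * rl))
    if n_frags == 0:
        return
    hap_seq = haplotype_sequence(ref, segs)
    mapper = _ReadMapper(segs, ref, config, dup_content)
    seg_starts = mapper.seg_starts
    seg_plus = np.array([s.strand == "+" for s in segs])

    flens = np.clip(np.rint(rng.normal(config.insert_mu, config.insert_sigma,
                                       n_frags)).astype(np.int64),
                    2 * rl + 10, max(2 * rl + 10, hap_len - 1))
    starts = (rng.random(n_frags) * (hap_len - flens)).astype(np.int64)

    # fragments fully inside a single forward segment take the fast path
    i0 = np.searchsorted(seg_starts, starts, side="right") - 1
    i1 = np.searchsorted(seg_starts, starts + flens - 1, side="right") - 1
    simple = (i0 == i1) & seg_plus[np.clip(i0, 0, len(segs) - 1)]

    # substitution errors: (read_index, offset) pairs, sorted by read index
    n_reads = 2 * n_frags
    n_err = rng.poisson(n_reads * rl * config.base_error_rate)
    err_reads = np.sort(rng.integers(0, n_reads, n_err))
    err_offsets = rng.integers(0, rl, n_err)
    err_bases = rng.integers(0, 3, n_err)
    chimera = rng.random(n_reads) < config.chimera_rate
    chim_pair = rng.random(n_frags) < config.chimera_pair_rate
    lowq = rng.random(n_reads) < config.low_mapq_noise
    lowq_vals = rng.integers(0, 20, n_reads)
    clip_ok = rng.random(n_reads) < config.clip_fraction
    duplicate = rng.random(n_frags) < config.duplicate_rate
    chrom_names = list(ref.keys())

    def random_partner() -> Optional[_Placement]:
        """A read from an unrelated locus: a ligation-artifact mate."""
        c = chrom_names[int(rng.integers(0, len(chrom_names)))]
        if len(ref[c]) <= rl + 1:
            return None
        p = int(rng.integers(0, len(ref[c]) - rl))
        return _Placement(c, p, f"{rl}M", ref[c][p:p + rl],
                          bool(rng.integers(0, 2)), ref_end=p + rl)

    err_ptr = 0

    def read_errors(ridx: int, seq: str) -> str:
        nonlocal err_ptr
        while err_ptr < n_err and err_reads[err_ptr] < ridx:
            err_ptr += 1
        j = err_ptr
        chars = None
        while j < n_err and err_reads[j] == ridx:
            off = int(err_offsets[j])
            if chars is None:
                chars = list(seq)
            old = chars[off]
            alts = _BASES.replace(old, "") if old in _BASES else _BASES[:3]
            chars[off] = alts[int(err_bases[j]) % len(alts)]
            j += 1
        return "".join(chars) if chars is not None else seq

    def apply_chimera(p: _Placement, tail: int = 40) -> _Placement:
        if len(p.seq) != rl or "S" in p.cigar:
            return p
        junk = "".join(_BASES[int(x)] for x in rng.integers(0, 4, tail))
        return replace(p, seq=p.seq[:rl - tail] + junk,
                       cigar=f"{rl - tail}M{tail}S", sa="",
                       ref_end=p.pos + rl - tail)

    mu, sigma = config.insert_mu, config.insert_sigma
    for k in range(n_frags):
        s = int(starts[k])
        flen = int(flens[k])
        r1_idx, r2_idx = 2 * k, 2 * k + 1
        a1, b1 = s, s + rl
        a2, b2 = s + flen - rl, s + flen
        seq1 = read_errors(r1_idx, hap_seq[a1:b1])
        seq2 = read_errors(r2_idx, hap_seq[a2:b2])
        name = f"{sample}.{hap}.{chrom}.{k}"

        if fq1 is not None:
            q = "I" * rl
            fq1.write(f"@{name}\n{seq1}\n+\n{q}\n")
            fq2.write(f"@{name}\n{_revcomp(seq2)}\n+\n{q}\n")

        if simple[k]:
            seg = segs[int(i0[k])]
            off = seg.r0 - seg.hap_start
            p1 = _Placement(seg.chrom, a1 + off, f"{rl}M", seq1, False,
                            ref_end=a1 + off + rl)
            p2 = _Placement(seg.chrom, a2 + off, f"{rl}M", seq2, True,
                            ref_end=a2 + off + rl)
            for p in (p1, p2):
                hit = mapper._in_dup_content(p.chrom, p.pos, p.ref_end)
                if hit is not None:
                    p.mapq = config.cnv_mapq
                    if hit[2] is not None:
                        strand = "-" if p.reverse else "+"
                        p.xa = f"{hit[2]},{strand}{hit[3] + 1},{rl}M,0;"
            sup1: List[_Placement] = []
            sup2: List[_Placement] = []
        else:
            m1 = mapper.map_read(a1, b1, "+", seq1, bool(clip_ok[r1_idx]))
            m2 = mapper.map_read(a2, b2, "-", seq2, bool(clip_ok[r2_idx]))
            if m1 is None or m2 is None:
                continue                   # unanchorable pair: aligner loss
            p1, sup1 = m1
            p2, sup2 = m2
        if chimera[r1_idx]:
            p1 = apply_chimera(p1)
        if chimera[r2_idx]:
            p2 = apply_chimera(p2)
        if chim_pair[k]:
            partner = random_partner()
            if partner is not None:
                p2, sup2 = partner, []
        if lowq[r1_idx]:
            p1 = replace(p1, mapq=int(lowq_vals[r1_idx]))
        if lowq[r2_idx]:
            p2 = replace(p2, mapq=int(lowq_vals[r2_idx]))

        f1, f2, t1, t2 = _pair_flags(p1, p2, mu, sigma)
        lines = [_sam_line(name, f1, p1, p2, t1, sample),
                 _sam_line(name, f2, p2, p1, t2, sample)]
        for sp in sup1:
            lines.append(_sam_line(name, f1, sp, p2, 0, sample, True))
        for sp in sup2:
            lines.append(_sam_line(name, f2, sp, p1, 0, sample, True))
        sam.write("\n".join(lines) + "\n")
        if duplicate[k]:
            # a PCR duplicate of the whole fragment, duplicate-flagged
            dup_lines = [_sam_line(f"{name}.dup", f1 | 0x400, p1, p2, t1, sample),
                         _sam_line(f"{name}.dup", f2 | 0x400, p2, p1, t2, sample)]
            sam.write("\n".join(dup_lines) + "\n")


# ---------------------------------------------------------------------------
# one-call convenience
# ---------------------------------------------------------------------------

@dataclass
class SimOutput:
    fasta: str
    bams: List[str]
    truth_bed: str
    truth_table: str
    truth_vcf: str
    truth: List[TruthSV]


def simulate(config: SimConfig, outdir: str,
             per_sample_bams: bool = True,
             fastq: bool = False) -> SimOutput:
    """Run the full generator: FASTA(+fai), BAM(+bai) per sample, truth files."""
    os.makedirs(outdir, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(3 + len(config.samples))
    ref = generate_reference(config, np.random.default_rng(child[0]))
    truth = implant_svs(ref, config, np.random.default_rng(child[1]))

    fasta = os.path.join(outdir, "reference.fa")
    write_fasta(ref, fasta)
    truth_bed = os.path.join(outdir, "truth.bed")
    write_truth_bed(truth, truth_bed)
    truth_table = os.path.join(outdir, "truth.tsv")
    write_truth_table(truth, truth_table)
    truth_vcf = os.path.join(outdir, "truth.vcf")
    write_truth_vcf(truth, ref, truth_vcf)

    bams = []
    if per_sample_bams:
        for i, sample in enumerate(config.samples):
            sub = replace(config, samples=(sample,))
            bam = os.path.join(outdir, f"{sample}.bam")
            emit_alignments(ref, truth, sub, bam,
                            rng=np.random.default_rng(child[3 + i]),
                            fastq_prefix=os.path.join(outdir, sample) if fastq else None)
            bams.append(bam)
    else:
        bam = os.path.join(outdir, "all_samples.bam")
        emit_alignments(ref, truth, config, bam,
                        rng=np.random.default_rng(child[2]),
                        fastq_prefix=os.path.join(outdir, "reads") if fastq else None)
        bams.append(bam)
    return SimOutput(fasta, bams, truth_bed, truth_table, truth_vcf, truth)
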