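"""End-to-end orchestration: detect -> resolve mate -> filter -> genotype
-> (associate) -> annotate -> write VCF.

The pipeline is single-threaded and fully deterministic for fixed inputs;
a ``threads`` knob is accepted for interface compatibility but execution
order never depends on it, so output bytes are identical regardless.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pyfaidx
import pysam

from . import assoc, bench, classify, detect, genotype, mate, vcfio
from .bamio import AlignedRead, ClipSignature, from_pysam, sample_map
from .classify import ClassifierModel, TrainingRow
from .mate import SWParams
from .variants import Breakpoint, SVCall, UNKNOWN_CLASS

log = logging.getLogger(__name__)

_UNMAPPED_OR_DUP = 0x4 | 0x400
_NOT_PRIMARY = 0x100 | 0x800
_PROPER = 0x2


class FastaAccessor:
    """Indexed-FASTA adapter: contig -> subsequence, 0-based half-open."""

    def __init__(self, path: str):
        self.fasta = pyfaidx.Fasta(path, sequence_always_upper=True)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        start = max(0, start)
        end = min(end, self.length(chrom))
        if end <= start:
            return ""
        return str(self.fasta[chrom][start:end])

    def length(self, chrom: str) -> int:
        return len(self.fasta[chrom])

    def contigs(self) -> Dict[str, int]:
        return {name: len(rec) for name, rec in self.fasta.records.items()}


@dataclass
class RunConfig:
    target_bams: List[str]
    reference: str
    background_bams: List[str] = field(default_factory=list)
    min_support: int = detect.DEFAULT_MIN_SUPPORT
    sw: SWParams = field(default_factory=SWParams)
    seed: int = 1
    threads: int = 1
    output: Optional[str] = None

    @property
    def association_mode(self) -> bool:
        return bool(self.background_bams)

    @property
    def all_bams(self) -> List[str]:
        return list(self.target_bams) + list(self.background_bams)


@dataclass
class _ScanResult:
    index: Dict[tuple, List[ClipSignature]]
    insert_stats: genotype.InsertStats
    samples: List[str]                  # ordered, unique
    bam_samples: Dict[str, Set[str]]    # bam path -> samples it contributes
    read_length: int


def scan_bams(bam_paths: Sequence[str]) -> _ScanResult:
    """One linear pass over every BAM: clip index + insert statistics.

    Only clipped records are materialized as :class:`AlignedRead`; unclipped
    records contribute insert-size observations and nothing else, which keeps
    the scan linear-time with a small constant on deep genomes.
    """
    index: Dict[tuple, List[ClipSignature]] = {}
    tlens: List[int] = []
    samples: List[str] = []
    bam_samples: Dict[str, Set[str]] = {}
    read_len = 100
    read_len_seen = 0
    for path in bam_paths:
        with pysam.AlignmentFile(path, "rb") as bam:
            hd = bam.header.to_dict().get("HD", {})
            if hd.get("SO") != "coordinate":
                raise ValueError(f"{path}: BAM is not coordinate-sorted")
            smap = sample_map(bam, path)
            contributed: Set[str] = set()
            for rec in bam.fetch(until_eof=True):
                flag = rec.flag
                if flag & _UNMAPPED_OR_DUP:
                    continue
                if (flag & _PROPER and not flag & _NOT_PRIMARY
                        and rec.template_length > 0 and len(tlens) < 100_000):
                    tlens.append(rec.template_length)
                    if read_len_seen < 1000:
                        read_len = max(read_len, rec.query_length or 0)
                        read_len_seen += 1
                ct = rec.cigartuples
                if not ct:
                    continue
                if ct[0][0] in (4, 5) or (len(ct) > 1 and ct[-1][0] in (4, 5)):
                    rg = rec.get_tag("RG") if rec.has_tag("RG") else None
                    sid = smap.get(rg, smap[None])
                    contributed.add(sid)
                    read = from_pysam(rec, sid)
                    for sig in detect.clip_signatures(read):
                        index.setdefault(
                            (sig.chrom, sig.break_pos, sig.side), []).append(sig)
            bam_samples[path] = contributed or {smap[None]}
            for sid in sorted(set(smap.values())):
                if sid not in samples:
                    samples.append(sid)
    stats = genotype.estimate_insert_stats(tlens)
    return _ScanResult(index, stats, samples, bam_samples, read_len)


def _bam_sample_names(bam_paths: Sequence[str]) -> List[str]:
    names: List[str] = []
    for path in bam_paths:
        with pysam.AlignmentFile(path, "rb") as bam:
            for sid in sorted(set(sample_map(bam, path).values())):
                if sid not in names:
                    names.append(sid)
    return names


def _fetch_pileup(bam_handles, chrom: str, pos: int,
                  ) -> Dict[str, List[AlignedRead]]:
    """Reads covering ``pos`` (clip boundaries at pos included), per sample.

    Duplicate-flagged primary records are kept: the attribute extractor
    counts them (f_duplicate_flagged); genotyping filters them downstream.
    """
    per_sample: Dict[str, List[AlignedRead]] = {}
    for bam, smap in bam_handles:
        if chrom not in bam.references:
            continue
        for rec in bam.fetch(chrom, max(0, pos - 1), pos + 1):
            flag = rec.flag
            if flag & (0x4 | _NOT_PRIMARY):
                continue
            rg = rec.get_tag("RG") if rec.has_tag("RG") else None
            sid = smap.get(rg, smap[None])
            per_sample.setdefault(sid, []).append(from_pysam(rec, sid, load_seq=False))
    return per_sample


def _split_read_chroms(candidate: detect.BreakpointCandidate) -> Set[str]:
    chroms = {candidate.chrom}
    for sig in candidate.signatures:
        if sig.read is not None:
            for tag in sig.read.sa_entries:
                chroms.add(tag.chrom)
    return chroms


def run_call(config: RunConfig) -> List[SVCall]:
    """Run the full calling pipeline; writes a VCF when configured."""
    ref = FastaAccessor(config.reference)
    scan = scan_bams(config.all_bams)
    log.info("scan: %d clip positions, insert mu=%.1f sigma=%.1f",
             len(scan.index), scan.insert_stats.mu, scan.insert_stats.sigma)

    candidates = detect.find_candidates(scan.index, config.min_support)
    log.info("%d breakpoint candidates with support >= %d",
             len(candidates), config.min_support)

    target_samples: Set[str] = set()
    for path in config.target_bams:
        target_samples |= set(_bam_sample_names([path]))
    background_samples: Set[str] = set()
    for path in config.background_bams:
        background_samples |= set(_bam_sample_names([path]))

    bam_handles = []
    for path in config.all_bams:
        bam = pysam.AlignmentFile(path, "rb")
        bam_handles.append((bam, sample_map(bam, path)))

    calls: List[SVCall] = []
    try:
        for cand in candidates:
            cand.consensus = detect.build_consensus(cand.signatures, cand.side)
            keep, _reason = detect.filter_consensus(cand)
            if not keep:
                continue

            endpoints = mate.candidate_endpoints(cand, scan.read_length)
            precise = bool(endpoints) and endpoints[0].precise
            _clusters, winner = mate.cluster_endpoints(endpoints)
            mate_bp: Optional[Breakpoint] = None
            if winner is not None:
                # the exact endpoint most reads agree on; SW refinement of the
                # clip consensus overrides the position (they can differ by a
                # few bases of junction microhomology) but the read count at
                # the modal endpoint remains the distal support
                modal_pos, modal_count = winner.modal()
                mpos = modal_pos
                if precise:
                    refined = mate.refine_with_sw(
                        cand.consensus.sequence, ref, winner, cand.side, config.sw)
                    if refined is not None:
                        mpos = refined
                mate_bp = Breakpoint(winner.chrom, mpos, modal_count)

            call = SVCall(chrom=cand.chrom, pos=cand.pos, side=cand.side,
                          support=cand.support, mate=mate_bp,
                          consensus=cand.consensus.sequence)
            keep, _reason = mate.apply_distance_filters(
                call, len(_split_read_chroms(cand)))
            if not keep:
                continue

            pileup = _fetch_pileup(bam_handles, cand.chrom, cand.pos)
            evidence: Dict[str, list] = {}
            alt_counts: Dict[str, int] = {}
            for sid, reads in pileup.items():
                evs = []
                for r in reads:
                    if r.is_duplicate:
                        continue
                    ev = genotype.classify_read(r, call, scan.insert_stats)
                    if ev is not None:
                        evs.append(ev)
                evidence[sid] = evs
                alt_counts[sid] = sum(1 for e in evs if e.allele == "alt")
            if not genotype.joint_site_filter(alt_counts):
                continue
            for sid in scan.samples:
                call.genotypes[sid] = genotype.genotype_likelihoods(
                    evidence.get(sid, []))

            combined = [r for reads in pileup.values() for r in reads]
            call.at = classify.extract_attributes(combined, scan.insert_stats)

            if config.association_mode:
                counts = assoc.counts_from_genotypes(
                    call.genotypes, sorted(target_samples),
                    sorted(background_samples))
                if counts is not None:
                    call.lrt = assoc.lrt_statistic(counts)
            calls.append(call)
    finally:
        for bam, _ in bam_handles:
            bam.close()

    calls.sort(key=lambda c: (c.chrom, c.pos, c.side))
    for i, call in enumerate(calls, 1):
        call.call_id = f"sv{i}"
    log.info("%d calls after filtering", len(calls))
    if config.output:
        vcfio.write_vcf(calls, scan.samples, os.path.abspath(config.reference),
                        config.output, ref.contigs())
    return calls


# ---------------------------------------------------------------------------
# classification plumbing
# ---------------------------------------------------------------------------

def run_classify(vcf_in: str, vcf_out: str,
                 training_file: Optional[str] = None,
                 model: Optional[ClassifierModel] = None,
                 seed: int = 1, k: int = classify.DEFAULT_K_FOLDS
                 ) -> Tuple[List[SVCall], ClassifierModel]:
    """Annotate an existing VCF with WC/WP; nothing else changes."""
    if model is None:
        if training_file is None:
            raise ValueError("need a training file or a fitted model")
        rows = classify.read_training_file(training_file)
        model = classify.train_classifier(rows, seed=seed, k=k)
    calls = vcfio.read_vcf(vcf_in)
    for call in calls:
        if call.at is None:
            log.warning("record %s:%d has no AT field; leaving WC=UNK",
                        call.chrom, call.pos + 1)
            call.wc = UNKNOWN_CLASS
            call.wp = None
            continue
        call.wc, call.wp = model.predict(call.at)
    samples = sorted({s for c in calls for s in c.genotypes})
    vcfio.write_vcf(calls, samples, vcfio.read_reference_name(vcf_in), vcf_out,
                    vcfio.read_contigs(vcf_in))
    return calls, model


def collect_training_rows(bam_paths: Sequence[str],
                          labelled_positions: Sequence[Tuple[str, int, str]],
                          ) -> List[TrainingRow]:
    """Attribute vectors at given (chrom, pos, label) pileup positions."""
    scan_stats = None
    tlens: List[int] = []
    for path in bam_paths:
        with pysam.AlignmentFile(path, "rb") as bam:
            for rec in bam.fetch(until_eof=True):
                if rec.flag & _PROPER and not rec.flag & _NOT_PRIMARY \
                        and rec.template_length > 0:
                    tlens.append(rec.template_length)
                    if len(tlens) >= 100_000:
                        break
        if len(tlens) >= 100_000:
            break
    stats = genotype.estimate_insert_stats(tlens)

    handles = []
    for path in bam_paths:
        bam = pysam.AlignmentFile(path, "rb")
        handles.append((bam, sample_map(bam, path)))
    rows: List[TrainingRow] = []
    try:
        for chrom, pos, label in labelled_positions:
            pileup = _fetch_pileup(handles, chrom, pos)
            combined = [r for reads in pileup.values() for r in reads]
            if not combined:
                continue
            rows.append(TrainingRow(
                classify.extract_attributes(combined, stats), label))
    finally:
        for bam, _ in handles:
            bam.close()
    return rows


# ---------------------------------------------------------------------------
# association on an existing VCF
# ---------------------------------------------------------------------------

def run_assoc(vcf_in: str, vcf_out: str, target_samples: Sequence[str],
              background_samples: Sequence[str]) -> List[SVCall]:
    """Recompute the LRT on an already-genotyped VCF with new cohort lists."""
    calls = vcfio.read_vcf(vcf_in)
    for call in calls:
        counts = assoc.counts_from_genotypes(call.genotypes, target_samples,
                                             background_samples)
        call.lrt = assoc.lrt_statistic(counts) if counts is not None else None
    samples = sorted({s for c in calls for s in c.genotypes})
    vcfio.write_vcf(calls, samples, vcfio.read_reference_name(vcf_in), vcf_out,
                    vcfio.read_contigs(vcf_in))
    return calls


def run_bench(calls_vcf: str, truth_bed: str, slop: int,
              out_tsv: Optional[str] = None) -> bench.BenchmarkResult:
    """Score a call VCF against a truth-interval BED.

    The BED's own interval width is respected: breakpoints are the interval
    midpoints and the confidence padding is the median interval half-width,
    extended by ``slop`` on both sides during matching.
    """
    calls = vcfio.read_vcf(calls_vcf)
    truth, pad = bench.load_truth_bed(truth_bed, return_pad=True)
    result = bench.evaluate_calls(calls, truth, slop=slop, pad=pad)
    if out_tsv:
        result.to_tsv(out_tsv)
    return result
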