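"""Determinism, truth geometry and evidence realism of the simulator."""

import collections

import numpy as np
import pysam
import pytest

from clipsv.simulate import (SimConfig, TruthSV, generate_reference,
                             haplotype_segments, haplotype_sequence,
                             implant_svs, read_truth_table, simulate,
                             write_truth_bed, write_truth_table)

SMALL = dict(n_chroms=2, chrom_length=300_000, n_svs_per_class=3,
             max_sv_size=20_000, coverage=25.0)


class TestReference:
    def test_deterministic_per_seed(self):
        r1 = generate_reference(SimConfig(seed=3, **SMALL))
        r2 = generate_reference(SimConfig(seed=3, **SMALL))
        assert r1 == r2

    def test_seeds_differ(self):
        r1 = generate_reference(SimConfig(seed=3, **SMALL))
        r2 = generate_reference(SimConfig(seed=4, **SMALL))
        assert r1 != r2

    def test_base_composition_uniform(self):
        cfg = SimConfig(seed=3, n_chroms=1, chrom_length=1_000_000)
        seq = generate_reference(cfg)["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.01     # ~6 sigma for a 1 Mb binomial


class TestImplant:
    @pytest.fixture(scope="class")
    def truth(self):
        cfg = SimConfig(seed=21, **SMALL)
        ref = generate_reference(cfg)
        return implant_svs(ref, cfg), cfg

    def test_class_counts(self, truth):
        svs, cfg = truth
        counts = collections.Counter(sv.sv_class for sv in svs)
        assert all(counts[c] == cfg.n_svs_per_class
                   for c in ("DEL", "DUP", "INS", "INV"))

    def test_spacing_and_sizes(self, truth):
        svs, cfg = truth
        by_chrom = collections.defaultdict(list)
        for sv in svs:
            by_chrom[sv.chrom].append((sv.start, max(sv.end, sv.start + 1)))
            if sv.donor_chrom:
                by_chrom[sv.donor_chrom].append((sv.donor_start, sv.donor_end))
            assert cfg.min_sv_size <= sv.size <= cfg.max_sv_size
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert s2 - e1 >= cfg.min_gap

    def test_insertion_donor_recorded(self, truth):
        svs, _ = truth
        ins = [sv for sv in svs if sv.sv_class == "INS"]
        assert all(sv.donor_chrom and sv.donor_end - sv.donor_start == sv.size
                   and sv.donor_chrom != sv.chrom for sv in ins)

    def test_truth_bed_pads_breakpoints(self, tmp_path):
        sv = TruthSV("sv1", "DEL", "chr1", 10_000, 10_500, 500,
                     zygosity={"s1": "hom"})
        path = str(tmp_path / "t.bed")
        write_truth_bed([sv], path)
        rows = [l.split("\t") for l in open(path).read().splitlines()]
        assert [(r[0], int(r[1]), int(r[2])) for r in rows] == \
            [("chr1", 9_975, 10_025), ("chr1", 10_475, 10_525)]

    def test_zero_svs(self):
        cfg = SimConfig(seed=1, n_chroms=1, chrom_length=100_000,
                        n_svs_per_class=0)
        ref = generate_reference(cfg)
        assert implant_svs(ref, cfg) == []

    def test_overloaded_genome_fatal(self):
        cfg = SimConfig(seed=1, n_chroms=1, chrom_length=40_000,
                        n_svs_per_class=40)
        ref = generate_reference(cfg)
        with pytest.raises(ValueError, match="too small"):
            implant_svs(ref, cfg)

    def test_truth_table_round_trip(self, truth, tmp_path):
        svs, _ = truth
        path = str(tmp_path / "truth.tsv")
        write_truth_table(svs, path)
        back = read_truth_table(path)
        assert len(back) == len(svs)
        for a, b in zip(svs, back):
            assert (a.sv_id, a.sv_class, a.chrom, a.start, a.end, a.size,
                    a.donor_chrom, a.donor_start, a.zygosity) == \
                   (b.sv_id, b.sv_class, b.chrom, b.start, b.end, b.size,
                    b.donor_chrom, b.donor_start, b.zygosity)


class TestHaplotypes:
    def test_segment_maps_partition_each_edit(self):
        cfg = SimConfig(seed=21, **SMALL)
        ref = generate_reference(cfg)
        truth = implant_svs(ref, cfg)
        segs = haplotype_segments(ref, truth, "s1", 0)
        for chrom, seg_list in segs.items():
            hap = haplotype_sequence(ref, seg_list)
            assert len(hap) == sum(s.length for s in seg_list)
            # deletions shorten, duplications/insertions lengthen
            delta = sum({"DEL": -sv.size, "DUP": sv.size, "INS": sv.size,
                         "INV": 0}[sv.sv_class]
                        for sv in truth
                        if sv.chrom == chrom and sv.on_haplotype("s1", 0))
            assert len(hap) == len(ref[chrom]) + delta


class TestEmission:
    @pytest.fixture(scope="class")
    def sim(self, tmp_path_factory):
        # seed chosen so the truth set contains a large heterozygous deletion
        cfg = SimConfig(seed=35, **SMALL)
        return simulate(cfg, str(tmp_path_factory.mktemp("sim"))), cfg

    def test_mean_depth_near_target(self, sim):
        out, cfg = sim
        depths = []
        with pysam.AlignmentFile(out.bams[0]) as bam:
            occupied = {(sv.chrom, p)
                        for sv in out.truth
                        for p in range(max(0, sv.start - 1000), sv.end + 1000)}
            rng = np.random.default_rng(1)
            for _ in range(150):
                chrom = f"chr{rng.integers(1, cfg.n_chroms + 1)}"
                pos = int(rng.integers(10_000, cfg.chrom_length - 10_000))
                if (chrom, pos) in occupied:
                    continue
                d = sum(1 for r in bam.fetch(chrom, pos, pos + 1)
                        if not r.is_duplicate and not r.is_supplementary)
                depths.append(d)
        assert abs(np.mean(depths) - cfg.coverage) / cfg.coverage < 0.05

    def test_het_deletion_clips_about_half(self, sim):
        out, cfg = sim
        het_dels = [sv for sv in out.truth if sv.sv_class == "DEL"
                    and sv.zygosity["s1"] == "het" and sv.size > 300]
        assert het_dels, "fixture should contain a usable het deletion"
        sv = het_dels[0]
        with pysam.AlignmentFile(out.bams[0]) as bam:
            clipped = spanning = 0
            for r in bam.fetch(sv.chrom, sv.start - 150, sv.start + 150):
                if r.is_duplicate or r.is_supplementary:
                    continue
                ct = r.cigartuples
                if ct and (ct[0][0] in (4, 5) or ct[-1][0] in (4, 5)):
                    clipped += 1
                elif r.reference_start < sv.start - 5 and \
                        r.reference_end > sv.start + 5:
                    spanning += 1
        frac = clipped / max(1, clipped + spanning)
        assert 0.2 < frac < 0.75    # binomial window around ~1/2

    def test_deterministic_per_seed(self, tmp_path):
        cfg = SimConfig(seed=8, n_chroms=1, chrom_length=150_000,
                        n_svs_per_class=2, max_sv_size=5_000, coverage=15.0)
        out1 = simulate(cfg, str(tmp_path / "a"))
        out2 = simulate(cfg, str(tmp_path / "b"))
        def digest(bam_path):
            with pysam.AlignmentFile(bam_path) as bam:
                return [r.to_string() for r in bam.fetch(until_eof=True)]
        assert digest(out1.bams[0]) == digest(out2.bams[0])
        assert open(out1.truth_bed).read() == open(out2.truth_bed).read()
        assert open(out1.fasta).read() == open(out2.fasta).read()

    def test_sv_free_genome_has_no_shared_clips(self, tmp_path):
        cfg = SimConfig(seed=9, n_chroms=1, chrom_length=150_000,
                        n_svs_per_class=0, coverage=20.0)
        out = simulate(cfg, str(tmp_path / "clean"))
        clip_pos = collections.Counter()
        with pysam.AlignmentFile(out.bams[0]) as bam:
            for r in bam.fetch(until_eof=True):
                ct = r.cigartuples
                if not ct or r.is_duplicate:
                    continue
                if ct[0][0] in (4, 5):
                    clip_pos[(r.reference_name, r.reference_start, "L")] += 1
                if ct[-1][0] in (4, 5):
                    clip_pos[(r.reference_name, r.reference_end, "R")] += 1
        assert not [k for k, v in clip_pos.items() if v >= 3]
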