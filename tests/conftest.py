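import os

import pysam
import pytest

from clipsv.bamio import AlignedRead, parse_cigar
from clipsv.simulate import SimConfig, simulate
from clipsv import pipeline


def make_read(name="r", sample="s1", chrom="chr1", pos=100, mapq=60,
              cigar="100M", seq=None, **flags) -> AlignedRead:
    """Convenience constructor for unit tests."""
    cig = parse_cigar(cigar)
    if seq is None:
        qlen = sum(n for op, n in cig if op in "MIS=X")
        seq = "A" * qlen
    defaults = dict(is_paired=True, is_proper_pair=True, is_reverse=False,
                    mate_is_reverse=True, is_secondary=False,
                    is_supplementary=False, is_duplicate=False,
                    is_unmapped=False, mate_is_unmapped=False,
                    mate_chrom=chrom, mate_pos=pos + 200, tlen=400)
    defaults.update(flags)
    return AlignedRead(query_name=name, sample_id=sample, chrom=chrom,
                       pos=pos, mapq=mapq, cigar=cig, seq=seq, **defaults)


@pytest.fixture
def bam_factory(tmp_path):
    """Build a sorted, indexed BAM from SAM record lines."""
    def build(records, contigs=(("chr1", 100000),), name="test.bam",
              sample="s1"):
        header = ["@HD\tVN:1.6\tSO:coordinate"]
        for cname, clen in contigs:
            header.append(f"@SQ\tSN:{cname}\tLN:{clen}")
        header.append(f"@RG\tID:{sample}\tSM:{sample}")
        sam_path = tmp_path / "tmp.sam"
        sam_path.write_text("\n".join(header + list(records)) + "\n")
        bam_path = str(tmp_path / name)
        pysam.sort("-o", bam_path, str(sam_path))
        pysam.index(bam_path)
        return bam_path
    return build


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A compact simulated dataset shared across integration tests."""
    outdir = str(tmp_path_factory.mktemp("smallsim"))
    config = SimConfig(seed=5, n_chroms=2, chrom_length=800_000,
                       n_svs_per_class=8, max_sv_size=40_000, coverage=40.0)
    return simulate(config, outdir)


@pytest.fixture(scope="session")
def small_calls(small_sim, tmp_path_factory):
    out_vcf = str(tmp_path_factory.mktemp("smallcalls") / "calls.vcf")
    config = pipeline.RunConfig(target_bams=small_sim.bams,
                                reference=small_sim.fasta, output=out_vcf)
    calls = pipeline.run_call(config)
    return calls, out_vcf
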