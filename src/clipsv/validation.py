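"""The package's standard simulation-validation protocol.

One seeded run: generate the default-scale synthetic dataset (4 x 5 Mb
contigs, 100 SVs per class with log-uniform sizes from 50 bp up to 1 Mb,
50x paired-end evidence), call SVs, and summarize

* overall sensitivity and FDR at 25 bp truth intervals + 50 bp slop,
* deletion breakpoint sensitivity at 1 bp slop (no truth padding),
* stratified 5-fold cross-validation accuracy of the SV-type classifier
  trained on attribute vectors extracted at the true breakpoints.
"""

from __future__ import annotations

import os
from dataclasses import dataclass


from . import bench, classify, pipeline
from .simulate import SimConfig, SimOutput, simulate


@dataclass
class ValidationResult:
    sensitivity: float
    fdr: float
    del_bp1_sensitivity: float
    classifier_cv: float
    n_truth: int
    n_truth_del: int
    n_calls: int
    n_training_rows: int
    sim: SimOutput
    calls: list


def run_validation(seed: int, outdir: str,
                   config: SimConfig | None = None) -> ValidationResult:
    """Simulate, call and score with everything derived from ``seed``."""
    config = config or SimConfig(seed=seed)
    sim = simulate(config, outdir)

    calls_vcf = os.path.join(outdir, "calls.vcf")
    run_cfg = pipeline.RunConfig(target_bams=sim.bams, reference=sim.fasta,
                                 seed=seed, output=calls_vcf)
    calls = pipeline.run_call(run_cfg)

    overall = bench.evaluate_calls(calls, sim.truth, slop=50, pad=25)

    dels = [sv for sv in sim.truth if sv.sv_class == "DEL"]
    curve = bench.breakpoint_accuracy_curve(calls, dels, slops=(1,))

    positions = [(chrom, pos, sv.sv_class)
                 for sv in sim.truth for chrom, pos in sv.breakpoints()]
    rows = pipeline.collect_training_rows(sim.bams, positions)
    model = classify.train_classifier(rows, seed=seed, k=5)

    return ValidationResult(
        sensitivity=overall.sensitivity,
        fdr=overall.fdr,
        del_bp1_sensitivity=curve[1],
        classifier_cv=model.cv_score,
        n_truth=len(sim.truth),
        n_truth_del=len(dels),
        n_calls=len(calls),
        n_training_rows=len(rows),
        sim=sim,
        calls=calls)
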