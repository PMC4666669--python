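"""Read-evidence classification and the mapping-quality genotype likelihoods."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clipsv import genotype
from clipsv.genotype import (InsertStats, ReadEvidence, classify_read,
                             estimate_insert_stats, genotype_likelihoods,
                             joint_site_filter)
from clipsv.variants import Breakpoint, SVCall
from conftest import make_read

STATS = InsertStats(400.0, 50.0)


def ev(allele, mapq=60, name="r"):
    basis = "clipped_at_breakpoint" if allele == "alt" else "reference_spanning"
    return ReadEvidence(name, allele, mapq, basis)


def brute_force_gl(evidence):
    """Independent per-read product evaluated in linear space."""
    out = []
    for g in (0, 1, 2):
        p = 1.0
        for e_ in evidence:
            err = min(10 ** (-e_.mapq / 10), 0.5)
            p_alt = (g / 2) * (1 - err) + (1 - g / 2) * err
            p *= p_alt if e_.allele == "alt" else 1 - p_alt
        out.append(math.log10(max(p, 1e-300)))
    m = max(out)
    return tuple(v - m for v in out)


class TestClassifyRead:
    def _call(self, pos=500):
        return SVCall("chr1", pos, "right", 5, Breakpoint("chr1", 700, 3))

    def test_clip_at_breakpoint_is_alt(self):
        read = make_read(pos=410, cigar="90M10S")
        out = classify_read(read, self._call(500), STATS)
        assert (out.allele, out.basis) == ("alt", "clipped_at_breakpoint")

    def test_spanning_proper_pair_is_ref(self):
        read = make_read(pos=460, cigar="100M")
        out = classify_read(read, self._call(500), STATS)
        assert (out.allele, out.basis) == ("ref", "reference_spanning")

    def test_same_strand_pair_is_alt(self):
        read = make_read(pos=460, cigar="100M", is_reverse=False,
                         mate_is_reverse=False, is_proper_pair=False)
        out = classify_read(read, self._call(500), STATS)
        assert (out.allele, out.basis) == ("alt", "same_strand_pair")

    def test_long_insert_is_discordant(self):
        read = make_read(pos=460, cigar="100M", tlen=900, is_proper_pair=False)
        out = classify_read(read, self._call(500), STATS)
        assert (out.allele, out.basis) == ("alt", "discordant_pair")

    def test_internal_deletion_spanning_breakpoint(self):
        read = make_read(pos=450, cigar="50M20D50M")
        out = classify_read(read, self._call(510), STATS)
        assert (out.allele, out.basis) == ("alt", "internal_breakpoint")

    def test_distant_read_is_none(self):
        read = make_read(pos=5000, cigar="100M")
        assert classify_read(read, self._call(500), STATS) is None


class TestGenotypeLikelihoods:
    def test_unanimous_reference(self):
        g = genotype_likelihoods([ev("ref", name=str(i)) for i in range(10)])
        assert g.gt == "0/0" and g.alt_count == 0 and g.depth == 10

    def test_two_alt_reads_closed_form(self):
        g = genotype_likelihoods([ev("alt", name="a"), ev("alt", name="b")])
        assert g.gt == "1/1"
        # e = 1e-6: L0 = e^2, L1 = 0.25, L2 = (1-e)^2
        assert g.gl[0] == pytest.approx(-12.0, abs=1e-4)
        assert g.gl[1] == pytest.approx(math.log10(0.25), abs=1e-4)
        assert g.gl[2] == pytest.approx(0.0, abs=1e-6)

    def test_balanced_evidence_is_het(self):
        evidence = [ev("ref", name=f"r{i}") for i in range(5)] + \
                   [ev("alt", name=f"a{i}") for i in range(5)]
        assert genotype_likelihoods(evidence).gt == "0/1"

    def test_empty_evidence_is_missing(self):
        g = genotype_likelihoods([])
        assert g.gt == "./." and g.gl == (0.0, 0.0, 0.0)

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from(["ref", "alt"]),
                              st.integers(0, 60)), max_size=20))
    def test_equals_brute_force_product(self, draws):
        evidence = [ev(a, mapq=q, name=str(i)) for i, (a, q) in enumerate(draws)]
        got = genotype_likelihoods(evidence).gl
        expected = brute_force_gl(evidence)
        assert np.allclose(got, expected, atol=1e-9)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from(["ref", "alt"]),
                              st.integers(1, 60)), min_size=1, max_size=15))
    def test_label_swap_symmetry(self, draws):
        """Swapping ref<->alt maps (L0,L1,L2) to (L2,L1,L0)."""
        fwd = [ev(a, mapq=q, name=str(i)) for i, (a, q) in enumerate(draws)]
        swp = [ev("alt" if a == "ref" else "ref", mapq=q, name=str(i))
               for i, (a, q) in enumerate(draws)]
        gl_f = genotype_likelihoods(fwd).gl
        gl_s = genotype_likelihoods(swp).gl
        assert np.allclose(gl_f, gl_s[::-1], atol=1e-9)

    def test_mapq_zero_reads_are_uninformative(self):
        base = [ev("alt", name="a"), ev("alt", name="b"), ev("ref", name="c")]
        noisy = base + [ev("alt", mapq=0, name="z1"), ev("ref", mapq=0, name="z2")]
        assert np.allclose(genotype_likelihoods(base).gl,
                           genotype_likelihoods(noisy).gl, atol=1e-12)


class TestJointSiteFilter:
    @pytest.mark.parametrize("counts,expected", [
        ({"A": 2, "B": 2, "C": 2}, False),
        ({"A": 3, "B": 0}, True),
        ({}, False),
    ])
    def test_threshold(self, counts, expected):
        assert joint_site_filter(counts) is expected


class TestInsertStats:
    def test_robust_recovery(self):
        rng = np.random.default_rng(0)
        tlens = rng.normal(350, 40, 20000).astype(int)
        stats = estimate_insert_stats(tlens)
        assert stats.mu == pytest.approx(350, abs=5)
        assert stats.sigma == pytest.approx(40, rel=0.15)

    def test_empty_defaults(self):
        stats = estimate_insert_stats([])
        assert stats.mu > 0 and stats.sigma > 0


class TestGenotypeConcordance:
    def test_planted_genotypes_recovered_at_20x(self):
        """Parameter recovery: planted genotypes at 20x, clean evidence.

        Homozygous sites must reach >= 95% concordance (heterozygous draws
        can be unlucky, so they get a slightly looser bar).
        """
        rng = np.random.default_rng(8)
        stats = {0: [0, 0], 1: [0, 0], 2: [0, 0]}
        for _ in range(600):
            planted = int(rng.integers(0, 3))
            evidence = []
            for i in range(20):
                allele = "alt" if rng.random() < planted / 2 else "ref"
                mapq = int(rng.choice([60, 40, 27, 13]))
                evidence.append(ev(allele, mapq=mapq, name=str(i)))
            called = genotype_likelihoods(evidence).n_alt_alleles
            stats[planted][0] += 1
            stats[planted][1] += called == planted
        for g in (0, 2):
            assert stats[g][1] / stats[g][0] >= 0.95
        assert stats[1][1] / stats[1][0] >= 0.90
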