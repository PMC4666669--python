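"""Partner-endpoint inference, 10 bp clustering, SW refinement and filters."""

import numpy as np
import pytest

from clipsv import mate
from clipsv.bamio import RIGHT, LEFT, ClipSignature
from clipsv.detect import BreakpointCandidate
from clipsv.mate import (Endpoint, EndpointCluster, SWParams, cluster_endpoints,
                         candidate_endpoints, refine_with_sw, round_to_ten,
                         apply_distance_filters)
from clipsv.variants import Breakpoint, SVCall
from conftest import make_read


class DictReference:
    def __init__(self, seqs):
        self.seqs = seqs

    def fetch(self, chrom, start, end):
        return self.seqs[chrom][max(0, start):end]

    def length(self, chrom):
        return len(self.seqs[chrom])


def candidate_with_read(read, pos=190, side=RIGHT):
    sig = ClipSignature(read.chrom, pos, side, "ACGTACGTAC", 10,
                        read.query_name, True, read)
    return BreakpointCandidate(read.chrom, pos, side, 3, [sig])


class TestCandidateEndpoints:
    def test_sa_leading_clip_implies_start(self):
        read = make_read(pos=100, cigar="90M10S")
        read.sa_raw = "chr1,1001,+,10S90M,60,0;"
        eps = candidate_endpoints(candidate_with_read(read))
        assert [(e.chrom, e.pos, e.precise) for e in eps] == [("chr1", 1000, True)]

    def test_sa_trailing_clip_implies_end(self):
        read = make_read(pos=100, cigar="10S90M")
        read.sa_raw = "chr1,2001,+,90M10S,60,0;"
        eps = candidate_endpoints(candidate_with_read(read, pos=100, side=LEFT))
        assert [(e.chrom, e.pos) for e in eps] == [("chr1", 2090)]

    def test_mate_fallback_when_no_tags(self):
        read = make_read(pos=100, cigar="90M10S", mate_pos=5100,
                         is_proper_pair=False)
        eps = candidate_endpoints(candidate_with_read(read))
        assert len(eps) == 1 and not eps[0].precise

    def test_tag_endpoints_preempt_fallback(self):
        read = make_read(pos=100, cigar="90M10S", mate_pos=5100,
                         is_proper_pair=False)
        read.sa_raw = "chr2,1001,+,10S90M,60,0;"
        eps = candidate_endpoints(candidate_with_read(read))
        assert [(e.chrom, e.precise) for e in eps] == [("chr2", True)]


class TestClustering:
    def test_half_up_rounding(self):
        assert [round_to_ten(p) for p in (1003, 1004, 1005, 1008, 1102)] == \
            [1000, 1000, 1010, 1010, 1100]

    def test_grouping_and_winner(self):
        eps = [Endpoint("chr1", p) for p in (1003, 1004, 1008, 1102)]
        clusters, winner = cluster_endpoints(eps)
        got = {c.rounded_pos: sorted(c.member_positions) for c in clusters}
        assert got == {1000: [1003, 1004], 1010: [1008], 1100: [1102]}
        assert winner.rounded_pos == 1000 and winner.support == 2

    def test_single_endpoint(self):
        clusters, winner = cluster_endpoints([Endpoint("chr1", 77)])
        assert winner.support == 1 and winner.rounded_pos == 80

    def test_tie_breaks_leftmost(self):
        eps = [Endpoint("chr1", 2001)] * 3 + [Endpoint("chr1", 1001)] * 3
        _, winner = cluster_endpoints(eps)
        assert winner.rounded_pos == 1000

    def test_empty_input_no_winner(self):
        clusters, winner = cluster_endpoints([])
        assert clusters == [] and winner is None

    def test_rounding_idempotent(self):
        eps = [Endpoint("chr1", p) for p in (1003, 1008, 1102, 57, 55)]
        clusters, _ = cluster_endpoints(eps)
        again, _ = cluster_endpoints(
            [Endpoint(c.chrom, c.rounded_pos) for c in clusters])
        assert sorted(c.rounded_pos for c in again) == \
            sorted(c.rounded_pos for c in clusters)

    def test_modal_exact_endpoint(self):
        cl = EndpointCluster("chr1", 1000, [1003, 1003, 1004])
        assert cl.modal() == (1003, 2)


class TestSWRefinement:
    @pytest.fixture
    def reference(self):
        rng = np.random.default_rng(123)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        return DictReference({"chr1": seq}), seq

    def test_exact_match_right_side(self, reference):
        ref, seq = reference
        cons = seq[1400:1430]
        cluster = EndpointCluster("chr1", 1400, [1400])
        assert refine_with_sw(cons, ref, cluster, RIGHT) == 1400

    def test_planted_offset_recovered(self, reference):
        ref, seq = reference
        cons = seq[1407:1437]
        cluster = EndpointCluster("chr1", 1400, [1407])
        assert refine_with_sw(cons, ref, cluster, RIGHT) == 1407

    def test_left_side_reports_alignment_end(self, reference):
        ref, seq = reference
        cons = seq[1370:1400]
        cluster = EndpointCluster("chr1", 1400, [1400])
        assert refine_with_sw(cons, ref, cluster, LEFT) == 1400

    def test_reverse_complement_match(self, reference):
        ref, seq = reference
        comp = str.maketrans("ACGT", "TGCA")
        cons = seq[1400:1430].translate(comp)[::-1]
        cluster = EndpointCluster("chr1", 1400, [1400])
        # right-side clip matching in reverse orientation: junction at the end
        assert refine_with_sw(cons, ref, cluster, RIGHT) == 1430

    def test_random_consensus_rejected(self, reference):
        ref, _ = reference
        rng = np.random.default_rng(99)
        cluster = EndpointCluster("chr1", 1400, [1400])
        hits = 0
        for _ in range(50):
            cons = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
            if refine_with_sw(cons, ref, cluster, RIGHT) is not None:
                hits += 1
        assert hits == 0

    def test_window_truncated_at_contig_edge(self, reference):
        ref, seq = reference
        cons = seq[10:40]
        cluster = EndpointCluster("chr1", 10, [10])
        assert refine_with_sw(cons, ref, cluster, RIGHT) == 10

    def test_refinement_stays_within_window(self, reference):
        ref, seq = reference
        params = SWParams()
        cons = seq[1450:1480]
        cluster = EndpointCluster("chr1", 1400, [1450])
        refined = refine_with_sw(cons, ref, cluster, RIGHT, params)
        assert refined is not None
        assert abs(refined - 1400) <= params.window


class TestDistanceFilters:
    def _call(self, pos, mate_chrom, mate_pos, mate_support):
        return SVCall("chr1", pos, RIGHT, 5,
                      Breakpoint(mate_chrom, mate_pos, mate_support))

    def test_sub_megabase_span_kept_regardless(self):
        call = self._call(0, "chr1", 999_999, 1)
        assert apply_distance_filters(call) == (True, "ok")

    def test_interchromosomal_needs_two_exact_reads(self):
        call = self._call(100, "chr2", 5000, 1)
        assert apply_distance_filters(call)[0] is False
        call = self._call(100, "chr2", 5000, 2)
        assert apply_distance_filters(call)[0] is True

    def test_large_span_needs_two_exact_reads(self):
        call = self._call(0, "chr1", 1_500_000, 1)
        assert apply_distance_filters(call)[0] is False

    def test_too_many_chromosomes_dropped(self):
        call = self._call(100, "chr1", 500, 9)
        assert apply_distance_filters(call, n_split_chroms=4)[0] is False
        assert apply_distance_filters(call, n_split_chroms=3)[0] is True

    def test_more_mate_support_never_drops_a_kept_call(self):
        for support in range(1, 6):
            call = self._call(0, "chr1", 500_000, support)
            assert apply_distance_filters(call)[0] is True
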