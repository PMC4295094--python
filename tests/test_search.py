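"""Solver exactness, quorum handling, and the tuple-stage heuristics."""

import pytest

from plantedmotif.datagen import generate_instance
from plantedmotif.kmer_core import LMerTuple
from plantedmotif.oracle import brute_solve
from plantedmotif.search import (
    MotifParams,
    choose_k,
    gen_tuples,
    is_alive,
    qgen_tuples,
    reorder_strings,
    solve,
    verify_candidate,
)
from plantedmotif.seq_io import SequenceSet


class TestMotifParams:
    @pytest.mark.parametrize("n, q, expected", [(20, 100.0, 20), (4, 75.0, 3), (20, 50.0, 10), (3, 34.0, 2)])
    def test_quorum_count_is_ceiling(self, n, q, expected):
        assert MotifParams(l=5, d=1, q=q).quorum_count(n) == expected

    @pytest.mark.parametrize("kwargs", [dict(l=5, d=6), dict(l=5, d=1, q=0.0), dict(l=5, d=1, q=101.0), dict(l=0, d=0)])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MotifParams(**{"q": 100.0, **kwargs})


class TestIsAlive:
    def test_empty_tuple_keeps_everything_alive(self):
        assert is_alive("ACGT", LMerTuple(), 1)

    def test_pairwise_distance_beyond_2d_kills(self):
        assert not is_alive("AAAA", LMerTuple(["TTTT"]), 1)

    def test_consensus_bound_applies(self):
        # pairwise distances 2 and 4 are within 2d=4; Cd of the triple is 4 <= 3d=6
        T = LMerTuple(["AAAA", "CCAA"])
        assert is_alive("AACC", T, 2)

    def test_survivor_has_a_common_neighbor(self):
        from plantedmotif.neighborhood import common_neighborhood

        assert "AAAA" in common_neighborhood(("AAAA", "CCAA", "AACC"), 2)


class TestReorderStrings:
    def test_largest_minimum_additional_distance_first(self):
        T = LMerTuple(["AAAA"])
        alive = {0: ["AACA"], 1: ["CCAA"]}  # min additional distances 1, 2
        assert reorder_strings(T, alive) == [1, 0]

    def test_tie_broken_by_fewer_alive_words(self):
        T = LMerTuple(["AAAA"])
        alive = {0: ["CAAA", "ACAA", "AACA"], 1: ["CAAA"]}  # same min distance 1
        assert reorder_strings(T, alive) == [1, 0]

    def test_single_string_is_identity(self):
        assert reorder_strings(LMerTuple(["AA"]), {3: ["AC"]}) == [3]

    def test_remaining_tie_by_original_index(self):
        T = LMerTuple(["AAAA"])
        alive = {2: ["CAAA"], 1: ["ACAA"]}
        assert reorder_strings(T, alive) == [1, 2]


class TestVerifyCandidate:
    def test_motif_present_in_all(self):
        seqs = SequenceSet([("a", "AAC"), ("b", "AAG")])
        ok, occ = verify_candidate("AA", seqs, MotifParams(l=2, d=0))
        assert ok
        assert occ == [(0, 0), (0, 0)]

    def test_absent_candidate_rejected(self):
        seqs = SequenceSet([("a", "AAC"), ("b", "AAG")])
        ok, occ = verify_candidate("CC", seqs, MotifParams(l=2, d=0))
        assert not ok
        assert occ == [None, None]

    def test_within_distance_counts_and_reports_leftmost_best(self):
        seqs = SequenceSet([("a", "AAC"), ("b", "AAG")])
        ok, occ = verify_candidate("AG", seqs, MotifParams(l=2, d=1))
        assert ok
        assert occ == [(0, 1), (1, 0)]


class TestChooseK:
    def test_user_override_wins(self):
        assert choose_k(MotifParams(l=13, d=4), 20, 600, user_k=3) == 3

    def test_exact_match_needs_single_anchor(self):
        assert choose_k(MotifParams(l=9, d=0), 20, 600) == 1

    def test_benchmark_13_4_uses_three(self):
        assert choose_k(MotifParams(l=13, d=4), 20, 600) == 3


class TestTupleGeneration:
    def test_gen_tuples_drives_exact_pms(self):
        seqs = SequenceSet([("a", "AAC"), ("b", "AAG")])
        params = MotifParams(l=2, d=0)
        seen = []
        gen_tuples(seqs, params, seen.append, k=2)
        members = {t.members for t in seen}
        assert ("AA", "AA") in members  # the tuple whose neighborhood is the motif

    def test_qgen_reduces_to_gen_at_full_quorum(self, rng, make_seqs):
        seqs = make_seqs(rng, 3, 15)
        params = MotifParams(l=3, d=1, q=100.0)
        a, b = [], []
        gen_tuples(seqs, params, lambda t: a.append(t.members), k=2)
        qgen_tuples(seqs, params, lambda t: b.append(t.members), k=2)
        assert a == b

    def test_single_anchor_tuples_enumerate_string_windows(self):
        seqs = SequenceSet([("a", "ACGT"), ("b", "ACGA")])
        params = MotifParams(l=3, d=1)
        seen = []
        gen_tuples(seqs, params, lambda t: seen.append(t.members), k=1)
        assert [m[0] for m in seen] == ["ACG", "CGT"]


class TestSolve:
    def test_two_string_exact_match(self):
        seqs = SequenceSet([("a", "AAC"), ("b", "AAG")])
        assert solve(seqs, MotifParams(l=2, d=0)).sorted() == ["AA"]

    def test_half_quorum_unions_exact_words(self):
        seqs = SequenceSet([("a", "AAC"), ("b", "GGT")])
        result = solve(seqs, MotifParams(l=2, d=0, q=50.0))
        assert result.sorted() == ["AA", "AC", "GG", "GT"]

    def test_three_string_radius_one(self):
        seqs = SequenceSet([("a", "AAAA"), ("b", "AAAT"), ("c", "AATT")])
        params = MotifParams(l=4, d=1)
        expected = brute_solve(seqs, params).motifs
        assert solve(seqs, params).motifs == expected
        assert expected == {"AAAT"}

    def test_matches_oracle_on_random_instances(self, rng, make_seqs):
        for _ in range(25):
            n, m = rng.randint(2, 5), rng.randint(8, 30)
            l = rng.randint(2, 6)
            d = rng.randint(0, min(3, l))
            q = rng.choice([50.0, 75.0, 100.0])
            seqs = make_seqs(rng, n, m)
            params = MotifParams(l=l, d=d, q=q)
            assert solve(seqs, params).motifs == brute_solve(seqs, params).motifs

    def test_input_order_invariance(self, rng, make_seqs):
        seqs = make_seqs(rng, 4, 20)
        params = MotifParams(l=4, d=1, q=75.0)
        expected = solve(seqs, params).motifs
        order = list(range(4))
        for _ in range(3):
            rng.shuffle(order)
            permuted = SequenceSet([seqs.records[i] for i in order])
            assert solve(permuted, params).motifs == expected

    def test_reordering_is_performance_only(self, rng, make_seqs):
        for _ in range(10):
            seqs = make_seqs(rng, 4, 18)
            params = MotifParams(l=3, d=1, q=rng.choice([50.0, 100.0]))
            assert (
                solve(seqs, params, reorder=False).motifs
                == solve(seqs, params, reorder=True).motifs
            )

    def test_quorum_relaxation_is_monotone(self, rng, make_seqs):
        seqs = make_seqs(rng, 4, 20)
        previous = None
        for q in (100.0, 75.0, 50.0):
            current = solve(seqs, MotifParams(l=3, d=1, q=q)).motifs
            if previous is not None:
                assert previous <= current
            previous = current

    def test_planted_motif_always_recovered(self, rng):
        for _ in range(5):
            seed = rng.randint(0, 10**6)
            inst = generate_instance(n=6, m=40, l=6, d=1, q=100.0, seed=seed)
            params = MotifParams(l=6, d=1)
            assert inst.motif in solve(inst.sequences, params).motifs

    def test_occurrences_respect_radius(self):
        seqs = SequenceSet([("a", "AACGT"), ("b", "TTTTT")])
        result = solve(seqs, MotifParams(l=3, d=1, q=50.0))
        for motif, occ in result.occurrences.items():
            hits = [o for o in occ if o is not None]
            assert len(hits) >= 1
            assert all(dist <= 1 for _, dist in hits)

    def test_string_shorter_than_motif_rejected(self):
        seqs = SequenceSet([("a", "AC")])
        with pytest.raises(ValueError):
            solve(seqs, MotifParams(l=3, d=1))
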