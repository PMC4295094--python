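"""Common d-neighborhood generation against an exhaustive oracle."""

import itertools
import random

import pytest

from plantedmotif.kmer_core import hamming
from plantedmotif.neighborhood import (
    NodeCounter,
    common_neighborhood,
    prefix_prunable,
    single_neighborhood_size,
)


def exhaustive_neighborhood(members, d):
    """Filter the whole word space by the definition (independent oracle)."""
    l = len(members[0])
    return {
        "".join(chars)
        for chars in itertools.product("ACGT", repeat=l)
        if all(hamming("".join(chars), t) <= d for t in members)
    }


class TestCommonNeighborhood:
    @pytest.mark.parametrize(
        "members, d, expected",
        [
            (("ACGT",), 0, {"ACGT"}),
            (("AA", "CC"), 1, {"AC", "CA"}),
            (("AAAA", "CCCC"), 1, set()),  # pairwise distance 4 > 2d
        ],
    )
    def test_examples(self, members, d, expected):
        assert common_neighborhood(members, d) == expected

    def test_radius_one_ball_has_seven_two_mers(self):
        assert len(common_neighborhood(("AC",), 1)) == 7

    def test_empty_tuple_rejected(self):
        with pytest.raises(ValueError):
            common_neighborhood((), 1)

    def test_matches_exhaustive_oracle_on_random_tuples(self):
        rng = random.Random(42)
        for _ in range(60):
            l = rng.randint(1, 7)
            k = rng.randint(1, 4)
            members = [
                "".join(rng.choice("ACGT") for _ in range(l)) for _ in range(k)
            ]
            for d in range(l + 1):
                expected = exhaustive_neighborhood(members, d)
                for suffix_prune in (False, True):
                    got = common_neighborhood(members, d, suffix_prune=suffix_prune)
                    assert got == expected, (members, d, suffix_prune)

    def test_singleton_size_matches_closed_form(self):
        rng = random.Random(1)
        for _ in range(10):
            l = rng.randint(1, 6)
            d = rng.randint(0, l)
            u = "".join(rng.choice("ACGT") for _ in range(l))
            assert len(common_neighborhood((u,), d)) == single_neighborhood_size(l, d, 4)

    def test_monotone_in_tuple_and_radius(self):
        rng = random.Random(3)
        for _ in range(20):
            l = rng.randint(2, 6)
            members = ["".join(rng.choice("ACGT") for _ in range(l)) for _ in range(3)]
            d = rng.randint(0, l - 1)
            assert common_neighborhood(members, d) <= common_neighborhood(members[:2], d)
            assert common_neighborhood(members, d) <= common_neighborhood(members, d + 1)

    def test_suffix_prune_only_reduces_node_count(self):
        rng = random.Random(9)
        for _ in range(20):
            l = rng.randint(3, 7)
            d = rng.randint(1, l - 1)
            members = ["".join(rng.choice("ACGT") for _ in range(l)) for _ in range(3)]
            off, on = NodeCounter(), NodeCounter()
            res_off = common_neighborhood(members, d, counter=off)
            res_on = common_neighborhood(members, d, suffix_prune=True, counter=on)
            assert res_on == res_off
            assert on.nodes <= off.nodes


class TestSingleNeighborhoodSize:
    @pytest.mark.parametrize(
        "l, d, sigma, expected",
        [
            (2, 1, 4, 7),
            (5, 0, 4, 1),
            (3, 3, 4, 64),  # whole space
            (2, 1, 20, 39),
        ],
    )
    def test_examples(self, l, d, sigma, expected):
        assert single_neighborhood_size(l, d, sigma) == expected

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            single_neighborhood_size(3, 4, 4)


class TestPrefixPrunable:
    def test_prefix_beyond_budget_is_prunable(self):
        assert prefix_prunable("CC", ("AAAA",), 1) is True

    def test_prefix_within_budget_is_not_prunable(self):
        assert prefix_prunable("CA", ("AAAA",), 1) is False

    def test_suffix_bound_prunes_where_minimal_test_cannot(self):
        # no word is within 1 of both AAAA and TTTT (total distance to the
        # pair is at least their pairwise distance 4 > 2d); the per-member
        # prefix test cannot see this from prefix "A", the suffix bound can
        members = ("AAAA", "TTTT")
        assert exhaustive_neighborhood(members, 1) == set()
        assert prefix_prunable("A", members, 1, suffix_prune=True) is True
        assert prefix_prunable("A", members, 1) is False

    def test_never_prunes_a_viable_prefix(self):
        rng = random.Random(5)
        for _ in range(40):
            l = rng.randint(2, 6)
            d = rng.randint(0, l)
            members = ["".join(rng.choice("ACGT") for _ in range(l)) for _ in range(2)]
            viable_prefixes = {
                m[: rng.randint(1, l)] for m in exhaustive_neighborhood(members, d)
            }
            for prefix in viable_prefixes:
                assert not prefix_prunable(prefix, members, d, suffix_prune=True)
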