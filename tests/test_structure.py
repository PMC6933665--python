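import itertools

import pytest
from hypothesis import given, settings, strategies as st

from prsa import (
    FixtureSpec,
    StemConstraints,
    count_pseudoknot_stems,
    crossing,
    enumerate_stems,
    random_sequence,
    resolve_conflicts,
    stem_positions,
    stems_to_mapping,
)
from prsa.stems import Stem
from prsa.structure import check_conflict_free, stems_to_pairmap
from conftest import BCRV1_M1, BCRV1_M2


class TestMapping:
    def test_single_stem_mapping(self):
        # one three-pair stem anchored at (2, 14) on a 15-mer
        y = stems_to_mapping([Stem(2, 14, 3)], n=15)
        assert tuple(y) == (1, 14, 13, 12, 5, 6, 7, 8, 9, 10, 11, 4, 3, 2, 15)

    def test_empty_is_identity(self):
        assert stems_to_mapping([], n=5) == [1, 2, 3, 4, 5]

    def test_full_hairpin(self):
        assert tuple(stems_to_mapping([Stem(1, 9, 3)], n=9)) == (9, 8, 7, 4, 5, 6, 3, 2, 1)

    def test_conflict_names_position(self):
        with pytest.raises(ValueError, match="position"):
            stems_to_mapping([Stem(1, 9, 3), Stem(3, 12, 3)], n=12)

    def test_mapping_is_involution(self):
        y = stems_to_mapping(list(BCRV1_M1), n=98)
        assert all(y[y[p - 1] - 1] == p for p in range(1, 99))


class TestStemPositions:
    @pytest.mark.parametrize(
        "stem, expected",
        [
            (Stem(9, 19, 3), {9, 10, 11, 17, 18, 19}),
            (Stem(2, 20, 3), {2, 3, 4, 18, 19, 20}),
            (Stem(1, 9, 3), {1, 2, 3, 7, 8, 9}),
        ],
    )
    def test_positions(self, stem, expected):
        assert stem_positions(stem) == expected


class TestResolveConflicts:
    def test_short_remnant_is_discarded(self, default_constraints):
        # inserting (2,20,3) strips two of (9,19,3)'s pairs; the surviving
        # single pair (11,17) is below MinStem and is dropped entirely
        out = resolve_conflicts((Stem(9, 19, 3),), Stem(2, 20, 3), default_constraints)
        assert out == (Stem(2, 20, 3),)

    def test_no_conflict_appends(self, default_constraints):
        assert resolve_conflicts((), Stem(2, 20, 3), default_constraints) == (Stem(2, 20, 3),)

    def test_full_overlap_replaces(self, default_constraints):
        out = resolve_conflicts((Stem(1, 9, 3),), Stem(1, 9, 3), default_constraints)
        assert out == (Stem(1, 9, 3),)

    def test_long_stem_keeps_outer_remnant(self):
        # candidate hits only the innermost pairs of a 6-pair stem; the
        # outer run of 4 survives as its own stem
        c = StemConstraints(3, 3)
        incumbent = Stem(1, 20, 6)  # pairs (1,20)..(6,15)
        candidate = Stem(5, 16, 3)  # occupies 5,6,7 and 14,15,16
        out = resolve_conflicts((incumbent,), candidate, c)
        assert set(out) == {Stem(1, 20, 4), candidate}
        check_conflict_free(out, c)

    def test_untouched_stems_survive_whole(self, default_constraints):
        incumbents = (Stem(1, 9, 3), Stem(30, 40, 3))
        out = resolve_conflicts(incumbents, Stem(12, 25, 3), default_constraints)
        assert set(incumbents) <= set(out)

    @given(seed=st.integers(0, 2000))
    @settings(max_examples=50)
    def test_result_always_valid(self, seed):
        """Random insertion chains stay conflict-free and constraint-clean."""
        import numpy as np

        c = StemConstraints(3, 3)
        seq = random_sequence(FixtureSpec(n=50, seed=seed, gc_bias=0.6))
        pool = enumerate_stems(seq, c)
        if not pool:
            return
        rng = np.random.default_rng(seed)
        stems = ()
        for _ in range(15):
            cand = pool[int(rng.integers(len(pool)))]
            stems = resolve_conflicts(stems, cand, c)
            check_conflict_free(stems, c)
            # the newcomer's positions pair exactly as it dictates
            pm = stems_to_pairmap(stems, seq.n)
            for p, q in ((cand.i + t, cand.j - t) for t in range(cand.k)):
                assert pm[p] == q


class TestCrossing:
    def test_interleaved(self):
        assert crossing(Stem(5, 47, 6), Stem(14, 80, 6))

    def test_nested_and_disjoint(self):
        assert not crossing(Stem(14, 80, 6), Stem(20, 38, 5))
        assert not crossing(Stem(5, 47, 6), Stem(53, 74, 9))

    @given(
        a=st.tuples(st.integers(1, 40), st.integers(41, 80)),
        b=st.tuples(st.integers(1, 40), st.integers(41, 80)),
    )
    def test_symmetry(self, a, b):
        sa, sb = Stem(a[0], a[1], 2), Stem(b[0], b[1], 2)
        assert crossing(sa, sb) == crossing(sb, sa)


class TestPseudoknotCount:
    def test_two_crossing_classes(self):
        assert count_pseudoknot_stems(BCRV1_M1) == 2

    def test_single_crossing(self):
        assert count_pseudoknot_stems(BCRV1_M2) == 1

    def test_nested_only_is_zero(self):
        nested = [Stem(1, 50, 3), Stem(10, 40, 3), Stem(20, 30, 3)]
        assert count_pseudoknot_stems(nested) == 0

    @given(seed=st.integers(0, 2000))
    @settings(max_examples=50)
    def test_zero_iff_no_crossing_pair(self, seed):
        """PG == 0 exactly when the quadratic crossing oracle finds none."""
        import numpy as np

        c = StemConstraints(3, 3)
        seq = random_sequence(FixtureSpec(n=60, seed=seed, gc_bias=0.6))
        pool = enumerate_stems(seq, c)
        if not pool:
            return
        rng = np.random.default_rng(seed + 1)
        stems = ()
        for _ in range(10):
            stems = resolve_conflicts(stems, pool[int(rng.integers(len(pool)))], c)
        any_cross = any(
            crossing(a, b) for a, b in itertools.combinations(stems, 2)
        )
        assert (count_pseudoknot_stems(stems) == 0) == (not any_cross)
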