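import itertools

import pytest
from hypothesis import settings

from prsa import RnaSequence, StemConstraints, fitness, validate_sequence
from prsa.stems import Stem
from prsa.structure import stem_positions

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

# Mengo virus 5'UTR pseudoknot fragment (PseudoBase PKB295), the standard
# 24-nt worked example for stem enumeration.
MENGO_PKB = "ACGUGAAGGCUACGAUAGUGCCAG"

# Two alternative BCRV1 structures used to exercise the fitness function.
BCRV1_M1 = (Stem(5, 47, 6), Stem(14, 80, 6), Stem(20, 38, 5), Stem(26, 98, 7), Stem(53, 74, 9))
BCRV1_M2 = (Stem(4, 48, 8), Stem(19, 39, 6), Stem(26, 98, 7), Stem(52, 75, 10))


@pytest.fixture
def mengo() -> RnaSequence:
    return validate_sequence(MENGO_PKB, id="Mengo_PKB")


@pytest.fixture
def default_constraints() -> StemConstraints:
    return StemConstraints(min_stem=3, min_loop=3)


def exhaustive_optimum(triplets, mg=1):
    """Brute-force best fitness over all mutually conflict-free stem subsets.

    Independent of the annealer: plain subset enumeration with a pairwise
    position-disjointness check.  Only usable for small pools.
    """
    best_f, best_sub = 0.0, ()
    for r in range(len(triplets) + 1):
        for sub in itertools.combinations(triplets, r):
            positions = set()
            ok = True
            for m in sub:
                sp = stem_positions(m)
                if positions & sp:
                    ok = False
                    break
                positions |= sp
            if ok:
                f = fitness(sub, mg=mg).f
                if f > best_f:
                    best_f, best_sub = f, sub
    return best_f, best_sub
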