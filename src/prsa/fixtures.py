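"""Deterministic synthetic inputs: random sequences and planted structures.

``random_sequence`` draws i.i.d. residues with a tunable G+C weight.
``planted_structure_sequence`` embeds a known conflict-free stem set by
writing Watson-Crick partners at the stem positions and filling the rest
with A-biased residues (A minimizes accidental complementarity, since A
only pairs with U).  Planting guarantees the ground-truth stems appear in
the enumerated pool; it does not forbid accidental extra stems, so tests
should assert membership, not uniqueness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

from .sequences import RnaSequence
from .stems import Stem, StemConstraints
from .structure import check_conflict_free, stem_pairs

_WC = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]
#: filler distribution over A, U, G, C — strongly A-biased
_FILL_P = (0.7, 0.1, 0.1, 0.1)


@dataclass(frozen=True)
class FixtureSpec:
    n: int
    seed: int = 0
    gc_bias: float = 0.5
    planted: Tuple[Stem, ...] = ()

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.gc_bias <= 1.0:
            raise ValueError("gc_bias must lie in [0, 1]")


def random_sequence(spec: FixtureSpec) -> RnaSequence:
    """I.i.d. sequence with P(G) = P(C) = gc_bias/2, P(A) = P(U) = (1-gc_bias)/2."""
    rng = np.random.default_rng(spec.seed)
    g = spec.gc_bias / 2.0
    a = (1.0 - spec.gc_bias) / 2.0
    letters = rng.choice(np.array(list("AUGC")), size=spec.n, p=[a, a, g, g])
    return RnaSequence(id=f"random_n{spec.n}_s{spec.seed}", residues="".join(letters))


def planted_structure_sequence(spec: FixtureSpec) -> Tuple[RnaSequence, Tuple[Stem, ...]]:
    """Sequence with the given stems embedded, plus the ground truth.

    Stem positions get randomly chosen Watson-Crick partners; remaining
    positions are filled A-biased.  Raises if the planted stems conflict or
    exceed the sequence length.
    """
    stems = tuple(sorted(spec.planted))
    check_conflict_free(stems, StemConstraints(min_stem=2, min_loop=3))
    if stems and max(m.j for m in stems) > spec.n:
        raise ValueError("planted stem exceeds sequence length")
    rng = np.random.default_rng(spec.seed)
    residues: list = [None] * spec.n
    for m in stems:
        for p, q in stem_pairs(m):
            a, b = _WC[int(rng.integers(len(_WC)))]
            for pos, letter in ((p, a), (q, b)):
                if residues[pos - 1] is not None and residues[pos - 1] != letter:
                    raise ValueError(f"position {pos} forced to two letters")
                residues[pos - 1] = letter
    filler = rng.choice(np.array(list("AUGC")), size=spec.n, p=_FILL_P)
    seq = "".join(
        r if r is not None else filler[idx] for idx, r in enumerate(residues)
    )
    return (
        RnaSequence(id=f"planted_n{spec.n}_s{spec.seed}", residues=seq),
        stems,
    )
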