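"""Enumeration of consecutive-base-pair stems and the merged candidate pool.

A stem is a run of k consecutive complementary base pairs
{(i, j), (i+1, j-1), ..., (i+k-1, j-k+1)}, encoded as the triplet (i, j, k)
where (i, j) is the outermost pair.  Admissible pairings are the Watson-Crick
pairs plus the G·U wobble.  Given a minimum stem length (MinStem, in pairs)
and a minimum hairpin loop length (MinLoop, in unpaired bases), the anchor
and length of every admissible stem satisfy

    1 <= i <= n - 2*MinStem - MinLoop + 1
    i + 2*MinStem + MinLoop - 1 <= j <= n
    MinStem <= k <= floor((j - i - MinLoop + 1) / 2)

and every one of the k pairs is complementary.  Every admissible sub-length
k >= MinStem of a longer complementary run is enumerated as its own triplet.
Triplets sharing an anchor (i, j) are merged into one pool entry carrying the
ascending set of admissible lengths; the merged pool is what the annealer's
neighbor move draws from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .sequences import RnaSequence

#: Admissible base pairs: Watson-Crick plus the G·U wobble.
WOBBLE_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)


@dataclass(frozen=True, order=True)
class Stem:
    """A run of ``k`` consecutive base pairs with outermost pair (``i``, ``j``)."""

    i: int
    j: int
    k: int

    def __post_init__(self):
        if not (1 <= self.i < self.j and self.k >= 1):
            raise ValueError(f"invalid stem triplet ({self.i},{self.j},{self.k})")

    @property
    def hairpin_gap(self) -> int:
        """Unpaired span enclosed by the innermost pair: j - i - 2k + 1."""
        return self.j - self.i - 2 * self.k + 1


@dataclass(frozen=True)
class StemConstraints:
    """Minimum stem length (pairs) and minimum hairpin loop length (bases)."""

    min_stem: int = 3
    min_loop: int = 3

    def __post_init__(self):
        if self.min_stem < 2:
            raise ValueError("min_stem must be >= 2")
        if self.min_loop < 3:
            raise ValueError("min_loop must be >= 3")


@dataclass(frozen=True)
class MergedStemEntry:
    """An anchor (i, j) with all of its admissible stem lengths, ascending."""

    i: int
    j: int
    ks: Tuple[int, ...]


def is_complementary(a: str, b: str) -> bool:
    """True exactly for the six admissible ordered pairs (WC + G·U wobble)."""
    return (a, b) in WOBBLE_PAIRS


def enumerate_stems(seq: RnaSequence, c: StemConstraints) -> List[Stem]:
    """All admissible stem triplets of ``seq``, sorted by (i, j, k).

    For each anchor (i, j) the complementary run is extended inward once and
    every length from ``min_stem`` up to the run length (capped by the loop
    constraint) is emitted.
    """
    n = seq.n
    x = seq.residues
    span = 2 * c.min_stem + c.min_loop  # minimal j - i + 1
    out: List[Stem] = []
    for i in range(1, n - span + 2):
        for j in range(i + span - 1, n + 1):
            k_cap = (j - i - c.min_loop + 1) // 2
            run = 0
            while run < k_cap and (x[i + run - 1], x[j - run - 1]) in WOBBLE_PAIRS:
                run += 1
            for k in range(c.min_stem, run + 1):
                out.append(Stem(i, j, k))
    out.sort()
    return out


def brute_force_stems(seq: RnaSequence, c: StemConstraints) -> List[Stem]:
    """Independent oracle: literal triple loop over all (i, j, k).

    Checks the three anchor/length inequalities and per-pair complementarity
    verbatim for every candidate triplet.  Quadratic-ish and meant for test
    sequences of at most a few hundred bases.
    """
    n = seq.n
    out = []
    for i in range(1, n + 1):
        if not i <= n - 2 * c.min_stem - c.min_loop + 1:
            continue
        for j in range(1, n + 1):
            if not i + 2 * c.min_stem + c.min_loop - 1 <= j <= n:
                continue
            for k in range(c.min_stem, (j - i - c.min_loop + 1) // 2 + 1):
                if all(
                    is_complementary(seq.base(i + t), seq.base(j - t))
                    for t in range(k)
                ):
                    out.append(Stem(i, j, k))
    out.sort()
    return out


def merge_stems(triplets: Sequence[Stem]) -> List[MergedStemEntry]:
    """Merge triplets sharing an anchor (i, j) into pool entries.

    Output is sorted by (i, j) and conserves the triplet count:
    sum(len(e.ks)) == len(triplets).
    """
    by_anchor: Dict[Tuple[int, int], List[int]] = {}
    for m in triplets:
        by_anchor.setdefault((m.i, m.j), []).append(m.k)
    return [
        MergedStemEntry(i=i, j=j, ks=tuple(sorted(set(ks))))
        for (i, j), ks in sorted(by_anchor.items())
    ]


def stem_pool(seq: RnaSequence, c: StemConstraints) -> List[MergedStemEntry]:
    """Convenience: enumerate and merge in one call."""
    return merge_stems(enumerate_stems(seq, c))
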