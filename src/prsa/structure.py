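"""Candidate structures as conflict-free stem sets.

A candidate secondary structure is a list of stems in which no base position
participates in more than one pair.  Its pairing is equivalently expressed
as a *mapping string*: an array y of length n where y[p] = q if p pairs with
q and y[p] = p otherwise (an involution over 1..n).

When the annealer inserts a new stem that clashes with the current
structure, the clash is resolved in four steps: every existing base pair
touching a position claimed by the new stem is removed; the surviving pairs
of each trimmed stem are split into maximal consecutive runs; runs shorter
than MinStem, or whose hairpin gap drops below MinLoop, are discarded; and
the new stem enters intact.

Two stems form a pseudoknot when their outermost pairs interleave
(i1 < i2 < j1 < j2).  Because a stem is an internally nested block, checking
outermost pairs decides crossing for every pair inside.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, List, Sequence, Tuple

from .sequences import PairMap
from .stems import Stem, StemConstraints

StemSet = Tuple[Stem, ...]


def stem_pairs(m: Stem) -> List[Tuple[int, int]]:
    """The k base pairs of a stem, outermost first."""
    return [(m.i + t, m.j - t) for t in range(m.k)]


def stem_positions(m: Stem) -> FrozenSet[int]:
    """All 2k paired positions: {i..i+k-1} ∪ {j-k+1..j}."""
    return frozenset(range(m.i, m.i + m.k)) | frozenset(range(m.j - m.k + 1, m.j + 1))


def stems_to_mapping(stems: Sequence[Stem], n: int) -> List[int]:
    """Mapping string of a conflict-free stem set.

    Returns a length-n list of 1-based indices with y[p-1] == p for unpaired
    positions.  Raises on the first position claimed twice.
    """
    y = list(range(1, n + 1))
    for m in stems:
        for p, q in stem_pairs(m):
            if q > n:
                raise ValueError(f"stem {m} exceeds sequence length {n}")
            if y[p - 1] != p or y[q - 1] != q:
                clash = p if y[p - 1] != p else q
                raise ValueError(f"conflicting stems: position {clash} paired twice")
            y[p - 1] = q
            y[q - 1] = p
    return y


def stems_to_pairmap(stems: Sequence[Stem], n: int) -> PairMap:
    """Pair map (symmetric dict) of a conflict-free stem set."""
    y = stems_to_mapping(stems, n)
    return {p: q for p, q in zip(range(1, n + 1), y) if p != q}


def resolve_conflicts(
    stems: Sequence[Stem], candidate: Stem, c: StemConstraints
) -> StemSet:
    """Insert ``candidate`` into a conflict-free stem set, trimming clashes.

    Existing pairs touching the candidate's positions are removed; each
    trimmed stem's survivors are split into maximal consecutive runs and
    re-checked against MinStem and the MinLoop hairpin gap; the candidate
    always enters whole.  The input is not modified.
    """
    taken = stem_positions(candidate)
    out: List[Stem] = []
    for m in stems:
        survivors = [
            t
            for t, (p, q) in enumerate(stem_pairs(m))
            if p not in taken and q not in taken
        ]
        for run_start, run_len in _consecutive_runs(survivors):
            remnant = Stem(m.i + run_start, m.j - run_start, run_len)
            if remnant.k >= c.min_stem and remnant.hairpin_gap >= c.min_loop:
                out.append(remnant)
    out.append(candidate)
    return tuple(out)


def _consecutive_runs(sorted_ints: List[int]) -> List[Tuple[int, int]]:
    """(start value, length) of each maximal run of consecutive integers."""
    runs = []
    idx = 0
    while idx < len(sorted_ints):
        start = sorted_ints[idx]
        length = 1
        while idx + length < len(sorted_ints) and sorted_ints[idx + length] == start + length:
            length += 1
        runs.append((start, length))
        idx += length
    return runs


def crossing(a: Stem, b: Stem) -> bool:
    """True iff the outermost pairs of a and b interleave (pseudoknot)."""
    return a.i < b.i < a.j < b.j or b.i < a.i < b.j < a.j


def count_pseudoknot_stems(stems: Sequence[Stem]) -> int:
    """Number of stems crossing at least one earlier-starting stem (PG).

    Counting each stem that interleaves with a stem of strictly smaller
    start index charges every pseudoknot to its later-starting member.
    """
    ordered = sorted(stems, key=lambda m: (m.i, m.j, m.k))
    return sum(
        1
        for t, m in enumerate(ordered)
        if any(prev.i < m.i and crossing(prev, m) for prev in ordered[:t])
    )


def check_conflict_free(stems: Sequence[Stem], c: StemConstraints) -> None:
    """Validate stem-set invariants; raises on violation."""
    seen: Dict[int, Stem] = {}
    for m in stems:
        if m.k < c.min_stem:
            raise ValueError(f"stem {m} shorter than MinStem={c.min_stem}")
        if m.hairpin_gap < c.min_loop:
            raise ValueError(f"stem {m} hairpin gap {m.hairpin_gap} < MinLoop={c.min_loop}")
        for p in stem_positions(m):
            if p in seen:
                raise ValueError(f"position {p} shared by {seen[p]} and {m}")
            seen[p] = m
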