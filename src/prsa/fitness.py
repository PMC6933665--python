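"""Stem-based surrogate fitness for candidate structures.

Instead of a full thermodynamic free-energy model, a candidate stem set M is
scored from the quantities

    TP    — total base pairs, sum of k over the stems,
    Group — number of stems |M|,
    AP    — average pairs per stem, TP / Group,
    PG    — predicted pseudoknot count (crossing stems),
    MG    — expected pseudoknot count, a user parameter (default 1),

as

    F(M) = TP * AP^2                              if PG <= MG
    F(M) = TP * AP^2 * (Group - PG) / Group       if PG > MG

Squaring AP rewards few, long stems over many short ones — the consecutive
pairs are what lower free energy — while the (Group - PG)/Group factor
penalizes structures with more crossings than expected.  The empty structure
scores 0 by convention (AP is defined as 0 when Group is 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .stems import Stem
from .structure import count_pseudoknot_stems


@dataclass(frozen=True)
class FitnessReport:
    """All scoring quantities of one candidate stem set."""

    tp: int
    group: int
    ap: float
    pg: int
    mg: int
    f: float


def total_pairs(stems: Sequence[Stem]) -> int:
    """TP: sum of stem lengths in base pairs."""
    return sum(m.k for m in stems)


def average_pairs(stems: Sequence[Stem]) -> float:
    """AP = TP / Group; 0 for the empty structure."""
    if not stems:
        return 0.0
    return total_pairs(stems) / len(stems)


def fitness(stems: Sequence[Stem], mg: int = 1) -> FitnessReport:
    """Score a conflict-free stem set; see the module docstring for F."""
    if mg < 0:
        raise ValueError("mg must be >= 0")
    group = len(stems)
    if group == 0:
        return FitnessReport(tp=0, group=0, ap=0.0, pg=0, mg=mg, f=0.0)
    tp = total_pairs(stems)
    ap = Fraction(tp, group)  # exact ratio; floats only at the report edge
    pg = count_pseudoknot_stems(stems)
    f = Fraction(tp) * ap * ap
    if pg > mg:
        f *= Fraction(group - pg, group)
    return FitnessReport(tp=tp, group=group, ap=float(ap), pg=pg, mg=mg, f=float(f))
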