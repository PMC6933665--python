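"""Base-pair level accuracy of a predicted structure against a reference.

A predicted pair counts as correct only if both endpoints match a reference
pair exactly (no slippage tolerance).  From the counts

    tp — pairs present in both structures,
    fp — predicted pairs absent from the reference,
    fn — reference pairs that were missed,

sensitivity, specificity (precision-like: tp / predicted pairs) and their
harmonic mean are reported in percent:

    SN = 100 * tp / (tp + fn)
    SP = 100 * tp / (tp + fp)
    F  = 2 * SP * SN / (SN + SP)

Degenerate cases: an empty reference matched by an empty prediction is
vacuously perfect (all three metrics 100); otherwise a zero denominator
yields 0 for the affected metric, and F is 0 when SN + SP is 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

from .sequences import PairMap, check_pair_map, pairs_as_tuples


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int
    sn: float
    sp: float
    f: float


def compare_pairs(
    pred: PairMap, ref: PairMap, n: int | None = None
) -> Tuple[int, int, int]:
    """Count (tp, fp, fn) over unordered base pairs."""
    if n is not None:
        check_pair_map(pred, n)
        check_pair_map(ref, n)
    p = set(pairs_as_tuples(pred))
    r = set(pairs_as_tuples(ref))
    return len(p & r), len(p - r), len(r - p)


def metrics(tp: int, fp: int, fn: int) -> EvalResult:
    """Sensitivity, specificity and F-measure in percent from pair counts."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp == 0 and fp == 0 and fn == 0:
        return EvalResult(0, 0, 0, sn=100.0, sp=100.0, f=100.0)
    sn = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    sp = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    f = 2.0 * sp * sn / (sn + sp) if sn + sp else 0.0
    return EvalResult(tp=tp, fp=fp, fn=fn, sn=sn, sp=sp, f=f)


def evaluate(pred: PairMap, ref: PairMap, n: int | None = None) -> EvalResult:
    """Compare and score in one call."""
    return metrics(*compare_pairs(pred, ref, n))
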