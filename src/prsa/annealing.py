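"""The simulated-annealing search over the merged stem pool.

The search state is a conflict-free stem set, initially empty.  A neighbor
is generated with two uniform draws — a pool entry, then one of its
admissible lengths — and the drawn stem is inserted through conflict
resolution, so deletions happen implicitly when the newcomer clashes with
the incumbents.  Moves are accepted by the maximizing Boltzmann rule:
improvements always, a fitness drop dF < 0 with probability exp(dF / T).
Temperature decays geometrically; the best structure ever visited
(``MaxPairs`` in the field's vocabulary) is tracked separately from the
current one and returned.

The schedule defaults are desk-scale choices: T0 = 100 * MinStem (the order
of a typical fitness jump), alpha = 0.95, 10n proposals per temperature
level, T_min = 0.01, and a global cap of 500n proposals; they solve the
published benchmark lengths (n <= 134) in seconds.  All randomness flows
from a single seeded numpy Generator, so runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .fitness import FitnessReport, fitness
from .sequences import RnaSequence
from .stems import MergedStemEntry, Stem, StemConstraints, stem_pool
from .structure import StemSet, resolve_conflicts


@dataclass(frozen=True)
class AnnealingConfig:
    """Search parameters; ``None`` fields are resolved from the sequence length."""

    t0: Optional[float] = None  # default 100 * min_stem
    alpha: float = 0.95
    steps_per_temp: Optional[int] = None  # default 10 * n
    t_min: float = 0.01
    max_iters: Optional[int] = None  # default 500 * n
    seed: int = 0
    mg: int = 1
    constraints: StemConstraints = field(default_factory=StemConstraints)

    def resolved(self, n: int) -> "AnnealingConfig":
        cfg = replace(
            self,
            t0=self.t0 if self.t0 is not None else 100.0 * self.constraints.min_stem,
            steps_per_temp=self.steps_per_temp
            if self.steps_per_temp is not None
            else 10 * n,
            max_iters=self.max_iters if self.max_iters is not None else 500 * n,
        )
        if not cfg.t0 > cfg.t_min > 0:
            raise ValueError("need t0 > t_min > 0")
        if not 0 < cfg.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if cfg.steps_per_temp < 1 or cfg.max_iters < 1:
            raise ValueError("steps_per_temp and max_iters must be >= 1")
        return cfg


@dataclass(frozen=True)
class PredictionResult:
    """Best structure found, its score, and the per-proposal trajectory."""

    best: StemSet
    best_report: FitnessReport
    #: rows of (iteration, temperature, current F, best F)
    trajectory: Tuple[Tuple[int, float, float, float], ...]
    seed: int


def propose_neighbor(
    stems: Sequence[Stem],
    pool: Sequence[MergedStemEntry],
    c: StemConstraints,
    rng: np.random.Generator,
) -> StemSet:
    """Draw a stem from the pool and insert it with conflict resolution."""
    if not pool:
        raise ValueError("empty stem pool: no move available")
    entry = pool[int(rng.integers(len(pool)))]
    k = entry.ks[int(rng.integers(len(entry.ks)))]
    return resolve_conflicts(stems, Stem(entry.i, entry.j, k), c)


def accept(
    f_new: float, f_old: float, temperature: float, rng: np.random.Generator
) -> bool:
    """Maximizing Boltzmann acceptance at the given temperature."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if f_new >= f_old:
        return True
    return rng.random() < math.exp((f_new - f_old) / temperature)


def anneal(seq: RnaSequence, config: AnnealingConfig = AnnealingConfig()) -> PredictionResult:
    """Run the full annealing search on one sequence.

    Builds the merged stem pool, walks the neighbor chain from the empty
    structure, and returns the highest-fitness structure ever visited.  A
    sequence with an empty pool (nothing can pair) yields the empty
    structure with F = 0.
    """
    cfg = config.resolved(seq.n)
    pool = stem_pool(seq, cfg.constraints)
    empty_report = fitness((), cfg.mg)
    if not pool:
        return PredictionResult(
            best=(), best_report=empty_report, trajectory=(), seed=cfg.seed
        )

    rng = np.random.default_rng(cfg.seed)
    current: StemSet = ()
    current_report = empty_report
    best: StemSet = ()
    best_report = empty_report
    trajectory: List[Tuple[int, float, float, float]] = []

    iteration = 0
    temperature = float(cfg.t0)
    while temperature > cfg.t_min and iteration < cfg.max_iters:
        for _ in range(cfg.steps_per_temp):
            if iteration >= cfg.max_iters:
                break
            proposal = propose_neighbor(current, pool, cfg.constraints, rng)
            report = fitness(proposal, cfg.mg)
            if accept(report.f, current_report.f, temperature, rng):
                current, current_report = proposal, report
            if current_report.f > best_report.f:
                best, best_report = current, current_report
            iteration += 1
            trajectory.append(
                (iteration, temperature, current_report.f, best_report.f)
            )
        temperature *= cfg.alpha
    return PredictionResult(
        best=tuple(sorted(best)),
        best_report=best_report,
        trajectory=tuple(trajectory),
        seed=cfg.seed,
    )
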