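# Methods

## Problem and model

`prsa` predicts the secondary structure of an RNA sequence, pseudoknots
included. The search space is not individual base pairs but *stems*: runs of
k consecutive complementary pairs {(i, j), (i+1, j−1), …, (i+k−1, j−k+1)},
encoded as triplets (i, j, k) with (i, j) the outermost pair. Isolated pairs
are excluded because single pairs do not meaningfully lower free energy; only
consecutive stacking does. Admissible pairings are the Watson–Crick pairs
plus the G·U wobble: W = {AU, UA, GC, CG, GU, UG}.

Two parameters bound what counts as a stem:

| parameter | meaning                                 | unit  | constraint | default |
|-----------|-----------------------------------------|-------|------------|---------|
| MinStem   | minimum stem length                     | pairs | ≥ 2        | 3       |
| MinLoop   | minimum hairpin loop length             | bases | ≥ 3        | 3       |

For a sequence of length n, an admissible (i, j, k) satisfies

    1 ≤ i ≤ n − 2·MinStem − MinLoop + 1
    i + 2·MinStem + MinLoop − 1 ≤ j ≤ n
    MinStem ≤ k ≤ ⌊(j − i − MinLoop + 1) / 2⌋

together with per-pair complementarity. Every sub-length k ≥ MinStem of a
longer complementary run is a distinct triplet; triplets sharing an anchor
(i, j) merge into one *pool entry* carrying all admissible lengths. The
upper bound on k uses integer floor division since k counts pairs. On the
24-nt Mengo virus pseudoknot fragment at MinStem = MinLoop = 3 the pool has
10 triplets over 8 anchors.

A candidate structure is a conflict-free stem set M (no position in two
pairs), equivalently a mapping string y with y[p] = q iff p pairs with q and
y[p] = p otherwise — an involution over 1..n. Two stems form a pseudoknot
when their outermost pairs interleave (i₁ < i₂ < j₁ < j₂); because a stem is
an internally nested block, outermost pairs decide crossing for all pairs
inside.

## Fitness

Rather than a nearest-neighbor thermodynamic model, candidates are scored by
the stem statistics

    TP = Σ k  (total pairs), Group = |M|, AP = TP / Group,
    PG = predicted pseudoknot count, MG = expected pseudoknot count,

    F(M) = TP·AP²                         if PG ≤ MG
    F(M) = TP·AP²·(Group − PG)/Group      if PG > MG

AP² rewards few, long stems; the penalty factor discourages more crossings
than the expected count MG (a per-run user parameter, default 1 — no
selection rule for MG is established, so it is exposed rather than guessed).
Conventions chosen here: an empty structure has TP = AP = F = 0, avoiding a
0/0 and making F monotone from the empty start state. F is accumulated in
exact rationals (`fractions.Fraction`) and converted to float only in the
report, so equal-by-construction scores compare equal.

PG is counted as the number of stems that cross at least one stem with a
strictly smaller start index — i.e., each pseudoknot is charged to its
later-starting member. "Number of pseudoknots" admits other readings (e.g.
minimum stems to delete to become crossing-free); both rules agree on every
case with known expected output, and the stem-level rule is the simplest
O(|M|²) choice. It would need revisiting against richer ground truth.

## Neighbor move and conflict resolution

The only move is *insert a stem drawn from the pool*, with conflicts
resolved in four steps:

1. every existing base pair touching one of the newcomer's 2k positions is
   removed;
2. each trimmed stem's surviving pairs are split into maximal consecutive
   runs, each a remnant stem;
3. remnants shorter than MinStem, or whose hairpin gap j − i − 2k + 1 drops
   below MinLoop, are discarded;
4. the newcomer enters intact.

Deletions therefore happen implicitly — there is no explicit removal move.
This is a known stagnation risk on large pools, accepted here for fidelity
to the move's definition; the Boltzmann rule still lets fitness fall, which
is how the chain escapes local optima. MinLoop is enforced uniformly on
remnants even when another stem bridges the remnant's hairpin span; the
alternative (exempting bridged hairpins) has no established answer.

## Annealing schedule

The chain starts from the empty structure. A proposal draws a pool entry
uniformly, then one of its lengths uniformly. Acceptance is the maximizing
Boltzmann rule: always when F does not decrease, else with probability
exp(ΔF/T). Temperature decays geometrically. Schedule defaults:

| parameter      | default       | rationale                                   |
|----------------|---------------|---------------------------------------------|
| T0             | 100 · MinStem | order of a typical early fitness jump       |
| alpha          | 0.95          | standard geometric decay                    |
| steps_per_temp | 10 · n        | proposals scale with pool size ∝ n          |
| T_min          | 0.01          | effectively frozen chain                    |
| max_iters      | 500 · n       | global cap; seconds at benchmark lengths    |

The best structure ever visited is tracked separately from the current one
and returned, so the best-F trajectory is non-decreasing by construction.
The current state is never reset to the best. One seeded numpy Generator
drives both draws and acceptance, making runs bit-reproducible; the seed is
echoed in the result.

## Evaluation

Predictions are compared to references at the base-pair level with exact
endpoint matching (no ±1 slippage): tp = |pred ∩ ref|, fp = |pred \ ref|,
fn = |ref \ pred| over unordered pairs, then

    SN = 100·tp/(tp+fn),  SP = 100·tp/(tp+fp),  F = 2·SP·SN/(SN+SP).

Degenerate conventions: empty reference matched by empty prediction is
vacuously perfect (all 100); otherwise a zero denominator gives 0 for the
affected metric, and F = 0 when SN + SP = 0. Percentages print to one
decimal.

## Structure I/O

Pair maps round-trip through extended dot-bracket, CT, and bpseq. The
dot-bracket writer assigns bracket layers `()`, `[]`, `{}`, `<>`, then
`Aa`..`Zz` by first-fit: a pair goes to the lowest layer where it crosses
nothing already placed, so each layer is properly nested; more than 30
crossing classes is an error (unreachable at realistic scale). DNA-style T
is silently read as U; any other non-ACGU letter is a hard error naming the
position. Coordinates are 1-based inclusive throughout the library,
converted only at I/O edges.

## Synthetic fixtures

`random_sequence` draws i.i.d. residues with P(G) = P(C) = gc_bias/2.
`planted_structure_sequence` embeds a known conflict-free stem set by
writing randomly chosen Watson–Crick partners at stem positions and filling
elsewhere A-biased (A pairs only with U, minimizing accidental
complementarity). Planting guarantees the truth appears in the enumerated
pool; it does *not* prevent accidental competing stems, and the surrogate
fitness need not rank the planted truth first — so recovery experiments on
planted fixtures measure the method's behavior under its own objective, not
an upper bound on real-data accuracy. Real structures differ from these
fixtures in base composition, stem length distribution, and the presence of
non-canonical interactions; passing tests on fixtures shows algorithmic
correctness, not biological accuracy.

## Problem sizes and verification scale

The test suite verifies enumeration against a literal brute-force oracle on
200 seeded random sequences (n ∈ [4, 60], two constraint settings), and the
annealer against exhaustive subset enumeration of the Mengo pool (10
triplets → 1024 subsets) across 10 seeds. `scripts/acceptance.py` re-runs
those checks plus a 5-replicate planted-pseudoknot recovery at n = 30.
These sizes were chosen so the whole suite runs in seconds while the
oracles remain exhaustive.

## Known limitations

- The surrogate fitness ignores loop entropies and stacking identities; as
  sequences grow, many-stem structures dilute AP and accuracy degrades —
  the method is strongest below a few hundred nucleotides.
- MG must be supplied; there is no data-driven estimate of the expected
  pseudoknot count.
- No restarts or parallel tempering; a single chain per run.
- The insert-only move set can stagnate when the optimum requires removing
  a stem without a replacement at its positions.
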