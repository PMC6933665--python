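# prsa

Simulated-annealing prediction of RNA secondary structure **with
pseudoknots**, for structural-bioinformatics users who need fast,
reproducible pseudoknot-capable predictions on sequences up to a few
hundred nucleotides — a regime where exact thermodynamic pseudoknot
prediction is NP-complete and dynamic-programming tools either forbid
crossings or become impractically slow.

## Method in brief

The unit of search is the *stem*: a run of k consecutive complementary base
pairs {(i, j), (i+1, j−1), …}, encoded (i, j, k), over the admissible pair
set W = {AU, UA, GC, CG, GU, UG}. Given MinStem (≥ 2 pairs, default 3) and
MinLoop (≥ 3 bases, default 3), all admissible stems are enumerated once
and merged into a candidate pool keyed by anchor (i, j). A candidate
structure M is a conflict-free stem subset, scored by

    TP = Σ k,  Group = |M|,  AP = TP / Group,

    F(M) = TP·AP²                        if PG ≤ MG
         = TP·AP²·(Group − PG)/Group     if PG > MG

where PG counts crossing (pseudoknotted) stems and MG is the expected
pseudoknot count (default 1). Simulated annealing walks the pool: a
uniformly drawn stem is inserted with conflict resolution (clashing pairs
removed, remnant runs re-checked against MinStem/MinLoop), moves are
accepted by the maximizing Boltzmann rule exp(ΔF/T) under geometric
cooling, and the best structure ever visited is returned. Predictions are
scored against references by base-pair sensitivity, specificity, and
F-measure. See `docs/methods.md` for the full model.

## Worked example

Scoring two alternative structures of the BCRV1 molecule (stem triplets as
`i j k` per line, MG = 1):

```sh
$ cat m1.tsv
5   47  6
14  80  6
20  38  5
26  98  7
53  74  9
$ prsa score bcrv1.fasta --stems m1.tsv --mg 1 --format json
{
  "id": "BCRV1",
  "TP": 33,
  "Group": 5,
  "AP": 6.6,
  "PG": 2,
  "MG": 1,
  "F": 862.488
}
```

The five stems hold 33 pairs, average 6.6 pairs each, and form two
pseudoknot crossings — one more than expected, so F is penalized by
(5 − 2)/5. The four-stem alternative scores F = 1861.9375 (31 pairs, AP
7.75, PG 1, no penalty) and is therefore preferred: fewer, longer stems win.

Predicting and evaluating a small hairpin:

```sh
$ prsa predict hairpin.fasta --seed 0
# hairpin F=27.00 TP=3 Group=1 AP=3.00 PG=0 seed=0
GGGAAACCC
(((...)))
```

Other subcommands: `prsa stems` (dump the candidate pool), `prsa evaluate`
(SN/SP/F-measure of a prediction against a reference in dot-bracket, CT, or
bpseq), and `prsa fixtures` (deterministic synthetic sequences with planted
stems, for regression corpora).

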