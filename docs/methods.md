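# Methods

This note documents the models, conventions and numerical choices behind
`gcnet`, and what the synthetic benchmarks do and do not demonstrate.

## GC maps and orientation

A GC map is a dense N×N nonnegative matrix over electrode nodes with a zero
diagonal. The package-wide convention is **row = source, column = target**:
`weights[i, j]` measures how strongly node *i*'s past predicts node *j*'s
future. Published maps do not always state their orientation, so
`gcnet.reverse` (a transpose) lets either convention be ingested with one
call. "Granger causality" is predictive, not mechanistic: an edge says one
signal statistically leads another, nothing more.

`to_transition` row-normalizes outgoing weights into jump probabilities.
Nodes left with no outgoing edges after F-test pruning ("dangling" nodes)
keep an all-zero row rather than a patched uniform row: a random walk that
lands on one stops, which is itself informative — such nodes absorb rather
than propagate activity.

## Pairwise Granger causality

For every ordered channel pair (i → j), two nested OLS autoregressions of
channel j are fitted after mean-centring: restricted (j's own p lags) and
full (plus p lags of i). The reported magnitude is the Geweke log variance
ratio `ln(RSS_r / RSS_f)` (nonnegative by nesting) and the edge F statistic
is `((RSS_r − RSS_f)/p) / (RSS_f/(T_eff − 2p − 1))` with `T_eff = T − p`.
Edges below the F critical value at level α (default 0.05, per-edge) are
zeroed.

Choices worth flagging:

* **Bivariate, not conditional.** Each pair is tested in isolation; common
  drivers can produce spurious pairwise edges. Conditional multivariate GC
  is out of scope.
* **Model order** is caller-supplied (library default 10 for 20 s iEEG-like
  segments; an AIC selector over 1..20 is provided). Benchmarks that
  simulate a VAR fit near the true order, since the order is known there.
* **No multiple-comparison correction by default** — the F test is applied
  per edge; a Bonferroni flag (α / N(N−1)) is available. With ~10⁴ edges per
  map the uncorrected default deliberately trades false edges for
  sensitivity, mirroring common practice for this statistic.
* Numerically singular pairs (constant channels, collinear designs) are set
  to zero GC with a warning rather than aborting a whole segment.

## Monte Carlo walkers

One restart = a uniform-random start node (counted as the first visitation)
followed by weighted jumps until `max_steps` visitations or a dangling node.
Defaults 1000 restarts × 1000 visitations per map. Variants:

* **Reversed edges** ("uphill"): transpose the map first, so frequently
  visited nodes are the *generators* of activity, not the receivers.
* **Revisit intervals:** per node, the gap between consecutive visitations
  within one restart, counted inclusively — a visit followed by three other
  nodes and a return records interval 4. Gaps never cross a restart
  boundary. Nodes revisited in no restart have an undefined mean interval
  and rank last: a never-revisited node shows no cyclic involvement, which
  is the signal this metric exists to detect. Short mean interval = tight
  cyclic engagement = rank 1.
* **Multi-token:** k tokens (default 2) start at independent uniform nodes
  and advance synchronously, each by its own draw; a visitation is recorded
  only when all tokens coincide at a node. Coincidence is checked at the
  synchronized start and at each subsequent position, `max_steps` checks per
  restart; a restart ends when any token occupies a dangling node (that
  final landing check still counts, consistent with the single-token rule
  that the dangling node's own visitation counts before the chain stops).

RNG contract: one PCG64 generator per run, draws consumed in a fixed
documented order (all start nodes, then one batch of uniforms per step for
every restart and token, drawn even for terminated chains). Restarts are
independent chains, so the implementation advances them in lockstep,
vectorised across restarts; identical seed + config ⇒ bit-identical output.
Reverse-direction sampling is literally forward sampling on the transposed
map (one code path), so the two are bit-identical for the same seed.

## Deterministic rankings

* **PageRank** (damped, weighted): outflow split proportionally to outgoing
  weights; a dangling node's mass is spread evenly over all *other* nodes
  (not uniformly over all nodes — the node keeps nothing). Damping 0.85,
  L1 tolerance 1e−8, max 200 iterations; non-convergence raises, carrying
  the last iterate. A reversed-edges variant transposes first.
* **Didactic PageRank**: the undamped, unnormalized synchronous
  mass-transfer update, kept as a separate operation because damping and
  normalization change the numbers; it exactly conserves total mass and
  reproduces the textbook-style worked example. One algorithm cannot be
  both this update and the damped fixed point, hence two operations.
* **Betweenness / harmonic centrality** use edge distance = 1/weight
  (heavier GC edge = shorter path) and are computed through networkx, the
  same library family these analyses conventionally use; the test suite
  validates both against an independent brute-force enumeration of all
  simple paths with exact integer distances. Harmonic centrality measures
  distances *into* the node by default (`inward=False` and
  `distance="hops"` variants exist; inverse-weight inward is the default
  because the inward formulation matches the printed formula and the
  inverse-weight dialect matches the betweenness convention).
* **In/outdegree centrality** count edges (not weights) surviving the
  F test, isolating edge *quantity* from edge magnitude; a weighted flag
  recovers weight sums. The weighted in-variant reduces a contiguous
  transpose so the in/out reversal duality holds bit-exactly.
* **Total GC outdegree**: row sums — the baseline this package's
  alternatives are measured against.

All metrics are wrapped in rankings 1..N with midranks for ties (rank sum
exactly N(N+1)/2, invariant to node order); undefined metric values rank
after all defined ones. `top_k` breaks boundary ties lexicographically.

## Rank-order-sum evaluation

For target set Z (|Z| = k) the observed statistic is the sum of Z's
midranks. The null draws k ranks from {1..N} **without replacement** by
default — node ranks are distinct, so this is the faithful chance model
(the Wilcoxon rank-sum null: mean k(N+1)/2, variance k(N−k)(N+1)/12); a
with-replacement flag covers the looser independent-draws reading. Default
10⁵ repetitions. The p-value is one-sided lower-tail (small sum = clinical
zone ranked early). Three methods: `mc_normal` (normal fitted to the
simulated null; the default), `mc_empirical` (add-one empirical tail,
recommended at small N where the lattice and skew make the normal fit
crude), `closed_form` (exact moments, no simulation). α defaults to 0.05
and is configurable.

**Per-patient combination.** Sixty segment maps yield sixty rankings; the
default policy runs the algorithm per segment and averages the per-node
metric values across segments before ranking ("metrics"), preserving each
segment's F-test sparsity. Averaging the weight matrices first and ranking
once ("map") is provided as an alternative; for linear metrics such as
total GC outdegree the two coincide, for walkers and path-based
centralities they need not. Which combination produced published per-patient
numbers is generally unstated, hence both.

Cohort runs replicate stochastic algorithms (the walkers) 5 times with
distinct derived seeds and report the mean and standard error of the
significant-patient count; deterministic algorithms run once (SE exactly 0).
Seeds everywhere derive from a global seed plus a stage tag via SHA-256, so
adding a patient never perturbs another patient's stream.

## Synthetic data

`gen_patient` emulates the *output* of the GC-map stage, post F-test: sparse
nonnegative matrices in which a planted hub subset (the ground-truth SOZ)
emits edges with probability `edge_density × hub_out_multiplier` versus
`edge_density` for background nodes, with exponential edge weights whose
mean scales the same way. Defaults: 100 nodes, 20 hubs, 60 segments, edge
density 0.1, multiplier 3 — node counts and set sizes sized to a realistic
ECoG grid cohort (≈103 electrodes, ≈20-node SOZ, ≈22-node RZ on average).
The RZ is the hub set with 2 hubs dropped and 4 background nodes added,
emulating the clinical reality that resections neither cover nor confine
themselves to the SOZ. The exponential weight choice is a modelling
convenience (nonnegative, right-skewed), not an empirical claim.

`gen_var_segment` simulates a stable VAR process: self-decay 0.5 on each
channel's first lag, planted directed couplings (default 0.5) on chosen
(source, target) pairs, unit-variance Gaussian innovations, 200-sample
burn-in; coefficients are shrunk deterministically if the companion
spectral radius reaches 0.98.

What these benchmarks show — and don't: they establish that each algorithm
recovers planted high-outdegree structure at realistic sizes and that the
statistic is calibrated (type-I error ≈ α when hubs are exchangeable). They
do not reproduce real iEEG physiology: no volume conduction, no common
drivers, no nonstationarity, no electrode geometry, and hub structure that
is i.i.d. across segments rather than waxing and waning. Passing them is
necessary, not sufficient, for clinical validity.

## Problem sizes in the checked benchmarks

The test suite exercises walker correctness at 300 restarts × 200 steps
across 10 independent runs per graph (exact finite-horizon chain
expectations as oracle, 3 Monte-Carlo-SE bands), centralities on 100 random
digraphs of ≤7 nodes against exhaustive path enumeration, Granger recovery
on 50 seeded 5-channel VAR runs of 4000 samples plus 200 null pairs, and
end-to-end recovery on 50 synthetic patients per effect-size level at the
full default patient size (100 nodes × 60 segments, 10⁵-repetition nulls).

## Known limitations

* Pairwise GC inherits all caveats of bivariate causality measures.
* The F-test pruning level interacts with walk behaviour (more pruning →
  more dangling nodes → shorter chains); no adaptive choice is attempted.
* The normal fit to the null is poor in the extreme tails; use
  `mc_empirical` when p-values near machine-small magnitudes matter, or at
  small N.
* Selecting a surgical zone from a ranking (top-k or otherwise) is
  deliberately out of scope beyond the trivial `top_k` helper.
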