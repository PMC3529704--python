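# Methods

## Model

A gene network over `n` genes is a set of lag-annotated arcs
`(regulator, target, lag)` with lags in `0..d_max`.  Lag-0 arcs model
regulation whose effect appears within one sampling interval; an arc of
order δ ≥ 1 models an effect appearing δ intervals later.  Three
consistency conditions define the search space: the lag-0 subgraph is
acyclic; delayed arcs point forward in time (guaranteed by construction
— a delayed arc always reads the parent at an earlier slice); and the
parameterization is stationary (one conditional distribution per child,
reused at every time step).  Acyclicity is therefore enforced on the
lag-0 subgraph only: unrolling any such network over time yields a DAG,
and mutually regulating pairs remain representable with at least one
delayed direction.  A given ordered pair may carry several arcs at
different lags; duplicate `(pair, lag)` triples are forbidden.  Lagged
self-arcs are representable but disabled by default, since regulatory
self-delays are rarely modelled and they enlarge the search space.

The data model is one or more discrete series (genes × time, integer
levels below each gene's arity).  Continuous input is discretized per
gene into a fixed number of levels (default 3) by equal-frequency
binning — boundaries at empirical quantiles `k/levels`, ties assigned
to the lower level — or equal-width binning.  Equal-frequency is the
default because mutual-information estimates are most stable when the
marginal level counts are balanced; any external discretizer can be
substituted upstream, since scoring only consumes integer levels.  A
constant gene cannot be binned meaningfully: it maps to level 0 with a
warning, and its declared arity is kept, so degrees of freedom
overcount there (also logged).

## Sample alignment and effective counts

Scoring a child against parents of mixed lags requires lag-aligned
sample rows.  For an aperiodic series of length `N` with maximum parent
lag δ, child times `t = δ .. N−1` are usable and each parent is read at
`t − lag`, leaving `N − δ` rows.  Periodic series (e.g. cell-cycle
compendia) wrap circularly and keep all `N` rows.  δ is the maximum lag
of the *current* parent set, not the global `d_max`, so small parent
sets keep more samples.  Multiple series are aligned independently and
their rows pooled; a lag never crosses a series boundary (replicates
are not one long recording).  Periodicity is a dataset-level flag
supplied by the user; the default is aperiodic.

## Score

Local score of a child with non-empty parent set:
`2·N_eff·MI(child, parents) − penalty`, summed over children.  MI is
the plug-in estimator in natural log, so `2N·MI` is the
likelihood-ratio G-statistic (the suite cross-checks this against an
independent implementation); zero cells contribute zero, and no
pseudocounts are added by default because the χ² threshold calibrates
the raw statistic (optional Laplace smoothing exists for exploratory
use).  The joint MI conditions parents of all lags *together*: the
contingency table is child level versus the joint parent configuration
over the union of lags.  This is what separates the combined score from
baselines that score the instantaneous and delayed halves independently
(`mit0` + `mit1`); the two coincide exactly if and only if no child
mixes regulation orders, and the suite verifies both the difference and
the collapse.

Penalties subtract χ² critical values at confidence level α (default
0.9) with degrees of freedom
`l_1 = (r_i−1)(r_1−1)`, `l_j = (r_i−1)(r_j−1)·Π_{m<j} r_m` for the
chained tests of one parent class, arities ordered descending.  In
per-order mode (default) each lag class is penalized as if it were the
sole parent set; in joint mode the whole parent set forms one class,
which reproduces the classical MIT penalization (for 3-level data and
three parents: 4 + 12 + 36 df versus per-order 4 + 4 + 12 when the
parents split two-and-one across lags).  The penalty is defined as the
maximum of the chained sum over parent orderings.  A property test
found that the descending-arity ordering does **not** attain that
maximum for every (arity, α) combination — a counterexample exists at
child arity 4, parents [3,2,2], α ≈ 0.51 — so the implementation
maximizes explicitly over orderings (cached; trivial at fan-in ≤ 4).
At the default α = 0.9 the maximizer is the descending ordering.

Numerical conventions: χ² quantiles are cached per (α, df); score
comparisons use an absolute tolerance of 1e−12 .. 1e−9; the score of an
empty parent set is exactly 0; arity used for df is the declared level
count, not the observed distinct-value count.

## Search

Best-improvement hill climbing from the empty graph with single-arc
addition, deletion and reversal (reversal keeps the lag).  The score
decomposes per child, so a move rescores only the one or two children
it touches; local scores are memoized by (child, parent set) across
iterations.  Ties between equal-gain moves prefer deletion over
reversal over addition, then lower lag, then lexicographic
(regulator, target) — a deterministic bias toward sparser, lower-order
models.  The fan-in cap defaults to 4 parents per child across lags:
df grows exponentially in the parent count, and regulatory networks
are sparse.  Optional random restarts rerun the climb from random
graphs whose density spans the reachable space (up to
`n · max_fan_in` arcs) and keep the best result; runs are fully
deterministic given the seed.  An exhaustive enumerator (guarded to
n ≤ 4, d_max ≤ 1) scores every parent-set assignment per child and
combines them under lag-0 acyclicity; it is the optimality oracle in
tests, with ties resolved to the lexicographically smallest arc set.

## Simulator

The simulator is the package's self-contained data source.  Random
networks draw ordered pairs uniformly and lags uniformly from an
allowed set, rejecting draws that violate lag-0 acyclicity or an
in-degree cap.  Conditional distributions come from three families:
binomial-noisy single-parent regulation (excitation
P(on|on) = 0.9, P(on|off) = 0.1; inhibition swapped), noisy-XOR
two-parent co-regulation (P(on) = 0.9 iff exactly one parent on, 0.1
otherwise), and Dirichlet rows with equivalent sample size 10 around a
normalized harmonic basis vector `(1, 1/2, …, 1/k)/H_k` cyclically
right-shifted by `(j mod k)` positions for the j-th parent
configuration — the shift keeps connected variables visibly dependent.
Forward sampling fills the first `d_max` slices with uniform draws (no
burn-in by default; a discard option exists) and then samples each
slice in lag-0 topological order, reading lag-k parents k slices back
and lag-0 parents in the current, already-sampled slice.

Two presets reproduce the studied regimes at generation time rather
than from stored data: a 20-node binary benchmark (12 regulated genes,
11 interactions at random orders 0–3 with in-degree ≤ 2, binomial/XOR
conditionals, plus 8 arc-free confounder genes as false-positive
controls) and a 35-node, 52-arc three-level benchmark with orders 1–2
and Dirichlet conditionals.  Topologies are drawn randomly with the
stated sizes; per-dataset lag assignments are redrawn per seed.  The
simulator emulates discrete multinomial dynamics only: no measurement
noise on continuous values, no ODE dynamics, no missing values or
uneven sampling — so passing tests demonstrate correctness of the
discrete machinery, not robustness to microarray noise.

## Evaluation

Order-agnostic confusion counts collapse both networks to ordered gene
pairs (any lag counts as an edge) over the universe of `n(n−1)`
non-self directed pairs — the only universe that makes specificity
well-defined; order-aware counts require the exact (pair, lag) slot
over `n(n−1)(d_max+1)` slots.  Self-pairs are excluded unless lagged
self-arcs are in play.  Se, Sp, Pr and F follow the standard formulas,
with 0/0 reported as NaN plus a warning.  The scale-freeness
diagnostic fits log10 frequency against log10 total degree by ordinary
least squares over raw frequency bins (a CCDF variant is not provided)
and reports R²; it requires at least three distinct positive degrees.

## Known limitations

* **Liberal thresholds produce dense networks.**  At the conventional
  α = 0.9, each embedded CI test runs at a 10% type-I level, and a
  best-improvement search over hundreds of candidate moves will keep
  finding "significant" spurious arcs until children saturate the
  fan-in cap.  On the 20-node benchmark at N = 100 the learned
  networks carry far more arcs than the 11 true ones (specificity
  ≈ 0.8).  This is a property of the score-plus-search combination
  itself, measured here with an exactly calibrated statistic (the
  suite verifies the 10% null rejection rate empirically); users who
  need high precision should raise α substantially (0.999+) or lower
  the fan-in cap.
* **Greedy search cannot discover parity-style co-regulation.**  The
  individual parents of a noisy-XOR child carry no marginal signal, so
  no single-arc move has positive gain and the first step is never
  taken; only enumeration (or a lucky restart) finds such pairs.
* **Global optima can require coordinated moves.**  Because of the
  density effect above, the score's global optimum often contains
  multi-parent blocks that single-arc climbs from the empty graph
  cannot assemble; random restarts with density-spanning start graphs
  recover the enumerated optimum reliably at tiny scale.
* Discretization here is unsupervised (equal-frequency/width); whether
  a persistence-based discretizer would change inferred networks is
  untested.
* The exhaustive oracle is exponential and guarded to toy sizes; the
  evaluation module produces no ranking scores, so AUROC/AUPR curves
  are out of scope.
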