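# Methods

## Cascade dynamics

The engine implements the fixed-threshold linear threshold model as integer
bookkeeping: node *i* holds a residual resistance r_i (initially the minimal
integer satisfying the "fraction of active neighbors ≥ φ_i" rule, i.e.
⌈φ_i k_i⌉), every activation decrements the residuals of its inactive
neighbors by one, and a node activates when its residual reaches zero.
Propagation is level-synchronous (frontier BFS). Because activation is
monotone and irreversible, the fixed point is independent of both the order
in which seeds are added and the order in which the frontier is processed;
the level structure is retained because it provides the natural
sphere-of-influence truncation used by the CI-TM-style scorer and by
optional truncated greedy evaluation. The engine exposes incremental seeding
(`CascadeState.add_seeds`) whose end state is identical to re-running the
full cascade with the enlarged seed set.

Undirected edges are stored internally as two directed influence channels,
so in- and out-degree coincide (k_i^in = k_i^out = k_i) throughout; a
directed-graph extension would only change the adjacency construction.

Two documented edge cases:

- **φ = 0 on a connected node** gives r = 0; such nodes activate in the
  first evaluation of any cascade state, even with no active neighbor.
  Continuous threshold distributions produce them with probability zero, but
  user-supplied threshold files can contain them.
- **Isolated nodes (k = 0)** receive an `UNREACHABLE` resistance sentinel:
  they can only become active as seeds, are excluded from total-resistance
  sums, and score below every reachable node in all selection heuristics
  (seeding one gains exactly one node).

## Threshold family

Thresholds are drawn from a normal distribution truncated to [0, 1] with
underlying mean fixed at the target mean (0.5 throughout the bundled
experiments). The family is parameterized by the standard deviation σ of
the *truncated* distribution rather than the underlying scale τ, which makes
σ = 1/√12 ≈ 0.288675 exactly the uniform limit (τ → ∞) and σ = 0 the
degenerate all-at-mean limit. The τ matching a requested σ is solved with
Brent's method on the truncated-normal sd (accuracy 1e-6); requests within
1e-6 of the uniform limit (or up to 1e-3 above it, absorbing printed
roundings such as 0.2887) return the uniform sentinel. Sampling is by
inverse CDF — exactly one uniform draw per node — so the draw count per seed
is deterministic and threshold vectors are reproducible regardless of σ.

Resistances use ⌈φk − 10⁻⁹⌉: the subtraction absorbs float noise so that an
exactly integral product φk maps to that integer (the "≥" rule), e.g.
φ = 0.5, k = 10 gives r = 5, never 6.

## Graph ensemble and assortativity control

ER graphs are sampled from G(N, p_ER) with p_ER = ⟨k⟩/(N − 1) via networkx's
exact G(n, p) sampler. Degree assortativity is measured as the Spearman rank
correlation of endpoint degrees over the directed edge multiset (both
orientations of each edge, making the measure orientation-symmetric); it is
defined as 0 for zero-variance degree sequences so regular graphs cannot
crash ensemble runs. Disconnected components are kept: their probability in
the reference ensemble is quantified (the isolated-node probability
(1 − p_ER)^(N−1) ≈ 4.5 × 10⁻⁵ for N = 10⁴, ⟨k⟩ = 10), not pruned away.

Rewiring toward a target ρ uses degree-preserving double-edge swaps with
greedy acceptance: a proposal picks two random edges, considers both
reconnection patterns, and applies the one that moves ρ furthest toward the
target iff it strictly improves and keeps the graph simple. Because swaps
preserve every degree, each node's rank within the endpoint-degree multiset
is invariant, so ρ can be updated exactly in O(1) per proposal (only the
rank cross-product term changes); the loop aims slightly inside the
requested tolerance and the final value is re-measured exactly. The
tolerance contract is best-effort: an unreachable target returns the best
graph found plus diagnostics (achieved ρ, swap and proposal counts,
converged flag) rather than raising. Greedy acceptance without an annealing
schedule reaches |ρ| = 0.9 within tolerance 0.02 on ER (N = 2000, ⟨k⟩ = 10)
in well under a second; a schedule was therefore judged unnecessary.

## Selection strategies

All heuristic scores are evaluated on the dynamic inactive subgraph. After
each seeding event only inactive nodes within 2 hops of a newly activated
node are rescored (L + 1 hops for the CI-TM-style scorer), which is exact
because every score formula depends only on quantities within that radius;
the full-rescan path is retained and the test suite asserts trajectory-level
agreement. Ties are broken uniformly at random with the run's seeded RNG —
deterministic index order would bias ensemble statistics.

Conventions that the underlying formulas leave open:

- **thres** divides the dynamic resistance by the *original* degree, keeping
  the score in [0, 1] and equal to φ_i before any spread.
- **CI-TM scorer**: implemented as a subcritical-chain BFS — from node *i*,
  follow inactive neighbors with residual exactly 1 up to depth L, summing
  (k^out − 1) with visited-marking so loops are not double-counted (the
  original derivation is tree-like; the marking is this package's
  interpretation). At L = 1 the score is identically id − r, which is the
  enforced compatibility contract; the default comparator depth is L = 6.
- **Greedy** evaluates the exact marginal cascade of every inactive
  candidate by default (feasible at the desk scales used here); L-truncated
  evaluation is opt-in.

The indirect-drop score ID is a lower bound on the realized total-resistance
drop only when the subcritical shells around the seed are disjoint (tree-like
neighborhoods): adjacent subcritical neighbors or shared second neighbors
are double-counted and ID can then exceed the measured drop. The direct-drop
bound DD ≤ drop holds on any graph. The test suite asserts the ID bound on
random trees and the DD bound on arbitrary dense instances.

## Group Performance Index

Each outer step runs v independent trials against disposable copies of the
current state: a trial draws uniformly random inactive nodes one at a time,
cascading after each, until the trial spread covers the *remaining* goal
(S_goal·N minus what is already active). GPI_i is the mean size of the trial
teams containing *i*; smaller is better. The batch Q of ⌈sN⌉ best-ranked
nodes is then seeded one by one; batch members activated by an earlier seed
of the same batch are excluded from the initiator set (not replaced), and
seeding stops as soon as the goal is met, so the reported |Y|/N is the
trajectory's goal-crossing point — the same reading used for every other
strategy's p_c.

Nodes never drawn in any trial are ranked worst rather than treated as
errors: they are exactly the nodes most easily activated by diffusion, which
should not be spent as seeds. Per-trial RNG streams are derived from
(master seed, outer step, trial index), so increasing v extends the trial
set without reshuffling earlier trials — v-sweeps are paired by
construction. Defaults are s = 10⁻³, v = 10⁵, S_goal = 0.5 (the reference
study conditions); the bundled desk-scale analyses use s = 0.01, v = 2000 on
N = 500 so that a 20-pair comparison completes in seconds. Trials compute
the full spread by default; sphere-of-influence truncation is opt-in.

## Experiment harness

Ensembles follow a common-random-numbers discipline: every strategy compared
within a realization sees the same graph, the same thresholds and the same
run seed, and realization seeds are spawned deterministically from the base
seed. Trajectories record the cumulative spread after every single seed, so
S_eq(p) is exact at every p = m/N with no interpolation; p_c is read off as
the first crossing of ⌈S_goal·N⌉. Both fresh-graph ensembles (new graph and
thresholds per realization) and fixed-graph ensembles (one graph, new
thresholds per realization — the protocol behind winner-probability tables)
are explicit modes. Aggregates report mean ± sd/√n over realizations and are
always recomputable from the stored per-realization rows; failed
realizations are logged and excluded with a count rather than aborting.

The reference conditions are N = 10⁴, ⟨k⟩ = 10, mean threshold 0.5 and
500 realizations (20 for GPI). The bundled analyses and the acceptance
script run scaled-down variants — N = 1000 with 20–50 realizations, N = 500
for GPI pairings — chosen as the package's own desk-scale defaults; the full
scale remains available by overriding `ExperimentConfig` fields.

## What the synthetic ensembles do and do not show

The generators reproduce the study conditions faithfully: Bernoulli ER
ensembles (including their isolated-node mass), exact-σ truncated-normal
thresholds, and degree-preserved assortativity rewiring. They do not emulate
degree heterogeneity beyond ER (no scale-free tails), clustering,
communities, or threshold–degree correlations, so passing ensemble tests
demonstrates correctness of the algorithms and the qualitative strategy
ordering (id ≤ deg/res on average; BI with a > 0 beating resistance-blind
weightings; GPI beating local heuristics head-to-head), not performance
claims on empirical networks.

## Numerical choices and limitations

- All inner loops (propagation, scoring, GPI trials) are numba kernels on
  CSR adjacency; results are integer-exact, and float scores only arise for
  BI/thres where exact corner identities are preserved by construction
  (weights that are dyadic rationals compare bit-exactly; thirds agree to
  1e-12 relative tolerance in tests).
- Seeds everywhere are integers below 2³¹; every public entry point takes an
  explicit seed and is bit-reproducible for a fixed seed.
- The weight scan returns the first grid argmin under numpy's deterministic
  scan order; at desk scale neighboring grid points are often within one
  standard error, so the argmin's b-vs-a ordering can fluctuate between
  seeds even when a > 0 and c ≤ b are stable.
- Greedy is O(N²⟨k⟩) per seed and intended for small instances or truncated
  evaluation; GPI cost scales as v/s and dominates wall time at full
  reference settings.
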