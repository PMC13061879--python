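# Methods

## The crowding ensemble

Each target node's in-neighbourhood is built independently: the `N - 1`
candidate sources are scanned in some order and, with `r` edges already
accepted, the next candidate is accepted with probability `exp(-alpha r)`.
The exponential form is the unique rule in which every accepted synapse
lowers the log-acceptance probability by the same decrement.  The first
proposal is always accepted, so the minimum in-degree is 1; `alpha = 0`
gives the complete digraph.

The accepted-count distribution after `m` proposals obeys the two-term
recursion `P_{m+1}(r) = P_m(r)(1 - e^{-alpha r}) + P_m(r-1) e^{-alpha(r-1)}`
from `P_0(0) = 1`; the in-degree law is its state after `N - 1` steps.  The
implementation (`degree.indegree_pmf`) iterates this in plain probabilities
(bulk masses are O(1); tail underflow is irrelevant downstream) over a
moving support window.  For `N <= 10^4` the window only sheds exact zeros;
for larger `N`, leading entries with mass below `1e-15` are trimmed and
upward flow below `1e-18` is not propagated, with all dropped mass recorded
(`truncated_mass`, about `1e-13` at `N = 10^6`) and the final vector
renormalised.  `alpha = 0` is returned as the exact point mass at `N - 1`
without iterating.  The inner loop is numba-compiled with a pure-Python
fallback.

Moments are taken from the final pmf; the generating-function recursion
`G_{m+1}(z) = G_m(z) + (z-1) G_m(e^{-alpha} z)` is kept as an independent
route (`degree.generating_function`).  Its z-lattice evaluation loses
relative accuracy to cancellation for small `z` beyond a few dozen steps in
float64 (verified against a 40-digit reference), so the acceptance profile
`p_m = G_{m-1}(e^{-alpha})` is computed from the recursion states as
`sum_r P_{m-1}(r) e^{-alpha r}`, which is exact; the two routes are
cross-checked at small rank in the tests.

A second, structurally independent sampler
(`degree.sample_indegree_inverse_process`) draws the in-degree as the
largest `r` whose cumulative geometric waiting times (success probability
`e^{-alpha r}`, counting proposals up to and including the success) fit in
the budget of `N - 1` proposals, with the in-progress stage not counted.
Stages whose success probability falls below `1e-9 / budget` are cut off —
their contribution is below the resolution of any feasible sample size.

### Scaling behaviour and its fine structure

The mean grows like `ln(N)/alpha` and the acceptance tail like
`1/(alpha m)`; both are verified numerically (the rescaled ratios are
1.019 at `N = 10^6` and 0.99994 at `m = 10^4` for `alpha = 1`).  Two
fine-structure effects of strong crowding are worth knowing:

- `alpha * m * p_m` does not converge monotonically: the geometric waiting
  times impose a log-periodic modulation whose amplitude grows with
  `alpha` (about 5% at `alpha = 2`).
- `Var(k)` is bounded and is often near `1/(2 alpha)` in the sparse regime
  (`2 alpha Var = 1.04` at `alpha = 0.5`, `N = 10^4`), but at strong
  crowding it cycles with `ln N` instead of settling (0.18-0.28 at
  `alpha = 2.66` between `N = 10^4` and `4x10^4`).  Boundedness, not
  convergence, is the law; no exact saturation constant is claimed.

`solve_alpha_for_mean` inverts the strictly decreasing map
`alpha -> mean(alpha, N)` by bisection on `[1e-8, 50]` (up to 200
iterations, stopping when the mean matches within `1e-3`) — a bracket that
covers all practically distinguishable densities.

## Graph generation

`generate.generate_crowding` performs the literal per-candidate Bernoulli
scan (numba-compiled), so the generator and the degree theory are coupled
only through the model, not through shared code paths.  Orderings:

- **uniform** — a fresh random permutation per target;
- **distance** — nearest-first under a ring or periodic square-lattice
  (torus, Euclidean wrapped metric) embedding, with candidates at equal
  distance randomly permuted within each shell.  Torus shells are defined
  by exact integer squared distances, so no shell ever splits by floating
  error;
- **soft** — nearest-first, except each proposal is drawn uniformly from
  the not-yet-proposed candidates with probability `epsilon` (default
  choice in examples: 0.1, a weak perturbation that preserves the
  heavy-tailed length profile; no canonical value exists).

Because acceptance depends only on the running count, all orderings share
the exact in-degree law — tested by two-sample chi-square across ensembles.

Shortcut rewiring selects each edge independently with probability `rho`
(all Bernoulli draws made up front), then processes selected edges in
canonical (target, source) order, replacing the source by a uniform draw
from nodes that are neither the target nor a *current* in-neighbour — the
original source included, so a target fed by all other nodes has no valid
replacement and its edges are left unchanged and counted
(`metadata["rewire_skipped"]`).  In-degrees are preserved exactly.

The ER+ baseline draws each target's in-degree from the zero-truncated
`Binomial(N-1, p)` (p tuned so the conditional mean matches) and then a
uniform source subset — the exact conditional law of a binomial row
resampled until nonempty.  The regular baseline gives every target exactly
`k` uniformly chosen distinct sources.

Randomness: every generator accepts either a seed or a `numpy` Generator.
Ensemble drivers (`basin_curve`) spawn one child `SeedSequence` per trial
from the root seed, so results are reproducible and independent of how
trials are batched.  Within a graph, one Generator serves all targets in
fixed index order; per-node named substreams were considered and rejected
because Generator construction would dominate ensemble-scale generation.

## Inference

The log-likelihood `L(alpha) = sum_k n_k log P_alpha(k)` uses the exact
recursion at the model size `N` (defaulting to the histogram total — one
degree per node for in-model data); observed degrees outside `[1, N-1]`
are rejected as outside the support.  The MLE is located on a 40-point
log-spaced grid over `[0.01, 10]` and refined by bounded scalar
minimisation to `1e-4`; pmfs are memoised per `(alpha, N)`.  The
confidence interval is `alpha_hat +/- z_{1-gamma/2} / sqrt(I)` with
`I = -L''` by central differences at step `h = 1e-3 * max(alpha_hat, 1)`,
balancing truncation against cancellation for likelihoods of this
smoothness.  A maximum pinned at the grid boundary is flagged and reported
without an interval.  Single-graph fits at `N = 500` cover the generating
`alpha` in ~92-97 of 100 repeats at nominal 95%.

## Mean-field map and committor

`hmf_k` is the binomial upper tail with lower limit `ceil((k + theta)/2)`
clamped to `[0, k+1]` (real `theta` allowed; the ceiling encodes the
`sign(0) = +1` tie convention), evaluated via `scipy.stats.binom.sf` for
stability at large `k`.  `fixed_points` scans a 2001-point grid for sign
changes of `F(x) - x`, refines by bisection to `1e-10`, classifies
stability by the numerical slope (central difference, step `1e-6`;
magnitude within `1e-8` of 1 is "marginal"), and flags the identity-map
degeneracy (all mass at `k = 1`, `theta = 0`, detected by
`max|F(x) - x| < 1e-12`) instead of enumerating a continuum.

The committor system is solved densely for `N <= 1000` (binomial rows are
full); row entries below `1e-16` are zeroed with row renormalisation, a
conditioning aid that leaves the solution unchanged beyond `~1e-12`.
Larger `N` routes to Monte Carlo simulation of the binomial chain
(default trajectory cap `10^5` steps; censoring is reported per start and
warned about above 1%, never silently dropped).  The `k = 1`, `theta = 0`
martingale limit (`u_a = a/N`, by optional stopping) and linear-vs-MC
agreement serve as internal oracles.

## Threshold dynamics

Synchronous updates are exact sparse matrix-vector products with the
configured tie rule (`plus` is the default `sign(0) = +1`; `minus` and
`random` support robustness checks, as do `theta = 1` and asynchronous
random-sequential sweeps of `N` single-node updates).  Initial states set
a uniformly random subset of exactly `a` nodes to +1.  Synchronous
trajectories are classified exactly by a visited-state registry (packed
state bytes; capacity `10^5` states, falling back to censoring beyond it):
uniform states are the absorbing outcomes, any revisit is a cycle, and a
non-uniform fixed point is recorded as a period-1 cycle so "absorbed" is
reserved for the two uniform macrostates the closure models.  Basin curves
report, per initial count, the fraction absorbed all-active and the
fraction in neither uniform state within `t_max` sweeps (default 200).

## Structural diagnostics

Wiring-length fits use logarithmic bins (ratio 1.25) over `d` in
`[2, N/10]` (ring) or `[2, side/3]` (torus) — excluding the boundary shell
and the wraparound-compressed tail; on the ring, bin edges snap to
integers so each bin spans a whole number of attainable distances
(sub-integer bins bias the density).  Densities are per unit distance;
fits with fewer than 50 pooled edges or 3 occupied bins are refused.  The
per-distance connection probability table divides pooled edge counts by
exact shell pair counts (which sum to `N(N-1)`).  Small-world summaries
use the symmetrized simple graph: mean local clustering with degree-<2
nodes contributing 0, and mean shortest path over connected unordered
pairs (connected fraction reported), both normalised by the mean over a
fully rewired (`rho = 1`) ensemble.  At `side = 32` the torus *marginal*
length exponent fits near 1.18 rather than 1: the exact acceptance profile
predicts 1.18 for this size and fit range, so the deviation is a
finite-size transient of the model, not an estimator artifact.

## What the synthetic conditions do and do not show

All experiments are in-model: graphs are drawn from the generator being
analysed, at the reference conditions used throughout (`alpha = 0.77` and
`2.66`, `N = 100`-`500` for dynamics, `N` up to `10^6` for degree theory,
500 graphs per ensemble comparison, 400-500 trials per basin point —
sizes at which every ensemble statistic has sampling error well below the
tolerances asserted).  Passing tests therefore validate the mathematics
and the implementation, not the biological fidelity of the wiring rule:
real connectomes have weighted, signed synapses, heterogeneous thresholds,
spatial anisotropy, and degree-dependent mechanisms beyond a single
crowding penalty.  The inference module in particular assumes the data
were produced by the crowding family at the stated `N`.

## Known limitations

- `P(1)` underflows float64 for weak crowding at large `N`
  (`(1 - e^{-alpha})^{N-2}` below `~1e-308`), so the support-starts-at-1
  property is only numerically visible where it is representable.
- The dense committor solve is capped at `N = 1000`; beyond that only the
  Monte Carlo route is available.
- Asynchronous dynamics has no cycle detection (states revisit without
  period there being meaningful); unabsorbed asynchronous runs are
  censored.
- The generating-function lattice route should not be used to extract
  small probabilities at large `m`; use the recursion pmf.
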