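"""Exact in-degree statistics of the crowding wiring rule.

For each target node the generator scans the ``N - 1`` candidate sources in
some order; with ``r`` incoming edges already accepted, the next candidate is
accepted with probability ``exp(-alpha * r)``.  Because acceptance depends
only on the running count ``r``, the number of accepted edges after ``m``
proposals obeys the two-term recursion

    P_{m+1}(r) = P_m(r) (1 - e^{-alpha r}) + P_m(r-1) e^{-alpha (r-1)},

starting from ``P_0(0) = 1``.  The terminal state ``P_{N-1}(k)`` is the exact
finite-``N`` in-degree distribution: every node has in-degree at least one
(the first proposal is always accepted), the mean grows like
``log(N) / alpha`` and the variance stays bounded as ``N`` grows.

The probability generating function ``G_m(z) = sum_r P_m(r) z^r`` satisfies
the compact recursion ``G_{m+1}(z) = G_m(z) + (z - 1) G_m(e^{-alpha} z)``
with ``G_0(z) = 1``.  The probability that the ``m``-th proposal (in scan
order) is accepted is ``p_m = G_{m-1}(e^{-alpha})``, which decays like
``1 / (alpha m)`` — the heavy-tailed acceptance profile responsible for the
emergent ``1/d`` wiring-length law when candidates are scanned nearest-first.

An independent waiting-time ("inverse process") sampler is provided as a
cross-check: the number of proposals consumed between the ``r``-th and the
``(r+1)``-th acceptance is geometric with success probability
``exp(-alpha r)``, so the final in-degree is the largest ``r`` whose
cumulative proposal count fits inside the budget of ``N - 1`` proposals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None

__all__ = [
    "CrowdingParams",
    "InDegreePmf",
    "MomentSummary",
    "AcceptanceProfile",
    "indegree_pmf",
    "generating_function",
    "acceptance_profile",
    "moments",
    "solve_alpha_for_mean",
    "sample_indegree_inverse_process",
]

#: keep the full recursion support up to this many proposals; beyond it,
#: negligible-mass window truncation kicks in (see _run_recursion).
EXACT_SUPPORT_LIMIT = 10_000

_TRUNC_TOL = 1e-15  # leading-entry mass below which the window front is trimmed
_EXT_TOL = 1e-18  # upward mass flow below which the window top is not extended


@dataclass(frozen=True)
class CrowdingParams:
    """Parameters of the crowding ensemble.

    alpha : per-accepted-edge log-acceptance penalty (>= 0).  ``alpha = 0``
        accepts every proposal (complete digraph); large ``alpha`` pins the
        typical in-degree at O(1).
    n_nodes : number of nodes N (>= 2); each target sees N - 1 candidates.
    """

    alpha: float
    n_nodes: int

    def __post_init__(self) -> None:
        if not (self.alpha >= 0.0) or not math.isfinite(self.alpha):
            raise ValueError(f"alpha must be a finite nonnegative real, got {self.alpha}")
        if int(self.n_nodes) != self.n_nodes or self.n_nodes < 2:
            raise ValueError(f"n_nodes must be an integer >= 2, got {self.n_nodes}")
        object.__setattr__(self, "n_nodes", int(self.n_nodes))


@dataclass(frozen=True)
class InDegreePmf:
    """Exact finite-N in-degree distribution P_alpha(k), k = 0 .. N-1.

    ``probs[0]`` is exactly zero (the first proposal is always accepted) and
    ``truncated_mass`` records the total probability dropped by window
    truncation before the final renormalisation (zero for exact runs).
    """

    probs: np.ndarray
    params: CrowdingParams
    truncated_mass: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.shape != (self.params.n_nodes,):
            raise ValueError("probs must have one entry per possible in-degree 0..N-1")


@dataclass(frozen=True)
class MomentSummary:
    mean: float
    variance: float
    m_steps: int


@dataclass(frozen=True)
class AcceptanceProfile:
    """Per-rank acceptance probabilities p_m = G_{m-1}(e^{-alpha}).

    ``p[0]`` corresponds to proposal rank m = 1 (always accepted).
    """

    p: np.ndarray
    params: CrowdingParams = field(repr=False, default=None)

    def at_rank(self, m: int) -> float:
        """Acceptance probability of the m-th proposal, m = 1 .. M."""
        if not 1 <= m <= self.p.size:
            raise IndexError(f"rank {m} outside profile of length {self.p.size}")
        return float(self.p[m - 1])


def _recursion_core_py(wexp, m_steps, trunc_tol, ext_tol, profile):
    """Iterate the count recursion over m_steps proposals.

    ``wexp[r] = exp(-alpha r)``.  The live window of the distribution is
    buf[lo..hi]; mass below trunc_tol is trimmed at the front and upward flow
    below ext_tol is dropped at the top (both accounted in ``dropped``).
    When ``profile`` is nonempty, profile[step] receives the acceptance
    probability of proposal step+1, i.e. sum_r P_step(r) wexp[r].
    """
    buf = np.zeros(m_steps + 2)
    buf[0] = 1.0
    lo = 0
    hi = 0
    dropped = 0.0
    record = profile.shape[0] > 0
    for step in range(m_steps):
        if record:
            s = 0.0
            for r in range(lo, hi + 1):
                s += buf[r] * wexp[r]
            profile[step] = s
        flow_top = buf[hi] * wexp[hi]
        if flow_top > 0.0 and flow_top >= ext_tol:
            buf[hi + 1] = flow_top
            new_hi = hi + 1
        else:
            dropped += flow_top
            new_hi = hi
        for r in range(hi, lo, -1):
            buf[r] = buf[r] * (1.0 - wexp[r]) + buf[r - 1] * wexp[r - 1]
        buf[lo] = buf[lo] * (1.0 - wexp[lo])
        hi = new_hi
        while hi > lo and buf[lo] < trunc_tol:
            dropped += buf[lo]
            buf[lo] = 0.0
            lo += 1
    return buf, lo, hi, dropped


if njit is not None:
    _recursion_core = njit(cache=False)(_recursion_core_py)
else:  # pragma: no cover
    _recursion_core = _recursion_core_py


def _run_recursion(alpha: float, m_steps: int, want_profile: bool = False):
    wexp = np.exp(-alpha * np.arange(m_steps + 2, dtype=float))
    exact = m_steps <= EXACT_SUPPORT_LIMIT
    trunc_tol = 0.0 if exact else _TRUNC_TOL
    ext_tol = 0.0 if exact else _EXT_TOL
    profile = np.empty(m_steps if want_profile else 0)
    buf, lo, hi, dropped = _recursion_core(wexp, m_steps, trunc_tol, ext_tol, profile)
    return buf, lo, hi, dropped, profile


def indegree_pmf(params: CrowdingParams) -> InDegreePmf:
    """Exact in-degree distribution P_alpha(k) = P_{N-1}(k).

    Runs the two-term count recursion over the N - 1 proposals.  For
    ``alpha = 0`` every proposal is accepted and the distribution is a point
    mass at N - 1 (handled exactly without iterating).
    """
    n = params.n_nodes
    probs = np.zeros(n)
    if params.alpha == 0.0:
        probs[n - 1] = 1.0
        return InDegreePmf(probs=probs, params=params)
    buf, lo, hi, dropped, _ = _run_recursion(params.alpha, n - 1)
    probs[lo : hi + 1] = buf[lo : hi + 1]
    total = probs.sum()
    probs /= total
    return InDegreePmf(probs=probs, params=params, truncated_mass=float(dropped))


def generating_function(params: CrowdingParams, m: int, z) -> float | complex:
    """G_m(z) via the lattice form of G_{m+1}(z) = G_m(z) + (z-1) G_m(e^{-alpha} z).

    Evaluating G_m at z requires G_{m-1} on the geometric lattice
    ``z * exp(-j alpha)``; the recursion consumes one lattice point per step,
    which costs O(m^2) overall.  Accepts complex ``z`` (useful for extracting
    coefficients via roots of unity).  Raises OverflowError if the iteration
    leaves the representable range (possible for |z| > 1 at large m).

    For small |z| and m beyond a few dozen the lattice update subtracts
    nearly equal terms and loses relative accuracy; :func:`acceptance_profile`
    therefore evaluates p_m from the count-recursion states instead.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if m == 0:
        return 1.0 + 0j if np.iscomplexobj(np.asarray(z)) else 1.0
    lattice = np.asarray(z) * np.exp(-params.alpha * np.arange(m + 1))
    g = np.ones(m + 1, dtype=lattice.dtype if lattice.dtype.kind == "c" else float)
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(m):
            g = g[:-1] + (lattice[: g.size - 1] - 1.0) * g[1:]
            lattice = lattice[: g.size]
    if not np.all(np.isfinite(np.atleast_1d(g[0]).view(float))):
        raise OverflowError(f"generating function overflowed at m={m}, z={z!r}")
    out = g[0]
    return complex(out) if np.iscomplexobj(out) else float(out)


def acceptance_profile(params: CrowdingParams, M: int) -> AcceptanceProfile:
    """Acceptance probability of each proposal rank m = 1 .. M.

    p_m = G_{m-1}(e^{-alpha}) = sum_r P_{m-1}(r) e^{-alpha r}, computed from
    the count-recursion states.  p_1 = 1 exactly; p_m decays like 1/(alpha m).
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if params.alpha == 0.0:
        return AcceptanceProfile(p=np.ones(M), params=params)
    _, _, _, _, profile = _run_recursion(params.alpha, M, want_profile=True)
    return AcceptanceProfile(p=profile, params=params)


def moments(pmf: InDegreePmf) -> MomentSummary:
    """Mean and variance of the in-degree under the exact pmf."""
    k = np.arange(pmf.probs.size, dtype=float)
    mean = float(k @ pmf.probs)
    var = float((k - mean) ** 2 @ pmf.probs)
    return MomentSummary(mean=mean, variance=var, m_steps=pmf.params.n_nodes - 1)


def solve_alpha_for_mean(
    n_nodes: int,
    target_mean: float,
    *,
    tol: float = 1e-3,
    max_iter: int = 200,
    bracket: tuple[float, float] = (1e-8, 50.0),
) -> float:
    """Crowding strength whose exact mean in-degree equals ``target_mean``.

    The mean is strictly decreasing in alpha (from N - 1 at alpha = 0 down to
    1 as alpha grows), so bisection on the bracket converges to the unique
    root; iteration stops once the mean matches within ``tol``.
    """
    if not 1.0 <= target_mean <= n_nodes - 1:
        raise ValueError(
            f"target mean {target_mean} outside attainable range [1, {n_nodes - 1}]"
        )
    if target_mean == n_nodes - 1:
        return 0.0

    def mean_at(alpha: float) -> float:
        return moments(indegree_pmf(CrowdingParams(alpha=alpha, n_nodes=n_nodes))).mean

    lo, hi = bracket
    if mean_at(lo) <= target_mean:
        return lo
    if mean_at(hi) >= target_mean:
        return hi
    mid = 0.5 * (lo + hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        m = mean_at(mid)
        if abs(m - target_mean) < tol:
            return mid
        if m > target_mean:
            lo = mid
        else:
            hi = mid
    return mid


def sample_indegree_inverse_process(
    params: CrowdingParams,
    n_samples: int,
    seed=None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw in-degrees via the dual waiting-time construction.

    The number of proposals spent between the r-th and (r+1)-th acceptance is
    Geometric(exp(-alpha r)) (counting proposals up to and including the
    success, support >= 1).  A sample's in-degree is the largest r whose
    cumulative proposal count fits within the budget of N - 1 proposals; the
    stage still in progress when the budget runs out is not counted.

    Requires ``alpha > 0`` (at alpha = 0 the distribution is degenerate at
    N - 1 and the geometric representation is vacuous).
    """
    if params.alpha == 0.0:
        raise ValueError("alpha = 0 is degenerate: every in-degree equals n_nodes - 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    budget = params.n_nodes - 1
    k = np.zeros(n_samples, dtype=np.int64)
    cum = np.zeros(n_samples, dtype=np.int64)
    alive = np.arange(n_samples)
    r = 0
    while alive.size:
        p = math.exp(-params.alpha * r)
        if p * budget < 1e-9:
            # success within the remaining budget has probability <= budget*p;
            # below this cutoff no further acceptance can occur in practice
            break
        draws = rng.geometric(p, size=alive.size)
        cum[alive] = np.minimum(cum[alive] + draws, budget + 1)  # avoid overflow
        done = cum[alive] > budget
        alive = alive[~done]
        k[alive] = r + 1
        r += 1
    return k
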