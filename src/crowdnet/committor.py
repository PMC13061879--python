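"""Finite-size basin probabilities via the binomial absorbing-Markov closure.

Collapsing the network dynamics onto the active count R(t) and treating node
updates as conditionally independent gives the one-dimensional chain

    R(t+1) | R(t) = a  ~  Binomial(N, q_a),    q_a = F(a / N; theta),

where F is the heterogeneous mean-field map.  When F(0) = 0 and F(1) = 1 the
uniform macrostates R = 0 and R = N are absorbing, and the basin (hitting)
probability u_a of reaching R = N before R = 0 solves the committor system

    u_0 = 0,  u_N = 1,  u_a = sum_n C(N, n) q_a^n (1 - q_a)^{N-n} u_n.

For moderate N this is a dense linear solve; for larger N ``committor_mc``
estimates u_a by direct Monte Carlo simulation of the chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import binom as _binom

from .meanfield import HmfSpec, hmf_map

__all__ = ["CommittorSolution", "committor_linear", "committor_mc", "DENSE_SOLVE_CAP"]

#: largest N accepted by the dense linear solve (the binomial rows are full,
#: so the system is dense); beyond this use committor_mc.
DENSE_SOLVE_CAP = 1000


@dataclass(frozen=True)
class CommittorSolution:
    """Hitting probabilities u_a, a = 0..N, of the all-active macrostate."""

    u: np.ndarray
    method: Literal["linear", "monte_carlo"]
    std_err: np.ndarray | None = None
    n_traj: int | None = None
    censored_fraction: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.u.size - 1


def _absorbing_rates(spec: HmfSpec, n_nodes: int) -> np.ndarray:
    q = np.asarray(hmf_map(np.arange(n_nodes + 1) / n_nodes, spec), dtype=float)
    if abs(q[0]) > 1e-12 or abs(q[-1] - 1.0) > 1e-12:
        raise ValueError(
            "spec is not absorbing at the uniform macrostates: "
            f"F(0)={q[0]:.3g}, F(1)={q[-1]:.3g} (need 0 and 1)"
        )
    return q


def committor_linear(spec: HmfSpec, n_nodes: int) -> CommittorSolution:
    """Solve the committor system exactly as a dense linear system.

    Binomial row entries below 1e-16 are zeroed with row renormalisation
    (a conditioning aid that leaves the solution unchanged to ~1e-12).
    """
    if n_nodes > DENSE_SOLVE_CAP:
        raise ValueError(
            f"n_nodes={n_nodes} exceeds the dense-solve cap {DENSE_SOLVE_CAP}; "
            "use committor_mc"
        )
    n = n_nodes
    q = _absorbing_rates(spec, n)
    states = np.arange(n + 1)
    rows = _binom.pmf(states[None, :], n, q[1:n, None])  # (n-1, n+1)
    rows[rows < 1e-16] = 0.0
    rows /= rows.sum(axis=1, keepdims=True)
    a_mat = np.eye(n - 1) - rows[:, 1:n]
    b = rows[:, n]
    u_int = np.linalg.solve(a_mat, b)
    u = np.concatenate([[0.0], np.clip(u_int, 0.0, 1.0), [1.0]])
    return CommittorSolution(u=u, method="linear")


def committor_mc(
    spec: HmfSpec,
    n_nodes: int,
    n_traj: int,
    t_cap: int = 100_000,
    seed=None,
    rng: np.random.Generator | None = None,
) -> CommittorSolution:
    """Monte Carlo committor: simulate the binomial chain from every start a.

    For each a the estimate is the fraction of absorbed trajectories that hit
    R = N; ``std_err`` is the binomial standard error and trajectories not
    absorbed within ``t_cap`` are reported in ``censored_fraction`` (a warning
    is emitted if any exceeds 1%).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = n_nodes
    q = _absorbing_rates(spec, n)
    starts = np.repeat(np.arange(n + 1), n_traj)
    r = starts.copy()
    active = (r > 0) & (r < n)
    t = 0
    while active.any() and t < t_cap:
        idx = np.flatnonzero(active)
        r[idx] = rng.binomial(n, q[r[idx]])
        active[idx] = (r[idx] > 0) & (r[idx] < n)
        t += 1
    r2 = r.reshape(n + 1, n_traj)
    hit_n = (r2 == n).sum(axis=1)
    hit_0 = (r2 == 0).sum(axis=1)
    absorbed = hit_n + hit_0
    censored = 1.0 - absorbed / n_traj
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(absorbed > 0, hit_n / np.maximum(absorbed, 1), np.nan)
        se = np.sqrt(np.clip(u * (1.0 - u), 0.0, None) / np.maximum(absorbed, 1))
    if np.any(censored > 0.01):
        warnings.warn(
            f"censored fraction exceeds 1% at {int((censored > 0.01).sum())} start(s)",
            RuntimeWarning,
            stacklevel=2,
        )
    return CommittorSolution(
        u=u, method="monte_carlo", std_err=se, n_traj=n_traj, censored_fraction=censored
    )
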