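"""Exact threshold dynamics on concrete graphs.

Nodes carry states s_i in {-1, +1}; a synchronous update sets every node to
``sign(sum_i A_ij s_i - theta)`` simultaneously, with ties broken by the
configured rule (default sign(0) = +1).  The uniform states are the two
absorbing macrostates whenever they are fixed (theta in {0, 1} under the
plus tie rule).  Trajectories are classified as absorbed (all_plus /
all_minus), as an exact revisited cycle (synchronous mode; a non-uniform
fixed point counts as a period-1 cycle), or censored at the sweep budget.
``basin_curve`` aggregates outcome fractions over initial active counts,
the simulation counterpart of the absorbing-Markov committor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .generate import DirectedGraph

__all__ = [
    "UpdateConfig",
    "OutcomeRecord",
    "BasinCurve",
    "step_synchronous",
    "run_to_outcome",
    "basin_curve",
]

#: synchronous cycle detection stops registering states beyond this count
#: and falls back to censoring (graceful degradation at scale).
REGISTRY_CAP = 100_000


@dataclass(frozen=True)
class UpdateConfig:
    theta: float = 0.0
    mode: Literal["synchronous", "asynchronous"] = "synchronous"
    tie_rule: Literal["plus", "minus", "random"] = "plus"
    t_max: int = 200

    def __post_init__(self) -> None:
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if self.mode not in ("synchronous", "asynchronous"):
            raise ValueError(f"unknown update mode {self.mode!r}")
        if self.tie_rule not in ("plus", "minus", "random"):
            raise ValueError(f"unknown tie rule {self.tie_rule!r}")


@dataclass(frozen=True)
class OutcomeRecord:
    label: Literal["all_plus", "all_minus", "cycle", "censored"]
    absorb_time: int | None = None  # sweeps, for absorbing outcomes
    period: int | None = None  # for cycle outcomes (1 = non-uniform fixed point)


@dataclass(frozen=True)
class BasinCurve:
    a_grid: np.ndarray
    p_all_plus: np.ndarray
    p_nonabsorbing: np.ndarray
    n_trials: int
    t_max: int


def _resolve_ties(new: np.ndarray, ties: np.ndarray, tie_rule: str, rng) -> None:
    if not ties.any():
        return
    if tie_rule == "plus":
        new[ties] = 1
    elif tie_rule == "minus":
        new[ties] = -1
    else:
        if rng is None:
            raise ValueError("random tie rule needs an rng")
        new[ties] = rng.choice(np.array([-1, 1], dtype=np.int8), size=int(ties.sum()))


def step_synchronous(
    graph: DirectedGraph,
    state: np.ndarray,
    config: UpdateConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One synchronous sweep: s_j <- sign(sum_i A_ij s_i - theta) for all j."""
    h = graph.adjacency().T @ state.astype(np.int64)
    f = h - config.theta
    new = np.ones(graph.n_nodes, dtype=np.int8)
    new[f < 0] = -1
    _resolve_ties(new, f == 0, config.tie_rule, rng)
    return new


def _initial_state(n: int, a: int, rng: np.random.Generator) -> np.ndarray:
    state = np.full(n, -1, dtype=np.int8)
    if a > 0:
        state[rng.choice(n, size=a, replace=False)] = 1
    return state


def _uniform_label(state: np.ndarray) -> str | None:
    if state[0] == 1 and np.all(state == 1):
        return "all_plus"
    if state[0] == -1 and np.all(state == -1):
        return "all_minus"
    return None


def run_to_outcome(
    graph: DirectedGraph,
    initial_active: int,
    config: UpdateConfig,
    seed=None,
    rng: np.random.Generator | None = None,
) -> OutcomeRecord:
    """Run the dynamics from a random initial state with ``initial_active``
    +1 nodes until absorption, an exact cycle (synchronous), or t_max."""
    n = graph.n_nodes
    if not 0 <= initial_active <= n:
        raise ValueError("initial_active out of range")
    if rng is None:
        rng = np.random.default_rng(seed)
    state = _initial_state(n, initial_active, rng)
    label = _uniform_label(state)
    if label is not None:
        return OutcomeRecord(label=label, absorb_time=0)
    if config.mode == "synchronous":
        return _run_synchronous(graph, state, config, rng)
    return _run_asynchronous(graph, state, config, rng)


def _run_synchronous(graph, state, config, rng) -> OutcomeRecord:
    registry: dict[bytes, int] = {state.tobytes(): 0}
    for t in range(1, config.t_max + 1):
        state = step_synchronous(graph, state, config, rng)
        label = _uniform_label(state)
        if label is not None:
            return OutcomeRecord(label=label, absorb_time=t)
        key = state.tobytes()
        seen = registry.get(key)
        if seen is not None:
            return OutcomeRecord(label="cycle", period=t - seen)
        if len(registry) < REGISTRY_CAP:
            registry[key] = t
    return OutcomeRecord(label="censored")


def _run_asynchronous(graph, state, config, rng) -> OutcomeRecord:
    n = graph.n_nodes
    nbrs = graph.in_neighbor_lists()
    for sweep in range(1, config.t_max + 1):
        picks = rng.integers(n, size=n)
        for j in picks:
            f = int(state[nbrs[j]].sum()) - config.theta
            if f > 0:
                state[j] = 1
            elif f < 0:
                state[j] = -1
            elif config.tie_rule == "plus":
                state[j] = 1
            elif config.tie_rule == "minus":
                state[j] = -1
            else:
                state[j] = rng.choice((-1, 1))
        label = _uniform_label(state)
        if label is not None:
            return OutcomeRecord(label=label, absorb_time=sweep)
    return OutcomeRecord(label="censored")


def basin_curve(
    graph_source: DirectedGraph | Callable[[np.random.Generator], DirectedGraph],
    a_grid: Sequence[int],
    n_trials: int,
    config: UpdateConfig,
    seed=None,
) -> BasinCurve:
    """Outcome fractions per initial active count.

    ``graph_source`` is either a fixed graph (reused for every trial) or a
    callable receiving a trial-specific Generator and returning a fresh
    graph.  For each a the curve records the fraction of trials absorbed at
    all_plus and the fraction not absorbed in either uniform state within
    ``config.t_max`` sweeps (cycles and censored trajectories).
    """
    a_grid = np.asarray(list(a_grid), dtype=np.int64)
    root = np.random.SeedSequence(seed)
    children = root.spawn(a_grid.size * n_trials)
    p_plus = np.zeros(a_grid.size)
    p_non = np.zeros(a_grid.size)
    idx = 0
    for ai, a in enumerate(a_grid):
        n_plus = 0
        n_non = 0
        for _ in range(n_trials):
            rng = np.random.default_rng(children[idx])
            idx += 1
            graph = graph_source(rng) if callable(graph_source) else graph_source
            rec = run_to_outcome(graph, int(a), config, rng=rng)
            if rec.label == "all_plus":
                n_plus += 1
            elif rec.label in ("cycle", "censored"):
                n_non += 1
        p_plus[ai] = n_plus / n_trials
        p_non[ai] = n_non / n_trials
    return BasinCurve(
        a_grid=a_grid,
        p_all_plus=p_plus,
        p_nonabsorbing=p_non,
        n_trials=n_trials,
        t_max=config.t_max,
    )
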