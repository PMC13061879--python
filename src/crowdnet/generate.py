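"""Graph generators for the crowding ensemble and its matched baselines.

The crowding generator builds each target's in-neighbourhood independently:
candidates are proposed in an order set by the :class:`OrderingPolicy`
(uniformly random, nearest-first under a spatial layout, or a soft mixture of
the two) and each proposal is accepted with probability ``exp(-alpha * r)``
where ``r`` is the running accepted count.  Because acceptance depends only
on ``r``, the in-degree distribution is invariant under any permutation of
the candidate list — spatial ordering changes the geometry of the selected
edges but not the exact in-degree law.

Also provided: shortcut rewiring (the small-world interpolation, which
preserves every target's in-degree while destroying spatial locality), and
two matched-mean baselines — a directed Erdos-Renyi graph conditioned on
minimum in-degree one (ER+) and a regular in-degree graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse as sp
from scipy.optimize import brentq
from scipy.stats import binom as _binom

from .degree import CrowdingParams

try:
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None

__all__ = [
    "DirectedGraph",
    "SpatialLayout",
    "OrderingPolicy",
    "generate_crowding",
    "ring_distance",
    "torus_distance",
    "rewire_shortcuts",
    "generate_er_min1",
    "generate_regular_indegree",
    "er_min1_edge_probability",
    "er_min1_pmf",
    "regular_pmf",
]


@dataclass
class DirectedGraph:
    """Simple directed graph: no self-loops, no duplicate edges.

    ``edges`` is an (E, 2) integer array of (source, target) pairs.
    ``metadata`` records provenance (generator name, parameters, seed).
    """

    n_nodes: int
    edges: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.edges = e
        if e.size:
            if e.min() < 0 or e.max() >= self.n_nodes:
                raise ValueError("edge endpoints out of range")
            if np.any(e[:, 0] == e[:, 1]):
                raise ValueError("self-loops are not allowed")
            if np.unique(e, axis=0).shape[0] != e.shape[0]:
                raise ValueError("duplicate edges are not allowed")

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.edges[:, 1], minlength=self.n_nodes)

    def out_degrees(self) -> np.ndarray:
        return np.bincount(self.edges[:, 0], minlength=self.n_nodes)

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(s), int(t)) for s, t in self.edges}

    def adjacency(self) -> sp.csr_matrix:
        """Sparse adjacency A with A[i, j] = 1 for edge i -> j (cached)."""
        adj = self.__dict__.get("_adj")
        if adj is None:
            adj = sp.csr_matrix(
                (np.ones(self.n_edges, dtype=np.int64), (self.edges[:, 0], self.edges[:, 1])),
                shape=(self.n_nodes, self.n_nodes),
            )
            self.__dict__["_adj"] = adj
        return adj

    def in_neighbor_lists(self) -> list[np.ndarray]:
        """Per-target arrays of in-neighbours (cached)."""
        lists = self.__dict__.get("_in_nbrs")
        if lists is None:
            csc = self.adjacency().tocsc()
            lists = [csc.indices[csc.indptr[j] : csc.indptr[j + 1]] for j in range(self.n_nodes)]
            self.__dict__["_in_nbrs"] = lists
        return lists


@dataclass(frozen=True)
class SpatialLayout:
    """Periodic spatial embedding: a ring (D=1) or a square torus (D=2).

    Torus node ``i`` sits at lattice coordinates ``(i // side, i % side)``.
    """

    kind: Literal["ring", "torus"]
    n_nodes: int
    side: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "ring":
            if self.side is not None:
                raise ValueError("ring layout takes no side")
        elif self.kind == "torus":
            if self.side is None or self.side**2 != self.n_nodes:
                raise ValueError("torus layout requires side**2 == n_nodes")
        else:
            raise ValueError(f"unknown layout kind {self.kind!r}")

    @property
    def dimension(self) -> int:
        return 1 if self.kind == "ring" else 2

    @classmethod
    def ring(cls, n_nodes: int) -> "SpatialLayout":
        return cls(kind="ring", n_nodes=n_nodes)

    @classmethod
    def torus(cls, side: int) -> "SpatialLayout":
        return cls(kind="torus", n_nodes=side * side, side=side)

    def distances(self, i, j) -> np.ndarray:
        """Vectorised periodic distance between node index arrays."""
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        if self.kind == "ring":
            d = np.abs(i - j)
            return np.minimum(d, self.n_nodes - d).astype(float)
        s = self.side
        dx = np.abs(i // s - j // s)
        dy = np.abs(i % s - j % s)
        dx = np.minimum(dx, s - dx)
        dy = np.minimum(dy, s - dy)
        return np.sqrt((dx * dx + dy * dy).astype(float))

    def shell_distances(self) -> np.ndarray:
        """Sorted distinct nonzero pairwise distances (shell radii)."""
        return self._tables()[0]

    def shell_pair_counts(self) -> np.ndarray:
        """Number of ordered node pairs at each shell radius."""
        return self._tables()[1]

    def _tables(self):
        cached = _LAYOUT_CACHE.get((self.kind, self.n_nodes, self.side))
        if cached is None:
            cached = _build_layout_tables(self)
            _LAYOUT_CACHE[(self.kind, self.n_nodes, self.side)] = cached
        return cached


_LAYOUT_CACHE: dict = {}


def _build_layout_tables(layout: SpatialLayout):
    """(shell radii, ordered-pair counts, per-offset shell index tables)."""
    n = layout.n_nodes
    if layout.kind == "ring":
        half = n // 2
        if n % 2 == 0:
            radii = np.arange(1, half + 1, dtype=float)
            counts = np.full(half, 2 * n, dtype=np.int64)
            counts[-1] = n  # antipodal shell has a single member per node
        else:
            radii = np.arange(1, half + 1, dtype=float)
            counts = np.full(half, 2 * n, dtype=np.int64)
        return radii, counts, None
    s = layout.side
    wrap = np.minimum(np.arange(s), s - np.arange(s))
    sq = (wrap[:, None] ** 2 + wrap[None, :] ** 2).ravel()  # offset index dx*s + dy
    offs = np.arange(1, s * s)  # offset (0,0) excluded
    sqv = sq[offs]
    order = np.argsort(sqv, kind="stable")
    sorted_offs = offs[order]
    sorted_sq = sqv[order]
    uniq_sq, shell_of_sorted = np.unique(sorted_sq, return_inverse=True)
    radii = np.sqrt(uniq_sq.astype(float))
    counts = np.bincount(shell_of_sorted).astype(np.int64) * n
    return radii, counts, (sorted_offs, shell_of_sorted, sq, uniq_sq)


def ring_distance(layout: SpatialLayout, i: int, j: int) -> int:
    """Periodic ring distance min(|i-j|, N - |i-j|)."""
    if layout.kind != "ring":
        raise ValueError("ring_distance requires a ring layout")
    if i == j:
        raise ValueError("distance between a node and itself is undefined here")
    d = abs(i - j)
    return int(min(d, layout.n_nodes - d))


def torus_distance(layout: SpatialLayout, i: int, j: int) -> float:
    """Euclidean distance on the periodic square lattice."""
    if layout.kind != "torus":
        raise ValueError("torus_distance requires a torus layout")
    if i == j:
        raise ValueError("distance between a node and itself is undefined here")
    return float(layout.distances(i, j))


@dataclass(frozen=True)
class OrderingPolicy:
    """How candidate sources are ordered for each target.

    uniform  : a fresh uniformly random permutation per target.
    distance : nearest-first under the layout, with candidates at equal
               distance randomly permuted within each shell.
    soft     : nearest-first, except each proposal is drawn uniformly from
               the not-yet-proposed candidates with probability ``epsilon``.
    """

    mode: Literal["uniform", "distance", "soft"]
    epsilon: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "soft":
            if self.epsilon is None or not 0.0 <= self.epsilon <= 1.0:
                raise ValueError("soft ordering requires epsilon in [0, 1]")
        elif self.mode in ("uniform", "distance"):
            if self.epsilon is not None:
                raise ValueError(f"epsilon is only meaningful for soft ordering")
        else:
            raise ValueError(f"unknown ordering mode {self.mode!r}")


def _scan_accept_py(u, thr):
    out = np.empty(u.shape[0], dtype=np.int64)
    r = 0
    for m in range(u.shape[0]):
        if u[m] < thr[r]:
            out[r] = m
            r += 1
    return out[:r]


if njit is not None:
    _scan_accept = njit(cache=False)(_scan_accept_py)
else:  # pragma: no cover
    _scan_accept = _scan_accept_py


def _order_uniform(j: int, n: int, rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(n - 1)
    return perm + (perm >= j)


def _order_ring(j: int, n: int, rng: np.random.Generator) -> np.ndarray:
    half = n // 2
    n_pairs = half - 1 if n % 2 == 0 else half
    ds = np.arange(1, n_pairs + 1)
    flip = rng.random(n_pairs) < 0.5
    first = np.where(flip, ds, -ds)
    offs = np.empty(2 * n_pairs, dtype=np.int64)
    offs[0::2] = first
    offs[1::2] = -first
    if n % 2 == 0:
        offs = np.concatenate([offs, [half]])
    return (j + offs) % n


def _order_torus(j: int, layout: SpatialLayout, rng: np.random.Generator) -> np.ndarray:
    sorted_offs, shell_of_sorted, _, _ = layout._tables()[2]
    keys = shell_of_sorted + rng.random(sorted_offs.size)
    o = sorted_offs[np.argsort(keys, kind="stable")]
    s = layout.side
    x, y = j // s, j % s
    return ((x + o // s) % s) * s + (y + o % s) % s


def _order_soft(
    base_order: np.ndarray, epsilon: float, rng: np.random.Generator
) -> np.ndarray:
    m = base_order.size
    taken = np.zeros(m, dtype=bool)
    out = np.empty(m, dtype=np.int64)
    ptr = 0
    remaining = m
    for t in range(m):
        if epsilon > 0.0 and rng.random() < epsilon:
            idx = int(np.flatnonzero(~taken)[rng.integers(remaining)])
        else:
            while taken[ptr]:
                ptr += 1
            idx = ptr
        taken[idx] = True
        remaining -= 1
        out[t] = base_order[idx]
    return out


def _candidate_order(
    j: int,
    n: int,
    policy: OrderingPolicy,
    layout: SpatialLayout | None,
    rng: np.random.Generator,
) -> np.ndarray:
    if policy.mode == "uniform":
        return _order_uniform(j, n, rng)
    base = _order_ring(j, n, rng) if layout.kind == "ring" else _order_torus(j, layout, rng)
    if policy.mode == "distance":
        return base
    return _order_soft(base, policy.epsilon, rng)


def generate_crowding(
    params: CrowdingParams,
    policy: OrderingPolicy | None = None,
    layout: SpatialLayout | None = None,
    seed=None,
    rng: np.random.Generator | None = None,
) -> DirectedGraph:
    """Draw one graph from the crowding ensemble.

    Every target's candidate list is scanned in policy order and the next
    candidate is accepted with probability ``exp(-alpha r)`` given ``r``
    already-accepted edges, so every node ends with in-degree >= 1 and the
    in-degree law is the exact recursion pmf regardless of the ordering.
    """
    if policy is None:
        policy = OrderingPolicy(mode="uniform")
    if policy.mode in ("distance", "soft"):
        if layout is None:
            raise ValueError(f"{policy.mode} ordering requires a spatial layout")
        if layout.n_nodes != params.n_nodes:
            raise ValueError("layout size does not match n_nodes")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = params.n_nodes
    thr = np.exp(-params.alpha * np.arange(n, dtype=float))
    srcs: list[np.ndarray] = []
    tgts: list[np.ndarray] = []
    for j in range(n):
        order = _candidate_order(j, n, policy, layout, rng)
        u = rng.random(n - 1)
        pos = _scan_accept(u, thr)
        srcs.append(order[pos])
        tgts.append(np.full(pos.size, j, dtype=np.int64))
    edges = np.column_stack([np.concatenate(srcs), np.concatenate(tgts)])
    meta = {
        "generator": "crowding",
        "alpha": params.alpha,
        "policy": policy.mode,
        "epsilon": policy.epsilon,
        "layout": None if layout is None else layout.kind,
        "seed": seed,
    }
    return DirectedGraph(n_nodes=n, edges=edges, metadata=meta)


def rewire_shortcuts(
    graph: DirectedGraph,
    rho: float,
    seed=None,
    rng: np.random.Generator | None = None,
) -> DirectedGraph:
    """Small-world interpolation: rewire each edge's source with probability rho.

    Each edge is independently selected with probability ``rho``; a selected
    edge (i -> j) has its source replaced by a uniform draw from nodes that
    are neither j nor a current in-neighbour of j (the original source i
    included), resampling until valid.  Every target's in-degree — and hence
    the in-degree distribution — is preserved exactly.  Targets already
    receiving edges from all other nodes cannot be rewired; such edges are
    left in place and counted in ``metadata['rewire_skipped']``.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = graph.n_nodes
    order = np.lexsort((graph.edges[:, 0], graph.edges[:, 1]))
    edges = graph.edges[order].copy()
    selected = rng.random(edges.shape[0]) < rho
    in_nbrs: list[set[int]] = [set() for _ in range(n)]
    for s, t in edges:
        in_nbrs[t].add(int(s))
    skipped = 0
    for e in np.flatnonzero(selected):
        i, j = int(edges[e, 0]), int(edges[e, 1])
        excl = in_nbrs[j]
        if len(excl) + 1 >= n:  # every non-target node already feeds j
            skipped += 1
            continue
        while True:
            c = int(rng.integers(n))
            if c != j and c not in excl:
                break
        excl.discard(i)
        excl.add(c)
        edges[e, 0] = c
    meta = dict(graph.metadata)
    meta.update({"rho": rho, "rewire_skipped": skipped, "rewire_seed": seed})
    return DirectedGraph(n_nodes=n, edges=edges, metadata=meta)


def er_min1_edge_probability(n_nodes: int, target_mean: float) -> float:
    """Bernoulli rate p so the zero-truncated Binomial(N-1, p) row mean matches."""
    if not 1.0 <= target_mean <= n_nodes - 1:
        raise ValueError(
            f"target mean {target_mean} outside attainable range [1, {n_nodes - 1}]"
        )
    m = n_nodes - 1
    if target_mean == m:
        return 1.0
    if target_mean <= 1.0 + 1e-12:
        return 0.0  # p -> 0 limit: exactly one uniform in-edge per target

    def cond_mean(p: float) -> float:
        return m * p / (1.0 - (1.0 - p) ** m)

    return float(brentq(lambda p: cond_mean(p) - target_mean, 1e-12, 1.0 - 1e-15))


def er_min1_pmf(n_nodes: int, target_mean: float) -> np.ndarray:
    """In-degree pmf of the ER+ baseline: Binomial(N-1, p) conditioned on k >= 1."""
    p = er_min1_edge_probability(n_nodes, target_mean)
    k = np.arange(n_nodes)
    if p == 0.0:
        out = np.zeros(n_nodes)
        out[1] = 1.0
        return out
    pmf = _binom.pmf(k, n_nodes - 1, p)
    pmf[0] = 0.0
    return pmf / pmf.sum()


def regular_pmf(n_nodes: int, k: int) -> np.ndarray:
    """Degenerate in-degree pmf of the regular baseline (point mass at k)."""
    if not 1 <= k <= n_nodes - 1:
        raise ValueError("k out of range")
    out = np.zeros(n_nodes)
    out[k] = 1.0
    return out


def _pick_sources(j: int, n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    picks = rng.choice(n - 1, size=k, replace=False)
    return picks + (picks >= j)


def generate_er_min1(
    n_nodes: int,
    target_mean: float,
    seed=None,
    rng: np.random.Generator | None = None,
) -> DirectedGraph:
    """Directed Erdos-Renyi baseline conditioned on minimum in-degree one.

    Each target's in-neighbourhood is a Binomial(N-1, p) row conditioned to
    be nonempty, with p tuned so the conditional mean equals ``target_mean``.
    Row counts are drawn from the zero-truncated binomial and sources as a
    uniform subset — the exact conditional law of a resampled-if-empty row.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = n_nodes
    p = er_min1_edge_probability(n, target_mean)
    if p == 0.0:
        counts = np.ones(n, dtype=np.int64)
    else:
        counts = rng.binomial(n - 1, p, size=n)
        while np.any(counts == 0):
            zero = counts == 0
            counts[zero] = rng.binomial(n - 1, p, size=int(zero.sum()))
    srcs = []
    tgts = []
    for j in range(n):
        s = _pick_sources(j, n, int(counts[j]), rng)
        srcs.append(s)
        tgts.append(np.full(s.size, j, dtype=np.int64))
    edges = np.column_stack([np.concatenate(srcs), np.concatenate(tgts)])
    meta = {"generator": "er_min1", "target_mean": target_mean, "p": p, "seed": seed}
    return DirectedGraph(n_nodes=n, edges=edges, metadata=meta)


def generate_regular_indegree(
    n_nodes: int,
    k: int,
    seed=None,
    rng: np.random.Generator | None = None,
) -> DirectedGraph:
    """Regular baseline: every target receives exactly k in-edges from
    k distinct uniformly chosen sources."""
    if not 1 <= k <= n_nodes - 1:
        raise ValueError(f"k must lie in [1, {n_nodes - 1}]")
    if rng is None:
        rng = np.random.default_rng(seed)
    srcs = []
    tgts = []
    for j in range(n_nodes):
        s = _pick_sources(j, n_nodes, k, rng)
        srcs.append(s)
        tgts.append(np.full(k, j, dtype=np.int64))
    edges = np.column_stack([np.concatenate(srcs), np.concatenate(tgts)])
    meta = {"generator": "regular_indegree", "k": k, "seed": seed}
    return DirectedGraph(n_nodes=n_nodes, edges=edges, metadata=meta)
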