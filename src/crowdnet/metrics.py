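"""Structural diagnostics for spatially embedded crowding graphs.

Wiring-length distributions with log-binned power-law fits (the spatially
ordered ensemble shows the emergent ``P(d) ~ 1/d`` law), the per-distance
connection probability (the Kleinberg-type ``d^{-D}`` kernel), symmetrized
clustering / path-length summaries normalised by the fully rewired baseline,
and out-degree / in-out-correlation summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path
from scipy.stats import binom as _binom, poisson as _poisson

from .generate import DirectedGraph, SpatialLayout

__all__ = [
    "LengthDistribution",
    "SmallWorldSummary",
    "OutDegreeSummary",
    "wiring_length_distribution",
    "pairwise_connection_vs_distance",
    "symmetrize",
    "small_world_summary",
    "outdegree_summary",
    "inout_correlation",
]

#: minimum pooled edge count below which a power-law fit is refused
MIN_FIT_EDGES = 50


def _as_graph_list(graphs) -> list[DirectedGraph]:
    if isinstance(graphs, DirectedGraph):
        return [graphs]
    out = list(graphs)
    if not out:
        raise ValueError("need at least one graph")
    return out


def _edge_distances(graphs: list[DirectedGraph], layout: SpatialLayout) -> np.ndarray:
    for g in graphs:
        if g.n_nodes != layout.n_nodes:
            raise ValueError("layout does not match graph size")
    src = np.concatenate([g.edges[:, 0] for g in graphs])
    tgt = np.concatenate([g.edges[:, 1] for g in graphs])
    return layout.distances(src, tgt)


@dataclass(frozen=True)
class LengthDistribution:
    """Pooled edge-length histogram with a log-binned power-law fit.

    ``exponent_magnitude`` is |slope| of log density vs log distance over
    the fit range; for the spatially ordered ensemble it is close to 1.
    """

    distances: np.ndarray  # distinct observed edge lengths
    counts: np.ndarray  # pooled edge counts per distance
    bin_centers: np.ndarray
    bin_densities: np.ndarray
    exponent_magnitude: float
    r_squared: float
    fit_range: tuple[float, float]
    n_edges: int


def _log_bins(lo: float, hi: float, ratio: float, integer: bool) -> np.ndarray:
    """Geometric bin edges; on integer distance grids (ring) edges snap to
    integers so every bin width counts a whole number of attainable
    distances — otherwise sub-integer bins bias the density estimate."""
    edges = [lo]
    while edges[-1] < hi:
        nxt = edges[-1] * ratio
        if integer:
            nxt = max(np.ceil(nxt), edges[-1] + 1)
        edges.append(nxt)
    return np.asarray(edges)


def wiring_length_distribution(
    graphs: DirectedGraph | Iterable[DirectedGraph],
    layout: SpatialLayout,
    fit_range: tuple[float, float] | None = None,
    bin_ratio: float = 1.25,
) -> LengthDistribution:
    """Histogram of edge lengths with a least-squares power-law exponent.

    The default fit range excludes the d = 1 boundary shell and the
    wraparound-compressed tail: d in [2, N/10] on the ring and [2, side/3]
    on the torus.  Densities are per unit distance within logarithmic bins
    (ratio 1.25).  Refuses to fit fewer than 50 pooled edges.
    """
    graphs = _as_graph_list(graphs)
    dists = _edge_distances(graphs, layout)
    if dists.size < MIN_FIT_EDGES:
        raise ValueError(
            f"only {dists.size} pooled edges; need >= {MIN_FIT_EDGES} for a stable fit"
        )
    if fit_range is None:
        hi = layout.n_nodes / 10 if layout.kind == "ring" else layout.side / 3
        fit_range = (2.0, float(hi))
    uniq, counts = np.unique(dists, return_counts=True)
    edges = _log_bins(fit_range[0], fit_range[1], bin_ratio, integer=layout.kind == "ring")
    binned, _ = np.histogram(dists, bins=edges)
    widths = np.diff(edges)
    if layout.kind == "ring":
        # bins cover the integers [e_i, e_{i+1} - 1]
        centers = np.sqrt(edges[:-1] * (edges[1:] - 1.0))
    else:
        centers = np.sqrt(edges[:-1] * edges[1:])
    keep = binned > 0
    density = binned[keep] / widths[keep] / dists.size
    centers = centers[keep]
    if centers.size < 3:
        raise ValueError("fewer than 3 occupied bins in the fit range")
    x = np.log(centers)
    y = np.log(density)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return LengthDistribution(
        distances=uniq,
        counts=counts,
        bin_centers=centers,
        bin_densities=density,
        exponent_magnitude=float(abs(slope)),
        r_squared=r2,
        fit_range=fit_range,
        n_edges=int(dists.size),
    )


def pairwise_connection_vs_distance(
    graphs: DirectedGraph | Iterable[DirectedGraph],
    layout: SpatialLayout,
) -> pd.DataFrame:
    """Empirical edge probability per distance shell, pooled over graphs.

    Torus distances are matched to the exact grid of attainable radii (via
    integer squared distances), so shells never split by floating error.
    Returns columns (distance, n_pairs, n_edges, probability); ``n_pairs``
    counts ordered pairs per graph, so sum(n_pairs) = N(N-1).
    """
    graphs = _as_graph_list(graphs)
    radii = layout.shell_distances()
    pair_counts = layout.shell_pair_counts()
    dists = _edge_distances(graphs, layout)
    # snap to shell radii exactly (distances are computed from the same grid)
    idx = np.searchsorted(radii, dists)
    idx = np.clip(idx, 0, radii.size - 1)
    left = np.clip(idx - 1, 0, radii.size - 1)
    idx = np.where(
        np.abs(radii[left] - dists) < np.abs(radii[idx] - dists), left, idx
    )
    edge_counts = np.bincount(idx, minlength=radii.size)
    prob = edge_counts / (pair_counts * len(graphs))
    return pd.DataFrame(
        {
            "distance": radii,
            "n_pairs": pair_counts,
            "n_edges": edge_counts,
            "probability": prob,
        }
    )


def symmetrize(graph: DirectedGraph) -> nx.Graph:
    """Undirected simple graph with edge {i, j} iff i->j or j->i."""
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_nodes))
    a, b = graph.edges[:, 0], graph.edges[:, 1]
    g.add_edges_from(zip(np.minimum(a, b).tolist(), np.maximum(a, b).tolist()))
    return g


def _clustering_and_path(graph: DirectedGraph) -> tuple[float, float, float]:
    """(mean local clustering, mean shortest path over connected pairs,
    connected pair fraction) of the symmetrized simple graph."""
    sym = symmetrize(graph)
    clustering = nx.average_clustering(sym, count_zeros=True)
    n = graph.n_nodes
    adj = nx.to_scipy_sparse_array(sym, nodelist=range(n), format="csr")
    dist = shortest_path(sp.csr_matrix(adj), method="D", unweighted=True)
    iu = np.triu_indices(n, k=1)
    vals = dist[iu]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("graph has no connected node pairs")
    return float(clustering), float(vals[finite].mean()), float(finite.mean())


@dataclass(frozen=True)
class SmallWorldSummary:
    """Clustering / path length of the symmetrized graph, raw and normalised
    by the mean over a fully rewired (rho = 1) baseline ensemble."""

    clustering_mean: float
    path_length_mean: float
    connected_fraction: float
    clustering_norm: float
    path_norm: float
    baseline_clustering: float
    baseline_path: float


def small_world_summary(
    graph: DirectedGraph,
    baseline_graphs: Iterable[DirectedGraph],
) -> SmallWorldSummary:
    """Small-world diagnostics relative to the rho = 1 rewired baseline.

    Nodes with undirected degree < 2 contribute clustering 0; path length is
    averaged over connected unordered pairs only, with the connected fraction
    reported alongside.
    """
    baseline_graphs = _as_graph_list(baseline_graphs)
    c, l, frac = _clustering_and_path(graph)
    base = np.array([_clustering_and_path(g)[:2] for g in baseline_graphs])
    c0, l0 = base[:, 0].mean(), base[:, 1].mean()
    return SmallWorldSummary(
        clustering_mean=c,
        path_length_mean=l,
        connected_fraction=frac,
        clustering_norm=c / c0,
        path_norm=l / l0,
        baseline_clustering=float(c0),
        baseline_path=float(l0),
    )


@dataclass(frozen=True)
class OutDegreeSummary:
    hist: np.ndarray  # pooled out-degree counts, index = degree
    mean: float
    tv_binomial: float
    tv_poisson: float
    n_nodes: int
    n_graphs: int


def _total_variation(emp: np.ndarray, model: np.ndarray) -> float:
    tail = max(0.0, 1.0 - model.sum())
    return 0.5 * (np.abs(emp - model).sum() + tail)


def outdegree_summary(graphs: DirectedGraph | Iterable[DirectedGraph]) -> OutDegreeSummary:
    """Pooled out-degree histogram with TV distances to the matched
    Binomial(N-1, <k>/(N-1)) and Poisson(<k>) references."""
    graphs = _as_graph_list(graphs)
    n = graphs[0].n_nodes
    degs = np.concatenate([g.out_degrees() for g in graphs])
    hist = np.bincount(degs, minlength=n)
    emp = hist / degs.size
    mean = float(degs.mean())
    k = np.arange(hist.size)
    tv_b = _total_variation(emp, _binom.pmf(k, n - 1, mean / (n - 1)))
    tv_p = _total_variation(emp, _poisson.pmf(k, mean))
    return OutDegreeSummary(
        hist=hist,
        mean=mean,
        tv_binomial=float(tv_b),
        tv_poisson=float(tv_p),
        n_nodes=n,
        n_graphs=len(graphs),
    )


def inout_correlation(graphs: DirectedGraph | Iterable[DirectedGraph]) -> np.ndarray:
    """Per-graph Pearson correlation of (in-degree, out-degree) across nodes.

    Graphs with a constant degree vector have no defined correlation and
    yield NaN.
    """
    graphs = _as_graph_list(graphs)
    out = np.empty(len(graphs))
    for i, g in enumerate(graphs):
        ind = g.in_degrees().astype(float)
        outd = g.out_degrees().astype(float)
        if ind.std() == 0.0 or outd.std() == 0.0:
            out[i] = np.nan
        else:
            out[i] = float(np.corrcoef(ind, outd)[0, 1])
    return out
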