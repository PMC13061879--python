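"""Plain-text interchange formats.

Graphs travel as an edge-list TSV (``source<TAB>target``, one edge per row,
0-based indices, header line) with a JSON sidecar at ``<path>.json``
carrying n_nodes and provenance metadata.  Degree pmfs and histograms are
two-column CSVs with the same sidecar convention.  Readers validate
structure (self-loops, bounds, duplicates) and report offending line
numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .degree import CrowdingParams, InDegreePmf
from .generate import DirectedGraph
from .inference import DegreeHistogram

__all__ = [
    "GraphFormatError",
    "write_graph",
    "read_graph",
    "write_pmf",
    "read_pmf",
    "write_histogram",
    "read_histogram",
    "sidecar_path",
]

_FORMAT_VERSION = "1"


class GraphFormatError(ValueError):
    """Malformed graph file (carries a descriptive message with line numbers)."""


def sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def _jsonable(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    return value


def write_graph(graph: DirectedGraph, path) -> None:
    path = Path(path)
    lines = ["source\ttarget"]
    lines += [f"{int(s)}\t{int(t)}" for s, t in graph.edges]
    path.write_text("\n".join(lines) + "\n")
    meta = {k: _jsonable(v) for k, v in graph.metadata.items()}
    meta.update({"n_nodes": graph.n_nodes, "format_version": _FORMAT_VERSION})
    sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_graph(path) -> DirectedGraph:
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise GraphFormatError(f"missing metadata sidecar {side}")
    meta = json.loads(side.read_text())
    n_nodes = meta.pop("n_nodes", None)
    meta.pop("format_version", None)
    if n_nodes is None:
        raise GraphFormatError(f"{side}: sidecar lacks n_nodes")
    edges = []
    seen: set[tuple[int, int]] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or (lineno == 1 and line.lower().startswith("source")):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise GraphFormatError(f"{path}:{lineno}: expected two tab-separated fields")
        try:
            s, t = int(parts[0]), int(parts[1])
        except ValueError:
            raise GraphFormatError(f"{path}:{lineno}: non-integer node index") from None
        if s == t:
            raise GraphFormatError(f"{path}:{lineno}: self-loop {s}->{t}")
        if not (0 <= s < n_nodes and 0 <= t < n_nodes):
            raise GraphFormatError(
                f"{path}:{lineno}: index out of range for n_nodes={n_nodes}"
            )
        if (s, t) in seen:
            raise GraphFormatError(f"{path}:{lineno}: duplicate edge {s}->{t}")
        seen.add((s, t))
        edges.append((s, t))
    arr = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    return DirectedGraph(n_nodes=int(n_nodes), edges=arr, metadata=meta)


def write_pmf(pmf: InDegreePmf, path) -> None:
    path = Path(path)
    lines = ["k,probability"]
    lines += [f"{k},{float(p)!r}" for k, p in enumerate(pmf.probs)]
    path.write_text("\n".join(lines) + "\n")
    sidecar_path(path).write_text(
        json.dumps(
            {
                "alpha": pmf.params.alpha,
                "n_nodes": pmf.params.n_nodes,
                "truncated_mass": pmf.truncated_mass,
            },
            indent=2,
        )
        + "\n"
    )


def read_pmf(path) -> InDegreePmf:
    path = Path(path)
    meta = json.loads(sidecar_path(path).read_text())
    params = CrowdingParams(alpha=meta["alpha"], n_nodes=meta["n_nodes"])
    rows = path.read_text().splitlines()[1:]
    probs = np.zeros(params.n_nodes)
    for row in rows:
        if not row.strip():
            continue
        k, p = row.split(",")
        probs[int(k)] = float(p)
    return InDegreePmf(probs=probs, params=params, truncated_mass=meta.get("truncated_mass", 0.0))


def write_histogram(hist: DegreeHistogram, path) -> None:
    path = Path(path)
    lines = ["k,count"]
    lines += [f"{k},{hist.counts[k]}" for k in sorted(hist.counts)]
    path.write_text("\n".join(lines) + "\n")


def read_histogram(path) -> DegreeHistogram:
    rows = Path(path).read_text().splitlines()
    counts: dict[int, int] = {}
    for lineno, row in enumerate(rows, start=1):
        line = row.strip()
        if not line or (lineno == 1 and line.lower().startswith("k,")):
            continue
        try:
            k, c = line.split(",")
            counts[int(k)] = counts.get(int(k), 0) + int(c)
        except ValueError:
            raise GraphFormatError(f"{path}:{lineno}: malformed histogram row") from None
    return DegreeHistogram(counts=counts)
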