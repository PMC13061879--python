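"""Heterogeneous mean-field (HMF) map for synchronous threshold dynamics.

Assume node states are i.i.d. active with probability ``x`` and edges are
annealed apart from the in-degree ``k``.  A node with ``k`` inputs becomes
active when the signed input sum clears the threshold ``theta`` (ties break
to +1), which happens with the binomial upper-tail probability

    F_k(x; theta) = sum_{l = ceil((k + theta)/2)}^{k} C(k, l) x^l (1-x)^{k-l}.

Averaging over a degree distribution P(k) gives the one-dimensional map
``x(t+1) = F(x(t)) = sum_k P(k) F_k(x(t); theta)`` whose interior unstable
fixed points locate macroscopic basin boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom as _binom

from .degree import InDegreePmf

__all__ = ["HmfSpec", "FixedPoint", "FixedPointScan", "hmf_k", "hmf_map", "fixed_points"]


@dataclass(frozen=True)
class HmfSpec:
    """A degree pmf (indexed by k >= 0) together with the threshold theta."""

    pmf: np.ndarray
    theta: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.pmf, dtype=float)
        if p.ndim != 1 or p.size == 0 or np.any(p < 0):
            raise ValueError("pmf must be a 1-D nonnegative array")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("pmf must be normalised")
        object.__setattr__(self, "pmf", p)

    @classmethod
    def from_indegree(cls, pmf: InDegreePmf, theta: float = 0.0) -> "HmfSpec":
        return cls(pmf=pmf.probs, theta=theta)

    def support(self) -> np.ndarray:
        return np.flatnonzero(self.pmf)


def _lower_limit(k: int, theta: float) -> int:
    """ceil((k + theta)/2), clamped to [0, k + 1]."""
    l0 = math.ceil((k + theta) / 2.0)
    return int(min(max(l0, 0), k + 1))


def hmf_k(x, k: int, theta: float = 0.0):
    """Activation probability of a node with in-degree k at active fraction x.

    The binomial upper tail with lower limit ceil((k + theta)/2); an empty
    sum gives 0 and a full sum gives 1.  Accepts scalar or array ``x``.
    """
    xa = np.asarray(x, dtype=float)
    if np.any((xa < 0) | (xa > 1)):
        raise ValueError("x must lie in [0, 1]")
    l0 = _lower_limit(k, theta)
    if l0 <= 0:
        out = np.ones_like(xa)
    elif l0 > k:
        out = np.zeros_like(xa)
    else:
        out = _binom.sf(l0 - 1, k, xa)
    return float(out) if np.isscalar(x) or xa.ndim == 0 else out


def hmf_map(x, spec: HmfSpec):
    """Ensemble map F(x) = sum_k P(k) F_k(x; theta). Scalar or array x."""
    xa = np.asarray(x, dtype=float)
    out = np.zeros_like(xa, dtype=float)
    for k in spec.support():
        out += spec.pmf[k] * np.asarray(hmf_k(xa, int(k), spec.theta))
    return float(out) if np.isscalar(x) or xa.ndim == 0 else out


@dataclass(frozen=True)
class FixedPoint:
    x_star: float
    stability: Literal["stable", "unstable", "marginal"]
    slope: float


@dataclass(frozen=True)
class FixedPointScan:
    """All fixed points of the map, or a degeneracy flag when the map is the
    identity (pmf entirely at k = 1 with theta = 0) and every point is fixed."""

    points: tuple[FixedPoint, ...]
    identity_degenerate: bool = False


def _slope_at(f, x: float, step: float = 1e-6) -> float:
    a = max(0.0, x - step)
    b = min(1.0, x + step)
    return (f(b) - f(a)) / (b - a)


def _classify(slope: float, tol: float = 1e-8) -> str:
    if abs(abs(slope) - 1.0) <= tol:
        return "marginal"
    return "stable" if abs(slope) < 1.0 else "unstable"


def fixed_points(spec: HmfSpec, grid_size: int = 2001) -> FixedPointScan:
    """Locate all fixed points of F on [0, 1] by grid sign changes + bisection.

    Endpoint fixed points are included when F(0) = 0 / F(1) = 1 hold (they do
    whenever the pmf has support >= 1 and the tail limits behave).  Stability
    is classified from the numerical slope at the fixed point.
    """
    grid = np.linspace(0.0, 1.0, grid_size)
    fvals = hmf_map(grid, spec)
    resid = fvals - grid
    if np.max(np.abs(resid)) < 1e-12:
        return FixedPointScan(points=(), identity_degenerate=True)

    def f(x: float) -> float:
        return hmf_map(float(x), spec)

    roots: list[float] = []
    if abs(resid[0]) < 1e-12:
        roots.append(0.0)
    if abs(resid[-1]) < 1e-12:
        roots.append(1.0)
    for i in range(grid_size - 1):
        a, b = resid[i], resid[i + 1]
        if a == 0.0 and grid[i] not in (0.0, 1.0):
            roots.append(float(grid[i]))
        elif a * b < 0.0:
            roots.append(float(brentq(lambda x: f(x) - x, grid[i], grid[i + 1], xtol=1e-12)))
    roots = sorted(set(round(r, 12) for r in roots))
    deduped: list[float] = []
    for r in roots:
        if not deduped or r - deduped[-1] > 1e-9:
            deduped.append(r)
    pts = []
    for r in deduped:
        slope = _slope_at(f, r)
        pts.append(FixedPoint(x_star=r, stability=_classify(slope), slope=slope))
    return FixedPointScan(points=tuple(pts))
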