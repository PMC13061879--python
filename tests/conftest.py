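"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's recursions: the pmf oracle
enumerates every accept/reject sequence and the activation oracle
enumerates every input pattern, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def brute_force_indegree_pmf(alpha: float, n_nodes: int) -> np.ndarray:
    """Exact pmf by enumerating all 2^(N-1) accept/reject sequences.

    Each sequence is weighted by the product over proposals of
    e^{-alpha r} (accept) or 1 - e^{-alpha r} (reject) with r the running
    accepted count.  Only feasible for small N.
    """
    m = n_nodes - 1
    probs = np.zeros(n_nodes)
    for seq in itertools.product((0, 1), repeat=m):
        w = 1.0
        r = 0
        for accept in seq:
            p = math.exp(-alpha * r)
            w *= p if accept else (1.0 - p)
            if accept:
                r += 1
        probs[r] += w
    return probs


def brute_force_activation(x: float, k: int, theta: float) -> float:
    """P(node with k iid +/-1 inputs activates) by enumerating 2^k patterns.

    Inputs are +1 with probability x; the node activates when the input sum
    minus theta is positive, with sign(0) = +1.
    """
    total = 0.0
    for pattern in itertools.product((1, -1), repeat=k):
        n_plus = sum(1 for s in pattern if s == 1)
        w = x**n_plus * (1 - x) ** (k - n_plus)
        if sum(pattern) - theta >= 0:
            total += w
    return total


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
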