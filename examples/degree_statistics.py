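"""Exact in-degree statistics of the crowding rule and their scaling laws.

Builds the exact finite-N in-degree distribution for a few crowding
strengths, checks it against the independent waiting-time sampler, and
shows the two scaling laws: logarithmic growth of the mean and the
1/(alpha m) acceptance-profile tail.
"""

import math

import numpy as np

from crowdnet import (
    CrowdingParams,
    acceptance_profile,
    indegree_pmf,
    moments,
    sample_indegree_inverse_process,
)

N = 100
for alpha in (0.3, 0.77, 2.66):
    params = CrowdingParams(alpha=alpha, n_nodes=N)
    pmf = indegree_pmf(params)
    m = moments(pmf)
    print(f"alpha={alpha:4.2f}  N={N}:  mean in-degree {m.mean:6.3f}, variance {m.variance:6.3f}")

# the waiting-time (inverse-process) sampler draws from the same law
params = CrowdingParams(alpha=0.77, n_nodes=N)
samples = sample_indegree_inverse_process(params, 50_000, seed=1)
emp = np.bincount(samples, minlength=N) / samples.size
tv = 0.5 * np.abs(emp - indegree_pmf(params).probs).sum()
print(f"\nindependent sampler vs recursion, total-variation distance: {tv:.4f}")
print("(small TV = the recursion and the geometric waiting-time view agree)")

# mean grows like ln(N)/alpha ...
print("\nalpha * mean / ln N  (approaches 1 as N grows):")
for n in (10**3, 10**4, 10**5):
    mm = moments(indegree_pmf(CrowdingParams(1.0, n)))
    print(f"  N={n:>7}: {mm.mean / math.log(n):.4f}")

# ... because the m-th proposal is accepted with probability ~ 1/(alpha m)
ap = acceptance_profile(CrowdingParams(1.0, 2), 10_000)
print("\nalpha * m * p_m (the heavy acceptance tail, approaches 1):")
for m_rank in (10, 100, 1000, 10_000):
    print(f"  m={m_rank:>6}: {1.0 * m_rank * ap.at_rank(m_rank):.4f}")
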