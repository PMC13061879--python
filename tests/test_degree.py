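"""Exact in-degree recursion, generating function, and acceptance profile."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdnet import (
    CrowdingParams,
    acceptance_profile,
    generating_function,
    indegree_pmf,
    moments,
    sample_indegree_inverse_process,
    solve_alpha_for_mean,
)
from conftest import brute_force_indegree_pmf


class TestInDegreePmf:
    def test_single_candidate_always_accepted(self):
        pmf = indegree_pmf(CrowdingParams(alpha=3.7, n_nodes=2))
        assert pmf.probs[1] == pytest.approx(1.0, abs=1e-15)

    def test_three_nodes_log2_splits_evenly(self):
        # second proposal accepted with probability e^{-ln 2} = 1/2
        pmf = indegree_pmf(CrowdingParams(alpha=math.log(2), n_nodes=3))
        assert pmf.probs[1] == pytest.approx(0.5, abs=1e-14)
        assert pmf.probs[2] == pytest.approx(0.5, abs=1e-14)

    def test_zero_alpha_complete_graph(self):
        pmf = indegree_pmf(CrowdingParams(alpha=0.0, n_nodes=100))
        assert pmf.probs[99] == 1.0

    @pytest.mark.parametrize("alpha", [0.3, 1.0, 2.5])
    @pytest.mark.parametrize("n", [2, 5, 9, 12])
    def test_matches_sequence_enumeration(self, alpha, n):
        expected = brute_force_indegree_pmf(alpha, n)
        pmf = indegree_pmf(CrowdingParams(alpha=alpha, n_nodes=n))
        assert np.max(np.abs(pmf.probs - expected)) < 1e-10

    @given(
        alpha=st.floats(min_value=0.0, max_value=8.0),
        n=st.integers(min_value=2, max_value=300),
    )
    @settings(max_examples=40, deadline=None)
    def test_normalisation_and_support(self, alpha, n):
        pmf = indegree_pmf(CrowdingParams(alpha=alpha, n_nodes=n))
        assert abs(pmf.probs.sum() - 1.0) < 1e-12
        assert pmf.probs[0] == 0.0
        assert np.all(pmf.probs >= 0.0)
        if alpha > 0 and n > 2:
            # P(1) = (1 - e^-a)^(n-2) * (tail factor) can underflow for tiny
            # alpha; the support claim is only checkable when representable
            if (1.0 - math.exp(-alpha)) ** (n - 2) > 1e-290:
                assert int(np.flatnonzero(pmf.probs > 0)[0]) == 1

    def test_mean_monotone_in_alpha_and_n(self):
        means_a = [
            moments(indegree_pmf(CrowdingParams(a, 200))).mean
            for a in (0.2, 0.5, 1.0, 2.0, 4.0)
        ]
        assert np.all(np.diff(means_a) < 0)
        means_n = [
            moments(indegree_pmf(CrowdingParams(1.0, n))).mean
            for n in (50, 100, 400, 1600)
        ]
        assert np.all(np.diff(means_n) > 0)

    @pytest.mark.parametrize("alpha", [0.5, 1.0])
    def test_variance_saturates_with_n(self, alpha):
        v1 = moments(indegree_pmf(CrowdingParams(alpha, 10_000))).variance
        v2 = moments(indegree_pmf(CrowdingParams(alpha, 40_000))).variance
        assert abs(v2 - v1) / v1 < 0.02

    def test_variance_bounded_but_oscillatory_at_strong_crowding(self):
        # at alpha = 2.66 the variance stays O(1) but cycles with ln N
        # (log-periodic modulation of the near-degenerate distribution)
        # rather than settling: boundedness, not convergence, is the law
        alpha = 2.66
        vs = [
            moments(indegree_pmf(CrowdingParams(alpha, n))).variance
            for n in (10_000, 20_000, 40_000)
        ]
        assert all(0.5 / (2 * alpha) < v < 2.0 / alpha for v in vs)


class TestGeneratingFunction:
    def test_base_case_is_one(self):
        assert generating_function(CrowdingParams(1.7, 10), 0, 0.7) == 1.0

    def test_one_step_gives_z(self):
        assert generating_function(CrowdingParams(0.9, 10), 1, 0.3) == pytest.approx(
            0.3, abs=1e-15
        )

    def test_normalisation_at_z_one(self):
        assert generating_function(CrowdingParams(1.3, 60), 50, 1.0) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_overflow_signalled_for_large_z(self):
        # alpha = 0 keeps every factor at z, so G_m(z) = z^m blows past the
        # double range for z = 2, m > 1024
        with pytest.raises(OverflowError):
            generating_function(CrowdingParams(0.0, 2), 1200, 2.0)

    @pytest.mark.parametrize("n", [6, 12, 20])
    def test_coefficients_match_recursion_pmf(self, n):
        # extract P(k) from G_{N-1} evaluated at roots of unity
        alpha = 0.8
        params = CrowdingParams(alpha, n)
        pmf = indegree_pmf(params)
        n_pts = n
        z = np.exp(2j * np.pi * np.arange(n_pts) / n_pts)
        vals = np.array([generating_function(params, n - 1, zz) for zz in z])
        coeffs = (np.fft.fft(vals) / n_pts).real
        assert np.max(np.abs(coeffs - pmf.probs[:n_pts])) < 1e-10


class TestAcceptanceProfile:
    def test_first_proposal_always_accepted(self):
        ap = acceptance_profile(CrowdingParams(1.0, 10), 1)
        assert ap.at_rank(1) == 1.0

    def test_second_rank_is_exp_minus_alpha(self):
        ap = acceptance_profile(CrowdingParams(1.0, 10), 2)
        assert ap.at_rank(2) == pytest.approx(math.exp(-1.0), abs=1e-14)

    def test_profile_nonincreasing(self):
        ap = acceptance_profile(CrowdingParams(0.7, 10), 2000)
        assert np.all(np.diff(ap.p) <= 1e-15)
        assert np.all((ap.p > 0) & (ap.p <= 1.0))

    @pytest.mark.parametrize("alpha,rel", [(0.5, 0.05), (1.0, 0.05), (2.0, 0.10)])
    def test_tail_decays_like_inverse_alpha_m(self, alpha, rel):
        # strong crowding approaches the 1/(alpha m) law more slowly: the
        # geometric waiting times induce a log-periodic modulation whose
        # amplitude grows with alpha (~5% at alpha = 2)
        m = 10_000
        ap = acceptance_profile(CrowdingParams(alpha, 10), m)
        assert alpha * m * ap.at_rank(m) == pytest.approx(1.0, rel=rel)

    def test_profile_equals_generating_function_at_exp_minus_alpha(self):
        params = CrowdingParams(1.3, 10)
        # the float64 lattice route loses digits to cancellation at small z
        # beyond m ~ 30, so the cross-check stays at small ranks
        ap = acceptance_profile(params, 40)
        for m in (1, 5, 20):
            assert ap.at_rank(m) == pytest.approx(
                generating_function(params, m - 1, math.exp(-1.3)), abs=1e-9
            )


class TestMoments:
    def test_two_point_distribution(self):
        m = moments(indegree_pmf(CrowdingParams(math.log(2), 3)))
        assert m.mean == pytest.approx(1.5, abs=1e-12)
        assert m.variance == pytest.approx(0.25, abs=1e-12)

    def test_degenerate_complete_limit(self):
        m = moments(indegree_pmf(CrowdingParams(0.0, 100)))
        assert (m.mean, m.variance) == (99.0, 0.0)

    def test_log_growth_of_mean(self):
        m = moments(indegree_pmf(CrowdingParams(1.0, 10**6)))
        assert m.mean / math.log(10**6) == pytest.approx(1.0, rel=0.1)


class TestSolveAlphaForMean:
    def test_complete_graph_limit(self):
        assert solve_alpha_for_mean(100, 99.0) == 0.0

    def test_sparse_target_recovers_known_pairing(self):
        alpha = solve_alpha_for_mean(500, 3.0)
        assert 2.3 <= alpha <= 3.1
        mean = moments(indegree_pmf(CrowdingParams(alpha, 500))).mean
        assert mean == pytest.approx(3.0, abs=1e-3)

    def test_unattainable_mean_rejected(self):
        with pytest.raises(ValueError):
            solve_alpha_for_mean(500, 0.5)


class TestInverseProcessSampler:
    def test_matches_recursion_pmf(self):
        params = CrowdingParams(0.77, 100)
        pmf = indegree_pmf(params)
        samples = sample_indegree_inverse_process(params, 100_000, seed=7)
        emp = np.bincount(samples, minlength=100) / samples.size
        assert 0.5 * np.abs(emp - pmf.probs).sum() < 0.02

    def test_two_nodes_always_one(self):
        samples = sample_indegree_inverse_process(CrowdingParams(4.2, 2), 500, seed=1)
        assert np.all(samples == 1)

    def test_strong_crowding_mean_agrees(self):
        params = CrowdingParams(5.0, 100)
        m = moments(indegree_pmf(params))
        samples = sample_indegree_inverse_process(params, 20_000, seed=3)
        se = math.sqrt(m.variance / samples.size)
        assert abs(samples.mean() - m.mean) < 3 * se

    def test_zero_alpha_rejected(self):
        with pytest.raises(ValueError):
            sample_indegree_inverse_process(CrowdingParams(0.0, 10), 10, seed=0)
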