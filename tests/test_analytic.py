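"""Unit and property tests of the closed-form layer.

Oracles: brute-force pmf summation, adaptive quadrature, literal
transcriptions of the separately printed n = 1, 2 nearest-neighbour curves,
and an independent quadrature solution of the min2 recursion.
"""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from yuledist import (CHERRY, MIN2, NMIN1, NMIN2, PAIRWISE, ContractError,
                      ParameterError, PairStatisticKind, YuleParams, analytic)
from yuledist.analytic import (cherry_density, conditional_pair_density,
                               density_curve, density_maximum_location,
                               divisors, leaf_count_pmf,
                               mean_ancestral_lineages, mean_leaves,
                               mean_pairs, min2_density, nth_min_density,
                               pairwise_density, prob_more_than,
                               prob_pair_count_in_bin,
                               reconstructed_branch_length, sigma_threshold,
                               total_branch_length)

# 20 reproducible random parameter sets (supercritical growth, mu < lam)
_rng = np.random.default_rng(12345)
PARAM_GRID = []
for _ in range(20):
    _lam = float(_rng.uniform(0.5, 8.0))
    PARAM_GRID.append(YuleParams(lam=_lam,
                                 mu=float(_rng.uniform(0.0, 0.95)) * _lam,
                                 sigma=float(_rng.uniform(0.05, 1.0)),
                                 T=float(_rng.uniform(0.2, 1.5))))

params_st = st.builds(
    YuleParams,
    lam=st.floats(0.2, 8.0),
    mu=st.floats(0.0, 6.0),
    sigma=st.floats(0.01, 1.0),
    T=st.floats(0.05, 1.5),
)


# ----------------------------------------------------------------------------
# leaf-count law
# ----------------------------------------------------------------------------

class TestLeafCountLaw:
    def test_survival_is_certain_without_extinction(self):
        assert leaf_count_pmf(YuleParams(3.0, 0.0, 1.0, 2.0), 0) == pytest.approx(0.0, abs=1e-14)

    def test_reference_extinction_probability(self):
        # direct evaluation of the complete-sampling law: 1 - 1/(2 - e^{-1})
        p = leaf_count_pmf(YuleParams(2.0, 1.0, 1.0, 1.0), 0)
        assert p == pytest.approx(1.0 - 1.0 / (2.0 - math.exp(-1.0)), rel=1e-12)
        assert p == pytest.approx(0.38730, abs=5e-6)

    def test_height_zero_is_a_bernoulli_leaf(self):
        p = YuleParams(1.0, 0.0, 0.5, 0.0)
        assert leaf_count_pmf(p, 1) == pytest.approx(0.5)
        assert leaf_count_pmf(p, 0) == pytest.approx(0.5)

    @pytest.mark.parametrize("params", PARAM_GRID)
    def test_normalizes_and_matches_moments(self, params):
        # geometric tail => truncation point with tail mass < 1e-10
        pmf = np.array([leaf_count_pmf(params, m) for m in range(20000)])
        assert pmf.sum() == pytest.approx(1.0, abs=1e-10)
        m = np.arange(pmf.size)
        assert np.sum(m * pmf) == pytest.approx(mean_leaves(params), rel=1e-8)
        mp = mean_pairs(params)
        assert np.sum(m * (m - 1) / 2 * pmf) == pytest.approx(mp, rel=1e-8, abs=1e-12)

    @pytest.mark.parametrize("params", PARAM_GRID)
    def test_sampled_law_reduces_to_complete_law_at_sigma_one(self, params):
        full = YuleParams(params.lam, params.mu, 1.0, params.T)
        lam, mu, T = params.lam, params.mu, params.T
        r = lam - mu
        e = math.exp(-r * T)
        p0 = 1.0 - r / (lam - mu * e)
        beta = (1.0 - e) / (1.0 - (mu / lam) * e)
        assert leaf_count_pmf(full, 0) == pytest.approx(p0, rel=1e-12, abs=1e-12)
        for m in range(1, 8):
            direct = (1.0 - p0) * (1.0 - beta) * beta ** (m - 1)
            assert leaf_count_pmf(full, m) == pytest.approx(direct, rel=1e-12)

    def test_prob_more_than_is_complement_of_cumulative_sum(self):
        params = YuleParams(2.0, 1.0, 0.7, 1.0)
        for k in range(6):
            brute = 1.0 - sum(leaf_count_pmf(params, m) for m in range(k + 1))
            assert prob_more_than(params, k) == pytest.approx(brute, rel=1e-12)
        assert prob_more_than(YuleParams(2, 1, 1, 1), 0) == pytest.approx(0.61270, abs=5e-6)
        assert prob_more_than(params, 500) == pytest.approx(0.0, abs=1e-12)

    def test_invalid_arguments_raise(self):
        with pytest.raises(ParameterError):
            leaf_count_pmf(YuleParams(1, 0, 1, 1), -1)
        with pytest.raises(ParameterError):
            YuleParams(-1.0, 0.0, 1.0, 1.0)
        with pytest.raises(ParameterError):
            YuleParams(1.0, 0.0, 1.5, 1.0)


# ----------------------------------------------------------------------------
# moments and branch lengths
# ----------------------------------------------------------------------------

class TestMomentsAndBranchLengths:
    def test_mean_leaves_closed_form(self):
        assert mean_leaves(YuleParams(1, 0, 0.7, 0.0)) == pytest.approx(0.7)
        assert mean_leaves(YuleParams(1, 0, 1, math.log(2))) == pytest.approx(2.0)
        assert mean_leaves(YuleParams(6, 3, 0.1, 1)) == pytest.approx(0.1 * math.e ** 3, rel=1e-12)

    def test_mean_pairs_scales_with_sigma_squared(self):
        base = mean_pairs(YuleParams(6, 0, 1.0, 1))
        assert mean_pairs(YuleParams(6, 0, 0.1, 1)) == pytest.approx(0.01 * base, rel=1e-12)
        assert mean_pairs(YuleParams(6, 0, 1, 0.0)) == 0.0

    def test_total_branch_length(self):
        assert total_branch_length(YuleParams(1, 0, 1, 1)) == pytest.approx(math.e - 1, rel=1e-12)
        assert total_branch_length(YuleParams(2, 1, 1, 2)) == pytest.approx(math.e ** 2 - 1, rel=1e-12)
        # lam = mu limit -> T
        assert total_branch_length(YuleParams(2, 2, 1, 1.7)) == pytest.approx(1.7, rel=1e-10)

    def test_ancestral_lineages_boundaries(self):
        assert mean_ancestral_lineages(YuleParams(3, 0, 1, 1), 0.0) == pytest.approx(1.0)
        p = YuleParams(2, 1, 0.5, 1)
        assert mean_ancestral_lineages(p, p.T) == pytest.approx(mean_leaves(p), rel=1e-12)
        expected = math.exp(0.5) * (1 - leaf_count_pmf(YuleParams(2, 1, 0.5, 0.5), 0))
        assert mean_ancestral_lineages(p, 0.5) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("params", PARAM_GRID)
    def test_reconstructed_length_equals_lineage_integral(self, params):
        val, _ = quad(lambda t: mean_ancestral_lineages(params, t), 0, params.T, limit=200)
        assert reconstructed_branch_length(params) == pytest.approx(val, rel=1e-8)

    def test_reconstructed_length_limits(self):
        p = YuleParams(2.0, 1e-9, 1 - 1e-9, 1.0)
        assert reconstructed_branch_length(p) == pytest.approx(total_branch_length(p), rel=1e-6)
        assert reconstructed_branch_length(YuleParams(2, 1, 0.0, 1)) == pytest.approx(0.0, abs=1e-12)


# ----------------------------------------------------------------------------
# density families
# ----------------------------------------------------------------------------

class TestDensities:
    def test_pairwise_boundary_value_and_cutoff(self):
        p = YuleParams(6, 0, 1, 1)
        assert float(pairwise_density(p, 0.0)) == pytest.approx(3 * math.e ** 6, rel=1e-12)
        assert float(pairwise_density(p, 2.0 + 1e-9)) == 0.0
        assert float(pairwise_density(p, -1e-9)) == 0.0

    @pytest.mark.parametrize("params", PARAM_GRID)
    def test_pairwise_integral_equals_mean_pairs(self, params):
        val, _ = quad(lambda t: float(pairwise_density(params, t)),
                      0, 2 * params.T, limit=200)
        assert val == pytest.approx(mean_pairs(params), rel=1e-8, abs=1e-12)

    @pytest.mark.parametrize("params", PARAM_GRID[:8])
    def test_nth_min_matches_printed_special_cases(self, params):
        """The general n formula must agree with the separately printed
        n = 1 and n = 2 closed forms (literal transcriptions)."""
        lam, mu, sig, T = params.lam, params.mu, params.sigma, params.T

        def printed_n1(t):
            num = math.exp(lam * t / 2 + lam * T + mu * t - mu * T) * lam \
                * (lam - mu) ** 3 * sig ** 2
            den = (math.exp(lam * t / 2) * lam * sig
                   - math.exp(mu * t / 2) * (mu - lam + sig * lam)) ** 3
            return num / den

        def printed_n2(t):
            num = 3 * lam ** 2 * (lam - mu) ** 3 * sig ** 3 \
                * (math.exp(t * lam / 2) - math.exp(t * mu / 2)) \
                * math.exp(t * lam / 2 + T * lam + t * mu - T * mu)
            den = (math.exp(t * mu / 2) * (mu - lam + sig * lam)
                   - math.exp(t * lam / 2) * lam * sig) ** 4
            return num / den

        for t in np.linspace(0.05, 2 * T - 0.05, 7):
            assert float(nth_min_density(params, 1, t)) == pytest.approx(
                printed_n1(t), rel=1e-11)
            assert float(nth_min_density(params, 2, t)) == pytest.approx(
                printed_n2(t), rel=1e-11)

    def test_nth_min_integral_counts_leaves_with_enough_neighbours(self):
        # every leaf on a tree with >= 2 observed leaves has one nearest
        # neighbour: integral of N1 = <M> - P(1)
        p = YuleParams(6, 2, 0.3, 1)
        val, _ = quad(lambda t: float(nth_min_density(p, 1, t)), 0, 2, limit=300)
        assert val == pytest.approx(mean_leaves(p) - leaf_count_pmf(p, 1), rel=1e-8)

    def test_nth_min_value_at_origin(self):
        # N1(0) = lam sigma^2 e^{rT}: the density of leaves whose nearest
        # neighbour split off immediately before the present
        p = YuleParams(6, 0, 1, 1)
        assert float(nth_min_density(p, 1, 0.0)) == pytest.approx(6 * math.e ** 6, rel=1e-12)
        p = YuleParams(6, 0, 0.1, 1)
        assert float(nth_min_density(p, 1, 0.0)) == pytest.approx(
            6 * 0.01 * math.e ** 6, rel=1e-12)

    def test_nth_min_requires_positive_rank(self):
        with pytest.raises(ParameterError):
            nth_min_density(YuleParams(2, 0, 1, 1), 0, 0.5)

    def test_cherry_outside_support_and_count_bound(self):
        p = YuleParams(6, 2, 0.3, 1)
        assert float(cherry_density(p, -0.1)) == 0.0
        n_cherry, _ = quad(lambda t: float(cherry_density(p, t)), 0, 2, limit=300)
        n_nearest, _ = quad(lambda t: float(nth_min_density(p, 1, t)), 0, 2, limit=300)
        assert 2 * n_cherry <= n_nearest + 1e-9

    def test_cherry_third_law_at_complete_sampling(self):
        # with sigma=1, mu=0 the expected cherry count approaches <M>/3
        p = YuleParams(6, 0, 1, 1)
        n_cherry, _ = quad(lambda t: float(cherry_density(p, t)), 0, 2, limit=300)
        assert n_cherry == pytest.approx(math.e ** 6 / 3, rel=1e-3)

    @pytest.mark.parametrize("params", PARAM_GRID[:6])
    def test_min2_matches_recursion_quadrature(self, params):
        """Independent oracle: the min2 density solves
        N_min2(t|T) = 2 lam int_{t/2}^T e^{r(T-T')}
                      (sigma e^{rT'} - C1(t|T')) N1(t|T') dT'."""
        lam, mu, sig, T = params.lam, params.mu, params.sigma, params.T
        r = lam - mu
        t = 0.8 * T

        def n1(tt, h):
            return float(nth_min_density(YuleParams(lam, mu, sig, h), 1, tt))

        def c1(h):
            return quad(lambda x: n1(x, h), 0, min(t, 2 * h), limit=200)[0]

        oracle = 2 * lam * quad(
            lambda Tp: math.exp(r * (T - Tp)) * (sig * math.exp(r * Tp) - c1(Tp)) * n1(t, Tp),
            t / 2, T, limit=200)[0]
        # the full min2 density adds the cherry component (pairs where both
        # sides of the separating split hold exactly one observed leaf)
        core = float(min2_density(params, t)) - float(cherry_density(params, t))
        assert core == pytest.approx(oracle, rel=1e-6)

    def test_min2_outside_support(self):
        p = YuleParams(5, 0, 0.1, 1)
        assert float(min2_density(p, 2.0 + 1e-9)) == 0.0

    @pytest.mark.parametrize("params", PARAM_GRID[:10])
    @pytest.mark.parametrize("kind", [PAIRWISE, NMIN1, NMIN2, CHERRY, MIN2])
    def test_densities_nonnegative_on_support(self, params, kind):
        ts = np.linspace(0, 2 * params.T, 50)
        vals = np.asarray(analytic.density(params, kind, ts))
        assert np.all(vals >= 0)
        assert np.all(np.isfinite(vals))

    def test_critical_case_continuity(self):
        """Every density is continuous in lam - mu across zero: the series
        branch at r = 1e-10 agrees with the analytic branch at r = 1e-6."""
        for kind in [PAIRWISE, NMIN1, NMIN2, CHERRY, MIN2]:
            for t in [0.3, 1.0, 1.7]:
                a = float(analytic.density(YuleParams(2, 2 - 1e-10, 0.5, 1), kind, t))
                b = float(analytic.density(YuleParams(2, 2 - 1e-6, 0.5, 1), kind, t))
                assert a == pytest.approx(b, rel=1e-4)
        for op in (mean_pairs, total_branch_length, reconstructed_branch_length):
            a = op(YuleParams(2, 2 - 1e-10, 0.5, 1))
            b = op(YuleParams(2, 2 - 1e-6, 0.5, 1))
            assert a == pytest.approx(b, rel=1e-4)


# ----------------------------------------------------------------------------
# maxima and thresholds
# ----------------------------------------------------------------------------

class TestMaximaAndThresholds:
    def test_threshold_values(self):
        assert sigma_threshold(NMIN1, 0.0) == pytest.approx(1 / 3)
        assert sigma_threshold(CHERRY, 0.0) == pytest.approx(1 / 4)
        assert sigma_threshold(MIN2, 0.0) == pytest.approx(1 / 5)
        assert sigma_threshold(NMIN1, 0.5) == pytest.approx(1 / 6)

    def test_threshold_rejects_pairwise(self):
        with pytest.raises(ContractError):
            sigma_threshold(PAIRWISE, 0.0)

    def test_nearest_maximum_location_matches_golden_section(self):
        p = YuleParams(6, 0, 0.1, 1)
        t_closed = density_maximum_location(NMIN1, p)
        assert t_closed == pytest.approx(math.log(4.5) / 3, rel=1e-12)
        # numeric argmax oracle
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(lambda t: -float(nth_min_density(p, 1, t)),
                              bounds=(0, 2), method="bounded",
                              options={"xatol": 1e-12})
        assert t_closed == pytest.approx(float(res.x), abs=1e-6)

    def test_cherry_maximum_location_is_stationary_point(self):
        p = YuleParams(6, 1, 0.05, 1)
        t_max = density_maximum_location(CHERRY, p)
        eps = 1e-6
        d = (float(cherry_density(p, t_max + eps))
             - float(cherry_density(p, t_max - eps))) / (2 * eps)
        assert abs(d) < 1e-4 * float(cherry_density(p, t_max))

    def test_maximum_absent_above_threshold(self):
        assert density_maximum_location(NMIN1, YuleParams(6, 0, 0.5, 1)) is None
        assert density_maximum_location(CHERRY, YuleParams(6, 0, 0.5, 1)) is None
        assert density_maximum_location(MIN2, YuleParams(5, 0, 0.21, 1)) is None

    def test_boundary_sigma_gives_zero_location(self):
        # at sigma exactly the threshold the log argument is 1
        assert density_maximum_location(NMIN1, YuleParams(6, 0, 1 / 3, 1)) == pytest.approx(0.0, abs=1e-9)
        assert density_maximum_location(CHERRY, YuleParams(6, 0, 1 / 4, 1)) == pytest.approx(0.0, abs=1e-9)

    def test_min2_unimodality_switches_at_one_fifth(self):
        """Just below sigma = 1/5 (mu = 0) the min2 curve rises then falls;
        just above it is monotone decreasing (numeric derivative signs)."""
        for sig, expect_max in [(0.19, True), (0.21, False)]:
            p = YuleParams(5, 0, sig, 1)
            loc = density_maximum_location(MIN2, p)
            assert (loc is not None) == expect_max
            ts = np.linspace(1e-4, 2 - 1e-4, 400)
            vals = np.asarray(min2_density(p, ts))
            signs = np.sign(np.diff(vals))
            if expect_max:
                flips = np.sum(signs[:-1] * signs[1:] < 0)
                assert flips == 1 and signs[0] > 0
            else:
                assert np.all(signs <= 0)

    @pytest.mark.parametrize("kind,factor", [(NMIN1, 3.0), (CHERRY, 4.0)])
    def test_monotone_above_threshold_unimodal_below(self, kind, factor):
        for mu in (0.0, 2.0):
            thr = sigma_threshold(kind, mu / 6.0)
            for sig, expect_max in [(0.6 * thr, True), (1.4 * thr, False)]:
                p = YuleParams(6.0, mu, sig, 1.0)
                ts = np.linspace(1e-4, 2 - 1e-4, 400)
                vals = np.asarray(analytic.density(p, kind, ts))
                signs = np.sign(np.diff(vals))
                flips = np.sum(signs[:-1] * signs[1:] < 0)
                if expect_max:
                    assert flips == 1 and signs[0] > 0
                    assert density_maximum_location(kind, p) is not None
                else:
                    assert flips == 0
                    assert density_maximum_location(kind, p) is None


# ----------------------------------------------------------------------------
# bin occupancy and conditional density
# ----------------------------------------------------------------------------

class TestOccupancyAndConditional:
    def test_divisor_enumeration(self):
        assert divisors(6) == [1, 2, 3, 6]
        assert divisors(1) == [1]
        assert divisors(36) == [1, 2, 3, 4, 6, 9, 12, 18, 36]
        with pytest.raises(ParameterError):
            divisors(0)
        with pytest.raises(ParameterError):
            divisors(10 ** 6 + 1)

    def test_single_pair_probability_uses_only_divisor_one(self):
        p = YuleParams(11, 5, 0.01, 1)
        t, dt = 1.5, 1e-5
        half = YuleParams(11, 5, 0.01, t / 2)
        branch = 11 * math.exp(6 * (1 - t / 2)) * dt / 2
        from yuledist.analytic import leaf_count_pmf as pmf
        assert prob_pair_count_in_bin(p, t, dt, 1) == pytest.approx(
            branch * pmf(half, 1) ** 2, rel=1e-12)

    def test_occupancy_probabilities_sum_to_one(self):
        p = YuleParams(11, 5, 0.01, 1)
        t, dt = 1.5, 1e-5
        total = sum(prob_pair_count_in_bin(p, t, dt, n) for n in range(400))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_occupancy_mean_recovers_pair_density(self):
        p = YuleParams(11, 5, 0.01, 1)
        t, dt = 1.5, 1e-5
        mean = sum(n * prob_pair_count_in_bin(p, t, dt, n) for n in range(1, 4001))
        assert mean == pytest.approx(float(pairwise_density(p, t)) * dt, rel=1e-6)

    def test_wide_bin_warns(self):
        p = YuleParams(6, 0, 1, 1)
        with pytest.warns(UserWarning):
            prob_pair_count_in_bin(p, 1.0, 0.5, 0)

    def test_conditional_density_identity_and_closed_form(self):
        p = YuleParams(11, 5, 0.01, 1)
        for t in (0.5, 1.0, 1.5):
            dt = 0.005
            pr0 = prob_pair_count_in_bin(p, t, dt, 0)
            ntil = conditional_pair_density(p, t, dt)
            # N dt = Ntilde dt (1 - Pr0) holds by construction
            assert ntil * (1 - pr0) == pytest.approx(
                float(pairwise_density(p, t)), rel=1e-12)
            # and equals the closed form (1 + q (e^{rt/2}-1)/r)^2 / dt
            r, q = p.r, p.lam * p.sigma
            closed = (1 + q * (math.exp(r * t / 2) - 1) / r) ** 2 / dt
            assert ntil == pytest.approx(closed, rel=1e-10)
            assert ntil >= float(pairwise_density(p, t))

    def test_conditional_reduces_to_plain_density_when_bins_full(self):
        # large sigma*lam and a bin wide enough that P(empty) ~ 1%: Ntilde -> N
        p = YuleParams(6, 0, 1, 1)
        t = 1.0
        dt = 0.99 / (p.lam * math.exp(p.r * (p.T - t / 2)) / 2)
        with pytest.warns(UserWarning):
            ratio = conditional_pair_density(p, t, dt) / float(pairwise_density(p, t))
        assert ratio == pytest.approx(1.0, rel=0.05)


# ----------------------------------------------------------------------------
# properties
# ----------------------------------------------------------------------------

@settings(max_examples=40, deadline=None, derandomize=True)
@given(params=params_st, t=st.floats(-0.5, 3.5))
def test_density_support_and_sign_property(params, t):
    for kind in (PAIRWISE, NMIN1, CHERRY, MIN2):
        v = float(analytic.density(params, kind, t))
        assert v >= 0.0
        if not (0.0 <= t <= 2 * params.T):
            assert v == 0.0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(params=params_st, k=st.integers(0, 30))
def test_tail_probability_is_monotone_property(params, k):
    assert prob_more_than(params, k + 1) <= prob_more_than(params, k) + 1e-15
    assert 0.0 <= prob_more_than(params, k) <= 1.0


def test_density_curve_wrapper():
    p = YuleParams(6, 0, 0.1, 1)
    curve = density_curve(PairStatisticKind.nth_min(1), p)
    assert curve.support == (0.0, 2.0)
    assert float(curve(0.5)) == pytest.approx(float(nth_min_density(p, 1, 0.5)))
    with pytest.raises(ParameterError):
        density_curve(PAIRWISE, YuleParams(0.0, 0.0, 1.0, 1.0))
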