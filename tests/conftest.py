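"""Shared fixtures: reference parameter sets and (session-cached) ensembles."""
import numpy as np
import pytest
from scipy.integrate import quad

from yuledist import (PAIRWISE, CHERRY, MIN2, NMIN1, NMIN2, SimulationConfig,
                      YuleParams, analytic, ensemble_histograms)


def bin_averaged_theory(params, kind, edges):
    """Average of the analytic density over each bin (what a histogram estimates)."""
    out = []
    for a, b in zip(edges[:-1], edges[1:]):
        v, _ = quad(lambda t: float(analytic.density(params, kind, t)), a, b, limit=200)
        out.append(v / (b - a))
    return np.array(out)


def assert_histogram_matches_theory(hist, params, kind,
                                    max_se: float = 3.0,
                                    outlier_fraction: float = 0.01,
                                    hard_cap_se: float = 6.0):
    """Per-bin z-test of an ensemble histogram against the closed form.

    Bins where the ensemble variance is estimable are compared at |z| <= 3;
    with hundreds of bins a ~0.3% chance excess beyond 3 s.e. is expected, so
    up to ``outlier_fraction`` of bins may exceed 3 s.e. but none may exceed
    the hard cap.  Empty bins are checked against the expected count on a
    Poisson scale.
    """
    th = bin_averaged_theory(params, kind, hist.edges)
    se = hist.density_se
    S, w = hist.n_trees, hist.widths
    nz = hist.nonzero_trees
    # Sparse bins are filled in clusters (one tree contributes several
    # values), so the count variance is at least cluster_size * expectation
    # (quasi-Poisson); the empirical variance from a handful of trees can
    # undershoot that badly.  Use whichever error estimate is larger.
    cluster_global = max(1.0, hist.counts.sum() / max(nz.sum(), 1))
    z = np.empty(hist.n_bins)
    for i in range(hist.n_bins):
        exp_cnt = th[i] * w[i] * S
        if nz[i] > 0:
            cluster = max(1.0, hist.counts[i] / nz[i])
            se_model = np.sqrt(cluster * exp_cnt) / (S * w[i])
            z[i] = (hist.density[i] - th[i]) / max(se[i], se_model)
        else:
            # bin empty in every tree: the expected number of contributing
            # trees must be small enough that zero is unsurprising
            z[i] = np.sqrt(exp_cnt / cluster_global)
    n_out = int(np.sum(np.abs(z) > max_se))
    allowed = max(1, int(np.ceil(outlier_fraction * z.size)))
    assert n_out <= allowed, (
        f"{n_out} bins beyond {max_se} s.e. for {kind} (allowed {allowed}); "
        f"worst |z| = {np.max(np.abs(z)):.2f}")
    assert np.max(np.abs(z)) <= hard_cap_se, (
        f"bin deviates {np.max(np.abs(z)):.2f} s.e. from theory for {kind}")


#: the four simulation-vs-theory reference configurations
REFERENCE_CONFIGS = [
    YuleParams(6.0, 0.0, 1.0, 1.0),
    YuleParams(6.0, 0.0, 0.1, 1.0),
    YuleParams(6.0, 3.0, 1.0, 1.0),
    YuleParams(6.0, 3.0, 0.1, 1.0),
]


@pytest.fixture(scope="session")
def reference_ensembles():
    """S = 10^4 ensembles of the four reference configurations, 40 bins."""
    out = {}
    for i, p in enumerate(REFERENCE_CONFIGS):
        cfg = SimulationConfig(p, n_trees=10_000, seed=2000 + i)
        out[p] = ensemble_histograms(cfg, [PAIRWISE, NMIN1, NMIN2, CHERRY, MIN2],
                                     bins=40)
    return out


@pytest.fixture(scope="session")
def sparse_ensemble():
    """The sparse-sampling regime (lam=11, mu=5, sigma=0.01), S = 10^5,
    bin width 0.005 -- the single-tree / conditional-mean study condition."""
    p = YuleParams(11.0, 5.0, 0.01, 1.0)
    cfg = SimulationConfig(p, n_trees=100_000, seed=2100)
    return ensemble_histograms(cfg, [PAIRWISE], bins=400)


@pytest.fixture(scope="session")
def fixture_bundle():
    from yuledist.io import make_fixtures
    return make_fixtures(seed=17)
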