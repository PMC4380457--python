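"""Closed-form statistics of pairwise leaf distances on a Yule tree.

Every function here is a pure function of the model parameters
(lambda, mu, sigma, T) and, for the densities, the separation time ``t``.
The leaf-count law of the sampled birth-death process is a zero-inflated
geometric distribution; writing the growth factor ``w = e^{rT}`` (with
``r = lambda - mu``) and ``phi = (e^{rT}-1)/r``,

    P(M = 0 | T) = 1 - sigma*w / (lambda*sigma*phi + 1)
    P(M | T)     = (1 - P0) * (1 - beta) * beta^(M-1),
    beta         = lambda*sigma*phi / (lambda*sigma*phi + 1)

which reduces to the classical complete-sampling law at sigma = 1.  All
densities below are expressed through ``phi``-type factors so that the
critical case lambda -> mu is handled by the same code path (the series
branch of ``phi`` switches on automatically when |r t| is tiny).

Densities have units "pairs (or leaves) per unit time", are supported on
[0, 2T] and vanish outside.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import ContractError, ParameterError
from .params import PairStatisticKind, YuleParams

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "leaf_count_pmf",
    "prob_more_than",
    "mean_leaves",
    "mean_pairs",
    "total_branch_length",
    "mean_ancestral_lineages",
    "reconstructed_branch_length",
    "pairwise_density",
    "nth_min_density",
    "cherry_density",
    "min2_density",
    "sigma_threshold",
    "density_maximum_location",
    "prob_pair_count_in_bin",
    "conditional_pair_density",
    "divisors",
    "DensityCurve",
    "density_curve",
]


# ----------------------------------------------------------------------------
# numerically stable primitives
# ----------------------------------------------------------------------------

def _em1r(r: float, x: ArrayLike) -> ArrayLike:
    """(e^{r x} - 1) / r, continuous through r = 0 (-> x)."""
    x = np.asarray(x, dtype=float)
    z = r * x
    small = np.abs(z) < 1e-5
    rsafe = r if r != 0.0 else 1.0
    with np.errstate(over="ignore"):
        out = np.where(small, x * (1.0 + z * (0.5 + z / 6.0)), np.expm1(z) / rsafe)
    return out if out.ndim else float(out)


def _neglog1p_over(b: float, x: float) -> float:
    """-log(1 - b*x)/b, continuous through b = 0 (-> x)."""
    z = b * x
    if abs(z) < 1e-6:
        return x * (1.0 + z * (0.5 + z / 3.0))
    return -math.log1p(-z) / b


def _pmf_pieces(params: YuleParams):
    """Return (p0, beta) of the zero-inflated geometric leaf-count law."""
    r, lam, sig, T = params.r, params.lam, params.sigma, params.T
    phi = float(_em1r(r, T))
    k = lam * sig
    denom = k * phi + 1.0
    surv = sig * math.exp(r * T) / denom
    beta = k * phi / denom
    return 1.0 - surv, beta


# ----------------------------------------------------------------------------
# leaf-count law and moments
# ----------------------------------------------------------------------------

def leaf_count_pmf(params: YuleParams, M: int) -> float:
    """P(M observed leaves | height T) under Bernoulli(sigma) leaf sampling.

    At sigma = 1 this is the classical birth-death leaf-count law.
    """
    if M < 0 or M != int(M):
        raise ParameterError(f"leaf count must be a nonnegative integer, got {M}")
    p0, beta = _pmf_pieces(params)
    if M == 0:
        return p0
    return (1.0 - p0) * (1.0 - beta) * beta ** (M - 1)


def prob_more_than(params: YuleParams, k: int) -> float:
    """P(more than k leaves observed) = (1 - P(0)) * beta^k.

    Equals 1 - sum_{m<=k} P(m) exactly (geometric tail).
    """
    if k < 0 or k != int(k):
        raise ParameterError(f"k must be a nonnegative integer, got {k}")
    p0, beta = _pmf_pieces(params)
    return (1.0 - p0) * beta ** k


def mean_leaves(params: YuleParams) -> float:
    """Expected number of observed leaves, sigma * e^{(lambda-mu) T}."""
    return params.sigma * math.exp(params.r * params.T)


def mean_pairs(params: YuleParams) -> float:
    """Expected number of observed leaf pairs.

    sigma^2 * lambda * e^{rT} * (e^{rT} - 1)/r, with the r -> 0 limit
    sigma^2 * lambda * T taken by the series branch.
    """
    r, T = params.r, params.T
    return params.sigma ** 2 * params.lam * math.exp(r * T) * float(_em1r(r, T))


def total_branch_length(params: YuleParams) -> float:
    """Expected total branch length of the complete tree, (e^{rT} - 1)/r."""
    return float(_em1r(params.r, params.T))


def mean_ancestral_lineages(params: YuleParams, t: float) -> float:
    """Expected number of lineages at time t with >= 1 observed descendant at T.

    e^{rt} * [1 - P(0 | T - t)]; equals ``mean_leaves`` at t = T.
    """
    if not (0.0 <= t <= params.T):
        raise ParameterError(f"t must lie in [0, T], got {t}")
    r, lam, sig = params.r, params.lam, params.sigma
    h = params.T - t
    phi = float(_em1r(r, h))
    return sig * math.exp(r * params.T) / (lam * sig * phi + 1.0)


def reconstructed_branch_length(params: YuleParams) -> float:
    """Expected total branch length of the subtree spanned by observed leaves.

    sigma e^{rT}/b * log( r / (lambda sigma + b e^{-rT}) ) with
    b = lambda - mu - lambda*sigma; continuous through b = 0 and r = 0, and
    converging to ``total_branch_length`` as mu -> 0, sigma -> 1.
    """
    r, lam, sig, T = params.r, params.lam, params.sigma, params.T
    b = r - lam * sig
    g = float(_em1r(r, T)) * math.exp(-r * T)  # (1 - e^{-rT})/r
    return sig * math.exp(r * T) * _neglog1p_over(b, g)


# ----------------------------------------------------------------------------
# density families (internal forms shared with the fitter)
# ----------------------------------------------------------------------------
# All densities depend on the identifiable combinations r = lambda - mu,
# q = lambda*sigma and A = sigma*e^{rT} only (min2 also needs e^{rT} itself,
# i.e. the height T once r is known).

def _pairwise_rqa(r: float, q: float, A: float, t: ArrayLike) -> ArrayLike:
    return 0.5 * q * A * np.exp(0.5 * r * np.asarray(t, float))


def _psi(r: float, t: ArrayLike) -> ArrayLike:
    """(1 - e^{-r t/2}) / r, continuous through r = 0 (-> t/2)."""
    t = np.asarray(t, float)
    z = -0.5 * r * t
    small = np.abs(z) < 1e-5
    rsafe = r if r != 0.0 else 1.0
    with np.errstate(over="ignore"):
        out = np.where(small, 0.5 * t * (1.0 + z * (0.5 + z / 6.0)), -np.expm1(z) / rsafe)
    return out


def _nth_min_rqa(r: float, q: float, A: float, n: int, t: ArrayLike) -> ArrayLike:
    t = np.asarray(t, float)
    u = np.exp(-0.5 * r * t)
    psi = _psi(r, t)
    denom = q * psi + u
    pref = 0.5 * n * (n + 1.0) * A * q ** n
    with np.errstate(over="ignore", invalid="ignore"):
        out = pref * psi ** (n - 1) * np.exp(-r * t) / denom ** (n + 2)
    return out


def _cherry_rqa(r: float, q: float, A: float, t: ArrayLike) -> ArrayLike:
    t = np.asarray(t, float)
    u = np.exp(-0.5 * r * t)
    psi = _psi(r, t)
    denom = q * psi + u
    return 0.5 * q * A * np.exp(-1.5 * r * t) / denom ** 4


def _min2_core_rqa(r: float, q: float, A: float, T: float, t: ArrayLike) -> ArrayLike:
    """Solution of the min2 recursion whose source counts only one-vs-many
    subtree splits (the component the derivation writes down explicitly)."""
    t = np.asarray(t, float)
    u = np.exp(-0.5 * r * t)
    psi = _psi(r, t)
    denom = q * psi + u
    # chi = (e^{rT} - e^{rt/2})/r, written to stay finite at r -> 0
    chi = np.exp(0.5 * r * t) * np.asarray(_em1r(r, T - 0.5 * t))
    return 2.0 * q * q * A * chi * np.exp(-2.0 * r * t) / denom ** 5


def _min2_rqa(r: float, q: float, A: float, T: float, t: ArrayLike) -> ArrayLike:
    """Density of min(t1, t2) over pairs, t_i the members' nearest distances.

    The recursion's explicit source misses splits with exactly one observed
    leaf on *both* sides -- cherry pairs, whose min2 value is their mutual
    distance.  That omitted source is identical to the cherry recursion's,
    so the full density is the recursion solution plus the cherry density
    (confirmed against simulation, which otherwise sits systematically above
    the bare recursion solution).
    """
    return _min2_core_rqa(r, q, A, T, t) + _cherry_rqa(r, q, A, t)


def _support_mask(params: YuleParams, t: ArrayLike, values: ArrayLike) -> ArrayLike:
    t = np.asarray(t, float)
    out = np.where((t >= 0.0) & (t <= 2.0 * params.T), values, 0.0)
    return out if out.ndim else float(out)


def pairwise_density(params: YuleParams, t: ArrayLike) -> ArrayLike:
    """N(t|T): expected density of leaf pairs separated by time t.

    (sigma^2 lambda / 2) e^{rT} e^{rt/2} on [0, 2T], zero outside.  A pure
    increasing (r > 0) exponential -- the signature of a Yule process.
    """
    params.require_branching()
    r, q, A = params.r, params.lam * params.sigma, mean_leaves(params)
    return _support_mask(params, t, _pairwise_rqa(r, q, A, t))


def nth_min_density(params: YuleParams, n: int, t: ArrayLike) -> ArrayLike:
    """N_n(t|T): expected density of leaves whose n-th nearest neighbour is at t."""
    if n < 1 or n != int(n):
        raise ParameterError(f"nth_min requires n >= 1, got {n}")
    params.require_branching()
    r, q, A = params.r, params.lam * params.sigma, mean_leaves(params)
    return _support_mask(params, t, _nth_min_rqa(r, q, A, int(n), t))


def cherry_density(params: YuleParams, t: ArrayLike) -> ArrayLike:
    """N_Lambda(t|T): expected density of cherries (mutual nearest pairs) at separation t."""
    params.require_branching()
    r, q, A = params.r, params.lam * params.sigma, mean_leaves(params)
    return _support_mask(params, t, _cherry_rqa(r, q, A, t))


def min2_density(params: YuleParams, t: ArrayLike) -> ArrayLike:
    """N_min2(t|T): density over pairs of the smaller of the two nearest-neighbour distances."""
    params.require_branching()
    r, q, A = params.r, params.lam * params.sigma, mean_leaves(params)
    return _support_mask(params, t, _min2_rqa(r, q, A, params.T, t))


def density(params: YuleParams, kind: PairStatisticKind, t: ArrayLike) -> ArrayLike:
    """Dispatch to the density family named by ``kind``."""
    if kind.name == "pairwise":
        return pairwise_density(params, t)
    if kind.name == "nth_min":
        return nth_min_density(params, kind.n, t)
    if kind.name == "cherry":
        return cherry_density(params, t)
    if kind.name == "min2":
        return min2_density(params, t)
    raise ContractError(f"unknown kind {kind}")


@dataclass(frozen=True)
class DensityCurve:
    """A density family bound to a parameter set; callable on times."""

    kind: PairStatisticKind
    params: YuleParams

    @property
    def support(self) -> tuple[float, float]:
        return (0.0, 2.0 * self.params.T)

    def __call__(self, t: ArrayLike) -> ArrayLike:
        return density(self.params, self.kind, t)


def density_curve(kind: PairStatisticKind, params: YuleParams) -> DensityCurve:
    params.require_branching()
    return DensityCurve(kind, params)


# ----------------------------------------------------------------------------
# maxima and sampling-fraction thresholds
# ----------------------------------------------------------------------------

#: multiple of lambda*sigma that (lambda - mu) must exceed for an interior maximum
_MAX_FACTOR = {"nth_min": 3.0, "cherry": 4.0, "min2": 5.0}


def sigma_threshold(kind: PairStatisticKind, mu_over_lambda: float) -> float:
    """Critical sampling fraction below which the density has an interior maximum.

    (1/3)(1 - mu/lambda) for the nearest-neighbour density, (1/4)(...) for
    cherries, (1/5)(...) for min2.  The pairwise density is monotone for all
    sigma and has no criterion.
    """
    if not (0.0 <= mu_over_lambda < 1.0):
        raise ParameterError(f"mu/lambda must lie in [0, 1), got {mu_over_lambda}")
    if kind.name == "pairwise" or (kind.name == "nth_min" and kind.n != 1):
        raise ContractError(f"no maximum criterion exists for kind {kind}")
    return (1.0 - mu_over_lambda) / _MAX_FACTOR[kind.name]


def density_maximum_location(kind: PairStatisticKind, params: YuleParams) -> Optional[float]:
    """Location of the interior maximum of the density, or None if absent.

    Closed forms: t_max = (2/r) log(b / (2 lambda sigma)) for the
    nearest-neighbour density and (2/r) log(b / (3 lambda sigma)) for
    cherries, with b = lambda - mu - lambda*sigma.  The min2 (and n >= 2)
    maxima are located numerically.  Returns None when the maximum does not
    exist or falls outside [0, 2T].
    """
    params.require_branching()
    r, lam, sig, T = params.r, params.lam, params.sigma, params.T
    q = lam * sig
    b = r - q
    if kind.name == "pairwise":
        raise ContractError("the pairwise density is monotone; no maximum criterion exists")
    if kind.name in ("nth_min", "cherry") and (kind.name == "cherry" or kind.n == 1):
        factor = 2.0 if kind.name == "nth_min" else 3.0
        if b <= factor * q:
            if b == factor * q:  # boundary: log argument exactly 1
                return 0.0
            return None
        if r == 0.0:
            return None
        t_max = (2.0 / r) * math.log(b / (factor * q))
        return t_max if 0.0 <= t_max <= 2.0 * T else None
    if kind.name == "min2" or kind.name == "nth_min":
        curve = density_curve(kind, params)
        res = minimize_scalar(lambda t: -float(curve(t)), bounds=(0.0, 2.0 * T), method="bounded",
                              options={"xatol": 1e-10 * max(1.0, T)})
        t_max = float(res.x)
        edge = 1e-6 * 2.0 * T
        if t_max <= edge or t_max >= 2.0 * T - edge:
            return None
        # genuine interior maximum, not a plateau of a monotone curve
        if float(curve(t_max)) <= float(curve(0.0)) or float(curve(t_max)) <= float(curve(2.0 * T)):
            return None
        return t_max
    raise ContractError(f"unknown kind {kind}")


# ----------------------------------------------------------------------------
# bin-occupancy distribution and conditional density
# ----------------------------------------------------------------------------

def divisors(n: int) -> list[int]:
    """All positive divisors of n (trial division; n capped at 10^6)."""
    if n < 1 or n != int(n):
        raise ParameterError(f"n must be a positive integer, got {n}")
    if n > 10 ** 6:
        raise ParameterError(f"divisor enumeration capped at n = 10^6, got {n}")
    small, large = [], []
    d = 1
    while d * d <= n:
        if n % d == 0:
            small.append(d)
            if d != n // d:
                large.append(n // d)
        d += 1
    return small + large[::-1]


def _branch_prob(params: YuleParams, t: float, dt: float) -> float:
    """Probability of a branching event in [T - t/2 - dt/2, T - t/2]."""
    return params.lam * math.exp(params.r * (params.T - 0.5 * t)) * 0.5 * dt


def prob_pair_count_in_bin(params: YuleParams, t: float, dt: float, n: int) -> float:
    """P(exactly n observed pairs separated by a time in [t, t+dt]).

    For n = 0: 1 - B(t) [1 - P(0|t/2)]^2 with B the branch probability of the
    interval; for n > 0: B(t) * sum over divisors d of n of P(d|t/2) P(n/d|t/2).
    Valid in the small-bin regime N(t)dt << 1.
    """
    if dt <= 0.0:
        raise ParameterError(f"bin width must be positive, got {dt}")
    if n < 0 or n != int(n):
        raise ParameterError(f"pair count must be a nonnegative integer, got {n}")
    params.require_branching()
    if not (0.0 <= t <= 2.0 * params.T):
        return 1.0 if n == 0 else 0.0
    nd = float(pairwise_density(params, t)) * dt
    if nd > 0.1:
        warnings.warn(
            f"bin width dt = {dt} gives N(t)dt = {nd:.3g} > 0.1; the small-bin "
            f"occupancy formula is unreliable here", stacklevel=2)
    half = YuleParams(params.lam, params.mu, params.sigma, 0.5 * t)
    branch = _branch_prob(params, t, dt)
    if n == 0:
        return 1.0 - branch * (1.0 - leaf_count_pmf(half, 0)) ** 2
    return branch * sum(
        leaf_count_pmf(half, d) * leaf_count_pmf(half, n // d) for d in divisors(n))


def conditional_pair_density(params: YuleParams, t: float, dt: float) -> float:
    """Ntilde(t|T): expected pair density conditioned on the bin being nonempty.

    Defined (and implemented) as N(t|T) / [1 - P(count = 0)], already divided
    by dt so that a pure density is returned; algebraically equal to
    (1 + lambda sigma (e^{rt/2}-1)/r)^2 / dt.
    """
    pr0 = prob_pair_count_in_bin(params, t, dt, 0)
    nonzero = 1.0 - pr0
    if nonzero <= 0.0:
        raise ContractError(
            f"P(zero pairs) = 1 at t = {t}; the conditional density is undefined")
    return float(pairwise_density(params, t)) / nonzero
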