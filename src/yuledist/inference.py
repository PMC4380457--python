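"""Fitting the analytic curves to distance histograms.

The distance densities depend on (lambda, mu, sigma, T) only through three
identifiable combinations:

    r = lambda - mu          (net growth rate, per unit time)
    q = lambda * sigma       (observed branching intensity, per unit time)
    A = sigma * e^{rT}       (expected number of observed leaves)

so the fitter estimates exactly (r, q, A) -- the individual parameters are
not recoverable from distances alone.  What remains identifiable about the
sampling fraction is the bound sigma <= q/r (tight at mu = 0) and the family
sigma(mu/lambda) = (q/r)(1 - mu/lambda) under an assumed turnover ratio.

The fit is iteratively reweighted least squares with bisquare (Tukey)
weights, the standard robust choice, jointly over any subset of the
pairwise / n-th nearest / cherry (and, given the height, min2) curves.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .analytic import _cherry_rqa, _min2_rqa, _nth_min_rqa, _pairwise_rqa, _psi
from .errors import ContractError, ParameterError
from .params import PairStatisticKind, YuleParams
from .stats import DistanceHistogram

__all__ = [
    "FitResult",
    "BoundClaim",
    "fit_densities",
    "sigma_upper_bound",
    "implied_sigma",
    "maximum_based_sigma_bound",
    "model_density",
]

#: bisquare tuning constant (95% Gaussian efficiency)
BISQUARE_C = 4.685

#: interior-maximum sigma bounds by statistic kind
_BOUNDS = {"nth_min": 1.0 / 3.0, "cherry": 1.0 / 4.0, "min2": 1.0 / 5.0}


def model_density(kind: PairStatisticKind, r: float, q: float, A: float,
                  t: np.ndarray, T: Optional[float] = None) -> np.ndarray:
    """Analytic density of ``kind`` in the identifiable parameterization.

    ``T`` is only required for the min2 family (its curve carries an explicit
    e^{rT} factor beyond the three combinations).
    """
    t = np.asarray(t, float)
    if kind.name == "pairwise":
        return _pairwise_rqa(r, q, A, t)
    if kind.name == "nth_min":
        return _nth_min_rqa(r, q, A, kind.n, t)
    if kind.name == "cherry":
        return _cherry_rqa(r, q, A, t)
    if kind.name == "min2":
        if T is None:
            raise ContractError("the min2 curve needs the tree height T")
        return _min2_rqa(r, q, A, T, t)
    raise ContractError(f"unknown kind {kind}")


def _conditional_model(r: float, q: float, t: np.ndarray, dt: float) -> np.ndarray:
    """Ntilde(t) = (1 + q (e^{rt/2}-1)/r)^2 / dt (A drops out)."""
    t = np.asarray(t, float)
    phi_half = np.exp(0.5 * r * t) * _psi(r, t)  # (e^{rt/2} - 1)/r
    return (1.0 + q * phi_half) ** 2 / dt


@dataclass(frozen=True)
class FitResult:
    """Estimates of the identifiable combinations with uncertainties.

    ``A`` is NaN when the fitted curves do not constrain it (pure
    conditional-density fits).  Standard errors are robust (IRLS-weighted)
    delta-method values; NaN when not estimable.
    """

    r: float
    q: float
    A: float = math.nan
    se_r: float = math.nan
    se_q: float = math.nan
    se_A: float = math.nan
    converged: bool = True
    n_iter: int = 0
    n_points: int = 0
    rms: float = math.nan
    window: Optional[Tuple[float, float]] = None

    @classmethod
    def from_combinations(cls, r: float, q: float, A: float = math.nan) -> "FitResult":
        """Wrap externally obtained combinations (e.g. published fit values)."""
        if r <= 0 or q <= 0:
            raise ParameterError("r and q must be positive")
        return cls(r=float(r), q=float(q), A=float(A))

    @property
    def sigma_bound(self) -> float:
        return sigma_upper_bound(self)


def sigma_upper_bound(fit: FitResult) -> float:
    """Upper bound on the sampling fraction, sigma <= q/r (mu >= 0), capped at 1."""
    if not (fit.r > 0 and fit.q > 0):
        raise ParameterError("sigma bound requires positive fitted r and q")
    return min(fit.q / fit.r, 1.0)


def implied_sigma(fit: FitResult, mu_over_lambda: float) -> float:
    """Sampling fraction implied by an assumed turnover ratio mu/lambda.

    sigma = (q/r)(1 - mu/lambda); equals the upper bound at mu = 0 and
    decreases linearly in the assumed ratio.
    """
    if not (0.0 <= mu_over_lambda < 1.0):
        raise ParameterError(f"mu/lambda must lie in [0, 1), got {mu_over_lambda}")
    if not (fit.r > 0 and fit.q > 0):
        raise ParameterError("implied sigma requires positive fitted r and q")
    return min((fit.q / fit.r) * (1.0 - mu_over_lambda), 1.0)


@dataclass(frozen=True)
class BoundClaim:
    """A sampling-fraction bound implied by an interior maximum of a fitted curve."""

    kind: PairStatisticKind
    bound: float
    t_peak: float
    caveat: str = "upper bound assumes μ ≥ 0"

    def __str__(self) -> str:
        return (f"interior maximum of the {self.kind} curve at t = {self.t_peak:.4g} "
                f"implies sigma < {self.bound:.4g} ({self.caveat})")


def maximum_based_sigma_bound(histogram: DistanceHistogram,
                              fit: FitResult) -> Optional[BoundClaim]:
    """Test the fitted curve of the histogram's kind for an interior maximum.

    A maximum of the nearest-neighbour / cherry / min2 curve inside (0, 2T)
    implies sigma < 1/3, 1/4, 1/5 respectively.  The test is run on the
    fitted curve, not the raw counts.  Returns None when the curve is
    monotone over the histogram support.
    """
    kind = histogram.kind
    if kind is None:
        raise ContractError("histogram carries no statistic kind")
    if kind.name == "pairwise":
        raise ContractError("the pairwise curve is monotone for all sigma; no criterion exists")
    if kind.name == "nth_min" and kind.n != 1:
        raise ContractError("the maximum criterion applies to the 1st-nearest curve only")
    hi = float(histogram.edges[-1])
    T = hi / 2.0
    curve = lambda t: float(model_density(kind, fit.r, fit.q,
                                          1.0 if math.isnan(fit.A) else fit.A,
                                          np.asarray(t, float), T=T))
    res = minimize_scalar(lambda t: -curve(t), bounds=(0.0, hi), method="bounded",
                          options={"xatol": 1e-10 * max(1.0, hi)})
    t_peak = float(res.x)
    edge = 1e-5 * hi
    if t_peak <= edge or t_peak >= hi - edge:
        return None
    if curve(t_peak) <= curve(0.0) or curve(t_peak) <= curve(hi):
        return None
    return BoundClaim(kind=kind, bound=_BOUNDS[kind.name], t_peak=t_peak)


# ----------------------------------------------------------------------------
# the IRLS fitter
# ----------------------------------------------------------------------------

def _as_hist_list(histograms) -> List[DistanceHistogram]:
    if isinstance(histograms, DistanceHistogram):
        return [histograms]
    out = list(histograms)
    if not out:
        raise ParameterError("at least one histogram is required")
    return out


def _collect_points(hists: List[DistanceHistogram],
                    window: Optional[Tuple[float, float]],
                    conditional: bool):
    """Flatten histograms into (kind, t, y, dt, hist-index) arrays."""
    pts = []
    for hidx, h in enumerate(hists):
        if h.kind is None:
            raise ParameterError("every fitted histogram must carry its statistic kind")
        t = h.centers
        dt = h.widths
        y = h.density
        mask = np.ones(t.size, bool)
        if window is not None:
            lo, hi = window
            if hi <= lo:
                raise ParameterError(f"empty fit window [{lo}, {hi}]")
            mask &= (t >= lo) & (t <= hi)
        if conditional:
            mask &= h.counts > 0  # the Ntilde regime ignores empty bins
        for i in np.flatnonzero(mask):
            pts.append((h.kind, float(t[i]), float(y[i]), float(dt[i]), hidx))
    return pts


def _initial_guess(pts, T_scale: float) -> Tuple[float, float, float]:
    """Log-linear slope of the pairwise histogram seeds r and q*A; the
    1st-nearest peak location seeds q (falls back to q = r/2)."""
    pw = [(t, y) for k, t, y, _, _ in pts if k.name == "pairwise" and y > 0]
    if len(pw) >= 2:
        t = np.array([p[0] for p in pw])
        ly = np.log([p[1] for p in pw])
        slope, icept = np.polyfit(t, ly, 1)
        r0 = max(2.0 * slope, 0.1 / T_scale)
        qa0 = max(2.0 * math.exp(icept), 1e-12)
    else:
        r0 = 2.0 / T_scale
        qa0 = None
    n1 = [(t, y) for k, t, y, _, _ in pts if k.name == "nth_min" and k.n == 1]
    q0 = None
    if n1:
        n1.sort()
        ts = np.array([p[0] for p in n1])
        ys = np.array([p[1] for p in n1])
        ipk = int(np.argmax(ys))
        if 0 < ipk < ts.size - 1:  # interior peak: invert t_peak = (2/r) ln((r-q)/2q)
            q0 = r0 / (1.0 + 2.0 * math.exp(0.5 * r0 * ts[ipk]))
    if q0 is None:
        q0 = r0 / 2.0
    if qa0 is None:
        y0 = max((y for k, t, y, _, _ in pts if y > 0), default=1.0)
        qa0 = q0 * y0
    return r0, q0, max(qa0 / q0, 1e-12)


def _bisquare(u: np.ndarray) -> np.ndarray:
    w = np.zeros_like(u)
    inside = np.abs(u) < 1.0
    w[inside] = (1.0 - u[inside] ** 2) ** 2
    return w


def fit_densities(histograms: Union[DistanceHistogram, Iterable[DistanceHistogram]],
                  window: Optional[Tuple[float, float]] = None,
                  conditional: bool = False,
                  initializer: Optional[Tuple[float, float, float]] = None,
                  max_iter: int = 100,
                  tol: float = 1e-8) -> FitResult:
    """Jointly fit the analytic curves to one or more distance histograms.

    Each histogram must carry its statistic kind; the curves share (r, q, A).
    ``conditional`` switches the pairwise model from the ensemble mean N to
    the nonzero-bin mean Ntilde and drops empty bins (the single-tree
    regime).  Non-convergence is flagged on the result, never raised.
    """
    hists = _as_hist_list(histograms)
    pts = _collect_points(hists, window, conditional)
    if not pts or all(y == 0 for _, _, y, _, _ in pts):
        return FitResult(r=math.nan, q=math.nan, A=math.nan, converged=False,
                         n_points=len(pts), window=window)
    T_scale = max(h.edges[-1] for h in hists) / 2.0
    kinds = [p[0] for p in pts]
    t = np.array([p[1] for p in pts])
    y = np.array([p[2] for p in pts])
    dt = np.array([p[3] for p in pts])
    hidx = np.array([p[4] for p in pts])
    # A enters only through unconditional curves
    fit_A = not conditional or any(k.name != "pairwise" for k in kinds)
    heights = {i: float(h.edges[-1]) / 2.0 for i, h in enumerate(hists)}

    kind_groups: List[Tuple[PairStatisticKind, bool, np.ndarray]] = []
    seen = {}
    for i, (k, c) in enumerate(zip(kinds, [conditional and k.name == "pairwise"
                                           for k in kinds])):
        key = (str(k), c, heights[hidx[i]] if k.name == "min2" else None)
        seen.setdefault(key, []).append(i)
    for (kname, cond, T_h), idx in seen.items():
        kind_groups.append((kinds[idx[0]], cond, np.array(idx)))

    def model(theta: np.ndarray) -> np.ndarray:
        r = math.exp(theta[0])
        q = math.exp(theta[1])
        A = math.exp(theta[2]) if fit_A else math.nan
        out = np.empty_like(y)
        for k, cond, idx in kind_groups:
            if cond:
                out[idx] = _conditional_model(r, q, t[idx], dt[idx])
            else:
                T_h = heights[hidx[idx[0]]] if k.name == "min2" else None
                out[idx] = model_density(k, r, q, A, t[idx], T=T_h)
        return out

    r0, q0, A0 = initializer if initializer is not None else _initial_guess(pts, T_scale)
    theta = np.log([max(r0, 1e-12), max(q0, 1e-12), max(A0, 1e-12)])
    if not fit_A:
        theta = theta[:2]

        def model2(th):
            return model(np.array([th[0], th[1], 0.0]))
        mfun = model2
    else:
        mfun = model

    # Per-point noise scale: bin densities span orders of magnitude, so the
    # residuals must be standardized before robust weighting.  Ensemble
    # histograms carry an empirical per-bin standard error; otherwise a
    # Poisson-count scale sqrt(model/(width * trees)) is refreshed from the
    # current model each IRLS sweep.
    S_trees = np.array([hists[i].n_trees for i in hidx], float)
    se_emp = np.full(y.size, np.nan)
    for i, h in enumerate(hists):
        se_h = h.density_se
        if se_h is not None:
            m = hidx == i
            se_emp[m] = np.interp(t[m], h.centers, se_h)

    floor = 1e-12 * max(float(np.max(y)), 1.0)

    def point_scale(model_vals: np.ndarray) -> np.ndarray:
        base = np.sqrt(np.maximum(model_vals, floor) / (dt * S_trees))
        s = np.where(np.isfinite(se_emp) & (se_emp > 0), se_emp, base)
        return np.maximum(s, 1e-300)

    w = np.ones_like(y)
    pscale = point_scale(mfun(theta))
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        sw = np.sqrt(np.maximum(w, 1e-12))
        ps = pscale

        def wres(th, _sw=sw, _ps=ps):
            return _sw * (mfun(th) - y) / _ps

        sol = least_squares(wres, theta, method="trf",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        pscale = point_scale(mfun(sol.x))
        res = (mfun(sol.x) - y) / pscale
        mad = float(np.median(np.abs(res - np.median(res))))
        s = mad / 0.6745
        if s <= 1e-10:
            w_new = np.ones_like(y)  # (near-)noiseless data: plain least squares
        else:
            w_new = _bisquare(res / (BISQUARE_C * s))
            if not np.any(w_new > 0):
                w_new = np.ones_like(y)
        delta = float(np.max(np.abs(sol.x - theta))) if n_iter > 1 else math.inf
        theta = sol.x
        w = w_new
        if delta < tol:
            converged = True
            break

    r = math.exp(theta[0])
    q = math.exp(theta[1])
    A = math.exp(theta[2]) if fit_A else math.nan
    res = (mfun(theta) - y) / pscale
    p_par = theta.size
    # heteroscedasticity-robust (sandwich) covariance of the weighted
    # estimating equations, in log-parameter space; the densities span many
    # orders of magnitude so a homoscedastic residual variance would be badly
    # miscalibrated
    res = (mfun(theta) - y) / pscale
    eps = 1e-6
    J = np.empty((y.size, p_par))
    base = mfun(theta)
    for j in range(p_par):
        th = theta.copy()
        th[j] += eps
        J[:, j] = (mfun(th) - base) / eps / pscale
    n_eff = float(np.sum(w > 0))
    dof_corr = n_eff / max(n_eff - p_par, 1.0)
    Jw = J * w[:, None]
    try:
        bread = np.linalg.inv(Jw.T @ J)
        meat = (Jw * (res ** 2)[:, None]).T @ Jw
        cov = dof_corr * bread @ meat @ bread.T
        se_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_log = np.full(p_par, math.nan)
    se_r = r * se_log[0]
    se_q = q * se_log[1]
    se_A = A * se_log[2] if fit_A else math.nan
    ok = converged and math.isfinite(r) and math.isfinite(q) and r > 0 and q > 0
    rms = math.sqrt(float(np.mean(res ** 2)))
    return FitResult(r=r, q=q, A=A, se_r=se_r, se_q=se_q, se_A=se_A,
                     converged=bool(ok), n_iter=n_iter, n_points=y.size,
                     rms=rms, window=window)
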