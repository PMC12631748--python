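"""Estimation stage: Nallet-model fits, thickness and swelling regressions.

The three estimators follow the scikit-learn protocol (``fit``,
``predict`` where meaningful, ``get_params``/``set_params``, fitted
attributes with a trailing underscore) so they compose with sklearn
pipelines and model selection.  The module-level functions
(:func:`fit_nallet`, :func:`estimate_thickness_kratky`,
:func:`fit_swelling`) are thin wrappers over them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, optimize, signal, stats
from sklearn.base import BaseEstimator

from .datatypes import NalletParameters, ScatteringCurve, _require
from .models import nallet_intensity

__all__ = [
    "FitResult",
    "ThicknessEstimate",
    "SwellingFit",
    "ThicknessNotDeterminableError",
    "NalletFitter",
    "KratkyPorodThickness",
    "SwellingLawFit",
    "fit_nallet",
    "estimate_thickness_kratky",
    "fit_swelling",
    "detect_bragg_peak",
    "porod_representation",
    "highq_overlap_metric",
]


class ThicknessNotDeterminableError(ValueError):
    """Raised when the Kratky–Porod slope is non-negative (no thin-sheet
    decay in the chosen window: non-lamellar signal or wrong window)."""


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a Nallet-model fit.

    ``uncertainties`` holds one standard error per parameter in the order
    (A_z, xi_p, A_B, xi_l, q0[, background]); NaN marks a direction in
    which the covariance is singular — rendered "N.D." in reports.
    """

    parameters: NalletParameters
    uncertainties: np.ndarray
    chi2_reduced: float
    q_window: Tuple[float, float]
    converged: bool
    n_points: int = 0
    cost: float = np.nan

    def is_determined(self) -> np.ndarray:
        return np.isfinite(self.uncertainties)


@dataclass
class ThicknessEstimate:
    """Bilayer thickness from the ln(q²I/ϕ) vs q² regression."""

    delta: float
    delta_err: float
    q_window: Tuple[float, float]
    r_squared: float


@dataclass
class SwellingFit:
    """Dry bilayer thickness from the dilution law d = δ/ϕ."""

    delta: float
    delta_err: float
    points: np.ndarray  # (n, 2) array of (phi, d)
    intercept: float = 0.0


# ---------------------------------------------------------------------------
# peak detection and representations
# ---------------------------------------------------------------------------

def detect_bragg_peak(curve: ScatteringCurve, prominence_factor: float = 3.0,
                      window: int = 15) -> Optional[float]:
    """Locate the first-order Bragg peak, or report that none exists.

    Works on the Porod representation y = q²I(q), where the q⁻² thin-sheet
    decay is flattened and structure-factor maxima stand out.  A local
    maximum is accepted when its prominence exceeds ``prominence_factor``
    times the robust local fluctuation scale of y (median absolute
    deviation of y about its running median over ``window`` points).  The
    reported position is then refined to the local maximum of I(q) itself
    near the accepted peak: the q² weighting skews the apex of a
    resolution-broadened peak upward on a log grid, while the intensity
    maximum stays on the Bragg position.  Returns the grid q of the
    winning maximum, or None — absence is a valid result: dilute stacks
    with strong undulations show no peak at all.
    """
    _require(len(curve) >= 20, "need at least 20 points for peak detection")
    y = curve.q**2 * curve.intensity
    peaks, props = signal.find_peaks(y, prominence=0.0)
    if peaks.size == 0:
        return None
    running_med = ndimage.median_filter(y, size=window, mode="nearest")
    resid = y - running_med
    scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    threshold = prominence_factor * max(scale, 1e-12 * float(np.max(y)))
    keep = props["prominences"] >= threshold
    if not np.any(keep):
        return None
    best = int(peaks[keep][np.argmax(props["prominences"][keep])])
    lo, hi = max(best - window // 2, 0), min(best + window // 2 + 1, y.size)
    local, _ = signal.find_peaks(curve.intensity[lo:hi])
    if local.size:
        best = lo + int(local[np.argmax(curve.intensity[lo:hi][local])])
    return float(curve.q[best])


def porod_representation(curve: ScatteringCurve, phi: float) -> ScatteringCurve:
    """Transform a curve to the bilayer representation (q, q²I/ϕ).

    Flattens the q⁻² decay of thin sheets so that curves of equal bilayer
    thickness collapse at high q regardless of concentration, and
    amplifies higher-order Bragg reflections.
    """
    _require(np.isfinite(phi) and phi > 0.0, "phi must be positive")
    factor = curve.q**2 / phi
    return ScatteringCurve(
        curve.q,
        factor * curve.intensity,
        None if curve.sigma is None else factor * curve.sigma,
        label=(curve.label + " [q^2 I/phi]").strip(),
        meta=dict(curve.meta),
    )


def highq_overlap_metric(curve_a: ScatteringCurve, curve_b: ScatteringCurve,
                         q_threshold: float) -> float:
    """Median relative discrepancy of two transformed curves above a q cut.

    Both curves are interpolated onto the merged q grid of their common
    support above ``q_threshold``; the statistic is the median of
    |a − b| / min(a, b), which is symmetric in its arguments, zero for
    identical curves and c − 1 for a constant ratio c.
    """
    lo = max(q_threshold, float(curve_a.q[0]), float(curve_b.q[0]))
    hi = min(float(curve_a.q[-1]), float(curve_b.q[-1]))
    if lo >= hi:
        raise ValueError("curves have no common q support above q_threshold")
    grid = np.union1d(curve_a.q, curve_b.q)
    grid = grid[(grid >= lo) & (grid <= hi)]
    ya = np.interp(grid, curve_a.q, curve_a.intensity)
    yb = np.interp(grid, curve_b.q, curve_b.intensity)
    denom = np.maximum(np.minimum(np.abs(ya), np.abs(yb)), 1e-300)
    return float(np.median(np.abs(ya - yb) / denom))


# ---------------------------------------------------------------------------
# Nallet-model fitter
# ---------------------------------------------------------------------------

def _initial_guess(q: np.ndarray, intensity: np.ndarray,
                   fit_background: bool) -> Tuple[NalletParameters, bool]:
    """Heuristic starting point; returns (params, bragg_frozen).

    q0 from the most prominent peak of q²I (if any, else the Bragg term is
    frozen at zero); xi_l from the peak width; diffuse amplitude and
    correlation length from a linearised Lorentzian fit to the lowest
    decade of q; background from the high-q tail.
    """
    background = float(np.median(intensity[q >= 0.9 * q[-1]])) if fit_background else 0.0

    curve = ScatteringCurve(q, np.maximum(intensity, 0.0))
    q_peak = detect_bragg_peak(curve) if len(curve) >= 20 else None

    # diffuse term from the lowest decade: 1/(I - bkg) is linear in q²
    low = q <= 10.0 * q[0]
    if q_peak is not None:
        low &= q < 0.7 * q_peak
    if np.count_nonzero(low) >= 3:
        y = np.maximum(intensity[low] - background, 1e-12)
        res = stats.linregress(q[low] ** 2, 1.0 / y)
        if res.intercept > 0 and res.slope > 0:
            A_z0 = 1.0 / res.intercept
            xi_p0 = float(np.sqrt(res.slope / res.intercept))
        else:
            A_z0 = max(float(y[0]), 1e-6)
            xi_p0 = 1.0 / float(np.median(q))
    else:
        A_z0 = max(float(intensity[0] - background), 1e-6)
        xi_p0 = 1.0 / float(np.median(q))

    if q_peak is None:
        return NalletParameters(A_z0, xi_p0, 0.0, 0.0, 0.0, background), True

    idx = int(np.argmin(np.abs(q - q_peak)))
    y2 = q**2 * intensity
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-width peaks are handled below
            widths = signal.peak_widths(y2, [idx], rel_height=0.5)[0]
        fwhm = float(widths[0]) * float(np.median(np.diff(q)))
    except ValueError:
        fwhm = 0.0
    xi_l0 = 2.0 / fwhm if fwhm > 0 else 10.0 / q_peak
    diffuse_at_peak = A_z0 / (1.0 + (q_peak * xi_p0) ** 2)
    A_B0 = max(float(intensity[idx]) - background - diffuse_at_peak, 1e-3 * A_z0 + 1e-6)
    return NalletParameters(A_z0, xi_p0, A_B0, xi_l0, q_peak, background), False


class NalletFitter(BaseEstimator):
    """Bounded nonlinear least-squares fit of the lamellar lineshape.

    Parameters
    ----------
    initial : NalletParameters, optional
        Starting point; derived heuristically from the data when absent.
    q_window : (float, float), optional
        Fit range in Å⁻¹; full range when absent.
    fit_background : bool
        Free the constant incoherent background (default False: the bare
        five-parameter model).
    n_restarts : int
        Number of jittered restarts around the starting point; the lowest
        cost wins.
    jitter : float
        Relative half-width of the multiplicative restart jitter.
    jitter_initial : bool
        Also jitter the very first start (used for identifiability
        exercises where the starting point is the ground truth).
    random_state : int
        Seed for the restart jitter.

    Attributes
    ----------
    parameters_ : NalletParameters
    uncertainties_ : ndarray
        Standard errors, NaN where the covariance is singular ("N.D.").
    chi2_reduced_ : float
    converged_ : bool
    result_ : FitResult
    """

    _THETA_NAMES = ("A_z", "xi_p", "A_B", "xi_l", "q0", "background")

    def __init__(self, initial: Optional[NalletParameters] = None,
                 q_window: Optional[Tuple[float, float]] = None,
                 fit_background: bool = False, n_restarts: int = 5,
                 jitter: float = 0.2, jitter_initial: bool = False,
                 random_state: int = 0):
        self.initial = initial
        self.q_window = q_window
        self.fit_background = fit_background
        self.n_restarts = n_restarts
        self.jitter = jitter
        self.jitter_initial = jitter_initial
        self.random_state = random_state

    # -- internals --------------------------------------------------------

    def _unpack(self, q, intensity, sigma):
        if isinstance(q, ScatteringCurve):
            curve = q
            return curve.q, curve.intensity, curve.sigma
        q = np.asarray(q, dtype=float).ravel()
        _require(intensity is not None, "intensity must be provided with a bare q array")
        intensity = np.asarray(intensity, dtype=float).ravel()
        if sigma is not None:
            sigma = np.asarray(sigma, dtype=float).ravel()
        return q, intensity, sigma

    @staticmethod
    def _model(theta: np.ndarray, q: np.ndarray, frozen_bragg: bool) -> np.ndarray:
        A_z, xi_p, A_B, xi_l, q0, background = theta
        if frozen_bragg:
            A_B = 0.0
        diffuse = A_z / (1.0 + (q * xi_p) ** 2)
        bragg = A_B / (1.0 + ((q - q0) * xi_l) ** 2)
        return diffuse + bragg + background

    def fit(self, q, intensity=None, sigma=None):
        """Fit the model to one curve.

        ``q`` may be a :class:`ScatteringCurve` (then ``intensity`` and
        ``sigma`` are taken from it) or a bare array with ``intensity``
        (and optional ``sigma``) alongside.  Weights are 1/σ² when
        uncertainties are present, unweighted otherwise.
        """
        q, intensity, sigma = self._unpack(q, intensity, sigma)
        if self.q_window is not None:
            m = (q >= self.q_window[0]) & (q <= self.q_window[1])
            q, intensity = q[m], intensity[m]
            sigma = None if sigma is None else sigma[m]
        _require(q.size >= 10, "need at least 10 points in the fit window")
        window = (float(q[0]), float(q[-1]))

        weights = np.ones_like(q)
        if sigma is not None:
            pos = sigma > 0
            weights = np.where(pos, 1.0 / np.where(pos, sigma, 1.0), 1.0)

        if self.initial is not None:
            init, frozen_bragg = self.initial, False
        else:
            init, frozen_bragg = _initial_guess(q, intensity, self.fit_background)

        theta0 = np.array([init.A_z, init.xi_p, init.A_B, init.xi_l, init.q0,
                           init.background])
        free = np.ones(6, dtype=bool)
        free[5] = self.fit_background
        if frozen_bragg:
            free[2] = free[3] = free[4] = False

        lower = np.zeros(6)
        upper = np.array([np.inf, np.inf, np.inf, np.inf, 2.0 * float(q[-1]), np.inf])
        theta0 = np.clip(theta0, lower, upper)

        def residual(free_theta, base):
            theta = base.copy()
            theta[free] = free_theta
            return (self._model(theta, q, frozen_bragg) - intensity) * weights

        rng = np.random.default_rng(self.random_state)
        best = None
        for restart in range(max(1, int(self.n_restarts))):
            start = theta0.copy()
            if restart > 0 or self.jitter_initial:
                factor = rng.uniform(1.0 - self.jitter, 1.0 + self.jitter, size=6)
                start = np.clip(start * factor, lower, upper)
            x0 = start[free]
            scale = np.maximum(np.abs(x0), 1e-8)
            try:
                res = optimize.least_squares(
                    residual, x0, args=(start,),
                    bounds=(lower[free], upper[free]),
                    x_scale=scale, method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception:
                continue
            if best is None or res.cost < best[0].cost:
                best = (res, start)
        if best is None:
            raise RuntimeError("Nallet fit failed in every restart")
        res, base = best

        theta = base.copy()
        theta[free] = res.x
        if frozen_bragg:
            theta[2] = theta[3] = theta[4] = 0.0
        params = NalletParameters(*theta)

        n, p = q.size, int(np.count_nonzero(free))
        dof = max(n - p, 1)
        rss = 2.0 * res.cost
        chi2_reduced = rss / dof

        uncertainties = np.full(6, np.nan)
        jac = res.jac
        if jac.size:
            u, s, vt = np.linalg.svd(jac, full_matrices=False)
            tol = s[0] * max(jac.shape) * np.finfo(float).eps if s.size else 0.0
            s_inv2 = np.where(s > tol, 1.0 / np.where(s > tol, s, 1.0) ** 2, 0.0)
            cov = (vt.T * s_inv2) @ vt * chi2_reduced
            determined = np.ones(p, dtype=bool)
            if np.any(s <= tol):
                null_proj = np.sum(vt[s <= tol] ** 2, axis=0)
                determined = null_proj < 1e-8
            err = np.sqrt(np.maximum(np.diag(cov), 0.0))
            err[~determined] = np.nan
            uncertainties[free] = err
        # structurally frozen parameters are not determined at all
        uncertainties[~free] = np.nan

        self.parameters_ = params
        self.uncertainties_ = uncertainties
        self.chi2_reduced_ = float(chi2_reduced)
        self.converged_ = bool(res.success)
        self.n_features_in_ = 1
        self.result_ = FitResult(
            parameters=params, uncertainties=uncertainties,
            chi2_reduced=float(chi2_reduced), q_window=window,
            converged=bool(res.success), n_points=n, cost=float(res.cost),
        )
        if not res.success:
            warnings.warn("Nallet fit did not report convergence; best candidate kept",
                          RuntimeWarning)
        return self

    def predict(self, q) -> np.ndarray:
        """Model intensity at ``q`` for the fitted parameters."""
        if not hasattr(self, "parameters_"):
            raise AttributeError("fit must be called before predict")
        q = q.q if isinstance(q, ScatteringCurve) else np.asarray(q, dtype=float)
        return nallet_intensity(q, self.parameters_)


# ---------------------------------------------------------------------------
# thickness and swelling estimators
# ---------------------------------------------------------------------------

class KratkyPorodThickness(BaseEstimator):
    """Bilayer thickness from the thin-sheet representation.

    Least-squares line through (q², ln(q²I/ϕ)) inside ``q_window``; the
    slope −δ²/12 of the Guinier expansion gives δ = √(−12·slope).
    Normalising by ϕ removes the concentration dependence, so curves of a
    dilution series give the same thickness.  Scaling the intensity by
    any positive constant shifts the line vertically and leaves δ
    unchanged.

    Attributes: ``delta_`` (Å), ``delta_err_`` (Å, propagated from the
    slope standard error), ``r_squared_``, ``estimate_``.
    """

    def __init__(self, phi: float = 1.0,
                 q_window: Optional[Tuple[float, float]] = None):
        self.phi = phi
        self.q_window = q_window

    def fit(self, q, intensity=None):
        _require(np.isfinite(self.phi) and self.phi > 0.0, "phi must be positive")
        if isinstance(q, ScatteringCurve):
            q, intensity = q.q, q.intensity
        q = np.asarray(q, dtype=float).ravel()
        intensity = np.asarray(intensity, dtype=float).ravel()
        if self.q_window is not None:
            _require(self.q_window[0] >= q[0] - 1e-12 and self.q_window[1] <= q[-1] + 1e-12,
                     "q_window must lie inside the curve span")
            m = (q >= self.q_window[0]) & (q <= self.q_window[1])
            q, intensity = q[m], intensity[m]
        _require(q.size >= 3, "need at least 3 points in the regression window")
        _require(np.all(intensity > 0.0), "intensity must be positive inside the window")

        x = q**2
        y = np.log(x * intensity / self.phi)
        res = stats.linregress(x, y)
        if not res.slope < 0.0:
            raise ThicknessNotDeterminableError(
                "non-negative Kratky-Porod slope: no thickness determinable "
                "(non-lamellar signal or wrong q window)")
        delta = float(np.sqrt(-12.0 * res.slope))
        stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
        delta_err = 6.0 * stderr / delta
        self.delta_ = delta
        self.delta_err_ = delta_err
        self.r_squared_ = float(res.rvalue**2)
        self.estimate_ = ThicknessEstimate(delta, delta_err,
                                           (float(q[0]), float(q[-1])),
                                           self.r_squared_)
        return self


class SwellingLawFit(BaseEstimator):
    """Dry bilayer thickness from a dilution series, d = δ/ϕ.

    Through-origin least squares of the repeat distance d on 1/ϕ by
    default — the swelling law has no intercept; set
    ``through_origin=False`` for the diagnostic free-intercept variant.

    Attributes: ``delta_`` (Å), ``delta_err_`` (Å), ``intercept_`` (Å),
    ``fit_``.
    """

    def __init__(self, through_origin: bool = True):
        self.through_origin = through_origin

    def fit(self, phi, d=None):
        if d is None:
            pts = np.asarray(phi, dtype=float)
            _require(pts.ndim == 2 and pts.shape[1] == 2,
                     "points must be an (n, 2) array of (phi, d)")
            phi, d = pts[:, 0], pts[:, 1]
        phi = np.asarray(phi, dtype=float).ravel()
        d = np.asarray(d, dtype=float).ravel()
        _require(phi.size == d.size, "phi and d must have equal length")
        _require(phi.size >= 1, "need at least one (phi, d) point")
        _require(np.all(phi > 0.0) and np.all(phi < 1.0), "phi must lie in (0, 1)")
        _require(np.unique(phi).size == phi.size, "phi values must be distinct")

        x = 1.0 / phi
        if self.through_origin or phi.size == 1:
            slope = float(np.sum(x * d) / np.sum(x * x))
            resid = d - slope * x
            if phi.size > 1:
                err = float(np.sqrt(np.sum(resid**2) / ((phi.size - 1) * np.sum(x * x))))
            else:
                err = 0.0
            intercept = 0.0
        else:
            _require(phi.size >= 2, "free-intercept fit needs at least 2 points")
            res = stats.linregress(x, d)
            slope, intercept = float(res.slope), float(res.intercept)
            err = float(res.stderr) if np.isfinite(res.stderr) else 0.0
        self.delta_ = slope
        self.delta_err_ = err
        self.intercept_ = intercept
        self.fit_ = SwellingFit(slope, err, np.column_stack([phi, d]), intercept)
        return self


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_nallet(curve: ScatteringCurve,
               initial: Optional[NalletParameters] = None,
               q_window: Optional[Tuple[float, float]] = None,
               **kwargs) -> FitResult:
    """Fit the lamellar lineshape to one curve; see :class:`NalletFitter`."""
    fitter = NalletFitter(initial=initial, q_window=q_window, **kwargs)
    return fitter.fit(curve).result_


def estimate_thickness_kratky(curve: ScatteringCurve, phi: float,
                              q_window: Tuple[float, float]) -> ThicknessEstimate:
    """Bilayer thickness via the ln(q²I/ϕ) vs q² regression; see
    :class:`KratkyPorodThickness`."""
    est = KratkyPorodThickness(phi=phi, q_window=q_window)
    return est.fit(curve).estimate_


def fit_swelling(points: Sequence[Tuple[float, float]],
                 through_origin: bool = True) -> SwellingFit:
    """Swelling-law fit of (ϕ, d) pairs; see :class:`SwellingLawFit`."""
    pts = np.asarray(list(points), dtype=float)
    if pts.size == 0:
        raise ValueError("need at least one (phi, d) point")
    return SwellingLawFit(through_origin=through_origin).fit(pts).fit_
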