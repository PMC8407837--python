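"""Grid-constrained Gauss-Newton fitting against lookup-table templates.

Each detected candidate gets a square window (matching the template size)
fitted with the five-parameter model

    I_ij = theta_bg + theta_p * PSF_ij(theta_x, theta_y, theta_z)

where bg (mean background) and p (peak intensity) are unconstrained and
the position parameters are constrained to the lookup-table grid: after
every Gauss-Newton update they are rounded to the nearest grid step and
the template index is refreshed.  Iteration stops on convergence, on
leaving the lateral/axial grid range, or at the iteration cap (default 5;
the discretization stabilizes the fit enough that a handful of iterations
suffices and avoids local minima).

A continuous (unconstrained) elliptical-Gaussian least-squares fitter is
provided as a reference implementation for benchmarking the discrete
method against.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .detection import Candidate, find_candidates
from .lookup_table import GridRangeError, LookupTable, template_at
from .psf_model import psf_gradient, psf_value


class Termination(enum.Enum):
    CONVERGED = "converged"
    MAX_ITERATIONS = "max_iterations"
    LEFT_LATERAL_RANGE = "left_lateral_range"
    LEFT_AXIAL_RANGE = "left_axial_range"
    DEGENERATE = "degenerate"


@dataclass(frozen=True)
class FitParams:
    """Model parameters: background/peak in counts, x/y in pixels, z in nm."""

    bg: float
    p: float
    x: float
    y: float
    z: float


@dataclass(frozen=True)
class FitResult:
    params: FitParams
    frame_index: int
    n_iterations: int
    termination: Termination
    residual_norm: float
    crlb: tuple[float, float, float, float, float] | None = None


@dataclass(frozen=True)
class DetectionConfig:
    threshold: float = 200.0
    suppression_radius: float = 9.0
    bg_window: int = 10


@dataclass(frozen=True)
class FitConfig:
    max_iterations: int = 5
    tol: float = 1e-3
    compute_crlb: bool = True
    excess_noise_factor: float = 1.0


class DegenerateFitError(RuntimeError):
    """Singular normal equations; treated as a non-converged fit."""


def _snap(table: LookupTable, x: float, y: float, z: float):
    """Round a position to the nearest grid step (half away from center)."""
    spec = table.spec
    c = spec.center
    zc = table.calib.z_focus

    def rnd(t: float) -> float:
        return np.sign(t) * np.floor(abs(t) + 0.5)

    return (c + rnd((x - c) / spec.dxy) * spec.dxy,
            c + rnd((y - c) / spec.dxy) * spec.dxy,
            zc + rnd((z - zc) / spec.dz) * spec.dz)


def _jacobian(table: LookupTable, theta: FitParams):
    k = table.index_of(theta.x, theta.y, theta.z)
    t, tx, ty, tz = template_at(table, k)
    n = t.size
    J = np.empty((n, 5))
    J[:, 0] = 1.0
    J[:, 1] = t.ravel()
    J[:, 2] = theta.p * tx.ravel()
    J[:, 3] = theta.p * ty.ravel()
    J[:, 4] = theta.p * tz.ravel()
    return J, t


def _initial_peak(table: LookupTable, candidate: Candidate) -> float:
    """Initial theta_p from the candidate's NMS estimates.

    Prefers the 3x3-mean score, scaled by the peak/(3x3 mean) ratio of the
    in-focus template so it is an unbiased peak estimate with a third of
    the single-pixel noise; falls back to the raw peak when no score is
    attached.
    """
    bg = candidate.background_estimate
    if candidate.score is None:
        return max(candidate.peak_estimate - bg, 1.0)
    gain = getattr(table, "_p_init_gain", None)
    if gain is None:
        spec = table.spec
        c = spec.center
        k0 = table.index_of(c, c, table.calib.z_focus)
        t = table.templates[k0, :, :, 0]
        m = spec.window // 2
        gain = 1.0 / float(t[m - 1:m + 2, m - 1:m + 2].mean())
        table._p_init_gain = gain
    return max((candidate.score - bg) * gain, 1.0)


def gauss_newton_step(window: np.ndarray, table: LookupTable,
                      theta: FitParams) -> tuple[FitParams, float]:
    """One Gauss-Newton update of all five parameters.

    Builds the Jacobian from the template at the current grid index, forms
    the residual ``r = I - (bg + p * template)``, solves the symmetric 5x5
    normal equations ``(J^T J) delta = J^T r`` and applies the update; the
    positional components are rounded back to the grid before returning.
    Raises :class:`DegenerateFitError` on singular normal equations.
    """
    J, t = _jacobian(table, theta)
    r = np.asarray(window, float).ravel() - (theta.bg + theta.p * t.ravel())
    A = J.T @ J
    b = J.T @ r
    try:
        delta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise DegenerateFitError(str(exc)) from exc
    if not np.all(np.isfinite(delta)):
        raise DegenerateFitError("non-finite update")
    x, y, z = _snap(table, theta.x + delta[2], theta.y + delta[3],
                    theta.z + delta[4])
    new = FitParams(theta.bg + delta[0], theta.p + delta[1], x, y, z)
    return new, float(np.linalg.norm(r))


def fit_emitter(window: np.ndarray, table: LookupTable, candidate: Candidate,
                max_iterations: int = 5, tol: float = 1e-3,
                compute_crlb: bool = True,
                excess_noise_factor: float = 1.0) -> FitResult:
    """Fit one candidate window; returns the result in frame coordinates.

    Initialization: x, y at the window center, z at the calibration focal
    plane, bg and p from the candidate's NMS estimates.  Convergence is
    declared when the rounded position is unchanged and the relative
    changes of bg and p fall below ``tol``.  Reaching the iteration cap is
    a normal termination (the grid constraint can cycle between two
    adjacent steps forever); in that case, as on convergence, the visited
    iterate with the smallest residual norm is returned as the best fit.
    Only range exits and degenerate normal equations mark a failed fit.
    """
    spec = table.spec
    c = spec.center
    half_xy = spec.rxy / 2.0 + 1e-9
    half_z = spec.rz / 2.0 + 1e-9
    zc = table.calib.z_focus
    theta = FitParams(candidate.background_estimate,
                      _initial_peak(table, candidate), c, c, zc)
    termination = Termination.MAX_ITERATIONS
    n_iter = 0
    best: FitParams | None = None
    best_norm = np.inf
    for s in range(max_iterations):
        try:
            new, res_norm = gauss_newton_step(window, table, theta)
        except (DegenerateFitError, GridRangeError):
            termination = Termination.DEGENERATE
            n_iter = s
            break
        # the residual was evaluated at the entry iterate; the lowest one
        # seen is "the best fit" among the visited grid positions
        if res_norm < best_norm:
            best, best_norm = theta, res_norm
        n_iter = s + 1
        if abs(new.x - c) > half_xy or abs(new.y - c) > half_xy:
            theta = new
            termination = Termination.LEFT_LATERAL_RANGE
            break
        if abs(new.z - zc) > half_z:
            theta = new
            termination = Termination.LEFT_AXIAL_RANGE
            break
        pos_fixed = (new.x == theta.x and new.y == theta.y and new.z == theta.z)
        bg_ok = abs(new.bg - theta.bg) <= tol * max(abs(theta.bg), 1.0)
        p_ok = abs(new.p - theta.p) <= tol * max(abs(theta.p), 1.0)
        theta = new
        if pos_fixed and bg_ok and p_ok:
            termination = Termination.CONVERGED
            break
    if termination in (Termination.CONVERGED, Termination.MAX_ITERATIONS):
        norm = _residual_norm(window, table, theta)
        if norm is not None and norm < best_norm:
            best, best_norm = theta, norm
        theta, res_norm = best, best_norm
    else:
        res_norm = best_norm

    bounds = None
    if compute_crlb and termination in (Termination.CONVERGED,
                                        Termination.MAX_ITERATIONS):
        bounds = crlb(theta, table, excess_noise_factor=excess_noise_factor)
    # convert window coordinates to frame coordinates
    m = spec.window // 2
    frame_params = replace(theta, x=theta.x + candidate.px - m,
                           y=theta.y + candidate.py - m)
    return FitResult(frame_params, candidate.frame_index, n_iter,
                     termination, res_norm, bounds)


def _residual_norm(window: np.ndarray, table: LookupTable,
                   theta: FitParams) -> float | None:
    try:
        k = table.index_of(theta.x, theta.y, theta.z)
    except GridRangeError:
        return None
    t = table.templates[k, :, :, 0]
    r = np.asarray(window, float) - (theta.bg + theta.p * t)
    return float(np.linalg.norm(r))


def crlb(theta: FitParams, table: LookupTable,
         excess_noise_factor: float = 1.0):
    """Cramér-Rao lower bounds for the five fit parameters.

    The Fisher information is built from the template and its derivatives
    under independent per-pixel Poisson statistics on the expected counts
    ``mu = bg + p * template``; with ``excess_noise_factor`` > 1 the
    variance is inflated accordingly (EMCCD multiplication noise doubles
    the Poisson variance).  Returns (s_bg, s_p, s_x px, s_y px, s_z nm),
    or None when the information matrix is not invertible.
    """
    try:
        J, t = _jacobian(table, theta)
    except GridRangeError:
        return None
    mu = theta.bg + theta.p * t.ravel()
    if np.any(mu <= 0):
        return None
    W = J / (excess_noise_factor * mu)[:, None]
    info = J.T @ W
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None
    d = np.diag(cov)
    if np.any(d <= 0):
        return None
    return tuple(np.sqrt(d))


def extract_window(frame: np.ndarray, candidate: Candidate,
                   window: int) -> np.ndarray:
    m = window // 2
    return np.asarray(
        frame[candidate.px - m:candidate.px + m + 1,
              candidate.py - m:candidate.py + m + 1], float)


def fit_frame(frame: np.ndarray, table: LookupTable,
              detection: DetectionConfig = DetectionConfig(),
              fit: FitConfig = FitConfig(), frame_index: int = 0,
              diagnostics: dict | None = None) -> list[FitResult]:
    """Detect and fit every candidate in one frame (deterministic).

    Returns the accepted fits only (terminated by convergence or by the
    iteration cap, with positive peak and position inside the grid);
    range exits and degenerate fits are tallied into ``diagnostics`` when
    a dict is supplied.
    """
    cands = find_candidates(frame, detection.suppression_radius,
                            detection.threshold, detection.bg_window,
                            fit_window=table.spec.window,
                            frame_index=frame_index)
    accepted: list[FitResult] = []
    tally: dict[str, int] = {}
    for cand in cands:
        win = extract_window(frame, cand, table.spec.window)
        result = fit_emitter(win, table, cand, fit.max_iterations, fit.tol,
                             fit.compute_crlb, fit.excess_noise_factor)
        if (result.termination in (Termination.CONVERGED,
                                   Termination.MAX_ITERATIONS)
                and result.params.p > 0):
            accepted.append(result)
        tally[result.termination.value] = tally.get(result.termination.value, 0) + 1
    if diagnostics is not None:
        diagnostics["n_candidates"] = diagnostics.get("n_candidates", 0) + len(cands)
        diagnostics["n_accepted"] = diagnostics.get("n_accepted", 0) + len(accepted)
        for key, v in tally.items():
            diagnostics[key] = diagnostics.get(key, 0) + v
    return accepted


# ---------------------------------------------------------------------------
# Continuous reference fitter
# ---------------------------------------------------------------------------

def fit_emitter_continuous(window: np.ndarray, table: LookupTable,
                           candidate: Candidate,
                           max_nfev: int = 100) -> FitResult:
    """Unconstrained continuous least-squares fit of the same 5-parameter model.

    Uses the analytic elliptical-Gaussian model directly (no grid) with the
    same width calibration; serves as the reference the discrete fitter is
    benchmarked against.  z stays bounded to the calibrated axial span of
    the grid so both fitters explore the same axial range.
    """
    spec = table.spec
    calib = table.calib
    w = spec.window
    c = spec.center
    zc = calib.z_focus
    data = np.asarray(window, float).ravel()
    px = np.arange(w, dtype=float)
    ii = px[:, None]
    jj = px[None, :]

    def resid(q):
        bg, p, x, y, z = q
        return bg + p * psf_value(x, y, z, calib, ii, jj).ravel() - data

    def jac(q):
        bg, p, x, y, z = q
        t = psf_value(x, y, z, calib, ii, jj).ravel()
        gx, gy, gz = psf_gradient(x, y, z, calib, ii, jj)
        J = np.empty((t.size, 5))
        J[:, 0] = 1.0
        J[:, 1] = t
        J[:, 2] = p * gx.ravel()
        J[:, 3] = p * gy.ravel()
        J[:, 4] = p * gz.ravel()
        return J

    bg0 = candidate.background_estimate
    p0 = _initial_peak(table, candidate)
    lo = [-np.inf, 0.0, c - spec.rxy / 2, c - spec.rxy / 2, zc - spec.rz / 2]
    hi = [np.inf, np.inf, c + spec.rxy / 2, c + spec.rxy / 2, zc + spec.rz / 2]
    res = least_squares(resid, [bg0, p0, c, c, zc], jac=jac,
                        bounds=(lo, hi), max_nfev=max_nfev)
    bg, p, x, y, z = res.x
    on_bound = (abs(x - c) >= spec.rxy / 2 - 1e-9
                or abs(y - c) >= spec.rxy / 2 - 1e-9)
    z_on_bound = abs(z - zc) >= spec.rz / 2 - 1e-9
    if not res.success:
        term = Termination.MAX_ITERATIONS
    elif on_bound:
        term = Termination.LEFT_LATERAL_RANGE
    elif z_on_bound:
        term = Termination.LEFT_AXIAL_RANGE
    else:
        term = Termination.CONVERGED
    m = w // 2
    params = FitParams(bg, p, x + candidate.px - m, y + candidate.py - m, z)
    return FitResult(params, candidate.frame_index, int(res.nfev), term,
                     float(np.linalg.norm(res.fun)), None)


def fit_frame_continuous(frame: np.ndarray, table: LookupTable,
                         detection: DetectionConfig = DetectionConfig(),
                         frame_index: int = 0) -> list[FitResult]:
    """Continuous-reference analogue of :func:`fit_frame`."""
    cands = find_candidates(frame, detection.suppression_radius,
                            detection.threshold, detection.bg_window,
                            fit_window=table.spec.window,
                            frame_index=frame_index)
    out = []
    for cand in cands:
        win = extract_window(frame, cand, table.spec.window)
        result = fit_emitter_continuous(win, table, cand)
        if result.termination is Termination.CONVERGED and result.params.p > 0:
            out.append(result)
    return out
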