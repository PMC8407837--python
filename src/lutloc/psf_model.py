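"""Astigmatic elliptical-Gaussian PSF model and its calibration.

In astigmatic 3D SMLM a cylindrical lens makes the widths of the emitter
image depend on defocus with opposite signs, so the pair ``(sigma_x(z),
sigma_y(z))`` encodes the axial position.  This module defines the
unit-peak elliptical Gaussian PSF, its analytic partial derivatives with
respect to the emitter position (needed by the Gauss-Newton fitter), a
pixel-integrated variant, and the calibration of the width curves from a
bead z-stack.

Coordinate convention (used throughout the package): pixel centers sit at
integer coordinates, lateral positions are in pixel units (0-based), and z
is in nanometers relative to the stage zero of the calibration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline, make_interp_spline, make_lsq_spline
from scipy.ndimage import maximum_filter
from scipy.optimize import least_squares
from scipy.special import ndtr


class ZRangeError(ValueError):
    """Axial position outside the calibrated range (never extrapolated)."""


class CalibrationError(RuntimeError):
    """Bead calibration could not be performed."""


@dataclass
class AstigmaticCalibration:
    """The z -> PSF-shape map obtained from a bead z-stack.

    Attributes
    ----------
    sigma_x_curve, sigma_y_curve : scipy.interpolate.BSpline
        Cubic B-splines mapping z (nm) to Gaussian widths (pixels).
    phi : float
        Clockwise rotation of the elliptical Gaussian, radians.
    z_range : tuple of float
        (z_min, z_max) in nm over which the splines are valid.
    z_focus : float
        z of best overall focus (argmin of sigma_x*sigma_y), nm.
    pixel_size_nm : float
        Lateral image pixel size, nm per pixel.
    """

    sigma_x_curve: BSpline
    sigma_y_curve: BSpline
    phi: float
    z_range: tuple[float, float]
    z_focus: float
    pixel_size_nm: float = 100.0
    _dsx: BSpline = field(init=False, repr=False)
    _dsy: BSpline = field(init=False, repr=False)

    def __post_init__(self) -> None:
        zmin, zmax = self.z_range
        if not zmin < zmax:
            raise ValueError("z_range must satisfy z_min < z_max")
        if not zmin <= self.z_focus <= zmax:
            raise ValueError("z_focus must lie inside z_range")
        zz = np.linspace(zmin, zmax, 512)
        if np.any(self.sigma_x_curve(zz) <= 0) or np.any(self.sigma_y_curve(zz) <= 0):
            raise ValueError("sigma curves must be strictly positive over z_range")
        self._dsx = self.sigma_x_curve.derivative()
        self._dsy = self.sigma_y_curve.derivative()

    # -- serialization ----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "phi": self.phi,
            "z_range": list(self.z_range),
            "z_focus": self.z_focus,
            "pixel_size_nm": self.pixel_size_nm,
            "sigma_x_curve": _spline_to_dict(self.sigma_x_curve),
            "sigma_y_curve": _spline_to_dict(self.sigma_y_curve),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "AstigmaticCalibration":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            sigma_x_curve=_spline_from_dict(d["sigma_x_curve"]),
            sigma_y_curve=_spline_from_dict(d["sigma_y_curve"]),
            phi=d["phi"],
            z_range=tuple(d["z_range"]),
            z_focus=d["z_focus"],
            pixel_size_nm=d["pixel_size_nm"],
        )


def _spline_to_dict(sp: BSpline) -> dict:
    return {"t": sp.t.tolist(), "c": sp.c.tolist(), "k": int(sp.k)}


def _spline_from_dict(d: dict) -> BSpline:
    return BSpline(np.asarray(d["t"]), np.asarray(d["c"]), d["k"])


def calibration_from_samples(
    z: np.ndarray,
    sigma_x: np.ndarray,
    sigma_y: np.ndarray,
    phi: float = 0.0,
    pixel_size_nm: float = 100.0,
) -> AstigmaticCalibration:
    """Build a calibration by cubic-spline interpolation through width samples.

    Convenience constructor used by the simulator and by tests; the spline
    passes exactly through the samples (interpolation, not smoothing).
    """
    z = np.asarray(z, float)
    sx = make_interp_spline(z, np.asarray(sigma_x, float), k=3)
    sy = make_interp_spline(z, np.asarray(sigma_y, float), k=3)
    z_focus = _find_focus(sx, sy, (z[0], z[-1]))
    return AstigmaticCalibration(sx, sy, phi, (float(z[0]), float(z[-1])),
                                 z_focus, pixel_size_nm)


def _find_focus(sx: BSpline, sy: BSpline, z_range) -> float:
    zz = np.linspace(z_range[0], z_range[1], 4001)
    return float(zz[np.argmin(sx(zz) * sy(zz))])


def _check_z(calib: AstigmaticCalibration, z) -> None:
    z = np.asarray(z, float)
    zmin, zmax = calib.z_range
    if np.any(z < zmin) or np.any(z > zmax):
        raise ZRangeError(
            f"z={z} outside calibrated range [{zmin}, {zmax}] nm")


def sigma_of_z(calib: AstigmaticCalibration, z):
    """Evaluate the calibrated widths (sigma_x, sigma_y) in pixels at z (nm)."""
    _check_z(calib, z)
    return float(calib.sigma_x_curve(z)), float(calib.sigma_y_curve(z))


def dsigma_of_z(calib: AstigmaticCalibration, z):
    """First derivatives (dsigma_x/dz, dsigma_y/dz) in px/nm at z (nm)."""
    _check_z(calib, z)
    return float(calib._dsx(z)), float(calib._dsy(z))


# ---------------------------------------------------------------------------
# PSF evaluation
# ---------------------------------------------------------------------------

def _rotated_offsets(x, y, phi, i, j):
    """Offsets in the rotated (principal-axis) frame of the Gaussian."""
    di = np.asarray(i, float) - x
    dj = np.asarray(j, float) - y
    c, s = np.cos(phi), np.sin(phi)
    u = di * c + dj * s
    v = -di * s + dj * c
    return u, v


def psf_value(x, y, z, calib: AstigmaticCalibration, i, j):
    """Unit-peak elliptical Gaussian at pixel (i, j) for an emitter at (x, y, z).

    The model is
    ``exp(-u^2 / (2 sigma_x(z)^2) - v^2 / (2 sigma_y(z)^2))`` where (u, v)
    is the pixel offset rotated by the calibration angle phi.  The value is
    in (0, 1] and equals 1 exactly at the emitter position.
    """
    sx, sy = sigma_of_z(calib, z)
    u, v = _rotated_offsets(x, y, calib.phi, i, j)
    return np.exp(-u * u / (2 * sx * sx) - v * v / (2 * sy * sy))


def psf_gradient(x, y, z, calib: AstigmaticCalibration, i, j):
    """Analytic partials (d/dx, d/dy, d/dz) of :func:`psf_value`.

    Obtained by differentiating the unit-peak Gaussian; the z derivative
    goes through the spline derivatives of sigma_x and sigma_y.
    """
    sx, sy = sigma_of_z(calib, z)
    dsx, dsy = dsigma_of_z(calib, z)
    u, v = _rotated_offsets(x, y, calib.phi, i, j)
    c, s = np.cos(calib.phi), np.sin(calib.phi)
    p = np.exp(-u * u / (2 * sx * sx) - v * v / (2 * sy * sy))
    # d u / d x = -c, d v / d x = s ; d u / d y = -s, d v / d y = c
    d_dx = p * (u * c / (sx * sx) - v * s / (sy * sy))
    d_dy = p * (u * s / (sx * sx) + v * c / (sy * sy))
    d_dz = p * (u * u / sx**3 * dsx + v * v / sy**3 * dsy)
    return d_dx, d_dy, d_dz


def psf_value_integrated(x, y, z, calib: AstigmaticCalibration, i, j):
    """Pixel-integrated Gaussian, rescaled to peak-intensity units.

    Integrates the normalized Gaussian over the unit pixel area (error
    function form, separable, so phi must be 0) and multiplies by
    ``2*pi*sigma_x(z)*sigma_y(z)`` so the values are on the same
    peak-intensity scale as :func:`psf_value`; the central-pixel value
    approaches 1 as sigma grows.  For phi != 0 the sampled model is used
    instead, with a warning.
    """
    if calib.phi != 0.0:
        warnings.warn("integrated PSF model requires phi=0; "
                      "falling back to the sampled model")
        return psf_value(x, y, z, calib, i, j)
    sx, sy = sigma_of_z(calib, z)
    di = np.asarray(i, float) - x
    dj = np.asarray(j, float) - y
    fx = ndtr((di + 0.5) / sx) - ndtr((di - 0.5) / sx)
    fy = ndtr((dj + 0.5) / sy) - ndtr((dj - 0.5) / sy)
    return 2.0 * np.pi * sx * sy * fx * fy


# ---------------------------------------------------------------------------
# Bead calibration
# ---------------------------------------------------------------------------

def _gauss2d_residual(p, img, ii, jj):
    bg, amp, x, y, sx, sy = p
    di, dj = ii - x, jj - y
    model = bg + amp * np.exp(-di * di / (2 * sx * sx) - dj * dj / (2 * sy * sy))
    return (model - img).ravel()


def _fit_bead_plane(frame, cx, cy, half=7):
    """Unconstrained elliptical-Gaussian fit in a window around (cx, cy)."""
    x0, x1 = int(cx) - half, int(cx) + half + 1
    y0, y1 = int(cy) - half, int(cy) + half + 1
    if x0 < 0 or y0 < 0 or x1 > frame.shape[0] or y1 > frame.shape[1]:
        return None
    win = frame[x0:x1, y0:y1].astype(float)
    ii, jj = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1), indexing="ij")
    bg0 = float(np.median(win))
    amp0 = float(win.max() - bg0)
    if amp0 <= 0:
        return None
    p0 = [bg0, amp0, cx, cy, 1.5, 1.5]
    res = least_squares(
        _gauss2d_residual, p0, args=(win, ii, jj),
        bounds=([-np.inf, 0, x0, y0, 0.3, 0.3],
                [np.inf, np.inf, x1 - 1, y1 - 1, half, half]),
        max_nfev=200)
    if not res.success:
        return None
    return res.x


def _detect_beads(ref_frame, n_beads_max=16, min_sep=15):
    score = maximum_filter(ref_frame, size=5)
    thr = ref_frame.mean() + 4 * ref_frame.std()
    peaks = np.argwhere((ref_frame == score) & (ref_frame > thr))
    # keep well-separated bright peaks
    order = np.argsort(-ref_frame[peaks[:, 0], peaks[:, 1]])
    kept: list[tuple[int, int]] = []
    for idx in order:
        p = peaks[idx]
        if all(max(abs(p[0] - q[0]), abs(p[1] - q[1])) >= min_sep for q in kept):
            kept.append((int(p[0]), int(p[1])))
        if len(kept) >= n_beads_max:
            break
    return kept


def calibrate_from_beads(
    stack: np.ndarray,
    z_positions,
    phi: float = 0.0,
    pixel_size_nm: float = 100.0,
    fit_window_half: int = 7,
) -> AstigmaticCalibration:
    """Calibrate sigma_x(z), sigma_y(z) from a bead z-stack.

    Parameters
    ----------
    stack : array, shape (n_planes, H, W)
        One frame per stage position, each containing >= 1 isolated bead.
    z_positions : array of float, nm
        Strictly monotone stage positions, one per plane.

    Each plane gets an unconstrained elliptical-Gaussian fit per bead; the
    per-plane median widths are then smoothed with a least-squares cubic
    B-spline with knots at every other plane (clamped ends).  z_focus is
    the argmin of sigma_x*sigma_y on the fitted curves.
    """
    stack = np.asarray(stack, float)
    z = np.asarray(z_positions, float)
    if stack.ndim != 3 or stack.shape[0] != z.size:
        raise ValueError("stack must be (n_planes, H, W) matching z_positions")
    dz = np.diff(z)
    if not (np.all(dz > 0) or np.all(dz < 0)):
        raise ValueError("z_positions must be strictly monotone")
    if z[0] > z[-1]:
        z = z[::-1]
        stack = stack[::-1]

    # bead positions from the sharpest plane (highest peak counts)
    ref = int(np.argmax(stack.max(axis=(1, 2))))
    beads = _detect_beads(stack[ref])
    if not beads:
        raise CalibrationError("no bead detected in reference plane")

    sx_planes = np.empty(z.size)
    sy_planes = np.empty(z.size)
    for n in range(z.size):
        sxs, sys = [], []
        for (cx, cy) in beads:
            fit = _fit_bead_plane(stack[n], cx, cy, half=fit_window_half)
            if fit is not None:
                sxs.append(fit[4])
                sys.append(fit[5])
        if not sxs:
            raise CalibrationError(f"no detectable bead in plane {n}")
        sx_planes[n] = np.median(sxs)
        sy_planes[n] = np.median(sys)

    sx_curve = _lsq_cubic_spline(z, sx_planes)
    sy_curve = _lsq_cubic_spline(z, sy_planes)
    z_range = (float(z[0]), float(z[-1]))
    z_focus = _find_focus(sx_curve, sy_curve, z_range)
    return AstigmaticCalibration(sx_curve, sy_curve, phi, z_range, z_focus,
                                 pixel_size_nm)


def _lsq_cubic_spline(z: np.ndarray, y: np.ndarray) -> BSpline:
    """Least-squares cubic B-spline with knots at every other plane."""
    interior = z[2:-2:2]
    t = np.concatenate([[z[0]] * 4, interior, [z[-1]] * 4])
    try:
        return make_lsq_spline(z, y, t, k=3)
    except Exception:
        # too few planes for smoothing knots: interpolate instead
        return make_interp_spline(z, y, k=min(3, z.size - 1))
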