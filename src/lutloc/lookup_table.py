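"""Precomputed PSF template tables over a discrete (x, y, z) grid.

The fitter never evaluates the PSF model at run time.  Instead, template
images of the PSF and its three positional derivatives are computed once
for every discrete lateral offset and axial position, and fitting reduces
to rounding the current position estimate to the nearest grid point and
looking up the corresponding template in O(1).

Grid convention: lateral offsets run over {-rxy/2 ... +rxy/2} inclusive in
steps of dxy around the window center; axial positions over
{z_focus - rz/2 ... z_focus + rz/2} in steps of dz.  Templates are stored
in one contiguous array with index ``k = ((ix * n_xy) + iy) * n_z + iz``
(z fastest, cache-friendly for the fitter's axial scan).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .psf_model import AstigmaticCalibration, psf_gradient, psf_value


class ConfigurationError(ValueError):
    """Invalid lookup-table specification or insufficient calibration range."""


class GridRangeError(Exception):
    """Position outside the grid; inside the fitter this terminates the fit."""


@dataclass(frozen=True)
class LookupTableSpec:
    """Discretization parameters of the template grid.

    window : odd template side length in pixels (default 9)
    dxy    : lateral step in pixels (default 0.1)
    rxy    : total lateral span in pixels (default 4, i.e. +-2 px)
    dz     : axial step in nm (default 25)
    rz     : total axial span in nm (default 1000, i.e. +-500 nm)
    """

    window: int = 9
    dxy: float = 0.1
    rxy: float = 4.0
    dz: float = 25.0
    rz: float = 1000.0
    precision: str = "double"  # or "single"

    def __post_init__(self) -> None:
        if self.window < 5 or self.window % 2 == 0:
            raise ConfigurationError("window must be odd and >= 5")
        for name in ("dxy", "rxy", "dz", "rz"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for r, d, nm in ((self.rxy, self.dxy, "rxy/dxy"), (self.rz, self.dz, "rz/dz")):
            steps = r / d
            if abs(steps - round(steps)) > 1e-9 * max(1.0, steps):
                raise ConfigurationError(f"{nm} must be an integer number of steps")
        if self.precision not in ("double", "single"):
            raise ConfigurationError("precision must be 'double' or 'single'")

    @property
    def n_xy(self) -> int:
        """Lateral grid points per axis (span rxy, step dxy, inclusive)."""
        return int(round(self.rxy / self.dxy)) + 1

    @property
    def n_z(self) -> int:
        return int(round(self.rz / self.dz)) + 1

    @property
    def n_templates(self) -> int:
        return self.n_xy * self.n_xy * self.n_z

    @property
    def center(self) -> float:
        """Window-center coordinate (pixel units, 0-based)."""
        return (self.window - 1) / 2.0

    @property
    def dtype(self):
        return np.float64 if self.precision == "double" else np.float32


@dataclass
class LookupTable:
    """Template array plus the grid axes it is indexed by."""

    spec: LookupTableSpec
    calib: AstigmaticCalibration
    templates: np.ndarray          # (n_templates, window, window, 4)
    x_offsets: np.ndarray          # (n_xy,) pixel offsets from window center
    y_offsets: np.ndarray
    z_values: np.ndarray           # (n_z,) absolute z in nm

    @property
    def nbytes(self) -> int:
        return self.templates.nbytes

    def index_of(self, theta_x: float, theta_y: float, theta_z: float) -> int:
        """Nearest-grid-point index for a window-frame (x, y) and absolute z."""
        return index_of(theta_x, theta_y, theta_z, self.spec,
                        z_center=float(self.z_values[(len(self.z_values) - 1) // 2]))

    def grid_point(self, k: int) -> tuple[float, float, float]:
        """Inverse of :meth:`index_of` for on-grid positions."""
        n_xy, n_z = self.spec.n_xy, self.spec.n_z
        ix, rem = divmod(int(k), n_xy * n_z)
        iy, iz = divmod(rem, n_z)
        c = self.spec.center
        return (c + self.x_offsets[ix], c + self.y_offsets[iy],
                float(self.z_values[iz]))


def _round_half_away(t: float) -> int:
    return int(np.sign(t) * np.floor(abs(t) + 0.5))


def index_of(theta_x: float, theta_y: float, theta_z: float,
             spec: LookupTableSpec, z_center: float = 0.0) -> int:
    """Template index of the grid point nearest to (theta_x, theta_y, theta_z).

    theta_x/theta_y are window coordinates (pixels, window center at
    ``spec.center``); theta_z is in nm, measured against ``z_center`` (the
    grid's central z, i.e. the calibration focal plane).  Ties round half
    away from the grid center.  Raises :class:`GridRangeError` when the
    nearest step lies outside the grid.
    """
    half_xy = (spec.n_xy - 1) // 2
    half_z = (spec.n_z - 1) // 2
    ix = _round_half_away((theta_x - spec.center) / spec.dxy)
    iy = _round_half_away((theta_y - spec.center) / spec.dxy)
    if abs(ix) > half_xy or abs(iy) > half_xy:
        raise GridRangeError("lateral position outside r_xy")
    iz = _round_half_away((theta_z - z_center) / spec.dz)
    if abs(iz) > half_z:
        raise GridRangeError("axial position outside r_z")
    return ((ix + half_xy) * spec.n_xy + (iy + half_xy)) * spec.n_z + (iz + half_z)


def build_table(spec: LookupTableSpec, calib: AstigmaticCalibration) -> LookupTable:
    """Populate the template array from the PSF model (deterministic).

    Each template holds, per pixel, the unit-peak PSF value and its three
    positional derivatives at one discrete emitter position.  The
    calibration must cover ``z_focus +- rz/2``.
    """
    half_span = spec.rz / 2.0
    zmin, zmax = calib.z_range
    if calib.z_focus - half_span < zmin or calib.z_focus + half_span > zmax:
        raise ConfigurationError(
            "calibration z_range does not cover z_focus +- rz/2")

    n_xy, n_z, w = spec.n_xy, spec.n_z, spec.window
    c = spec.center
    x_offsets = (np.arange(n_xy) - (n_xy - 1) // 2) * spec.dxy
    y_offsets = x_offsets.copy()
    z_values = calib.z_focus + (np.arange(n_z) - (n_z - 1) // 2) * spec.dz

    out = np.empty((n_xy, n_xy, n_z, w, w, 4), dtype=spec.dtype)
    px = np.arange(w, dtype=float)
    xs = (c + x_offsets)[:, None, None, None]
    ys = (c + y_offsets)[None, :, None, None]
    ii = px[None, None, :, None]
    jj = px[None, None, None, :]
    for iz, zv in enumerate(z_values):
        p = psf_value(xs, ys, zv, calib, ii, jj)
        gx, gy, gz = psf_gradient(xs, ys, zv, calib, ii, jj)
        out[:, :, iz, :, :, 0] = p
        out[:, :, iz, :, :, 1] = gx
        out[:, :, iz, :, :, 2] = gy
        out[:, :, iz, :, :, 3] = gz
    templates = out.reshape(spec.n_templates, w, w, 4)
    return LookupTable(spec, calib, templates, x_offsets, y_offsets, z_values)


def save_table(table: LookupTable, path) -> None:
    """Cache a built table to HDF5 (templates plus grid and spec echo)."""
    import dataclasses
    import json as _json

    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("templates", data=table.templates)
        fh.create_dataset("x_offsets", data=table.x_offsets)
        fh.create_dataset("z_values", data=table.z_values)
        fh.attrs["spec"] = _json.dumps(dataclasses.asdict(table.spec))
        fh.attrs["calib"] = _json.dumps({
            "phi": table.calib.phi, "z_range": list(table.calib.z_range),
            "z_focus": table.calib.z_focus,
            "pixel_size_nm": table.calib.pixel_size_nm,
            "sigma_x_curve": _cal_spline(table.calib.sigma_x_curve),
            "sigma_y_curve": _cal_spline(table.calib.sigma_y_curve)})


def _cal_spline(sp):
    return {"t": sp.t.tolist(), "c": sp.c.tolist(), "k": int(sp.k)}


def load_table(path) -> LookupTable:
    import json as _json

    import h5py
    from scipy.interpolate import BSpline

    with h5py.File(path, "r") as fh:
        spec = LookupTableSpec(**_json.loads(fh.attrs["spec"]))
        cd = _json.loads(fh.attrs["calib"])
        calib = AstigmaticCalibration(
            BSpline(np.asarray(cd["sigma_x_curve"]["t"]),
                    np.asarray(cd["sigma_x_curve"]["c"]),
                    cd["sigma_x_curve"]["k"]),
            BSpline(np.asarray(cd["sigma_y_curve"]["t"]),
                    np.asarray(cd["sigma_y_curve"]["c"]),
                    cd["sigma_y_curve"]["k"]),
            cd["phi"], tuple(cd["z_range"]), cd["z_focus"],
            cd["pixel_size_nm"])
        x_off = fh["x_offsets"][()]
        return LookupTable(spec, calib, fh["templates"][()], x_off,
                           x_off.copy(), fh["z_values"][()])


def template_at(table: LookupTable, k: int):
    """Constant-time views (psf, d/dx, d/dy, d/dz) of template k."""
    if not 0 <= k < table.spec.n_templates:
        raise IndexError(f"template index {k} out of range")
    t = table.templates[k]
    return t[:, :, 0], t[:, :, 1], t[:, :, 2], t[:, :, 3]
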