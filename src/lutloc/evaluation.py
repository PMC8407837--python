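"""Ground-truth matching, challenge metrics, FRC, and histogram rendering.

The detection/precision metrics follow the SMLM-challenge conventions:
localizations are paired one-to-one with ground-truth emitters of the same
frame by a globally optimal assignment restricted to pairs within a
lateral and an axial tolerance gate; from the pairing come the Jaccard
index TP/(TP+FP+FN), lateral/axial RMSE over the matched pairs, and the
combined efficiency score.  Image resolution is estimated by Fourier ring
correlation between two half-dataset renderings with the 1/7 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment


@dataclass
class MatchResult:
    pairs: list[tuple[int, int]]        # (ground-truth row, fit row)
    n_tp: int
    n_fp: int
    n_fn: int
    lateral_errors: np.ndarray          # nm, one per pair
    axial_errors: np.ndarray            # nm, one per pair


@dataclass
class FRCResult:
    spatial_frequencies: np.ndarray     # cycles per pixel
    correlation: np.ndarray
    resolution: float | None            # nm, first threshold crossing
    threshold: float
    crossings: list[float] = field(default_factory=list)   # all crossings, nm


_COLS = ("x_nm", "y_nm", "z_nm")


def _as_table(obj) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        df = obj.copy()
        if "frame" not in df:
            df["frame"] = 0
        return df
    arr = np.asarray(obj, float).reshape(-1, 3)
    return pd.DataFrame({"frame": 0, "x_nm": arr[:, 0], "y_nm": arr[:, 1],
                         "z_nm": arr[:, 2]})


def match_localizations(fits, ground_truth, lateral_tol: float = 250.0,
                        axial_tol: float = 500.0) -> MatchResult:
    """Optimal one-to-one matching of fits to ground truth within tolerances.

    Both inputs are DataFrames with columns (frame, x_nm, y_nm, z_nm) or
    plain (N, 3) arrays in nm (then treated as a single frame).  Pairs must
    lie within ``lateral_tol`` (2D Euclidean) and ``axial_tol`` (|dz|);
    among admissible pairings the total 3D distance is minimized per frame.
    """
    fits_t = _as_table(fits)
    gt_t = _as_table(ground_truth)
    pairs: list[tuple[int, int]] = []
    lat_err: list[float] = []
    ax_err: list[float] = []
    frames = np.union1d(fits_t["frame"].unique(), gt_t["frame"].unique())
    BIG = 1e12
    for f in frames:
        fi = fits_t.index[fits_t["frame"] == f]
        gi = gt_t.index[gt_t["frame"] == f]
        if len(fi) == 0 or len(gi) == 0:
            continue
        fxyz = fits_t.loc[fi, list(_COLS)].to_numpy(float)
        gxyz = gt_t.loc[gi, list(_COLS)].to_numpy(float)
        dlat = np.hypot(gxyz[:, None, 0] - fxyz[None, :, 0],
                        gxyz[:, None, 1] - fxyz[None, :, 1])
        dax = np.abs(gxyz[:, None, 2] - fxyz[None, :, 2])
        feasible = (dlat <= lateral_tol) & (dax <= axial_tol)
        cost = np.where(feasible, np.sqrt(dlat ** 2 + dax ** 2), BIG)
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            if feasible[r, c]:
                pairs.append((int(gi[r]), int(fi[c])))
                lat_err.append(float(dlat[r, c]))
                ax_err.append(float(dax[r, c]))
    n_tp = len(pairs)
    return MatchResult(pairs, n_tp, len(fits_t) - n_tp, len(gt_t) - n_tp,
                       np.asarray(lat_err), np.asarray(ax_err))


def jaccard_index(match: MatchResult) -> float:
    denom = match.n_tp + match.n_fp + match.n_fn
    return match.n_tp / denom if denom else 1.0


def rmse(match: MatchResult) -> tuple[float, float]:
    """(lateral_rmse, axial_rmse) in nm over the matched pairs."""
    if match.n_tp == 0:
        return float("nan"), float("nan")
    return (float(np.sqrt(np.mean(match.lateral_errors ** 2))),
            float(np.sqrt(np.mean(match.axial_errors ** 2))))


def efficiency(jaccard: float, lateral_rmse: float, axial_rmse: float,
               alpha_lateral: float = 1.0,
               alpha_axial: float = 0.5) -> tuple[float, float, float]:
    """Challenge efficiency scores (lateral, axial, overall), in percent.

    ``E = 100 - sqrt((100 * (1 - JI))^2 + (alpha * RMSE)^2)`` with the
    challenge weights alpha = 1/nm laterally and 0.5/nm axially; the
    overall score is the mean of the two.
    """
    miss = 100.0 * (1.0 - jaccard)
    e_lat = 100.0 - float(np.hypot(miss, alpha_lateral * lateral_rmse))
    e_ax = 100.0 - float(np.hypot(miss, alpha_axial * axial_rmse))
    return e_lat, e_ax, 0.5 * (e_lat + e_ax)


# ---------------------------------------------------------------------------
# Fourier ring correlation
# ---------------------------------------------------------------------------

def frc(image_a: np.ndarray, image_b: np.ndarray, pixel_size: float,
        threshold: float = 1.0 / 7.0, smooth_rings: int = 3) -> FRCResult:
    """Fourier ring correlation between two half-dataset images.

    Correlates the Fourier transforms ring by ring (ring width one
    frequency bin), smooths the curve with a moving average over
    ``smooth_rings`` rings, and reads the resolution as 1/frequency at the
    first crossing below ``threshold`` (all crossings are also reported).
    ``pixel_size`` is in nm per rendered pixel.
    """
    a = np.asarray(image_a, float)
    b = np.asarray(image_b, float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("images must be square and of equal shape")
    n = a.shape[0]
    fa = np.fft.fftshift(np.fft.fft2(a))
    fb = np.fft.fftshift(np.fft.fft2(b))
    c = n // 2
    yy, xx = np.indices(a.shape)
    r = np.hypot(xx - c, yy - c)
    rings = r.astype(int).ravel()
    n_rings = n // 2
    num = np.bincount(rings, (fa * np.conj(fb)).real.ravel(),
                      minlength=n_rings)[:n_rings]
    den_a = np.bincount(rings, np.abs(fa).ravel() ** 2,
                        minlength=n_rings)[:n_rings]
    den_b = np.bincount(rings, np.abs(fb).ravel() ** 2,
                        minlength=n_rings)[:n_rings]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / np.sqrt(den_a * den_b)
    corr = np.nan_to_num(corr, nan=0.0)
    if smooth_rings > 1:
        kernel = np.ones(smooth_rings) / smooth_rings
        pad = smooth_rings // 2
        smoothed = np.convolve(np.pad(corr, pad, mode="edge"), kernel,
                               mode="valid")[:n_rings]
        smoothed[0] = corr[0]
    else:
        smoothed = corr
    freqs = np.arange(n_rings) / n          # cycles per pixel
    crossings_nm: list[float] = []
    for i in range(1, n_rings):
        if smoothed[i - 1] >= threshold > smoothed[i]:
            # linear interpolation between ring i-1 and i
            t = (smoothed[i - 1] - threshold) / (smoothed[i - 1] - smoothed[i])
            fq = (freqs[i - 1] + t * (freqs[i] - freqs[i - 1]))
            if fq > 0:
                crossings_nm.append(float(pixel_size / fq))
    resolution = crossings_nm[0] if crossings_nm else None
    return FRCResult(freqs, smoothed, resolution, threshold, crossings_nm)


def render_gaussian_image(localizations: pd.DataFrame, shape: tuple[int, int],
                          render_pixel_nm: float = 16.67,
                          sigma_nm: float = 25.0) -> np.ndarray:
    """Render localizations as symmetric 2D Gaussians (for FRC input).

    ``localizations`` needs columns x_nm, y_nm; ``shape`` is the rendered
    image shape in render pixels.
    """
    img = np.zeros(shape, float)
    s = sigma_nm / render_pixel_nm
    h = int(np.ceil(4 * s))
    for x_nm, y_nm in zip(localizations["x_nm"], localizations["y_nm"]):
        x = x_nm / render_pixel_nm
        y = y_nm / render_pixel_nm
        i0, i1 = max(int(x) - h, 0), min(int(x) + h + 1, shape[0])
        j0, j1 = max(int(y) - h, 0), min(int(y) + h + 1, shape[1])
        if i0 >= i1 or j0 >= j1:
            continue
        ii = np.arange(i0, i1, dtype=float)[:, None]
        jj = np.arange(j0, j1, dtype=float)[None, :]
        img[i0:i1, j0:j1] += np.exp(-((ii - x) ** 2 + (jj - y) ** 2)
                                    / (2 * s * s))
    return img


# ---------------------------------------------------------------------------
# Real-time histogram rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderState:
    """Incremental state of the max-z histogram renderer."""

    z_map: np.ndarray
    occupied: np.ndarray
    scale: int
    frames_seen: int = 0


def _bin_localizations(state: RenderState, localizations: pd.DataFrame) -> None:
    for x, y, z in zip(localizations["x_px"], localizations["y_px"],
                       localizations["z_nm"]):
        ix = int(x * state.scale)
        iy = int(y * state.scale)
        if not (0 <= ix < state.z_map.shape[0]
                and 0 <= iy < state.z_map.shape[1]):
            continue
        if state.occupied[ix, iy]:
            state.z_map[ix, iy] = max(state.z_map[ix, iy], z)
        else:
            state.z_map[ix, iy] = z
            state.occupied[ix, iy] = True


def _colorize(state: RenderState, z_limits: tuple[float, float],
              sigma_px: float = 1.0) -> np.ndarray:
    """Rainbow-coded z map with a Gaussian gradient into empty neighbors."""
    from matplotlib import colormaps

    cmap = colormaps["rainbow"]
    zlo, zhi = z_limits
    norm = np.clip((state.z_map - zlo) / (zhi - zlo), 0, 1)
    rgb = np.zeros(state.z_map.shape + (3,), float)
    occ = state.occupied
    rgb[occ] = cmap(norm[occ])[:, :3]
    # empty pixels adopt the color of their highest-z occupied 8-neighbor,
    # faded by a Gaussian in the neighbor distance
    best_z = np.full(state.z_map.shape, -np.inf)
    best_rgb = np.zeros_like(rgb)
    best_w = np.zeros(state.z_map.shape)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            sh_occ = _shift(occ, dx, dy)
            sh_z = _shift(state.z_map, dx, dy, fill=-np.inf)
            w = float(np.exp(-(dx * dx + dy * dy) / (2 * sigma_px ** 2)))
            take = (~occ) & sh_occ & (sh_z > best_z)
            if np.any(take):
                sh_norm = _shift(norm, dx, dy)
                best_z[take] = sh_z[take]
                best_rgb[take] = cmap(sh_norm[take])[:, :3]
                best_w[take] = w
    halo = (~occ) & np.isfinite(best_z) & (best_z > -np.inf)
    rgb[halo] = best_rgb[halo] * best_w[halo][:, None]
    return rgb


def _shift(arr: np.ndarray, dx: int, dy: int, fill=0):
    out = np.full_like(arr, fill)
    xs = slice(max(dx, 0), arr.shape[0] + min(dx, 0))
    xd = slice(max(-dx, 0), arr.shape[0] + min(-dx, 0))
    ys = slice(max(dy, 0), arr.shape[1] + min(dy, 0))
    yd = slice(max(-dy, 0), arr.shape[1] + min(-dy, 0))
    out[xd, yd] = arr[xs, ys]
    return out


def render_histogram(localizations: pd.DataFrame, scale: int = 10,
                     frame_shape: tuple[int, int] = (256, 256),
                     sigma_px: float = 1.0,
                     z_limits: tuple[float, float] = (-500.0, 500.0)):
    """Batch super-resolution rendering: (max-z map, rainbow RGB image).

    Localizations (columns x_px, y_px, z_nm, input-frame pixel units) are
    binned into an image ``scale`` times the input frame size; collisions
    keep the highest axial position.
    """
    shape = (frame_shape[0] * scale, frame_shape[1] * scale)
    state = RenderState(np.zeros(shape), np.zeros(shape, bool), scale)
    _bin_localizations(state, localizations)
    return state.z_map, _colorize(state, z_limits, sigma_px)


def render_incremental(state: RenderState, new_localizations: pd.DataFrame,
                       every_n_frames: int = 10,
                       z_limits: tuple[float, float] = (-500.0, 500.0),
                       sigma_px: float = 1.0):
    """Stream one frame's localizations into the state.

    The z map is updated on every call; the expensive color rendering is
    produced only every ``every_n_frames`` calls (returns (state, rgb or
    None)).  The final z map is identical to a batch render of the same
    localizations.
    """
    _bin_localizations(state, new_localizations)
    state.frames_seen += 1
    rgb = None
    if state.frames_seen % every_n_frames == 0:
        rgb = _colorize(state, z_limits, sigma_px)
    return state, rgb


def new_render_state(frame_shape: tuple[int, int] = (256, 256),
                     scale: int = 10) -> RenderState:
    shape = (frame_shape[0] * scale, frame_shape[1] * scale)
    return RenderState(np.zeros(shape), np.zeros(shape, bool), scale)
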