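"""Synthetic-data generators: EMCCD noise, 3D Siemens star, bead stacks,
and blinking movies for closed-loop activation tests.

All generators are bit-for-bit reproducible from (parameters, seed) via
``numpy.random.default_rng``.

Camera model: expected photons per pixel are converted to electrons by a
Poisson draw of ``QE * photons + spurious_charge``, amplified through the
EM register (Gamma with shape = electron count and scale = gain, the
standard approximation giving the excess-noise factor of 2), read out with
additive Gaussian noise, offset by the baseline and rounded to integer
counts.  Counts below zero are kept (no clipping) so sample statistics
match the closed forms exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psf_model import AstigmaticCalibration, calibration_from_samples, psf_value


class GenerationError(RuntimeError):
    """Emitter placement failed (pattern too dense for the min-distance rule)."""


@dataclass(frozen=True)
class EMCCDNoiseModel:
    """EMCCD counting statistics; defaults are typical back-illuminated values."""

    baseline: float = 100.0
    em_gain: float = 300.0
    quantum_efficiency: float = 0.9
    readout_noise: float = 74.4
    spurious_charge: float = 2e-4

    def __post_init__(self) -> None:
        if min(self.baseline, self.em_gain, self.quantum_efficiency,
               self.readout_noise, self.spurious_charge) < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.quantum_efficiency > 1:
            raise ValueError("quantum_efficiency must be <= 1")

    @property
    def counts_per_photon(self) -> float:
        return self.em_gain * self.quantum_efficiency


@dataclass
class SyntheticMovie:
    frames: np.ndarray                 # (n_frames, H, W) integer counts
    ground_truth: pd.DataFrame         # frame, x_px, y_px, z_nm, peak_counts
    pixel_size_nm: float
    noise: EMCCDNoiseModel | None
    seed: int


def apply_emccd_noise(clean_photon_image: np.ndarray,
                      noise: EMCCDNoiseModel, seed_or_rng) -> np.ndarray:
    """Turn an expected-photons image into a noisy EMCCD counts image."""
    img = np.asarray(clean_photon_image, float)
    if np.any(img < 0):
        raise ValueError("expected photon image must be non-negative")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    electrons = rng.poisson(noise.quantum_efficiency * img
                            + noise.spurious_charge)
    amplified = rng.standard_gamma(electrons) * noise.em_gain
    counts = amplified + rng.normal(0.0, noise.readout_noise, img.shape) \
        + noise.baseline
    return np.rint(counts).astype(np.int32)


# ---------------------------------------------------------------------------
# Default calibration used for simulations
# ---------------------------------------------------------------------------

def default_calibration(sigma0: float = 1.3, gamma_nm: float = 250.0,
                        depth_nm: float = 350.0,
                        z_range: tuple[float, float] = (-750.0, 750.0),
                        pixel_size_nm: float = 100.0) -> AstigmaticCalibration:
    """Synthetic astigmatic width calibration from ideal defocus curves.

    sigma_x(z) = sigma0 * sqrt(1 + ((z - gamma)/d)^2) and the mirrored
    sigma_y; gamma is the astigmatic focal offset introduced by the
    cylindrical lens and d the depth of focus.  Sampled every 50 nm and
    interpolated with a cubic spline so it goes through the same machinery
    as a measured calibration.
    """
    z = np.arange(z_range[0], z_range[1] + 1, 50.0)
    sx = sigma0 * np.sqrt(1 + ((z - gamma_nm) / depth_nm) ** 2)
    sy = sigma0 * np.sqrt(1 + ((z + gamma_nm) / depth_nm) ** 2)
    return calibration_from_samples(z, sx, sy, phi=0.0,
                                    pixel_size_nm=pixel_size_nm)


# ---------------------------------------------------------------------------
# Frame rendering
# ---------------------------------------------------------------------------

def render_emitters(frame_shape: tuple[int, int], emitters,
                    calib: AstigmaticCalibration, peak_counts: float,
                    noise: EMCCDNoiseModel | None) -> np.ndarray:
    """Render emitters into an expected-photons image (no noise applied).

    ``emitters`` is an iterable of (x_px, y_px, z_nm).  The in-focus peak
    is ``peak_counts`` above baseline; away from focus the peak falls off
    as 1/(sigma_x * sigma_y) so the integrated photon flux per emitter is
    constant (defocused spots are dimmer per pixel, as on a real camera).
    Returns (photon image, list of per-emitter peak counts).
    """
    img = np.zeros(frame_shape, float)
    cpp = noise.counts_per_photon if noise is not None else 1.0
    sx0 = float(calib.sigma_x_curve(calib.z_focus))
    sy0 = float(calib.sigma_y_curve(calib.z_focus))
    peaks = []
    for (x, y, z) in emitters:
        sx = float(calib.sigma_x_curve(z))
        sy = float(calib.sigma_y_curve(z))
        pk_counts = peak_counts * (sx0 * sy0) / (sx * sy)
        amp = pk_counts / cpp
        h = int(np.ceil(5 * max(sx, sy)))
        i0, i1 = max(int(x) - h, 0), min(int(x) + h + 1, frame_shape[0])
        j0, j1 = max(int(y) - h, 0), min(int(y) + h + 1, frame_shape[1])
        if i0 >= i1 or j0 >= j1:
            continue
        ii = np.arange(i0, i1, dtype=float)[:, None]
        jj = np.arange(j0, j1, dtype=float)[None, :]
        img[i0:i1, j0:j1] += amp * psf_value(x, y, z, calib, ii, jj)
        peaks.append(pk_counts)
    return img, peaks


# ---------------------------------------------------------------------------
# 3D Siemens star
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiemensStarPattern:
    """40-spoke star: 20 filled 9-degree sectors at staircased z, 20 blank.

    Filled sector s (s = 0..19) sits at z = z_start + s * z_step nm, with
    per-emitter Gaussian jitter of ``z_jitter_sigma``.
    """

    n_filled_sectors: int = 20
    z_start: float = -450.0
    z_step: float = 45.0
    z_jitter_sigma: float = 25.0
    outer_radius_frac: float = 0.4
    inner_radius_px: float = 5.0

    @property
    def z_levels(self) -> np.ndarray:
        return self.z_start + self.z_step * np.arange(self.n_filled_sectors)


def simulate_siemens_star(
    n_emitters: int = 225_000,
    n_frames: int = 5000,
    pattern: SiemensStarPattern = SiemensStarPattern(),
    calib: AstigmaticCalibration | None = None,
    noise: EMCCDNoiseModel | None = EMCCDNoiseModel(),
    seed: int = 0,
    frame_shape: tuple[int, int] = (256, 256),
    peak_counts: float = 2000.0,
    min_distance: float = 7.5,
    pixel_size_nm: float = 100.0,
    max_attempts: int = 10_000,
) -> SyntheticMovie:
    """Simulate a 3D Siemens-star SMLM movie with ground truth.

    Emitters are distributed evenly across frames (exactly n_emitters rows
    in the ground truth), placed uniformly inside the filled sectors with the
    per-frame minimum lateral distance enforced by rejection sampling,
    rendered through the astigmatic PSF and passed through the EMCCD model.
    """
    if n_emitters <= 0 or n_frames <= 0:
        raise ValueError("n_emitters and n_frames must be positive")
    if calib is None:
        calib = default_calibration(pixel_size_nm=pixel_size_nm)
    rng = np.random.default_rng(seed)
    cx, cy = (frame_shape[0] - 1) / 2.0, (frame_shape[1] - 1) / 2.0
    r_out = pattern.outer_radius_frac * min(frame_shape)
    r_in = pattern.inner_radius_px
    sector_width = 2 * np.pi / (2 * pattern.n_filled_sectors)
    levels = pattern.z_levels

    base = n_emitters // n_frames
    extra = n_emitters - base * n_frames
    dtype = np.int32
    frames = np.empty((n_frames,) + tuple(frame_shape), dtype=dtype)
    rows = []
    for f in range(n_frames):
        n_here = base + (1 if f < extra else 0)
        placed: list[tuple[float, float, float]] = []
        sectors: list[int] = []
        for _ in range(n_here):
            for attempt in range(max_attempts):
                s = rng.integers(0, pattern.n_filled_sectors)
                ang = (2 * s) * sector_width + rng.uniform(0, sector_width)
                r = np.sqrt(rng.uniform(r_in ** 2, r_out ** 2))
                x = cx + r * np.cos(ang)
                y = cy + r * np.sin(ang)
                if all((x - px) ** 2 + (y - py) ** 2 >= min_distance ** 2
                       for (px, py, _) in placed):
                    z = levels[s] + rng.normal(0, pattern.z_jitter_sigma)
                    placed.append((x, y, z))
                    sectors.append(int(s))
                    break
            else:
                raise GenerationError(
                    f"could not place emitter in frame {f} after "
                    f"{max_attempts} attempts")
        img, peaks = render_emitters(frame_shape, placed, calib,
                                     peak_counts, noise)
        if noise is not None:
            frames[f] = apply_emccd_noise(img, noise, rng)
        else:
            frames[f] = np.rint(img).astype(dtype)
        for (x, y, z), s, pk in zip(placed, sectors, peaks):
            rows.append((f, x, y, z, float(levels[s]), pk))
    gt = pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "z_nm",
                                     "z_level_nm", "peak_counts"])
    return SyntheticMovie(frames, gt, pixel_size_nm, noise, seed)


# ---------------------------------------------------------------------------
# Bead calibration stacks
# ---------------------------------------------------------------------------

def simulate_bead_stack(
    calib_true: AstigmaticCalibration,
    z_positions,
    n_beads: int = 4,
    peak_counts: float = 2000.0,
    noise: EMCCDNoiseModel | None = None,
    seed: int = 0,
    frame_shape: tuple[int, int] = (96, 96),
    window: int = 9,
):
    """One frame per stage z position, each bead rendered with the true widths.

    Beads are laid out on a coarse grid separated by >= 2 * window pixels
    with small random subpixel offsets.  Returns (stack, bead positions).
    """
    rng = np.random.default_rng(seed)
    z_positions = np.asarray(z_positions, float)
    sep = 2 * window + 2      # >= 2*window apart even after subpixel jitter
    per_row = max(frame_shape[0] // sep - 1, 1)
    if per_row * per_row < n_beads:
        raise ValueError("frame too small for that many separated beads")
    positions = []
    for b in range(n_beads):
        gx, gy = divmod(b, per_row)
        positions.append((sep * (gx + 1) + rng.uniform(-0.5, 0.5),
                          sep * (gy + 1) + rng.uniform(-0.5, 0.5)))
    stack = np.empty((z_positions.size,) + tuple(frame_shape), np.int32)
    for n, z in enumerate(z_positions):
        emitters = [(x, y, float(z)) for (x, y) in positions]
        img, _ = render_emitters(frame_shape, emitters, calib_true,
                                 peak_counts, noise)
        if noise is not None:
            stack[n] = apply_emccd_noise(img, noise, rng)
        else:
            stack[n] = np.rint(img).astype(np.int32)
    return stack, positions


# ---------------------------------------------------------------------------
# Blinking movies (two-state + bleached photoswitching)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Photophysics:
    """Per-frame transition probabilities of the fluorophore state machine.

    dark -> on happens with probability ``on_prob(uv_power)``; an on
    emitter bleaches with probability ``bleach_rate`` or returns to the
    dark state with probability ``off_rate``.  The UV activation laser
    raises the on-switching probability linearly.
    """

    on_rate_base: float = 0.0005
    on_rate_per_mw: float = 0.002
    off_rate: float = 0.5
    bleach_rate: float = 0.02

    def __post_init__(self) -> None:
        if min(self.on_rate_base, self.on_rate_per_mw, self.off_rate,
               self.bleach_rate) < 0:
            raise ValueError("rates must be non-negative")

    def on_prob(self, uv_power_mw: float) -> float:
        return min(1.0, self.on_rate_base + self.on_rate_per_mw * uv_power_mw)


DARK, ON, BLEACHED = 0, 1, 2


class BlinkingSimulator:
    """Frame source whose emitter activity responds to the UV laser power.

    Implements the one-method hardware port ``set_power(mw)`` used by the
    feedback controller; ``next_frame()`` advances the photoswitching
    Markov chain one step and renders the active emitters.
    """

    def __init__(self, structure: np.ndarray, photophysics: Photophysics,
                 calib: AstigmaticCalibration | None = None,
                 noise: EMCCDNoiseModel | None = EMCCDNoiseModel(),
                 frame_shape: tuple[int, int] = (128, 128),
                 peak_counts: float = 2000.0, seed: int = 0,
                 start_on_fraction: float = 0.005):
        self.structure = np.asarray(structure, float).reshape(-1, 3)
        self.photophysics = photophysics
        self.calib = calib if calib is not None else default_calibration()
        self.noise = noise
        self.frame_shape = frame_shape
        self.peak_counts = peak_counts
        self.rng = np.random.default_rng(seed)
        self.power_mw = 0.0
        n = len(self.structure)
        self.states = np.where(self.rng.random(n) < start_on_fraction, ON, DARK)

    def set_power(self, power_mw: float) -> None:
        self.power_mw = float(power_mw)

    def _advance(self) -> None:
        ph = self.photophysics
        u = self.rng.random(self.states.size)
        on = self.states == ON
        dark = self.states == DARK
        self.states = np.where(on & (u < ph.bleach_rate), BLEACHED, self.states)
        self.states = np.where(on & (u >= ph.bleach_rate)
                               & (u < ph.bleach_rate + ph.off_rate),
                               DARK, self.states)
        self.states = np.where(dark & (u < ph.on_prob(self.power_mw)),
                               ON, self.states)

    def next_frame(self) -> tuple[np.ndarray, int]:
        """Advance one frame; returns (counts image, true active count)."""
        self._advance()
        active = self.structure[self.states == ON]
        img, _ = render_emitters(self.frame_shape, active, self.calib,
                                 self.peak_counts, self.noise)
        if self.noise is not None:
            frame = apply_emccd_noise(img, self.noise, self.rng)
        else:
            frame = np.rint(img).astype(np.int32)
        return frame, int(len(active))


def simulate_blinking_movie(structure, photophysics: Photophysics,
                            n_frames: int,
                            noise: EMCCDNoiseModel | None = EMCCDNoiseModel(),
                            seed: int = 0, uv_power_mw: float = 0.0,
                            **kwargs) -> tuple[SyntheticMovie, np.ndarray]:
    """Fixed-power blinking movie; returns (movie, per-frame active counts)."""
    sim = BlinkingSimulator(structure, photophysics, noise=noise, seed=seed,
                            **kwargs)
    sim.set_power(uv_power_mw)
    frames = []
    counts = np.empty(n_frames, int)
    rows = []
    for f in range(n_frames):
        frame, n_active = sim.next_frame()
        frames.append(frame)
        counts[f] = n_active
        for (x, y, z) in sim.structure[sim.states == ON]:
            rows.append((f, x, y, z, sim.peak_counts))
    gt = pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "z_nm",
                                     "peak_counts"])
    movie = SyntheticMovie(np.stack(frames), gt, sim.calib.pixel_size_nm,
                           noise, seed)
    return movie, counts
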