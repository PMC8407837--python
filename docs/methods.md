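# Methods

## Model and coordinate conventions

The PSF is a unit-peak 2D elliptical Gaussian whose widths σx(z), σy(z)
(in pixels) are cubic B-splines of the axial position z (in nm), obtained
from a bead-stack calibration; φ is a global rotation of the ellipse.
Pixel centers sit at integer coordinates, lateral positions are 0-based
pixel units, and z is absolute in the calibration's stage frame, with
`z_focus` the plane minimizing σx·σy. Evaluating a calibration outside its
z range raises an error — the splines are never extrapolated.

The fitted model for a candidate window is

    I_ij = θ_bg + θ_p · PSF_ij(θ_x, θ_y, θ_z),

with θ_bg the mean background and θ_p the peak intensity, both in camera
counts. A pixel-integrated variant (error-function form, φ=0 only,
rescaled by 2πσxσy to stay on the peak-intensity scale) is available for
when pixelation matters; for φ≠0 it falls back to the sampled model with a
warning.

## Lookup table

Templates hold the PSF and its three positional derivatives per pixel in a
window of 9×9 px (odd, configurable). The grid covers lateral offsets
±rxy/2 in steps of Δxy and axial positions z_focus ± rz/2 in steps of Δz
(defaults: Δxy = 0.1 px, rxy = 4 px, Δz = 25 nm, rz = 1000 nm → 41·41·41 =
68 921 templates, ≈180 MB in double precision; single precision is an
option for fine grids). Storage is one contiguous array with index
k = ((ix·n_xy)+iy)·n_z+iz (z fastest). Position-to-index rounding is
round-half-away-from-the-grid-center. Published descriptions of this kind
of table are ambiguous about whether the lateral range is a full span or a
half-width (the template counts printed alongside them fit neither reading
exactly); the convention above is fixed here and the count is derived, not
asserted.

## Detection

Pixels are scored by their 3×3 mean; candidates are accepted greedily in
descending score order (ties broken by the raw pixel value, then
lexicographically — a pure lexicographic rule would let an equal-scoring
neighbor suppress the true peak), each accepted maximum suppressing all
pixels within the suppression radius (Euclidean, default = the 9 px fit
window). The local background is the mean over the one-pixel-wide boundary
line of a square window (default 10×10) around the peak, clipped at frame
borders. A candidate is kept when peak − background exceeds the intensity
threshold and its fit window lies fully inside the frame. The threshold is
inherently experiment-specific; the default of 300 counts is ≈4× the
readout-noise floor of the default camera model and can be changed at run
time (including mid-run in streaming mode).

## Fitting

θ_x, θ_y start at the window center, θ_z at the focal plane; θ_bg starts
at the local background and θ_p at the 3×3-mean score minus background,
rescaled by the in-focus template's peak/3×3-mean ratio. The raw peak
pixel is deliberately not used to seed θ_p: at EM gain 300 a 2000-count
peak carries ≈50% relative noise in a single pixel, and a badly scaled θ_p
destabilizes the first Gauss–Newton position step (the positional Jacobian
columns are proportional to θ_p).

Each iteration solves the symmetric 5×5 normal equations
(JᵀJ)δ = Jᵀr with r = I − (θ_bg + θ_p·template), applies the update and
rounds the positions back to the grid. Iteration stops when (a) the
rounded position repeats and θ_bg, θ_p change by < 0.1% (converged), (b)
the lateral or axial position leaves the grid, (c) the normal equations
are singular, or (d) the iteration cap (default 5) is reached. Because the
grid quantizes the state, the iteration can enter a two-cycle between
adjacent steps that never satisfies (a); reaching the cap is therefore a
normal termination, not a failure, and both (a) and (d) return the visited
iterate with the smallest residual norm ("the best fit"). Accepted fits
are those terminating by (a) or (d) with θ_p > 0; range exits and
degenerate systems are counted separately in the diagnostics.

The continuous reference fitter optimizes the same five parameters with an
unconstrained trust-region least-squares solver (analytic Jacobian, z
bounded to the same axial span as the grid) and is used to benchmark the
cost of the discretization.

## CRLB

Per-fit bounds come from the inverse Fisher information of the template
model under independent per-pixel Poisson statistics on the expected
counts, optionally inflated by the EMCCD excess-noise factor 2. Treating
counts as Poisson is the conventional baseline and is internally
consistent with the Monte-Carlo tests (which draw Poisson replicates in
count space); for real EM-amplified data the photon flux per count is
1/(gain·QE), so these bounds are optimistic by roughly √(gain·QE) unless
the excess-noise/gain correction is applied by the caller.

## Synthetic data

*Camera*: expected photons → Poisson(QE·photons + spurious charge)
electrons → Gamma(shape = electrons, scale = gain) EM register (the
standard approximation; it reproduces the excess-noise factor 2) →
Gaussian readout noise → + baseline → integer counts. Counts are not
clipped at zero so sample moments match the closed forms exactly; the
TIFF writer clips to the camera-like uint16 range. Defaults: baseline 100,
gain 300, QE 0.9, readout 74.4, spurious 2×10⁻⁴ per pixel per frame.

*Siemens star*: 40 spokes — 20 filled 9° sectors alternating with 20 blank
ones, outer radius 40% of the 256×256 frame, inner radius 5 px (the spoke
apex is excluded so the per-frame minimum-distance constraint stays
satisfiable). Filled sector s sits at z = −450 + 45·s nm (s = 0..19; a
staircase "from −450 to 450 nm in 45 nm steps" cannot place 21 distinct
levels on 20 sectors, so the upper level is 405 nm), with per-emitter
Gaussian jitter of σ = 25 nm. Emitters are spread evenly over frames
(default 45/frame) and placed by rejection sampling with a 7.5 px minimum
pairwise distance (10⁴ attempts per emitter before failing loudly).

*Emitter intensity*: the in-focus expected peak is 2000 counts above
baseline and the integrated photon flux per emitter is constant, so the
peak falls off as 1/(σxσy) away from focus. This matches the physical
picture (defocused photons spread over more pixels → lower SNR, making
|z| ≳ 400 nm emitters the hardest to detect) rather than a constant-peak
reading, under which defocus would cost no SNR at all. With counts read as
post-gain, the in-focus peak corresponds to ≈7.4 photo-electrons in the
brightest pixel — a deliberately harsh regime.

*Default calibration*: σx(z) = σ0·√(1+((z−γ)/d)²) and the mirrored σy,
with σ0 = 1.3 px, astigmatic offset γ = 250 nm, depth of focus d = 350 nm,
sampled every 50 nm over ±750 nm and splined — typical values for a
cylindrical-lens astigmatic setup at ~100 nm pixels. The generator emulates
sparse, non-overlapping blinking emitters with ideal Gaussian PSFs; it does
not model dipole orientation effects, aberrations beyond astigmatism,
sample drift, or per-pixel gain variation, so passing tests demonstrate
correctness of the algorithmic chain, not robustness to those artifacts.

*Blinking movies*: per-fluorophore three-state Markov chain
(dark → on with probability base + slope·UV power per frame; on → dark or
bleached) rendered through the same PSF and camera model; the simulator
exposes the one-method `set_power(mW)` port the feedback controller
drives.

## Evaluation

Matching is per-frame optimal assignment (Hungarian) restricted to pairs
within 250 nm lateral and 500 nm axial gates (the published challenge
gates), minimizing total 3D distance. Efficiency uses
E = 100 − √((100(1−JI))² + (α·RMSE)²) with α = 1 nm⁻¹ laterally and
0.5 nm⁻¹ axially; the overall score is the mean of the two. FRC rings are
one frequency bin wide, the curve is smoothed by a 3-ring moving average
(edge-padded), and the resolution is read at the first crossing below 1/7
with linear interpolation; all crossings are reported because curves from
discretely fitted data can dip below the threshold more than once.
Rendering for FRC uses symmetric 2D Gaussians of σ = 25 nm on a 16.67 nm
grid. The live renderer bins localizations into a 10×-oversampled
histogram keeping the maximum z per bin, and colors z through a rainbow
map with a Gaussian-faded halo into empty 8-neighbors; the streaming
variant updates the z map every frame and re-colors every 10th frame,
yielding bitwise the same z map as a batch render.

## Feedback controller

Strictly-below-threshold frames increment a streak; a frame at or above
the threshold resets it. When the streak reaches its length (default 5)
the first trigger turns the laser on at one power step and every later
trigger adds a step (default 5 mW), clamped at a 50 mW safety maximum; the
streak re-arms after every trigger. Defaults: threshold 25
localizations/frame. The controller is a pure function of (state, count),
so runs are replayable.

## Problem sizes and numerical choices

The packaged star studies run at 10% of the full 225 000-emitter / 5000-
frame condition (500 frames, 22 500 emitters) with identical per-frame
density, geometry and noise; recovered fractions at this scale carry a
sampling error of ≈0.2 percentage points. Spline smoothing in bead
calibration uses least-squares cubic B-splines with knots at every other
plane (clamped ends), falling back to interpolation when too few planes
are provided. The 5×5 normal equations are solved directly (the matrix is
symmetric positive semi-definite by construction); singularity is treated
as a failed fit rather than regularized. Grid rounding uses
half-away-from-center so the two half-step boundary cases on either side
of a grid point behave symmetrically.

## Known limitations

Overlapping emitters are not resolved (the suppression radius simply
discards close pairs — with a 9 px radius and a 7.5 px simulated minimum
distance a few percent of emitters are intentionally lost); thresholding
is manual by design; CRLB defaults ignore EM excess noise (see above);
the integrated PSF variant requires φ = 0; and the challenge-style
evaluation reproduces the published metric definitions but not the
challenge's exact server-side pairing heuristics.
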