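# lutloc — real-time 3D astigmatic SMLM localization with lookup tables

Single-molecule localization microscopy (SMLM) reconstructs super-resolved
images by fitting thousands of camera frames, each containing a sparse set
of blinking fluorophores. With a cylindrical lens in the detection path the
point-spread function (PSF) becomes elliptical, and the pair of Gaussian
widths (σx(z), σy(z)) encodes the emitter's axial position. Fitting is
normally the bottleneck: if it can keep up with acquisition, the microscope
can render the image live and steer the experiment (for example, drive the
UV activation laser to keep the emitter density constant).

`lutloc` implements a localization algorithm built for that real-time
budget. Instead of evaluating a continuous PSF model inside the optimizer,
it precomputes a **lookup table** of template images — the elliptical
Gaussian

PSF<sub>i,j</sub>(x, y, z, φ) = exp(−[(i−x)cos φ + (j−y)sin φ]² / 2σx(z)² −
[−(i−x)sin φ + (j−y)cos φ]² / 2σy(z)²)

and its partial derivatives ∂PSF/∂x, ∂PSF/∂y, ∂PSF/∂z — at every discrete
lateral offset (step Δxy, default 0.1 px over ±2 px) and axial position
(step Δz, default 25 nm over ±500 nm). Each candidate emitter, found by a
modified non-maximum suppression (suppression by the 3×3-mean score rather
than the single pixel), is then fitted by Gauss–Newton least squares of the
five-parameter model I = θ<sub>bg</sub> + θ<sub>p</sub>·PSF(θx, θy, θz):
the Jacobian J = (1, PSF, θp∂x, θp∂y, θp∂z) comes straight out of the
table, the update is θ ← θ + (JᵀJ)⁻¹Jᵀr, and after every iteration the
position parameters are rounded back to the grid so the next template is an
O(1) array lookup. The discretization stabilizes the fit enough that five
iterations suffice.

The package also contains everything needed to validate the method without
external data:

* `simulation` — EMCCD camera noise (Poisson photo-electrons, Gamma EM
  register with excess-noise factor 2, Gaussian readout, baseline), a 3D
  Siemens-star test pattern (40 spokes whose filled sectors staircase from
  −450 nm upward in 45 nm steps), bead calibration stacks, and blinking
  movies with UV-dependent photoswitching;
* `evaluation` — ground-truth matching (optimal assignment within gates),
  Jaccard index, lateral/axial RMSE, challenge efficiency, Fourier ring
  correlation with the 1/7 threshold, and the real-time max-z histogram
  renderer;
* `fitting.crlb` — per-fit Cramér–Rao lower bounds from the Poisson Fisher
  information of the template model;
* `feedback` — the activation-laser controller (below 25 localizations for
  5 consecutive frames → laser on, later triggers +5 mW).

## Worked example

Simulate a sparse Siemens star, analyze it, and score against ground truth:

```sh
lutloc simulate --n-emitters 500 --n-frames 50 --seed 3 --out sim
lutloc analyze  --stack sim/movie.tif --out run
lutloc evaluate --fits run/localizations.csv \
                --ground-truth sim/ground_truth.csv --out report.json
```

which prints

```
wrote 50 frames to sim
accepted 439 localizations (469 candidates)
{
 "n_fits": 439,
 "n_ground_truth": 500,
 "tp": 426,
 "fp": 13,
 "fn": 74,
 "jaccard": 0.8304093567251462,
 "lateral_rmse_nm": 56.0161664321388,
 "axial_rmse_nm": 136.6289207020495,
 ...
}
```

439 of the 500 simulated emitters were detected and fitted; 426 of them
pair with a true emitter within the 250 nm lateral / 500 nm axial gates
(Jaccard 0.83). The lateral scatter of 56 nm RMS and axial 137 nm RMS
reflect the deliberately harsh camera model: at EM gain 300 a peak of 2000
counts corresponds to only ≈7 photo-electrons in the brightest pixel.
The localization table (`run/localizations.csv`) has one row per accepted
fit: frame, position (px and nm), peak and background counts, per-axis
CRLB, iteration count and termination reason. `lutloc analyze --streaming`
processes frames one at a time, prints per-frame counts, runs the
activation-laser controller and refreshes the incremental rendering every
10 frames; `lutloc calibrate` fits the σx/σy(z) spline calibration from a
bead z-stack TIFF.

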