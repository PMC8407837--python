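"""Candidate detection: modified non-maximum suppression + local background.

A plain NMS keeps pixels that are the largest single pixel within a radius;
here each pixel is instead scored by the mean of the 3x3 block centered on
it, which suppresses isolated hot pixels.  Surviving maxima get a local
background estimate from the perimeter of a square window, and candidates
whose peak does not clear the background by a configurable intensity
threshold are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter


@dataclass(frozen=True)
class Candidate:
    """An NMS-detected peak with its initial intensity estimates (counts).

    ``peak_estimate`` is the raw peak-pixel value (used for thresholding);
    ``score`` is the 3x3-mean NMS score at the peak, a much less noisy
    intensity estimate that the fitter prefers for initializing the peak
    parameter (a single EMCCD pixel at these gains carries ~50% relative
    noise).
    """

    frame_index: int
    px: int
    py: int
    peak_estimate: float
    background_estimate: float
    score: float | None = None


def local_background(frame: np.ndarray, center: tuple[int, int],
                     bg_window: int) -> float:
    """Mean intensity along the square boundary line of ``bg_window`` pixels.

    Only the perimeter pixels of the window enter the mean; the window is
    clipped at frame borders.
    """
    if bg_window <= 2:
        raise ValueError("bg_window must exceed 2 pixels")
    h = bg_window // 2
    cx, cy = center
    x0, x1 = cx - h, cx + (bg_window - 1) - h
    y0, y1 = cy - h, cy + (bg_window - 1) - h
    xs0, xs1 = max(x0, 0), min(x1, frame.shape[0] - 1)
    ys0, ys1 = max(y0, 0), min(y1, frame.shape[1] - 1)
    vals = []
    if x0 >= 0:
        vals.append(frame[x0, ys0:ys1 + 1])
    if x1 <= frame.shape[0] - 1:
        vals.append(frame[x1, ys0:ys1 + 1])
    inner0, inner1 = xs0 + (1 if x0 >= 0 else 0), xs1 - (1 if x1 < frame.shape[0] else 0)
    if y0 >= 0 and inner1 >= inner0:
        vals.append(frame[inner0:inner1 + 1, y0])
    if y1 <= frame.shape[1] - 1 and inner1 >= inner0:
        vals.append(frame[inner0:inner1 + 1, y1])
    allv = np.concatenate([np.atleast_1d(v) for v in vals])
    return float(allv.mean())


def find_candidates(frame: np.ndarray, suppression_radius: float = 9.0,
                    threshold: float = 0.0, bg_window: int = 10,
                    fit_window: int = 9, frame_index: int = 0) -> list[Candidate]:
    """Detect isolated single-emitter candidates in one frame.

    Pixels are scored by their 3x3 mean; maxima are kept greedily in order
    of descending score (ties broken toward the smaller (row, col)), each
    accepted maximum suppressing all competitors within ``suppression_radius``
    (Euclidean).  Candidates whose fit window of ``fit_window`` pixels would
    cross the frame border are discarded, as are candidates with
    ``peak - background <= threshold``.  Returned sorted by descending peak.
    """
    frame = np.asarray(frame, float)
    if frame.size == 0:
        raise ValueError("empty frame")
    score = uniform_filter(frame, size=3, mode="nearest")
    nx, ny = frame.shape
    xs, ys = np.unravel_index(np.arange(frame.size), frame.shape)
    # descending score; ties broken by raw pixel value (so the true peak
    # beats its equal-scoring neighbors), then lexicographically
    order = np.lexsort((ys, xs, -frame.ravel(), -score.ravel()))
    xs, ys = xs[order], ys[order]

    # greedy pass in descending score order; each accepted maximum stamps a
    # Euclidean suppression disk into the mask
    ri = int(np.floor(suppression_radius))
    dy, dx = np.meshgrid(np.arange(-ri, ri + 1), np.arange(-ri, ri + 1))
    disk = (dx * dx + dy * dy) <= suppression_radius * suppression_radius
    suppressed = np.zeros(frame.shape, dtype=bool)
    acc_x: list[int] = []
    acc_y: list[int] = []
    for x, y in zip(xs.tolist(), ys.tolist()):
        if suppressed[x, y]:
            continue
        acc_x.append(x)
        acc_y.append(y)
        x0, x1 = max(x - ri, 0), min(x + ri + 1, nx)
        y0, y1 = max(y - ri, 0), min(y + ri + 1, ny)
        suppressed[x0:x1, y0:y1] |= disk[x0 - x + ri:x1 - x + ri,
                                         y0 - y + ri:y1 - y + ri]

    margin = fit_window // 2
    out: list[Candidate] = []
    for x, y in zip(acc_x, acc_y):
        if (x < margin or y < margin or x >= frame.shape[0] - margin
                or y >= frame.shape[1] - margin):
            continue
        bg = local_background(frame, (x, y), bg_window)
        peak = float(frame[x, y])
        if peak - bg > threshold:
            out.append(Candidate(frame_index, x, y, peak, bg,
                                 float(score[x, y])))
    out.sort(key=lambda c: (-c.peak_estimate, c.px, c.py))
    return out
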