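"""Optical-mapping analysis of voltage-dye movies.

Fluorescence is normalized per pixel to its resting intensity (F/F0), one
activation cycle is windowed out of the recording, and a per-pixel
activation time is assigned — by default the linearly interpolated instant
the upstroke crosses 50% of its local amplitude, alternatively the time of
maximum temporal derivative.  Sub-frame interpolation gives timing
resolution well below the frame period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import VoltageMovie

__all__ = ["ActivationMap", "dff", "extract_cycle", "activation_map"]


@dataclass
class ActivationMap:
    """Per-pixel activation time (ms; NaN where no upstroke) and amplitude."""

    t_act: np.ndarray
    amp: np.ndarray


def dff(movie: VoltageMovie, baseline_mode: str = "percentile", k: int = 5) -> VoltageMovie:
    """Per-pixel F/F0 normalization.

    baseline_mode "percentile" (default): F0 is the per-pixel 10th
    percentile over time, robust when the rest period is short;
    "first_k": F0 is the mean of the first ``k`` frames.  Pixels with
    F0 <= 0 are set to NaN (no meaningful baseline).
    """
    if baseline_mode == "percentile":
        f0 = np.percentile(movie.frames, 10, axis=0)
    elif baseline_mode == "first_k":
        if movie.frames.shape[0] < k:
            raise ValueError(f"first_k baseline needs at least {k} frames")
        f0 = movie.frames[:k].mean(axis=0)
    else:
        raise ValueError("baseline_mode must be 'percentile' or 'first_k'")
    if np.all(f0 <= 0):
        raise ValueError("no pixel has a positive baseline")
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(f0 > 0, movie.frames / np.where(f0 > 0, f0, 1.0), np.nan)
    return VoltageMovie(frames=norm, fps=movie.fps, roi_mask=movie.roi_mask)


def extract_cycle(movie: VoltageMovie, smooth_frames: int = 3) -> tuple[int, int]:
    """Frame window (start, stop) spanning the first activation cycle.

    The spatial-mean F/F0 trace is smoothed with a short moving average;
    the window runs from the last sub-baseline frame before the first
    upstroke to the trace's return toward baseline (or the next upstroke).
    Deterministic; raises ``ValueError`` when no upstroke is present.
    """
    nt = movie.frames.shape[0]
    trace = np.nanmean(movie.frames.reshape(nt, -1), axis=1)
    trace = uniform_filter1d(trace, max(1, smooth_frames))
    lo, hi = float(np.min(trace)), float(np.max(trace))
    if hi - lo <= 1e-12 * max(abs(hi), 1.0):
        raise ValueError("flat trace: no detectable activation cycle")
    half = lo + 0.5 * (hi - lo)
    onset_level = lo + 0.1 * (hi - lo)
    above = trace >= half
    rising = np.flatnonzero(~above[:-1] & above[1:])
    if rising.size == 0:
        raise ValueError("no upstroke crossing found")
    # back up from the first half-max crossing to the upstroke onset so the
    # window contains the whole transit
    quiet = np.flatnonzero(trace[: rising[0] + 1] <= onset_level)
    start = int(quiet[-1]) if quiet.size else 0
    if rising.size > 1:
        # first cycle ends at the onset of the second upstroke
        r1 = int(rising[1])
        quiet2 = np.flatnonzero(trace[:r1] <= onset_level)
        quiet2 = quiet2[quiet2 > rising[0]]
        stop = int(quiet2[-1]) + 1 if quiet2.size else r1
    else:
        # recovery below the onset level, else the end of the recording
        rec = np.flatnonzero(trace[rising[0] :] <= onset_level)
        stop = int(rising[0] + rec[0]) + 1 if rec.size else nt
    return start, stop


def activation_map(
    movie: VoltageMovie,
    method: str = "half_max",
    threshold_frac: float = 0.5,
    noise_floor: float = 0.02,
    smooth_frames: int = 3,
) -> ActivationMap:
    """Per-pixel activation times from a normalized single-cycle movie.

    method "half_max" (default): time at which the pixel's trace crosses
    ``threshold_frac`` of its own upstroke amplitude, linearly interpolated
    between frames; method "dvdt": time of the maximum temporal derivative
    of the (lightly smoothed) trace.  Pixels whose upstroke amplitude
    (max - min of F/F0) is below ``noise_floor`` get NaN.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must lie in (0, 1)")
    frames = movie.frames
    nt = frames.shape[0]
    times = movie.times_ms
    fmin = np.nanmin(frames, axis=0)
    fmax = np.nanmax(frames, axis=0)
    amp = fmax - fmin
    ok = np.isfinite(amp) & (amp >= noise_floor)
    if movie.roi_mask is not None:
        ok &= movie.roi_mask

    t_act = np.full(frames.shape[1:], np.nan)
    if method == "half_max":
        level = fmin + threshold_frac * amp
        above = frames >= level[None, :, :]
        first = above.argmax(axis=0)  # first True along time
        ever = above.any(axis=0)
        ok &= ever & (first > 0)  # need a frame below threshold before crossing
        i1 = np.clip(first, 1, nt - 1)
        i0 = i1 - 1
        yx = np.indices(frames.shape[1:])
        f0v = frames[i0, yx[0], yx[1]]
        f1v = frames[i1, yx[0], yx[1]]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(f1v != f0v, (level - f0v) / (f1v - f0v), 0.0)
        t = times[i0] + frac * (times[i1] - times[i0])
        t_act[ok] = t[ok]
    elif method == "dvdt":
        sm = uniform_filter1d(frames, max(1, smooth_frames), axis=0)
        dv = np.diff(sm, axis=0)
        imax = dv.argmax(axis=0)
        # parabolic refinement of the discrete derivative peak
        yx = np.indices(frames.shape[1:])
        i = np.clip(imax, 1, nt - 3)
        d0, d1, d2 = (dv[i - 1, yx[0], yx[1]], dv[i, yx[0], yx[1]], dv[i + 1, yx[0], yx[1]])
        denom = d0 - 2 * d1 + d2
        with np.errstate(invalid="ignore", divide="ignore"):
            shift = np.where(np.abs(denom) > 1e-300, 0.5 * (d0 - d2) / denom, 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        t = times[i] + (0.5 + shift) * (1000.0 / movie.fps)
        t_act[ok] = t[ok]
    else:
        raise ValueError("method must be 'half_max' or 'dvdt'")
    amp_out = np.where(ok, amp, np.nan)
    return ActivationMap(t_act=t_act, amp=amp_out)
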