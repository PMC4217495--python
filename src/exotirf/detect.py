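"""Preprocessing, exocytic-event detection and trace extraction.

Events appear in TIRF movies as rapid discrete increases in fluorescence.
The detector works on a temporally differenced, spatially smoothed stack:
a pixel is a candidate when its 2-frame forward difference exceeds
``min_rise_sigma`` times a robust (MAD-based) noise SD and is a spatial
local maximum; candidates at the same site are merged within a refractory
window so that a genuine consecutive event (a second rise after a longer
gap) remains a separate detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .config import colocalization_halfwidth_px, roi_side_px
from .synthetic import Movie

__all__ = [
    "Trace",
    "DetectedEvent",
    "BleachEstimate",
    "subtract_background",
    "correct_bleaching",
    "detect_events",
    "extract_trace",
    "measure_rise_time",
    "kymograph",
]


@dataclass
class Trace:
    """Per-event intensity time series.

    ``spot`` is the per-frame maximum inside the small (default 4 um^2)
    box centered on the insertion site; ``surround`` the per-frame mean of
    the large (16 um^2) box excluding the small one.  ``background_B`` is
    the pre-onset median of the spot trace.
    """

    event_id: int
    channel: str
    times_s: np.ndarray
    spot: np.ndarray
    surround: np.ndarray
    background_B: float
    t_on_s: float = 0.0


@dataclass
class DetectedEvent:
    event_id: int
    x_px: int
    y_px: int
    t_on_s: float
    peak_intensity: float
    rise_score: float = 0.0
    traces: dict = field(default_factory=dict)


@dataclass
class BleachEstimate:
    loss_fraction: float
    model: str
    trend: np.ndarray


def _frames(movie, channel: str | None) -> np.ndarray:
    if isinstance(movie, Movie):
        return movie.channel(channel or "SEP")
    arr = np.asarray(movie)
    if arr.ndim == 4:
        return arr[..., 0]
    return arr


def _robust_mode(values: np.ndarray) -> float:
    """Histogram mode of a (background-dominated) sample."""
    lo, hi = np.percentile(values, [0.5, 99.5])
    if hi <= lo:
        return float(lo)
    hist, edges = np.histogram(values, bins=64, range=(lo, hi))
    k = int(np.argmax(hist))
    return float(0.5 * (edges[k] + edges[k + 1]))


def subtract_background(
    movie: np.ndarray | Movie,
    blank_field: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    channel: str | None = None,
) -> np.ndarray:
    """Background subtraction, clipped at zero.

    With a ``blank_field`` (one frame or a stack imaged without the cell)
    the time-averaged blank is subtracted per pixel.  Without one, the
    per-frame mode of off-mask pixels (or of all pixels when no mask is
    given) estimates the background level.
    """
    frames = _frames(movie, channel)
    if blank_field is not None:
        blank = np.asarray(blank_field, dtype=np.float64)
        if blank.ndim == 3:
            blank = blank.mean(axis=0)
        if blank.shape != frames.shape[1:]:
            raise ValueError("blank field shape mismatch")
        out = frames - blank[None]
    else:
        sel = ~mask if mask is not None else np.ones(frames.shape[1:], bool)
        levels = np.array([_robust_mode(f[sel]) for f in frames])
        out = frames - levels[:, None, None]
    return np.clip(out, 0.0, None)


def correct_bleaching(
    movie: np.ndarray | Movie,
    exclude_mask: np.ndarray | None = None,
    model: str = "exponential",
    channel: str | None = None,
) -> tuple[np.ndarray, BleachEstimate]:
    """Estimate and divide out the photobleaching trend.

    The whole-field mean over time (optionally excluding event ROIs) is
    fit with a monoexponential (or straight line); each frame is divided
    by the trend normalized to its first value.  Returns the corrected
    stack and the estimated fractional loss over the movie.
    """
    frames = _frames(movie, channel).astype(np.float64)
    T = frames.shape[0]
    if T < 10:
        raise ValueError("need at least 10 frames to estimate bleaching")
    if exclude_mask is not None:
        sel = ~exclude_mask
        series = frames[:, sel].mean(axis=1)
    else:
        series = frames.mean(axis=(1, 2))
    t = np.arange(T, dtype=np.float64)
    if model == "linear":
        b, a = np.polyfit(t, series, 1)
        trend = a + b * t
    elif model == "exponential":
        # log-linear seed, then one nonlinear refinement
        coef = np.polyfit(t, np.log(np.clip(series, 1e-9, None)), 1)
        p0 = [float(np.exp(coef[1])), float(-coef[0])]
        try:
            popt, _ = optimize.curve_fit(
                lambda x, a, b: a * np.exp(-b * x), t, series, p0=p0, maxfev=2000
            )
            trend = popt[0] * np.exp(-popt[1] * t)
        except RuntimeError:
            trend = np.exp(coef[1] + coef[0] * t)
    else:
        raise ValueError("model must be 'exponential' or 'linear'")
    trend = trend / trend[0]
    loss = float(1.0 - trend[-1])
    if loss > 0.5:
        warnings.warn(
            f"fitted intensity loss {loss:.0%} exceeds 50%; likely focus "
            "drift rather than bleaching", stacklevel=2,
        )
    corrected = frames / np.clip(trend, 1e-6, None)[:, None, None]
    return corrected, BleachEstimate(loss, model, trend)


def detect_events(
    movie: np.ndarray | Movie,
    frame_rate_hz: float | None = None,
    pixel_pitch_um: float | None = None,
    min_rise_sigma: float = 5.0,
    smooth_sigma_px: float = 1.5,
    min_separation_s: float = 0.3,
    merge_window_um2: float = 1.0,
    channel: str | None = None,
) -> list[DetectedEvent]:
    """Detect fusion events as supra-threshold rises of smoothed frames.

    Returns events sorted by onset time.  Candidates at the same site
    (within a 1 um^2 neighborhood) merge while they belong to one rise —
    a step occupies two 2-frame difference windows, so ``min_separation_s``
    defaults to 3 frames at 10 Hz; an independent supra-threshold rise
    later at the same site is reported as its own detection (the
    consecutive-event case).
    """
    frames = _frames(movie, channel).astype(np.float32)
    if isinstance(movie, Movie):
        frame_rate_hz = frame_rate_hz or movie.frame_rate_hz
        pixel_pitch_um = pixel_pitch_um or movie.pixel_pitch_um
    if frame_rate_hz is None or pixel_pitch_um is None:
        raise ValueError("frame_rate_hz and pixel_pitch_um are required")

    sm = ndimage.gaussian_filter1d(
        ndimage.gaussian_filter1d(frames, smooth_sigma_px, axis=1),
        smooth_sigma_px, axis=2,
    )
    diff = sm[2:] - sm[:-2]
    sample = diff[:: max(1, diff.shape[0] // 50)]
    sigma = float(1.4826 * np.median(np.abs(sample - np.median(sample))))
    # shot noise scales with intensity: a per-pixel temporal MAD keeps the
    # threshold honest on top of bright (e.g. persistent) spots
    sigma_px = 1.4826 * np.median(np.abs(diff - np.median(diff, axis=0)), axis=0)
    thr_map = min_rise_sigma * np.maximum(sigma, sigma_px)

    local_max = ndimage.maximum_filter(diff, size=(1, 3, 3)) == diff
    # a genuine step stays high in the next 2-frame window as well, a
    # single-frame noise spike does not
    sustained = np.ones_like(diff, dtype=bool)
    sustained[:-1] = diff[1:] > 0.5 * thr_map[None]
    cand = np.nonzero((diff > thr_map[None]) & local_max & sustained)
    if cand[0].size == 0:
        return []
    tt, yy, xx = (c.astype(np.int64) for c in cand)
    vals = diff[cand]
    order = np.argsort(tt, kind="stable")
    tt, yy, xx, vals = tt[order], yy[order], xx[order], vals[order]

    halfwidth = colocalization_halfwidth_px(merge_window_um2, pixel_pitch_um)
    sep_frames = min_separation_s * frame_rate_hz
    groups: list[dict] = []
    for t, y, x, v in zip(tt, yy, xx, vals):
        merged = False
        for g in reversed(groups):
            if t - g["t_last"] > sep_frames:
                break
            if abs(x - g["x"]) <= 2 * halfwidth and abs(y - g["y"]) <= 2 * halfwidth:
                g["t_last"] = t
                if v > g["val"]:
                    g["val"], g["x"], g["y"] = v, x, y
                merged = True
                break
        if not merged:
            groups.append({"t_on": t, "t_last": t, "x": x, "y": y, "val": v})

    events = []
    for i, g in enumerate(sorted(groups, key=lambda g: g["t_on"])):
        f0 = int(g["t_on"]) + 2  # diff[t] spans frames t..t+2; rise lands at t+2
        f0 = min(f0, frames.shape[0] - 1)
        peak = float(frames[f0: f0 + 5, g["y"], g["x"]].max())
        events.append(
            DetectedEvent(
                event_id=i, x_px=int(g["x"]), y_px=int(g["y"]),
                t_on_s=f0 / frame_rate_hz, peak_intensity=peak,
                rise_score=float(g["val"] / sigma),
            )
        )
    return events


def extract_trace(
    movie: np.ndarray | Movie,
    event,
    frame_rate_hz: float | None = None,
    pixel_pitch_um: float | None = None,
    roi_small_um2: float = 4.0,
    roi_large_um2: float = 16.0,
    channel: str | None = None,
    baseline_frames: int = 10,
    smooth_sigma_px: float = 0.0,
) -> Trace:
    """Spot (max of small ROI) and surround (mean of large ROI minus small
    ROI) intensity traces around an event.

    ROIs are odd-sided squares closest to the requested physical area.
    ``smooth_sigma_px`` > 0 applies a spatial Gaussian (matched-filter
    photometry) before taking the ROI maximum, which suppresses the
    noise-maximum bias of the raw max statistic; the default leaves the
    frames untouched.  ROIs clipped at the frame border raise an error
    when more than half of the small box falls outside, otherwise a
    warning is emitted.
    """
    frames = _frames(movie, channel)
    if smooth_sigma_px > 0:
        frames = ndimage.gaussian_filter1d(
            ndimage.gaussian_filter1d(frames.astype(np.float32), smooth_sigma_px, axis=1),
            smooth_sigma_px, axis=2,
        )
    if isinstance(movie, Movie):
        frame_rate_hz = frame_rate_hz or movie.frame_rate_hz
        pixel_pitch_um = pixel_pitch_um or movie.pixel_pitch_um
    if frame_rate_hz is None or pixel_pitch_um is None:
        raise ValueError("frame_rate_hz and pixel_pitch_um are required")
    x, y = int(event.x_px), int(event.y_px)
    t_on = float(event.t_on_s)
    H, W = frames.shape[1:]

    def box(side: int) -> tuple[slice, slice, int]:
        r = side // 2
        ys = slice(max(0, y - r), min(H, y + r + 1))
        xs = slice(max(0, x - r), min(W, x + r + 1))
        inside = (ys.stop - ys.start) * (xs.stop - xs.start)
        return ys, xs, inside

    side_s = roi_side_px(roi_small_um2, pixel_pitch_um)
    side_l = roi_side_px(roi_large_um2, pixel_pitch_um)
    ys_s, xs_s, n_in = box(side_s)
    if n_in < 0.5 * side_s**2:
        raise ValueError("event ROI clipped by more than 50% at the frame border")
    ys_l, xs_l, n_in_l = box(side_l)
    if n_in < side_s**2 or n_in_l < side_l**2:
        warnings.warn("ROI clipped at frame border", stacklevel=2)

    spot = frames[:, ys_s, xs_s].max(axis=(1, 2)).astype(np.float64)
    large = frames[:, ys_l, xs_l].sum(axis=(1, 2), dtype=np.float64)
    small_sum = frames[:, ys_s, xs_s].sum(axis=(1, 2), dtype=np.float64)
    n_sur = n_in_l - n_in
    surround = (large - small_sum) / max(1, n_sur)

    f_on = int(round(t_on * frame_rate_hz))
    lo = max(0, f_on - baseline_frames)
    pre = spot[lo:f_on]
    if pre.size < 3:
        pre = spot[: max(3, f_on)]
    background = float(np.median(pre)) if pre.size else float(np.median(spot))

    return Trace(
        event_id=getattr(event, "event_id", -1),
        channel=channel or "SEP",
        times_s=np.arange(frames.shape[0]) / frame_rate_hz,
        spot=spot,
        surround=surround,
        background_B=background,
        t_on_s=t_on,
    )


def measure_rise_time(
    trace: Trace, peak_window_s: float | None = 2.0
) -> float:
    """10-90% rise time (s) from baseline to peak, linearly interpolated.

    The peak is searched within ``peak_window_s`` after the trace onset so
    that unrelated later events inside the ROI do not shift it, and the
    baseline is the local pre-onset level (median of the 3 frames before
    onset; falls back to ``background_B``) so that an earlier event at a
    nearby site does not stretch the apparent rise.  A peak at the very
    first frame leaves the rise undefined and raises.
    """
    y = np.asarray(trace.spot, dtype=np.float64)
    t = np.asarray(trace.times_s, dtype=np.float64)
    f_on = int(np.searchsorted(t, trace.t_on_s))
    if peak_window_s is None:
        hi = y.size
    else:
        hi = min(y.size, int(np.searchsorted(t, trace.t_on_s + peak_window_s)) + 1)
    seg = y[: hi]
    p = int(np.argmax(seg[max(0, f_on - 2):])) + max(0, f_on - 2)
    if p == 0:
        raise ValueError("peak at first frame; rise time undefined")
    B = trace.background_B
    peak = y[p]
    if f_on >= 1:
        local = float(np.median(y[max(0, f_on - 3): f_on]))
        if peak > local > B:
            B = local
    if peak <= B:
        raise ValueError("peak does not exceed background")
    lvl10 = B + 0.1 * (peak - B)
    lvl90 = B + 0.9 * (peak - B)

    def crossing(level: float) -> float:
        below = np.nonzero(y[:p] < level)[0]
        if below.size == 0:
            return t[0]
        i = below[-1]
        y0, y1 = y[i], y[i + 1]
        frac = (level - y0) / (y1 - y0) if y1 != y0 else 0.0
        return t[i] + frac * (t[i + 1] - t[i])

    return float(crossing(lvl90) - crossing(lvl10))


def kymograph(
    movie: np.ndarray | Movie,
    path_px: np.ndarray,
    width_px: int = 1,
    channel: str | None = None,
) -> np.ndarray:
    """Intensity along a polyline over time: rows = positions, cols = frames.

    ``path_px`` is an (n, 2) array of (x, y) vertices.  Intensity is
    sampled at 1-px spacing along the path and averaged over ``width_px``
    samples perpendicular to it.
    """
    frames = _frames(movie, channel)
    pts = np.asarray(path_px, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("path must contain at least two (x, y) points")
    H, W = frames.shape[1:]
    if (pts[:, 0].min() < 0 or pts[:, 0].max() >= W
            or pts[:, 1].min() < 0 or pts[:, 1].max() >= H):
        raise ValueError("path outside the frame")

    # resample the polyline at ~1 px spacing
    seglen = np.hypot(*(np.diff(pts, axis=0).T))
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    n = max(2, int(np.ceil(s[-1])) + 1)
    si = np.linspace(0.0, s[-1], n)
    xs = np.interp(si, s, pts[:, 0])
    ys = np.interp(si, s, pts[:, 1])
    dx = np.gradient(xs)
    dy = np.gradient(ys)
    norm = np.hypot(dx, dy)
    nx, ny = -dy / np.clip(norm, 1e-9, None), dx / np.clip(norm, 1e-9, None)

    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    sample_x = xs[:, None] + offsets[None, :] * nx[:, None]
    sample_y = ys[:, None] + offsets[None, :] * ny[:, None]
    coords = np.stack([sample_y.ravel(), sample_x.ravel()])

    out = np.empty((n, frames.shape[0]), dtype=np.float64)
    for ti in range(frames.shape[0]):
        vals = ndimage.map_coordinates(frames[ti], coords, order=1, mode="nearest")
        out[:, ti] = vals.reshape(n, width_px).mean(axis=1)
    return out
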