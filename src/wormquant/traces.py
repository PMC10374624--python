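"""Photobleach baseline estimation and F/F0 correction of ROI traces.

Spontaneous GCaMP recordings decay slowly under illumination; transient
quantification therefore operates on a bleach-corrected F/F0 series.  The
baseline is estimated by placing one anchor per fixed-width time window — a
low percentile of the (optionally event-masked) fluorescence in that window
— and passing a cubic interpolant through the anchors.  Dividing the
background-subtracted trace by this baseline yields F/F0 ≈ 1 at rest.

Percentile anchors of a noisy signal are biased low by the corresponding
Gaussian quantile of the noise; anchors are therefore de-biased by adding
back ``z_p * sigma`` with sigma estimated robustly per window from first
differences (MAD / sqrt(2)).  For a flat noiseless trace the correction is
exactly zero, so the constant fixed point F/F0 ≡ 1 is preserved.

The recommended entry point is :func:`correct_pipeline`, which runs two
passes: a provisional event-robust baseline (low percentile), provisional
event detection, then a final baseline with event frames masked (median
anchors, which are unbiased at the window centre for monotone bleach).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.stats import norm

from .errors import ValidationError, NumericalError

logger = logging.getLogger(__name__)

_GRID_RTOL = 1e-6


def _check_uniform_grid(time_s: np.ndarray) -> float:
    if time_s.ndim != 1 or time_s.size < 2:
        raise ValidationError("time_s", "need at least two samples")
    steps = np.diff(time_s)
    dt = steps[0]
    if dt <= 0 or not np.allclose(steps, dt, rtol=0, atol=_GRID_RTOL * dt):
        raise ValidationError("time_s",
                              "must be strictly increasing with constant step")
    return float(dt)


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class RawTrace:
    """Uniformly sampled per-ROI fluorescence with optional background."""

    time_s: np.ndarray
    f_total: np.ndarray
    f_bg: float | np.ndarray = 0.0
    sample_rate_hz: float = 1.0
    roi_label: str = "roi_0"

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f_total = np.asarray(self.f_total, dtype=float)
        _check_uniform_grid(self.time_s)
        if self.f_total.shape != self.time_s.shape:
            raise ValidationError("f_total", "length must match time_s")
        if np.ndim(self.f_bg) > 0:
            self.f_bg = np.asarray(self.f_bg, dtype=float)
            if self.f_bg.shape != self.time_s.shape:
                raise ValidationError(
                    "f_bg", "per-frame background must match trace length")


@dataclass
class Trace:
    """Background-subtracted fluorescence on the source grid."""

    time_s: np.ndarray
    f: np.ndarray
    sample_rate_hz: float = 1.0
    roi_label: str = "roi_0"

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.f.shape != self.time_s.shape:
            raise ValidationError("f", "length must match time_s")


@dataclass
class BaselineFit:
    anchor_times_s: np.ndarray
    anchor_values: np.ndarray
    baseline: np.ndarray
    method: str

    def __post_init__(self):
        if np.any(~np.isfinite(self.baseline)):
            raise NumericalError("baseline contains non-finite values")


@dataclass
class NormalizedTrace:
    """Bleach-corrected F/F0 series (≈ 1 at rest)."""

    time_s: np.ndarray
    ffz: np.ndarray
    baseline_used: BaselineFit
    sample_rate_hz: float = 1.0
    roi_label: str = "roi_0"
    provenance: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def subtract_background(raw: RawTrace) -> Trace:
    """F = F_total - F_bg elementwise (scalar or per-frame background)."""
    f = raw.f_total - raw.f_bg
    return Trace(time_s=raw.time_s, f=f, sample_rate_hz=raw.sample_rate_hz,
                 roi_label=raw.roi_label)


def _window_sigma(values: np.ndarray) -> float:
    """Robust noise SD from first differences (immune to slow trends)."""
    if values.size < 3:
        return 0.0
    d = np.diff(values)
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad * 1.4826 / math.sqrt(2.0))


def estimate_baseline(trace: Trace, window_s: float = 30.0,
                      percentile: float = 0.08,
                      exclusion_mask: np.ndarray | None = None,
                      bias_correct: bool = True) -> BaselineFit:
    """Anchor-and-interpolate baseline estimate.

    One anchor per non-overlapping ``window_s`` window: the given percentile
    of the unmasked fluorescence, placed at the window centre.  With
    ``bias_correct`` (default) the Gaussian quantile offset of the noise is
    added back so the anchor is an unbiased baseline estimate rather than a
    noise-floor estimate.  Anchors are joined by a cubic spline, extended
    linearly (end-anchor secant slope) beyond the outermost anchors; with
    fewer than 4 anchors the interpolation falls back to linear (with a
    logged warning).

    A fully masked window contributes no anchor.
    """
    dt = _check_uniform_grid(trace.time_s)
    n = trace.time_s.size
    win = max(int(round(window_s / dt)), 1)
    if n < 3 * win:
        raise ValidationError("trace", "need at least 3 windows of data")
    if not (0 < percentile <= 0.5):
        raise ValidationError("percentile", "must be in (0, 0.5]")
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
        if exclusion_mask.shape != trace.f.shape:
            raise ValidationError("exclusion_mask", "length must match trace")

    z_offset = float(norm.ppf(percentile))  # <= 0; 0 at the median
    anchor_t, anchor_v = [], []
    for start in range(0, n - win + 1, win):
        sl = slice(start, start + win)
        vals = trace.f[sl]
        if exclusion_mask is not None:
            vals = vals[~exclusion_mask[sl]]
            # a nearly fully masked window yields an anchor dominated by
            # whatever leaked past the mask; skip it instead
            if vals.size < max(3, win // 6):
                continue
        if vals.size == 0:
            continue
        anchor = float(np.quantile(vals, percentile))
        if bias_correct and percentile != 0.5:
            anchor -= z_offset * _window_sigma(vals)
        anchor_t.append(float(np.mean(trace.time_s[sl])))
        anchor_v.append(anchor)

    anchor_t = np.asarray(anchor_t)
    anchor_v = np.asarray(anchor_v)
    if anchor_t.size == 0:
        raise NumericalError("no usable anchors: every window fully masked")

    if anchor_t.size >= 4:
        interp = CubicSpline(anchor_t, anchor_v)
        method = "cubic"
    elif anchor_t.size >= 2:
        logger.warning("only %d baseline anchors; falling back to linear "
                       "interpolation", anchor_t.size)

        def interp(x):
            return np.interp(x, anchor_t, anchor_v)

        method = "linear"
    else:
        logger.warning("single baseline anchor; baseline is constant")
        const = anchor_v[0]

        def interp(x):
            return np.full_like(np.asarray(x, dtype=float), const)

        method = "constant"

    # interpolate inside the anchor span; extend linearly beyond it using
    # the secant slope of the two outermost anchors (cubic extrapolation is
    # unstable, constant clamping ignores the bleach slope at the edges)
    t_clamped = np.clip(trace.time_s, anchor_t[0], anchor_t[-1])
    baseline = np.asarray(interp(t_clamped), dtype=float)
    if anchor_t.size >= 2:
        lo = trace.time_s < anchor_t[0]
        hi = trace.time_s > anchor_t[-1]
        slope0 = (anchor_v[1] - anchor_v[0]) / (anchor_t[1] - anchor_t[0])
        slope1 = (anchor_v[-1] - anchor_v[-2]) / (anchor_t[-1] - anchor_t[-2])
        baseline[lo] = anchor_v[0] + slope0 * (trace.time_s[lo] - anchor_t[0])
        baseline[hi] = anchor_v[-1] + slope1 * (trace.time_s[hi]
                                                - anchor_t[-1])
    fit = BaselineFit(anchor_times_s=anchor_t, anchor_values=anchor_v,
                      baseline=baseline, method=method)
    if np.any(fit.baseline <= 0):
        bad = int(np.argmax(fit.baseline <= 0))
        raise NumericalError(f"non-positive baseline at frame {bad} "
                             f"(t={trace.time_s[bad]:.3f} s)")
    return fit


def bleach_correct(trace: Trace, baseline: BaselineFit) -> NormalizedTrace:
    """F/F0 = F divided by the fitted baseline, frame by frame."""
    if baseline.baseline.shape != trace.f.shape:
        raise ValidationError("baseline", "length must match trace")
    nonpos = baseline.baseline <= 0
    if np.any(nonpos):
        bad = int(np.argmax(nonpos))
        raise NumericalError(f"non-positive baseline at frame {bad}")
    ffz = trace.f / baseline.baseline
    return NormalizedTrace(time_s=trace.time_s, ffz=ffz,
                           baseline_used=baseline,
                           sample_rate_hz=trace.sample_rate_hz,
                           roi_label=trace.roi_label)


def correct_pipeline(raw: RawTrace, window_s: float = 30.0,
                     percentile_pass1: float = 0.08,
                     percentile_pass2: float = 0.5,
                     two_pass: bool = True,
                     event_threshold: float = 0.1,
                     event_min_duration_s: float = 3.0,
                     mask_pad_pre_s: float = 2.0,
                     mask_pad_post_s: float = 6.0) -> NormalizedTrace:
    """Two-pass bleach correction.

    Pass 1 estimates an event-robust baseline (low percentile, de-biased)
    and detects provisional transients on the provisional F/F0.  Pass 2
    masks the detected event frames — padded by ``mask_pad_pre_s`` before
    the onset and by the longer ``mask_pad_post_s`` after the offset, since
    the decaying tail of a transient stays above the resting level well
    after it falls below the detection gate — and re-estimates the baseline
    with median anchors, which are unbiased at the window centre for a
    monotone bleach trend.  The returned trace carries both passes in its
    provenance.
    """
    from .events import detect_events  # late import: events consumes our types

    if raw.time_s.size == 0:
        raise ValidationError("raw", "zero-length trace")
    trace = subtract_background(raw)
    base1 = estimate_baseline(trace, window_s=window_s,
                              percentile=percentile_pass1)
    nt1 = bleach_correct(trace, base1)
    params = {
        "window_s": window_s, "percentile_pass1": percentile_pass1,
        "percentile_pass2": percentile_pass2, "two_pass": two_pass,
        "event_threshold": event_threshold,
        "event_min_duration_s": event_min_duration_s,
        "mask_pad_pre_s": mask_pad_pre_s,
        "mask_pad_post_s": mask_pad_post_s,
    }
    if not two_pass:
        nt1.provenance = {"passes": 1, "params": params,
                          "baseline_method_pass1": base1.method}
        return nt1

    events = detect_events(nt1, threshold=event_threshold,
                           min_duration_s=event_min_duration_s)
    # mask detected events with their pads, plus every supra-threshold frame
    # even in runs too short to qualify as events (e.g. truncated at the
    # recording edge) — such frames are never baseline
    mask = nt1.ffz >= 1.0 + event_threshold
    for ev in events:
        lo = ev.onset_s - mask_pad_pre_s
        hi = ev.offset_s + mask_pad_post_s
        mask |= (trace.time_s >= lo) & (trace.time_s < hi)

    try:
        base2 = estimate_baseline(trace, window_s=window_s,
                                  percentile=percentile_pass2,
                                  exclusion_mask=mask)
    except NumericalError:
        logger.warning("pass-2 baseline unusable (all windows masked); "
                       "keeping the pass-1 baseline")
        base2 = base1
    nt2 = bleach_correct(trace, base2)
    nt2.provenance = {"passes": 2, "params": params,
                      "baseline_method_pass1": base1.method,
                      "baseline_method_pass2": base2.method,
                      "n_provisional_events": len(events),
                      "masked_frames": int(mask.sum())}
    return nt2
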