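"""Spontaneous Ca²⁺ transient detection and cross-neuron synchrony.

A transient is any maximal run of frames with F/F0 at least a threshold
above the resting level of 1 (default 0.1) that lasts at least a minimum
duration (default 3 s).  Both gates act jointly: raising either can only
remove events, never create them.  Events are reported on half-open
intervals [onset, offset) so durations are exact multiples of the frame
interval; no merging across sub-threshold gaps is performed.

Synchrony between two corrected traces is measured by the Pearson
correlation coefficient, at zero lag (the comparison statistic) and over a
symmetric grid of integer-sample lags (the correlogram), each lag normalized
over its own overlap so every value lies in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .traces import NormalizedTrace, _check_uniform_grid


@dataclass
class CaEvent:
    onset_s: float
    offset_s: float        # half-open: [onset_s, offset_s)
    peak_time_s: float
    amplitude: float       # max F/F0 minus 1 within the run
    duration_s: float

    def __post_init__(self):
        if not (self.onset_s <= self.peak_time_s < self.offset_s):
            raise ValidationError("peak_time_s",
                                  "must lie within [onset, offset)")


@dataclass
class EventStats:
    frequency_per_min: float
    mean_amplitude: float | None   # None when there are no events
    n_events: int
    recording_min: float


@dataclass
class XcorrResult:
    lags_s: np.ndarray
    r: np.ndarray
    r0: float
    label_a: str
    label_b: str


def detect_events(nt: NormalizedTrace, threshold: float = 0.1,
                  min_duration_s: float = 3.0) -> list[CaEvent]:
    """Threshold-and-duration gate on a bleach-corrected F/F0 trace.

    An event spans every maximal run of frames with ffz >= 1 + threshold;
    runs shorter than ``min_duration_s`` are discarded.  Amplitude is the
    run maximum minus 1; the peak time is the earliest maximal frame.
    """
    if threshold <= 0:
        raise ValidationError("threshold", "must be > 0")
    dt = _check_uniform_grid(nt.time_s)
    above = nt.ffz >= 1.0 + threshold
    if not above.any():
        return []

    # run boundaries of the boolean mask
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[0::2], edges[1::2]  # stop is exclusive

    events: list[CaEvent] = []
    for s, e in zip(starts, stops):
        duration = (e - s) * dt
        if duration < min_duration_s:
            continue
        seg = nt.ffz[s:e]
        peak_idx = s + int(np.argmax(seg))
        events.append(CaEvent(onset_s=float(nt.time_s[s]),
                              offset_s=float(nt.time_s[s] + (e - s) * dt),
                              peak_time_s=float(nt.time_s[peak_idx]),
                              amplitude=float(seg.max() - 1.0),
                              duration_s=float(duration)))
    events.sort(key=lambda ev: ev.onset_s)
    return events


def summarize_events(events: list[CaEvent],
                     recording_duration_s: float) -> EventStats:
    """Event frequency (per minute) and mean amplitude over a recording."""
    if recording_duration_s <= 0:
        raise ValidationError("recording_duration_s", "must be > 0")
    minutes = recording_duration_s / 60.0
    n = len(events)
    mean_amp = float(np.mean([ev.amplitude for ev in events])) if n else None
    return EventStats(frequency_per_min=n / minutes, mean_amplitude=mean_amp,
                      n_events=n, recording_min=minutes)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return np.nan
    return float((xc @ yc) / denom)


def cross_correlate(a: NormalizedTrace, b: NormalizedTrace,
                    max_lag_s: float = 30.0) -> XcorrResult:
    """Lagged Pearson correlation between two traces on a shared grid.

    r(lag) correlates a(t) with b(t + lag) over their overlap, each series
    mean-centred and variance-normalized on that overlap, so r(0) is the
    plain Pearson coefficient of the aligned traces and every value is
    bounded by [-1, 1].
    """
    dt_a = _check_uniform_grid(a.time_s)
    dt_b = _check_uniform_grid(b.time_s)
    if a.time_s.shape != b.time_s.shape or \
            not np.allclose(a.time_s, b.time_s, rtol=0, atol=1e-6 * dt_a):
        raise ValidationError("time_s", "traces must share one time grid")
    dt = dt_a
    del dt_b
    for nt in (a, b):
        if np.std(nt.ffz) == 0:
            raise ValidationError(nt.roi_label, "zero-variance trace")

    n = a.ffz.size
    max_lag = min(int(round(max_lag_s / dt)), n - 2)
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if lag >= 0:
            x, y = a.ffz[: n - lag], b.ffz[lag:]
        else:
            x, y = a.ffz[-lag:], b.ffz[: n + lag]
        r[i] = _pearson(x, y)
    r0 = float(r[max_lag])
    return XcorrResult(lags_s=lags * dt, r=r, r0=r0,
                       label_a=a.roi_label, label_b=b.roi_label)
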