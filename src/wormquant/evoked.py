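"""Stimulus-evoked Ca²⁺-drop quantification and training-induced changes.

Application of bacterial supernatant to the nose evokes a drop in
interneuron Ca²⁺; its attenuation after aversive training is the imaging
correlate of learning.  Quantification follows fixed windowing rules:

* ΔF/F0 = (F - F0)/F0 with F0 the mean fluorescence of the 10 s before
  stimulus onset;
* response amplitude = mean ΔF/F0 over the first 20 s of the stimulus
  (signed, negative for a drop);
* drop duration runs from the sharp downward deflection to the moment at
  least 70% of the drop has perished, with sub-frame linear interpolation
  of the recovery crossing;
* training effects are ((trained / naïve) - 1) x 100% on the amplitude
  magnitude and on the duration.

The drop onset is operationalized as the first frame at or after stimulus
onset more than ``onset_k`` pre-stimulus noise SDs below zero, sustained for
``sustain_frames`` consecutive frames; both knobs are recorded in output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .traces import Trace, _check_uniform_grid


@dataclass(frozen=True)
class StimWindow:
    stim_onset_s: float
    stim_dur_s: float = 30.0
    pre_window_s: float = 10.0      # F0 window
    analysis_window_s: float = 20.0  # amplitude window

    def __post_init__(self):
        if self.stim_onset_s < self.pre_window_s:
            raise ValidationError("stim_onset_s",
                                  "must be >= pre_window_s")
        if self.analysis_window_s > self.stim_dur_s:
            raise ValidationError("analysis_window_s",
                                  "must be <= stim_dur_s")


@dataclass
class DffTrace:
    time_s: np.ndarray
    dff: np.ndarray
    f0_pre: float
    sample_rate_hz: float = 1.0
    roi_label: str = "roi_0"


@dataclass
class EvokedMetrics:
    amplitude: float            # mean dff over first 20 s of stimulus
    drop_detected: bool
    drop_onset_s: float = math.nan
    trough_value: float = math.nan
    drop_magnitude: float = math.nan
    duration_s: float = math.nan
    roi_label: str = "roi_0"


@dataclass
class TrainingEffect:
    amp_change_pct: float
    dur_change_pct: float


def compute_dff(trace: Trace, w: StimWindow) -> DffTrace:
    """ΔF/F0 relative to the mean of the 10 s preceding the stimulus."""
    _check_uniform_grid(trace.time_s)
    pre = (trace.time_s >= w.stim_onset_s - w.pre_window_s) & \
          (trace.time_s < w.stim_onset_s)
    expected = w.pre_window_s * trace.sample_rate_hz
    if pre.sum() < math.floor(expected):
        raise ValidationError("pre_window",
                              f"only {int(pre.sum())} pre-stimulus frames; "
                              f"need {int(expected)}")
    f0 = float(trace.f[pre].mean())
    if f0 <= 0:
        raise ValidationError("f0_pre", "pre-stimulus mean must be > 0")
    return DffTrace(time_s=trace.time_s, dff=(trace.f - f0) / f0, f0_pre=f0,
                    sample_rate_hz=trace.sample_rate_hz,
                    roi_label=trace.roi_label)


def evoked_amplitude(d: DffTrace, w: StimWindow) -> float:
    """Mean ΔF/F0 over the first ``analysis_window_s`` of the stimulus."""
    sel = (d.time_s >= w.stim_onset_s) & \
          (d.time_s < w.stim_onset_s + w.analysis_window_s)
    expected = int(round(w.analysis_window_s * d.sample_rate_hz))
    if sel.sum() < expected:
        raise ValidationError("analysis_window",
                              f"only {int(sel.sum())} in-stimulus frames; "
                              f"need {expected}")
    return float(d.dff[sel].mean())


def drop_duration(d: DffTrace, w: StimWindow, onset_k: float = 3.0,
                  sustain_frames: int = 2) -> EvokedMetrics:
    """Full drop metrics: onset, trough, magnitude, and 70%-perished duration.

    Onset: first frame at/after stimulus onset with dff below
    ``-onset_k * sigma_pre`` for ``sustain_frames`` consecutive frames,
    where sigma_pre is the SD of the pre-stimulus dff.  Trough: minimum dff
    from onset onward.  The drop ends at the first crossing (after the
    trough) of 30% of the trough depth, located by linear interpolation
    between frames.  Returns a no-drop flag when no onset qualifies.
    """
    amplitude = evoked_amplitude(d, w)
    pre = (d.time_s >= w.stim_onset_s - w.pre_window_s) & \
          (d.time_s < w.stim_onset_s)
    sigma_pre = float(d.dff[pre].std(ddof=1))
    gate = -onset_k * sigma_pre

    post = np.flatnonzero(d.time_s >= w.stim_onset_s)
    onset_idx = None
    below = d.dff < gate
    for i in post:
        if i + sustain_frames <= d.dff.size and below[i:i + sustain_frames].all():
            onset_idx = i
            break
    if onset_idx is None:
        return EvokedMetrics(amplitude=amplitude, drop_detected=False,
                             roi_label=d.roi_label)

    after = d.dff[onset_idx:]
    trough_rel = int(np.argmin(after))
    trough_idx = onset_idx + trough_rel
    trough = float(d.dff[trough_idx])
    level = 0.3 * trough          # 70% of the drop has perished

    end_t = None
    for j in range(trough_idx + 1, d.dff.size):
        if d.dff[j] >= level:
            prev, cur = d.dff[j - 1], d.dff[j]
            t_prev, t_cur = d.time_s[j - 1], d.time_s[j]
            if cur == prev:
                end_t = float(t_cur)
            else:
                frac = (level - prev) / (cur - prev)
                end_t = float(t_prev + frac * (t_cur - t_prev))
            break
    if end_t is None:
        # never recovered within the recording; duration runs to the end
        end_t = float(d.time_s[-1])

    onset_t = float(d.time_s[onset_idx])
    return EvokedMetrics(amplitude=amplitude, drop_detected=True,
                         drop_onset_s=onset_t, trough_value=trough,
                         drop_magnitude=abs(trough),
                         duration_s=end_t - onset_t, roi_label=d.roi_label)


def training_effect(naive: EvokedMetrics,
                    trained: EvokedMetrics) -> TrainingEffect:
    """Percent change of trained vs naïve response, on magnitudes.

    amp_change = ((|amp_trained| / |amp_naive|) - 1) x 100;
    dur_change = ((dur_trained / dur_naive) - 1) x 100.
    """
    if naive.amplitude == 0:
        raise ValidationError("naive.amplitude", "must be nonzero")
    if not naive.duration_s or math.isnan(naive.duration_s) \
            or naive.duration_s == 0:
        raise ValidationError("naive.duration_s", "must be nonzero")
    trained_dur = trained.duration_s if trained.drop_detected else 0.0
    amp = (abs(trained.amplitude) / abs(naive.amplitude) - 1.0) * 100.0
    dur = (trained_dur / naive.duration_s - 1.0) * 100.0
    return TrainingEffect(amp_change_pct=amp, dur_change_pct=dur)


def group_training_effect(naive: list[EvokedMetrics],
                          trained: list[EvokedMetrics]) -> TrainingEffect:
    """Training effect computed from group means of the per-animal metrics."""
    if not naive or not trained:
        raise ValidationError("groups", "both groups must be non-empty")

    def _mean_amp(group):
        return float(np.mean([abs(m.amplitude) for m in group]))

    def _mean_dur(group):
        return float(np.mean([m.duration_s if m.drop_detected else 0.0
                              for m in group]))

    na, nd = _mean_amp(naive), _mean_dur(naive)
    if na == 0:
        raise ValidationError("naive amplitude mean", "must be nonzero")
    if nd == 0:
        raise ValidationError("naive duration mean", "must be nonzero")
    return TrainingEffect(
        amp_change_pct=(_mean_amp(trained) / na - 1.0) * 100.0,
        dur_change_pct=(_mean_dur(trained) / nd - 1.0) * 100.0)
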