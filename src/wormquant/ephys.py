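"""Junctional-current, mechanoreceptor-current, and stimulus-mean analysis.

Dual whole-cell recordings hold neuron #1 at -30 mV while voltage steps are
applied to neuron #2; the transjunctional voltage is Vj = -30 mV - Vm2, and
the junctional current Ij is the mean current over the last 100 ms of the
step, baseline-subtracted against the 100 ms preceding it.  Fitting
through-origin slopes to the two signs of Vj gives per-direction
conductances whose ratio quantifies rectification (which Vj sign is the
antidromic direction comes from the protocol descriptor, never from the
data).

Mechanoreceptor currents (MRCs) show a fast peak and a sustained plateau;
the sustained component is again the mean of the last 100 ms of the
stimulus.  Kinetics use 10%/90%-of-peak crossings with linear
interpolation; MRC duration is the total time the baseline-subtracted
current stays at or above 10% of the peak magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .traces import _check_uniform_grid


@dataclass(frozen=True)
class ProtocolWindow:
    onset_ms: float
    offset_ms: float
    level: float = 0.0       # step level (mV) or stimulus marker
    kind: str = "stimulus"   # vj_step | stimulus

    def __post_init__(self):
        if self.offset_ms <= self.onset_ms:
            raise ValidationError("offset_ms", "must exceed onset_ms")


@dataclass
class Sweep:
    time_ms: np.ndarray
    signal: np.ndarray        # pA or mV
    units: str = "pA"
    windows: list[ProtocolWindow] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        _check_uniform_grid(self.time_ms)
        if self.signal.shape != self.time_ms.shape:
            raise ValidationError("signal", "length must match time_ms")
        for w in self.windows:
            if w.onset_ms < self.time_ms[0] or w.offset_ms > \
                    self.time_ms[-1] + (self.time_ms[1] - self.time_ms[0]):
                raise ValidationError("windows", "annotation outside sweep")

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    def _sel(self, lo_ms: float, hi_ms: float) -> np.ndarray:
        return (self.time_ms >= lo_ms) & (self.time_ms < hi_ms)


@dataclass(frozen=True)
class IjPoint:
    vj_mV: float
    ij_pA: float


@dataclass
class IjCurve:
    points: list[IjPoint]
    slope_antidromic_nS: float
    slope_orthodromic_nS: float
    rectification_ratio: float
    ratio_infinite: bool = False


@dataclass
class MRCMetrics:
    peak_pA: float
    sustained_pA: float
    latency_ms: float = math.nan
    rise_ms: float = math.nan
    mrc_duration_ms: float = math.nan
    kinetics_defined: bool = True


@dataclass(frozen=True)
class PairedPulseResult:
    peak1_pA: float
    peak2_pA: float
    ratio: float
    inter_pulse_interval_ms: float


def compute_vj(vm2_mV: float, vm1_mV: float = -30.0) -> float:
    """Transjunctional voltage: Vm of neuron #1 minus Vm of neuron #2."""
    return vm1_mV - vm2_mV


def _single_window(sweep: Sweep, kind: str | None = None) -> ProtocolWindow:
    wins = [w for w in sweep.windows if kind is None or w.kind == kind]
    if not wins:
        raise ValidationError("windows", "sweep has no annotated window")
    return wins[0]


def quantify_ij(sweep: Sweep) -> IjPoint:
    """Mean current over the last 100 ms of the Vj step, baseline-subtracted.

    The baseline is the mean of the 100 ms immediately preceding the step.
    """
    w = _single_window(sweep)
    if w.offset_ms - w.onset_ms < 100.0:
        raise ValidationError("windows", "Vj step shorter than 100 ms")
    tail = sweep._sel(w.offset_ms - 100.0, w.offset_ms)
    base = sweep._sel(w.onset_ms - 100.0, w.onset_ms)
    if not base.any():
        raise ValidationError("windows", "no pre-step baseline available")
    ij = float(sweep.signal[tail].mean() - sweep.signal[base].mean())
    return IjPoint(vj_mV=w.level, ij_pA=ij)


def build_ij_curve(points: list[IjPoint],
                   antidromic_sign: int = 1) -> IjCurve:
    """Per-direction through-origin conductances and rectification ratio.

    Conductance per side is the through-origin OLS slope sum(Vj*Ij)/sum(Vj²)
    in nS (pA/mV).  The rectification ratio is the antidromic-side slope
    over the orthodromic-side slope; a zero orthodromic conductance yields
    an infinite ratio with ``ratio_infinite`` set.
    """
    if antidromic_sign not in (-1, 1):
        raise ValidationError("antidromic_sign", "must be -1 or +1")
    vj = np.array([p.vj_mV for p in points], dtype=float)
    ij = np.array([p.ij_pA for p in points], dtype=float)
    if np.unique(vj).size != vj.size:
        raise ValidationError("points", "duplicate Vj values in curve")

    def through_origin(mask):
        if mask.sum() < 2:
            raise ValidationError("points",
                                  "need >= 2 points on each Vj sign")
        v, i = vj[mask], ij[mask]
        return float((v @ i) / (v @ v))

    slope_pos = through_origin(vj > 0)
    slope_neg = through_origin(vj < 0)
    slope_anti = slope_pos if antidromic_sign == 1 else slope_neg
    slope_ortho = slope_neg if antidromic_sign == 1 else slope_pos

    if slope_ortho == 0:
        ratio, infinite = math.inf, True
    else:
        ratio, infinite = slope_anti / slope_ortho, False
    ordered = [IjPoint(v, i) for v, i in sorted(zip(vj, ij))]
    return IjCurve(points=ordered, slope_antidromic_nS=slope_anti,
                   slope_orthodromic_nS=slope_ortho,
                   rectification_ratio=ratio, ratio_infinite=infinite)


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float,
                     rising_toward_peak: bool) -> float:
    """First time y crosses `level` (in the direction of the peak)."""
    if rising_toward_peak:
        hit = np.flatnonzero(y >= level)
    else:
        hit = np.flatnonzero(y <= level)
    j = int(hit[0])
    if j == 0 or y[j] == y[j - 1]:
        return float(t[j])
    frac = (level - y[j - 1]) / (y[j] - y[j - 1])
    return float(t[j - 1] + frac * (t[j] - t[j - 1]))


def quantify_mrc(sweep: Sweep, baseline_ms: float = 50.0) -> MRCMetrics:
    """Peak, sustained level, latency, rise time and duration of an MRC."""
    w = _single_window(sweep)
    if w.offset_ms - w.onset_ms < 100.0:
        raise ValidationError("windows", "stimulus shorter than 100 ms")
    base_sel = sweep._sel(w.onset_ms - baseline_ms, w.onset_ms)
    if base_sel.sum() * sweep.dt_ms < baseline_ms - sweep.dt_ms:
        raise ValidationError("windows",
                              f"need >= {baseline_ms} ms pre-stimulus "
                              "baseline")
    baseline = float(sweep.signal[base_sel].mean())
    sig = sweep.signal - baseline

    stim = sweep._sel(w.onset_ms, w.offset_ms)
    seg = sig[stim]
    t_seg = sweep.time_ms[stim]
    peak_idx = int(np.argmax(np.abs(seg)))
    peak = float(seg[peak_idx])
    sustained = float(sig[sweep._sel(w.offset_ms - 100.0, w.offset_ms)].mean())

    if peak == 0:
        return MRCMetrics(peak_pA=0.0, sustained_pA=sustained,
                          kinetics_defined=False)

    sign = 1.0 if peak > 0 else -1.0
    mag = sign * seg[: peak_idx + 1]            # rising phase, positive-going
    t_rise = t_seg[: peak_idx + 1]
    t10 = _interp_crossing(t_rise, mag, 0.1 * abs(peak), True)
    t90 = _interp_crossing(t_rise, mag, 0.9 * abs(peak), True)
    duration = float((np.abs(sig) >= 0.1 * abs(peak)).sum() * sweep.dt_ms)
    return MRCMetrics(peak_pA=peak, sustained_pA=sustained,
                      latency_ms=t10 - w.onset_ms, rise_ms=t90 - t10,
                      mrc_duration_ms=duration, kinetics_defined=True)


def paired_pulse(sweep: Sweep, baseline_ms: float = 50.0,
                 ) -> PairedPulseResult:
    """Peak ratio of two stimulus windows, each locally baseline-referenced."""
    wins = [w for w in sweep.windows if w.kind == "stimulus"]
    if len(wins) != 2:
        raise ValidationError("windows", "need exactly two stimulus windows")
    w1, w2 = sorted(wins, key=lambda w: w.onset_ms)
    if w2.onset_ms < w1.offset_ms:
        raise ValidationError("windows", "stimulus windows overlap")

    def peak_in(w: ProtocolWindow) -> float:
        base_sel = sweep._sel(w.onset_ms - baseline_ms, w.onset_ms)
        if not base_sel.any():
            raise ValidationError("windows", "no local pre-pulse baseline")
        base = float(sweep.signal[base_sel].mean())
        seg = sweep.signal[sweep._sel(w.onset_ms, w.offset_ms)] - base
        return float(seg[np.argmax(np.abs(seg))])

    p1, p2 = peak_in(w1), peak_in(w2)
    if p1 == 0:
        raise ValidationError("signal", "first pulse has zero peak")
    return PairedPulseResult(peak1_pA=p1, peak2_pA=p2, ratio=p2 / p1,
                             inter_pulse_interval_ms=w2.onset_ms
                             - w1.offset_ms)


def stimulus_mean(sweep: Sweep) -> float:
    """Baseline-subtracted mean of the signal over the full stimulus window.

    Used for optogenetically evoked PSCs and for mechanically evoked
    interneuron currents or depolarizations.  The baseline is the mean of
    the 50 ms preceding the window (or all available pre-stimulus samples
    if the window starts earlier than that).
    """
    w = _single_window(sweep)
    stim = sweep._sel(w.onset_ms, w.offset_ms)
    if not stim.any():
        raise ValidationError("windows", "empty stimulus window")
    base_sel = sweep._sel(max(w.onset_ms - 50.0, sweep.time_ms[0]),
                          w.onset_ms)
    base = float(sweep.signal[base_sel].mean()) if base_sel.any() else 0.0
    return float(sweep.signal[stim].mean() - base)
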