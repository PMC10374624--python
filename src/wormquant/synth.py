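"""Synthetic-data generators with attached ground truth.

Every input class the pipeline consumes can be produced here: spontaneous
GCaMP-like ROI traces on a photobleaching baseline, multi-neuron trace sets
with a controllable fraction of shared (synchronous) transients,
stimulus-evoked Ca²⁺-drop traces with parametric recovery, binomial
choice-assay counts, dual-clamp junctional-current sweeps with direction-
dependent conductance, and speed–learning point clouds.  All generators are
deterministic given their seed, and each returns the exact parameters of
what was injected so downstream estimators can be scored against truth.

Model conventions
-----------------
A Ca²⁺ transient is a double-exponential kernel, peak-normalized so the
configured amplitude is the true F/F0 excursion above baseline:

    k(t) = (1 - exp(-t/rise)) * exp(-t/decay) / K,   K = max of the product.

Transients and noise act multiplicatively on the bleaching baseline,

    F(t) = B(t) * (1 + sum_k a_k * k(t - t_k) + eps(t)),
    B(t) = F_base * (1 - bleach_frac * (1 - exp(-t/bleach_tau))),

so that amplitudes and noise_sd are in F/F0 units and a perfect baseline
estimate recovers them exactly regardless of the raw fluorescence scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import ValidationError
from .traces import RawTrace
from .ephys import Sweep, ProtocolWindow
from .behavior import ChoiceCounts, SpeedLearningPoint


# --------------------------------------------------------------------------
# configs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpontaneousConfig:
    """Parameters of a spontaneous-activity recording (180 s at 1 Hz)."""

    duration_s: float = 180.0
    sample_rate_hz: float = 1.0
    event_rate_per_min: float = 2.0
    amp_mean: float = 0.5
    amp_sd: float = 0.1
    rise_s: float = 1.0
    decay_s: float = 3.0
    min_event_sep_s: float = 10.0
    bleach_tau_s: float = 200.0
    bleach_frac: float = 0.3
    noise_sd: float = 0.02
    f_base: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValidationError("duration_s", "must be > 0")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz", "must be > 0")
        if self.event_rate_per_min < 0:
            raise ValidationError("event_rate_per_min", "must be >= 0")
        if not (0 <= self.bleach_frac < 1):
            raise ValidationError("bleach_frac", "must be in [0, 1)")
        if self.amp_mean <= 0:
            raise ValidationError("amp_mean", "must be > 0")
        if self.rise_s <= 0 or self.decay_s <= 0:
            raise ValidationError("rise_s/decay_s", "kinetics must be > 0")
        if self.f_base <= 0:
            raise ValidationError("f_base", "must be > 0")


@dataclass(frozen=True)
class CouplingConfig:
    """Cross-neuron event coupling: a fraction of transients is shared."""

    n_neurons: int = 2
    shared_fraction: float = 0.5
    jitter_s: float = 0.0

    def __post_init__(self):
        if self.n_neurons < 2:
            raise ValidationError("n_neurons", "must be >= 2")
        if not (0 <= self.shared_fraction <= 1):
            raise ValidationError("shared_fraction", "must be in [0, 1]")
        if self.jitter_s < 0:
            raise ValidationError("jitter_s", "must be >= 0")


@dataclass(frozen=True)
class EvokedConfig:
    """A stimulus-locked Ca²⁺ drop with parametric recovery.

    The 30-s stimulus default matches pressure-ejection application of
    bacterial supernatant; the drop may outlast the stimulus.
    """

    duration_s: float = 180.0
    sample_rate_hz: float = 1.0
    pre_s: float = 10.0
    stim_onset_s: float = 30.0
    stim_dur_s: float = 30.0
    drop_amp: float = -0.5
    drop_dur_s: float = 50.0
    recovery_shape: str = "linear"   # step | linear | exponential
    recovery_s: float = 10.0
    noise_sd: float = 0.0
    f_base: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.pre_s < 10:
            raise ValidationError("pre_s", "must be >= 10 s (F0 window)")
        if self.stim_onset_s < self.pre_s:
            raise ValidationError("stim_onset_s", "must be >= pre_s")
        if self.drop_amp > 0:
            raise ValidationError("drop_amp", "must be <= 0 for drop scenarios")
        if self.recovery_shape not in ("step", "linear", "exponential"):
            raise ValidationError("recovery_shape",
                                  "must be step, linear or exponential")
        if self.recovery_shape != "step" and self.recovery_s <= 0:
            raise ValidationError("recovery_s", "must be > 0")
        if self.duration_s <= self.stim_onset_s + self.drop_dur_s:
            raise ValidationError("duration_s", "recording ends before the "
                                  "drop does")


@dataclass(frozen=True)
class AssayConfig:
    """A two-spot choice assay with a known per-animal PA14 probability."""

    n_animals: int = 120
    p_pa14: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_animals <= 0:
            raise ValidationError("n_animals", "must be > 0")
        if not (0 <= self.p_pa14 <= 1):
            raise ValidationError("p_pa14", "must be in [0, 1]")


@dataclass(frozen=True)
class JunctionConfig:
    """Dual whole-cell Vj-step protocol with direction-dependent conductance.

    Neuron #1 is held at -30 mV; steps applied to neuron #2 set the
    transjunctional voltage Vj = -30 mV - Vm2.  The junctional current
    settles exponentially to g(direction) * Vj.  Which Vj sign is the
    antidromic direction is declared, never inferred.
    """

    g_anti_nS: float = 1.0
    g_ortho_nS: float = 0.1
    v_hold_mV: float = -30.0
    vj_steps_mV: tuple = (-50, -40, -30, -20, -10, 10, 20, 30, 40, 50)
    step_dur_ms: float = 500.0
    settle_tau_ms: float = 5.0
    noise_pA: float = 0.5
    sample_rate_khz: float = 10.0
    pre_ms: float = 150.0
    antidromic_sign: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.g_anti_nS < 0 or self.g_ortho_nS < 0:
            raise ValidationError("g_anti_nS/g_ortho_nS", "must be >= 0")
        if self.step_dur_ms < 200:
            raise ValidationError("step_dur_ms",
                                  "must be >= 200 ms (2x the 100-ms window)")
        if self.pre_ms < 100:
            raise ValidationError("pre_ms", "must be >= 100 ms baseline")
        if self.antidromic_sign not in (-1, 1):
            raise ValidationError("antidromic_sign", "must be -1 or +1")


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

@dataclass
class TrueEvent:
    onset_s: float
    amplitude: float
    duration_s: float          # time the noiseless kernel exceeds 0.1 F/F0
    shared: bool | None = None


@dataclass
class DropTruth:
    has_drop: bool
    onset_s: float
    magnitude: float           # |drop_amp|, Delta F/F0 units
    recovery70_s: float        # absolute time at which 70% has perished
    duration_s: float          # onset -> recovery70_s


@dataclass
class JunctionTruth:
    g_anti_nS: float
    g_ortho_nS: float
    antidromic_sign: int


@dataclass
class GroundTruth:
    """Everything that was injected, keyed by trace/ROI label."""

    events: dict = field(default_factory=dict)   # roi -> list[TrueEvent]
    baselines: dict = field(default_factory=dict)  # roi -> ndarray B(t)
    drop: DropTruth | None = None
    junction: JunctionTruth | None = None


# --------------------------------------------------------------------------
# transient kernel
# --------------------------------------------------------------------------

EVENT_REFERENCE_LEVEL = 0.1   # F/F0 level defining true event duration


def _kernel_norm(rise_s: float, decay_s: float) -> tuple[float, float]:
    """Peak time and peak value of (1-e^-t/r)e^-t/d."""
    t_peak = rise_s * math.log1p(decay_s / rise_s)
    k_peak = (1 - math.exp(-t_peak / rise_s)) * math.exp(-t_peak / decay_s)
    return t_peak, k_peak


def event_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Double-exponential transient, peak-normalized to 1, zero for t < 0."""
    _, k_peak = _kernel_norm(rise_s, decay_s)
    out = np.zeros_like(t, dtype=float)
    pos = t >= 0
    tp = t[pos]
    out[pos] = (1 - np.exp(-tp / rise_s)) * np.exp(-tp / decay_s) / k_peak
    return out


def kernel_width_above(amplitude: float, level: float,
                       rise_s: float, decay_s: float) -> float:
    """Time a transient of given amplitude spends above `level` (F/F0)."""
    if amplitude <= level:
        return 0.0
    t_peak, k_peak = _kernel_norm(rise_s, decay_s)

    def f(t):
        return (amplitude * (1 - math.exp(-t / rise_s))
                * math.exp(-t / decay_s) / k_peak - level)

    t_lo = brentq(f, 1e-12, t_peak)
    # bracket the falling crossing: expand until below level
    hi = t_peak * 2
    while f(hi) > 0:
        hi *= 2
    t_hi = brentq(f, t_peak, hi)
    return t_hi - t_lo


def _bleach_baseline(t: np.ndarray, cfg: SpontaneousConfig) -> np.ndarray:
    return cfg.f_base * (1 - cfg.bleach_frac * (1 - np.exp(-t / cfg.bleach_tau_s)))


def _place_onsets(rng: np.random.Generator, n_events: int,
                  duration_s: float, min_sep_s: float,
                  max_tries: int = 1000) -> np.ndarray:
    """Uniform onsets thinned by rejection-and-redraw to respect min_sep."""
    placed: list[float] = []
    for _ in range(n_events):
        for _ in range(max_tries):
            cand = rng.uniform(0, duration_s)
            if all(abs(cand - p) >= min_sep_s for p in placed):
                placed.append(cand)
                break
        # an unplaceable event (saturated recording) is dropped
    return np.sort(np.asarray(placed))


def _events_signal(t: np.ndarray, onsets: np.ndarray, amps: np.ndarray,
                   cfg: SpontaneousConfig) -> np.ndarray:
    sig = np.zeros_like(t)
    for onset, amp in zip(onsets, amps):
        sig += amp * event_kernel(t - onset, cfg.rise_s, cfg.decay_s)
    return sig


def _draw_amplitudes(rng: np.random.Generator, n: int,
                     cfg: SpontaneousConfig) -> np.ndarray:
    amps = rng.normal(cfg.amp_mean, cfg.amp_sd, size=n)
    return np.clip(amps, 0.05 * cfg.amp_mean, None)


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def generate_spontaneous(cfg: SpontaneousConfig,
                         roi_label: str = "roi_0",
                         rng: np.random.Generator | None = None,
                         ) -> tuple[RawTrace, GroundTruth]:
    """One spontaneous-activity trace plus the list of injected transients."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.sample_rate_hz))
    t = np.arange(n) / cfg.sample_rate_hz

    n_events = rng.poisson(cfg.event_rate_per_min / 60.0 * cfg.duration_s)
    onsets = _place_onsets(rng, n_events, cfg.duration_s, cfg.min_event_sep_s)
    amps = _draw_amplitudes(rng, len(onsets), cfg)

    baseline = _bleach_baseline(t, cfg)
    relative = 1.0 + _events_signal(t, onsets, amps, cfg)
    relative += rng.normal(0.0, cfg.noise_sd, size=n)
    raw = RawTrace(time_s=t, f_total=baseline * relative, f_bg=0.0,
                   sample_rate_hz=cfg.sample_rate_hz, roi_label=roi_label)

    truth = GroundTruth()
    truth.events[roi_label] = [
        TrueEvent(onset_s=float(o), amplitude=float(a),
                  duration_s=kernel_width_above(float(a),
                                                EVENT_REFERENCE_LEVEL,
                                                cfg.rise_s, cfg.decay_s))
        for o, a in zip(onsets, amps)
    ]
    truth.baselines[roi_label] = baseline
    return raw, truth


def generate_coupled(cfg: SpontaneousConfig, cc: CouplingConfig,
                     ) -> tuple[list[RawTrace], GroundTruth]:
    """Trace set in which a configured fraction of transients is shared.

    A master event train is drawn once; each master event is either copied
    to every neuron (with per-neuron Gaussian timing jitter) with
    probability ``shared_fraction``, or replaced by an independent uniform
    onset per neuron.  Amplitudes are always drawn per neuron.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.sample_rate_hz))
    t = np.arange(n) / cfg.sample_rate_hz
    baseline = _bleach_baseline(t, cfg)

    n_events = rng.poisson(cfg.event_rate_per_min / 60.0 * cfg.duration_s)
    master = _place_onsets(rng, n_events, cfg.duration_s, cfg.min_event_sep_s)
    shared_flags = rng.random(len(master)) < cc.shared_fraction

    per_neuron_onsets: list[list[tuple[float, bool]]] = [
        [] for _ in range(cc.n_neurons)
    ]
    for onset, is_shared in zip(master, shared_flags):
        if is_shared:
            for lst in per_neuron_onsets:
                jittered = onset + (rng.normal(0, cc.jitter_s)
                                    if cc.jitter_s > 0 else 0.0)
                jittered = float(np.clip(jittered, 0, cfg.duration_s - 1e-9))
                lst.append((jittered, True))
        else:
            for lst in per_neuron_onsets:
                lst.append((float(rng.uniform(0, cfg.duration_s)), False))

    truth = GroundTruth()
    traces: list[RawTrace] = []
    for i, onset_list in enumerate(per_neuron_onsets):
        label = f"roi_{i}"
        onset_list.sort()
        onsets = np.array([o for o, _ in onset_list])
        amps = _draw_amplitudes(rng, len(onsets), cfg)
        relative = 1.0 + _events_signal(t, onsets, amps, cfg)
        relative += rng.normal(0.0, cfg.noise_sd, size=n)
        traces.append(RawTrace(time_s=t, f_total=baseline * relative,
                               f_bg=0.0, sample_rate_hz=cfg.sample_rate_hz,
                               roi_label=label))
        truth.events[label] = [
            TrueEvent(onset_s=o, amplitude=float(a),
                      duration_s=kernel_width_above(
                          float(a), EVENT_REFERENCE_LEVEL,
                          cfg.rise_s, cfg.decay_s),
                      shared=s)
            for (o, s), a in zip(onset_list, amps)
        ]
        truth.baselines[label] = baseline
    return traces, truth


def generate_evoked(cfg: EvokedConfig, roi_label: str = "roi_0",
                    ) -> tuple[RawTrace, GroundTruth]:
    """Flat unit-baseline trace with a stimulus-locked drop and recovery.

    Truth carries the analytic time at which 70% of the drop has perished:
    the drop end itself for step recovery, drop end + 0.7*recovery_s for a
    linear ramp, and drop end - recovery_s*ln(0.3) for exponential recovery.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.sample_rate_hz))
    t = np.arange(n) / cfg.sample_rate_hz

    rel = np.ones(n)
    drop_end = cfg.stim_onset_s + cfg.drop_dur_s
    in_drop = (t >= cfg.stim_onset_s) & (t < drop_end)
    rel[in_drop] += cfg.drop_amp
    after = t >= drop_end
    if cfg.recovery_shape == "step":
        pass  # instantaneous return to baseline
    elif cfg.recovery_shape == "linear":
        ramp = after & (t < drop_end + cfg.recovery_s)
        rel[ramp] += cfg.drop_amp * (1 - (t[ramp] - drop_end) / cfg.recovery_s)
    else:  # exponential
        rel[after] += cfg.drop_amp * np.exp(-(t[after] - drop_end)
                                            / cfg.recovery_s)
    if cfg.noise_sd > 0:
        rel += rng.normal(0.0, cfg.noise_sd, size=n)

    raw = RawTrace(time_s=t, f_total=cfg.f_base * rel, f_bg=0.0,
                   sample_rate_hz=cfg.sample_rate_hz, roi_label=roi_label)

    if cfg.drop_amp == 0:
        drop = DropTruth(has_drop=False, onset_s=math.nan, magnitude=0.0,
                         recovery70_s=math.nan, duration_s=math.nan)
    else:
        if cfg.recovery_shape == "step":
            t70 = drop_end
        elif cfg.recovery_shape == "linear":
            t70 = drop_end + 0.7 * cfg.recovery_s
        else:
            t70 = drop_end - cfg.recovery_s * math.log(0.3)
        drop = DropTruth(has_drop=True, onset_s=cfg.stim_onset_s,
                         magnitude=abs(cfg.drop_amp), recovery70_s=t70,
                         duration_s=t70 - cfg.stim_onset_s)
    truth = GroundTruth(drop=drop)
    return raw, truth


def generate_choice_counts(cfg: AssayConfig) -> ChoiceCounts:
    """Binomial split of animals between the PA14 and OP50 spots."""
    rng = np.random.default_rng(cfg.seed)
    n_pa14 = int(rng.binomial(cfg.n_animals, cfg.p_pa14))
    return ChoiceCounts(n_pa14=n_pa14, n_op50=cfg.n_animals - n_pa14)


def generate_junction_sweeps(cfg: JunctionConfig,
                             ) -> tuple[list[Sweep], GroundTruth]:
    """One current sweep per Vj step, with exponential settling and noise."""
    rng = np.random.default_rng(cfg.seed)
    dt_ms = 1.0 / cfg.sample_rate_khz
    post_ms = 50.0
    total_ms = cfg.pre_ms + cfg.step_dur_ms + post_ms
    n = int(round(total_ms / dt_ms))
    t = np.arange(n) * dt_ms

    sweeps: list[Sweep] = []
    for vj in cfg.vj_steps_mV:
        g = cfg.g_anti_nS if np.sign(vj) == cfg.antidromic_sign \
            else cfg.g_ortho_nS
        i = np.zeros(n)
        in_step = (t >= cfg.pre_ms) & (t < cfg.pre_ms + cfg.step_dur_ms)
        ts = t[in_step] - cfg.pre_ms
        i[in_step] = g * vj * (1 - np.exp(-ts / cfg.settle_tau_ms))
        i += rng.normal(0.0, cfg.noise_pA, size=n)
        window = ProtocolWindow(onset_ms=cfg.pre_ms,
                                offset_ms=cfg.pre_ms + cfg.step_dur_ms,
                                level=float(vj), kind="vj_step")
        sweeps.append(Sweep(time_ms=t, signal=i, units="pA",
                            windows=[window],
                            meta={"antidromic_sign": cfg.antidromic_sign,
                                  "v_hold_mV": cfg.v_hold_mV}))
    truth = GroundTruth(junction=JunctionTruth(
        g_anti_nS=cfg.g_anti_nS, g_ortho_nS=cfg.g_ortho_nS,
        antidromic_sign=cfg.antidromic_sign))
    return sweeps, truth


def generate_paired_pulse_sweep(ipi_ms: float,
                                peak_pA: float = -60.0,
                                desens_frac: float = 0.5,
                                recovery_tau_ms: float = 200.0,
                                pulse_dur_ms: float = 50.0,
                                decay_tau_ms: float = 10.0,
                                noise_pA: float = 0.0,
                                sample_rate_khz: float = 10.0,
                                seed: int = 0) -> Sweep:
    """Two mechanical pulses; the second peak recovers with the interval.

    The second peak is scaled by 1 - desens_frac * exp(-ipi/recovery_tau),
    so the paired-pulse ratio increases strictly with the inter-pulse
    interval — the qualitative signature of desensitization.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate_khz
    pre = 100.0
    onset2 = pre + pulse_dur_ms + ipi_ms
    total = onset2 + pulse_dur_ms + 100.0
    n = int(round(total / dt))
    t = np.arange(n) * dt

    def pulse(onset, amp):
        out = np.zeros(n)
        during = (t >= onset) & (t < onset + pulse_dur_ms)
        out[during] = amp * np.exp(-(t[during] - onset) / decay_tau_ms)
        return out

    amp2 = peak_pA * (1 - desens_frac * math.exp(-ipi_ms / recovery_tau_ms))
    sig = pulse(pre, peak_pA) + pulse(onset2, amp2)
    if noise_pA > 0:
        sig += rng.normal(0, noise_pA, size=n)
    windows = [ProtocolWindow(pre, pre + pulse_dur_ms, 1.0, "stimulus"),
               ProtocolWindow(onset2, onset2 + pulse_dur_ms, 1.0, "stimulus")]
    return Sweep(time_ms=t, signal=sig, units="pA", windows=windows,
                 meta={"ipi_ms": ipi_ms})


def generate_speed_learning(slope: float, intercept: float, noise_sd: float,
                            speeds, seed: int = 0,
                            ) -> list[SpeedLearningPoint]:
    """Learning-index points linear in locomotion speed plus Gaussian noise."""
    speeds = np.asarray(list(speeds), dtype=float)
    if speeds.size == 0:
        raise ValidationError("speeds", "must be non-empty")
    rng = np.random.default_rng(seed)
    li = intercept + slope * speeds + rng.normal(0, noise_sd, size=speeds.size)
    return [SpeedLearningPoint(speed=float(v), learning_index=float(y))
            for v, y in zip(speeds, li)]


def hill_response(dose, top: float, bottom: float, ic50: float,
                  hill: float) -> np.ndarray:
    """Four-parameter logistic inhibition curve (response falls with dose)."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (dose / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1 + ratio)
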