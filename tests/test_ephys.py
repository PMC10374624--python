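"""Windowed means, Ij–Vj rectification, MRC metrics, paired pulses."""

import math

import numpy as np
import pytest

from wormquant import synth
from wormquant.ephys import (IjPoint, ProtocolWindow, Sweep, build_ij_curve,
                             compute_vj, paired_pulse, quantify_ij,
                             quantify_mrc, stimulus_mean)
from wormquant.errors import ValidationError


def _sweep(signal, rate_khz=10.0, windows=(), units="pA"):
    signal = np.asarray(signal, dtype=float)
    t = np.arange(signal.size) / rate_khz
    return Sweep(time_ms=t, signal=signal, units=units,
                 windows=list(windows))


def _step_sweep(level, pre_ms=150.0, dur_ms=500.0, rate_khz=10.0,
                tau_ms=None):
    n_pre = int(pre_ms * rate_khz)
    n_dur = int(dur_ms * rate_khz)
    n_post = int(50 * rate_khz)
    sig = np.zeros(n_pre + n_dur + n_post)
    ts = np.arange(n_dur) / rate_khz
    sig[n_pre:n_pre + n_dur] = level if tau_ms is None else \
        level * (1 - np.exp(-ts / tau_ms))
    w = ProtocolWindow(onset_ms=pre_ms, offset_ms=pre_ms + dur_ms,
                       level=level, kind="vj_step")
    return _sweep(sig, rate_khz, [w])


class TestComputeVj:
    @pytest.mark.parametrize("vm2,expected", [
        (-30.0, 0.0), (-80.0, 50.0), (20.0, -50.0),
    ])
    def test_sign_convention(self, vm2, expected):
        assert compute_vj(vm2) == expected


class TestQuantifyIj:
    def test_constant_step(self):
        assert quantify_ij(_step_sweep(10.0)).ij_pA == pytest.approx(10.0)

    def test_exponential_settle_converges(self):
        # mean of the final 100 ms of a 500-ms step with tau = 5 ms is
        # within e^-80 of the asymptote
        pt = quantify_ij(_step_sweep(20.0, tau_ms=5.0))
        assert pt.ij_pA == pytest.approx(20.0, abs=1e-6)

    def test_short_step_rejected(self):
        with pytest.raises(ValidationError, match="100 ms"):
            quantify_ij(_step_sweep(10.0, dur_ms=80.0))

    @pytest.mark.parametrize("rate_khz", [10.0, 20.0, 50.0])
    def test_last_100ms_matches_brute_force(self, rate_khz):
        rng = np.random.default_rng(int(rate_khz))
        sweep = _step_sweep(15.0, rate_khz=rate_khz, tau_ms=3.0)
        sweep.signal = sweep.signal + rng.normal(0, 0.5, sweep.signal.size)
        w = sweep.windows[0]
        n100 = int(round(100.0 * rate_khz))
        stop = int(round(w.offset_ms * rate_khz))
        pre_stop = int(round(w.onset_ms * rate_khz))
        brute = (sweep.signal[stop - n100:stop].mean()
                 - sweep.signal[pre_stop - n100:pre_stop].mean())
        assert quantify_ij(sweep).ij_pA == pytest.approx(brute, rel=1e-12)

    def test_linearity_by_superposition(self):
        a = _step_sweep(10.0, tau_ms=4.0)
        b = _step_sweep(-6.0, tau_ms=9.0)
        both = _step_sweep(0.0)
        both.signal = a.signal + b.signal
        assert quantify_ij(both).ij_pA == pytest.approx(
            quantify_ij(a).ij_pA + quantify_ij(b).ij_pA, rel=1e-12)


class TestIjCurve:
    def test_ohmic_ratio_one(self):
        pts = [IjPoint(v, 0.5 * v) for v in (-40, -20, 20, 40)]
        curve = build_ij_curve(pts)
        assert curve.rectification_ratio == pytest.approx(1.0, rel=0.02)

    def test_rectified_recovery_from_generator(self):
        cfg = synth.JunctionConfig(g_anti_nS=1.0, g_ortho_nS=0.1,
                                   noise_pA=0.5, seed=2)
        sweeps, truth = synth.generate_junction_sweeps(cfg)
        pts = [quantify_ij(s) for s in sweeps if s.windows[0].level != 0]
        curve = build_ij_curve(pts, truth.junction.antidromic_sign)
        assert curve.slope_antidromic_nS == pytest.approx(1.0, rel=0.02)
        assert curve.slope_orthodromic_nS == pytest.approx(0.1, rel=0.02)
        assert curve.rectification_ratio == pytest.approx(10.0, rel=0.05)

    def test_zero_orthodromic_flagged_infinite(self):
        pts = [IjPoint(v, v if v > 0 else 0.0) for v in (-40, -20, 20, 40)]
        curve = build_ij_curve(pts)
        assert curve.ratio_infinite
        assert math.isinf(curve.rectification_ratio)

    def test_one_sided_data_rejected(self):
        pts = [IjPoint(v, v) for v in (10, 20, 30)]
        with pytest.raises(ValidationError, match="each Vj sign"):
            build_ij_curve(pts)


class TestQuantifyMRC:
    def test_square_pulse(self):
        n = int(300 * 10)
        sig = np.zeros(1000 + n + 500)
        sig[1000:1000 + n] = -50.0
        w = ProtocolWindow(onset_ms=100, offset_ms=400)
        m = quantify_mrc(_sweep(sig, 10.0, [w]))
        assert m.peak_pA == pytest.approx(-50.0)
        assert m.sustained_pA == pytest.approx(-50.0)
        assert m.mrc_duration_ms == pytest.approx(300.0)
        assert m.latency_ms == pytest.approx(0.0, abs=0.2)

    def test_peak_then_plateau_sustained(self):
        # -60 pA decaying with tau = 30 ms to a -20 pA plateau, 300-ms
        # stimulus: the last-100-ms mean is within 1% of the plateau
        rate = 10.0
        t = np.arange(int(500 * rate)) / rate
        sig = np.zeros_like(t)
        during = (t >= 100) & (t < 400)
        ts = t[during] - 100
        sig[during] = -20 - 40 * np.exp(-ts / 30.0)
        w = ProtocolWindow(onset_ms=100, offset_ms=400)
        m = quantify_mrc(_sweep(sig, rate, [w]))
        assert m.sustained_pA == pytest.approx(-20.0, rel=0.01)
        assert m.peak_pA == pytest.approx(-60.0, rel=0.01)
        assert abs(m.sustained_pA) <= abs(m.peak_pA)

    def test_latency_and_rise_interpolated(self):
        # linear ramp from 0 to -100 pA over 10 ms, then flat: 10% crossing
        # at 1 ms, 90% at 9 ms
        rate = 10.0
        t = np.arange(int(400 * rate)) / rate
        sig = np.zeros_like(t)
        during = (t >= 100) & (t < 300)
        ts = t[during] - 100
        sig[during] = -100 * np.clip(ts / 10.0, 0, 1)
        w = ProtocolWindow(onset_ms=100, offset_ms=300)
        m = quantify_mrc(_sweep(sig, rate, [w]))
        assert m.latency_ms == pytest.approx(1.0, abs=0.2)
        assert m.rise_ms == pytest.approx(8.0, abs=0.3)

    def test_flat_sweep_kinetics_undefined(self):
        sig = np.zeros(5000)
        w = ProtocolWindow(onset_ms=100, offset_ms=300)
        m = quantify_mrc(_sweep(sig, 10.0, [w]))
        assert m.peak_pA == 0.0
        assert not m.kinetics_defined

    def test_sustained_never_exceeds_peak_on_generated_sweeps(self):
        for seed in range(5):
            sweep = synth.generate_paired_pulse_sweep(
                ipi_ms=300, pulse_dur_ms=150, noise_pA=0.3, seed=seed)
            sweep.windows = [sweep.windows[0]]
            m = quantify_mrc(sweep)
            assert abs(m.sustained_pA) <= abs(m.peak_pA) + 1e-9


class TestPairedPulse:
    def test_identical_pulses_unity_ratio(self):
        sweep = synth.generate_paired_pulse_sweep(ipi_ms=500, desens_frac=0.0)
        assert paired_pulse(sweep).ratio == pytest.approx(1.0, rel=1e-6)

    def test_half_second_peak(self):
        sweep = synth.generate_paired_pulse_sweep(
            ipi_ms=60, desens_frac=0.5, recovery_tau_ms=1e9)
        assert paired_pulse(sweep).ratio == pytest.approx(0.5, rel=1e-3)

    def test_ratio_increases_with_interval(self):
        ratios = [paired_pulse(synth.generate_paired_pulse_sweep(
            ipi_ms=ipi)).ratio for ipi in (50, 100, 200, 400, 800)]
        assert ratios == sorted(ratios)
        assert ratios[0] < ratios[-1] < 1.0 + 1e-9

    def test_overlapping_windows_rejected(self):
        sig = np.zeros(5000)
        wins = [ProtocolWindow(100, 200), ProtocolWindow(150, 250)]
        with pytest.raises(ValidationError, match="overlap"):
            paired_pulse(_sweep(sig, 10.0, wins))


class TestStimulusMean:
    def test_constant_current(self):
        sig = np.zeros(4000)
        sig[1000:3000] = 8.0
        w = ProtocolWindow(onset_ms=100, offset_ms=300)
        assert stimulus_mean(_sweep(sig, 10.0, [w])) == pytest.approx(8.0)

    def test_triangular_pulse(self):
        rate = 10.0
        t = np.arange(int(400 * rate)) / rate
        sig = np.zeros_like(t)
        during = (t >= 100) & (t < 300)
        ts = t[during] - 100
        sig[during] = 10 * (1 - np.abs(ts - 100) / 100)
        w = ProtocolWindow(onset_ms=100, offset_ms=300)
        assert stimulus_mean(_sweep(sig, rate, [w])) == \
            pytest.approx(5.0, rel=0.01)

    def test_missing_annotation_rejected(self):
        with pytest.raises(ValidationError, match="window"):
            stimulus_mean(_sweep(np.zeros(1000), 10.0, []))
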