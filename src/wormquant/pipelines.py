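"""End-to-end pipelines: spontaneous-synchrony and naïve-vs-trained evoked.

Each pipeline reads trace CSVs, runs the corresponding library stages, and
writes its tables with provenance headers.  Given identical inputs, config
and seed, a rerun produces byte-identical outputs; the returned
:class:`RunReport` carries SHA-256 digests of every file written so
determinism can be checked by hash comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as wio
from .errors import ValidationError
from .events import cross_correlate, detect_events, summarize_events
from .evoked import StimWindow, compute_dff, drop_duration, \
    group_training_effect
from .traces import Trace, correct_pipeline


def _header_params(params: dict) -> dict:
    """Analysis parameters only: paths stay out of table headers so the
    same computation lands byte-identical wherever it is written."""
    return {k: v for k, v in params.items()
            if not (k.endswith("_csv") or k.endswith("_dir"))}


def _from_mapping(cls, payload: dict):
    """Build a config dataclass from a mapping, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValidationError("config",
                              f"unknown keys: {', '.join(sorted(unknown))}")
    return cls(**payload)


@dataclass(frozen=True)
class SpontaneousRunConfig:
    traces_csv: str = ""
    out_dir: str = "out"
    window_s: float = 30.0
    percentile_pass1: float = 0.08
    percentile_pass2: float = 0.5
    two_pass: bool = True
    threshold: float = 0.1
    min_duration_s: float = 3.0
    max_lag_s: float = 30.0

    @classmethod
    def from_mapping(cls, payload: dict) -> "SpontaneousRunConfig":
        return _from_mapping(cls, payload)


@dataclass(frozen=True)
class EvokedRunConfig:
    naive_csv: str = ""
    trained_csv: str = ""
    out_dir: str = "out"
    stim_onset_s: float = 30.0
    stim_dur_s: float = 30.0
    onset_k: float = 3.0
    sustain_frames: int = 2

    @classmethod
    def from_mapping(cls, payload: dict) -> "EvokedRunConfig":
        return _from_mapping(cls, payload)


@dataclass
class RunReport:
    pipeline: str
    params: dict
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)   # path -> sha256

    def add_output(self, path: Path):
        self.outputs[str(path)] = wio.sha256_of(path)


def run_spontaneous_pipeline(cfg: SpontaneousRunConfig) -> RunReport:
    """correct -> detect -> summarize -> pairwise xcorr, with tables."""
    raws = wio.read_traces_csv(cfg.traces_csv)
    if not raws:
        raise ValidationError("traces_csv", "no ROI traces found")
    out = Path(cfg.out_dir)
    params = asdict(cfg)
    report = RunReport(pipeline="spontaneous", params=params)

    corrected = {}
    corrected_cols = {"time_s": raws[0].time_s}
    event_rows, stats_rows = [], []
    for raw in raws:
        try:
            nt = correct_pipeline(raw, window_s=cfg.window_s,
                                  percentile_pass1=cfg.percentile_pass1,
                                  percentile_pass2=cfg.percentile_pass2,
                                  two_pass=cfg.two_pass,
                                  event_threshold=cfg.threshold,
                                  event_min_duration_s=cfg.min_duration_s)
        except Exception as exc:
            exc.args = (f"[correct stage, roi {raw.roi_label}] {exc}",)
            raise
        corrected[raw.roi_label] = nt
        corrected_cols[f"{raw.roi_label}"] = raw.f_total
        corrected_cols[f"{raw.roi_label}_baseline"] = \
            nt.baseline_used.baseline
        corrected_cols[f"{raw.roi_label}_ffz"] = nt.ffz

        events = detect_events(nt, threshold=cfg.threshold,
                               min_duration_s=cfg.min_duration_s)
        duration = raw.time_s[-1] - raw.time_s[0] + 1.0 / raw.sample_rate_hz
        stats = summarize_events(events, duration)
        for ev in events:
            event_rows.append({"roi": raw.roi_label, "onset_s": ev.onset_s,
                               "offset_s": ev.offset_s,
                               "peak_time_s": ev.peak_time_s,
                               "amplitude": ev.amplitude,
                               "duration_s": ev.duration_s})
        stats_rows.append({"roi": raw.roi_label,
                           "frequency_per_min": stats.frequency_per_min,
                           "mean_amplitude": stats.mean_amplitude
                           if stats.mean_amplitude is not None else "",
                           "n_events": stats.n_events,
                           "recording_min": stats.recording_min})
    report.stages.append({"stage": "correct+detect", "n_rois": len(raws)})

    xcorr_rows, correlogram_cols = [], {}
    labels = [r.roi_label for r in raws]
    for la, lb in combinations(labels, 2):
        res = cross_correlate(corrected[la], corrected[lb],
                              max_lag_s=cfg.max_lag_s)
        xcorr_rows.append({"roi_a": la, "roi_b": lb, "r0": res.r0})
        correlogram_cols.setdefault("lag_s", res.lags_s)
        correlogram_cols[f"{la}|{lb}"] = res.r
    report.stages.append({"stage": "xcorr", "n_pairs": len(xcorr_rows)})

    report.add_output(wio.write_table(
        out / "corrected.csv", pd.DataFrame(corrected_cols),
        stage="correct", params=_header_params(params),
        units="seconds"))
    report.add_output(wio.write_table(
        out / "events.tsv", pd.DataFrame(
            event_rows, columns=["roi", "onset_s", "offset_s", "peak_time_s",
                                 "amplitude", "duration_s"]),
        stage="detect", params=_header_params(params), units="seconds",
        sep="\t"))
    report.add_output(wio.write_table(
        out / "stats.tsv", pd.DataFrame(stats_rows),
        stage="summarize", params=_header_params(params),
        units="seconds", sep="\t"))
    if xcorr_rows:
        report.add_output(wio.write_table(
            out / "xcorr.csv", pd.DataFrame(xcorr_rows),
            stage="xcorr", params=_header_params(params)))
        report.add_output(wio.write_table(
            out / "correlogram.csv", pd.DataFrame(correlogram_cols),
            stage="xcorr", params=_header_params(params),
            units="seconds"))
    report.add_output(wio.write_yaml(out / "run_config.yaml",
                                     {"pipeline": "spontaneous",
                                      "params": params}))
    return report


def _evoked_metrics_frame(raws, w: StimWindow, onset_k: float,
                          sustain_frames: int, condition: str,
                          ) -> tuple[pd.DataFrame, list]:
    rows, metrics = [], []
    for raw in raws:
        trace = Trace(time_s=raw.time_s, f=raw.f_total - raw.f_bg,
                      sample_rate_hz=raw.sample_rate_hz,
                      roi_label=raw.roi_label)
        d = compute_dff(trace, w)
        m = drop_duration(d, w, onset_k=onset_k,
                          sustain_frames=sustain_frames)
        metrics.append(m)
        rows.append({"condition": condition, "roi": raw.roi_label,
                     "amplitude": m.amplitude,
                     "drop_detected": m.drop_detected,
                     "drop_onset_s": m.drop_onset_s,
                     "trough_value": m.trough_value,
                     "drop_magnitude": m.drop_magnitude,
                     "duration_s": m.duration_s})
    return pd.DataFrame(rows), metrics


def run_evoked_pipeline(cfg: EvokedRunConfig) -> RunReport:
    """Per-animal evoked metrics, group means, and training-effect table."""
    w = StimWindow(stim_onset_s=cfg.stim_onset_s, stim_dur_s=cfg.stim_dur_s)
    naive_raws = wio.read_traces_csv(cfg.naive_csv)
    trained_raws = wio.read_traces_csv(cfg.trained_csv)
    out = Path(cfg.out_dir)
    params = asdict(cfg)
    report = RunReport(pipeline="evoked", params=params)

    df_n, metrics_n = _evoked_metrics_frame(naive_raws, w, cfg.onset_k,
                                            cfg.sustain_frames, "naive")
    df_t, metrics_t = _evoked_metrics_frame(trained_raws, w, cfg.onset_k,
                                            cfg.sustain_frames, "trained")
    per_animal = pd.concat([df_n, df_t], ignore_index=True)

    # heatmap row order: within condition, descending response duration
    per_animal["heatmap_order"] = (
        per_animal.groupby("condition")["duration_s"]
        .rank(ascending=False, method="first").astype(int))

    effect = group_training_effect(metrics_n, metrics_t)
    summary = pd.DataFrame([{
        "n_naive": len(metrics_n), "n_trained": len(metrics_t),
        "naive_mean_amp": np.mean([abs(m.amplitude) for m in metrics_n]),
        "trained_mean_amp": np.mean([abs(m.amplitude) for m in metrics_t]),
        "naive_mean_duration_s": np.mean(
            [m.duration_s if m.drop_detected else 0.0 for m in metrics_n]),
        "trained_mean_duration_s": np.mean(
            [m.duration_s if m.drop_detected else 0.0 for m in metrics_t]),
        "amp_change_pct": effect.amp_change_pct,
        "dur_change_pct": effect.dur_change_pct,
    }])

    report.stages.append({"stage": "evoked",
                          "n_naive": len(metrics_n),
                          "n_trained": len(metrics_t)})
    report.add_output(wio.write_table(out / "evoked_metrics.tsv", per_animal,
                                      stage="evoked",
                                      params=_header_params(params),
                                      units="seconds", sep="\t"))
    report.add_output(wio.write_table(out / "training_effect.tsv", summary,
                                      stage="training-effect",
                                      params=_header_params(params),
                                      sep="\t"))
    report.add_output(wio.write_yaml(out / "run_config.yaml",
                                     {"pipeline": "evoked",
                                      "params": params}))
    return report
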