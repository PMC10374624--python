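"""Tabular file formats shared by the pipeline stages.

All tables are UTF-8 CSV/TSV with a mandatory header row and `.` decimals.
Lines beginning with ``#`` are provenance comments: a ``#units:`` line
states the time unit, further ``#`` lines record the package version and
the resolved parameters of the producing stage, so every output is
self-describing and reruns are byte-comparable.  Missing values are empty
fields; an NA inside an analysis window is an error upstream, never
silently skipped.
"""

from __future__ import annotations

import hashlib
import io as _stdio
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .traces import RawTrace


def provenance_lines(stage: str, params: dict | None = None,
                     units: str | None = None) -> list[str]:
    lines = [f"# wormquant {__version__} :: {stage}"]
    if units:
        lines.append(f"#units: {units}")
    for key in sorted(params or {}):
        lines.append(f"# {key}: {params[key]}")
    return lines


def write_table(path: str | Path, df: pd.DataFrame, stage: str,
                params: dict | None = None, units: str | None = None,
                sep: str = ",") -> Path:
    """Write a DataFrame with a ``#`` provenance header, deterministically."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _stdio.StringIO()
    for line in provenance_lines(stage, params, units):
        buf.write(line + "\n")
    df.to_csv(buf, sep=sep, index=False, lineterminator="\n")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, comment="#")
    if df.isna().any().any():
        raise ValidationError(str(path), "table contains missing values")
    return df


# --------------------------------------------------------------------------
# trace CSV  (column 1 `time_s`, one `roi_<label>` column per ROI)
# --------------------------------------------------------------------------

def write_traces_csv(path: str | Path, traces: list[RawTrace],
                     stage: str = "simulate", params: dict | None = None,
                     ) -> Path:
    if not traces:
        raise ValidationError("traces", "empty trace list")
    time = traces[0].time_s
    data = {"time_s": time}
    for tr in traces:
        if tr.time_s.shape != time.shape or not np.allclose(tr.time_s, time):
            raise ValidationError("traces", "ROIs must share one time grid")
        data[tr.roi_label] = tr.f_total
    return write_table(path, pd.DataFrame(data), stage=stage, params=params,
                       units="seconds")


def read_traces_csv(path: str | Path) -> list[RawTrace]:
    df = read_table(path)
    if df.columns[0] != "time_s":
        raise ValidationError(str(path), "first column must be time_s")
    time = df["time_s"].to_numpy(dtype=float)
    if time.size < 2:
        raise ValidationError(str(path), "trace file too short")
    rate = 1.0 / float(time[1] - time[0])
    rois = [c for c in df.columns if c != "time_s"]
    if not rois:
        raise ValidationError(str(path), "no ROI columns found")
    return [RawTrace(time_s=time, f_total=df[c].to_numpy(dtype=float),
                     sample_rate_hz=rate, roi_label=c) for c in rois]


def write_truth_tsv(path: str | Path, truth, stage: str = "simulate") -> Path:
    rows = []
    for roi, events in truth.events.items():
        for ev in events:
            rows.append({"trace_id": roi, "onset_s": ev.onset_s,
                         "amplitude": ev.amplitude,
                         "duration_s": ev.duration_s,
                         "shared": "" if ev.shared is None else ev.shared})
    df = pd.DataFrame(rows, columns=["trace_id", "onset_s", "amplitude",
                                     "duration_s", "shared"])
    return write_table(path, df, stage=stage, units="seconds", sep="\t")


def write_yaml(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(payload, sort_keys=True),
                    encoding="utf-8")
    return path


def read_yaml(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise ValidationError(str(path), "config must be a YAML mapping")
    return payload


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
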