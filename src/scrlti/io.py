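"""Plain-text serialization: time/value CSV, event CSV, parameter YAML/JSON.

All interchange uses small, human-readable formats:

- time series: two-column CSV ``time_s,value`` with a header (rate is
  inferred from the uniform time column), written via pandas;
- events: CSV with columns ``onset_s,event_type,subject,repetition``;
- parameter sets: YAML or JSON mapping (``theta1..theta4`` for a response
  function, ``A,mu,sigma,c`` for a burst model);
- datasets: one directory with per-subject CSVs, a ``truth.yaml`` and a
  ``manifest.json`` carrying config, seed and content hashes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import DataError
from .lti import GaussianBurstParams, ScrfParams
from .timeseries import EventSchedule, TimeSeries

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_events",
    "write_events",
    "read_params",
    "write_params",
    "write_dataset",
    "read_dataset",
]


def write_timeseries(ts: TimeSeries, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": ts.times, "value": ts.values})
    df.to_csv(path, index=False, float_format="%.10g")


def read_timeseries(path: str | Path, channel: str = "") -> TimeSeries:
    df = pd.read_csv(path)
    if not {"time_s", "value"}.issubset(df.columns):
        raise DataError(f"{path}: expected columns time_s,value")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise DataError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise DataError(f"{path}: time column is not uniform")
    return TimeSeries(
        df["value"].to_numpy(float), rate=1.0 / float(dt[0]), start=float(t[0]),
        channel=channel or Path(path).stem,
    )


def write_events(events: EventSchedule, path: str | Path) -> None:
    pd.DataFrame(
        {
            "onset_s": events.onsets,
            "event_type": events.types,
            "subject": events.subject,
            "repetition": events.repetition,
        }
    ).to_csv(path, index=False, float_format="%.6f")


def read_events(path: str | Path) -> EventSchedule:
    df = pd.read_csv(path)
    needed = {"onset_s", "event_type"}
    if not needed.issubset(df.columns):
        raise DataError(f"{path}: expected columns onset_s,event_type")
    subject = str(df["subject"].iloc[0]) if "subject" in df.columns and len(df) else ""
    rep = df["repetition"].to_numpy(int) if "repetition" in df.columns else None
    return EventSchedule(
        df["onset_s"].to_numpy(float),
        [str(t) for t in df["event_type"]],
        rep,
        subject=subject,
    )


def write_params(params, path: str | Path) -> None:
    d = params.as_dict() if hasattr(params, "as_dict") else dict(params)
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=True))
    else:
        path.write_text(json.dumps(d, indent=2, sort_keys=True))


def read_params(path: str | Path):
    """Load a parameter mapping; returns :class:`ScrfParams` or
    :class:`GaussianBurstParams` depending on the keys found."""
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    if {"theta1", "theta2", "theta3"}.issubset(d):
        return ScrfParams(
            d["theta1"], d["theta2"], d["theta3"], d.get("theta4", 0.0)
        )
    if {"A", "mu", "sigma"}.issubset(d):
        return GaussianBurstParams(d["A"], d["mu"], d["sigma"], d.get("c", 0.0))
    raise DataError(f"{path}: unrecognized parameter keys {sorted(d)}")


def write_dataset(dataset, out_dir: str | Path) -> None:
    """Write a synthetic dataset as per-subject CSVs + truth + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for subj in dataset.subjects:
        for ch, ts in dataset.signals[subj].items():
            name = f"{subj}_{ch}.csv"
            write_timeseries(ts, out / name)
            files[name] = ch
        name = f"{subj}_events.csv"
        write_events(dataset.schedules[subj], out / name)
        files[name] = "events"
    (out / "truth.yaml").write_text(yaml.safe_dump(dataset.truth, sort_keys=True))
    manifest = {
        "style": dataset.style,
        "seed": dataset.seed,
        "config": dataset.config.as_dict(),
        "content_hash": dataset.content_hash(),
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_dataset(in_dir: str | Path):
    """Read a dataset directory back into (style, signals, schedules, truth).

    The manifest's config is returned as a plain dict; the ground-truth
    record is optional (absent for real recordings laid out the same way).
    """
    in_dir = Path(in_dir)
    manifest_path = in_dir / "manifest.json"
    if not manifest_path.exists():
        raise DataError(f"{in_dir}: no manifest.json")
    manifest = json.loads(manifest_path.read_text())
    signals: dict = {}
    schedules: dict = {}
    for name, ch in manifest["files"].items():
        subj = name.split("_")[0]
        if ch == "events":
            schedules[subj] = read_events(in_dir / name)
        else:
            signals.setdefault(subj, {})[ch] = read_timeseries(in_dir / name, channel=ch)
    truth = None
    if (in_dir / "truth.yaml").exists():
        truth = yaml.safe_load((in_dir / "truth.yaml").read_text())
    return manifest["style"], signals, schedules, truth, manifest
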