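"""CSV/JSON/YAML I/O for recordings, event timelines, configs and results.

The on-disk corpus layout is one recording CSV per subject (``time_s`` plus
``ch{1..8}_HbO`` and ``ch{1..8}_HbR`` columns) with a companion event CSV
(``onset_s, duration_s, kind, condition``).  Column order is irrelevant —
everything is keyed by name — and an optional column map adapts externally
named files.  All floats are written with shortest round-trip precision,
so write/read cycles are loss-free.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import CVResult
from .protocol import SessionTimeline, TimelineEvent, build_session_timeline, segment_trials
from .recording import CHROMOPHORES, Recording, default_montage
from .simulate import SimConfig, simulate_recording

_SIGNAL_COL = re.compile(r"^ch(\d+)_(HbO|HbR)$")
TIME_TOLERANCE_S = 1e-6


class FormatError(ValueError):
    """Raised when an input file violates the expected CSV schema."""


@dataclass
class Dataset:
    """A recording plus its timeline and provenance."""

    recording: Recording
    timeline: SessionTimeline
    subject_id: str = "sim"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.recording.duration_s + TIME_TOLERANCE_S < self.timeline.duration_s:
            raise ValueError("recording shorter than its timeline")

    def trials(self):
        return segment_trials(self.recording, self.timeline)


def simulate_dataset(seed: int, config: SimConfig | None = None,
                     subject_id: str | None = None) -> Dataset:
    """Build a fully seeded synthetic session as a Dataset."""
    if config is None:
        config = SimConfig(seed=seed)
    else:
        config = dataclasses.replace(config, seed=seed)
    timeline = build_session_timeline(rng_seed=seed)
    recording = simulate_recording(timeline, config)
    digest = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return Dataset(
        recording=recording,
        timeline=timeline,
        subject_id=subject_id or f"sim{seed:04d}",
        provenance={"simulated": True, "seed": seed, "config_hash": digest},
    )


# ---------------------------------------------------------------------------
# recordings


def signal_columns(n_channels: int = 8) -> list[str]:
    return [f"ch{c + 1}_{chromo}" for chromo in CHROMOPHORES for c in range(n_channels)]


def write_recording(recording: Recording, path: str | Path) -> None:
    cols = {"time_s": recording.times()}
    for chromo_idx, chromo in enumerate(CHROMOPHORES):
        for ch in range(recording.n_channels):
            cols[f"ch{ch + 1}_{chromo}"] = recording.data[ch, chromo_idx]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_recording(path: str | Path, column_map: dict[str, str] | None = None) -> Recording:
    """Read a recording CSV; validates schema, sampling uniformity and NaNs.

    ``column_map`` renames externally named columns to the canonical
    ``time_s`` / ``ch{N}_{HbO,HbR}`` scheme before validation.  Short NaN
    gaps (at most 1 s) are linearly interpolated; longer runs are a format
    error.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing 'time_s' column")
    matched = {c: _SIGNAL_COL.match(c) for c in df.columns if _SIGNAL_COL.match(c)}
    channels = sorted({int(m.group(1)) for m in matched.values()})
    expected = signal_columns(len(channels))
    missing = [c for c in expected if c not in df.columns]
    if missing or len(matched) != 2 * len(channels):
        raise FormatError(
            f"{path}: expected {2 * len(channels)} signal columns "
            f"(ch1..ch{len(channels)} x {CHROMOPHORES}), missing {missing or 'none'}, "
            f"found {sorted(matched)}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(np.abs(dt - dt[0]) > TIME_TOLERANCE_S) or dt[0] <= 0:
        bad = int(np.argmax(np.abs(dt - dt[0]) > TIME_TOLERANCE_S)) + 1
        raise FormatError(f"{path}: non-uniform time axis near row {bad}")
    fs = 1.0 / dt[0]
    data = np.empty((len(channels), len(CHROMOPHORES), t.size))
    for chromo_idx, chromo in enumerate(CHROMOPHORES):
        for ch in channels:
            col = f"ch{ch}_{chromo}"
            x = df[col].to_numpy(dtype=float)
            x = _fill_short_gaps(x, max_run=int(round(fs)), col=col, path=path)
            data[ch - 1, chromo_idx] = x
    return Recording(data=data, sampling_rate=fs, channel_meta=default_montage(len(channels)))


def _fill_short_gaps(x: np.ndarray, max_run: int, col: str, path) -> np.ndarray:
    nan = ~np.isfinite(x)
    if not nan.any():
        return x
    # run-length encode the NaN mask
    edges = np.flatnonzero(np.diff(np.concatenate(([0], nan.astype(int), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start > max_run:
            raise FormatError(f"{path}: column {col} has a NaN run of "
                              f"{stop - start} samples starting at row {start}")
    good = np.flatnonzero(~nan)
    if good.size < 2:
        raise FormatError(f"{path}: column {col} is almost entirely NaN")
    out = x.copy()
    out[nan] = np.interp(np.flatnonzero(nan), good, x[good])
    return out


# ---------------------------------------------------------------------------
# event timelines


def write_events(timeline: SessionTimeline, path: str | Path) -> None:
    rows = [
        {"onset_s": e.onset_s, "duration_s": e.duration_s, "kind": e.kind,
         "condition": "" if e.condition is None else e.condition}
        for e in timeline.events
    ]
    pd.DataFrame(rows, columns=["onset_s", "duration_s", "kind", "condition"]).to_csv(
        path, index=False)


def read_events(path: str | Path, sampling_rate: float = 25.0) -> SessionTimeline:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"onset_s", "duration_s", "kind"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: event file needs columns {sorted(required)}")
    events = []
    for _, row in df.iterrows():
        cond = row.get("condition")
        cond = None if pd.isna(cond) or cond == "" else int(cond)
        events.append(TimelineEvent(onset_s=float(row["onset_s"]),
                                    duration_s=float(row["duration_s"]),
                                    kind=str(row["kind"]), condition=cond))
    return SessionTimeline(events=events, sampling_rate=sampling_rate)


# ---------------------------------------------------------------------------
# results and configs


RESULT_COLUMNS = ["scenario", "window_length_s", "offset_s", "fold", "accuracy", "chance"]


def write_results(results: list[CVResult], path: str | Path) -> Path:
    """Per-fold accuracies as CSV plus a JSON summary next to it.

    The summary lists mean/std accuracy and chance per scenario and window,
    mirroring how such results are tabulated.  Returns the JSON path.
    """
    path = Path(path)
    rows = []
    summary = []
    for r in results:
        for fold, acc in enumerate(r.fold_accuracies):
            rows.append({"scenario": r.scenario, "window_length_s": r.length_s,
                         "offset_s": r.offset_s, "fold": fold,
                         "accuracy": float(acc), "chance": r.chance})
        summary.append({
            "scenario": r.scenario,
            "window_length_s": r.length_s,
            "offset_s": r.offset_s,
            "mean_accuracy": r.mean_accuracy,
            "std_accuracy": r.std_accuracy if len(r.fold_accuracies) > 1 else 0.0,
            "chance": r.chance,
            "n_instances": r.n_instances,
        })
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, index=False)
    json_path = path.with_suffix(".json")
    json_path.write_text(json.dumps(summary, indent=2))
    return json_path


def read_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        return SimConfig.from_dict(yaml.safe_load(fh) or {})


def write_config(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
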