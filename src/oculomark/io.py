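"""Plain-text I/O for gaze samples, events, metrics, and cohort manifests.

Samples files are delimited text with one row per 4 ms sample and header
``trial_id,paradigm,t_ms,gaze_x_deg,gaze_y_deg,target_x_deg,target_y_deg,valid``;
one file per subject.  Events and metrics tables are CSV.  A cohort manifest
(YAML) records subject ids, groups, file paths and seeds.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .detection import EventList
from .synthetic import (DEFAULT_RATE_HZ, PROSACCADE_ONSET_MS, SampleSeries,
                        SubjectRecord, TrialDesign, sinusoid_amplitude)

SAMPLES_HEADER = ["trial_id", "paradigm", "t_ms", "gaze_x_deg", "gaze_y_deg",
                  "target_x_deg", "target_y_deg", "valid"]
EVENTS_HEADER = ["trial_id", "event_type", "start_ms", "end_ms",
                 "x0", "y0", "x1", "y1", "amplitude_deg", "peak_velocity"]


def write_samples(series_list: Sequence[SampleSeries], path: str | Path) -> None:
    frames = []
    for s in series_list:
        frames.append(pd.DataFrame({
            "trial_id": s.trial_id, "paradigm": s.paradigm,
            "t_ms": s.t_ms, "gaze_x_deg": s.gaze_x, "gaze_y_deg": s.gaze_y,
            "target_x_deg": s.target_x, "target_y_deg": s.target_y,
            "valid": s.valid.astype(int),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.5f")


def infer_design(trial_id: str, paradigm: str, t: np.ndarray,
                 tgt: np.ndarray, trial_index: int) -> TrialDesign:
    """Reconstruct the trial design from the recorded target channel."""
    dt = float(t[1] - t[0]) if len(t) > 1 else 4.0
    duration = float(t[-1] - t[0] + dt)
    if paradigm == "fixation":
        return TrialDesign("fixation", duration, trial_index)
    if paradigm == "prosaccade":
        moved = np.flatnonzero(np.abs(tgt).sum(axis=1) > 1e-9)
        if len(moved) == 0:
            raise ValueError(f"{trial_id}: step target never appears")
        onset = float(t[moved[0]] - t[0])
        loc = (float(tgt[moved[0], 0]), float(tgt[moved[0], 1]))
        return TrialDesign("prosaccade", duration, trial_index,
                           location=loc, onset_ms=onset)
    if paradigm == "pursuit":
        var = tgt.var(axis=0)
        axis = "horizontal" if var[0] >= var[1] else "vertical"
        wave = tgt[:, 0 if axis == "horizontal" else 1]
        amp = float(np.abs(wave).max())
        # frequency from zero crossings (2 per cycle); exact-zero samples
        # are dropped so they are not double counted
        s = np.sign(wave)
        s = s[s != 0]
        crossings = int(np.sum(s[1:] * s[:-1] < 0))
        freq = crossings / 2.0 / (duration / 1000.0)
        freq = 0.25 if abs(freq - 0.25) < abs(freq - 0.5) else 0.5
        speed = amp * 2.0 * math.pi * freq
        speed = 10.0 if abs(speed - 10.0) < abs(speed - 20.0) else 20.0
        return TrialDesign("pursuit", duration, trial_index, axis=axis,
                           speed_deg_s=speed, frequency_hz=freq)
    raise ValueError(f"unknown paradigm {paradigm!r}")


def read_samples(path: str | Path) -> list[SampleSeries]:
    df = pd.read_csv(path)
    missing = [c for c in SAMPLES_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for i, (trial_id, sub) in enumerate(df.groupby("trial_id", sort=False)):
        t = sub["t_ms"].to_numpy(float)
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 4.0
        paradigm = str(sub["paradigm"].iloc[0])
        tgt = sub[["target_x_deg", "target_y_deg"]].to_numpy(float)
        out.append(SampleSeries(
            trial_id=str(trial_id), paradigm=paradigm,
            t_ms=t,
            gaze_x=sub["gaze_x_deg"].to_numpy(float),
            gaze_y=sub["gaze_y_deg"].to_numpy(float),
            target_x=tgt[:, 0], target_y=tgt[:, 1],
            valid=sub["valid"].to_numpy(int).astype(bool),
            sampling_rate=1000.0 / dt,
            design=infer_design(str(trial_id), paradigm, t, tgt, i),
        ))
    return out


def write_events(events_list: Iterable[EventList], path: str | Path) -> None:
    rows = []
    for ev in events_list:
        for s in ev.saccades:
            rows.append([ev.trial_id, "saccade", s.onset_ms, s.offset_ms,
                         s.start_x, s.start_y, s.end_x, s.end_y,
                         s.amplitude_deg, s.peak_velocity])
        for f in ev.fixations:
            rows.append([ev.trial_id, "fixation", f.start_ms, f.end_ms,
                         f.centroid_x, f.centroid_y, f.centroid_x,
                         f.centroid_y, 0.0, 0.0])
        for b in ev.blinks:
            rows.append([ev.trial_id, "blink", b.start_ms, b.end_ms,
                         np.nan, np.nan, np.nan, np.nan, np.nan, np.nan])
    pd.DataFrame(rows, columns=EVENTS_HEADER).to_csv(path, index=False,
                                                     float_format="%.4f")


def write_manifest(subjects: Sequence[SubjectRecord], paths: dict[str, str],
                   master_seed: int, path: str | Path) -> None:
    manifest = {
        "master_seed": master_seed,
        "subjects": [
            {"subject_id": s.subject_id, "group": s.group,
             "file": paths[s.subject_id]}
            for s in subjects
        ],
    }
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))


def read_manifest(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def validate_samples_file(path: str | Path,
                          expected_rate_hz: float = DEFAULT_RATE_HZ,
                          max_angle_deg: float = 60.0) -> list[dict]:
    """Machine-readable issue list for one samples file (reports only).

    Checks the header, per-trial time monotonicity, sampling-rate
    consistency, and plausible angle ranges.
    """
    issues: list[dict] = []
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # unreadable/corrupt file
        return [{"issue": "unreadable", "detail": str(exc)}]
    missing = [c for c in SAMPLES_HEADER if c not in df.columns]
    if missing:
        return [{"issue": "missing_columns", "detail": ",".join(missing)}]
    for trial_id, sub in df.groupby("trial_id", sort=False):
        t = sub["t_ms"].to_numpy(float)
        if len(t) > 1:
            dt = np.diff(t)
            if (dt <= 0).any():
                issues.append({"issue": "non_monotone_time",
                               "detail": str(trial_id)})
                continue
            rate = 1000.0 / np.median(dt)
            if abs(rate - expected_rate_hz) > 1.0:
                issues.append({
                    "issue": "sampling_rate_mismatch",
                    "detail": f"{trial_id}: {rate:.1f} Hz, expected "
                              f"{expected_rate_hz:.0f} Hz; resample before analysis",
                })
        for col in ("gaze_x_deg", "gaze_y_deg", "target_x_deg", "target_y_deg"):
            v = sub[col].to_numpy(float)
            v = v[np.isfinite(v)]
            if len(v) and np.abs(v).max() > max_angle_deg:
                issues.append({"issue": "angle_out_of_range",
                               "detail": f"{trial_id}:{col}"})
    return issues
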