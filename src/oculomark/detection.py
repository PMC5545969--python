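"""Saccade / fixation / blink parsing of gaze sample streams.

Re-implements the standard tracker-side event parser: a saccade is a maximal
run of samples whose smoothed velocity exceeds 30 deg/s or whose acceleration
exceeds 8,000 deg/s^2; the complementary valid periods are fixations; runs of
invalid samples (plus padding) are blinks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import SampleSeries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionConfig:
    velocity_threshold: float = 30.0          # deg/s
    acceleration_threshold: float = 8000.0    # deg/s^2
    min_saccade_duration_ms: float = 8.0
    min_fixation_duration_ms: float = 40.0
    blink_padding_ms: float = 50.0
    velocity_smoothing_halfwidth: int = 2     # boxcar of 2h+1 samples
    merge_gap_samples: int = 1                # sub-threshold gap merged into a saccade
    position_extension_samples: int = 2       # widen start/end position read-out
    exclusion_ceiling: float = 0.3            # max invalid fraction per trial

    def __post_init__(self) -> None:
        if self.velocity_threshold <= 0 or self.acceleration_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class Saccade:
    onset_ms: float
    offset_ms: float
    start_x: float
    start_y: float
    end_x: float
    end_y: float
    peak_velocity: float

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("saccade offset must follow onset")

    @property
    def amplitude_deg(self) -> float:
        return float(np.hypot(self.end_x - self.start_x, self.end_y - self.start_y))

    @property
    def direction_rad(self) -> float:
        return float(np.arctan2(self.end_y - self.start_y, self.end_x - self.start_x))

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class Fixation:
    start_ms: float
    end_ms: float
    centroid_x: float
    centroid_y: float

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass
class Blink:
    start_ms: float
    end_ms: float
    padding_ms: float


@dataclass
class EventList:
    trial_id: str
    paradigm: str
    saccades: list[Saccade] = field(default_factory=list)
    fixations: list[Fixation] = field(default_factory=list)
    blinks: list[Blink] = field(default_factory=list)
    invalid_fraction: float = 0.0
    excluded: bool = False


@dataclass
class Kinematics:
    """Per-sample speed and acceleration magnitude with a defined-ness mask."""

    velocity: np.ndarray   # (n, 2) deg/s, from the smoothed trace
    speed: np.ndarray      # (n,) deg/s, from the smoothed trace
    raw_speed: np.ndarray  # (n,) deg/s, unsmoothed central difference
    acceleration: np.ndarray  # (n,) deg/s^2, |dv/dt|
    ok: np.ndarray         # defined (not inside/adjacent to invalid runs)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) half-open index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def _smooth_valid(x: np.ndarray, valid: np.ndarray, half: int) -> np.ndarray:
    """Boxcar smoothing applied independently within each valid run."""
    out = x.copy()
    if half <= 0:
        return out
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    for i0, i1 in _runs(valid):
        seg = x[i0:i1]
        if len(seg) < 2 * half + 1:
            continue
        padded = np.concatenate([seg[half:0:-1], seg, seg[-2:-half - 2:-1]])
        out[i0:i1] = np.convolve(padded, kernel, mode="valid")
    return out


def compute_kinematics(series: SampleSeries,
                       config: DetectionConfig = DetectionConfig()) -> Kinematics:
    """Central-difference velocity/acceleration on a smoothed gaze trace.

    Samples inside or adjacent to invalid runs are flagged undefined.  A
    series with fewer than 5 valid samples yields an all-undefined result.
    """
    n = series.n_samples
    dt_s = series.dt_ms / 1000.0
    valid = series.valid.astype(bool)
    vel = np.zeros((n, 2))
    speed = np.zeros(n)
    raw_speed = np.zeros(n)
    acc = np.zeros(n)
    ok = np.zeros(n, dtype=bool)
    if valid.sum() < 5:
        logger.warning("trial %s: too few valid samples for kinematics",
                       series.trial_id)
        return Kinematics(vel, speed, raw_speed, acc, ok)

    h = config.velocity_smoothing_halfwidth
    gx = _smooth_valid(series.gaze_x, valid, h)
    gy = _smooth_valid(series.gaze_y, valid, h)
    for i0, i1 in _runs(valid):
        if i1 - i0 < 5:
            continue
        sl = slice(i0, i1)
        vx = np.gradient(gx[sl], dt_s)
        vy = np.gradient(gy[sl], dt_s)
        vel[sl, 0], vel[sl, 1] = vx, vy
        speed[sl] = np.hypot(vx, vy)
        raw_speed[sl] = np.hypot(np.gradient(series.gaze_x[sl], dt_s),
                                 np.gradient(series.gaze_y[sl], dt_s))
        ax = np.gradient(vx, dt_s)
        ay = np.gradient(vy, dt_s)
        acc[sl] = np.hypot(ax, ay)
        # boundary samples see one-sided differences and smoothing edge
        # effects: flag the first/last h+1 samples of each run undefined
        ok[i0 + h + 1:i1 - h - 1] = True
    return Kinematics(vel, speed, raw_speed, acc, ok)


def detect_events(series: SampleSeries,
                  config: DetectionConfig = DetectionConfig()) -> EventList:
    """Parse one trial into saccades, fixations, and blinks.

    Saccades: maximal runs with speed > velocity_threshold OR acceleration >
    acceleration_threshold (sub-threshold gaps up to ``merge_gap_samples``
    merged), at least ``min_saccade_duration_ms`` long.  Complementary valid
    runs of at least ``min_fixation_duration_ms`` become fixations.  Invalid
    runs, padded by ``blink_padding_ms``, become blinks.  Events never
    overlap.
    """
    t = series.t_ms
    dt = series.dt_ms
    n = series.n_samples
    valid = series.valid.astype(bool)
    events = EventList(series.trial_id, series.paradigm,
                       invalid_fraction=float(1.0 - valid.mean()) if n else 1.0)
    if not valid.any():
        events.excluded = True
        logger.warning("trial %s: all samples invalid", series.trial_id)
        return events

    # blinks: invalid runs +- padding; padded samples excluded from events
    pad = int(round(config.blink_padding_ms / dt))
    usable = valid.copy()
    for i0, i1 in _runs(~valid):
        events.blinks.append(Blink(float(t[max(i0 - pad, 0)]),
                                   float(t[min(i1 + pad, n) - 1] + dt),
                                   config.blink_padding_ms))
        usable[max(i0 - pad, 0):min(i1 + pad, n)] = False

    kin = compute_kinematics(series, config)
    hot = usable & kin.ok & ((kin.speed > config.velocity_threshold) |
                             (kin.acceleration > config.acceleration_threshold))

    # merge sub-threshold gaps of <= merge_gap_samples between hot runs
    runs = _runs(hot)
    merged: list[tuple[int, int]] = []
    for r in runs:
        if merged and r[0] - merged[-1][1] <= config.merge_gap_samples \
                and usable[merged[-1][1]:r[0]].all():
            merged[-1] = (merged[-1][0], r[1])
        else:
            merged.append(r)

    ext = config.position_extension_samples
    in_saccade = np.zeros(n, dtype=bool)
    for i0, i1 in merged:
        if (i1 - i0) * dt < config.min_saccade_duration_ms:
            continue
        j0, j1 = i0, i1 - 1
        # read positions slightly beyond the threshold crossings
        while j0 > 0 and i0 - j0 < ext and usable[j0 - 1]:
            j0 -= 1
        while j1 < n - 1 and j1 - (i1 - 1) < ext and usable[j1 + 1]:
            j1 += 1
        events.saccades.append(Saccade(
            onset_ms=float(t[i0]), offset_ms=float(t[i1 - 1] + dt),
            start_x=float(series.gaze_x[j0]), start_y=float(series.gaze_y[j0]),
            end_x=float(series.gaze_x[j1]), end_y=float(series.gaze_y[j1]),
            peak_velocity=float(kin.raw_speed[i0:i1].max()),
        ))
        in_saccade[i0:i1] = True

    for i0, i1 in _runs(usable & ~in_saccade):
        if (i1 - i0) * dt < config.min_fixation_duration_ms:
            continue
        events.fixations.append(Fixation(
            start_ms=float(t[i0]), end_ms=float(t[i1 - 1] + dt),
            centroid_x=float(series.gaze_x[i0:i1].mean()),
            centroid_y=float(series.gaze_y[i0:i1].mean()),
        ))

    if events.invalid_fraction > config.exclusion_ceiling:
        events.excluded = True
    return events


def exclude_bad_trials(pairs: list[tuple[SampleSeries, EventList]],
                       ceiling: float | None = None,
                       config: DetectionConfig = DetectionConfig()
                       ) -> tuple[list[tuple[SampleSeries, EventList]], pd.DataFrame]:
    """Drop trials whose invalid fraction exceeds the ceiling.

    Returns the retained (series, events) pairs and a per-paradigm exclusion
    report with columns paradigm, n_trials, n_excluded, pct_excluded.
    """
    ceiling = config.exclusion_ceiling if ceiling is None else ceiling
    kept = []
    rows: dict[str, list[int]] = {}
    for series, events in pairs:
        stats = rows.setdefault(series.paradigm, [0, 0])
        stats[0] += 1
        if events.invalid_fraction > ceiling:
            events.excluded = True
            stats[1] += 1
        else:
            kept.append((series, events))
    report = pd.DataFrame(
        [
            {"paradigm": p, "n_trials": nt, "n_excluded": ne,
             "pct_excluded": 100.0 * ne / nt if nt else 0.0}
            for p, (nt, ne) in sorted(rows.items())
        ]
    )
    return kept, report
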