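"""The eight oculomotor summary metrics.

Fixation stability: number of large (>2 deg) intrusive saccades, number of
square wave jerks, maximum fixation duration.  Pro-saccade: accuracy, time
to fixate the target, number of saccades needed to fixate it (fixations
count as on-target when they last at least 250 ms within 1.5 deg of the
target centre).  Smooth pursuit: pursuit gain (eye/target velocity along
the motion axis, ratios <= 0.5 dismissed) and proportion of time pursuing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import DetectionConfig, EventList, Fixation, Saccade, compute_kinematics
from .synthetic import SampleSeries, TrialDesign

MISSING = float("nan")

METRIC_NAMES = (
    "large_intrusive_saccades",
    "square_wave_jerks",
    "max_fixation_duration_ms",
    "accuracy",
    "time_to_fixate_ms",
    "saccades_to_fixate",
    "pursuit_gain",
    "proportion_time_pursuing",
)


@dataclass(frozen=True)
class MetricConfig:
    intrusive_amplitude_min: float = 2.0   # deg
    swj_amplitude_max: float = 2.0         # deg
    swj_return_window_ms: float = 300.0
    swj_amplitude_diff_max: float = 0.75   # deg
    swj_opposition_max_rad: float = math.pi / 4.0  # return within 45 deg of opposite
    interest_radius: float = 1.5           # deg
    fixation_on_target_min_ms: float = 250.0
    target_timeout_ms: float = 5000.0
    pursuit_gain_floor: float = 0.5
    ms_per_sample: float = 4.0
    target_velocity_min_deg_s: float = 1.0  # turnaround guard for velocity ratios

    def __post_init__(self) -> None:
        for name in ("intrusive_amplitude_min", "swj_amplitude_max",
                     "swj_return_window_ms", "swj_amplitude_diff_max",
                     "interest_radius", "fixation_on_target_min_ms",
                     "target_timeout_ms", "pursuit_gain_floor", "ms_per_sample"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# fixation stability
# ---------------------------------------------------------------------------

def count_large_intrusive_saccades(events: EventList,
                                   config: MetricConfig = MetricConfig()) -> float:
    """Number of saccades with amplitude > 2 deg during attempted fixation."""
    if events.excluded:
        return MISSING
    return float(sum(1 for s in events.saccades
                     if s.amplitude_deg > config.intrusive_amplitude_min))


def _angular_difference(a: float, b: float) -> float:
    """Absolute difference between two angles, folded to [0, pi]."""
    d = abs(a - b) % (2.0 * math.pi)
    return min(d, 2.0 * math.pi - d)


def detect_square_wave_jerks(events: EventList,
                             target_pos: tuple[float, float] = (0.0, 0.0),
                             config: MetricConfig = MetricConfig()) -> float:
    """Count square wave jerks: a small saccade away from the target followed
    within 300 ms by a similar-amplitude (difference < 0.75 deg) saccade that
    brings the gaze back.

    "Back to the target" is operationalized as: the second saccade ends closer
    to the target than the first one did, and its direction lies within 45 deg
    of the exact opposite of the first.  Pairing is greedy earliest-first and
    each saccade joins at most one pair.
    """
    if events.excluded:
        return MISSING
    tx, ty = target_pos
    sacc = sorted(events.saccades, key=lambda s: s.onset_ms)
    used = [False] * len(sacc)
    count = 0
    for i, s1 in enumerate(sacc):
        if used[i] or s1.amplitude_deg >= config.swj_amplitude_max:
            continue
        d1 = math.hypot(s1.end_x - tx, s1.end_y - ty)
        d1_start = math.hypot(s1.start_x - tx, s1.start_y - ty)
        if d1 <= d1_start:           # s1 must take the gaze away from the target
            continue
        for j in range(i + 1, len(sacc)):
            s2 = sacc[j]
            if used[j]:
                continue
            if s2.onset_ms - s1.offset_ms > config.swj_return_window_ms:
                break
            if s2.amplitude_deg >= config.swj_amplitude_max:
                continue
            if abs(s1.amplitude_deg - s2.amplitude_deg) >= config.swj_amplitude_diff_max:
                continue
            d2 = math.hypot(s2.end_x - tx, s2.end_y - ty)
            opposed = _angular_difference(
                s2.direction_rad, s1.direction_rad + math.pi
            ) <= config.swj_opposition_max_rad
            if d2 < d1 and opposed:
                used[i] = used[j] = True
                count += 1
                break
    return float(count)


def max_fixation_duration(events: EventList,
                          trial_duration_ms: float | None = None) -> float:
    """Longest period of fixation (time between saccades), blinks excised.

    Consecutive fixations separated only by a blink are merged, with the
    blink time itself excluded from the duration.
    """
    if events.excluded or not events.fixations:
        return MISSING
    fix = sorted(events.fixations, key=lambda f: f.start_ms)
    sacc_bounds = sorted((s.onset_ms, s.offset_ms) for s in events.saccades)
    best = 0.0
    cur = 0.0
    prev_end = None
    for f in fix:
        joined = False
        if prev_end is not None:
            gap_has_saccade = any(on < f.start_ms and off > prev_end
                                  for on, off in sacc_bounds)
            joined = not gap_has_saccade
        cur = cur + f.duration_ms if joined else f.duration_ms
        best = max(best, cur)
        prev_end = f.end_ms
    return float(best)


# ---------------------------------------------------------------------------
# pro-saccade
# ---------------------------------------------------------------------------

def _qualifying_fixations(events: EventList, design: TrialDesign,
                          config: MetricConfig) -> list[Fixation]:
    """Fixations on target: >= 250 ms, centroid within 1.5 deg, starting
    before the target timeout."""
    tx, ty = design.location
    out = []
    for f in sorted(events.fixations, key=lambda f: f.start_ms):
        if f.duration_ms < config.fixation_on_target_min_ms:
            continue
        if math.hypot(f.centroid_x - tx, f.centroid_y - ty) > config.interest_radius:
            continue
        if f.start_ms > design.onset_ms + config.target_timeout_ms:
            continue
        out.append(f)
    return out


def prosaccade_accuracy(events: EventList, design: TrialDesign,
                        config: MetricConfig = MetricConfig()) -> float:
    """1 if the participant fixated the target while it was presented."""
    if events.excluded:
        return MISSING
    qual = _qualifying_fixations(events, design, config)
    return 1.0 if any(f.end_ms > design.onset_ms for f in qual) else 0.0


def _first_post_onset_fixation(events: EventList, design: TrialDesign,
                               config: MetricConfig) -> Fixation | None:
    """First qualifying fixation starting at/after target onset; anticipatory
    qualifying fixations (start before onset) are skipped ("corrected")."""
    for f in _qualifying_fixations(events, design, config):
        if f.start_ms >= design.onset_ms:
            return f
    return None


def time_to_fixate(events: EventList, design: TrialDesign,
                   config: MetricConfig = MetricConfig()) -> float:
    """Target onset to the start of the first fixation reaching the target.

    Anticipatory first fixations are replaced by the next qualifying fixation
    if one exists, otherwise the trial is removed (missing); a timeout with
    no qualifying fixation is missing.
    """
    if events.excluded:
        return MISSING
    f = _first_post_onset_fixation(events, design, config)
    if f is None:
        return MISSING
    return float(f.start_ms - design.onset_ms)


def saccades_to_fixate(events: EventList, design: TrialDesign,
                       config: MetricConfig = MetricConfig()) -> float:
    """Number of saccades between target onset and the first on-target fixation."""
    if events.excluded:
        return MISSING
    qual = _qualifying_fixations(events, design, config)
    if not qual:
        return MISSING
    q = qual[0]
    # anticipatory fixation already on target at onset -> zero saccades needed
    window_end = max(q.start_ms, design.onset_ms)
    return float(sum(1 for s in events.saccades
                     if design.onset_ms <= s.onset_ms <= window_end))


# ---------------------------------------------------------------------------
# smooth pursuit
# ---------------------------------------------------------------------------

def _pursuit_ratio_mask(series: SampleSeries, events: EventList,
                        design: TrialDesign, config: MetricConfig,
                        detection_config: DetectionConfig
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Signed per-sample velocity ratio along the motion axis and the
    retained-sample mask (outside saccades/blinks, ratio > floor)."""
    axis = 0 if design.axis == "horizontal" else 1
    kin = compute_kinematics(series, detection_config)
    dt_s = series.dt_ms / 1000.0
    v_eye = kin.velocity[:, axis]
    v_tgt = np.gradient(series.target[:, axis], dt_s)

    inside_event = np.zeros(series.n_samples, dtype=bool)
    for s in events.saccades:
        inside_event |= (series.t_ms >= s.onset_ms) & (series.t_ms < s.offset_ms)
    for b in events.blinks:
        inside_event |= (series.t_ms >= b.start_ms) & (series.t_ms < b.end_ms)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = v_eye / v_tgt
    usable = (kin.ok & ~inside_event & np.isfinite(ratio)
              & (np.abs(v_tgt) >= config.target_velocity_min_deg_s))
    retained = usable & (ratio > config.pursuit_gain_floor)
    return ratio, retained


def pursuit_gain(series: SampleSeries, events: EventList, design: TrialDesign,
                 config: MetricConfig = MetricConfig(),
                 detection_config: DetectionConfig = DetectionConfig()) -> float:
    """Mean eye/target velocity ratio over retained pursuit samples."""
    if events.excluded:
        return MISSING
    ratio, retained = _pursuit_ratio_mask(series, events, design, config,
                                          detection_config)
    if not retained.any():
        return MISSING
    return float(ratio[retained].mean())


def proportion_time_pursuing(series: SampleSeries, events: EventList,
                             design: TrialDesign,
                             config: MetricConfig = MetricConfig(),
                             detection_config: DetectionConfig = DetectionConfig()
                             ) -> float:
    """Fraction of the trial spent pursuing: retained samples x 4 ms / duration."""
    if events.excluded:
        return MISSING
    _, retained = _pursuit_ratio_mask(series, events, design, config,
                                      detection_config)
    return float(retained.sum() * config.ms_per_sample / series.duration_ms)


# ---------------------------------------------------------------------------
# per-trial dispatch and aggregation
# ---------------------------------------------------------------------------

def compute_trial_metrics(series: SampleSeries, events: EventList,
                          subject_id: str, group: str,
                          config: MetricConfig = MetricConfig(),
                          detection_config: DetectionConfig = DetectionConfig()
                          ) -> list[dict]:
    """All metrics defined for one trial as long-format rows."""
    design = series.design
    base = {
        "subject_id": subject_id, "group": group,
        "paradigm": series.paradigm, "trial_id": series.trial_id,
        "distance_deg": design.distance_deg if design else None,
        "direction": design.direction if design else None,
        "axis": design.axis if design else None,
        "speed_deg_s": design.speed_deg_s if design else None,
    }
    values: dict[str, float] = {}
    if series.paradigm == "fixation":
        values["large_intrusive_saccades"] = count_large_intrusive_saccades(events, config)
        values["square_wave_jerks"] = detect_square_wave_jerks(events, (0.0, 0.0), config)
        values["max_fixation_duration_ms"] = max_fixation_duration(events)
    elif series.paradigm == "prosaccade":
        values["accuracy"] = prosaccade_accuracy(events, design, config)
        values["time_to_fixate_ms"] = time_to_fixate(events, design, config)
        values["saccades_to_fixate"] = saccades_to_fixate(events, design, config)
    elif series.paradigm == "pursuit":
        values["pursuit_gain"] = pursuit_gain(series, events, design, config,
                                              detection_config)
        values["proportion_time_pursuing"] = proportion_time_pursuing(
            series, events, design, config, detection_config)
    rows = []
    for name, value in values.items():
        missing = not np.isfinite(value)
        rows.append({**base, "metric": name,
                     "value": None if missing else value,
                     "missing": missing,
                     "reason": ("excluded_trial" if events.excluded else
                                "no_qualifying_event") if missing else ""})
    return rows


def _strata(sub: pd.DataFrame) -> list[tuple[str, pd.Series]]:
    out: list[tuple[str, pd.Series]] = [("Overall", pd.Series(True, index=sub.index))]
    paradigm = sub["paradigm"].iloc[0]
    if paradigm == "prosaccade":
        for d in (5.0, 10.0, 15.0):
            out.append((f"{d:g} deg", sub["distance_deg"] == d))
        for direction in ("up", "down", "right", "left"):
            out.append((direction.capitalize(), sub["direction"] == direction))
    elif paradigm == "pursuit":
        for v in (10.0, 20.0):
            out.append((f"{v:g} deg/s", sub["speed_deg_s"] == v))
        for ax in ("horizontal", "vertical"):
            out.append((ax.capitalize(), sub["axis"] == ax))
    return out


def aggregate_metrics(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-group x metric x condition-stratum mean (SD) summary table.

    Missing rows are excluded listwise per metric; ``n`` counts the non-missing
    trials entering each cell.
    """
    cols = ["group", "metric", "stratum", "n", "mean", "sd", "n_missing"]
    if rows.empty:
        return pd.DataFrame(columns=cols)
    out = []
    for (group, metric), sub in rows.groupby(["group", "metric"], sort=True):
        for stratum, mask in _strata(sub):
            cell = sub[mask]
            vals = cell.loc[~cell["missing"], "value"].astype(float)
            out.append({
                "group": group, "metric": metric, "stratum": stratum,
                "n": int(len(vals)),
                "mean": float(vals.mean()) if len(vals) else None,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else None,
                "n_missing": int(cell["missing"].sum()),
            })
    return pd.DataFrame(out, columns=cols)
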