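"""The eight summary metrics against brute-force and constructed oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_series
from oculomark.detection import EventList, Fixation, Saccade, detect_events
from oculomark.metrics import (MetricConfig, aggregate_metrics,
                               compute_trial_metrics,
                               count_large_intrusive_saccades,
                               detect_square_wave_jerks, max_fixation_duration,
                               proportion_time_pursuing, prosaccade_accuracy,
                               pursuit_gain, saccades_to_fixate, time_to_fixate)
from oculomark.synthetic import TrialDesign, design_experiment

CFG = MetricConfig()


def sac(onset, start, end, dur=30.0):
    return Saccade(onset_ms=onset, offset_ms=onset + dur,
                   start_x=start[0], start_y=start[1],
                   end_x=end[0], end_y=end[1], peak_velocity=200.0)


def fix(start, end, centroid):
    return Fixation(start_ms=start, end_ms=end,
                    centroid_x=centroid[0], centroid_y=centroid[1])


def ev(saccades=(), fixations=(), paradigm="fixation"):
    return EventList("t", paradigm, saccades=list(saccades),
                     fixations=list(fixations))


# ---------------------------------------------------------------------------
# fixation stability
# ---------------------------------------------------------------------------

def test_intrusive_count_examples():
    amps = [2.5, 1.0, 3.0]
    saccades = [sac(i * 1000.0, (0, 0), (a, 0)) for i, a in enumerate(amps)]
    assert count_large_intrusive_saccades(ev(saccades)) == 2
    assert count_large_intrusive_saccades(ev([])) == 0


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.floats(min_value=0.01, max_value=8.0), max_size=15))
def test_intrusive_count_matches_filter_oracle(amps):
    saccades = [sac(i * 400.0, (0, 0), (a, 0)) for i, a in enumerate(amps)]
    assert count_large_intrusive_saccades(ev(saccades)) == \
        sum(a > 2.0 for a in amps)


def test_intrusive_count_matches_scan_oracle():
    rng = np.random.default_rng(0)
    for _ in range(200):
        amps = rng.lognormal(0.3, 0.8, size=rng.integers(0, 12))
        saccades = [sac(i * 400.0, (0, 0), (a, 0)) for i, a in enumerate(amps)]
        expected = int(np.sum(amps > 2.0))
        assert count_large_intrusive_saccades(ev(saccades)) == expected


def test_swj_canonical_pair():
    # 1.2 deg rightward then 1.1 deg back 150 ms later
    s1 = sac(1000.0, (0, 0), (1.2, 0))
    s2 = sac(1000.0 + 30.0 + 150.0, (1.2, 0), (0.1, 0))
    assert detect_square_wave_jerks(ev([s1, s2])) == 1
    assert detect_square_wave_jerks(ev([s1])) == 0


def test_swj_rejects_late_or_unequal_return():
    s1 = sac(1000.0, (0, 0), (1.2, 0))
    late = sac(1400.0, (1.2, 0), (0.0, 0))        # 370 ms after offset
    assert detect_square_wave_jerks(ev([s1, late])) == 0
    unequal = sac(1200.0, (1.2, 0), (-0.9, 0))    # amplitude differs by >0.75
    assert detect_square_wave_jerks(ev([s1, unequal])) == 0


def _swj_oracle(saccades, cfg=CFG, target=(0.0, 0.0)):
    """Independent pair-enumeration with the same greedy earliest-first rule."""
    tx, ty = target
    order = sorted(saccades, key=lambda s: s.onset_ms)
    taken = set()
    n = 0
    for i, a in enumerate(order):
        if i in taken or a.amplitude_deg >= cfg.swj_amplitude_max:
            continue
        if math.hypot(a.end_x - tx, a.end_y - ty) <= \
                math.hypot(a.start_x - tx, a.start_y - ty):
            continue
        for j, b in enumerate(order):
            if j <= i or j in taken:
                continue
            if b.onset_ms - a.offset_ms > cfg.swj_return_window_ms:
                continue
            if b.amplitude_deg >= cfg.swj_amplitude_max:
                continue
            if abs(a.amplitude_deg - b.amplitude_deg) >= cfg.swj_amplitude_diff_max:
                continue
            if math.hypot(b.end_x - tx, b.end_y - ty) >= \
                    math.hypot(a.end_x - tx, a.end_y - ty):
                continue
            diff = abs((b.direction_rad - a.direction_rad - math.pi)
                       + math.pi) % (2 * math.pi) - math.pi
            if abs(diff) > cfg.swj_opposition_max_rad:
                continue
            taken.add(i)
            taken.add(j)
            n += 1
            break
    return n


def test_swj_matches_bruteforce_oracle_on_random_lists():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        k = rng.integers(0, 10)
        saccades = []
        t = 0.0
        for _ in range(k):
            t += rng.uniform(40.0, 400.0)
            start = rng.uniform(-2, 2, size=2)
            amp = rng.lognormal(0.0, 0.7)
            theta = rng.uniform(0, 2 * math.pi)
            end = start + amp * np.array([math.cos(theta), math.sin(theta)])
            saccades.append(sac(t, start, end))
        assert detect_square_wave_jerks(ev(saccades)) == _swj_oracle(saccades)


def test_max_fixation_duration():
    fixes = [fix(0.0, 3000.0, (0, 0)), fix(3100.0, 8100.0, (0, 0))]
    events = ev([sac(3000.0, (0, 0), (1, 0), dur=100.0)], fixes)
    assert max_fixation_duration(events) == pytest.approx(5000.0)
    # no saccade between fixations (blink split): durations merge
    events = ev([], fixes)
    assert max_fixation_duration(events) == pytest.approx(8000.0)
    assert np.isnan(max_fixation_duration(ev([])))


def test_max_fixation_matches_scan_oracle_on_random_lists():
    rng = np.random.default_rng(3)
    for _ in range(200):
        n = rng.integers(1, 8)
        t = 0.0
        fixes, saccades = [], []
        for i in range(n):
            d = rng.uniform(100.0, 3000.0)
            fixes.append(fix(t, t + d, (0, 0)))
            t += d
            saccades.append(sac(t, (0, 0), (1, 0), dur=50.0))
            t += 50.0
        expected = max(f.duration_ms for f in fixes)
        assert max_fixation_duration(ev(saccades, fixes)) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# pro-saccade
# ---------------------------------------------------------------------------

STEP = TrialDesign("prosaccade", 5700.0, 0, location=(10.0, 0.0))


def test_accuracy_radius_and_duration_rules():
    on = STEP.onset_ms
    inside = ev([], [fix(on + 400, on + 700, (10.0 + 1.4, 0.0))], "prosaccade")
    assert prosaccade_accuracy(inside, STEP) == 1
    outside = ev([], [fix(on + 400, on + 700, (10.0 + 1.6, 0.0))], "prosaccade")
    assert prosaccade_accuracy(outside, STEP) == 0
    brief = ev([], [fix(on + 400, on + 600, (10.0, 0.0))], "prosaccade")
    assert prosaccade_accuracy(brief, STEP) == 0


def test_time_to_fixate_and_anticipatory_correction():
    on = STEP.onset_ms
    events = ev([], [fix(on + 412, on + 900, (10.0, 0.0))], "prosaccade")
    assert time_to_fixate(events, STEP) == pytest.approx(412.0)
    # anticipatory qualifying fixation corrected to the next one
    events = ev([], [fix(on - 300, on + 50, (10.0, 0.0)),
                     fix(on + 600, on + 900, (10.0, 0.0))], "prosaccade")
    assert time_to_fixate(events, STEP) == pytest.approx(600.0)
    # anticipatory only, nothing afterwards: removed
    events = ev([], [fix(on - 300, on + 50, (10.0, 0.0))], "prosaccade")
    assert np.isnan(time_to_fixate(events, STEP))
    # nothing reaches the area within the timeout
    events = ev([], [fix(on + 5500, on + 5900, (10.0, 0.0))], "prosaccade")
    assert np.isnan(time_to_fixate(events, STEP))


def test_saccades_to_fixate():
    on = STEP.onset_ms
    qual = fix(on + 500, on + 900, (10.0, 0.0))
    primary = sac(on + 200, (0, 0), (8.0, 0))
    corr1 = sac(on + 330, (8.0, 0), (9.3, 0))
    corr2 = sac(on + 430, (9.3, 0), (10.0, 0))
    assert saccades_to_fixate(ev([primary], [qual], "prosaccade"), STEP) == 1
    assert saccades_to_fixate(ev([primary, corr1, corr2], [qual],
                                 "prosaccade"), STEP) == 3
    # fixation already on target at onset: zero saccades needed
    anticip = fix(on - 100, on + 400, (10.0, 0.0))
    assert saccades_to_fixate(ev([], [anticip], "prosaccade"), STEP) == 0
    assert np.isnan(saccades_to_fixate(ev([], [], "prosaccade"), STEP))


# ---------------------------------------------------------------------------
# smooth pursuit
# ---------------------------------------------------------------------------

def _sine_series(gain=1.0, n=2500, freq=0.25, amp=6.366, track_until=None):
    t = np.arange(n) * 4.0
    wave = amp * np.sin(2 * math.pi * freq * t / 1000.0)
    target = np.column_stack([wave, np.zeros(n)])
    gaze = np.column_stack([gain * wave, np.zeros(n)])
    if track_until is not None:
        k = int(track_until / 4.0)
        gaze[k:] = gaze[k - 1]
    design = TrialDesign("pursuit", n * 4.0, 0, axis="horizontal",
                         speed_deg_s=10.0, frequency_hz=freq)
    return make_series(gaze, target, paradigm="pursuit", design=design), design


def test_pursuit_identity_tracking():
    series, design = _sine_series(gain=1.0)
    events = detect_events(series)
    assert pursuit_gain(series, events, design) == pytest.approx(1.0, abs=1e-3)
    assert proportion_time_pursuing(series, events, design) > 0.9


def test_pursuit_stationary_eye_missing():
    series, design = _sine_series(gain=0.0)
    events = detect_events(series)
    assert np.isnan(pursuit_gain(series, events, design))
    assert proportion_time_pursuing(series, events, design) == 0.0


def test_pursuit_constant_gain_recovered():
    series, design = _sine_series(gain=0.8)
    events = detect_events(series)
    assert pursuit_gain(series, events, design) == pytest.approx(0.8, abs=0.02)


def test_pursuit_half_tracking_proportion():
    series, design = _sine_series(gain=1.0, track_until=5000.0)
    events = detect_events(series)
    prop = proportion_time_pursuing(series, events, design)
    assert prop == pytest.approx(0.47, abs=0.07)


# ---------------------------------------------------------------------------
# invariances and aggregation
# ---------------------------------------------------------------------------

def test_metrics_invariant_under_time_translation():
    s1 = sac(1000.0, (0, 0), (1.2, 0))
    s2 = sac(1180.0, (1.2, 0), (0.05, 0))
    f1 = fix(0.0, 1000.0, (0, 0))
    shift = 2000.0
    shifted = ev([sac(s.onset_ms + shift, (s.start_x, s.start_y),
                      (s.end_x, s.end_y)) for s in (s1, s2)],
                 [fix(f1.start_ms + shift, f1.end_ms + shift, (0, 0))])
    original = ev([s1, s2], [f1])
    assert detect_square_wave_jerks(original) == detect_square_wave_jerks(shifted)
    assert max_fixation_duration(original) == max_fixation_duration(shifted)


def test_metrics_invariant_under_reflection():
    saccades = [sac(1000.0, (0, 0), (2.5, 0.4)), sac(2000.0, (2.5, 0.4), (0, 0))]
    mirrored = [sac(s.onset_ms, (-s.start_x, s.start_y), (-s.end_x, s.end_y))
                for s in saccades]
    assert count_large_intrusive_saccades(ev(saccades)) == \
        count_large_intrusive_saccades(ev(mirrored))
    assert detect_square_wave_jerks(ev(saccades)) == \
        detect_square_wave_jerks(ev(mirrored))


def test_aggregate_metrics_table():
    import pandas as pd
    rows = pd.DataFrame([
        {"subject_id": "a", "group": "control", "paradigm": "prosaccade",
         "trial_id": "t1", "distance_deg": 5.0, "direction": "left",
         "axis": None, "speed_deg_s": None, "metric": "accuracy",
         "value": 2.0, "missing": False, "reason": ""},
        {"subject_id": "a", "group": "control", "paradigm": "prosaccade",
         "trial_id": "t2", "distance_deg": 10.0, "direction": "right",
         "axis": None, "speed_deg_s": None, "metric": "accuracy",
         "value": 4.0, "missing": False, "reason": ""},
        {"subject_id": "a", "group": "control", "paradigm": "prosaccade",
         "trial_id": "t3", "distance_deg": 15.0, "direction": "right",
         "axis": None, "speed_deg_s": None, "metric": "accuracy",
         "value": None, "missing": True, "reason": "excluded_trial"},
    ])
    table = aggregate_metrics(rows)
    overall = table[(table["stratum"] == "Overall")].iloc[0]
    assert overall["n"] == 2 and overall["n_missing"] == 1
    assert overall["mean"] == pytest.approx(3.0)
    assert overall["sd"] == pytest.approx(math.sqrt(2.0))
    assert set(table["stratum"]) == {"Overall", "5 deg", "10 deg", "15 deg",
                                     "Up", "Down", "Right", "Left"}
    assert aggregate_metrics(rows.iloc[0:0]).empty
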