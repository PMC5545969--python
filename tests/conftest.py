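"""Shared fixtures: small simulated cohorts and hand-built trials."""

from __future__ import annotations

import numpy as np
import pytest

from oculomark.detection import detect_events
from oculomark.synthetic import (CONTROL, CohortSpec, OculomotorProfile,
                                 SampleSeries, design_experiment,
                                 simulate_cohort, simulate_trial)

#: a profile that produces clean, deterministic traces (no noise, no blinks)
QUIET = OculomotorProfile(
    intrusive_saccade_rate=0.0, swj_rate=0.0, fixation_noise_sd=0.0,
    saccade_latency_mean=160.0, saccade_latency_sd=0.0,
    saccade_gain_mean=1.0, saccade_gain_sd=0.0, corrective_isi_ms=140.0,
    pursuit_tracking_fraction=1.0, pursuit_gain_mean=1.0, pursuit_gain_sd=0.0,
    catchup_saccade_rate_hz=0.0, blink_rate=0.0, miss_probability=0.0,
)


def make_series(gaze: np.ndarray, target: np.ndarray | None = None,
                valid: np.ndarray | None = None, paradigm: str = "fixation",
                trial_id: str = "t0", design=None) -> SampleSeries:
    """SampleSeries from a raw (n, 2) gaze array at 250 Hz."""
    n = len(gaze)
    t = np.arange(n) * 4.0
    if target is None:
        target = np.zeros((n, 2))
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return SampleSeries(trial_id=trial_id, paradigm=paradigm, t_ms=t,
                        gaze_x=gaze[:, 0], gaze_y=gaze[:, 1],
                        target_x=target[:, 0], target_y=target[:, 1],
                        valid=valid, design=design)


@pytest.fixture(scope="session")
def small_cohort():
    """4 controls + 5 patients, all three paradigms."""
    return simulate_cohort(CohortSpec(n_controls=4, n_patients=5,
                                      master_seed=11))


@pytest.fixture(scope="session")
def pursuit_designs():
    return design_experiment("pursuit", seed=0)


@pytest.fixture(scope="session")
def control_fixation_pair():
    """One control fixation trial with its detected events."""
    design = design_experiment("fixation", seed=0)[0]
    series = simulate_trial(CONTROL, design, seed=5)
    return series, detect_events(series)
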