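"""Synthetic gaze-trace generation for the three oculomotor paradigms.

Emulates 10-s eyetracking trials recorded at 250 Hz for three experiments —
fixation stability, step pro-saccades to ten peripheral locations, and
sinusoidal smooth pursuit — with group-conditioned oculomotor behaviour:
intrusive saccades, square-wave jerks, saccade latency and hypometria,
interrupted pursuit with catch-up saccades, and blinks.  Two shipped
profiles (:data:`CONTROL`, :data:`YOAD`) are calibrated so that cohorts of
21 controls and 36 young-onset Alzheimer's patients reproduce the direction
of every published group difference in the eight summary metrics.

All positions are degrees of visual angle relative to screen centre
(+x right, +y up), all times milliseconds from trial onset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.signal import lfilter

logger = logging.getLogger(__name__)

Paradigm = Literal["fixation", "prosaccade", "pursuit"]
PARADIGMS: tuple[str, ...] = ("fixation", "prosaccade", "pursuit")

#: sampling rate of the simulated tracker (samples/s)
DEFAULT_RATE_HZ = 250.0
#: trial length for fixation and pursuit trials (ms)
TRIAL_DURATION_MS = 10_000.0
#: central-fixation period before the pro-saccade target steps (ms)
PROSACCADE_ONSET_MS = 700.0
#: pro-saccade target timeout after onset (ms)
PROSACCADE_TIMEOUT_MS = 5_000.0

#: the ten pro-saccade target locations (deg): ±5/±10/±15 horizontal, ±5/±10 vertical
PROSACCADE_LOCATIONS: tuple[tuple[float, float], ...] = (
    (5.0, 0.0), (-5.0, 0.0), (10.0, 0.0), (-10.0, 0.0),
    (15.0, 0.0), (-15.0, 0.0), (0.0, 5.0), (0.0, -5.0),
    (0.0, 10.0), (0.0, -10.0),
)

#: pursuit (peak speed deg/s, oscillation frequency Hz) pairings
PURSUIT_CONDITIONS: tuple[tuple[float, float], ...] = ((10.0, 0.25), (20.0, 0.5))


def sinusoid_amplitude(speed_deg_s: float, frequency_hz: float) -> float:
    """Oscillation amplitude (deg) for a sinusoid with the given peak speed.

    Reading the stated target speeds as peak velocity, ``A = v / (2 pi f)``;
    both published (speed, frequency) pairings then share one amplitude of
    about 6.37 deg.
    """
    return speed_deg_s / (2.0 * math.pi * frequency_hz)


def saccade_duration_ms(amplitude_deg: float) -> float:
    """Main-sequence duration approximation: ``2.2 * amplitude + 21`` ms."""
    return 2.2 * amplitude_deg + 21.0


@dataclass(frozen=True)
class TrialDesign:
    """Design of one trial: paradigm, duration and target specification."""

    paradigm: str
    duration_ms: float
    trial_index: int
    # step targets (pro-saccade)
    location: tuple[float, float] | None = None
    onset_ms: float = PROSACCADE_ONSET_MS
    timeout_ms: float = PROSACCADE_TIMEOUT_MS
    # sinusoid targets (pursuit)
    axis: str | None = None          # "horizontal" | "vertical"
    speed_deg_s: float | None = None
    frequency_hz: float | None = None

    @property
    def amplitude_deg(self) -> float | None:
        if self.paradigm != "pursuit":
            return None
        return sinusoid_amplitude(self.speed_deg_s, self.frequency_hz)

    @property
    def distance_deg(self) -> float | None:
        """Target eccentricity for step trials (5, 10 or 15 deg)."""
        if self.location is None:
            return None
        return float(np.hypot(*self.location))

    @property
    def direction(self) -> str | None:
        """Cardinal direction of a step target (up/down/left/right)."""
        if self.location is None:
            return None
        x, y = self.location
        if abs(x) >= abs(y):
            return "right" if x > 0 else "left"
        return "up" if y > 0 else "down"


@dataclass
class SaccadeTruth:
    """Ground-truth record of one rendered saccade (generator event log)."""

    onset_ms: float
    duration_ms: float
    start: tuple[float, float]
    end: tuple[float, float]

    @property
    def amplitude_deg(self) -> float:
        return float(np.hypot(self.end[0] - self.start[0],
                              self.end[1] - self.start[1]))


@dataclass
class SampleSeries:
    """One trial of gaze + target samples at a constant rate.

    ``t_ms`` increases in constant 4 ms steps at 250 Hz; ``valid`` is False
    during blinks / signal loss.  ``truth`` carries the generator's own
    saccade event log when the series is synthetic (None for loaded data).
    """

    trial_id: str
    paradigm: str
    t_ms: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    target_x: np.ndarray
    target_y: np.ndarray
    valid: np.ndarray
    sampling_rate: float = DEFAULT_RATE_HZ
    design: TrialDesign | None = None
    truth: list[SaccadeTruth] | None = None

    def __post_init__(self) -> None:
        n = len(self.t_ms)
        for name in ("gaze_x", "gaze_y", "target_x", "target_y", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch with t_ms")
        dt = np.diff(self.t_ms)
        if len(dt) and (dt <= 0).any():
            raise ValueError("t_ms must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.t_ms)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    @property
    def duration_ms(self) -> float:
        return float(self.t_ms[-1] - self.t_ms[0] + self.dt_ms)

    @property
    def gaze(self) -> np.ndarray:
        return np.column_stack([self.gaze_x, self.gaze_y])

    @property
    def target(self) -> np.ndarray:
        return np.column_stack([self.target_x, self.target_y])


@dataclass(frozen=True)
class OculomotorProfile:
    """Group-level oculomotor behaviour parameters.

    Rates are events per 10-s trial unless suffixed otherwise; gains are
    dimensionless; latencies in ms.
    """

    intrusive_saccade_rate: float      # large (>2 deg) fixation intrusions / 10 s
    swj_rate: float                    # square-wave-jerk pairs / 10 s
    fixation_noise_sd: float           # deg, stationary sd of fixational drift
    saccade_latency_mean: float        # ms, pro-saccade primary latency
    saccade_latency_sd: float
    saccade_gain_mean: float           # primary saccade amplitude / target distance
    saccade_gain_sd: float
    corrective_isi_ms: float           # inter-saccade interval while correcting
    pursuit_tracking_fraction: float   # fraction of pursuit trial spent tracking
    pursuit_gain_mean: float           # eye/target velocity while tracking
    pursuit_gain_sd: float
    catchup_saccade_rate_hz: float     # catch-up saccades per second of tracking
    blink_rate: float                  # blinks / 10 s
    miss_probability: float            # pro-saccade trial never reaching target

    def __post_init__(self) -> None:
        for name in ("intrusive_saccade_rate", "swj_rate", "blink_rate",
                     "catchup_saccade_rate_hz", "fixation_noise_sd",
                     "saccade_latency_sd", "saccade_gain_sd", "pursuit_gain_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("pursuit_tracking_fraction", "miss_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


#: healthy age-matched control preset
CONTROL = OculomotorProfile(
    intrusive_saccade_rate=0.7,
    swj_rate=0.9,
    fixation_noise_sd=0.12,
    saccade_latency_mean=160.0,
    saccade_latency_sd=40.0,
    saccade_gain_mean=0.90,
    saccade_gain_sd=0.06,
    corrective_isi_ms=140.0,
    pursuit_tracking_fraction=0.6,
    pursuit_gain_mean=1.0,
    pursuit_gain_sd=0.08,
    catchup_saccade_rate_hz=1.0,
    blink_rate=1.5,
    miss_probability=0.06,
)

#: young-onset Alzheimer's disease preset
YOAD = OculomotorProfile(
    intrusive_saccade_rate=2.5,
    swj_rate=0.9,
    fixation_noise_sd=0.18,
    saccade_latency_mean=240.0,
    saccade_latency_sd=70.0,
    saccade_gain_mean=0.75,
    saccade_gain_sd=0.10,
    corrective_isi_ms=200.0,
    pursuit_tracking_fraction=0.4,
    pursuit_gain_mean=0.95,
    pursuit_gain_sd=0.12,
    catchup_saccade_rate_hz=1.4,
    blink_rate=2.0,
    miss_probability=0.15,
)

PROFILES = {"CONTROL": CONTROL, "YOAD": YOAD}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a simulated cohort, reproducible from master_seed."""

    n_controls: int = 21
    n_patients: int = 36
    control_profile: OculomotorProfile = CONTROL
    patient_profile: OculomotorProfile = YOAD
    master_seed: int = 0
    rate_jitter_sigma: float = 0.25    # log-normal sigma on event rates
    gain_jitter_sd: float = 0.04       # normal sd on gains/fractions
    latency_jitter_sd: float = 25.0    # normal sd on latency means (ms)

    def __post_init__(self) -> None:
        if self.n_controls <= 0 or self.n_patients <= 0:
            raise ValueError("group sizes must be positive")


@dataclass
class SubjectRecord:
    """All trials of one simulated participant."""

    subject_id: str
    group: str                       # "control" | "patient"
    profile: OculomotorProfile
    trials: dict[str, list[SampleSeries]]  # paradigm -> series list


# ---------------------------------------------------------------------------
# experiment designs
# ---------------------------------------------------------------------------

def design_experiment(paradigm: str, seed: int = 0) -> list[TrialDesign]:
    """Return the trial sequence for one paradigm.

    Fixation: 3 trials of 10 s.  Pro-saccade: 40 trials in two blocks of 20,
    each of the 10 locations twice per block, order pseudo-randomized from
    ``seed`` (fixed order shared by all participants).  Pursuit: 12 trials of
    10 s, 6 per axis, pairing 10 deg/s with 0.25 Hz and 20 deg/s with 0.5 Hz.
    """
    if paradigm == "fixation":
        return [TrialDesign("fixation", TRIAL_DURATION_MS, i) for i in range(3)]
    if paradigm == "prosaccade":
        rng = np.random.default_rng(seed)
        order: list[tuple[float, float]] = []
        for _ in range(2):  # two balanced blocks of 20
            block = [loc for loc in PROSACCADE_LOCATIONS for _ in range(2)]
            rng.shuffle(block)
            order.extend(block)
        return [
            TrialDesign(
                "prosaccade",
                PROSACCADE_ONSET_MS + PROSACCADE_TIMEOUT_MS,
                i,
                location=loc,
            )
            for i, loc in enumerate(order)
        ]
    if paradigm == "pursuit":
        designs = []
        i = 0
        for axis in ("horizontal", "vertical"):
            for speed, freq in PURSUIT_CONDITIONS:
                for _ in range(3):  # 3 repeats -> 6 per axis
                    designs.append(
                        TrialDesign(
                            "pursuit", TRIAL_DURATION_MS, i,
                            axis=axis, speed_deg_s=speed, frequency_hz=freq,
                        )
                    )
                    i += 1
        return designs
    raise ValueError(f"unknown paradigm {paradigm!r}; expected one of {PARADIGMS}")


def target_trajectory(design: TrialDesign,
                      sampling_rate: float = DEFAULT_RATE_HZ
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Target position over the trial: (t_ms, target[n, 2])."""
    dt = 1000.0 / sampling_rate
    t = np.arange(0.0, design.duration_ms - 0.5 * dt, dt)
    tgt = np.zeros((len(t), 2))
    if design.paradigm == "fixation":
        pass  # static cross at the centre
    elif design.paradigm == "prosaccade":
        on = t >= design.onset_ms
        tgt[on, 0] = design.location[0]
        tgt[on, 1] = design.location[1]
    elif design.paradigm == "pursuit":
        a = design.amplitude_deg
        wave = a * np.sin(2.0 * math.pi * design.frequency_hz * t / 1000.0)
        tgt[:, 0 if design.axis == "horizontal" else 1] = wave
    else:
        raise ValueError(f"unknown paradigm {design.paradigm!r}")
    return t, tgt


# ---------------------------------------------------------------------------
# trace synthesis helpers
# ---------------------------------------------------------------------------

def _min_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on tau in [0, 1]."""
    return 10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5


def _render_saccades(t: np.ndarray, start: np.ndarray,
                     jumps: Sequence[tuple[float, np.ndarray]],
                     truth: list[SaccadeTruth]) -> np.ndarray:
    """Piecewise-constant anchors joined by minimum-jerk saccades.

    ``jumps`` is a time-sorted list of (onset_ms, destination).  Overlapping
    jumps (onset before the previous saccade has landed) are thinned with a
    logged warning.
    """
    pos = np.tile(np.asarray(start, float), (len(t), 1))
    cur = np.asarray(start, float)
    busy_until = -np.inf
    n_thinned = 0
    for onset, dest in jumps:
        if onset < busy_until:
            n_thinned += 1
            continue
        dest = np.asarray(dest, float)
        amp = float(np.hypot(*(dest - cur)))
        if amp < 1e-9:
            continue
        dur = saccade_duration_ms(amp)
        seg = (t >= onset) & (t < onset + dur)
        tau = (t[seg] - onset) / dur
        pos[seg] = cur + np.outer(_min_jerk(tau), dest - cur)
        pos[t >= onset + dur] = dest
        truth.append(SaccadeTruth(onset, dur, tuple(cur), tuple(dest)))
        cur = dest
        busy_until = onset + dur
    if n_thinned:
        logger.warning("thinned %d overlapping saccade events", n_thinned)
    return pos


def _ou_noise(n: int, sd: float, rng: np.random.Generator,
              dt_ms: float, tau_ms: float = 100.0) -> np.ndarray:
    """Ornstein–Uhlenbeck fixational drift, stationary sd ``sd`` (deg), (n, 2)."""
    if sd <= 0 or n == 0:
        return np.zeros((n, 2))
    a = math.exp(-dt_ms / tau_ms)
    innov = rng.normal(0.0, sd * math.sqrt(1.0 - a * a), size=(n, 2))
    innov[0] = rng.normal(0.0, sd, size=2)
    return lfilter([1.0], [1.0, -a], innov, axis=0)


def _apply_blinks(t: np.ndarray, gaze: np.ndarray, valid: np.ndarray,
                  rate_per_trial: float, duration_ms: float,
                  rng: np.random.Generator) -> None:
    """Overlay blinks in place: invalid 100–300 ms gaps flanked by 20 ms spikes."""
    n_blinks = rng.poisson(rate_per_trial)
    for _ in range(n_blinks):
        b_dur = rng.uniform(100.0, 300.0)
        b_on = rng.uniform(100.0, max(duration_ms - b_dur - 100.0, 101.0))
        gap = (t >= b_on) & (t < b_on + b_dur)
        if not gap.any():
            continue
        valid[gap] = False
        # eyelid artefact: fast downward deflection flanking the gap
        for lo, hi, rising in ((b_on - 20.0, b_on, True),
                               (b_on + b_dur, b_on + b_dur + 20.0, False)):
            spike = (t >= lo) & (t < hi) & valid
            if spike.any():
                frac = (t[spike] - lo) / 20.0
                gaze[spike, 1] -= 3.0 * (frac if rising else 1.0 - frac)


# ---------------------------------------------------------------------------
# per-trial simulation
# ---------------------------------------------------------------------------

def simulate_trial(profile: OculomotorProfile, design: TrialDesign,
                   seed: int | np.random.Generator,
                   trial_id: str | None = None,
                   sampling_rate: float = DEFAULT_RATE_HZ) -> SampleSeries:
    """Simulate one trial of gaze behaviour under ``profile``.

    The trace is a sum of an anchor/tracking path with minimum-jerk saccades,
    Ornstein–Uhlenbeck fixational drift, and blink artefacts; deterministic
    for a fixed seed.  The returned series carries the generator's saccade
    event log in ``truth``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t, tgt = target_trajectory(design, sampling_rate)
    dt = 1000.0 / sampling_rate
    truth: list[SaccadeTruth] = []

    if design.paradigm == "fixation":
        gaze = _simulate_fixation(profile, t, rng, truth)
    elif design.paradigm == "prosaccade":
        gaze = _simulate_prosaccade(profile, design, t, rng, truth)
    elif design.paradigm == "pursuit":
        gaze = _simulate_pursuit(profile, design, t, tgt, rng, truth)
    else:
        raise ValueError(f"unknown paradigm {design.paradigm!r}")

    gaze = gaze + _ou_noise(len(t), profile.fixation_noise_sd, rng, dt)
    valid = np.ones(len(t), dtype=bool)
    _apply_blinks(t, gaze, valid, profile.blink_rate * design.duration_ms / 10_000.0,
                  design.duration_ms, rng)

    return SampleSeries(
        trial_id=trial_id or f"{design.paradigm}_{design.trial_index:03d}",
        paradigm=design.paradigm,
        t_ms=t, gaze_x=gaze[:, 0], gaze_y=gaze[:, 1],
        target_x=tgt[:, 0], target_y=tgt[:, 1],
        valid=valid, sampling_rate=sampling_rate,
        design=design, truth=truth,
    )


def _poisson_times(rate_per_trial: float, duration_ms: float,
                   rng: np.random.Generator,
                   lo: float = 300.0, margin: float = 500.0) -> np.ndarray:
    n = rng.poisson(rate_per_trial)
    if n == 0:
        return np.empty(0)
    return np.sort(rng.uniform(lo, duration_ms - margin, size=n))


def _simulate_fixation(profile: OculomotorProfile, t: np.ndarray,
                       rng: np.random.Generator,
                       truth: list[SaccadeTruth]) -> np.ndarray:
    dur = t[-1] + (t[1] - t[0])
    # events carry anchor semantics and are resolved to absolute
    # destinations in one time-ordered pass below
    events: list[tuple[float, str, np.ndarray | None]] = []

    # large intrusive saccades: ping-pong between centre and an eccentric
    # anchor, each jump > 2 deg so each event contributes one large saccade
    for onset in _poisson_times(profile.intrusive_saccade_rate, dur, rng):
        events.append((onset, "intrusion", None))

    # square wave jerks: small conjugate pair, out and back within 300 ms
    for onset in _poisson_times(profile.swj_rate, dur, rng):
        theta = rng.uniform(0, 2 * math.pi)
        amp = rng.uniform(0.7, 1.8)
        step = np.array([amp * math.cos(theta), amp * math.sin(theta)])
        events.append((onset, "swj_away", step))
        gap = rng.uniform(80.0, 220.0)
        events.append((onset + saccade_duration_ms(amp) + gap, "swj_back", None))

    events.sort(key=lambda e: e[0])
    jumps: list[tuple[float, np.ndarray]] = []
    anchor = np.zeros(2)   # where the eye rests between square wave jerks
    away = False
    for onset, kind, payload in events:
        if kind == "intrusion":
            if not away:
                theta = rng.uniform(0, 2 * math.pi)
                r = rng.uniform(2.3, 4.5)
                anchor = np.array([r * math.cos(theta), r * math.sin(theta)])
            else:
                anchor = np.zeros(2)
            away = not away
            jumps.append((onset, anchor.copy()))
        elif kind == "swj_away":
            jumps.append((onset, anchor + payload))
        else:  # swj_back: return to the current anchor
            jumps.append((onset, anchor.copy()))
    return _render_saccades(t, np.zeros(2), jumps, truth)


def _simulate_prosaccade(profile: OculomotorProfile, design: TrialDesign,
                         t: np.ndarray, rng: np.random.Generator,
                         truth: list[SaccadeTruth]) -> np.ndarray:
    target = np.asarray(design.location, float)
    latency = max(80.0, rng.normal(profile.saccade_latency_mean,
                                   profile.saccade_latency_sd))
    onset = design.onset_ms + latency
    jumps: list[tuple[float, np.ndarray]] = []
    miss = rng.random() < profile.miss_probability

    gain = np.clip(rng.normal(profile.saccade_gain_mean, profile.saccade_gain_sd),
                   0.3, 1.2)
    if miss:
        # trial that never reaches the interest area: hypometric primary
        # saccade, then small wandering saccades that stay > 1.6 deg away
        landing = target * min(gain, 0.7)
        if np.hypot(*(landing - target)) < 2.0:
            landing = target * (1.0 - 2.2 / max(design.distance_deg, 2.2))
        jumps.append((onset, landing))
        cur_t = onset + saccade_duration_ms(float(np.hypot(*landing)))
        cur = landing
        while cur_t < design.duration_ms - 400.0:
            cur_t += rng.uniform(350.0, 700.0)
            theta = rng.uniform(0, 2 * math.pi)
            cand = cur + 0.8 * np.array([math.cos(theta), math.sin(theta)])
            if np.hypot(*(cand - target)) < 2.0:
                cand = cur - 0.8 * np.array([math.cos(theta), math.sin(theta)])
            jumps.append((cur_t, cand))
            cur = cand
    else:
        cur = np.zeros(2)
        cur_t = onset
        err = target - cur
        g = gain
        # primary then corrective saccades until well inside the interest area
        for _ in range(6):
            landing = cur + g * err + rng.normal(0.0, 0.08, size=2)
            jumps.append((cur_t, landing))
            cur_t += saccade_duration_ms(float(np.hypot(*(landing - cur))))
            cur = landing
            err = target - cur
            if np.hypot(*err) <= 0.75:
                break
            cur_t += max(80.0, rng.normal(profile.corrective_isi_ms, 30.0))
            g = np.clip(rng.normal(0.85, 0.1), 0.4, 1.1)
    return _render_saccades(t, np.zeros(2), jumps, truth)


def _simulate_pursuit(profile: OculomotorProfile, design: TrialDesign,
                      t: np.ndarray, tgt: np.ndarray,
                      rng: np.random.Generator,
                      truth: list[SaccadeTruth]) -> np.ndarray:
    """Alternate tracking and non-tracking segments with catch-up saccades."""
    dur = t[-1] + (t[1] - t[0])
    frac = profile.pursuit_tracking_fraction
    # two-state alternation with exponential segment durations
    mean_on = 1400.0
    bounds: list[tuple[float, float, bool]] = []
    if frac >= 1.0 - 1e-9:
        bounds = [(0.0, dur, True)]
    elif frac <= 1e-9:
        bounds = [(0.0, dur, False)]
    else:
        mean_off = mean_on * (1.0 - frac) / frac
        cur, on = 0.0, rng.random() < frac
        while cur < dur:
            seg = max(250.0, rng.exponential(mean_on if on else mean_off))
            bounds.append((cur, min(cur + seg, dur), on))
            cur += seg
            on = not on

    pos = np.zeros_like(tgt)
    cur_pos = tgt[0].copy()

    def render_catchup(onset: float) -> float | None:
        """Minimum-jerk catch-up from cur_pos to the (moving) target.

        Returns the landing time in ms, or None if no saccade was needed.
        """
        nonlocal cur_pos
        i0 = np.searchsorted(t, onset)
        if i0 >= len(t):
            return None
        amp0 = float(np.hypot(*(tgt[i0] - cur_pos)))
        if amp0 < 0.25:
            return None
        d = saccade_duration_ms(amp0)
        i1 = min(np.searchsorted(t, onset + d), len(t) - 1)
        dest = tgt[i1]
        seg = slice(i0, i1 + 1)
        tau = (t[seg] - t[i0]) / max(t[i1] - t[i0], 1e-9)
        pos[seg] = cur_pos + np.outer(_min_jerk(np.clip(tau, 0, 1)), dest - cur_pos)
        truth.append(SaccadeTruth(float(t[i0]), d, tuple(cur_pos), tuple(dest)))
        cur_pos = dest.copy()
        return float(t[i0]) + d

    for (t0, t1, on) in bounds:
        i0, i1 = np.searchsorted(t, t0), np.searchsorted(t, t1)
        if i0 >= i1:
            continue
        if not on:
            pos[i0:i1] = cur_pos
            continue
        # catch-up saccade to target at segment start, then track at gain
        land0 = render_catchup(t0)
        gain = max(0.2, rng.normal(profile.pursuit_gain_mean, profile.pursuit_gain_sd))
        # scheduled catch-ups inside the segment
        n_cu = rng.poisson(profile.catchup_saccade_rate_hz * (t1 - t0) / 1000.0)
        if t1 - t0 <= 300.0:
            n_cu = 0
        cu_times = np.sort(rng.uniform(t0 + 300.0, t1, size=n_cu)) if n_cu else []
        seg_start = i0
        if land0 is not None:
            while seg_start < i1 and t[seg_start] < land0:
                seg_start += 1
        for cu in list(cu_times) + [t1]:
            j0, j1 = seg_start, min(np.searchsorted(t, cu), i1)
            if j1 > j0:
                # track from wherever the last saccade landed
                ref = tgt[j0 - 1] if j0 > 0 else tgt[0]
                pos[j0:j1] = cur_pos + gain * (tgt[j0:j1] - ref)
                cur_pos = pos[j1 - 1].copy()
            if cu < t1:
                land = render_catchup(cu)
                seg_start = max(np.searchsorted(t, cu), j1)
                if land is not None:
                    # skip samples consumed by the rendered saccade
                    while seg_start < i1 and t[seg_start] < land:
                        seg_start += 1
            else:
                seg_start = j1
    return pos


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _jitter_profile(profile: OculomotorProfile, spec: CohortSpec,
                    rng: np.random.Generator) -> OculomotorProfile:
    """Per-subject parameter jitter: log-normal on rates, normal on
    gains/latencies, truncated to valid ranges."""
    def ln(x: float) -> float:
        return float(x * rng.lognormal(0.0, spec.rate_jitter_sigma)) if x > 0 else 0.0

    def nrm(x: float, sd: float, lo: float, hi: float) -> float:
        return float(np.clip(rng.normal(x, sd), lo, hi))

    return replace(
        profile,
        intrusive_saccade_rate=ln(profile.intrusive_saccade_rate),
        swj_rate=ln(profile.swj_rate),
        blink_rate=ln(profile.blink_rate),
        catchup_saccade_rate_hz=ln(profile.catchup_saccade_rate_hz),
        saccade_latency_mean=nrm(profile.saccade_latency_mean,
                                 spec.latency_jitter_sd, 80.0, 600.0),
        saccade_gain_mean=nrm(profile.saccade_gain_mean, spec.gain_jitter_sd,
                              0.3, 1.2),
        pursuit_gain_mean=nrm(profile.pursuit_gain_mean, spec.gain_jitter_sd,
                              0.2, 1.6),
        pursuit_tracking_fraction=nrm(profile.pursuit_tracking_fraction,
                                      spec.gain_jitter_sd, 0.02, 1.0),
        miss_probability=nrm(profile.miss_probability,
                             spec.gain_jitter_sd / 2.0, 0.0, 1.0),
    )


def simulate_cohort(spec: CohortSpec,
                    paradigms: Sequence[str] = PARADIGMS) -> list[SubjectRecord]:
    """Simulate a full cohort, reproducible from ``spec.master_seed``.

    Trial orders are shared across participants (fixed design seed); all
    behavioural randomness derives from per-subject child seeds of the
    master seed.
    """
    designs = {p: design_experiment(p, seed=spec.master_seed) for p in paradigms}
    root = np.random.SeedSequence(spec.master_seed)
    subjects: list[SubjectRecord] = []
    groups = [("control", spec.control_profile)] * spec.n_controls + \
             [("patient", spec.patient_profile)] * spec.n_patients
    children = root.spawn(len(groups))
    for idx, ((group, base_profile), child) in enumerate(zip(groups, children)):
        rng = np.random.default_rng(child)
        profile = _jitter_profile(base_profile, spec, rng)
        sid = f"{'C' if group == 'control' else 'P'}{idx:03d}"
        trials: dict[str, list[SampleSeries]] = {}
        for p in paradigms:
            trials[p] = [
                simulate_trial(profile, d, rng,
                               trial_id=f"{sid}_{p}_{d.trial_index:03d}")
                for d in designs[p]
            ]
        subjects.append(SubjectRecord(sid, group, profile, trials))
    return subjects
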