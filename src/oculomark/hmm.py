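"""Direction-state hidden Markov model of pursuit gaze movements.

Each per-step gaze displacement is modelled as a noisy realization of one of
five latent intended movement directions — no movement, left, right, up,
down.  Before entering the Gaussian sub-model of a state, the displacement
is rotated by the inverse of that state's canonical direction (a fixed,
parameter-free isometry), so all four movement states share one geometry.
Knowledge of where the gaze *should* move is injected through a
parameter-free angular weight ``f(U_t | X_t)`` that decays logarithmically
to zero as the target direction diverges from the intended direction.

Parameters theta = (mu_X, Sigma_X, pi_1, P): per-state 2-vector means and
2x2 covariances of the transformed displacement, the initial state
distribution, and the 5x5 transition matrix — 10 + 15 + 5 + 25 = 55 free
coordinates under the symmetric-covariance / softmax parameterization used
for Fisher scores.

The Fisher feature vector of a sequence is the gradient of its forward
(marginal) log-likelihood at the fitted parameters, computed from
forward–backward expected sufficient statistics; simplex-constrained
parameters are differentiated in softmax coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .synthetic import SampleSeries

logger = logging.getLogger(__name__)

STATE_LABELS = ("no_movement", "left", "right", "up", "down")
N_STATES = 5
#: canonical unit vectors; the zero vector for no_movement
CANONICAL = np.array([
    [0.0, 0.0],
    [-1.0, 0.0],
    [1.0, 0.0],
    [0.0, 1.0],
    [0.0, -1.0],
])
_CANONICAL_ANGLE = np.array([0.0, math.pi, 0.0, math.pi / 2.0, -math.pi / 2.0])

#: truncation of the angular weight near zero divergence
ALIGNMENT_EPS = 1e-2
#: constant weight for the no-movement state and for an on-target gaze (U=0);
#: the value of the angular kernel at 90 degrees divergence
ALIGNMENT_CONST = math.log(2.0)

N_PARAMS = 55  # 10 means + 15 covariance elements + 5 pi + 25 P


def transform_movement(y: np.ndarray, state: int) -> np.ndarray:
    """Rotate displacement(s) by the inverse of the state's canonical angle.

    Maps motion along the intended direction onto +x; identity for
    no_movement.  Fixed, invertible, and norm-preserving.
    """
    if state == 0:
        return np.asarray(y, float)
    th = _CANONICAL_ANGLE[state]
    c, s = math.cos(th), math.sin(th)
    rot = np.array([[c, s], [-s, c]])  # rotation by -theta
    return np.asarray(y, float) @ rot.T


def target_alignment_weight(u: np.ndarray, state: int) -> float:
    """Parameter-free weight f(U | X): log(pi / phi) with phi the angle
    between the target direction and the state's canonical direction.

    Monotonically decreasing in phi, zero at phi = pi; truncated at
    ``ALIGNMENT_EPS`` near perfect alignment.  Constant for the no-movement
    state and whenever U is the zero vector (gaze on target).
    """
    u = np.asarray(u, float)
    if state == 0 or np.allclose(u, 0.0):
        return ALIGNMENT_CONST
    phi = math.atan2(*np.flip(u))  # angle of u
    dphi = abs(phi - _CANONICAL_ANGLE[state]) % (2.0 * math.pi)
    dphi = min(dphi, 2.0 * math.pi - dphi)
    return math.log(math.pi / max(dphi, ALIGNMENT_EPS))


@dataclass
class MovementSequence:
    """Per-step gaze displacements with target-direction unit vectors.

    ``Y[t]`` is the gaze displacement between successive samples (deg);
    ``U[t]`` the unit vector from the gaze location toward the target at the
    start of the step (zero inside the dead zone); ``valid[t]`` masks steps
    straddling blinks or signal loss.
    """

    Y: np.ndarray
    U: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.Y) == len(self.U) == len(self.valid)):
            raise ValueError("Y, U, valid must share length")
        norms = np.linalg.norm(self.U, axis=1)
        if not np.all((norms < 1e-9) | (np.abs(norms - 1.0) < 1e-6)):
            raise ValueError("U rows must be zero or unit vectors")

    @property
    def n_steps(self) -> int:
        return len(self.Y)

    def segments(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Contiguous valid (Y, U) runs, each treated as an independent chain."""
        out = []
        v = self.valid.astype(bool)
        if not v.any():
            return out
        idx = np.flatnonzero(np.diff(np.concatenate([[0], v.view(np.int8), [0]])))
        for i0, i1 in zip(idx[::2], idx[1::2]):
            out.append((self.Y[i0:i1], self.U[i0:i1]))
        return out


def build_movement_sequence(series: SampleSeries,
                            dead_zone_deg: float = 0.5) -> MovementSequence:
    """Displacement/target-direction sequence from a pursuit trial.

    ``Y_t = gaze(t) - gaze(t-1)`` over consecutive sample pairs;
    ``U_t = unit(target(t-1) - gaze(t-1))``, the zero vector when the gaze is
    already within ``dead_zone_deg`` of the target.
    """
    if series.valid.sum() < 2:
        raise ValueError("need at least 2 valid samples")
    g = series.gaze
    tgt = series.target
    Y = np.diff(g, axis=0)
    to_target = tgt[:-1] - g[:-1]
    dist = np.linalg.norm(to_target, axis=1)
    U = np.zeros_like(to_target)
    far = dist > dead_zone_deg
    U[far] = to_target[far] / dist[far, None]
    valid = series.valid[1:] & series.valid[:-1]
    return MovementSequence(Y, U, valid.astype(bool))


def aggregate_steps(seq: MovementSequence, factor: int = 5) -> MovementSequence:
    """Down-sample by summing ``factor`` consecutive displacements.

    Raw 4 ms displacements are noise-dominated; aggregating to 20 ms steps
    (default) gives the direction states meaningful support.  A block is
    valid only if all constituent steps are; ``U`` is taken from the block's
    first step.
    """
    if factor <= 1:
        return seq
    n = seq.n_steps // factor
    if n == 0:
        return MovementSequence(np.empty((0, 2)), np.empty((0, 2)),
                                np.empty(0, dtype=bool))
    Y = seq.Y[: n * factor].reshape(n, factor, 2).sum(axis=1)
    U = seq.U[: n * factor : factor]
    valid = seq.valid[: n * factor].reshape(n, factor).all(axis=1)
    return MovementSequence(Y, U, valid)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

@dataclass
class DirectionHMM:
    """theta = (mu, Sigma, pi, P) of the five-state model."""

    mu: np.ndarray      # (5, 2) transformed-frame emission means
    sigma: np.ndarray   # (5, 2, 2) symmetric positive definite
    pi: np.ndarray      # (5,) initial distribution
    P: np.ndarray       # (5, 5) row-stochastic transitions

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, float)
        self.sigma = np.asarray(self.sigma, float)
        self.pi = np.asarray(self.pi, float)
        self.P = np.asarray(self.P, float)
        if self.mu.shape != (N_STATES, 2) or self.sigma.shape != (N_STATES, 2, 2):
            raise ValueError("bad mu/sigma shape")
        if not np.allclose(self.pi.sum(), 1.0) or not np.allclose(self.P.sum(axis=1), 1.0):
            raise ValueError("pi and P rows must sum to 1")
        for s in range(N_STATES):
            if not np.allclose(self.sigma[s], self.sigma[s].T):
                raise ValueError("covariances must be symmetric")
            if np.linalg.eigvalsh(self.sigma[s]).min() <= 0:
                raise ValueError("covariances must be positive definite")

    @property
    def n_params(self) -> int:
        return N_PARAMS

    def copy(self) -> "DirectionHMM":
        return DirectionHMM(self.mu.copy(), self.sigma.copy(),
                            self.pi.copy(), self.P.copy())


def _alignment_weights(U: np.ndarray, state: int) -> np.ndarray:
    """Vectorized f(U | X) over the steps of one segment."""
    T = len(U)
    w = np.full(T, ALIGNMENT_CONST)
    if state == 0:
        return w
    moving = np.linalg.norm(U, axis=1) > 1e-9
    if moving.any():
        phi = np.arctan2(U[moving, 1], U[moving, 0])
        dphi = np.abs(phi - _CANONICAL_ANGLE[state]) % (2.0 * math.pi)
        dphi = np.minimum(dphi, 2.0 * math.pi - dphi)
        w[moving] = np.log(math.pi / np.maximum(dphi, ALIGNMENT_EPS))
    return w


def _log_emission_matrix(Y: np.ndarray, U: np.ndarray,
                         model: DirectionHMM) -> np.ndarray:
    """(T, 5) log emission densities: log Gaussian of the transformed
    displacement plus the log target-alignment weight (-inf where f = 0)."""
    T = len(Y)
    logE = np.empty((T, N_STATES))
    with np.errstate(divide="ignore"):
        for s in range(N_STATES):
            ty = transform_movement(Y, s)
            d = ty - model.mu[s]
            cov = model.sigma[s]
            det = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
            if det <= 0:
                raise ValueError("covariance not positive definite")
            inv = np.array([[cov[1, 1], -cov[0, 1]],
                            [-cov[1, 0], cov[0, 0]]]) / det
            mah = np.einsum("ti,ij,tj->t", d, inv, d)
            logE[:, s] = (-0.5 * mah - math.log(2.0 * math.pi)
                          - 0.5 * math.log(det)
                          + np.log(_alignment_weights(U, s)))
    return logE


def _shifted_emissions(logE: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-step max-shifted emissions: E_shift[t] = exp(logE[t] - m[t]).

    Keeps the scaled recursions inside double precision even when a step is
    dozens of standard deviations from every state; the shifts ``m`` are
    added back to the log-likelihood.
    """
    m = logE.max(axis=1)
    if not np.all(np.isfinite(m)):
        raise FloatingPointError("step with no admissible state")
    return np.exp(logE - m[:, None]), m


def _emission_matrix(Y: np.ndarray, U: np.ndarray, model: DirectionHMM) -> np.ndarray:
    """(T, 5) per-step emission densities (linear scale, may underflow;
    used by small-T oracles)."""
    return np.exp(_log_emission_matrix(Y, U, model))


def _forward_segment(logE: np.ndarray, model: DirectionHMM) -> float:
    """Scaled forward recursion on max-shifted emissions; returns the
    segment log-likelihood."""
    E, shift = _shifted_emissions(logE)
    T = len(E)
    ll = float(shift.sum())
    alpha = model.pi * E[0]
    c = alpha.sum()
    if c <= 0:
        return -np.inf
    alpha /= c
    ll += math.log(c)
    for t in range(1, T):
        alpha = (alpha @ model.P) * E[t]
        c = alpha.sum()
        if c <= 0:
            return -np.inf
        alpha /= c
        ll += math.log(c)
    return ll


def forward_log_likelihood(seq: MovementSequence, model: DirectionHMM) -> float:
    """log Pr(Y, U | theta), marginalizing the latent directions.

    Invalid steps split the trial into independent chains, each restarted
    from pi; their log-likelihoods add.
    """
    total = 0.0
    for Y, U in seq.segments():
        total += _forward_segment(_log_emission_matrix(Y, U, model), model)
    return total


@dataclass
class _Posteriors:
    """Forward–backward expected sufficient statistics over all segments."""

    gamma: list[np.ndarray]        # per-segment (T, 5) state posteriors
    gamma_first: np.ndarray        # (5,) summed first-step posteriors
    xi_sum: np.ndarray             # (5, 5) summed transition posteriors
    log_likelihood: float
    n_segments: int


def _forward_backward(seq: MovementSequence, model: DirectionHMM) -> _Posteriors:
    gammas: list[np.ndarray] = []
    gamma_first = np.zeros(N_STATES)
    xi_sum = np.zeros((N_STATES, N_STATES))
    ll = 0.0
    n_seg = 0
    for Y, U in seq.segments():
        E, shift = _shifted_emissions(_log_emission_matrix(Y, U, model))
        T = len(E)
        alpha = np.empty((T, N_STATES))
        c = np.empty(T)
        alpha[0] = model.pi * E[0]
        c[0] = alpha[0].sum()
        alpha[0] /= c[0]
        for t in range(1, T):
            alpha[t] = (alpha[t - 1] @ model.P) * E[t]
            c[t] = alpha[t].sum()
            alpha[t] /= c[t]
        beta = np.empty((T, N_STATES))
        beta[-1] = 1.0
        for t in range(T - 2, -1, -1):
            beta[t] = (model.P @ (E[t + 1] * beta[t + 1])) / c[t + 1]
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        if T > 1:
            right = E[1:] * beta[1:] / c[1:, None]
            xi_sum += np.einsum("ti,tj->ij", alpha[:-1], right) * model.P
        gammas.append(gamma)
        gamma_first += gamma[0]
        ll += float(np.log(c).sum() + shift.sum())
        n_seg += 1
    return _Posteriors(gammas, gamma_first, xi_sum, ll, n_seg)


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EMConfig:
    max_iter: int = 100
    tol: float = 1e-5              # absolute log-likelihood gain
    covariance_floor: float = 1e-8  # eigenvalue floor on Sigma
    min_steps: int = 20
    n_restarts: int = 3
    downsample_factor: int = 5     # 4 ms steps aggregated to 20 ms


def default_init(seq: MovementSequence, scale: float | None = None,
                 rng: np.random.Generator | None = None) -> DirectionHMM:
    """Emission means seeded from the canonical directions scaled by the
    median step length; mild self-persistent transitions."""
    Y = np.concatenate([y for y, _ in seq.segments()]) if seq.valid.any() else seq.Y
    if scale is None:
        lengths = np.linalg.norm(Y, axis=1)
        scale = float(np.median(lengths[lengths > 0])) if (lengths > 0).any() else 0.1
    # means live in each state's rotated frame: intended motion maps to +x,
    # so every moving state starts at (scale, 0); rest state at the origin
    mu = np.zeros((N_STATES, 2))
    mu[1:, 0] = scale
    sigma = np.tile(np.eye(2) * max(scale, 0.02) ** 2, (N_STATES, 1, 1))
    pi = np.full(N_STATES, 1.0 / N_STATES)
    P = np.full((N_STATES, N_STATES), 0.05)
    np.fill_diagonal(P, 0.8)
    if rng is not None:
        mu = mu + rng.normal(0.0, 0.2 * scale, size=mu.shape)
    return DirectionHMM(mu, sigma, pi, P)


def _floor_covariance(cov: np.ndarray, floor: float) -> np.ndarray:
    cov = (cov + cov.T) / 2.0
    w, v = np.linalg.eigh(cov)
    w = np.maximum(w, floor)
    return (v * w) @ v.T


def em_step(seq: MovementSequence, model: DirectionHMM,
            config: EMConfig) -> tuple[DirectionHMM, float]:
    """One EM iteration; returns the updated model and the log-likelihood of
    the *input* model (the E-step by-product)."""
    post = _forward_backward(seq, model)
    gamma_all = np.concatenate(post.gamma) if post.gamma else np.zeros((0, N_STATES))
    Y_all = np.concatenate([y for y, _ in seq.segments()])

    mu = model.mu.copy()
    sigma = model.sigma.copy()
    for s in range(N_STATES):
        w = gamma_all[:, s]
        tot = w.sum()
        ty = transform_movement(Y_all, s)
        if tot < 1e-8:
            logger.warning("state %s starved; covariance floored", STATE_LABELS[s])
            sigma[s] = _floor_covariance(sigma[s], config.covariance_floor)
            continue
        mu[s] = (w[:, None] * ty).sum(axis=0) / tot
        d = ty - mu[s]
        cov = (w[:, None, None] * (d[:, :, None] * d[:, None, :])).sum(axis=0) / tot
        sigma[s] = _floor_covariance(cov, config.covariance_floor)

    pi = post.gamma_first / post.n_segments
    pi = np.clip(pi, 1e-12, None)
    pi /= pi.sum()
    rowsum = post.xi_sum.sum(axis=1, keepdims=True)
    P = np.where(rowsum > 1e-12, post.xi_sum / np.clip(rowsum, 1e-12, None),
                 model.P)
    P = np.clip(P, 1e-12, None)
    P /= P.sum(axis=1, keepdims=True)
    return DirectionHMM(mu, sigma, pi, P), post.log_likelihood


def em_fit(seq: MovementSequence, init: DirectionHMM | None = None,
           config: EMConfig = EMConfig(), seed: int = 0,
           return_history: bool = False):
    """Fit the model by EM with restarts; log-likelihood is non-decreasing
    at every iteration (up to the covariance floor)."""
    n_valid = int(seq.valid.sum())
    if n_valid < config.min_steps:
        raise ValueError(f"sequence too short ({n_valid} valid steps)")
    rng = np.random.default_rng(seed)
    inits = [init or default_init(seq)]
    if init is None:
        inits += [default_init(seq, rng=rng) for _ in range(config.n_restarts - 1)]

    best_model, best_ll, best_hist = None, -np.inf, []
    for start in inits:
        model = start.copy()
        history: list[float] = []
        prev_ll = -np.inf
        for _ in range(config.max_iter):
            model_new, ll = em_step(seq, model, config)
            history.append(ll)
            if ll - prev_ll < config.tol and np.isfinite(prev_ll):
                break  # keep `model`, whose log-likelihood is `ll`
            prev_ll = ll
            model = model_new
        final_ll = history[-1]
        if final_ll > best_ll:
            best_model, best_ll, best_hist = model, final_ll, history
    if return_history:
        return best_model, best_hist
    return best_model


# ---------------------------------------------------------------------------
# Fisher feature vectors
# ---------------------------------------------------------------------------

def fisher_vector(seq: MovementSequence, model: DirectionHMM) -> np.ndarray:
    """Gradient of the forward log-likelihood at the fitted parameters.

    Computed via the Fisher identity from forward–backward expected
    sufficient statistics.  Layout (55 coordinates): per-state mean (10),
    per-state unique covariance elements s11, s12, s22 (15), initial
    distribution in softmax coordinates (5), transition rows in row-wise
    softmax coordinates (25).  The alignment weights f are parameter-free
    and contribute nothing.  A fully masked sequence yields the zero vector.
    """
    if not seq.valid.any():
        logger.warning("fully masked sequence: zero Fisher vector")
        return np.zeros(N_PARAMS)
    post = _forward_backward(seq, model)
    gamma_all = np.concatenate(post.gamma)
    Y_all = np.concatenate([y for y, _ in seq.segments()])

    g_mu = np.zeros((N_STATES, 2))
    g_sig = np.zeros((N_STATES, 3))
    for s in range(N_STATES):
        w = gamma_all[:, s]
        ty = transform_movement(Y_all, s)
        d = ty - model.mu[s]
        cov = model.sigma[s]
        inv = np.linalg.inv(cov)
        g_mu[s] = inv @ (w[:, None] * d).sum(axis=0)
        S = (w[:, None, None] * (d[:, :, None] * d[:, None, :])).sum(axis=0)
        M = 0.5 * (inv @ S @ inv - w.sum() * inv)
        g_sig[s] = [M[0, 0], 2.0 * M[0, 1], M[1, 1]]

    g_pi = post.gamma_first - post.n_segments * model.pi
    rowsum = post.xi_sum.sum(axis=1, keepdims=True)
    g_P = post.xi_sum - rowsum * model.P
    return np.concatenate([g_mu.ravel(), g_sig.ravel(), g_pi, g_P.ravel()])


def perturb_parameters(model: DirectionHMM, index: int,
                       delta: float) -> DirectionHMM:
    """Shift one of the 55 coordinates by ``delta`` in the chart used by
    :func:`fisher_vector` (finite-difference support)."""
    m = model.copy()
    if index < 10:
        s, k = divmod(index, 2)
        m.mu[s, k] += delta
    elif index < 25:
        s, k = divmod(index - 10, 3)
        if k == 0:
            m.sigma[s, 0, 0] += delta
        elif k == 1:
            m.sigma[s, 0, 1] += delta
            m.sigma[s, 1, 0] += delta
        else:
            m.sigma[s, 1, 1] += delta
    elif index < 30:
        a = np.log(m.pi)
        a[index - 25] += delta
        e = np.exp(a - a.max())
        m.pi = e / e.sum()
    else:
        i, j = divmod(index - 30, N_STATES)
        b = np.log(m.P[i])
        b[j] += delta
        e = np.exp(b - b.max())
        m.P[i] = e / e.sum()
    return DirectionHMM(m.mu, m.sigma, m.pi, m.P)


def expected_state_occupancy(seq: MovementSequence,
                             model: DirectionHMM) -> np.ndarray:
    """Mean posterior occupancy of each direction state over the sequence."""
    post = _forward_backward(seq, model)
    gamma_all = np.concatenate(post.gamma)
    return gamma_all.mean(axis=0)
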