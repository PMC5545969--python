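"""Direction-state HMM: forward algorithm, EM, and Fisher scores."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from conftest import make_series
from oculomark import hmm as H

rng_global = np.random.default_rng(12345)


def random_model(rng) -> H.DirectionHMM:
    mu = rng.normal(0, 0.3, (5, 2))
    sigma = np.empty((5, 2, 2))
    for s in range(5):
        a = rng.normal(0, 0.3, (2, 2))
        sigma[s] = a @ a.T + 0.1 * np.eye(2)
    return H.DirectionHMM(mu, sigma, rng.dirichlet(np.ones(5)),
                          rng.dirichlet(np.ones(5), size=5))


def random_sequence(rng, T, p_dead=0.3, p_invalid=0.0) -> H.MovementSequence:
    Y = rng.normal(0, 0.3, (T, 2))
    U = rng.normal(0, 1, (T, 2))
    U /= np.linalg.norm(U, axis=1)[:, None]
    U[rng.random(T) < p_dead] = 0.0
    valid = rng.random(T) >= p_invalid
    return H.MovementSequence(Y, U, valid)


def sample_from(model: H.DirectionHMM, T, rng):
    """Draw (states, world-frame displacements) from the generative model
    (ignoring the alignment factor, i.e. with U == 0 throughout)."""
    states = [np.searchsorted(np.cumsum(model.pi), rng.random())]
    for _ in range(1, T):
        states.append(np.searchsorted(np.cumsum(model.P[states[-1]]),
                                      rng.random()))
    Y = np.empty((T, 2))
    for t, x in enumerate(states):
        y = rng.multivariate_normal(model.mu[x], model.sigma[x])
        th = H._CANONICAL_ANGLE[x]
        c, s = math.cos(th), math.sin(th)
        Y[t] = np.array([[c, -s], [s, c]]) @ y if x else y
    return states, Y


def brute_force_loglik(seq: H.MovementSequence, model: H.DirectionHMM) -> float:
    """Exhaustive sum over all state paths (per valid segment)."""
    total = 0.0
    for Y, U in seq.segments():
        E = H._emission_matrix(Y, U, model)
        T = len(Y)
        acc = 0.0
        for path in itertools.product(range(5), repeat=T):
            p = model.pi[path[0]] * E[0, path[0]]
            for t in range(1, T):
                p *= model.P[path[t - 1], path[t]] * E[t, path[t]]
            acc += p
        total += math.log(acc)
    return total


# ---------------------------------------------------------------------------
# geometry and alignment
# ---------------------------------------------------------------------------

def test_transform_examples_and_isometry():
    assert np.allclose(H.transform_movement(np.array([0.0, -1.0]), 4), [1.0, 0.0])
    y = rng_global.normal(size=(1000, 2))
    assert np.allclose(H.transform_movement(y, 0), y)
    for s in range(1, 5):
        ty = H.transform_movement(y, s)
        np.testing.assert_allclose(np.linalg.norm(ty, axis=1),
                                   np.linalg.norm(y, axis=1), rtol=1e-12)


def test_alignment_weight_shape():
    right = np.array([1.0, 0.0])
    # diverging target direction drives the weight to zero
    assert H.target_alignment_weight(-right, 2) == pytest.approx(0.0, abs=1e-12)
    # strictly decreasing in the angular divergence
    phis = np.linspace(0.05, math.pi, 50)
    w = [H.target_alignment_weight(np.array([math.cos(p), math.sin(p)]), 2)
         for p in phis]
    assert all(a > b for a, b in zip(w, w[1:]))
    # constant for the rest state and for an on-target gaze
    assert H.target_alignment_weight(right, 0) == H.ALIGNMENT_CONST
    assert H.target_alignment_weight(np.zeros(2), 3) == H.ALIGNMENT_CONST


def test_build_movement_sequence():
    n = 2500
    gaze = np.cumsum(rng_global.normal(0, 0.05, (n, 2)), axis=0)
    series = make_series(gaze, paradigm="pursuit")
    seq = H.build_movement_sequence(series)
    assert seq.n_steps == n - 1
    np.testing.assert_allclose(seq.Y, np.diff(gaze, axis=0))

    static = make_series(np.zeros((100, 2)),
                         target=np.tile([5.0, 0.0], (100, 1)))
    seq = H.build_movement_sequence(static)
    assert np.all(seq.Y == 0.0)
    np.testing.assert_allclose(seq.U, np.tile([1.0, 0.0], (99, 1)))

    # gaze within the dead zone: U is the zero vector
    near = make_series(np.zeros((50, 2)), target=np.tile([0.2, 0.1], (50, 1)))
    assert np.all(H.build_movement_sequence(near).U == 0.0)

    with pytest.raises(ValueError, match="valid samples"):
        H.build_movement_sequence(
            make_series(np.zeros((10, 2)), valid=np.zeros(10, dtype=bool)))


def test_aggregate_steps():
    seq = random_sequence(rng_global, 23)
    agg = H.aggregate_steps(seq, factor=5)
    assert agg.n_steps == 4
    np.testing.assert_allclose(agg.Y[0], seq.Y[:5].sum(axis=0))


# ---------------------------------------------------------------------------
# forward algorithm
# ---------------------------------------------------------------------------

def test_forward_matches_exhaustive_enumeration():
    rng = np.random.default_rng(0)
    for T in (1, 2, 3, 4, 6):
        for _ in range(4):
            model = random_model(rng)
            seq = random_sequence(rng, T)
            assert H.forward_log_likelihood(seq, model) == pytest.approx(
                brute_force_loglik(seq, model), abs=1e-10)


def test_forward_segments_add():
    rng = np.random.default_rng(1)
    model = random_model(rng)
    a = random_sequence(rng, 20, p_invalid=0.0)
    b = random_sequence(rng, 25, p_invalid=0.0)
    joined = H.MovementSequence(
        np.vstack([a.Y, np.zeros((1, 2)), b.Y]),
        np.vstack([a.U, np.zeros((1, 2)), b.U]),
        np.concatenate([a.valid, [False], b.valid]))
    assert H.forward_log_likelihood(joined, model) == pytest.approx(
        H.forward_log_likelihood(a, model) + H.forward_log_likelihood(b, model),
        abs=1e-9)


def test_forward_invariant_under_state_relabeling():
    """Permuting the moving states together with (mu, Sigma, pi, P) — and
    the transforms, via the data — leaves the likelihood unchanged only when
    the permutation respects the canonical geometry; the plain relabeling
    check uses a U-free, direction-free model where states are exchangeable."""
    rng = np.random.default_rng(2)
    mu = np.tile(rng.normal(0, 0.2, 2), (5, 1))
    sigma = np.tile(0.05 * np.eye(2), (5, 1, 1))
    pi = rng.dirichlet(np.ones(5))
    P = rng.dirichlet(np.ones(5), size=5)
    T = 12
    Y = np.zeros((T, 2))  # zero displacements: identical under every transform
    seq = H.MovementSequence(Y, np.zeros((T, 2)), np.ones(T, dtype=bool))
    base = H.forward_log_likelihood(seq, H.DirectionHMM(mu, sigma, pi, P))
    perm = np.array([0, 2, 1, 4, 3])
    permuted = H.DirectionHMM(mu[perm], sigma[perm], pi[perm],
                              P[np.ix_(perm, perm)])
    assert H.forward_log_likelihood(seq, permuted) == pytest.approx(base,
                                                                    abs=1e-10)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def test_em_monotone_over_seeds():
    """Log-likelihood never decreases across iterations, many random starts."""
    rng = np.random.default_rng(3)
    seq = random_sequence(rng, 80)
    for seed in range(50):
        init = random_model(np.random.default_rng(seed + 1000))
        _, hist = H.em_fit(seq, init=init,
                           config=H.EMConfig(max_iter=12, n_restarts=1),
                           return_history=True)
        assert np.all(np.diff(hist) >= -1e-7)


def test_em_stopping_rule():
    rng = np.random.default_rng(4)
    seq = random_sequence(rng, 120)
    cfg = H.EMConfig(max_iter=500, tol=1e-3, n_restarts=1)
    _, hist = H.em_fit(seq, config=cfg, return_history=True)
    assert len(hist) < cfg.max_iter  # stopped by the tolerance, not the cap
    assert hist[-1] - hist[-2] < cfg.tol


def test_em_parameter_recovery():
    rng = np.random.default_rng(7)
    mu = np.zeros((5, 2))
    mu[1:] = [0.4, 0.0]
    true = H.DirectionHMM(mu, np.tile(0.008 * np.eye(2), (5, 1, 1)),
                          np.full(5, 0.2),
                          np.full((5, 5), 0.05) + np.eye(5) * 0.75)
    _, Y = sample_from(true, 5000, rng)
    seq = H.MovementSequence(Y, np.zeros((5000, 2)), np.ones(5000, dtype=bool))
    fit = H.em_fit(seq, config=H.EMConfig(max_iter=80), seed=1)
    assert np.abs(fit.mu - true.mu).max() < 0.05
    tv = 0.5 * np.abs(fit.P - true.P).sum(axis=1).max()
    assert tv < 0.05


def test_em_single_state_restriction_degenerates_to_moments():
    """Forcing all mass onto one state makes EM return that state's sample
    moments of the transformed steps."""
    rng = np.random.default_rng(8)
    Y = rng.normal(0.2, 0.1, (400, 2))
    seq = H.MovementSequence(Y, np.zeros((400, 2)), np.ones(400, dtype=bool))
    s = 2  # "right"
    pi = np.full(5, 1e-12)
    pi[s] = 1.0 - 4e-12
    P = np.full((5, 5), 1e-12)
    P[:, s] = 1.0 - 4e-12
    init = H.DirectionHMM(np.zeros((5, 2)), np.tile(np.eye(2), (5, 1, 1)),
                          pi / pi.sum(), P / P.sum(axis=1, keepdims=True))
    fit, _ = H.em_step(seq, init, H.EMConfig())
    ty = H.transform_movement(Y, s)
    np.testing.assert_allclose(fit.mu[s], ty.mean(axis=0), atol=1e-6)
    np.testing.assert_allclose(fit.sigma[s], np.cov(ty.T, bias=True), atol=1e-6)


def test_em_rejects_short_sequence():
    seq = random_sequence(np.random.default_rng(0), 5)
    with pytest.raises(ValueError, match="too short"):
        H.em_fit(seq, config=H.EMConfig(min_steps=20))


# ---------------------------------------------------------------------------
# Fisher scores
# ---------------------------------------------------------------------------

def test_fisher_matches_finite_differences():
    """Analytic scores vs central differences on 20 random instances."""
    rng = np.random.default_rng(9)
    eps = 1e-6
    for _ in range(20):
        model = random_model(rng)
        seq = random_sequence(rng, 25, p_invalid=0.1)
        if not seq.valid.any():
            continue
        g = H.fisher_vector(seq, model)
        assert len(g) == 55
        fd = np.empty(55)
        for i in range(55):
            lp = H.forward_log_likelihood(seq, H.perturb_parameters(model, i, eps))
            lm = H.forward_log_likelihood(seq, H.perturb_parameters(model, i, -eps))
            fd[i] = (lp - lm) / (2 * eps)
        rel = np.abs(g - fd) / np.maximum(np.abs(fd), 1e-3)
        assert rel.max() < 1e-4


def test_fisher_near_zero_at_em_optimum():
    rng = np.random.default_rng(10)
    seq = random_sequence(rng, 300, p_dead=1.0)
    fit = H.em_fit(seq, config=H.EMConfig(max_iter=300, tol=1e-10,
                                          n_restarts=1))
    g = H.fisher_vector(seq, fit)
    g0 = H.fisher_vector(seq, H.perturb_parameters(fit, 0, 0.3))
    assert np.linalg.norm(g) < 1e-2 * np.linalg.norm(g0)


def test_fisher_masked_sequence_is_zero():
    seq = H.MovementSequence(np.zeros((10, 2)), np.zeros((10, 2)),
                             np.zeros(10, dtype=bool))
    model = random_model(np.random.default_rng(0))
    assert np.all(H.fisher_vector(seq, model) == 0.0)


def test_fitted_reference_occupies_target_aligned_state():
    """On a clean rightward-tracking segment the fitted model puts its
    occupancy on states consistent with the motion."""
    T = 400
    Y = np.tile([0.08, 0.0], (T, 1)) + \
        np.random.default_rng(1).normal(0, 0.01, (T, 2))
    U = np.tile([1.0, 0.0], (T, 1))  # target always to the right
    seq = H.MovementSequence(Y, U, np.ones(T, dtype=bool))
    fit = H.em_fit(seq, config=H.EMConfig(max_iter=60), seed=0)
    occ = H.expected_state_occupancy(seq, fit)
    # the "right" state dominates "left", "up", "down"
    assert occ[2] > max(occ[1], occ[3], occ[4])
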