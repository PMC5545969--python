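"""Fisher-feature classification of patients vs. controls.

Per-subject feature vectors are sums of per-trial Fisher scores from twelve
reference HMMs (one per pursuit trial, each fitted by EM to the single
best-tracking control), normalized element-wise by the standard deviation
over individuals.  Classification uses Bayesian logistic regression with an
automatic-relevance-determination (ARD) sparsity prior: an independent
zero-mean Gaussian prior on each weight whose precision alpha_i is learned
by evidence-approximation fixed-point updates.  Predictive accuracy is
assessed by leave-one-out, leave-two-out, and leave-half-out
cross-validation, refitting the normalization and classifier on each
training fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .detection import DetectionConfig, detect_events
from .hmm import (DirectionHMM, EMConfig, MovementSequence, aggregate_steps,
                  build_movement_sequence, em_fit, fisher_vector)
from .metrics import MetricConfig, proportion_time_pursuing
from .synthetic import SubjectRecord

logger = logging.getLogger(__name__)

PROTOCOLS = ("l1o", "l2o", "lho")


# ---------------------------------------------------------------------------
# reference models and features
# ---------------------------------------------------------------------------

def pursuit_sequences(record: SubjectRecord,
                      em_config: EMConfig = EMConfig()) -> list[MovementSequence]:
    """Down-sampled movement sequences for each of a subject's pursuit trials."""
    return [aggregate_steps(build_movement_sequence(s), em_config.downsample_factor)
            for s in record.trials["pursuit"]]


def mean_tracking_score(record: SubjectRecord,
                        detection_config: DetectionConfig = DetectionConfig(),
                        metric_config: MetricConfig = MetricConfig()) -> float:
    """Mean proportion-of-time-pursuing over a subject's pursuit trials."""
    vals = []
    for series in record.trials["pursuit"]:
        ev = detect_events(series, detection_config)
        v = proportion_time_pursuing(series, ev, series.design, metric_config,
                                     detection_config)
        if np.isfinite(v):
            vals.append(v)
    return float(np.mean(vals)) if vals else float("-inf")


def select_reference_and_fit(subjects: Sequence[SubjectRecord],
                             em_config: EMConfig = EMConfig(),
                             seed: int = 0
                             ) -> tuple[str, list[DirectionHMM]]:
    """Fit one reference model per pursuit trial index.

    The reference control is the control with the highest mean
    proportion-of-time-pursuing (an objective stand-in for the hand-picked
    best tracker); ties break to the lowest subject id.  Returns the chosen
    subject id and the twelve fitted models in trial order.
    """
    controls = [s for s in subjects if s.group == "control"
                and s.trials.get("pursuit")]
    if not controls:
        raise ValueError("no control with pursuit trials")
    scored = sorted((-mean_tracking_score(c), c.subject_id, c) for c in controls)
    ref = scored[0][2]
    logger.info("reference control: %s", ref.subject_id)
    models = []
    for j, seq in enumerate(pursuit_sequences(ref, em_config)):
        models.append(em_fit(seq, config=em_config, seed=seed + j))
    return ref.subject_id, models


def subject_feature_matrix(subjects: Sequence[SubjectRecord],
                           models: Sequence[DirectionHMM],
                           em_config: EMConfig = EMConfig()) -> pd.DataFrame:
    """Un-normalized summed Fisher vectors, one row per subject.

    Trial j of every subject is scored against reference model j; available
    trials are summed (a subject with one trial keeps that trial's score).
    """
    rows = {}
    for rec in subjects:
        z = np.zeros(models[0].n_params)
        for j, seq in enumerate(pursuit_sequences(rec, em_config)):
            if j >= len(models):
                break
            z += fisher_vector(seq, models[j])
        rows[rec.subject_id] = z
    return pd.DataFrame.from_dict(rows, orient="index")


def normalize_features(train: np.ndarray, *apply_to: np.ndarray,
                       ddof: int = 1) -> tuple[list[np.ndarray], np.ndarray]:
    """Element-wise division by the SD over the (training) individuals.

    Constant features (zero SD) are dropped; returns the transformed
    matrices and the boolean mask of kept columns.
    """
    sd = np.std(train, axis=0, ddof=ddof)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all features are constant")
    out = [m[:, keep] / sd[keep] for m in (train, *apply_to)]
    return out, keep


# ---------------------------------------------------------------------------
# sparse Bayesian logistic regression (ARD)
# ---------------------------------------------------------------------------

@dataclass
class SparseBLR:
    """ARD logistic regression state: MAP weights, per-weight precisions,
    and the Laplace posterior covariance (weights include the intercept as
    the last coordinate)."""

    weights: np.ndarray
    alpha: np.ndarray
    posterior_cov: np.ndarray
    converged: bool
    n_iter: int

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        Xa = np.column_stack([X, np.ones(len(X))])
        return Xa @ self.weights

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(self.decision_values(X))

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)


def _map_weights(X: np.ndarray, y: np.ndarray, alpha: np.ndarray,
                 w0: np.ndarray) -> np.ndarray:
    """Penalized-logistic MAP weights for fixed prior precisions."""

    def objective(w):
        z = X @ w
        # log(1 + exp(-s*z)) computed stably
        s = 2.0 * y - 1.0
        nll = np.logaddexp(0.0, -s * z).sum()
        return nll + 0.5 * (alpha * w * w).sum()

    def grad(w):
        p = expit(X @ w)
        return X.T @ (p - y) + alpha * w

    res = minimize(objective, w0, jac=grad, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    return res.x


def fit_sparse_blr(features: np.ndarray, labels: Sequence[int],
                   max_outer: int = 50, alpha_init: float = 1.0,
                   alpha_max: float = 1e6, intercept_alpha: float = 1e-6,
                   tol: float = 1e-3) -> SparseBLR:
    """Evidence-approximation ARD: alternate MAP weight finding with
    MacKay fixed-point updates of the per-weight precisions.

    ``labels`` are 0 (control) / 1 (patient); both classes must be present.
    The intercept carries a fixed, effectively flat prior.
    """
    X = np.asarray(features, float)
    y = np.asarray(labels, float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    Xa = np.column_stack([X, np.ones(len(X))])
    d = Xa.shape[1]
    alpha = np.full(d, alpha_init)
    alpha[-1] = intercept_alpha
    w = np.zeros(d)
    converged = False
    it = 0
    cov = np.eye(d)
    for it in range(1, max_outer + 1):
        w = _map_weights(Xa, y, alpha, w)
        p = expit(Xa @ w)
        B = np.clip(p * (1.0 - p), 1e-10, None)
        H = (Xa * B[:, None]).T @ Xa + np.diag(alpha)
        cov = np.linalg.inv(H)
        gamma = 1.0 - alpha * np.diag(cov)
        new_alpha = np.clip(gamma / np.clip(w * w, 1e-12, None), 1e-8, alpha_max)
        new_alpha[-1] = intercept_alpha
        delta = np.max(np.abs(np.log(new_alpha) - np.log(alpha)))
        alpha = new_alpha
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("ARD updates stopped at max_outer=%d", max_outer)
    w = _map_weights(Xa, y, alpha, w)
    return SparseBLR(w, alpha, cov, converged, it)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    protocol: str
    per_class_accuracy: dict[str, float]   # "control", "patient"
    n_folds: int
    n_skipped: int
    table: pd.DataFrame = field(repr=False)


def _folds(protocol: str, labels: np.ndarray, seed: int,
           n_splits: int = 100, max_pairs: int = 400) -> list[np.ndarray]:
    """Held-out index sets for each protocol (stratified for leave-half-out)."""
    n = len(labels)
    rng = np.random.default_rng(seed)
    if protocol == "l1o":
        return [np.array([i]) for i in range(n)]
    if protocol == "l2o":
        pairs = list(combinations(range(n), 2))
        if len(pairs) > max_pairs:
            idx = rng.choice(len(pairs), size=max_pairs, replace=False)
            pairs = [pairs[i] for i in idx]
        return [np.array(p) for p in pairs]
    if protocol == "lho":
        folds = []
        for _ in range(n_splits):
            test = []
            for cls in (0, 1):
                members = np.flatnonzero(labels == cls)
                k = len(members) // 2
                test.extend(rng.choice(members, size=k, replace=False))
            folds.append(np.sort(np.array(test)))
        return folds
    raise ValueError(f"unknown protocol {protocol!r}")


def cross_validate(features: pd.DataFrame, labels: Sequence[int],
                   protocol: str = "l1o", seed: int = 0,
                   paper_faithful_normalization: bool = False,
                   n_splits: int = 100, max_pairs: int = 400) -> CVResult:
    """Cross-validated per-class accuracy of the ARD classifier.

    ``features`` holds the *un-normalized* summed Fisher vectors (subjects x
    coordinates).  By default the SD divisors are recomputed on every
    training fold so no test statistic leaks into training;
    ``paper_faithful_normalization`` restores one global normalization over
    all individuals before splitting.
    """
    X_raw = features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    folds = _folds(protocol, y, seed, n_splits=n_splits, max_pairs=max_pairs)

    if paper_faithful_normalization:
        (X_glob,), _ = normalize_features(X_raw)

    hits = {0: 0, 1: 0}
    tries = {0: 0, 1: 0}
    confusion = np.zeros((2, 2))
    skipped = 0
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        if len(np.unique(y[train_idx])) < 2:
            skipped += 1
            continue
        if paper_faithful_normalization:
            Xtr, Xte = X_glob[train_idx], X_glob[test_idx]
        else:
            (Xtr, Xte), _ = normalize_features(X_raw[train_idx],
                                               X_raw[test_idx])
        clf = fit_sparse_blr(Xtr, y[train_idx])
        pred = clf.predict(Xte)
        for yy, pp in zip(y[test_idx], pred):
            tries[yy] += 1
            hits[yy] += int(yy == pp)
            confusion[yy, pp] += 1
    acc = {
        "control": hits[0] / tries[0] if tries[0] else float("nan"),
        "patient": hits[1] / tries[1] if tries[1] else float("nan"),
    }
    with np.errstate(invalid="ignore"):
        rates = confusion / confusion.sum(axis=1, keepdims=True)
    table = pd.DataFrame(
        rates, index=["control", "patient"],
        columns=["predicted_control", "predicted_patient"],
    )
    table.insert(0, "protocol",
                 {"l1o": "L-1-O", "l2o": "L-2-O", "lho": "L-H-O"}[protocol])
    return CVResult(protocol, acc, len(folds) - skipped, skipped, table)
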