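"""Group-level statistics for the oculomotor metrics.

Cluster-robust linear regression of trial-level metrics on diagnostic group
(clustered by participant, sandwich SEs with CR1 small-sample scaling),
Shapiro–Wilk normality checks, Wilcoxon rank-sum / t demographic
comparisons, and the Spearman correlation grid between per-subject
oculomotor metrics and visual-cognition test scores.

Real neuropsychology scores are not distributable, so
:func:`simulate_cognition_scores` draws synthetic scores from a latent
severity factor tied to each subject's simulated oculomotor profile; they
reproduce the direction, not the magnitude, of the published correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .synthetic import SubjectRecord

COGNITION_TESTS = (
    "shape_detection", "object_decision", "fragmented_letters",
    "dot_counting", "a_cancellation_time", "nart_errors",
)

#: printed score ranges for each cognition test (low, high)
SCORE_RANGES: dict[str, tuple[float, float]] = {
    "shape_detection": (10, 20),
    "object_decision": (5, 20),
    "fragmented_letters": (0, 20),
    "dot_counting": (0, 10),
    "a_cancellation_time": (5, 90),
    "nart_errors": (0, 50),
    "mmse": (0, 30),
}


@dataclass
class ModelResult:
    """Coefficients with cluster-robust inference."""

    params: pd.Series
    bse: pd.Series          # cluster-robust standard errors
    tvalues: pd.Series
    pvalues: pd.Series
    nobs: int
    n_clusters: int

    def __post_init__(self) -> None:
        if (self.bse <= 0).any():
            raise ValueError("standard errors must be positive")
        if self.n_clusters > self.nobs:
            raise ValueError("more clusters than observations")


def cluster_robust_model(y: Sequence[float], X: pd.DataFrame,
                         cluster_ids: Sequence) -> ModelResult:
    """OLS point estimates with a CR1 cluster sandwich covariance.

    ``X`` is the covariate table without a constant (one is added).  Clusters
    are typically participants with repeated trials; singleton clusters are
    allowed.  Raises ``np.linalg.LinAlgError`` on a rank-deficient design.
    """
    X = sm.add_constant(pd.DataFrame(X), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    groups = pd.factorize(pd.Series(list(cluster_ids)))[0]
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit(
        cov_type="cluster",
        cov_kwds={"groups": groups, "use_correction": True},
    )
    return ModelResult(
        params=fit.params, bse=fit.bse, tvalues=fit.tvalues,
        pvalues=pd.Series(fit.pvalues, index=fit.params.index),
        nobs=int(fit.nobs), n_clusters=int(len(np.unique(groups))),
    )


def fit_metric_group_model(rows: pd.DataFrame, metric: str,
                           demographics: pd.DataFrame | None = None
                           ) -> ModelResult:
    """Regress one trial-level metric on group with age/gender covariates.

    ``rows`` is the long metric table; ``demographics`` (indexed by
    subject_id, columns age/gender) adds the covariates when provided.
    Condition covariates are included per paradigm: target distance and
    direction for pro-saccade metrics, axis and speed for pursuit metrics.
    """
    sub = rows[(rows["metric"] == metric) & (~rows["missing"])].copy()
    if sub.empty:
        raise ValueError(f"no observations for metric {metric!r}")
    X = pd.DataFrame(index=sub.index)
    X["group_patient"] = (sub["group"] == "patient").astype(float)
    if demographics is not None:
        X["age"] = sub["subject_id"].map(demographics["age"]).astype(float)
        X["gender"] = sub["subject_id"].map(demographics["gender"]).astype(float)
    paradigm = sub["paradigm"].iloc[0]
    if paradigm == "prosaccade":
        X["distance"] = sub["distance_deg"].astype(float)
        X["vertical_target"] = sub["direction"].isin(["up", "down"]).astype(float)
    elif paradigm == "pursuit":
        X["speed"] = sub["speed_deg_s"].astype(float)
        X["vertical_axis"] = (sub["axis"] == "vertical").astype(float)
    return cluster_robust_model(sub["value"].astype(float), X, sub["subject_id"])


def spearman_matrix(metric_table: pd.DataFrame, cognition: pd.DataFrame,
                    min_pairs: int = 4
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spearman rho and p between each oculomotor metric and cognition test.

    Both inputs are indexed by subject; pairwise-complete observations are
    used per cell, ties midranked.  Cells with fewer than ``min_pairs``
    complete pairs are NaN and flagged in the returned mask.
    """
    tests = [c for c in cognition.columns if c in COGNITION_TESTS] or list(cognition.columns)
    common = metric_table.index.intersection(cognition.index)
    rho = pd.DataFrame(index=tests, columns=metric_table.columns, dtype=float)
    pval = rho.copy()
    insufficient = pd.DataFrame(False, index=tests, columns=metric_table.columns)
    for m in metric_table.columns:
        for c in tests:
            pair = pd.concat([metric_table.loc[common, m],
                              cognition.loc[common, c]], axis=1).dropna()
            if len(pair) < min_pairs:
                insufficient.loc[c, m] = True
                continue
            r, p = sps.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            rho.loc[c, m], pval.loc[c, m] = r, p
    return rho, pval, insufficient


def benjamini_hochberg(pvals: pd.DataFrame) -> pd.DataFrame:
    """Optional FDR adjustment of a p-value grid (not applied by default)."""
    flat = pvals.to_numpy(dtype=float).ravel()
    mask = np.isfinite(flat)
    adj = np.full_like(flat, np.nan)
    if mask.any():
        adj[mask] = sm.stats.multipletests(flat[mask], method="fdr_bh")[1]
    return pd.DataFrame(adj.reshape(pvals.shape), index=pvals.index,
                        columns=pvals.columns)


def normality_and_group_tests(
    vectors: Mapping[str, np.ndarray],
    comparisons: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Shapiro–Wilk normality per vector plus two-sample demographic tests.

    Each comparison yields a two-sample t statistic and a Wilcoxon
    rank-sum z (normal-approximation).  Constant vectors are flagged rather
    than tested.
    """
    rows = []
    for name, v in vectors.items():
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < 3 or np.ptp(v) == 0:
            rows.append({"vector": name, "n": len(v), "W": None, "p": None,
                         "flag": "constant_or_too_short"})
            continue
        w, p = sps.shapiro(v)
        rows.append({"vector": name, "n": len(v), "W": float(w),
                     "p": float(p), "flag": ""})
    out = {"normality": pd.DataFrame(rows)}

    comp_rows = []
    for name, (a, b) in (comparisons or {}).items():
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        tt = sps.ttest_ind(a, b, equal_var=False)
        rs = sps.ranksums(a, b)
        comp_rows.append({
            "comparison": name, "n1": len(a), "n2": len(b),
            "t": float(tt.statistic), "p_t": float(tt.pvalue),
            "z": float(rs.statistic), "p_z": float(rs.pvalue),
        })
    out["group_tests"] = pd.DataFrame(comp_rows)
    return out


# ---------------------------------------------------------------------------
# synthetic cognition scores
# ---------------------------------------------------------------------------

def _severity(record: SubjectRecord) -> float:
    """Latent disease-severity score implied by a subject's oculomotor profile.

    A positive combination of the oculomotor abnormalities (intrusion rate,
    saccade latency, hypometria, tracking loss) standardized against the
    healthy preset, so cognition scores generated from it co-vary with the
    extracted metrics in the published directions.
    """
    p = record.profile
    return float(
        0.3 * (p.intrusive_saccade_rate - 0.7) / 1.0
        + 0.3 * (p.saccade_latency_mean - 160.0) / 60.0
        + 0.2 * (0.90 - p.saccade_gain_mean) / 0.10
        + 0.2 * (0.60 - p.pursuit_tracking_fraction) / 0.15
    )


def simulate_cognition_scores(subjects: Sequence[SubjectRecord],
                              seed: int = 0) -> pd.DataFrame:
    """Synthetic demographics and cognition scores, indexed by subject_id.

    Scores are affine in the latent severity factor plus noise, clipped to
    their printed ranges; controls centre on published control means.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rec in subjects:
        sev = _severity(rec) + rng.normal(0.0, 0.3)
        sev = max(sev, -0.5)

        def score(base: float, slope: float, sd: float, key: str) -> float:
            lo, hi = SCORE_RANGES[key]
            return float(np.clip(base + slope * sev + rng.normal(0.0, sd), lo, hi))

        rows.append({
            "subject_id": rec.subject_id,
            "group": rec.group,
            "age": float(np.clip(rng.normal(61.0, 5.3), 45, 75)),
            "gender": int(rng.random() < 0.5),
            "years_education": float(np.clip(rng.normal(16.0, 3.0), 8, 24)),
            "shape_detection": score(19.5, -0.9, 0.5, "shape_detection"),
            "object_decision": score(18.2, -2.2, 1.0, "object_decision"),
            "fragmented_letters": score(19.5, -4.5, 1.0, "fragmented_letters"),
            "dot_counting": score(9.9, -1.4, 0.4, "dot_counting"),
            "a_cancellation_time": score(21.0, 17.0, 5.0, "a_cancellation_time"),
            "nart_errors": score(11.5, 4.5, 4.0, "nart_errors"),
            "mmse": score(29.5, -4.5, 1.0, "mmse"),
        })
    return pd.DataFrame(rows).set_index("subject_id")
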