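#!/usr/bin/env python
"""Group-level inference on the summary metrics.

Fits a cluster-robust linear model (clustered by participant, CR1 sandwich
SEs, age and gender covariates, condition covariates per paradigm) for each
metric, runs Shapiro-Wilk normality checks, and computes the Spearman
correlation grid between per-subject metrics and the synthetic
visual-cognition scores.  Reads results/metrics.csv written by
03_summary_metrics.py.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from oculomark.stats import (fit_metric_group_model, normality_and_group_tests,
                             simulate_cognition_scores, spearman_matrix)
from oculomark.synthetic import CohortSpec, simulate_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=7)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

metric_rows = pd.read_csv(args.out / "metrics.csv")
subjects = simulate_cohort(CohortSpec(master_seed=args.seed))
cognition = simulate_cognition_scores(subjects, seed=args.seed + 1)
cognition.to_csv(args.out / "cognition.csv", float_format="%.3f")

model_rows = []
for metric in sorted(metric_rows["metric"].unique()):
    try:
        res = fit_metric_group_model(metric_rows, metric, cognition)
    except (ValueError, np.linalg.LinAlgError) as exc:
        print(f"skipping {metric}: {exc}")
        continue
    model_rows.append({
        "metric": metric,
        "group_coef": res.params["group_patient"],
        "group_se": res.bse["group_patient"],
        "group_t": res.tvalues["group_patient"],
        "group_p": res.pvalues["group_patient"],
        "n_obs": res.nobs, "n_clusters": res.n_clusters,
    })
models = pd.DataFrame(model_rows)
models.to_csv(args.out / "group_models.csv", index=False, float_format="%.5g")

subj_means = metric_rows[~metric_rows["missing"]].pivot_table(
    index="subject_id", columns="metric", values="value", aggfunc="mean")
rho, pval, _ = spearman_matrix(subj_means, cognition)
rho.to_csv(args.out / "spearman_rho.csv", float_format="%.3f")
pval.to_csv(args.out / "spearman_p.csv", float_format="%.4g")

norm = normality_and_group_tests(
    {m: subj_means[m].dropna().to_numpy() for m in subj_means.columns})
norm["normality"].to_csv(args.out / "normality.csv", index=False,
                         float_format="%.4g")

print("cluster-robust group effects (patient vs control):")
print(models[["metric", "group_coef", "group_t", "group_p"]].round(4)
      .to_string(index=False))
print("\nSpearman rho (cognition tests x oculomotor metrics):")
print(rho.round(2))
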