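"""End-to-end orchestration: simulate -> detect -> metrics -> stats -> classify.

A single :class:`RunConfig` holds every threshold and seed used anywhere in
the pipeline; reruns with an identical config are byte-identical and every
output directory carries a manifest with the config hash and file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as omio
from .classifier import (cross_validate, select_reference_and_fit,
                         subject_feature_matrix)
from .detection import DetectionConfig, detect_events, exclude_bad_trials
from .hmm import EMConfig
from .metrics import MetricConfig, aggregate_metrics, compute_trial_metrics
from .stats import (fit_metric_group_model, normality_and_group_tests,
                    simulate_cognition_scores, spearman_matrix)
from .synthetic import PARADIGMS, CohortSpec, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortSpec = CohortSpec()
    detection: DetectionConfig = DetectionConfig()
    metrics: MetricConfig = MetricConfig()
    em: EMConfig = EMConfig()
    paradigms: tuple[str, ...] = PARADIGMS
    cv_protocols: tuple[str, ...] = ("l1o",)
    paper_faithful_normalization: bool = False
    master_seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage and write a run directory; returns the manifest."""
    out = Path(out_dir)
    (out / "samples").mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(),
                      "master_seed": config.master_seed, "stages": {}}
    stage = "synthetic_gaze"
    try:
        cohort = dataclasses.replace(config.cohort,
                                     master_seed=config.master_seed)
        subjects = simulate_cohort(cohort, paradigms=config.paradigms)
        paths = {}
        for rec in subjects:
            p = out / "samples" / f"{rec.subject_id}.csv"
            series = [s for plist in rec.trials.values() for s in plist]
            omio.write_samples(series, p)
            paths[rec.subject_id] = str(p.relative_to(out))
        omio.write_manifest(subjects, paths, config.master_seed,
                            out / "cohort.yaml")
        manifest["stages"][stage] = {"n_subjects": len(subjects)}

        stage = "event_detection"
        all_events = {}
        pairs = []
        for rec in subjects:
            for plist in rec.trials.values():
                for s in plist:
                    ev = detect_events(s, config.detection)
                    all_events[s.trial_id] = ev
                    pairs.append((s, ev))
        kept, report = exclude_bad_trials(pairs, config=config.detection)
        omio.write_events(all_events.values(), out / "events.csv")
        report.to_csv(out / "exclusions.csv", index=False)
        manifest["stages"][stage] = {
            "n_trials": len(pairs), "n_kept": len(kept),
        }

        stage = "summary_metrics"
        rows = []
        kept_ids = {s.trial_id for s, _ in kept}
        for rec in subjects:
            for plist in rec.trials.values():
                for s in plist:
                    if s.trial_id not in kept_ids:
                        continue
                    rows.extend(compute_trial_metrics(
                        s, all_events[s.trial_id], rec.subject_id, rec.group,
                        config.metrics, config.detection))
        metric_rows = pd.DataFrame(rows)
        metric_rows.to_csv(out / "metrics.csv", index=False)
        aggregate_metrics(metric_rows).to_csv(out / "metrics_summary.csv",
                                              index=False, float_format="%.4f")
        manifest["stages"][stage] = {"n_rows": len(metric_rows)}

        stage = "group_stats"
        cognition = simulate_cognition_scores(subjects,
                                              seed=config.master_seed + 1)
        cognition.to_csv(out / "cognition.csv", float_format="%.3f")
        model_rows = []
        for metric in sorted(metric_rows["metric"].unique()):
            try:
                res = fit_metric_group_model(metric_rows, metric, cognition)
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("group model for %s failed: %s", metric, exc)
                continue
            model_rows.append({
                "metric": metric,
                "group_coef": res.params["group_patient"],
                "group_se": res.bse["group_patient"],
                "group_t": res.tvalues["group_patient"],
                "group_p": res.pvalues["group_patient"],
                "n_obs": res.nobs, "n_clusters": res.n_clusters,
            })
        pd.DataFrame(model_rows).to_csv(out / "group_models.csv", index=False,
                                        float_format="%.6g")
        subj_means = metric_rows[~metric_rows["missing"]].pivot_table(
            index="subject_id", columns="metric", values="value", aggfunc="mean")
        rho, pval, _ = spearman_matrix(subj_means, cognition)
        rho.to_csv(out / "spearman_rho.csv", float_format="%.4f")
        pval.to_csv(out / "spearman_p.csv", float_format="%.4g")
        norm = normality_and_group_tests(
            {m: subj_means[m].dropna().to_numpy() for m in subj_means.columns})
        norm["normality"].to_csv(out / "normality.csv", index=False,
                                 float_format="%.4g")
        manifest["stages"][stage] = {"n_models": len(model_rows)}

        stage = "hmm_fisher_classifier"
        if "pursuit" in config.paradigms:
            ref_id, models = select_reference_and_fit(
                subjects, config.em, seed=config.master_seed)
            feats = subject_feature_matrix(subjects, models, config.em)
            feats_out = feats.copy()
            feats_out.insert(0, "group",
                             [rec.group for rec in subjects])
            feats_out.to_csv(out / "features.csv", float_format="%.6g")
            labels = [0 if rec.group == "control" else 1 for rec in subjects]
            tables = []
            accs = {}
            for proto in config.cv_protocols:
                res = cross_validate(
                    feats, labels, proto, seed=config.master_seed,
                    paper_faithful_normalization=config.paper_faithful_normalization)
                tables.append(res.table)
                accs[proto] = res.per_class_accuracy
            pd.concat(tables).to_csv(out / "classification.csv",
                                     float_format="%.4f")
            manifest["stages"][stage] = {"reference": ref_id,
                                         "accuracy": accs}
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest["checksums"] = {
        p.name: _checksum(p) for p in sorted(out.rglob("*.csv"))
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest


def validate_inputs(samples_path: str | Path) -> list[dict]:
    """Input-validation report for a samples file (thin re-export)."""
    return omio.validate_samples_file(samples_path)
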