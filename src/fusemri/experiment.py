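"""End-to-end experiment driver.

Reproduces the study workflow on tabular inputs: per-set uni-modal
nested-LOOCV classification, the three multi-modal fusion strategies,
optional permutation / bootstrap inference on the best models, the
FDR-corrected group-difference screen and the feature-contribution
analysis.  All reports carry the config echo and seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .analysis import ablate_ensemble, outer_fold_contribution
from .config import ExperimentConfig
from .containers import Cohort
from .errors import SchemaError
from .fusion import concatenate_sets, ensemble_search, run_forced_fusion
from .io import read_clinical_csv, read_feature_dir, write_json_report
from .nested_cv import compute_metrics, run_nested_loocv
from .outcome import derive_outcome_labels
from .resampling import bootstrap_auc_ci, group_difference_screen, permutation_test

logger = logging.getLogger(__name__)

__all__ = ["task_labels", "run_experiment"]


def task_labels(cohort: Cohort, task: str):
    """(subject_ids, 0/1 labels) for a task; positive class MDD / PO."""
    df = cohort.clinical
    if task == "diagnosis":
        groups = set(df["group"])
        if not {"MDD", "HC"} <= groups and len(groups) != 2:
            raise SchemaError(f"expected two groups, found {sorted(groups)}")
        positive = "MDD" if "MDD" in groups else sorted(groups)[1]
        ids = list(df["subject_id"])
        y = (df["group"] == positive).to_numpy().astype(np.int64)
        return ids, y
    labels = derive_outcome_labels(cohort)
    ids = list(labels["subject_id"])
    y = (labels["outcome"] == "PO").to_numpy().astype(np.int64)
    return ids, y


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full workflow; writes JSON/CSV reports, returns a summary."""
    config.validate(check_paths=True)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = read_clinical_csv(config.clinical_path)
    sets = read_feature_dir(config.features_dir)
    ids, y = task_labels(cohort, config.task)
    sets = {name: fs.loc_subjects(ids) for name, fs in sets.items()}
    echo = {"config": config.echo(), "seed": config.seed}

    # uni-modal classification per feature set
    cv_results = {}
    unimodal = {}
    for name, fs in sorted(sets.items()):
        logger.info("uni-modal nested LOOCV: %s", name)
        cv = run_nested_loocv(fs.values, y, config.ranking)
        cv_results[name] = cv
        report = compute_metrics(cv.y_true, cv.y_pred, cv.decision)
        unimodal[name] = report
        contrib = outer_fold_contribution(cv, fs.element_labels, fs.values, y)
        contrib.to_csv(out_dir / f"contribution_{name}.csv", index=False)
        write_json_report(
            {**echo, "feature_set": name, "performance": report.as_dict(),
             "k_optimal": cv.k_optimal.tolist()},
            out_dir / f"unimodal_{name}.json",
        )

    # fusion 1: concatenation
    combined = concatenate_sets([sets[k] for k in sorted(sets)])
    cv_concat = run_nested_loocv(combined.values, y, config.ranking)
    concat_report = compute_metrics(cv_concat.y_true, cv_concat.y_pred,
                                    cv_concat.decision)

    # fusion 2: forced fusion
    cv_forced = run_forced_fusion([sets[k] for k in sorted(sets)], y,
                                  config.ranking)
    forced_report = compute_metrics(cv_forced.y_true, cv_forced.y_pred,
                                    cv_forced.decision)

    # fusion 3: majority-vote ensembles
    ensembles = {}
    best_ensemble = None
    for n_set in config.ensemble_sizes:
        if n_set > len(cv_results):
            continue
        ranked = ensemble_search(cv_results, n_set)
        ensembles[n_set] = ranked
        if best_ensemble is None or ranked[0].report.auc > best_ensemble.report.auc:
            best_ensemble = ranked[0]

    # inference on the best uni-modal model
    best_name = max(unimodal, key=lambda k: unimodal[k].auc)
    boot = bootstrap_auc_ci(cv_results[best_name].decision, y,
                            n_boot=config.n_boot, seed=config.seed)
    perm = None
    if config.n_perm > 0:
        X_best = sets[best_name].values

        def _run(labels):
            return run_nested_loocv(X_best, labels, config.ranking).test_auc()

        perm = permutation_test(_run, y, n_perm=config.n_perm, seed=config.seed)

    screen = group_difference_screen(sets, y)
    screen.to_csv(out_dir / "group_differences.csv", index=False)

    ablation = None
    if best_ensemble is not None and best_ensemble.spec.n_set >= 3:
        ablation = ablate_ensemble(cv_results, best_ensemble)
        ablation.to_csv(out_dir / "ablation.csv", index=False)

    summary = {
        **echo,
        "task": config.task,
        "n_subjects": int(len(y)),
        "unimodal": {k: v.as_dict() for k, v in unimodal.items()},
        "concatenation": concat_report.as_dict(),
        "forced_fusion": forced_report.as_dict(),
        "ensembles": {
            str(n): [
                {"members": list(r.spec.members), **r.report.as_dict()}
                for r in ranked[:10]
            ]
            for n, ranked in ensembles.items()
        },
        "best_unimodal": {
            "set": best_name,
            "auc": unimodal[best_name].auc,
            "bootstrap_ci": list(boot.ci),
            "permutation_p": None if perm is None else perm.p_value,
        },
        "significant_elements_fdr": int(screen["significant"].sum()),
    }
    write_json_report(summary, out_dir / "summary.json")
    return summary
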