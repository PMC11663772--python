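"""Post-hoc model interrogation.

Which elements drove a fitted nested-LOOCV model, and which member sets
drive an ensemble:

- **outer-fold contribution** — the percentage of outer folds whose
  selected feature subset contained an element; a stability measure
  independent of the weights.
- **beta impact** — the mean |beta| of the element over the folds where
  it was selected; weights live in standardized feature space, so their
  magnitudes are comparable across elements.  Contribution and impact
  rank elements differently in general; both are always reported.
- **ablation** — remove one member set at a time from a majority-vote
  ensemble (no refit; ties of the resulting even vote break by summed
  decision values) and record the AUC drop.  A negative drop (removal
  helps) is permitted and reported.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ParameterError
from .fusion import EnsembleResult, majority_vote
from .nested_cv import CvResult, compute_metrics

logger = logging.getLogger(__name__)

__all__ = [
    "outer_fold_contribution",
    "ablate_ensemble",
    "normalize_contributions",
]


def outer_fold_contribution(cv: CvResult, element_labels=None,
                            X: np.ndarray | None = None,
                            y: np.ndarray | None = None) -> pd.DataFrame:
    """Occurrence percentage and mean |beta| per element over outer folds.

    Elements never selected get 0 for both.  If the feature matrix and
    labels are supplied, the direction of the group difference (sign of
    mean of class 1 minus class 0) is included.
    """
    n_el = cv.n_elements
    n_folds = cv.n_folds
    count = np.zeros(n_el)
    beta_sum = np.zeros(n_el)
    for m in cv.fold_models:
        count[m.selected] += 1
        beta_sum[m.selected] += np.abs(m.beta)
    with np.errstate(invalid="ignore"):
        mean_beta = np.where(count > 0, beta_sum / np.maximum(count, 1), 0.0)
    table = pd.DataFrame({
        "element_index": np.arange(n_el),
        "element": element_labels if element_labels is not None
        else [f"e{j:04d}" for j in range(n_el)],
        "occurrence_pct": 100.0 * count / n_folds,
        "mean_abs_beta": mean_beta,
    })
    if X is not None and y is not None:
        y = np.asarray(y)
        X = np.asarray(X, dtype=np.float64)
        table["direction"] = np.sign(X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0))
    table["impact_rank"] = (
        table["mean_abs_beta"].rank(ascending=False, method="min").astype(int)
    )
    return table.sort_values(
        ["occurrence_pct", "mean_abs_beta", "element_index"],
        ascending=[False, False, True],
    ).reset_index(drop=True)


def ablate_ensemble(cv_results: dict, ensemble: EnsembleResult) -> pd.DataFrame:
    """Leave-one-member-out AUC loss for a majority-vote ensemble."""
    members = ensemble.spec.members
    if len(members) < 3:
        raise ParameterError("ablation needs an ensemble of at least 3 members")
    full_auc = ensemble.report.auc
    y = cv_results[members[0]].y_true
    rows = []
    for removed in members:
        kept = [m for m in members if m != removed]
        labels = np.vstack([cv_results[m].y_pred for m in kept])
        decisions = np.vstack([cv_results[m].decision for m in kept])
        fused = majority_vote(labels, decisions)
        auc = compute_metrics(y, fused).auc
        rows.append({"removed": removed, "auc_without": auc,
                     "delta_auc": full_auc - auc})
    out = pd.DataFrame(rows).sort_values(
        ["delta_auc", "removed"], ascending=[False, True]
    ).reset_index(drop=True)
    return out


def normalize_contributions(tables) -> list:
    """Min-max normalize occurrence percentages over the pooled models.

    The minimum and maximum are taken over *all* supplied contribution
    tables so normalized scores are comparable between models.  If every
    pooled value is identical the scores degenerate to 0 (logged).
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ParameterError("need at least 2 contribution tables to normalize")
    pooled = np.concatenate([t["occurrence_pct"].to_numpy() for t in tables])
    lo, hi = pooled.min(), pooled.max()
    out = []
    for t in tables:
        t = t.copy()
        if hi == lo:
            logger.warning("all pooled contributions equal; normalized scores set to 0")
            t["normalized_contribution"] = 0.0
        else:
            t["normalized_contribution"] = (t["occurrence_pct"] - lo) / (hi - lo)
        out.append(t)
    return out
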