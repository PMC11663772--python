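"""Resampling inference: permutation significance, bootstrap CIs, FDR screen.

- The permutation test keeps the entire classification machinery (nested
  LOOCV with double feature selection) and reruns it under shuffled
  class labels; p is the fraction of the ``n_perm`` null AUCs that reach
  the true-label AUC (ties count against the hypothesis).  A count of 0
  is reported as p = 0.0 with resolution 1/n_perm.
- Bootstrap CIs resample the fixed (decision value, label) pairs with
  replacement — the pipeline is not refit — and take percentile bounds
  over the AUC of each resample; resamples missing a class are redrawn.
- The mass-univariate group-difference screen applies the same
  normality-gated two-sample tests as the feature ranking and controls
  the false discovery rate with Benjamini-Hochberg at alpha = 0.05,
  separately within each feature set.

Replicate seeds derive from the master seed (counter scheme), so
replicates are independent and aggregation is order-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import auc_from_scores, benjamini_hochberg
from .errors import ParameterError
from .ranking import univariate_screen
from .seeds import child_rng

__all__ = [
    "PermutationReport",
    "BootstrapReport",
    "permutation_test",
    "bootstrap_auc_ci",
    "group_difference_screen",
]


@dataclass
class PermutationReport:
    true_auc: float
    null_aucs: np.ndarray
    p_value: float
    n_perm: int

    def summary(self) -> str:
        p = f"< {1.0 / self.n_perm:g}" if self.p_value == 0 else f"= {self.p_value:g}"
        return f"AUC {self.true_auc:.3f}, permutation p {p} ({self.n_perm} permutations)"


@dataclass
class BootstrapReport:
    auc_samples: np.ndarray
    ci: tuple
    n_boot: int
    redrawn: int = 0


def permutation_test(run_pipeline, y: np.ndarray, n_perm: int = 1000,
                     seed: int = 0) -> PermutationReport:
    """Pipeline-preserving permutation test of a model's test AUC.

    ``run_pipeline(labels) -> AUC`` must rerun the full classification
    (it is called once with the true labels and once per permutation
    with shuffled labels).  p = #(null AUC >= true AUC) / n_perm.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    y = np.asarray(y)
    true_auc = float(run_pipeline(y))
    null = np.empty(n_perm)
    for i in range(n_perm):
        rng = child_rng(seed, "perm", i)
        null[i] = run_pipeline(rng.permutation(y))
    p = float(np.mean(null >= true_auc))
    return PermutationReport(true_auc, null, p, n_perm)


def bootstrap_auc_ci(decision: np.ndarray, y: np.ndarray, n_boot: int = 1000,
                     seed: int = 0, level: float = 0.95,
                     max_redraw: int = 10000) -> BootstrapReport:
    """Percentile bootstrap CI for the AUC of fixed predictions."""
    decision = np.asarray(decision, dtype=np.float64)
    y = np.asarray(y).astype(np.int64)
    n = len(y)
    if min(np.sum(y == 1), np.sum(y == 0)) < 2:
        raise ParameterError("need at least 2 subjects per class for a CI")
    rng = child_rng(seed, "bootstrap")
    aucs = np.empty(n_boot)
    redrawn = 0
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if 0 < yb.sum() < n:
                break
            redrawn += 1
            if redrawn > max_redraw:
                raise ParameterError("bootstrap resampling keeps losing a class")
        aucs[i] = auc_from_scores(decision[idx], yb)
    lo, hi = np.quantile(aucs, [(1 - level) / 2, 1 - (1 - level) / 2])
    return BootstrapReport(aucs, (float(lo), float(hi)), n_boot, redrawn)


def group_difference_screen(feature_sets: dict, y: np.ndarray,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Mass-univariate group differences with per-set BH-FDR control.

    Returns one row per element: raw p, test used, direction of change
    (sign of mean difference, class 1 minus class 0), BH-adjusted p and
    the rejection decision at ``alpha`` (correction within each set).
    """
    y = np.asarray(y)
    frames = []
    for name, fs in feature_sets.items():
        X = fs.values
        p, stat, used_ranksum, _ = univariate_screen(X, y)
        direction = np.sign(X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0))
        reject, p_adj = benjamini_hochberg(p, alpha)
        frames.append(pd.DataFrame({
            "set": name,
            "element": fs.element_labels,
            "p_raw": p,
            "statistic": stat,
            "test": np.where(used_ranksum, "ranksum", "ttest"),
            "direction": direction,
            "p_fdr": p_adj,
            "significant": reject,
        }))
    return pd.concat(frames, ignore_index=True)
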