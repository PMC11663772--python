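"""Linear-SVM classification with nested leave-one-out cross-validation.

For every outer fold (one held-out subject) an inner leave-one-out loop
over the remaining n-1 subjects repeats the full double feature ranking
and evaluates candidate models of 1..k_final top-ranked elements; the
number of features k_optimal is the only tuned parameter (highest inner
AUC, ties to the smallest k).  The outer training set is then re-ranked,
a linear SVM (C = 1, never tuned) fit on the top k_optimal elements, and
the held-out subject predicted.  Features are z-scored with training-fold
statistics everywhere, so no information from a test subject reaches
ranking, standardization or fitting.

Inner-loop model selection pools the n-1 single held-out decision values
per candidate k into one AUC (each inner fold contributes one value, so
a per-fold AUC does not exist); an accuracy-averaging variant is
available via ``inner="averaged"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._stats import auc_from_scores
from ._svm import linear_svm_fit
from .errors import NumericalError, ParameterError, SingleClassError
from .ranking import RankingConfig, double_rank

__all__ = [
    "FoldModel",
    "CvResult",
    "PerfReport",
    "fit_linear_svm",
    "run_nested_loocv",
    "compute_metrics",
]


@dataclass
class FoldModel:
    """Hyperplane fitted on one outer training fold."""

    selected: np.ndarray     # element indices, ranking order
    beta: np.ndarray         # weights in standardized feature space
    bias: float
    k_optimal: int


@dataclass
class CvResult:
    """Per-subject LOO predictions plus the fold models that made them."""

    subject_index: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    decision: np.ndarray
    fold_models: list
    inner_auc: np.ndarray    # (n_folds, k_final), NaN where k unavailable
    n_elements: int
    skipped_inner_folds: int = 0

    @property
    def n_folds(self) -> int:
        return len(self.subject_index)

    @property
    def k_optimal(self) -> np.ndarray:
        return np.array([m.k_optimal for m in self.fold_models])

    def test_auc(self) -> float:
        return auc_from_scores(self.decision, self.y_true)


@dataclass
class PerfReport:
    """Classification metric suite; all values are fractions in [0, 1]."""

    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    ci: tuple | None = None
    p_value: float | None = None
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {
            "auc": self.auc, "accuracy": self.accuracy,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "precision": self.precision, "f1": self.f1,
        }
        if self.ci is not None:
            d["ci"] = [self.ci[0], self.ci[1]]
        if self.p_value is not None:
            d["p_value"] = self.p_value
        if self.flags:
            d["flags"] = list(self.flags)
        return d


def fit_linear_svm(X: np.ndarray, y: np.ndarray):
    """Fit the linear C-SVM (C = 1) on 0/1 labels; returns (w, bias).

    Decision values are signed distances (up to ||w||) with positive
    values voting for class 1.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise SingleClassError("training set contains a single class")
    y_signed = np.where(y == np.max(y), 1.0, -1.0)
    return linear_svm_fit(np.asarray(X, dtype=np.float64), y_signed)


def _standardize(Xtr: np.ndarray):
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def run_nested_loocv(X: np.ndarray, y: np.ndarray, cfg: RankingConfig | None = None,
                     ranker=None, inner: str = "pooled") -> CvResult:
    """Nested LOO cross-validation of the double-ranking linear SVM.

    ``ranker(X_train, y_train) -> ordered element indices`` defaults to
    the double ranking of ``cfg``; fusion strategies supply their own.
    """
    cfg = cfg or RankingConfig()
    cfg.validate()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(np.int64)
    n = len(y)
    if n < 6:
        raise ParameterError("nested LOOCV needs at least 6 subjects")
    if min(np.sum(y == 0), np.sum(y == 1)) < 3:
        raise ParameterError("each class needs at least 3 subjects")
    if inner not in ("pooled", "averaged"):
        raise ParameterError(f"unknown inner-loop mode {inner!r}")
    if ranker is None:
        ranker = lambda Xt, yt: double_rank(Xt, yt, cfg)  # noqa: E731

    k_final = cfg.k_final
    idx = np.arange(n)
    decision = np.empty(n)
    y_pred = np.empty(n, dtype=np.int64)
    fold_models = []
    inner_auc_all = np.full((n, k_final), np.nan)
    skipped = 0

    for outer in range(n):
        tr = idx != outer
        Xtr, ytr = X[tr], y[tr]
        m = len(ytr)
        dec = np.full((m, k_final), np.nan)
        for inner_i in range(m):
            itr = np.arange(m) != inner_i
            Xi, yi = Xtr[itr], ytr[itr]
            if np.unique(yi).size < 2:
                skipped += 1
                continue
            mu, sd = _standardize(Xi)
            Zi = (Xi - mu) / sd
            zi_val = (Xtr[inner_i] - mu) / sd
            order = ranker(Zi, yi)
            for k in range(1, min(k_final, len(order)) + 1):
                cols = order[:k]
                w, b = fit_linear_svm(Zi[:, cols], yi)
                dec[inner_i, k - 1] = zi_val[cols] @ w + b
        # inner model selection over candidate k
        scores = np.full(k_final, np.nan)
        for k in range(k_final):
            have = ~np.isnan(dec[:, k])
            if have.sum() < 2 or np.unique(ytr[have]).size < 2:
                continue
            if inner == "pooled":
                scores[k] = auc_from_scores(dec[have, k], ytr[have])
            else:
                scores[k] = np.mean((dec[have, k] > 0) == (ytr[have] == 1))
        if np.all(np.isnan(scores)):
            raise NumericalError("no inner fold produced a usable validation score")
        best = np.nanmax(scores)
        k_opt = int(np.where(scores == best)[0][0]) + 1  # ties -> smallest k
        inner_auc_all[outer] = scores

        mu, sd = _standardize(Xtr)
        Ztr = (Xtr - mu) / sd
        order = ranker(Ztr, ytr)
        cols = np.asarray(order[:k_opt])
        w, b = fit_linear_svm(Ztr[:, cols], ytr)
        z_test = (X[outer] - mu) / sd
        d = float(z_test[cols] @ w + b)
        decision[outer] = d
        y_pred[outer] = 1 if d > 0 else 0
        fold_models.append(FoldModel(cols, w, float(b), int(len(cols))))

    return CvResult(idx, y, y_pred, decision, fold_models, inner_auc_all,
                    X.shape[1], skipped)


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    decision: np.ndarray | None = None) -> PerfReport:
    """Metric suite for binary predictions (positive class = 1).

    AUC comes from continuous decision values when given (Mann-Whitney,
    ties count 1/2); for label-only predictions (ensembles) it is the
    single-operating-point value (sensitivity + specificity) / 2.
    """
    y_true = np.asarray(y_true).astype(np.int64)
    y_pred = np.asarray(y_pred).astype(np.int64)
    pos = y_true == 1
    neg = ~pos
    if not pos.any() or not neg.any():
        raise NumericalError("AUC undefined: one class absent from y_true")
    flags = []
    tp = int(np.sum(pos & (y_pred == 1)))
    tn = int(np.sum(neg & (y_pred == 0)))
    fp = int(np.sum(neg & (y_pred == 1)))
    fn = int(np.sum(pos & (y_pred == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / len(y_true)
    if tp + fp == 0:
        precision = 0.0
        flags.append("no positive predictions; precision set to 0")
    else:
        precision = tp / (tp + fp)
    f1 = 0.0 if precision + sens == 0 else 2 * precision * sens / (precision + sens)
    if decision is not None:
        auc = auc_from_scores(np.asarray(decision, dtype=np.float64), y_true)
    else:
        auc = (sens + spec) / 2.0
    return PerfReport(auc, acc, sens, spec, precision, f1, flags=flags)
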