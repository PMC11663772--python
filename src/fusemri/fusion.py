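"""Multi-modal fusion strategies.

Three ways to combine the eleven uni-modal feature sets:

1. **Concatenation** — all sets joined column-wise into one table; the
   uni-modal nested procedure runs unchanged on it.
2. **Forced fusion** — inside every training fold, the top 5 elements of
   each set by univariate group difference are pooled (so every set is
   represented), then the final MRMR / CV-SVM ranking and the k search
   run on the pool with k_final = 5.
3. **Majority-vote ensembles** — the stored uni-modal LOO label
   predictions of n_set member sets (n_set odd) vote per subject; no
   refitting.  Because the fused output is a label, its AUC is the
   single-operating-point value (sensitivity + specificity) / 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import FeatureSet
from .errors import ParameterError, SchemaError
from .nested_cv import CvResult, PerfReport, compute_metrics, run_nested_loocv
from .ranking import RankingConfig, cvsvm_rank, mrmr_rank, univariate_rank

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleSpec",
    "EnsembleResult",
    "concatenate_sets",
    "ForcedFusionRanker",
    "run_forced_fusion",
    "majority_vote",
    "enumerate_ensembles",
    "evaluate_ensemble",
    "ensemble_search",
]

VALID_N_SET = (3, 5, 7, 9, 11)


@dataclass(frozen=True)
class EnsembleSpec:
    members: tuple

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise ParameterError("ensemble members must be unique")
        if len(self.members) % 2 == 0:
            raise ParameterError("ensemble size must be odd")

    @property
    def n_set(self) -> int:
        return len(self.members)


@dataclass
class EnsembleResult:
    spec: EnsembleSpec
    fused_labels: np.ndarray
    report: PerfReport


def concatenate_sets(sets) -> FeatureSet:
    """Column-wise concatenation; element labels prefixed by set name.

    Subject rows must agree in content *and* order across sets — a
    mismatch is an error, never a silent reorder.
    """
    sets = list(sets)
    if not sets:
        raise ParameterError("no feature sets to concatenate")
    ref = sets[0].subject_ids
    for fs in sets[1:]:
        if fs.subject_ids != ref:
            raise SchemaError(
                f"subject rows of {fs.name!r} do not match {sets[0].name!r}"
            )
    frames = [
        fs.data.rename(columns={c: f"{fs.name}:{c}" for c in fs.data.columns})
        for fs in sets
    ]
    name = "+".join(fs.name for fs in sets)
    return FeatureSet(name, pd.concat(frames, axis=1))


class ForcedFusionRanker:
    """Fold-level ranker implementing the forced-fusion pool.

    Operates on the concatenated matrix; ``blocks`` holds the column
    slice of each member set.  Called inside every training fold, so the
    pool is recomputed without test-subject information.
    """

    def __init__(self, blocks: dict, cfg: RankingConfig, top_per_set: int = 5):
        self.blocks = blocks
        self.cfg = cfg
        self.top_per_set = top_per_set

    def __call__(self, X_train: np.ndarray, y_train: np.ndarray) -> np.ndarray:
        pooled = []
        for name, cols in self.blocks.items():
            cols = np.asarray(cols)
            if len(cols) < self.top_per_set:
                logger.debug("set %s has %d < %d elements; taking all",
                             name, len(cols), self.top_per_set)
                pooled.extend(cols)
                continue
            rr = univariate_rank(X_train[:, cols], y_train,
                                 k_initial=self.top_per_set,
                                 sw_alpha=self.cfg.sw_alpha)
            pooled.extend(cols[rr.order])
        pooled = np.asarray(pooled)
        if self.cfg.method == "mrmr":
            rr = mrmr_rank(X_train, y_train, candidates=pooled)
        else:
            rr = cvsvm_rank(X_train, y_train, candidates=pooled,
                            alpha=self.cfg.cvsvm_alpha,
                            lam=self.cfg.cvsvm_lambda,
                            max_iter=self.cfg.cvsvm_max_iter)
        return rr.order


def run_forced_fusion(sets, y, cfg: RankingConfig | None = None,
                      top_per_set: int = 5, inner: str = "pooled") -> CvResult:
    """Forced-fusion nested LOOCV over a list of feature sets."""
    cfg = cfg or RankingConfig(k_final=5)
    combined = concatenate_sets(sets)
    blocks = {}
    start = 0
    for fs in sets:
        blocks[fs.name] = np.arange(start, start + fs.n_elements)
        start += fs.n_elements
    ranker = ForcedFusionRanker(blocks, cfg, top_per_set)
    return run_nested_loocv(combined.values, y, cfg, ranker=ranker, inner=inner)


def majority_vote(member_labels: np.ndarray,
                  member_decisions: np.ndarray | None = None) -> np.ndarray:
    """Per-subject majority label over member predictions.

    ``member_labels`` is (n_members, n_subjects) of 0/1 votes.  With an
    odd member count no ties arise; an even count (reachable only via
    ablation) breaks ties by the summed decision values, logged.
    """
    votes = np.asarray(member_labels)
    n_members = votes.shape[0]
    pos = votes.sum(axis=0)
    fused = (pos * 2 > n_members).astype(np.int64)
    if n_members % 2 == 0:
        ties = pos * 2 == n_members
        if ties.any():
            if member_decisions is None:
                raise ParameterError(
                    "even member count with ties requires decision values"
                )
            logger.info("breaking %d majority-vote ties by summed decision values",
                        int(ties.sum()))
            sums = np.asarray(member_decisions).sum(axis=0)
            fused[ties] = (sums[ties] > 0).astype(np.int64)
    return fused


def enumerate_ensembles(set_names, n_set: int) -> list:
    """All unordered member combinations, in deterministic order."""
    names = list(set_names)
    if n_set > len(names):
        raise ParameterError("n_set exceeds the number of available sets")
    return [EnsembleSpec(tuple(c)) for c in combinations(names, n_set)]


def evaluate_ensemble(cv_results: dict, spec: EnsembleSpec) -> EnsembleResult:
    """Majority vote over stored uni-modal predictions; no joint refit."""
    missing = [m for m in spec.members if m not in cv_results]
    if missing:
        raise ParameterError(f"no uni-modal result for member {missing[0]!r}")
    cvs = [cv_results[m] for m in spec.members]
    y = cvs[0].y_true
    for cv in cvs[1:]:
        if not np.array_equal(cv.y_true, y):
            raise SchemaError("member CV results cover different subjects")
    labels = np.vstack([cv.y_pred for cv in cvs])
    decisions = np.vstack([cv.decision for cv in cvs])
    fused = majority_vote(labels, decisions)
    return EnsembleResult(spec, fused, compute_metrics(y, fused))


def ensemble_search(cv_results: dict, n_set: int) -> list:
    """Every n_set-member ensemble, sorted by fused AUC (descending)."""
    specs = enumerate_ensembles(sorted(cv_results), n_set)
    results = [evaluate_ensemble(cv_results, s) for s in specs]
    results.sort(key=lambda r: (-r.report.auc, r.spec.members))
    return results
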