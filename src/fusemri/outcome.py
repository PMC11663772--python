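"""Clinical outcome labeling.

Six-month treatment outcome is defined from the Hamilton Depression
Rating Scale (HDRS, 0-52): a relative reduction of at least 50 % from
baseline to follow-up is a positive outcome (PO), anything less a
negative outcome (NO).  The boundary counts as PO.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import Cohort
from .errors import SchemaError, UndefinedChangeError

__all__ = ["OutcomeLabel", "relative_change", "label_outcome", "derive_outcome_labels"]

#: Relative HDRS reduction at or above which the outcome is positive.
PO_THRESHOLD = 0.5


@dataclass(frozen=True)
class OutcomeLabel:
    value: str               # "PO" or "NO"
    relative_change: float   # (baseline - followup) / baseline; positive = improvement


def _check_scores(baseline: float, followup: float) -> None:
    for name, v in (("baseline", baseline), ("followup", followup)):
        if not 0 <= v <= 52:
            raise SchemaError(f"{name} HDRS score {v} outside the 0-52 range")
    if baseline == 0:
        raise UndefinedChangeError("relative change undefined for baseline HDRS of 0")


def relative_change(baseline: float, followup: float) -> float:
    """Relative HDRS improvement from baseline to follow-up.

    Returns ``(baseline - followup) / baseline``: 0.5 means the score
    halved, negative values mean worsening.
    """
    _check_scores(baseline, followup)
    return (baseline - followup) / baseline


def label_outcome(baseline: float, followup: float) -> OutcomeLabel:
    """PO iff the relative reduction is >= 50 % (boundary inclusive)."""
    rc = relative_change(baseline, followup)
    return OutcomeLabel("PO" if rc >= PO_THRESHOLD else "NO", rc)


def derive_outcome_labels(cohort: Cohort, patient_group: str | None = None) -> pd.DataFrame:
    """Outcome labels for every subject with a follow-up score.

    Subjects without a follow-up assessment (drop-outs, controls) are
    excluded (complete-case analysis).  If ``patient_group`` is given,
    only subjects of that group are considered.
    """
    df = cohort.clinical
    if patient_group is not None:
        df = df[df["group"] == patient_group]
    df = df.dropna(subset=["hdrs_followup"])
    labels, changes = [], []
    for b, f in zip(df["hdrs_baseline"], df["hdrs_followup"]):
        lab = label_outcome(float(b), float(f))
        labels.append(lab.value)
        changes.append(lab.relative_change)
    return pd.DataFrame(
        {
            "subject_id": df["subject_id"].to_numpy(),
            "outcome": labels,
            "relative_change": changes,
        }
    )
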