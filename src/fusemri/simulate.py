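"""Synthetic cohort generator.

The clinical data behind the depression diagnosis / outcome-prediction
study cannot be shared, so every downstream stage of the pipeline is
exercised on synthetic cohorts that reproduce the *statistical structure*
the analysis assumes:

- two groups of subjects (healthy controls vs patients, or positive vs
  negative 6-month outcome) with configurable sizes;
- eleven tabular feature sets with the canonical element counts (region
  volumes and cortical thickness, hippocampal/amygdalar subfield volumes,
  five 3486-element white-matter edge-metric sets, task-activation
  contrasts, and three resting-state network-interaction sets);
- planted group effects: chosen elements differ between groups by a
  standardized effect size d, all other elements are exchangeable;
- Gaussian marginals with equicorrelation rho inside each set, matching
  the mean-shift structure the univariate t / rank-sum screen assumes;
- HDRS symptom scores (0-52 integer scale) at baseline and 6-month
  follow-up, generated so that the >= 50 % reduction rule recovers a
  chosen outcome assignment up to a configurable label-noise rate;
- coupled-oscillator resting-state network time series: each network is
  unit-variance noise, and coupled pairs share a band-limited component
  with a controlled phase lag, which yields band-limited wavelet
  coherence with a known leader.

A single master seed expands into per-stage child streams (see
:mod:`fusemri.seeds`), so generation is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Cohort, FeatureSet
from .errors import ParameterError
from .seeds import child_rng

__all__ = [
    "Coupling",
    "TimeSeriesSpec",
    "HdrsModel",
    "SyntheticSpec",
    "STUDY_SET_DIMS",
    "DIAGNOSIS_GROUPS",
    "OUTCOME_GROUPS",
    "generate_feature_tables",
    "generate_cohort",
    "generate_hdrs",
    "generate_rsn_timeseries",
    "generate_cohort_timeseries",
]

#: Canonical element counts of the eleven feature sets.
STUDY_SET_DIMS = {
    "T1": 113,       # subcortical volumes + cortical thickness
    "T2": 66,        # hippocampal subfields + amygdalar nuclei
    "MD": 3486,      # C(84, 2) white-matter edge metrics
    "FA": 3486,
    "AD": 3486,
    "RD": 3486,
    "sSW": 3486,
    "Act": 22,       # 11 ROIs x 2 task contrasts
    "sFC": 105,      # C(15, 2) static network correlations
    "nCC": 105,      # coherence-cluster counts per network pair
    "leadCoh": 210,  # 15 x 14 directed lead-coherence values
}

#: (group A, group B, n_A, n_B) for the two classification tasks.
DIAGNOSIS_GROUPS = ("HC", "MDD", 31, 32)
OUTCOME_GROUPS = ("NO", "PO", 19, 12)


@dataclass
class Coupling:
    """A shared band-limited component between two networks.

    ``phase_lag`` (radians) is the phase by which the first network of
    ``pair`` leads the second at the band's center frequency; the lag is
    imposed as a time delay ``phase_lag / (2 pi freq)``.  ``strength`` is
    the amplitude of the shared component relative to the unit-variance
    private noise.
    """

    pair: tuple
    freq: float
    phase_lag: float = 0.0
    strength: float = 1.0
    rel_bandwidth: float = 0.25


@dataclass
class TimeSeriesSpec:
    n_networks: int = 15
    n_samples: int = 400
    dt: float = 1.35  # sampling interval (s)
    couplings: list = field(default_factory=list)

    def validate(self) -> None:
        if self.n_networks < 2:
            raise ParameterError("need at least 2 networks")
        if self.n_samples < 64:
            raise ParameterError("need at least 64 samples")
        if self.dt <= 0:
            raise ParameterError("sampling interval must be positive")
        nyquist = 0.5 / self.dt
        for c in self.couplings:
            i, j = c.pair
            if not (0 <= i < self.n_networks and 0 <= j < self.n_networks) or i == j:
                raise ParameterError(f"invalid coupled pair {c.pair}")
            if not (0 < c.freq < nyquist):
                raise ParameterError(
                    f"coupling band {c.freq} Hz outside (0, Nyquist={nyquist:.4g}) Hz"
                )


@dataclass
class HdrsModel:
    """Distributional model of the HDRS scores (0-52 integer scale)."""

    baseline_mean: float = 24.4
    baseline_sd: float = 4.62
    po_reduction_mean: float = 0.70   # relative reduction for positive outcome
    po_reduction_sd: float = 0.12
    no_reduction_mean: float = 0.20
    no_reduction_sd: float = 0.18
    label_noise: float = 0.0          # fraction of subjects whose scores flip the label


@dataclass
class SyntheticSpec:
    """Full description of a synthetic two-group cohort.

    ``informative`` maps a set name to a list of ``(element_index,
    effect_size_d, sign)`` triples: in group B the element mean is shifted
    by ``sign * d`` marginal standard deviations relative to group A.
    """

    n_group_a: int = 31
    n_group_b: int = 32
    group_names: tuple = ("A", "B")
    set_dims: dict = field(default_factory=lambda: dict(STUDY_SET_DIMS))
    informative: dict = field(default_factory=dict)
    within_set_correlation: float = 0.1
    hdrs_model: HdrsModel = field(default_factory=HdrsModel)
    ts_spec: TimeSeriesSpec | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ParameterError("both groups need at least one subject")
        if not (0 <= self.within_set_correlation < 1):
            raise ParameterError("within-set correlation must be in [0, 1)")
        for name, dim in self.set_dims.items():
            if dim < 1:
                raise ParameterError(f"set {name!r} has non-positive dimension")
        for name, items in self.informative.items():
            if name not in self.set_dims:
                raise ParameterError(f"informative entries for unknown set {name!r}")
            for idx, d, _sign in items:
                if not 0 <= idx < self.set_dims[name]:
                    raise IndexError(
                        f"informative element {idx} out of range for set {name!r} "
                        f"({self.set_dims[name]} elements)"
                    )
                if not np.isfinite(d):
                    raise ParameterError("effect size must be finite")
        if self.ts_spec is not None:
            self.ts_spec.validate()

    @property
    def n_subjects(self) -> int:
        return self.n_group_a + self.n_group_b

    def subject_ids(self) -> list:
        return [f"S{i + 1:03d}" for i in range(self.n_subjects)]

    def group_vector(self) -> np.ndarray:
        a, b = self.group_names
        return np.array([a] * self.n_group_a + [b] * self.n_group_b)


def generate_feature_tables(spec: SyntheticSpec) -> dict:
    """Generate one FeatureSet per entry of ``spec.set_dims``.

    Marginals are standard normal with equicorrelation rho inside a set
    (one shared standard-normal factor per subject and set, weight
    sqrt(rho)); informative elements get a mean shift of ``sign * d`` in
    group B.  Reproducible bit-for-bit under a fixed ``spec.seed``.
    """
    spec.validate()
    ids = spec.subject_ids()
    group_b = np.zeros(spec.n_subjects, dtype=bool)
    group_b[spec.n_group_a:] = True
    rho = spec.within_set_correlation
    out = {}
    for name, dim in spec.set_dims.items():
        rng = child_rng(spec.seed, "features", name)
        shared = rng.standard_normal((spec.n_subjects, 1))
        noise = rng.standard_normal((spec.n_subjects, dim))
        X = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
        for idx, d, sign in spec.informative.get(name, []):
            X[group_b, idx] += float(sign) * float(d)
        cols = [f"{name}_e{j:04d}" for j in range(dim)]
        out[name] = FeatureSet(name, pd.DataFrame(X, index=ids, columns=cols))
    return out


def generate_hdrs(spec: SyntheticSpec, outcome_assignment) -> pd.DataFrame:
    """Baseline / follow-up HDRS scores for a given PO/NO assignment.

    ``outcome_assignment`` holds ``"PO"`` or ``"NO"`` per subject.  Scores
    are drawn on a continuous scale, rounded to the integer instrument and
    clipped to [0, 52].  With ``label_noise == 0`` the >= 50 % reduction
    rule recovers the assignment exactly (the follow-up score is clamped
    to the correct side of the threshold after rounding); with noise rate
    p a Bernoulli(p) subset is generated on the wrong side.
    """
    m = spec.hdrs_model
    assignment = np.asarray(outcome_assignment)
    bad = set(np.unique(assignment)) - {"PO", "NO"}
    if bad:
        raise ParameterError(f"outcome assignment must be PO/NO, got {sorted(bad)}")
    n = assignment.size
    rng = child_rng(spec.seed, "hdrs")
    baseline = np.clip(np.round(rng.normal(m.baseline_mean, m.baseline_sd, n)), 1, 52)
    flip = rng.random(n) < m.label_noise
    effective_po = (assignment == "PO") ^ flip
    red_po = rng.normal(m.po_reduction_mean, m.po_reduction_sd, n)
    red_no = rng.normal(m.no_reduction_mean, m.no_reduction_sd, n)
    reduction = np.where(effective_po, red_po, red_no)
    followup = np.clip(np.round(baseline * (1.0 - reduction)), 0, 52)
    # rounding can push a score across the 50 % boundary; clamp back so the
    # effective label is encoded exactly in the integer scores
    half = baseline / 2.0
    po_bad = effective_po & (followup > half)
    followup[po_bad] = np.floor(half[po_bad])
    no_bad = ~effective_po & (followup <= half)
    followup[no_bad] = np.minimum(np.floor(half[no_bad]) + 1, 52)
    return pd.DataFrame(
        {"hdrs_baseline": baseline, "hdrs_followup": followup}
    )


def generate_cohort(spec: SyntheticSpec, task: str = "diagnosis") -> Cohort:
    """Clinical table for the cohort described by ``spec``.

    For ``task='diagnosis'`` group A plays the healthy-control role
    (baseline near zero, no follow-up) and group B the patient role.  For
    ``task='outcome'`` group A is the negative-outcome and group B the
    positive-outcome group, and the HDRS scores encode the assignment.
    """
    spec.validate()
    ids = spec.subject_ids()
    groups = spec.group_vector()
    if task == "outcome":
        assignment = np.where(groups == spec.group_names[1], "PO", "NO")
        scores = generate_hdrs(spec, assignment)
        clinical = pd.DataFrame(
            {
                "subject_id": ids,
                "group": assignment,
                "hdrs_baseline": scores["hdrs_baseline"].to_numpy(),
                "hdrs_followup": scores["hdrs_followup"].to_numpy(),
            }
        )
        return Cohort(clinical, groups=("NO", "PO"))
    if task != "diagnosis":
        raise ParameterError(f"unknown task {task!r}")
    rng = child_rng(spec.seed, "hdrs-controls")
    m = spec.hdrs_model
    is_b = groups == spec.group_names[1]
    baseline = np.where(
        is_b,
        np.clip(np.round(rng.normal(m.baseline_mean, m.baseline_sd, len(ids))), 1, 52),
        np.clip(np.round(rng.normal(0.67, 1.37, len(ids))), 0, 52),
    )
    clinical = pd.DataFrame(
        {
            "subject_id": ids,
            "group": np.where(is_b, "MDD", "HC"),
            "hdrs_baseline": baseline,
            "hdrs_followup": np.nan,
        }
    )
    return Cohort(clinical, groups=("HC", "MDD"))


def _bandlimited_noise(rng: np.random.Generator, n: int, dt: float,
                       freq: float, rel_bandwidth: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed around ``freq`` Hz."""
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, d=dt)
    window = np.exp(-0.5 * ((f - freq) / (rel_bandwidth * freq)) ** 2)
    sig = np.fft.irfft(np.fft.rfft(white) * window, n)
    sd = sig.std()
    if sd == 0:  # pragma: no cover - requires pathological window
        raise ParameterError("degenerate coupling band")
    return sig / sd


def _delay(sig: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """Delay a (periodic) signal by ``tau`` seconds via its spectrum."""
    n = sig.size
    f = np.fft.rfftfreq(n, d=dt)
    return np.fft.irfft(np.fft.rfft(sig) * np.exp(-2j * np.pi * f * tau), n)


def generate_rsn_timeseries(ts_spec: TimeSeriesSpec, seed: int,
                            subject: int = 0) -> np.ndarray:
    """One subject's (n_networks x n_samples) resting-state series.

    Each network is private unit-variance white noise; every coupling adds
    a shared band-limited component to its pair, delayed in the second
    network so the first leads by ``phase_lag`` radians at the band
    center.  Uncoupled pairs are independent.
    """
    ts_spec.validate()
    rng = child_rng(seed, "timeseries", subject)
    n_net, n = ts_spec.n_networks, ts_spec.n_samples
    series = rng.standard_normal((n_net, n))
    for c in ts_spec.couplings:
        i, j = c.pair
        shared = _bandlimited_noise(rng, n, ts_spec.dt, c.freq, c.rel_bandwidth)
        tau = c.phase_lag / (2.0 * np.pi * c.freq)
        series[i] += c.strength * shared
        series[j] += c.strength * _delay(shared, ts_spec.dt, tau)
    return series


def generate_cohort_timeseries(spec: SyntheticSpec) -> dict:
    """Per-subject RSN series keyed by subject id."""
    if spec.ts_spec is None:
        raise ParameterError("spec has no time-series component")
    spec.validate()
    return {
        sid: generate_rsn_timeseries(spec.ts_spec, spec.seed, subject=i)
        for i, sid in enumerate(spec.subject_ids())
    }
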