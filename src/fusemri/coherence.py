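"""Resting-state network-interaction features.

From 15 labeled resting-state network (RSN) time series per subject,
three feature sets are computed:

- **sFC** (static functional connectivity): Fisher-z transformed Pearson
  correlation per unordered network pair (105 elements for 15 networks).
- **nCC** (number of coherence clusters): per unordered pair, the number
  of connected regions of significant wavelet coherence on the
  time-scale plane, split by interaction kind (in-phase, out-of-phase,
  leading, lagging), capturing how many distinct episodes of interaction
  the pair shows (105 elements).
- **leadCoh** (lead coherence): per *ordered* pair, the extent to which
  the source network leads the target in phase over the significant
  cells; the matrix is not symmetric (210 elements).

Wavelet coherence uses a complex Morlet mother wavelet with scales
spanning the 0.01-0.2 Hz band of the fMRI band-pass filter, smoothing in
time (Gaussian, width proportional to scale) and across scales (boxcar)
before forming the magnitude-squared coherence.  Cells inside the cone
of influence are excluded.  Significance defaults to a per-scale
Monte-Carlo threshold (the 95th percentile of coherence between
independent white-noise series on the same grid, cached per grid
configuration), so that on null data about 5 % of usable cells are
flagged.  A fixed numeric cutoff can be configured instead.

Phase convention: ``phase > 0`` means the first series of the pair leads
(its band-limited content occurs earlier in time).

The module also vectorizes symmetric 84 x 84 edge-metric matrices
(white-matter tract measures) into the 3486-element upper-triangle
feature vectors used by the diffusion feature sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage

from .containers import FeatureSet
from .errors import DegenerateSeriesError, ParameterError, SchemaError

__all__ = [
    "WcaParams",
    "CoherenceMap",
    "NETWORK_NAMES",
    "static_fc",
    "wavelet_coherence",
    "count_coherence_clusters",
    "lead_coherence",
    "subject_network_features",
    "network_feature_tables",
    "vectorize_edge_matrix",
    "unvectorize_edge_matrix",
    "pair_labels",
    "directed_pair_labels",
]

#: Canonical ordering of the 15 resting-state networks; defines element
#: order for every pairwise feature.
NETWORK_NAMES = [
    "pVN", "latVN", "oVN", "DMN", "aDMN", "pDMN", "CN", "SMN",
    "latSMN", "AN", "lFPN", "rFPN", "SN", "BN", "DAN",
]

_FISHER_CAP = 1.0 - 1e-6


@dataclass
class WcaParams:
    """Wavelet-coherence configuration.

    ``threshold`` is either ``"mc"`` (per-scale Monte-Carlo null
    quantile, the default) or a fixed coherence cutoff in (0, 1).
    ``leadcoh_mode`` selects whether lead coherence aggregates a binary
    lead indicator (fraction of significant cells where the source
    leads) or a phase-weighted extent.
    """

    dt: float = 1.35
    fmin: float = 0.01
    fmax: float = 0.2
    n_scales: int = 24
    wavelet: str = "cmor1.5-1.0"
    time_smooth: float = 1.0
    scale_smooth: int = 3
    threshold: object = "mc"
    mc_quantile: float = 0.95
    n_null: int = 20
    leadcoh_mode: str = "binary"

    def validate(self) -> None:
        if not 0 < self.fmin < self.fmax:
            raise ParameterError("need 0 < fmin < fmax")
        nyquist = 0.5 / self.dt
        if self.fmax > nyquist:
            raise ParameterError(
                f"fmax {self.fmax} Hz above Nyquist {nyquist:.4g} Hz"
            )
        if isinstance(self.threshold, (int, float)) and not 0 < self.threshold < 1:
            raise ParameterError("fixed coherence threshold must be in (0, 1)")
        if self.leadcoh_mode not in ("binary", "weighted"):
            raise ParameterError(f"unknown leadcoh mode {self.leadcoh_mode!r}")

    def scales(self) -> np.ndarray:
        """Wavelet scales (in samples), small to large (fmax -> fmin)."""
        fc = pywt.central_frequency(self.wavelet)
        freqs = np.geomspace(self.fmax, self.fmin, self.n_scales)
        return fc / (freqs * self.dt)

    def frequencies(self) -> np.ndarray:
        fc = pywt.central_frequency(self.wavelet)
        return fc / (self.scales() * self.dt)


@dataclass
class CoherenceMap:
    """Time-scale coherence between an ordered pair of series."""

    pair: tuple
    frequencies: np.ndarray    # Hz, one per scale row
    magnitude: np.ndarray      # (n_scales, n_times), in [0, 1]
    phase: np.ndarray          # radians, >0 = first series leads
    valid: np.ndarray          # bool, outside the cone of influence
    significant: np.ndarray    # bool, valid and above threshold

    def swapped(self) -> "CoherenceMap":
        """The reverse-direction map: same magnitude, negated phase."""
        return CoherenceMap(
            (self.pair[1], self.pair[0]), self.frequencies, self.magnitude,
            -self.phase, self.valid, self.significant,
        )


def _check_series(series: np.ndarray) -> np.ndarray:
    series = np.asarray(series, dtype=np.float64)
    if series.ndim == 1:
        series = series[None, :]
    if np.any(series.std(axis=1) == 0):
        ch = int(np.where(series.std(axis=1) == 0)[0][0])
        raise DegenerateSeriesError(f"channel {ch} is constant")
    return series


def static_fc(series: np.ndarray, cap: float = _FISHER_CAP):
    """Fisher-z correlations over unordered network pairs.

    Element order is the row-major upper triangle of the correlation
    matrix under the fixed network ordering.  |r| is capped below 1 so
    the transform stays finite for (near-)identical series.
    """
    series = _check_series(series)
    r = np.corrcoef(series)
    iu = np.triu_indices(series.shape[0], k=1)
    vals = np.clip(r[iu], -cap, cap)
    return np.arctanh(vals)


def _cwt(x: np.ndarray, scales: np.ndarray, wavelet: str) -> np.ndarray:
    coef, _ = pywt.cwt(x, scales, wavelet)
    return coef


def _smooth_rows(F: np.ndarray, scales: np.ndarray, time_smooth: float,
                 scale_smooth: int) -> np.ndarray:
    out = np.empty_like(F)
    for k, s in enumerate(scales):
        sigma = max(time_smooth * s, 0.5)
        out[k] = ndimage.gaussian_filter1d(F[k], sigma, mode="reflect")
    if scale_smooth > 1:
        out = ndimage.uniform_filter1d(out, scale_smooth, axis=0, mode="nearest")
    return out


def _smooth(F: np.ndarray, scales, time_smooth, scale_smooth) -> np.ndarray:
    if np.iscomplexobj(F):
        return (
            _smooth_rows(F.real, scales, time_smooth, scale_smooth)
            + 1j * _smooth_rows(F.imag, scales, time_smooth, scale_smooth)
        )
    return _smooth_rows(F, scales, time_smooth, scale_smooth)


def _coi_mask(n_times: int, scales: np.ndarray) -> np.ndarray:
    """True where the cell lies outside the cone of influence."""
    t = np.arange(n_times)
    edge_dist = np.minimum(t, n_times - 1 - t)
    return edge_dist[None, :] >= np.sqrt(2.0) * scales[:, None]


def _coherence_from_cwt(Wx, Wy, Sxx, Syy, params: WcaParams, scales):
    cross = _smooth(Wx * np.conj(Wy), scales, params.time_smooth, params.scale_smooth)
    with np.errstate(divide="ignore", invalid="ignore"):
        mag2 = np.abs(cross) ** 2 / (Sxx * Syy)
    mag = np.sqrt(np.clip(mag2, 0.0, 1.0))
    phase = np.angle(cross)
    return mag, phase


_MC_CACHE: dict = {}


def _mc_threshold(n_times: int, params: WcaParams) -> np.ndarray:
    """Per-scale null coherence quantile for independent white noise.

    Estimated once per grid configuration from ``n_null`` pairs of
    white-noise series with a fixed internal seed, then cached.
    """
    key = (
        n_times, params.dt, params.fmin, params.fmax, params.n_scales,
        params.wavelet, params.time_smooth, params.scale_smooth,
        params.mc_quantile, params.n_null,
    )
    if key in _MC_CACHE:
        return _MC_CACHE[key]
    scales = params.scales()
    valid = _coi_mask(n_times, scales)
    rng = np.random.default_rng(np.random.SeedSequence(20240501))
    pooled = [[] for _ in range(params.n_scales)]
    for _ in range(params.n_null):
        x = rng.standard_normal(n_times)
        y = rng.standard_normal(n_times)
        Wx = _cwt(x, scales, params.wavelet)
        Wy = _cwt(y, scales, params.wavelet)
        Sxx = _smooth(np.abs(Wx) ** 2, scales, params.time_smooth, params.scale_smooth)
        Syy = _smooth(np.abs(Wy) ** 2, scales, params.time_smooth, params.scale_smooth)
        mag, _ = _coherence_from_cwt(Wx, Wy, Sxx, Syy, params, scales)
        for k in range(params.n_scales):
            pooled[k].append(mag[k, valid[k]])
    thr = np.array(
        [np.quantile(np.concatenate(cells), params.mc_quantile) for cells in pooled]
    )
    _MC_CACHE[key] = thr
    return thr


def _threshold(n_times: int, params: WcaParams) -> np.ndarray:
    if params.threshold == "mc":
        return _mc_threshold(n_times, params)
    return np.full(params.n_scales, float(params.threshold))


def _make_map(pair, Wx, Wy, Sxx, Syy, params: WcaParams, scales, valid, thr):
    mag, phase = _coherence_from_cwt(Wx, Wy, Sxx, Syy, params, scales)
    significant = valid & (mag >= thr[:, None])
    return CoherenceMap(pair, params.frequencies(), mag, phase, valid, significant)


def wavelet_coherence(x: np.ndarray, y: np.ndarray,
                      params: WcaParams | None = None) -> CoherenceMap:
    """Wavelet coherence magnitude/phase between two equal-length series."""
    params = params or WcaParams()
    params.validate()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("series must be two equal-length vectors")
    _check_series(np.vstack([x, y]))
    scales = params.scales()
    n = x.size
    if n <= 2 * np.sqrt(2.0) * scales.max():
        raise ParameterError(
            "series shorter than the support of the largest scale; "
            "raise fmin or lengthen the series"
        )
    Wx = _cwt(x, scales, params.wavelet)
    Wy = _cwt(y, scales, params.wavelet)
    Sxx = _smooth(np.abs(Wx) ** 2, scales, params.time_smooth, params.scale_smooth)
    Syy = _smooth(np.abs(Wy) ** 2, scales, params.time_smooth, params.scale_smooth)
    valid = _coi_mask(n, scales)
    thr = _threshold(n, params)
    return _make_map((0, 1), Wx, Wy, Sxx, Syy, params, scales, valid, thr)


# phase categories: 0 in-phase, 1 leading, 2 lagging, 3 out-of-phase
def _phase_category(phase: np.ndarray) -> np.ndarray:
    cat = np.empty(phase.shape, dtype=np.int8)
    absp = np.abs(phase)
    cat[absp < np.pi / 4] = 0
    cat[absp > 3 * np.pi / 4] = 3
    mid = (absp >= np.pi / 4) & (absp <= 3 * np.pi / 4)
    cat[mid & (phase > 0)] = 1
    cat[mid & (phase <= 0)] = 2
    return cat


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def count_coherence_clusters(cmap: CoherenceMap) -> int:
    """Number of distinct significant-interaction clusters.

    Connected components (4-neighbour connectivity) of the significant
    mask, with components split by interaction kind: cells of different
    phase categories never join a cluster.
    """
    if not cmap.significant.any():
        return 0
    cat = _phase_category(cmap.phase)
    total = 0
    for c in range(4):
        mask = cmap.significant & (cat == c)
        if mask.any():
            _, n = ndimage.label(mask, structure=_FOUR_CONN)
            total += n
    return int(total)


def lead_coherence(cmap: CoherenceMap, mode: str = "binary") -> float:
    """Directed lead extent of the map's first series over its second.

    ``binary``: fraction of significant cells with positive phase (the
    source leads).  ``weighted``: mean positive part of sin(phase), which
    weights a cell by how far the source is ahead.  Returns 0 when no
    cell is significant.
    """
    sig = cmap.significant
    if not sig.any():
        return 0.0
    ph = cmap.phase[sig]
    if mode == "binary":
        return float(np.mean(ph > 0))
    if mode == "weighted":
        return float(np.mean(np.maximum(np.sin(ph), 0.0)))
    raise ParameterError(f"unknown leadcoh mode {mode!r}")


def pair_labels(names=None) -> list:
    names = list(names) if names is not None else list(NETWORK_NAMES)
    n = len(names)
    return [f"{names[i]}|{names[j]}" for i in range(n) for j in range(i + 1, n)]


def directed_pair_labels(names=None) -> list:
    names = list(names) if names is not None else list(NETWORK_NAMES)
    n = len(names)
    return [f"{names[i]}->{names[j]}" for i in range(n) for j in range(n) if i != j]


def subject_network_features(series: np.ndarray,
                             params: WcaParams | None = None) -> dict:
    """sFC / nCC / leadCoh vectors for one subject's network series.

    The wavelet transform of each network is computed once and reused
    across the 105 unordered (and 210 directed) pairs.
    """
    params = params or WcaParams()
    params.validate()
    series = _check_series(series)
    n_net, n = series.shape
    scales = params.scales()
    if n <= 2 * np.sqrt(2.0) * scales.max():
        raise ParameterError("series too short for the largest scale")
    sfc = static_fc(series)
    W = [_cwt(series[i], scales, params.wavelet) for i in range(n_net)]
    S = [
        _smooth(np.abs(w) ** 2, scales, params.time_smooth, params.scale_smooth)
        for w in W
    ]
    valid = _coi_mask(n, scales)
    thr = _threshold(n, params)
    ncc = []
    lead = np.full((n_net, n_net), np.nan)
    for i in range(n_net):
        for j in range(i + 1, n_net):
            cmap = _make_map((i, j), W[i], W[j], S[i], S[j], params, scales, valid, thr)
            ncc.append(count_coherence_clusters(cmap))
            lead[i, j] = lead_coherence(cmap, params.leadcoh_mode)
            lead[j, i] = lead_coherence(cmap.swapped(), params.leadcoh_mode)
    leadcoh = np.array(
        [lead[i, j] for i in range(n_net) for j in range(n_net) if i != j]
    )
    return {"sFC": sfc, "nCC": np.array(ncc, dtype=float), "leadCoh": leadcoh}


def network_feature_tables(series_by_subject: dict,
                           params: WcaParams | None = None,
                           network_names=None) -> dict:
    """FeatureSets (sFC, nCC, leadCoh) for a cohort of network series."""
    names = list(network_names) if network_names is not None else list(NETWORK_NAMES)
    rows = {"sFC": [], "nCC": [], "leadCoh": []}
    ids = list(series_by_subject)
    for sid in ids:
        feats = subject_network_features(series_by_subject[sid], params)
        for key in rows:
            rows[key].append(feats[key])
    labels = {
        "sFC": pair_labels(names),
        "nCC": pair_labels(names),
        "leadCoh": directed_pair_labels(names),
    }
    return {
        key: FeatureSet(key, pd.DataFrame(np.vstack(rows[key]), index=ids,
                                          columns=labels[key]))
        for key in rows
    }


def vectorize_edge_matrix(matrix: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Row-major upper-triangle vector of a symmetric edge-metric matrix.

    84 regions -> 3486 elements.  The diagonal is ignored; asymmetry
    beyond ``tol`` is a format error.
    """
    M = np.asarray(matrix, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise SchemaError("edge matrix must be square")
    if not np.allclose(M, M.T, atol=tol, rtol=0):
        raise SchemaError("edge matrix is asymmetric beyond tolerance")
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def unvectorize_edge_matrix(vector: np.ndarray, diag: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_edge_matrix` (diagonal set to ``diag``)."""
    vector = np.asarray(vector, dtype=np.float64)
    m = vector.size
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n * (n - 1) // 2 != m:
        raise SchemaError(f"vector length {m} is not a triangular number")
    M = np.full((n, n), diag)
    iu = np.triu_indices(n, k=1)
    M[iu] = vector
    M[(iu[1], iu[0])] = vector
    return M
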