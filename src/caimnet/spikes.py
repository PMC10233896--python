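"""Spike inference by sparse nonnegative AR(1) deconvolution.

The calcium trace is modelled as an autoregressive process driven by spike
impulses, c(t) = gamma*c(t-1) + s(t) with s(t) >= 0, observed as
y(t) = c(t) + noise. Deconvolution minimises

    1/2 * sum_t (c_t - y_t)^2 + lambda * sum_t s_t

over nonnegative spike signals by an online pool-merging active-set scheme
(pool adjacent violators generalised to the AR(1) constraint). In the
thresholded variant, jumps are additionally constrained to be either 0 or at
least ``s_min``: pools whose boundary jump falls below ``s_min`` are merged
during the sweep rather than deleted afterwards, so the reconstruction stays
self-consistent. For ``s_min = 0`` the problem is convex and the sweep
returns the exact optimum.

Spike onsets are the bins whose deconvolved jump reaches ``s_min``; the
module also derives per-cell activity statistics (firing rate, inter-spike
intervals, bursts defined as concatenated spikes with gaps below 1 s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import NormalizedTraces, SpikeTrainSet

__all__ = [
    "DeconvolutionParams",
    "CellActivityFeatures",
    "estimate_ar_coefficient",
    "deconvolve_trace",
    "deconvolution_objective",
    "deconvolve_recording",
    "build_raster",
    "cell_activity_features",
]


@dataclass
class DeconvolutionParams:
    """Parameters of the thresholded AR(1) deconvolution.

    ``gamma`` is the per-frame decay of the calcium kernel ("auto" estimates
    it from the trace autocovariance); ``lambda_`` the l1 sparsity weight and
    ``s_min`` the minimum accepted spike signal, both in the %DFF units of
    the trace. ``baseline`` is the flat resting level subtracted before
    solving ("auto" uses the trace median, which for sparsely active cells
    estimates the resting %DFF level; any residual positive offset would
    otherwise be tracked by a stream of spurious small jumps).
    """

    gamma: float | str = "auto"
    lambda_: float = 5.0
    s_min: float = 0.3
    baseline: float | str = "auto"
    merge_adjacent_onsets: bool = True
    fallback_gamma: float = 0.9

    def validate(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.s_min < 0:
            raise ValueError("s_min must be >= 0")
        if self.gamma != "auto" and not 0.0 < float(self.gamma) < 1.0:
            raise ValueError("gamma must be in (0, 1) or 'auto'")


@dataclass
class CellActivityFeatures:
    """Single-cell spike and burst descriptors."""

    firing_rate_hz: float
    isi_s: np.ndarray
    burst_rate_hz: float
    spikes_per_burst: np.ndarray
    isi_in_burst_s: np.ndarray
    ibi_s: np.ndarray
    burst_duration_s: np.ndarray
    burst_amplitude: np.ndarray
    n_spikes: int
    n_bursts: int


def estimate_ar_coefficient(
    dff_trace: np.ndarray,
    fs_hz: float,
    fallback: float = 0.9,
) -> float:
    """AR(1) coefficient from the lag-2 / lag-1 autocovariance ratio.

    For an AR(1) signal observed in white noise the noise inflates only the
    lag-0 term, so acov(2)/acov(1) is a noise-robust estimate of gamma. A
    flat or non-identifiable trace returns ``fallback`` with a warning.
    """
    x = np.asarray(dff_trace, dtype=float)
    if x.size < 200:
        raise ValueError("need at least 200 frames to estimate gamma")
    x = x - x.mean()
    ac0 = float(np.dot(x, x))
    if ac0 <= 0:
        warnings.warn("gamma not identifiable from flat trace; using fallback")
        return fallback
    ac1 = float(np.dot(x[:-1], x[1:]))
    ac2 = float(np.dot(x[:-2], x[2:]))
    # no significant lag-1 structure (white noise): report 0, not the ratio
    if ac1 <= 3.0 * ac0 / np.sqrt(x.size):
        return 0.0
    g = ac2 / ac1
    if g <= 0.0:
        return 0.0
    if g >= 1.0:
        warnings.warn("gamma estimate outside (0,1); using fallback")
        return fallback
    return g


def _oasis_pools(y: np.ndarray, gamma: float, s_min: float) -> list[list[float]]:
    """One forward sweep of pool merging; returns [value, weight, start, length]."""
    pools: list[list[float]] = []
    for t in range(y.size):
        pools.append([float(y[t]), 1.0, t, 1])
        while len(pools) > 1:
            v2, w2, t2, l2 = pools[-1]
            v1, w1, t1, l1 = pools[-2]
            f = gamma**l1
            if v2 >= f * v1 + s_min:
                break
            wnew = w1 + f * f * w2
            vnew = (w1 * v1 + f * w2 * v2) / wnew
            pools[-2] = [vnew, wnew, t1, l1 + l2]
            pools.pop()
    return pools


def deconvolve_trace(
    dff_trace: np.ndarray,
    params: DeconvolutionParams | None = None,
    fs_hz: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deconvolve one %DFF trace.

    Returns ``(denoised, spike_signal, onset_bins)``: the AR(1)
    reconstruction plus the fitted flat baseline, the deconvolved jumps s
    (s[0] is the initial level, not a spike), and the bins t >= 1 with
    s[t] >= s_min (or s[t] > 0 when ``s_min == 0``).
    """
    params = params or DeconvolutionParams()
    params.validate()
    y = np.asarray(dff_trace, dtype=float)
    if y.ndim != 1:
        raise ValueError("dff_trace must be 1-D")
    if params.gamma == "auto":
        if fs_hz is None:
            raise ValueError("fs_hz required for gamma='auto'")
        try:
            gamma = estimate_ar_coefficient(y, fs_hz, params.fallback_gamma)
        except ValueError:
            gamma = params.fallback_gamma
        if not 0.0 < gamma < 1.0:  # structureless trace: any kernel works
            gamma = params.fallback_gamma
    else:
        gamma = float(params.gamma)
    T = y.size
    if T == 0:
        z = np.zeros(0)
        return z, z.copy(), np.zeros(0, dtype=int)
    b = float(np.median(y)) if params.baseline == "auto" else float(params.baseline)
    y = y - b

    # absorb the l1 penalty into the data: lambda * sum(s) = lambda * (G^T 1) . c
    yp = y - params.lambda_ * (1.0 - gamma)
    yp[-1] = y[-1] - params.lambda_

    pools = _oasis_pools(yp, gamma, params.s_min)

    # clamping a negative pool to zero can leave the next boundary jump in
    # (0, s_min); re-merge such pools so the hard threshold really holds
    if params.s_min > 0:
        changed = True
        while changed and len(pools) > 1:
            changed = False
            for i in range(len(pools) - 1):
                v1, w1, t1, l1 = pools[i]
                v2, w2, t2, l2 = pools[i + 1]
                jump = v2 - gamma**l1 * max(v1, 0.0)
                if 1e-12 < jump < params.s_min - 1e-12:
                    f = gamma**l1
                    wnew = w1 + f * f * w2
                    vnew = (w1 * v1 + f * w2 * v2) / wnew
                    pools[i] = [vnew, wnew, t1, l1 + l2]
                    pools.pop(i + 1)
                    changed = True
                    break

    c = np.zeros(T)
    for v, _w, t, l in pools:
        v = max(v, 0.0)
        c[t : t + l] = v * gamma ** np.arange(l)
    s = np.empty(T)
    s[0] = c[0]
    s[1:] = c[1:] - gamma * c[:-1]
    s[np.abs(s) < 1e-12] = 0.0
    if params.s_min > 0:
        onsets = np.flatnonzero(s[1:] >= params.s_min - 1e-12) + 1
    else:
        onsets = np.flatnonzero(s[1:] > 1e-12) + 1
    if params.merge_adjacent_onsets and onsets.size > 1:
        # pre-smoothed traces spread one spike's jump over several frames;
        # a run of consecutive onset bins is a single spike event
        keep = np.ones(onsets.size, dtype=bool)
        keep[1:] = np.diff(onsets) > 1
        onsets = onsets[keep]
    return c + b, s, onsets


def deconvolution_objective(
    y: np.ndarray, c: np.ndarray, gamma: float, lambda_: float
) -> float:
    """1/2 ||c - y||^2 + lambda * sum(s) for the AR(1) jump signal of ``c``."""
    y = np.asarray(y, dtype=float)
    c = np.asarray(c, dtype=float)
    s = np.empty_like(c)
    s[0] = c[0]
    s[1:] = c[1:] - gamma * c[:-1]
    return float(0.5 * np.sum((c - y) ** 2) + lambda_ * np.sum(s))


def deconvolve_recording(
    norm: NormalizedTraces,
    params: DeconvolutionParams | None = None,
) -> tuple[SpikeTrainSet, np.ndarray]:
    """Deconvolve every ROI of a normalised recording.

    Returns the spike-train set (with raster) and the frames x ROIs
    spike-signal matrix used for burst amplitudes.
    """
    params = params or DeconvolutionParams()
    n_frames, n_rois = norm.dff.shape
    duration = n_frames / norm.fs_hz
    onset_times: list[np.ndarray] = []
    signal = np.zeros((n_frames, n_rois))
    for i in range(n_rois):
        _c, s, bins = deconvolve_trace(norm.dff[:, i], params, fs_hz=norm.fs_hz)
        signal[:, i] = s
        onset_times.append(bins / norm.fs_hz)
    raster = build_raster(onset_times, norm.fs_hz, duration)
    trains = SpikeTrainSet(
        onsets=onset_times, fs_hz=norm.fs_hz, duration_s=duration, raster=raster
    )
    return trains, signal


def build_raster(
    onsets: list[np.ndarray], fs_hz: float, duration_s: float
) -> np.ndarray:
    """Binary ROIs x bins raster at frame resolution.

    Multiple onsets falling in one frame collapse to a single 1; the onset
    lists retain the full counts.
    """
    n_bins = int(round(duration_s * fs_hz))
    raster = np.zeros((len(onsets), n_bins), dtype=np.uint8)
    for i, o in enumerate(onsets):
        o = np.asarray(o, dtype=float)
        if o.size == 0:
            continue
        if np.any(np.diff(o) < 0):
            raise ValueError(f"onsets for ROI {i} not sorted")
        bins = np.floor(o * fs_hz).astype(int)
        if bins.min() < 0 or bins.max() >= n_bins:
            raise ValueError(f"onset beyond recording for ROI {i}")
        raster[i, bins] = 1
    return raster


def _find_bursts(
    onsets: np.ndarray, burst_gap_s: float, min_burst_spikes: int
) -> list[tuple[int, int]]:
    """Maximal runs of >= min_burst_spikes onsets with gaps strictly < gap."""
    bursts: list[tuple[int, int]] = []
    if onsets.size == 0:
        return bursts
    start = 0
    for k in range(1, onsets.size + 1):
        if k == onsets.size or onsets[k] - onsets[k - 1] >= burst_gap_s:
            if k - start >= min_burst_spikes:
                bursts.append((start, k))
            start = k
    return bursts


def cell_activity_features(
    onsets: np.ndarray,
    duration_s: float,
    spike_signal: np.ndarray | None = None,
    fs_hz: float | None = None,
    burst_gap_s: float = 1.0,
    min_burst_spikes: int = 2,
) -> CellActivityFeatures:
    """Spike/burst descriptors for one cell.

    A burst is a maximal run of at least ``min_burst_spikes`` onsets whose
    consecutive gaps are strictly below ``burst_gap_s``. Burst duration is
    last minus first onset; the inter-burst interval runs from the end of one
    burst to the start of the next; burst amplitude sums the deconvolved
    spike signal over the burst's frames (when a signal is supplied).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    onsets = np.asarray(onsets, dtype=float)
    isi = np.diff(onsets) if onsets.size > 1 else np.array([])
    bursts = _find_bursts(onsets, burst_gap_s, min_burst_spikes)
    durations, counts, isis_in, amps = [], [], [], []
    for a, b in bursts:
        durations.append(onsets[b - 1] - onsets[a])
        counts.append(b - a)
        isis_in.extend(np.diff(onsets[a:b]))
        if spike_signal is not None and fs_hz is not None:
            f0 = int(np.floor(onsets[a] * fs_hz))
            f1 = int(np.floor(onsets[b - 1] * fs_hz)) + 1
            amps.append(float(spike_signal[f0:f1].sum()))
    ibis = [
        onsets[bursts[j + 1][0]] - onsets[bursts[j][1] - 1]
        for j in range(len(bursts) - 1)
    ]
    return CellActivityFeatures(
        firing_rate_hz=onsets.size / duration_s,
        isi_s=isi,
        burst_rate_hz=len(bursts) / duration_s,
        spikes_per_burst=np.asarray(counts, dtype=float),
        isi_in_burst_s=np.asarray(isis_in, dtype=float),
        ibi_s=np.asarray(ibis, dtype=float),
        burst_duration_s=np.asarray(durations, dtype=float),
        burst_amplitude=np.asarray(amps, dtype=float),
        n_spikes=int(onsets.size),
        n_bursts=len(bursts),
    )
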