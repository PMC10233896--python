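"""Global network activity (GNA) and network-burst statistics.

GNA measures collective activation: in a sliding window (2 s wide, 0.5 s
step by default) it counts the neurons with at least one spike and divides
by the number of neurons active anywhere in the recording, so it runs from 0
(silence) to 1 (full-network activation). Network bursts are significant
peaks of the GNA profile — amplitude above the background mean + 3 SD, with
the background estimated by iterative sigma clipping so the bursts
themselves do not inflate the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GNAProfile",
    "NetworkBurst",
    "NetworkBurstSummary",
    "compute_gna",
    "detect_network_bursts",
    "summarize_network_bursts",
]


@dataclass
class GNAProfile:
    """Windowed network-coordination profile; times are window starts."""

    times_s: np.ndarray
    gna: np.ndarray
    window_s: float
    step_s: float
    n_active: int
    fs_hz: float


@dataclass
class NetworkBurst:
    """One significant collective activation event."""

    peak_time_s: float
    amplitude: float  # A_b, the GNA value at the peak
    start_s: float
    end_s: float
    duration_s: float
    participant_idx: np.ndarray


@dataclass
class NetworkBurstSummary:
    """Recording-level network-burst statistics."""

    n_bursts: int
    burst_rate_hz: float
    ibi_s: np.ndarray
    mean_duration_s: float
    mean_spikes_per_burst: float
    participation_fraction: np.ndarray
    amplitude_distribution: np.ndarray
    threshold: float


def compute_gna(
    raster: np.ndarray,
    fs_hz: float,
    window_s: float = 2.0,
    step_s: float = 0.5,
) -> GNAProfile:
    """Sliding-window fraction of co-activating neurons.

    Per window [t, t + window): count neurons with >= 1 spike, divided by the
    number of neurons with >= 1 spike anywhere in the recording. An entirely
    silent raster gives an all-zero profile.
    """
    raster = np.asarray(raster)
    if raster.ndim != 2 or raster.size == 0:
        raise ValueError("raster must be a non-empty 2-D matrix")
    if window_s < step_s:
        raise ValueError("window must be >= step")
    n_neurons, n_bins = raster.shape
    duration_s = n_bins / fs_hz
    if window_s > duration_s:
        raise ValueError("window longer than the recording")
    n_windows = int(np.floor((duration_s - window_s) / step_s)) + 1
    starts = np.arange(n_windows) * step_s
    active = raster.any(axis=1)
    n_active = int(active.sum())
    gna = np.zeros(n_windows)
    if n_active > 0:
        act = raster[active]
        # cumulative spike counts let each window reduce to two lookups
        cs = np.zeros((n_active, n_bins + 1), dtype=np.int64)
        np.cumsum(act, axis=1, out=cs[:, 1:])
        a = np.floor(starts * fs_hz).astype(int)
        b = np.minimum(np.floor((starts + window_s) * fs_hz).astype(int), n_bins)
        gna = (cs[:, b] - cs[:, a] > 0).sum(axis=0) / n_active
    return GNAProfile(
        times_s=starts,
        gna=gna,
        window_s=window_s,
        step_s=step_s,
        n_active=n_active,
        fs_hz=fs_hz,
    )


def sigma_clipped_background(
    values: np.ndarray, clip_k: float = 3.0, n_iter: int = 3
) -> tuple[float, float]:
    """Mean and SD of the background (non-burst) part of a GNA profile.

    Iterative sigma clipping initialised robustly: the first clip uses the
    median and a robust scale (MAD, falling back to IQR, then SD), so that
    bursts occupying a substantial fraction of windows — where a mean/SD clip
    would never exclude them — are still rejected from the background.
    """
    vals = np.asarray(values, dtype=float)
    med = np.median(vals)
    scale = 1.4826 * np.median(np.abs(vals - med))
    if scale == 0:
        q75, q25 = np.percentile(vals, [75, 25])
        scale = (q75 - q25) / 1.349
    if scale == 0:
        scale = vals.std()
    keep = vals <= med + clip_k * scale
    if not keep.any():
        keep = np.ones(vals.size, dtype=bool)
    for _ in range(n_iter):
        mu = vals[keep].mean()
        sd = vals[keep].std()
        # clipping only ever shrinks the kept set; re-admitting values would
        # let a heavy burst mode pull the background estimate back up
        new_keep = keep & (vals <= mu + clip_k * sd)
        if not new_keep.any() or new_keep.sum() == keep.sum():
            break
        keep = new_keep
    return float(vals[keep].mean()), float(vals[keep].std())


def _crossing_time(
    times: np.ndarray, gna: np.ndarray, idx_lo: int, idx_hi: int, thr: float
) -> float:
    """Linear interpolation of the threshold crossing between two samples."""
    t0, t1 = times[idx_lo], times[idx_hi]
    v0, v1 = gna[idx_lo], gna[idx_hi]
    if v1 == v0:
        return float(t1)
    return float(t0 + (thr - v0) / (v1 - v0) * (t1 - t0))


def detect_network_bursts(
    profile: GNAProfile,
    raster: np.ndarray | None = None,
    k_sd: float = 3.0,
    clip_k: float = 3.0,
) -> list[NetworkBurst]:
    """Significant GNA peaks: amplitude above background mean + ``k_sd`` SD.

    Each contiguous above-threshold region yields one burst at its highest
    local maximum (overlapping peaks merge); start and end are the
    interpolated threshold crossings. Participants are the neurons that spike
    within [start, end + window).
    """
    gna = profile.gna
    if gna.size == 0:
        return []
    mu, sd = sigma_clipped_background(gna, clip_k=clip_k)
    threshold = mu + k_sd * sd
    above = gna > threshold
    if not above.any():
        return []
    bursts: list[NetworkBurst] = []
    # contiguous above-threshold regions
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = [0] if above[0] else []
    starts += list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[-1]:
        ends.append(above.size)
    for a, b in zip(starts, ends):
        peak = a + int(np.argmax(gna[a:b]))
        if a > 0:
            start_s = _crossing_time(profile.times_s, gna, a - 1, a, threshold)
        else:
            start_s = float(profile.times_s[0])
        if b < gna.size:
            end_s = _crossing_time(profile.times_s, gna, b, b - 1, threshold)
        else:
            end_s = float(profile.times_s[-1])
        participants = np.array([], dtype=int)
        if raster is not None:
            f0 = max(int(np.floor(start_s * profile.fs_hz)), 0)
            f1 = min(
                int(np.ceil((end_s + profile.window_s) * profile.fs_hz)),
                raster.shape[1],
            )
            participants = np.flatnonzero(raster[:, f0:f1].any(axis=1))
        bursts.append(
            NetworkBurst(
                peak_time_s=float(profile.times_s[peak]),
                amplitude=float(gna[peak]),
                start_s=start_s,
                end_s=end_s,
                duration_s=end_s - start_s,
                participant_idx=participants,
            )
        )
    return bursts


def summarize_network_bursts(
    bursts: list[NetworkBurst],
    raster: np.ndarray,
    profile: GNAProfile,
) -> NetworkBurstSummary:
    """Pool burst statistics over a recording.

    Burst rate normalises by recording duration; IBIs are between
    consecutive peaks; spikes-per-burst counts raster spikes within each
    burst's extent; participation is each neuron's fraction of bursts joined.
    """
    n_neurons, n_bins = raster.shape
    duration_s = n_bins / profile.fs_hz
    mu, sd = sigma_clipped_background(profile.gna)
    if not bursts:
        return NetworkBurstSummary(
            n_bursts=0,
            burst_rate_hz=0.0,
            ibi_s=np.array([]),
            mean_duration_s=0.0,
            mean_spikes_per_burst=0.0,
            participation_fraction=np.zeros(n_neurons),
            amplitude_distribution=np.array([]),
            threshold=mu + 3.0 * sd,
        )
    peaks = np.array([b.peak_time_s for b in bursts])
    spikes_per_burst = []
    participation = np.zeros(n_neurons)
    for b in bursts:
        f0 = max(int(np.floor(b.start_s * profile.fs_hz)), 0)
        f1 = min(int(np.ceil((b.end_s + profile.window_s) * profile.fs_hz)), n_bins)
        seg = raster[:, f0:f1]
        spikes_per_burst.append(int(seg.sum()))
        participation += seg.any(axis=1)
    return NetworkBurstSummary(
        n_bursts=len(bursts),
        burst_rate_hz=len(bursts) / duration_s,
        ibi_s=np.diff(peaks),
        mean_duration_s=float(np.mean([b.duration_s for b in bursts])),
        mean_spikes_per_burst=float(np.mean(spikes_per_burst)),
        participation_fraction=participation / len(bursts),
        amplitude_distribution=np.array([b.amplitude for b in bursts]),
        threshold=mu + 3.0 * sd,
    )
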