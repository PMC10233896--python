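"""Shared containers for the calcium-imaging network pipeline.

The pipeline's entry object is a :class:`FluorescenceRecording` — a frames x
ROIs fluorescence matrix together with the sampling rate and ROI positions.
Everything downstream (dF/F traces, spike trains, network bursts, functional
networks) is derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FluorescenceRecording",
    "NormalizedTraces",
    "SpikeTrainSet",
]


@dataclass
class FluorescenceRecording:
    """Raw (or detrended) fluorescence traces for a set of ROIs.

    Parameters
    ----------
    traces : ndarray, shape (n_frames, n_rois)
        Fluorescence F_i(t) in arbitrary camera units.
    fs_hz : float
        Sampling rate in frames per second.
    positions : ndarray, shape (n_rois, 2)
        ROI centroid (x, y) in micrometres.
    roi_ids : sequence of str
        Stable ROI identifiers.
    labels : sequence of str or None
        Optional per-ROI class label ("neuron" / "astrocyte").
    """

    traces: np.ndarray
    fs_hz: float
    positions: np.ndarray
    roi_ids: list[str] = field(default_factory=list)
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be a 2-D frames x ROIs matrix")
        if not np.isfinite(self.traces).all():
            raise ValueError("traces contain non-finite values (missing frames?)")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if self.positions.shape[0] != self.n_rois:
            raise ValueError(
                f"positions length {self.positions.shape[0]} != ROI count {self.n_rois}"
            )
        if not self.roi_ids:
            self.roi_ids = [f"roi{i:04d}" for i in range(self.n_rois)]
        if len(self.roi_ids) != self.n_rois:
            raise ValueError("roi_ids length must match ROI count")
        if self.labels is not None:
            self.labels = list(self.labels)
            if len(self.labels) != self.n_rois:
                raise ValueError("labels length must match ROI count")

    @property
    def n_frames(self) -> int:
        return self.traces.shape[0]

    @property
    def n_rois(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fs_hz


@dataclass
class NormalizedTraces:
    """%DFF traces: 100*(F - F0)/F0 with per-ROI resting baseline F0."""

    dff: np.ndarray
    f0: np.ndarray
    fs_hz: float
    smoothing_window_s: float | None = None
    highband_cutoff_hz: float | None = None

    @property
    def n_frames(self) -> int:
        return self.dff.shape[0]

    @property
    def n_rois(self) -> int:
        return self.dff.shape[1]


@dataclass
class SpikeTrainSet:
    """Per-ROI spike onset times plus the binned binary raster.

    The raster bins are imaging frames: ``raster[i, t]`` is 1 when ROI ``i``
    has at least one onset in frame ``t``. Onset lists keep every event, so
    multiple onsets collapsing into one frame are preserved there.
    """

    onsets: list[np.ndarray]
    fs_hz: float
    duration_s: float
    raster: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.onsets = [np.asarray(o, dtype=float) for o in self.onsets]
        for i, o in enumerate(self.onsets):
            if o.size and (np.any(np.diff(o) < 0)):
                raise ValueError(f"onsets for ROI {i} are not sorted")
            if o.size and (o.min() < 0 or o.max() >= self.duration_s):
                raise ValueError(f"onsets for ROI {i} outside [0, duration)")

    @property
    def n_rois(self) -> int:
        return len(self.onsets)

    def spike_counts(self) -> np.ndarray:
        return np.array([o.size for o in self.onsets], dtype=int)
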