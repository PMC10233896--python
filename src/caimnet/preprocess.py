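"""Trace preprocessing: smoothing and drift correction, %DFF normalisation,
neuron/astrocyte classification, and stimulus-response summaries.

Normalisation follows the standard convention %DFF = 100*(F - F0)/F0 with F0
the resting-level fluorescence of the cell; the resting level is estimated
as a low running percentile so that transients do not contaminate the
baseline. Cell-type separation uses an adaptively boosted ensemble of
decision stumps on the statistical moments of the traces (mean, variance,
skewness) plus an autocorrelation time-scale feature — astrocyte transients
decay an order of magnitude more slowly than neuronal ones, which makes the
time-scale feature highly informative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy import signal, stats
from sklearn.ensemble import AdaBoostClassifier
from sklearn.tree import DecisionTreeClassifier

from .core import FluorescenceRecording, NormalizedTraces

logger = logging.getLogger(__name__)

__all__ = [
    "TraceFeatures",
    "StimulusResponseSummary",
    "smooth_and_detrend",
    "normalize_dff",
    "extract_trace_features",
    "classify_traces",
    "stimulus_response_summary",
]

#: names of the per-ROI classification features, in column order
FEATURE_NAMES = ("mean", "variance", "skewness", "decay_time_s")


@dataclass
class TraceFeatures:
    """Per-ROI moment features; matrix is ROIs x features."""

    matrix: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]


@dataclass
class StimulusResponseSummary:
    """ROIs that responded within the window after a stimulus."""

    responder_ids: list[str]
    responder_idx: np.ndarray
    mean_trace: np.ndarray
    max_amplitude: np.ndarray  # per responder, %DFF over pre-stimulus mean
    group_mean_amplitude: float


def smooth_and_detrend(
    rec: FluorescenceRecording,
    smoothing_window_s: float = 0.15,
    highband_cutoff_hz: float = 0.01,
) -> FluorescenceRecording:
    """Moving-window smoothing plus removal of slow drift.

    A short moving-average filter suppresses frame noise; a zero-phase
    second-order Butterworth high-pass at ``highband_cutoff_hz`` removes the
    slow drift, and the per-trace mean is restored so the output stays on the
    original fluorescence scale. Both stages are linear and the high-pass is
    zero-phase, so transient onset times are untouched.
    """
    if smoothing_window_s < 1.0 / rec.fs_hz:
        raise ValueError("smoothing window must cover at least one frame")
    w = int(round(smoothing_window_s * rec.fs_hz))
    if w > rec.n_frames:
        raise ValueError("smoothing window longer than the recording")
    sm = uniform_filter1d(rec.traces, size=max(w, 1), axis=0, mode="nearest")
    if highband_cutoff_hz and highband_cutoff_hz > 0:
        mean = sm.mean(axis=0, keepdims=True)
        sos = signal.butter(
            2, highband_cutoff_hz, btype="highpass", fs=rec.fs_hz, output="sos"
        )
        # pad on the scale of the filter's time constant to tame edge transients
        padlen = int(min(rec.n_frames - 1, 3 * rec.fs_hz / highband_cutoff_hz))
        sm = signal.sosfiltfilt(sos, sm - mean, axis=0, padlen=padlen) + mean
    return FluorescenceRecording(
        traces=sm,
        fs_hz=rec.fs_hz,
        positions=rec.positions,
        roi_ids=list(rec.roi_ids),
        labels=list(rec.labels) if rec.labels is not None else None,
    )


def _baseline_f0(
    traces: np.ndarray,
    fs_hz: float,
    method: str,
    percentile: float,
    window_s: float,
) -> np.ndarray:
    if method == "running_percentile":
        # percentile within consecutive windows, then median across windows;
        # block-wise evaluation keeps this O(n log w)
        w = min(max(int(round(window_s * fs_hz)), 1), traces.shape[0])
        n_blocks = traces.shape[0] // w
        if n_blocks < 1:
            return np.percentile(traces, percentile, axis=0)
        blocks = traces[: n_blocks * w].reshape(n_blocks, w, traces.shape[1])
        running = np.percentile(blocks, percentile, axis=1)
        return np.median(running, axis=0)
    if method == "percentile":
        return np.percentile(traces, percentile, axis=0)
    if method == "median":
        return np.median(traces, axis=0)
    raise ValueError(f"unknown baseline method {method!r}")


def normalize_dff(
    rec: FluorescenceRecording,
    baseline_method: str = "running_percentile",
    percentile: float = 10.0,
    window_s: float = 30.0,
) -> NormalizedTraces:
    """Normalise to %DFF = 100*(F - F0)/F0.

    The default resting level F0 is the median over time of a running
    10th-percentile filter (30 s window): robust to bursts, tracks nothing
    faster than the window. A constant trace maps to identically zero, and
    the result is invariant to rescaling a trace by any positive factor.
    """
    f0 = _baseline_f0(rec.traces, rec.fs_hz, baseline_method, percentile, window_s)
    bad = np.flatnonzero(f0 <= 0)
    if bad.size:
        names = [rec.roi_ids[i] for i in bad[:5]]
        raise ValueError(f"non-positive baseline F0 for ROI(s) {names}")
    dff = 100.0 * (rec.traces - f0) / f0
    return NormalizedTraces(dff=dff, f0=f0, fs_hz=rec.fs_hz)


def _acf_decay_time(x: np.ndarray, fs_hz: float, max_lag_s: float = 20.0) -> float:
    """Lag (s) where the autocorrelation first drops below 1/e; 0 if flat."""
    x = x - x.mean()
    v = np.dot(x, x)
    if v <= 0:
        return 0.0
    max_lag = min(int(max_lag_s * fs_hz), x.size - 1)
    target = v / np.e
    for lag in range(1, max_lag + 1):
        if np.dot(x[:-lag], x[lag:]) < target:
            return lag / fs_hz
    return max_lag / fs_hz


def extract_trace_features(
    dff: np.ndarray | NormalizedTraces, fs_hz: float | None = None
) -> TraceFeatures:
    """Per-ROI mean, variance, Fisher skewness and autocorrelation decay time.

    Constant (degenerate) traces get variance 0 and skewness 0 so that the
    feature set is total.
    """
    if isinstance(dff, NormalizedTraces):
        fs_hz = dff.fs_hz
        dff = dff.dff
    if fs_hz is None:
        raise ValueError("fs_hz required when passing a bare matrix")
    if dff.shape[0] < 100:
        raise ValueError("need at least 100 frames to extract features")
    mean = dff.mean(axis=0)
    var = dff.var(axis=0)
    # numerically constant traces get exact zeros so the features are total
    var[var <= np.finfo(float).eps * (mean**2 + 1.0)] = 0.0
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = stats.skew(dff, axis=0)
    skew = np.where(var > 0, np.nan_to_num(skew), 0.0)
    decay = np.array([_acf_decay_time(dff[:, i], fs_hz) for i in range(dff.shape[1])])
    return TraceFeatures(matrix=np.column_stack([mean, var, skew, decay]))


def classify_traces(
    features: TraceFeatures,
    training_idx: np.ndarray,
    training_labels: list[str],
    n_estimators: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Boosted decision stumps separating neurons from astrocytes.

    ``training_idx``/``training_labels`` give the manually curated subset; the
    classifier predicts a class for every ROI. A single-class training set
    degenerates to a constant prediction (with a logged warning) rather than
    an error.
    """
    training_idx = np.asarray(training_idx, dtype=int)
    if training_idx.size == 0:
        raise ValueError("empty training set")
    labels = np.asarray(training_labels)
    if labels.size != training_idx.size:
        raise ValueError("training_idx and training_labels lengths differ")
    classes = np.unique(labels)
    if classes.size == 1:
        logger.warning(
            "training set contains a single class %r; predicting it everywhere",
            classes[0],
        )
        return np.full(features.n_rois, classes[0], dtype=object)
    clf = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=1),
        n_estimators=n_estimators,
        random_state=seed,
    )
    clf.fit(features.matrix[training_idx], labels)
    return clf.predict(features.matrix)


def stimulus_response_summary(
    dff: np.ndarray,
    fs_hz: float,
    stimulus_time_s: float,
    response_window_s: float = 1.0,
    onset_k_sd: float = 3.0,
    roi_ids: list[str] | None = None,
) -> StimulusResponseSummary:
    """Identify ROIs responding within ``response_window_s`` of a stimulus.

    A responder's %DFF exceeds its pre-stimulus mean + ``onset_k_sd`` SD
    within the window. ``max_amplitude`` is the post-stimulus peak minus the
    pre-stimulus mean; ``mean_trace`` averages responder traces. No
    responders is a valid (empty) outcome.
    """
    n_frames, n_rois = dff.shape
    if not 0 <= stimulus_time_s < n_frames / fs_hz:
        raise ValueError("stimulus time outside the recording")
    if roi_ids is None:
        roi_ids = [f"roi{i:04d}" for i in range(n_rois)]
    f_stim = int(np.floor(stimulus_time_s * fs_hz))
    f_win = min(int(np.ceil((stimulus_time_s + response_window_s) * fs_hz)), n_frames)
    pre = dff[: max(f_stim, 1)]
    pre_mean = pre.mean(axis=0)
    pre_sd = pre.std(axis=0)
    thresh = pre_mean + onset_k_sd * pre_sd
    in_window = dff[f_stim:f_win]
    responders = np.flatnonzero((in_window > thresh).any(axis=0))
    if responders.size == 0:
        return StimulusResponseSummary(
            responder_ids=[],
            responder_idx=responders,
            mean_trace=np.zeros(n_frames),
            max_amplitude=np.array([]),
            group_mean_amplitude=float("nan"),
        )
    post = dff[f_stim:]
    max_amp = post[:, responders].max(axis=0) - pre_mean[responders]
    return StimulusResponseSummary(
        responder_ids=[roi_ids[i] for i in responders],
        responder_idx=responders,
        mean_trace=dff[:, responders].mean(axis=1),
        max_amplitude=max_amp,
        group_mean_amplitude=float(max_amp.mean()),
    )
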