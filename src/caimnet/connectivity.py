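"""Directed functional connectivity from spike trains via Generalized
Transfer Entropy (GTE).

For a source train X and target Y, the plug-in transfer entropy

    TE(X -> Y) = sum p(y_t, y_past, x_ctx) *
                 log2[ p(y_t | y_past, x_ctx) / p(y_t | y_past) ]

is estimated from joint histograms over binary words, where ``y_past`` is the
k last bins of Y (Markov order k, default 2) and ``x_ctx`` the k last bins of
X plus — with instant feedback, the default — X's same-bin state x_t.
Same-bin conditioning captures couplings faster than one frame, which
widefield calcium imaging cannot order in time.

Before estimation the binarized trains are filtered to remove concatenated
activations (each within-cell run of consecutive active bins is reduced to
its onset bin), suppressing the within-burst autocorrelation that otherwise
creates spurious links.

An edge X -> Y is significant when its score exceeds the mean + 2 SD of the
joint score pool of all inputs to Y and all outputs from X; the significant
scores are set to 1 and the rest to 0, yielding a binary directed adjacency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GTEParams",
    "ConnectivityResult",
    "binarize_and_filter_trains",
    "gte_pair",
    "significance_threshold",
    "infer_network",
]


@dataclass
class GTEParams:
    """Estimator settings: Markov order, instant feedback, binning, filtering.

    ``condition_on_global`` restricts estimation to bins where the fraction
    of simultaneously active neurons is at most ``conditioning_level`` — the
    low-activity regime in which pairwise transmission is identifiable.
    Inside a saturated network burst every neuron fires regardless of its
    inputs, so those bins carry no edge information and bias all pairs
    towards a uniform high score.
    """

    markov_order: int = 2
    instant_feedback: bool = True
    bin_s: float = 0.05
    onset_filtering: bool = True
    sig_k_sd: float = 2.0
    condition_on_global: bool = True
    conditioning_level: float = 0.1

    def validate(self) -> None:
        if self.markov_order < 1:
            raise ValueError("markov_order must be >= 1")
        if self.bin_s <= 0:
            raise ValueError("bin_s must be positive")
        if not 0.0 < self.conditioning_level <= 1.0:
            raise ValueError("conditioning_level must be in (0, 1]")


@dataclass
class ConnectivityResult:
    """GTE score matrix plus thresholded binary directed adjacency."""

    gte_scores: np.ndarray
    adjacency: np.ndarray
    sig_threshold: np.ndarray
    params: GTEParams


def binarize_and_filter_trains(
    onsets: list[np.ndarray],
    duration_s: float,
    params: GTEParams | None = None,
) -> np.ndarray:
    """Bin spike times at ``bin_s`` and reduce activation runs to onsets.

    With onset filtering (default), every within-cell run of consecutive
    active bins keeps only its first bin, so no row contains two consecutive
    ones.
    """
    params = params or GTEParams()
    params.validate()
    n_bins = int(round(duration_s / params.bin_s))
    trains = np.zeros((len(onsets), n_bins), dtype=np.uint8)
    for i, o in enumerate(onsets):
        o = np.asarray(o, dtype=float)
        if o.size == 0:
            continue
        bins = np.floor(o / params.bin_s).astype(int)
        bins = bins[(bins >= 0) & (bins < n_bins)]
        trains[i, bins] = 1
    if params.onset_filtering:
        keep_onset = np.ones_like(trains)
        keep_onset[:, 1:] = 1 - trains[:, :-1]
        trains = trains * keep_onset
    return trains


def _context_codes(
    trains: np.ndarray, k: int, instant_feedback: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron target and source context codes for bins t in [k, T).

    Target code = y_t * 2^k + sum_j y_{t-j} 2^(j-1);
    source code = sum_j x_{t-j} 2^(j-1) (+ x_t * 2^k with instant feedback).
    """
    x = np.asarray(trains, dtype=np.int64)
    n, T = x.shape
    if T <= k:
        raise ValueError("trains shorter than the Markov order")
    past = np.zeros((n, T - k), dtype=np.int64)
    for j in range(1, k + 1):
        past += x[:, k - j : T - j] << (j - 1)
    yt = x[:, k:]
    target = (yt << k) + past
    source = past.copy()
    if instant_feedback:
        source += yt << k
    return target, source


def _te_from_counts(
    counts: np.ndarray, k: int, instant_feedback: bool
) -> float:
    """Plug-in TE (bits) from a flat histogram over (y_t, y_past, x_ctx)."""
    n_src = 1 << (k + (1 if instant_feedback else 0))
    n_past = 1 << k
    c = counts.reshape(2, n_past, n_src).astype(float)  # [y_t, y_past, x_ctx]
    total = c.sum()
    if total == 0:
        return 0.0
    c_px = c.sum(axis=0, keepdims=True)  # joint (y_past, x_ctx)
    c_p = c.sum(axis=(0, 2), keepdims=True)  # y_past marginal
    c_yp = c.sum(axis=2, keepdims=True)  # (y_t, y_past)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (c * c_p) / (c_px * c_yp)
        term = c * np.log2(ratio)
    te = float(np.nansum(np.where(c > 0, term, 0.0)) / total)
    return te


def gte_pair(
    x_train: np.ndarray,
    y_train: np.ndarray,
    params: GTEParams | None = None,
) -> float:
    """TE(X -> Y) in bits between two equal-length binary trains."""
    params = params or GTEParams()
    params.validate()
    x = np.asarray(x_train).astype(np.int64).ravel()
    y = np.asarray(y_train).astype(np.int64).ravel()
    if x.size != y.size:
        raise ValueError("trains must have equal length")
    k = params.markov_order
    recommended = 10 * 2 ** (2 * k + 1)
    if x.size < recommended:
        warnings.warn(
            f"train length {x.size} below the recommended {recommended} bins "
            f"for Markov order {k}; estimates may be biased"
        )
    trains = np.vstack([x, y])
    target, source = _context_codes(trains, k, params.instant_feedback)
    n_src = 1 << (k + (1 if params.instant_feedback else 0))
    code = target[1] * n_src + source[0]
    counts = np.bincount(code, minlength=2 * (1 << k) * n_src)
    return _te_from_counts(counts, k, params.instant_feedback)


def significance_threshold(
    gte_scores: np.ndarray, sig_k_sd: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Binary adjacency from the joint input/output score-pool rule.

    For each ordered pair (X, Y) the pool is the union of all scores into Y
    (column Y) and all scores out of X (row X), excluding diagonal entries
    and the candidate score itself; the edge is significant iff its score
    strictly exceeds pool mean + ``sig_k_sd`` * pool SD. Returns
    ``(adjacency, thresholds)``.
    """
    s = np.asarray(gte_scores, dtype=float)
    n = s.shape[0]
    if s.ndim != 2 or s.shape[1] != n:
        raise ValueError("score matrix must be square")
    if n < 3:
        raise ValueError("need at least 3 neurons for the significance pool")
    col_sum = s.sum(axis=0)  # inputs to each Y (diagonal is zero)
    row_sum = s.sum(axis=1)  # outputs from each X
    col_sq = (s**2).sum(axis=0)
    row_sq = (s**2).sum(axis=1)
    pool_n = 2 * n - 4
    pool_sum = row_sum[:, None] + col_sum[None, :] - 2 * s
    pool_sq = row_sq[:, None] + col_sq[None, :] - 2 * s**2
    mean = pool_sum / pool_n
    var = np.maximum(pool_sq / pool_n - mean**2, 0.0)
    thresholds = mean + sig_k_sd * np.sqrt(var)
    adjacency = (s > thresholds).astype(np.uint8)
    np.fill_diagonal(adjacency, 0)
    np.fill_diagonal(thresholds, np.inf)
    return adjacency, thresholds


def infer_network(
    onsets: list[np.ndarray],
    duration_s: float,
    params: GTEParams | None = None,
) -> ConnectivityResult:
    """Full GTE pipeline: binarize/filter, all-pairs scores, significance.

    Deterministic; returns scores in bits with zero diagonal and the binary
    directed adjacency after the mean + 2 SD joint-pool rule.
    """
    params = params or GTEParams()
    params.validate()
    if len(onsets) < 3:
        raise ValueError("need at least 3 neurons")
    trains = binarize_and_filter_trains(onsets, duration_s, params)
    n = trains.shape[0]
    k = params.markov_order
    target, source = _context_codes(trains, k, params.instant_feedback)
    if params.condition_on_global:
        raw = binarize_and_filter_trains(
            onsets, duration_s, replace(params, onset_filtering=False)
        )
        active_count = raw.sum(axis=0)[k:]
        max_active = max(int(np.ceil(params.conditioning_level * n)), 2)
        valid = active_count <= max_active
        if valid.sum() < 10:
            warnings.warn(
                "low-activity conditioning left fewer than 10 bins; "
                "estimating without conditioning"
            )
        else:
            target = target[:, valid]
            source = source[:, valid]
    n_src = 1 << (k + (1 if params.instant_feedback else 0))
    n_states = 2 * (1 << k) * n_src
    scores = np.zeros((n, n))
    scaled_targets = [target[j] * n_src for j in range(n)]
    for j in range(n):  # target
        tj = scaled_targets[j]
        for i in range(n):  # source
            if i == j:
                continue
            counts = np.bincount(tj + source[i], minlength=n_states)
            scores[i, j] = _te_from_counts(counts, k, params.instant_feedback)
    scores[scores < 0] = 0.0  # guard against -0.0 / rounding
    adjacency, thresholds = significance_threshold(scores, params.sig_k_sd)
    return ConnectivityResult(
        gte_scores=scores,
        adjacency=adjacency,
        sig_threshold=thresholds,
        params=params,
    )
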