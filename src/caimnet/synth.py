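"""Synthetic co-culture recordings with planted ground truth.

Emulates 10-minute widefield calcium recordings of excitatory
neuron/astrocyte co-cultures at 20 frames/s in a ~4.2 x 3.2 mm field of
view: a modular directed synaptic network, stochastic cascade spiking with
collective network bursts, AR(1) calcium transients riding on slow drift and
shot noise for neurons, and slow double-exponential transients for
astrocytes. Two condition presets are provided: ``control_like`` (modular,
weakly inter-coupled) and ``ftd_like`` (strongly inter-coupled), which is the
contrast the downstream network analysis is designed to resolve.

The generator is the study's data source, not a fitting target: all defaults
are fixed, documented choices (see docs/methods.md) and everything is
reproducible from a single integer seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .core import FluorescenceRecording

__all__ = [
    "NetworkSpec",
    "DynamicsSpec",
    "CalciumRenderSpec",
    "SyntheticGroundTruth",
    "CONDITION_PRESETS",
    "make_modular_network",
    "simulate_spike_trains",
    "render_calcium_traces",
    "make_astrocyte_traces",
    "generate_dataset",
]


@dataclass
class NetworkSpec:
    """Planted modular directed network: who can drive whom.

    Edges i->j are Bernoulli with probability ``p_in`` inside a module and
    ``p_out`` across modules. ROI positions are drawn in a field of
    ``field_width_um`` x ``field_height_um`` (defaults match a 4.2 x 3.2 mm
    field of view).
    """

    n_neurons: int = 200
    n_modules: int = 5
    p_in: float = 0.3
    p_out: float = 0.01
    field_width_um: float = 4200.0
    field_height_um: float = 3200.0
    spatial_modules: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if self.n_neurons < self.n_modules:
            raise ValueError("n_neurons must be >= n_modules")
        for name in ("p_in", "p_out"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")


@dataclass
class DynamicsSpec:
    """Discrete-time cascade dynamics on the planted network.

    Each neuron fires spontaneously per bin with probability ``r0_hz * dt_s``
    (sparse ignition events), and a spike in neuron i recruits each
    out-neighbour after that edge's fixed synaptic delay (1 ..
    ``delay_max_bins`` bins) with probability ``p_trans`` scaled by i's
    synaptic resource, unless the neighbour is within ``refractory_bins`` of
    its own last spike.

    The synaptic resource implements short-term depression: each spike
    multiplies the sender's outgoing efficacy by ``1 - depletion`` and it
    recovers exponentially with time constant ``tau_rec_s``. Depression is
    what terminates network bursts and creates the quiet, weakly propagating
    inter-burst regime that real cultures show; without it the cascade is
    all-or-nothing and every ignition recruits the entire network.
    """

    dt_s: float = 0.05
    duration_s: float = 600.0
    r0_hz: float = 0.003
    p_trans: float = 0.5
    refractory_bins: int = 5
    delay_max_bins: int = 2
    depletion: float = 0.9
    tau_rec_s: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        n_bins = self.duration_s / self.dt_s
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError("duration_s must be an integer number of bins")
        if not 0.0 <= self.p_trans <= 1.0:
            raise ValueError("p_trans outside [0, 1]")
        if self.r0_hz < 0:
            raise ValueError("r0_hz must be >= 0")
        if self.refractory_bins < 0:
            raise ValueError("refractory_bins must be >= 0")
        if self.delay_max_bins < 1:
            raise ValueError("delay_max_bins must be >= 1")
        if not 0.0 <= self.depletion <= 1.0:
            raise ValueError("depletion must be in [0, 1]")
        if self.tau_rec_s <= 0:
            raise ValueError("tau_rec_s must be positive")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration_s / self.dt_s))

    @property
    def fs_hz(self) -> float:
        return 1.0 / self.dt_s


@dataclass
class CalciumRenderSpec:
    """Forward model from spikes to fluorescence.

    c(t) = gamma*c(t-1) + amp*s(t);  F(t) = baseline*(1 + c(t)) + drift + noise.
    With baseline-relative transients, one spike of ``amp`` = 0.2 produces a
    ~20 %DFF jump. Drift is a slow sinusoid plus an optional linear ramp.
    """

    gamma: float = 0.9
    amp: float = 0.2
    baseline: float = 100.0
    noise_sd: float = 0.25
    drift_amp: float = 5.0
    drift_period_s: float = 300.0
    drift_ramp: float = 0.0  # total linear drift over the recording, F units
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must be in (0, 1)")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticGroundTruth:
    """Planted truth bundled with a synthetic recording."""

    adjacency: np.ndarray
    module_labels: np.ndarray
    spike_times: list[np.ndarray]
    positions: np.ndarray
    cell_class: list[str] = field(default_factory=list)


#: Condition presets. The disease-like preset raises inter-module wiring
#: (p_out), within-module wiring (p_in), transmission strength (p_trans) and
#: spontaneous event rate (r0_hz) relative to control — hyperconnectivity
#: plus the hyperexcitability this disease model shows — which yields
#: network-wide, longer collective bursts instead of module-confined ones.
CONDITION_PRESETS: dict[str, dict[str, float]] = {
    "control_like": {"p_in": 0.30, "p_out": 0.01, "p_trans": 0.5, "r0_hz": 0.003},
    "ftd_like": {"p_in": 0.40, "p_out": 0.05, "p_trans": 0.7, "r0_hz": 0.0045},
}


def make_modular_network(
    spec: NetworkSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample a planted-partition directed graph and ROI positions.

    Returns ``(adjacency, module_labels, positions)``; adjacency is binary
    with zero diagonal, edge i->j present with probability ``p_in`` when i
    and j share a module and ``p_out`` otherwise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_neurons
    # near-equal module sizes
    labels = np.sort(np.arange(n) % spec.n_modules)
    same = labels[:, None] == labels[None, :]
    prob = np.where(same, spec.p_in, spec.p_out)
    adjacency = (rng.random((n, n)) < prob).astype(np.uint8)
    np.fill_diagonal(adjacency, 0)

    if spec.spatial_modules:
        # module centres on a jittered grid, members scattered around them
        centers = rng.uniform(
            [0.2 * spec.field_width_um, 0.2 * spec.field_height_um],
            [0.8 * spec.field_width_um, 0.8 * spec.field_height_um],
            size=(spec.n_modules, 2),
        )
        sd = 0.08 * min(spec.field_width_um, spec.field_height_um)
        positions = centers[labels] + rng.normal(0.0, sd, size=(n, 2))
        positions[:, 0] = np.clip(positions[:, 0], 0, spec.field_width_um)
        positions[:, 1] = np.clip(positions[:, 1], 0, spec.field_height_um)
    else:
        positions = rng.uniform(
            [0.0, 0.0], [spec.field_width_um, spec.field_height_um], size=(n, 2)
        )
    return adjacency, labels, positions


def simulate_spike_trains(
    adjacency: np.ndarray, dyn: DynamicsSpec
) -> list[np.ndarray]:
    """Run the depressing Bernoulli cascade; per-neuron sorted spike times (s).

    A spike in neuron i delivers drive ``R_i`` (i's synaptic resource) to each
    out-neighbour after the edge's fixed delay; the neighbour then fires with
    probability ``1 - (1 - p_trans) ** drive`` summed over arrivals, unless
    refractory. Spontaneous ignitions occur with probability
    ``r0_hz * dt_s`` per neuron per bin. Firing depletes the sender's
    resource by the factor ``1 - depletion``; resources recover towards 1
    with time constant ``tau_rec_s``. With ``delay_max_bins = 1`` and
    ``depletion = 0`` this reduces to plain one-bin-delayed Bernoulli
    propagation.
    """
    dyn.validate()
    adjacency = np.asarray(adjacency)
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError("adjacency must be square")
    n = adjacency.shape[0]
    rng = np.random.default_rng(dyn.seed)
    n_bins = dyn.n_bins
    p_spont = dyn.r0_hz * dyn.dt_s
    D = dyn.delay_max_bins
    if D > 1:
        delays = rng.integers(1, D + 1, size=adjacency.shape)
    else:
        delays = np.ones(adjacency.shape, dtype=int)
    targets = [np.flatnonzero(adjacency[i]) for i in range(n)]
    edge_delay = [delays[i, targets[i]] for i in range(n)]

    last_spike = np.full(n, -np.inf)
    resource = np.ones(n)
    recover = dyn.dt_s / dyn.tau_rec_s
    pending = np.zeros((n_bins + D + 1, n))  # summed presynaptic drive
    spikes: list[list[float]] = [[] for _ in range(n)]
    log1m = np.log1p(-min(dyn.p_trans, 1.0 - 1e-12))
    for t in range(n_bins):
        p_drive = -np.expm1(pending[t] * log1m)  # 1 - (1-p_trans)^drive
        p_fire = 1.0 - (1.0 - p_spont) * (1.0 - p_drive)
        fire = rng.random(n) < p_fire
        fire &= (t - last_spike) > dyn.refractory_bins
        if fire.any():
            last_spike[fire] = t
            t_s = t * dyn.dt_s
            for i in np.flatnonzero(fire):
                spikes[i].append(t_s)
                if targets[i].size:
                    np.add.at(pending, (t + edge_delay[i], targets[i]), resource[i])
            resource[fire] *= 1.0 - dyn.depletion
        resource += (1.0 - resource) * recover
    return [np.asarray(s) for s in spikes]


def _drift(render: CalciumRenderSpec, times_s: np.ndarray) -> np.ndarray:
    d = render.drift_amp * np.sin(2 * np.pi * times_s / render.drift_period_s)
    if render.drift_ramp:
        d = d + render.drift_ramp * times_s / max(times_s[-1], 1e-12)
    return d


def render_calcium_traces(
    spike_times: list[np.ndarray],
    render: CalciumRenderSpec,
    dyn: DynamicsSpec,
) -> FluorescenceRecording:
    """Render spike trains to fluorescence with the AR(1) forward model."""
    render.validate()
    dyn.validate()
    n = len(spike_times)
    n_frames = dyn.n_bins
    rng = np.random.default_rng(render.seed)
    s = np.zeros((n_frames, n))
    for i, onsets in enumerate(spike_times):
        onsets = np.asarray(onsets, dtype=float)
        if onsets.size:
            if onsets.max() >= dyn.duration_s or onsets.min() < 0:
                raise ValueError(f"spikes for neuron {i} outside recording")
            bins = np.floor(onsets * dyn.fs_hz).astype(int)
            np.add.at(s[:, i], bins, render.amp)
    c = np.empty_like(s)
    c[0] = s[0]
    for t in range(1, n_frames):
        c[t] = render.gamma * c[t - 1] + s[t]
    times = np.arange(n_frames) * dyn.dt_s
    f = render.baseline * (1.0 + c) + _drift(render, times)[:, None]
    if render.noise_sd > 0:
        f = f + rng.normal(0.0, render.noise_sd, size=f.shape)
    positions = np.zeros((n, 2))
    return FluorescenceRecording(traces=f, fs_hz=dyn.fs_hz, positions=positions)


def make_astrocyte_traces(
    n: int,
    dyn: DynamicsSpec,
    stimulus_time_s: float | None = None,
    responder_fraction: float = 1.0,
    peak_dff: float = 50.0,
    event_rate_hz: float = 0.01,
    rise_s: float = 1.0,
    decay_s: float = 8.0,
    baseline: float = 100.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Slow astrocytic calcium traces (frames x n, raw F units).

    Transients are double exponentials (default 1 s rise, 8 s decay) — an
    order of magnitude slower than the neuronal AR(1) decay, which is what
    makes moment/time-scale based classification well posed. Spontaneous
    events arrive as a Poisson process at ``event_rate_hz``; if
    ``stimulus_time_s`` is given, a ``responder_fraction`` of cells fires an
    extra transient with onset within 1 s of the stimulus and peak amplitude
    ``peak_dff`` (in %DFF of baseline).
    """
    dyn.validate()
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    n_frames = dyn.n_bins
    times = np.arange(n_frames) * dyn.dt_s
    traces = np.zeros((n_frames, n))
    if n == 0:
        return traces

    # unit-peak double-exponential kernel
    tk = np.arange(0, int((rise_s + 6 * decay_s) / dyn.dt_s)) * dyn.dt_s
    kernel = np.exp(-tk / decay_s) - np.exp(-tk / rise_s)
    if kernel.max() > 0:
        kernel = kernel / kernel.max()

    n_resp = int(round(responder_fraction * n))
    responders = rng.permutation(n)[:n_resp]
    is_resp = np.zeros(n, dtype=bool)
    is_resp[responders] = True

    for i in range(n):
        dff = np.zeros(n_frames)
        n_events = rng.poisson(event_rate_hz * dyn.duration_s)
        onsets = rng.uniform(0, dyn.duration_s, size=n_events)
        amps = rng.uniform(0.3, 1.0, size=n_events) * peak_dff / 100.0
        if stimulus_time_s is not None and is_resp[i]:
            onsets = np.append(onsets, stimulus_time_s + rng.uniform(0.0, 0.9))
            amps = np.append(amps, peak_dff / 100.0)
        for t0, a in zip(onsets, amps):
            b = int(np.floor(t0 / dyn.dt_s))
            if b >= n_frames:
                continue
            m = min(kernel.size, n_frames - b)
            dff[b : b + m] += a * kernel[:m]
        traces[:, i] = baseline * (1.0 + dff)
    if noise_sd > 0:
        traces = traces + rng.normal(0.0, noise_sd, size=traces.shape)
    return traces


def generate_dataset(
    network: NetworkSpec | None = None,
    dyn: DynamicsSpec | None = None,
    render: CalciumRenderSpec | None = None,
    condition: Literal["control_like", "ftd_like"] = "control_like",
    astrocyte_fraction: float = 0.3,
    seed: int | None = None,
) -> tuple[FluorescenceRecording, SyntheticGroundTruth]:
    """Generate a full co-culture recording plus its planted ground truth.

    ``condition`` applies the preset overrides (p_in/p_out to the network
    spec, p_trans/r0_hz to the dynamics spec) on top of the given specs.
    When ``seed`` is given it overrides the per-spec seeds (derived sub-seeds
    keep the three random stages independent).
    """
    if condition not in CONDITION_PRESETS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {sorted(CONDITION_PRESETS)}"
        )
    network = copy.deepcopy(network) if network is not None else NetworkSpec()
    dyn = copy.deepcopy(dyn) if dyn is not None else DynamicsSpec()
    render = copy.deepcopy(render) if render is not None else CalciumRenderSpec()
    preset = CONDITION_PRESETS[condition]
    network = replace(network, p_in=preset["p_in"], p_out=preset["p_out"])
    dyn = replace(dyn, p_trans=preset["p_trans"], r0_hz=preset["r0_hz"])
    if seed is not None:
        network = replace(network, seed=seed)
        dyn = replace(dyn, seed=seed + 1)
        render = replace(render, seed=seed + 2)

    adjacency, labels, positions = make_modular_network(network)
    spike_times = simulate_spike_trains(adjacency, dyn)
    rec_neuron = render_calcium_traces(spike_times, render, dyn)

    n_astro = int(round(astrocyte_fraction * network.n_neurons))
    astro = make_astrocyte_traces(
        n_astro,
        dyn,
        baseline=render.baseline,
        noise_sd=render.noise_sd,
        seed=render.seed + 1,
    )
    rng_pos = np.random.default_rng(network.seed + 1)
    astro_pos = rng_pos.uniform(
        [0.0, 0.0],
        [network.field_width_um, network.field_height_um],
        size=(n_astro, 2),
    )
    traces = np.hstack([rec_neuron.traces, astro])
    all_pos = np.vstack([positions, astro_pos])
    cell_class = ["neuron"] * network.n_neurons + ["astrocyte"] * n_astro
    rec = FluorescenceRecording(
        traces=traces,
        fs_hz=dyn.fs_hz,
        positions=all_pos,
        labels=cell_class,
    )
    truth = SyntheticGroundTruth(
        adjacency=adjacency,
        module_labels=labels,
        spike_times=spike_times,
        positions=all_pos,
        cell_class=cell_class,
    )
    return rec, truth
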