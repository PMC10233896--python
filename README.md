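# caimnet — calcium-imaging network analysis for neuron/astrocyte co-cultures

`caimnet` reimplements, as a tested and reusable pipeline, the network
analysis used to characterise spontaneous activity in human stem-cell-derived
neuron/astrocyte co-cultures imaged with a calcium indicator: the kind of
study that asks whether a disease line (here an FTD-like, hyperconnected
phenotype) forms networks that are more synchronous, more integrated and less
modular than its isogenic control. It is written for experimentalists and
computational neuroscientists who have frames × ROIs fluorescence trace
tables (10-minute widefield recordings at 20 frames/s, 150–300 ROIs in a
~4.2 × 3.2 mm field of view) and want the full chain from raw traces to
network statistics — plus a synthetic co-culture generator with planted
ground truth, since the analysis can then be validated against networks whose
wiring is known exactly.

## The pipeline

1. **Preprocessing** — moving-window smoothing, zero-phase high-pass drift
   correction, and normalisation to %DFF = 100·(F − F₀)/F₀ with a robust
   running-percentile resting level F₀.
2. **Cell-type classification** — adaptively boosted decision stumps on
   trace moments (mean, variance, skewness) plus an autocorrelation
   time-scale, separating fast neuronal transients from slow astrocytic ones.
3. **Spike inference** — sparse nonnegative AR(1) deconvolution
   (online pool-merging active-set solver) minimising
   ½·Σ(cₜ − yₜ)² + λ·Σsₜ with the thresholded variant sₜ ∈ {0} ∪ [S_min, ∞);
   defaults λ = 5 and S_min = 0.3 in %DFF units.
4. **Network bursts** — the global network activity (GNA) profile counts
   co-activating neurons in a sliding window (2 s wide, 0.5 s step) divided
   by the number of active neurons, so 0 = silence and 1 = full-network
   activation; significant bursts exceed the background mean + 3 SD, with
   the background estimated by robust iterative sigma clipping.
5. **Functional connectivity** — generalized transfer entropy between
   binarized, onset-filtered spike trains (Markov order 2, instant feedback,
   estimation restricted to the low-activity regime), with an edge X→Y
   declared significant when its score exceeds the mean + 2 SD of the joint
   pool of all inputs to Y and all outputs from X, yielding a binary
   directed network.
6. **Topology** — average connectivity over connected neurons, mean
   Euclidean distance between connected neurons, global efficiency
   G_EFF = ⟨1/d(i,j)⟩, local efficiency L_EFF (mean neighbourhood
   efficiency), and Newman modularity Q of a Louvain partition.

The synthetic module generates co-culture-like recordings from a planted
modular directed network driven by a depressing Bernoulli cascade, rendered
through the AR(1) calcium forward model with drift and noise, plus
slow-transient astrocyte traces. Two presets, `control_like` and `ftd_like`,
realise the healthy (modular, weakly inter-coupled) versus disease-like
(hyperconnected, hyperexcitable) contrast.

## Worked example

```python
import caimnet as cm

rec, truth = cm.generate_dataset(
    cm.NetworkSpec(n_neurons=60, n_modules=6),
    cm.DynamicsSpec(duration_s=600.0),
    condition="control_like",
    seed=0,
)
metrics = cm.analyze_recording(rec, recording_id="demo",
                               condition="control_like", seed=0)
```

prints (via the snippet in `analysis/`-style reporting):

```
recording: 12000 frames x 78 ROIs at 20 fps
ROIs classified as neurons: 62
mean_firing_rate_hz: 0.031
network_burst_rate_hz: 0.112
network_burst_duration_s: 2.885
avg_connectivity: 7.103
g_eff: 0.225
l_eff: 0.403
modularity_q: 0.694
n_modules: 10.000
```

Reading these numbers: 62 of 78 ROIs were classified as neurons (60 planted
neurons plus two astrocytes misassigned at this seed); the culture fires
sparsely (~0.03 Hz per neuron) but collectively (a significant network burst
every ~9 s, each lasting ~2.9 s); and the inferred functional network is
strongly modular (Q ≈ 0.69, ~10 detected modules, ~7 functional connections
per connected neuron) with moderate global efficiency — the signature of a
healthy, segregated control culture. An `ftd_like` dataset at the same seed
yields lower Q, fewer modules and higher global efficiency.

The numbered scripts under `analysis/` run the same steps as a narrative:
`01_simulate_cocultures.py` writes paired recordings (bulk data under
`scratch/data/`), `02`–`05` preprocess, classify, deconvolve, detect bursts
and infer connectivity (tables under `results/`), and
`06_topology_comparison.py` produces the condition comparison report.

A `caimnet` command-line interface wraps each stage
(`caimnet simulate|preprocess|spikes|gna|connectivity|topology|run-all|compare`);
`caimnet --help` lists options.

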