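# Methods

This note documents the models, parameter choices and numerical decisions
behind `caimnet`, and what the synthetic validation does and does not
establish about real recordings.

## Trace preprocessing

Fluorescence traces are smoothed with a centred moving average
(`smoothing_window_s`, default 0.15 s at 20 fps, i.e. 3 frames). A short
window was chosen deliberately: wider smoothing smears a spike's
single-frame fluorescence jump over the window, and during rapid
within-burst firing the deconvolution then fragments one spike into several
onsets. Drift is removed with a zero-phase second-order Butterworth
high-pass at `highband_cutoff_hz` (default 0.01 Hz), applied forward and
backward so transient onsets are not displaced, padded on the scale of the
filter time constant to control edge transients, and with the per-trace mean
restored so traces stay on their original positive scale. Both stages are
linear.

Normalisation is %DFF = 100·(F − F₀)/F₀. The resting level F₀ is the median
across windows of a 10th-percentile filter in consecutive 30 s windows — a
low percentile so that transients do not contaminate the baseline, and a
window long enough that the estimate does not track bursts. For a constant
trace the output is identically zero, and the normalisation is invariant to
rescaling a trace by any positive factor.

## Cell-type classification

Neurons and astrocytes are separated by an adaptively boosted ensemble of 50
depth-1 decision trees on four per-ROI features: mean, variance, Fisher
skewness, and the lag at which the autocorrelation first falls below 1/e (a
decay-time scale). The time-scale feature carries most of the signal:
neuronal calcium transients decay within ~0.5 s while astrocytic transients
decay over ~8 s. A constant trace is assigned variance 0 and skewness 0 so
the feature map is total; a single-class training set degenerates to a
constant prediction with a logged warning rather than an error.

## Spike inference

The calcium impulse response is AR(1): c(t) = γ·c(t−1) + s(t), s ≥ 0,
observed as y = c + noise. Deconvolution minimises
½‖c − y‖² + λ·Σs by an online pool-merging active-set sweep. For the
unthresholded problem (s_min = 0) the sweep returns the exact optimum of the
convex programme; the tests verify agreement with a nonnegative-least-squares
solution to machine precision. The thresholded variant constrains every jump
to be 0 or at least `s_min`, enforced during the sweep by merging pools whose
boundary jump falls below threshold (with a post-sweep repair pass for pools
clamped at zero), not by deleting onsets afterwards; the problem is then
non-convex and the sweep is the standard greedy solution.

Defaults: λ = 5 and S_min = 0.3, both in the %DFF units of the trace.
γ defaults to "auto": the ratio of lag-2 to lag-1 autocovariance, which for
an AR(1) signal in white observation noise is noise-robust (the noise
inflates only lag 0). A trace with no significant lag-1 structure reports
γ = 0 and the deconvolution falls back to γ = 0.9 (decay τ ≈ 0.5 s at 20
fps). A flat per-trace baseline (trace median, appropriate for sparsely
active cells) is subtracted before solving: a residual positive offset b is
otherwise tracked by a stream of spurious jumps, one every
s_min/((1−γ)·b) frames. Because the pre-smoothing spreads one spike's jump
over up to `smoothing_window` frames, runs of consecutive onset bins are
merged into a single event at the run onset.

Single-cell statistics: a burst is a maximal run of ≥ 2 spikes whose
consecutive gaps are strictly below 1 s; burst duration is last minus first
onset; the inter-burst interval runs from one burst's end to the next
burst's start; burst amplitude sums the deconvolved signal over the burst's
frames.

## Network bursts

The global network activity (GNA) profile counts, per sliding window (2 s
wide, 0.5 s step, half-open [t, t+window) with frames assigned by
floor(t·fs)), the neurons with at least one spike, divided by the number of
neurons active anywhere in the recording; it ranges from 0 to 1. A neuron
"activates" in a window if it has any spike there, not only burst onsets.

Bursts are contiguous above-threshold regions of the profile, one burst per
region at its highest peak, with start and end obtained by linear
interpolation of the threshold crossing (the profile is sampled every 0.5 s;
interpolation avoids quantizing durations to the step). The threshold is
background mean + 3 SD. Background estimation must be robust to the bursts
themselves: iterative sigma clipping is initialised from the median and a
robust scale (MAD, falling back to IQR, then SD), and the kept set only ever
shrinks across iterations. A mean/SD-initialised clip fails whenever bursts
occupy more than ~20% of windows — the threshold then lands above GNA = 1
and nothing is ever significant; a re-expanding clip fails the same way.
A flat profile has zero SD, threshold equal to its mean, and no bursts.

## Functional connectivity

Generalized transfer entropy between binarized spike trains (bin width =
one frame, 0.05 s), plug-in estimate over binary words with Markov order
k = 2 and instant feedback (the source context includes the same-bin state
x_t, since widefield imaging cannot order events within a frame). Zero-count
contexts contribute zero; no bias correction is applied. Two artifact
controls are on by default:

- **Onset filtering** — each within-cell run of consecutive active bins is
  reduced to its first bin, removing concatenated activations.
- **Low-activity conditioning** — estimation is restricted to bins where at
  most `conditioning_level` (default 10%, never fewer than 2) of the neurons
  are active. Inside a saturated network burst every neuron fires whatever
  its inputs, so burst-core bins carry no edge information and drag all
  pairwise scores towards a uniform high value; the informative samples are
  the inter-burst transmission events and the first recruitment steps of
  each burst. This is the "generalized" mechanism this estimator family was
  developed for. Without it, the relative significance rule below passes
  *fewer* edges in a hypersynchronous network than in a control one,
  inverting every downstream comparison.

Significance: an edge X→Y is declared when its score strictly exceeds the
mean + 2 SD of the joint pool of all scores into Y and all scores out of X,
excluding diagonal entries and the candidate score itself (the pool then has
2n − 4 members; with fewer than 3 neurons it is degenerate and an error).
Significant scores are set to 1, the rest to 0: a binary directed adjacency.

## Topology

Efficiencies are computed on the directed graph the significance rule
produces: global efficiency is the mean of 1/d(i, j) over ordered pairs
(unreachable pairs contribute 0), local efficiency the mean over nodes of
the global efficiency of the subgraph induced on the union of in- and
out-neighbours (nodes with fewer than two neighbours contribute 0). Average
connectivity is the mean of in+out degree over neurons with at least one
connection; mean connection distance averages the Euclidean distance over
directed edges and is undefined (None), not zero, for an empty graph.
Modularity uses Louvain community detection on the OR-symmetrized graph with
a seeded, hence reproducible, sweep, reporting Newman Q of the returned
partition; an edgeless graph is a single module with Q = 0.

## The synthetic co-culture generator

The generator emulates the study conditions: 10-minute recordings at 20
frames/s, a 4.2 × 3.2 mm field of view, planted-partition directed networks
(default 200 neurons, 5 modules for structure studies; the paired condition
comparison uses 60 neurons in 6 modules to keep full-pipeline runs fast),
plus 30% astrocytes.

**Dynamics.** Discrete-time cascade at the frame interval. Each neuron
ignites spontaneously at `r0_hz` (sparse: the population ignition rate sets
the collective-event rate); a spike recruits each out-neighbour after a
per-edge synaptic delay of 1–2 frames with probability `p_trans` scaled by
the sender's synaptic resource; firing depletes that resource by 90%, and it
recovers with a 10 s time constant; refractoriness is 0.25 s. Depression is
essential, not cosmetic: a plain Bernoulli cascade with realistic coupling
is so supercritical that every ignition recruits the entire network within
2–3 frames, producing degenerate all-or-nothing synchrony in which no
functional structure is recoverable by any estimator. With depression the
network self-organises near criticality: distinct collective bursts ride on
a weakly propagating inter-burst regime, which is what real cultures show
and what the connectivity estimator needs. The per-edge delays (50–100 ms,
the scale of synaptic and integration latencies) spread burst recruitment so
that spike timing carries edge identity.

**Condition presets.** `control_like`: p_in = 0.30, p_out = 0.01,
p_trans = 0.5, r0 = 0.003 Hz. `ftd_like`: p_in = 0.40, p_out = 0.05,
p_trans = 0.7, r0 = 0.0045 Hz. The disease preset is hyperconnected within
and across modules, transmits more reliably, and is hyperexcitable —
matching the disease phenotype this class of model shows. Its planted
modularity is well below control's while both remain genuinely modular.

**Calcium rendering.** c(t) = γ·c(t−1) + amp·s(t) with γ = 0.9 per frame,
amp = 0.2 (a ~20 %DFF transient per spike), baseline 100, Gaussian frame
noise 0.25 (0.25 %DFF — a good-quality widefield recording; chosen so the
fixed deconvolution settings λ = 5, S_min = 0.3 operate at a low
false-onset rate, ~0.01 Hz), and slow sinusoidal drift (±5 units over
300 s) plus an optional linear ramp to exercise the drift correction.
Astrocyte transients are double exponentials (1 s rise, 8 s decay), an order
of magnitude slower than the neuronal kernel, so the time-scale
classification feature is well posed.

**What the generator does not emulate:** inhibitory neurons (the modelled
co-cultures contain only excitatory ones), biophysical membrane dynamics,
astrocyte–neuron signalling, spatially structured wiring (positions and
connectivity are independent by default), photobleaching beyond a smooth
ramp, and movement artifacts. Passing the validation suite therefore shows
the pipeline is faithful to its own definitions and can recover planted
structure under these idealised conditions — not that every conclusion
transfers to arbitrary recordings.

## The paired condition comparison

The comparison study generates, per seed, one control-like and one
disease-like dataset from the same random realization (paired design: the
disease network is a denser superset drawn with the same uniforms), runs the
full pipeline on both, and compares per-condition medians over 10 seeds of:
global and local efficiency, average connectivity, modularity Q, module
count, and network-burst duration. In the frozen configuration the disease
condition shows higher global efficiency, longer network bursts, lower Q and
fewer modules — four of the six expected directions.

Two directions do **not** reproduce, and the reasons are structural, not
incidental. (1) *Average connectivity*: the relative significance rule
normalises per node — an edge must beat the mean + 2 SD of a pool that
already contains its own node's other true edges, so the denser the node's
true connectivity, the higher its threshold; recovering a fixed fraction of
a denser network needs quadratically more per-edge evidence, while the
depressing cascade self-organises both conditions to roughly one effective
transmission per probe spike regardless of density. The disease network's
recall is therefore systematically lower (~0.35 vs ~0.6), and detected
degree ends up similar or lower despite the planted degree being twice
control's. (2) *Local efficiency*: control's detected graph inherits
clustered module blocks (including clustered common-drive false positives
inside its module-confined bursts), while the disease condition's extra
long-range edges dilute neighbourhood clustering and its saturated global
bursts are excluded by the conditioning. Both effects are properties of the
published estimator applied to planted-partition surrogates; on real data,
where coupling heterogeneity is far richer, the published analysis had more
per-edge contrast to work with.

## Numerical details and degenerate inputs

- Deconvolution onsets never include bin 0 (the initial level is not a
  spike); jumps below 1e−12 are treated as zero.
- GNA with no active neurons is identically zero; silent neurons never enter
  the denominator.
- The significance pool uses population (ddof 0) SD; an all-equal score
  matrix has SD 0 and no score strictly exceeds the mean, so the adjacency
  is empty.
- Louvain ties are fixed by the seed; modules are relabelled largest-first
  by size then smallest member for stable output.
- Pipeline reports are byte-deterministic for a given config and seed: the
  provenance block carries a config hash, the seed and the package version,
  and no timestamps.

## Problem sizes

Oracle and closed-form checks run on instances where exhaustive computation
is feasible (≤ 5 neurons × 500 bins for transfer entropy, ≤ 60 frames for
deconvolution, ≤ 20 nodes for all-pairs shortest paths). Planted-partition
recovery uses the full 200-neuron, 5-module geometry. The end-to-end paired
comparison uses 60 neurons in 6 modules for 600 s at 20 fps (12,000 frames)
across 10 paired seeds — small enough that the whole comparison runs in
under a minute, while preserving the module structure and burst dynamics the
comparison is about.
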