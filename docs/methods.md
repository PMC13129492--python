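# Methods

This note documents the models, conventions and design choices behind
`fedherd`, in the order the pipeline runs.

## Synthetic herd generator

The generator produces the statistical situation the method is designed
for — heterogeneous animals, threshold-crossing stress episodes, noisy
and faulty sensors — without attempting to match any particular real
dataset's marginals.

**Generative model.** For each animal, a physiological baseline is
drawn once from a population distribution (heart rate N(70, 5²) bpm,
body temperature N(38.5, 0.2²) °C, activity index N(0.3, 0.1²),
truncated below at 0.05). Because baselines are per-animal and clients
are per-animal partitions, client data distributions differ — the
non-IID setting federated averaging must cope with. Per-sample
measurement noise is added on top (3 bpm, 0.15 °C, 0.08 activity
units). These noise scales are separate config fields from the
baseline spreads: the baseline sd controls *between-animal*
heterogeneity, the noise sd *within-animal* variability, and both are
needed for the signals to be realistic.

**Stress episodes** arrive per animal as a Poisson process at 2
episodes per animal-day with a fixed 60-minute duration, modelled as
animal-level intervals (not per-row coin flips) so that rolling-window
features have temporal structure to exploit. Inside an episode heart
rate gains +35 bpm and temperature +1.2 °C, placing episode rows mostly
(not always) above the 100 bpm / 39.5 °C label thresholds — the labels
are noisy around the latent state, as proxy labels are in practice.
Activity is perturbed by ±0.15 with a random per-episode sign
(agitation or lethargy). Episode rates/boosts were chosen from this
physiological reasoning, before any end-to-end evaluation, and are not
revisited.

**Environment.** Ambient temperature is shared herd-wide: daily mean
20 °C plus a 6 °C sinusoid peaking at 15:00, plus N(0, 0.5²) noise.
Humidity is N(60, 10²) % clipped to [0, 100], uncorrelated with
temperature (a simplification; real heat stress couples the two — see
limitations). Activity has a mild 0.1-amplitude diurnal component. GPS
is a per-animal Gaussian random walk (step sd 1e-4°) from a common
origin; coordinates are carried through the schema but are not model
inputs.

**Defaults**: 20 animals, 7 days, 15-minute sampling. At 15-minute
sampling the 30-minute rolling window spans 2–3 samples.

**Sensor faults** (injected separately so the clean signals are
recoverable): dropout in geometric-length runs (mean 3 samples) at an
expected 5% of physiological cells, emulating transmission gaps, and
spike outliers at 1% of cells displaced by at least 6 population SDs —
above the z > 3 screening threshold by construction, so the
preprocessing can remove them. A missing rate of 1 is special-cased to
blank every cell (the run process cannot reach full coverage).
Environmental and identity columns are never corrupted.

**Seeding.** Every stream (environment, each animal, faults,
partitioning, client sampling, batching, weight init) uses a sub-seed
derived by hashing (master seed, stage tag) with blake2b. Identical
(config, seed) therefore give byte-identical CSVs, and toggling fault
injection does not change the underlying signals.

## Preprocessing

Order of operations: fill → outlier screen → label → rolling features →
scale → window.

* **Filling** is per animal, forward then backward, carrying observed
  values verbatim — never interpolating. An animal with no observations
  at all for a feature is an error, not a guess.
* **Outlier screening** computes mean and population SD (ddof = 0) per
  feature over the whole client table (across its animals) and drops
  the entire row when any screened feature has |z| > 3. Zero-SD
  features flag nothing. Screening is per client table because each
  edge device preprocesses locally. Note the screen is blind to cause:
  a genuine extreme stress reading can exceed z = 3 and be dropped
  along with sensor spikes (see limitations).
* **Labels** are computed from *raw* units — `is_stressed = 1` iff
  heart rate > 100 bpm or body temperature > 39.5 °C, strict
  inequalities — and retained alongside the scaled features. The
  thresholds are meaningless after scaling, so the operation guards
  against being run on already-normalized data (every heart rate
  ≤ 1.0 trips it).
* **Rolling features** are trailing (causal) 30-minute time windows
  including the current sample: mean heart rate, mean temperature, and
  activity variance. Causal windows are used because real-time edge
  inference cannot see the future. Variance uses the population
  (divide-by-n) convention, so a single-sample window has variance 0
  and the two-sample case [0.2, 0.4] gives exactly 0.01.
* **Scaling** is min–max to [0, 1]. Bounds are learned once from the
  union of the training clients' processed tables, frozen, shipped with
  the model, and applied with clipping to held-out data. Degenerate
  features (max = min) map to 0. A single global bound set (rather
  than per-client bounds) keeps the feature geometry consistent across
  clients, which the shared global model requires.
* **Windows** slide per animal over contiguous samples (length 8,
  stride 1 for training, stride 8 for evaluation so test windows do not
  overlap). The window label is its final row's label — detection at
  window end. The model-input features are the five numeric sensor
  channels plus the three rolling features (8 total); GPS is excluded.

## Model and training

The classifier is a 1-D-convolutional LSTM: valid temporal convolution
with ReLU over the window, the standard four-gate LSTM recursion over
the resulting sequence, the last hidden state through a dense+ReLU
layer into a single sigmoid logit. The printed gate equations omit the
forget gate's own equation while using f_t in the cell update; the only
consistent completion is the standard f_t = σ(w_f·[h_{t−1},x_t]+b_f),
which is what is implemented. A single sigmoid logit is used because
σ(u) equals the class-1 probability of a two-class softmax with logits
(0, u); this honors both the softmax head description and the binary
cross-entropy loss.

Because no autodiff framework is a dependency, backpropagation through
time is hand-derived and verified against central finite differences
(relative error ≤ 1e-4 on a 49-parameter model; the suite checks both
the LSTM-only and the CNN+LSTM paths). Gradients follow the exact
(unclipped) objective dL/du = p − z; the loss value clips p to
[1e-7, 1−1e-7] to stay finite.

**Initialization**: weights uniform(−0.08, 0.08), biases 0, seeded.
**Optimizer**: mini-batch Adam (β₁ 0.9, β₂ 0.999, ε 1e-8), batch 32,
learning rate 0.001, seeded shuffling.

**Sizes.** Parameters are held in float64 during training and
serialized at 32-bit. The shipped default (32 conv channels, kernel 3,
256 LSTM units, 64 dense units, 8 features, window 8) has 313,249
parameters ≈ 1.20 MB serialized, inside the ~1–2 MB on-air budget the
communication model assumes; `init_params` enforces a 2 MiB ceiling.
For end-to-end experiments on a single CPU core the package also ships
`desk_model_config()` (8 channels / 32 LSTM / 16 dense, ~6k
parameters); this is the package's desk-scale choice for the study runs
and the acceptance script, while the full-size default is what the
size and communication accounting describe.

## Federated orchestration

Each round: broadcast the global vector, sample ⌈participation·n⌉
clients without replacement (round-derived seed; a no-op at the default
100% participation), run E = 5 local epochs per client with a *fresh*
Adam (stateless clients — the broadcast-then-train reading of the
protocol), aggregate by the sample-size-weighted mean. Defaults: 10
clients, 50 rounds, full participation.

Aggregation is computed in client-id-sorted order, anchored at the
first update (k₀ + Σ w_y(k_y − k₀)) with pairwise summation. This is
algebraically the weighted mean but bit-exactly permutation-invariant,
an exact fixed point when all updates agree, and exact in the
single-client case.

The **centralized baseline** trains the same architecture on the pooled
windows in T blocks of E epochs with a fresh Adam per block — the
identical schedule a lone federated client follows — so optimization
budgets match and the one-client federated run reproduces centralized
training bit for bit (a structural correctness check the suite
enforces).

The **communication ledger** books one uplink and one downlink payload
per participant per round, payload = 4 bytes × parameter count + a
fixed 64-byte container header. 1 MB = 2²⁰ bytes throughout. With the
~1.2 MB default model, 10 clients and 50 rounds this gives ≈600 MB each
way; no latency, transport, stragglers, encryption or differential
privacy are simulated.

**Evaluation** is window-level on a global held-out set: 20% of animals
(at least one) never assigned to any client. Decision threshold 0.5,
strict; undefined precision/recall map to 0 with a warning.

## Study sizes and determinism

The end-to-end study (tests and acceptance script) uses the default
herd — 20 animals × 7 days × 15-minute sampling ≈ 13,400 rows — 10
clients, 20 rounds × 5 epochs, and the desk-scale model; it completes
in a few minutes on one core. All results are bit-reproducible on one
platform from the master seed alone; the written manifest (config,
seeds, versions) suffices to re-run any experiment.

## Known limitations

* Proxy labels are thresholded physiology, not clinical ground truth;
  the simulator's stress construct is exactly the construct the labels
  measure, which is why near-ceiling test metrics are attainable here
  and should **not** be read as a claim about real herds. Passing the
  suite shows the machinery is correct, not that real cattle stress is
  97% detectable.
* The z-score screen removes some genuine extreme stress rows along
  with sensor spikes (anything beyond 3 SDs), slightly eroding the
  positive class.
* Humidity is uncorrelated with temperature and activity; real
  heat-stress indices (e.g., THI) couple them. Cross-channel
  correlations are not calibrated to any real dataset.
* Very small, heavily imbalanced training sets can park the model at
  the base-rate constant prediction (the input-pathway gradient is weak
  relative to mini-batch noise, and ReLU units can die at learning
  rates well above the 0.001 default); the study-scale runs are not in
  this regime.
* The CNN branch operates on sensor windows; an image/video branch is
  out of scope and exists only as the temporal front-end interface.
* No network transport is simulated; the ledger is analytic accounting,
  not a measurement.
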