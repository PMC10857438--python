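# Methods

## Data model and preprocessing

A CASAS-style event log is a time-ordered sequence of sensor firings:
motion sensors emit ON/OFF, door sensors OPEN/CLOSE, temperature sensors
numeric readings. Activity annotations mark only the first and last event
of an episode (`X begin` ... `X end`); `propagate_activity_labels` expands
these brackets to per-event labels. Brackets that nest or interleave are
resolved innermost-wins — the most recently opened activity claims the
events — with a warning; the annotation format does not define this case,
and innermost-wins matches the intuition that a briefly interrupting
activity (a bathroom visit during the night) is the one actually
happening. An unmatched `begin` is closed at the last event; a stray `end`
leaves its event unlabeled.

Cleaning removes records with missing fields, exact duplicates (identical
timestamp/sensor/state triple — annotation differences do not make two
firings distinct), and all temperature readings: temperature is excluded
from feature extraction and modeling throughout. Sorting is stable so
near-sorted logs keep their file order on timestamp ties. Timestamps with
either `.` or `:` fraction separators are accepted and normalized to
microseconds.

Aruba-dialect semantics drop windows without propagated labels and the
rare "Resperate" activity before modeling; Milan-dialect semantics map raw
annotations onto ten consolidated ADL categories and send unlabeled time
to "Other". Unknown raw labels map to "Other" by default (configurable to
raise) so a novel annotation cannot silently crash a long run.

## Feature extraction

Every non-overlapping block of 30 events becomes one vector of length
2S + 14 (S = number of non-temperature sensors): 14 window-level summaries
(clock features of the last event, block duration, inter-event gap,
dominant sensors of the two preceding blocks, last sensor and location,
entropy of the sensor-count distribution, event-rate change between block
halves, location transitions, distinct-sensor count), then S per-sensor
counts, then S per-sensor recencies. Choices where the layout leaves room:

- Categorical features (sensor and location identities, day-of-week) are
  integer indices over the sorted sensor map, not one-hot blocks — one-hot
  encoding would break the 2S + 14 dimensionality.
- "Time of the last event (seconds)" is seconds-of-day (not
  seconds-within-hour); the hour feature already carries the coarse scale.
- "Change in activity level" is the difference in event rate (events/s)
  between the second and first half of the block.
- Entropy uses the natural log; any fixed base differs only by a scale
  that standardization removes.
- Per-sensor recency is measured from that sensor's most recent firing to
  the block's last event; sensors never yet seen get a sentinel capped at
  the dataset's time span.
- A block's label is the majority of its events' labels, ties broken by
  the last event's label; windows may span activity boundaries and the
  window inherits the label of its last feature vector.
- The first block has no predecessor: the "dominant sensor of the previous
  window" features fall back to the current block's dominant sensor.

Vectors are cut into sliding windows (T = 10, stride 5 at the default 50 %
overlap, so n = floor((N−10)/5) + 1 windows), and standardized per feature
channel to zero mean and unit variance. Statistics are fit on the training
split only — fitting on all data would leak test information — and a
channel whose spread is rounding noise relative to its level is treated as
constant and mapped to zero rather than amplifying float cancellation.

## Augmentations

Five candidate view transforms: random signal inverting (sign flip with
probability 0.5 per window — a deterministic flip of both views would
cancel in the contrastive objective), time reversing, time warping (a
random monotone warp curve with 4 interior knots, log-normal increment
multipliers, linear re-sampling back to the T grid), additive Gaussian
noise, and multiplicative scaling. Scaling draws one factor ~ N(1, σ²)
per (window, channel), shared across the 10 timesteps: per-element factors
at σ = 0.1 would collapse into unstructured jitter. The default is scaling
with σ = 0.1, the strongest performer in the augmentation comparison; both
views of a window are augmented (symmetric view generation), and all view
generation is bit-reproducible under a fixed generator.

## Architecture

Input (batch, 10, F) → conv1d(32 filters, kernel 3, ReLU, dropout 0.1) →
conv1d(64, kernel 3, ReLU, dropout 0.1) → LSTM(64 units, all hidden
states) → multiplicative self-attention → global max-pool over time →
64-d embedding. The projection head (256 → 128 → 64, ReLU on the hidden
layers) is used only during pre-training. Classifier heads: a single dense
softmax layer for linear probing; dense-ReLU → dense-softmax (hidden 64)
for fine-tuning.

The parameter budget pins the architecture exactly:
conv1 (3F·32 + 32) + conv2 (32·3·64 + 64 = 6,208) + LSTM
(4·((64+64)·64 + 64) = 33,024) + attention (64² + 1 = 4,097) + projection
(57,792) = 109,217 for F = 84 and 108,833 for F = 80. This forces several
details: the attention bias is a single scalar, the attention layer has no
output projection, and the LSTM is the standard gate formulation with
biases and no peepholes. Convolutions use same-padding so attention always
sees all 10 steps (padding does not change parameter counts). Dropout
regularizes only the conv layers; L2 (1e-4) applies to conv kernels and to
the attention weight matrix. Max-pooling acts on the attention context
sequence, after the attention layer. An ablation switch
(`use_attention=False`) removes the attention layer for the plain
contrastive variant.

## Optimization

NT-Xent is computed in matrix form (row-normalized embeddings, full
similarity matrix, self-pairs excluded from each row's stabilized
log-sum-exp) and verified against a naive double-loop transcription to
1e-6. Pre-training uses SGD with cosine learning-rate decay (initial 0.1,
1000 decay steps, floor 0), batch 512, 100 epochs, temperature 0.1;
downstream phases use Adam (1e-3), batch 128, 300 (probe) / 200
(fine-tune) epochs. SAM computes the ascent direction from the global
gradient 2-norm over all parameters jointly, with ρ = 0.05 — the canonical
radius, since none is published for this model — and can wrap any phase,
so the four variants (plain, +SAM, +attention, +both) are expressible;
with ρ = 0 the trajectory is bit-identical to the base optimizer. During a
SAM step the dropout masks of the two loss evaluations are replayed
identically, so the perturbation is measured on the same stochastic
network. Cross-entropy (with the same L2 terms) drives both downstream
phases. No early stopping, learning-rate restarts, or class re-weighting.

The whole stack runs on a small in-repo reverse-mode autodiff engine over
numpy (float64). Gradients of every primitive and of the full model loss
are checked against central finite differences; the only caveat is the
ReLU kink, where one-sided derivatives differ and the engine returns the
standard subgradient.

## Synthetic data

The simulator realizes a semi-Markov activity process: an activity is
drawn from a time-of-day prior (a von-Mises-shaped weight around each
activity's peak hour) with an optional self-transition preference, holds
for a log-normal duration, and fires its room-affine motion sensors as a
Poisson process (ON plus a short OFF echo per firing); door-using
activities bracket the episode with OPEN/CLOSE. Episodes are contiguous —
CASAS activities are bracketed intervals, which a per-event Markov chain
would not reproduce. Annotations are written exactly as real logs
(begin/end on the episode's first/last event), ground truth is returned
per event, and `label_noise` drops a fraction of annotations without
touching events. With `tod_concentration = 0` everywhere, the expected
event count has a closed renewal-theory form used as the simulator's
statistical oracle.

The default home has 5 activities with disjoint room affinities and
realistic rates/durations (sleeping: long, sparse; toilet visits: short,
dense). Disjointness gives well-separated signatures, so a fully
supervised run approaches perfect F1 — the sanity ceiling for the
protocol tests. What the simulator deliberately does not model: shared
sensors between activities, visitor/pet noise, annotation ordering errors,
sensor failures, or any fit to real CASAS statistics. Passing protocol
tests therefore demonstrate that the pipeline learns transferable
structure when structure exists, not field performance on real homes.

## Reduced desk-scale budgets

Tests and the acceptance run use a week of simulated events (~1,400
windows), 10 pre-training epochs at batch 128, and 100-epoch downstream
runs. These budgets were chosen as the package's fast configuration: the
contrastive loss has visibly converged on the synthetic task and the
protocol orderings (pre-trained > random encoder; fine-tune ≥ probe;
monotonicity in label fraction) are stable across seeds at these sizes.
The full published budgets remain the `TrainConfig` defaults. The probe
comparison between pre-trained and random encoders is run at a 20 % label
fraction: with all labels revealed, a linear probe on this separable
synthetic task saturates for any encoder, and the limited-label regime is
precisely the setting the method targets.

## Known limitations

- Pure-numpy training is single-threaded per matmul chain and roughly two
  orders of magnitude slower than a GPU framework; full-budget replication
  on real CASAS corpora takes hours of CPU.
- The parser accepts the two timestamp dialects above; other CASAS field
  layouts (e.g. combined sensor-translate files) need pre-conversion.
- Weighted-average F1 is reported by default (switchable to macro); under
  heavy class imbalance weighted F1 tracks accuracy and can mask minority
  classes — inspect the per-class table in `EvalReport`.
- Checkpoints embed the architecture config but not optimizer state;
  training resumption restarts the schedule.
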