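# Methods

## Scope and model overview

breathnet implements a complete breathing-event analysis pipeline for
two-site (chest + upper abdomen) IMU recordings: signal simulation, event
injection into labeled 30-s segments, 1D-CNN window classifiers, a residual
per-second detector, and an evaluation toolkit. This note documents the
modeling choices, the defaults and their rationale, what the simulator does
and does not emulate, and the numerical conventions.

## The signal simulator

### Waveform model

Real annotated wearable recordings of simulated breathing events are not
publicly available, so the package generates them. Quiet breathing on each
channel is modeled as

```
x_c(t) = b_c + A k_c m(t) + sigma_c eps(t)
```

where `b_c` is a constant per-channel baseline (the accelerometer z-axes
carry the 1-g gravity offset; all other channels are zero-mean), `k_c` a
fixed per-channel respiratory coupling (z accelerometers dominate; gyro
couplings are scaled to deg/s), `A` the subject's breath amplitude, and
`m(t)` a quasi-sinusoid: unit cycles whose period and amplitude jitter
cycle-to-cycle (sd 6% and 10%) plus a 15% second harmonic for breath
asymmetry. `eps` is white Gaussian noise. The abdomen tracks the chest with
a small phase offset (default 0.1 rad).

This is deliberately the simplest model that carries the discriminative
structure of the six classes:

| class | morphology | default duration |
|---|---|---|
| normal | in-phase chest/abdomen quasi-sinusoid | — |
| CSA | respiratory amplitude 0 (breath hold); noise only | 30 s holds |
| OSA | chest/abdomen shifted anti-phase (default pi), 1.5x amplitude, 1.3x rate | 6-10 s |
| cough | 10-25 Hz bursts (one per ~0.7 s), 4x amplitude, breathing suppressed | 1-1.8 s |
| sigh | one exaggerated full breath cycle spanning the clip, 2.5x amplitude | 3-5 s |
| yawn | slow inspiration (>= 4 s rise) then faster release, 2x amplitude | 4.5-7 s |

The OSA anti-phase default encodes paradoxical thoraco-abdominal motion:
with the upper airway occluded, inspiratory effort moves chest and abdomen
in opposite directions. Amplitude multipliers, burst bands, and the phase
shift are all `SubjectProfile` fields, so class separation can be widened
or narrowed per experiment; the defaults are chosen to be strongly
separable (a respiratory-band-power matched filter separates CSA from
normal breathing with 100% accuracy over 50 draws, asserted in the tests),
because the learnability experiments are only meaningful if the classes are
separable in principle.

### Protocol sessions

`simulate_subject_session` emulates one subject's protocol: a 300-s normal
block, one 30-s CSA hold, and five repetitions each of cough, sigh, yawn,
and OSA, in seeded-random order, separated by 5-15 s normal gaps (the gap
range is a package choice; a physician-paced protocol leaves natural pauses
of this order). Every span, including gaps, is annotated. Cohorts draw
per-subject breathing rate and amplitude with 15% lognormal-ish jitter
(clipped Gaussian multipliers).

### What the simulator does not emulate

Posture changes, sensor drift and re-orientation, motion artifacts, cardiac
ballistics, and inter-subject morphology beyond rate/amplitude scaling.
Passing tests therefore demonstrate that the pipeline and models are
correct and can learn the encoded class structure — not that the trained
desk models would transfer to real wearable data.

## Dataset construction

Events are injected at integer-second boundaries so that the 30 per-second
labels are unambiguous (the documented alternative — arbitrary placement
with majority-occupancy labeling — would make label boundaries fuzzy).
Non-CSA clips keep their full duration, rounded up to whole seconds with
the remainder of the final second left as normal-breathing samples, capped
at 14 s; CSA clips are cropped from the clip start to the drawn duration.
Two events in one segment may repeat a class (draws are uniform over the
five classes without exclusion). The proportions of 0/1/2-event segments
default to 10/60/30% and are a config parameter. Boundary smoothing
replaces the first and last sample of the actually injected clip span with
their per-channel average with the adjacent sample; smoothed samples keep
the event label.

Classification windows are centered on each pooled event clip. Clips
shorter than the 7-s window are padded symmetrically with reservoir
normal-breathing context (excised clips carry none of their own) and the
pad boundaries are smoothed; longer clips are center-cropped with a
warning. Normal windows are drawn from reservoir positions; their default
count is the mean event-class count. Balancing down-samples every class to
the minimum class count. Splits are unstratified seeded uniform partitions
at the segment/window level with fractions 60/20/20.

At 40,000 segments the waveforms would occupy several GB, so
`build_detection_dataset(materialize=False)` draws the complete plans,
labels and split without synthesizing waveforms; ids, plans, and split are
identical to the materialized build at the same seed (asserted in tests).

## Models and training core

No GPU deep-learning framework is assumed: `breathnet.nn` is a compact
numpy training core (1D convolution with 'same' padding and arbitrary
stride, batch normalization, max pooling, dense/time-distributed dense,
inverted dropout, residual blocks with 1x1 projection shortcuts, sigmoid
and softmax cross-entropy from logits, RMSprop and Adam, reduce-on-plateau
lr schedule). All backward passes are hand-derived and checked against
central-difference gradients at 1e-7 tolerance in float64. L2
regularization is applied as weight decay (`dW += 2*l2*W`) on conv/dense
kernels, equivalent to adding `l2*sum(W^2)` to the loss; reported losses
exclude the penalty term.

### Architectures

Classifier (binary and multi-event): 6 x [conv -> batch norm -> ReLU ->
max-pool 2] then flatten and 3 x [dense -> ReLU -> dropout 0.5] and the
output layer — 6 convolutional and 4 fully connected layers. Defaults at
full scale: kernel 100, filters (32, 64, 96, 96, 64, 64), dense widths
(256, 128, 64); these widths are package choices in the AlexNet-style
progression, all overridable. L2 is 0.1 for the binary head and 0.001 for
the multi head; optimizer RMSprop at lr 1e-3.

Detector: initial conv -> batch norm -> ReLU, four residual blocks of two
convolutions each (widths doubling from the base), a per-second
time-distributed dense + softmax. Temporal downsampling is by strided
convolutions with total stride 125, chosen over pooling/interpolation so
the output time axis is exactly one row per second. The residual shortcut
is a 1x1 strided linear projection whenever width or resolution changes.
Optimizer Adam at lr 1e-3 with a reduce-on-plateau schedule (factor 10,
patience 3). With first kernel 384 and the same in-block kernel, the
full-scale parameter count is ~2.02 x 10^8; the in-block kernel size is a
package choice made for consistency with the wide first layer. Layer-depth
bookkeeping (conv + batch norm + activation + fc) is reported by
`Network.layer_counts()` but never asserted, since depth-counting
conventions vary.

### Scale presets

Full-scale training of the detector is a GPU-class workload, so every
architecture has a `desk` preset that preserves all structural relations
(6+4 classifier layers; 1+8 detector trunk convolutions; input length =
per-second outputs x 125) at CPU-friendly width: classifier kernel 25 with
filters (8, 8, 12, 12, 12, 12); detector first kernel 128 with stride 5,
in-block kernel 17, base 8 filters, block strides (5, 5, 1, 1). Moving the
first factor-5 downsampling into the initial convolution keeps the
receptive field wide while cutting the dominant first-layer cost
five-fold. The desk learnability experiment uses 500 segments from a
10-subject cohort, 15 epochs, batch 16 — sized to finish in a few minutes
on one CPU while leaving a comfortable margin over its macro-F1 bar.

### Determinism and numerical conventions

All randomness flows from explicit seeds through `numpy.random.Generator`
(SeedSequence spawning for independent streams: shuffling, dropout, splits,
plans). Two fits with identical data and seed produce identical histories
and weights. Activations and weights are float32 in production configs
(float64 in gradient tests). Batch normalization uses eps 1e-5 and
momentum 0.9; inference uses running statistics. Inputs are standardized
per channel with training-set statistics (stored with the model) — the 1-g
gravity offset otherwise dwarfs the respiratory signal. Max pooling drops a
trailing odd sample, as framework pooling conventionally does. Non-finite
batch or validation losses abort training with a diagnostic rather than
continuing silently.

## Evaluation conventions

Precision/recall/support and confusion matrices come from scikit-learn;
F1 is computed as the harmonic mean of the reported precision and recall,
with the convention 0 when both are 0; classes with zero support or zero
predictions are flagged in the report. Confusion percentages are
row-normalized (per true class). ROC/AUC uses the trapezoidal curve, which
equals the pairwise-probability definition with ties counted 1/2 (asserted
against a brute-force pairwise oracle). Onset lag matches each true event
span to the same-class predicted run with the largest overlap (earliest
onset breaks ties); unmatched events are listed separately rather than
assigned a lag.

## Known limitations

* Synthetic signals only; no claim of transfer to real wearable data.
* The desk-scale learnability result is a correctness/learnability check,
  not a performance benchmark; cough, the shortest class, loses the most
  F1 to single-second boundary effects at this scale.
* The numpy core trains small models efficiently but is not suitable for
  the ~2 x 10^8-parameter full-scale detector; that configuration is
  constructed and audited analytically.
* The accelerometer-only ablation is available via `channel_mask` but no
  tuned accelerometer-only configuration is shipped.
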