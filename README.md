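# breathnet

Detection and classification of clinically significant breathing events —
central sleep apnea (CSA), obstructive sleep apnea (OSA), coughing, sighing,
and yawning — in 12-channel inertial (IMU) recordings from two skin-worn
sensors on the chest and upper abdomen, using 1D convolutional neural
networks. The package is aimed at researchers in respiratory monitoring and
digital health who want a fully reproducible, self-contained pipeline: since
no public accession exists for this kind of annotated wearable recording, a
physiologically structured signal simulator stands in for subject data, and
every downstream stage (event injection, training, evaluation) runs on it.

## What it computes

Each recording is a `T x 12` matrix sampled at 125 Hz: {chest, abdomen} x
{accelerometer, gyroscope} x {x, y, z}, accelerometer in g, gyroscope in
deg/s. Three models operate on these signals:

* a **binary window classifier** (one event class vs normal breathing) and a
  **multi-event classifier** over all six classes, both AlexNet-style 1D
  CNNs — 6 convolutional layers (batch norm + max pooling after each) and 4
  fully connected layers with 50% dropout — applied to 7-s windows
  (875 time steps x 12 channels = 10,500 features);
* a **per-second residual detector**: a wide initial convolution (kernel
  384 at full scale, viewing ~3 s of signal) followed by 4 residual blocks
  of 2 convolutions each (widths doubling 64 -> 512, ~2 x 10^8 parameters at
  full scale), with strided convolutions downsampling time by a factor of
  125 so a 30-s segment (3750 samples) yields one six-class softmax per
  second: `y_s = softmax(W h_s + b)`, `s = 1..30`.

Training segments are built by **event injection**: 30-s spans of normal
breathing receive 0, 1 or 2 excised event clips. A single injected CSA draws
its duration from {10, 20, 23} s; with two events the first lands entirely in
the first 15 s and the second in the second 15 s (CSA then draws from
{10, 11, 13} s), so events never overlap. At each injection boundary the
first and last clip samples are averaged with the adjacent normal sample on
every channel. Each second gets a class label; the standard split is
60/20/20 train/validation/test.

Evaluation reports per-class precision P, recall R, F1 = 2PR/(P+R), support,
count and row-normalized confusion matrices, ROC/AUC for binary tasks (AUC
equals the probability that a random positive outscores a random negative),
and signed onset lag (predicted minus true onset) for matched event runs.

## Worked example

```python
import numpy as np
import breathnet as bn

# simulate a cohort, excise annotated events, build labeled segments
sessions = bn.simulate_cohort(10, seed=7)
pool = bn.extract_event_pool(sessions)
segments, split = bn.build_detection_dataset(pool, n_segments=500, seed=7)
by_id = {s.segment_id: s for s in segments}
X = np.stack([by_id[i].data for i in split.train]).astype(np.float32)
Y = np.array([by_id[i].labels for i in split.train])

det = bn.BreathingEventDetector(
    scale="desk", epochs=15, seed=7, validation_fraction=0.0
)
det.fit(X, Y)
Xt = np.stack([by_id[i].data for i in split.test]).astype(np.float32)
Yt = np.array([by_id[i].labels for i in split.test])
print(det.second_level_report(Xt, Yt).to_table())
```

prints (desk-scale run, 500 segments, seed 7):

```
           Precision  Recall F1-Score  Support
normal          0.98    0.99     0.99     2153
csa             0.99    0.99     0.99      340
cough           0.92    0.40     0.56       57
osa             0.98    1.00     0.99      222
sigh            1.00    0.99     1.00      105
yawn            0.98    0.99     0.98      123
macro avg       0.98    0.89     0.92     3000
```

Support counts are labeled seconds in the held-out test split (100 segments
x 30 s). Coughs are the hardest class at this scale: they last 1-2 s, so a
single mislabeled boundary second is a large fraction of their support.

The same pipeline is scriptable from the shell:

```bash
breathnet simulate --subjects 10 --seed 7 --out sims/
breathnet build-dataset --pool sims/ --n 500 --seed 7 --out data/
breathnet train --task detect --data data/ --epochs 15 --seed 7 --out det.npz
breathnet evaluate --model det.npz --data data/ --out eval/
breathnet run-all --subjects 10 --segments 500 --seed 7 --out run/
```

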