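# Methods

## Problem setting

A body-worn smartphone records nine synchronized channels — triaxial
accelerometer, triaxial gyroscope, and azimuth/pitch/roll orientation —
while the wearer moves through a sequence of activities. The package
addresses unsupervised discovery of those activities: a feature
extractor is trained once with labels (phase 1), after which clustering
of its latent features (phase 2) runs without labels and is evaluated
against the held-back ground truth. Transitional movements between
stable activities are of particular interest because they rarely carry
labels of their own and overlap both flanking activities.

## Stream simulator

The simulator produces labeled 9-channel streams with the statistical
features the pipeline is sensitive to; it is not a biomechanical model.

* **Per-activity signature.** Each activity `j` has per-channel
  amplitude `a`, frequency `f`, phase `φ` and DC baseline `b`; channel
  `c` emits `b_c + a_c sin(2π f_c t + φ_c)` plus i.i.d. Gaussian noise.
  Static postures use `f = 0`. Default signatures spread frequencies
  over 0.5–4.5 Hz (the human gait band) with 10% per-channel jitter,
  amplitudes over 0.5–2 sensor units, phases uniform.
* **Semi-Markov bouts.** Bout durations are truncated normal
  (default mean 5 s, SD 1.5 s, floor one sample — typical of scripted
  activity-trial segments); the next activity is drawn from a
  row-stochastic transition matrix. The default chain's stationary
  distribution is mildly imbalanced (largest/smallest weight ratio 2),
  so common activities outnumber rare ones as in real recordings.
* **Transitions.** Consecutive bouts are joined by a linear cross-fade
  (default 0.25 s) so activities flow into one another. Cross-fade
  samples are labeled with the incoming activity by default — mirroring
  how benchmark datasets label unannotated transitions — or with a
  reserved extra class (`transition_label="reserved"`) for studying
  transitional overlap explicitly.
* **Defaults.** 200 Hz sampling (smartphone-like; 50 Hz for UCI-style
  fixtures), noise SD 0.15 against signal amplitudes of 0.5–2, total
  duration 120 s for the study-scale experiments.

What the simulator does *not* reproduce: non-stationary signatures,
gravity orientation drift, sensor saturation, inter-subject variability,
or realistic fall dynamics. Passing results on simulated data therefore
demonstrate that the pipeline's machinery is correct and that it
recovers class structure when one exists — not that the published
accuracies on any real benchmark would be matched.

## Preprocessing

* **MinMax scaling** per channel to a target range, `(0, 1)` for
  sigmoid-output autoencoders and DEC, `(−1, 1)` where a symmetric range
  is wanted. Constant channels map to the lower bound. Statistics come
  only from the data given to `fit`; the pipeline fits on the training
  split by default (`fit_on: all` reproduces whole-dataset scaling).
* **Segmentation.** Sliding windows of `w` samples with step
  `max(round(w(1−overlap)), 1)`; the trailing partial window is
  discarded, giving `floor((T−w)/step)+1` windows. The window label is
  the majority sample label, ties resolved to the last sample's label.
  Default window 200 samples (1 s at 200 Hz) at 50% overlap; 128-sample
  windows are used for UCI-layout data, which ships pre-segmented.
* **SMOTE.** Minority classes are upsampled to the majority count by
  convex interpolation `x + u(x_nn − x)`, `u ~ U(0,1)`, between a window
  and one of its `k = 5` nearest same-class neighbours (Euclidean
  distance on flattened windows). Originals are never modified. Classes
  with a single window are rejected with advice to merge or exclude.

## Extractor families

All families end in a latent layer of `latent_dim` (default 64) and are
trained either as classifiers (softmax head, categorical cross-entropy)
or, for the three autoencoder families, with MSE reconstruction and a
sigmoid output layer (inputs must be scaled to `[0, 1]`).

| family | architecture |
|---|---|
| `cnn2d` | window reshaped to `[w, 3, 3]` (per time step the rows are the acc/gyro/orientation triples); two blocks of conv(3×3) → max-pool(2×1) → batch-norm; dense to latent |
| `mlp_ae` | flatten → dense 128 → bottleneck 32 (ReLU hidden, sigmoid output in the decoder) |
| `lstm_ae` | conv1d(64, k5) → pool(2) → LSTM 128 → LSTM 64; decoder repeats the latent and mirrors the recurrent stack (64 → 128) |
| `hybrid_conv_lstm` | conv1d 64 → pool 2 → conv1d 32 → pool 2 → dropout → LSTM 64 → dense 128 → latent |
| `timedist_te` | window cut into 8 slices; per-slice conv1d(64, k3) + pool + flatten (time-distributed); LSTM 64 over slices |
| `tri_head_te` | three conv1d heads with kernels 5, 7, 11 (each + dropout + pool), concatenated; BiLSTM 64 → BiLSTM 32 → dense latent + batch norm |

Hyperparameters the architecture descriptions leave open are fixed at
field-typical values and recorded in the resolved spec: 64 filters
(32 per tri-head branch), dropout 0.3, pooling 2, Adam at learning rate
1e-3, batch 32. LSTM forget-gate biases start at 1. A `bidirectional`
flag swaps LSTM for BiLSTM in the recurrent families. Geometry
constraints (window length divisible by the pooling/slicing factor) are
validated at spec time with a padding suggestion in the error. Training
seeds control weight initialization, shuffling and dropout; inference
disables dropout and uses batch-norm running statistics, so encoding is
deterministic.

The engine (`harclust.nn`) is a deliberately small numpy implementation
with hand-written backward passes; every layer is verified against
central finite differences in the test suite. Batch-norm running
statistics are seeded from the first training batch so that short
trainings are not biased by the arbitrary (0, 1) initialization.

## Clustering

**Student-t K-Means.** Centroids come from standard Lloyd iterations
with k-means++ seeding (best inertia of `n_init = 10` restarts). The
converged centroids are scored with the Student-t kernel

    q_ij = (1 + ‖z_i − μ_j‖²/α)^−(α+1)/2 / Σ_j' (…),   α = 1 by default.

Hard labels are `argmax_j q_ij` (ties to the lowest index). Whether the
soft responsibilities should also drive centroid re-estimation is left
open in the source method; the default scores the converged centroids
post hoc, and `soft_update=True` enables responsibility-weighted
centroid iteration until the centroids stabilize.

**DEC.** The clustering autoencoder is the classic dense
500–500–2000→10 with mirrored decoder (ReLU hidden layers, linear
bottleneck; sigmoid output when the input lies in `[0, 1]`, linear
otherwise — latent features are generally unbounded). The schedule is:
MSE pretraining (`pretrain_epochs`, 300 to follow the original recipe;
scaled down in tests), k-means initialization of the centroids on the
embeddings, then minibatch gradient steps on `KL(P‖Q)` with the target
`P` recomputed every `update_interval = 140` steps (50 at desk scale).
Training stops when the fraction of hard labels changed between
consecutive target updates falls below `tol = 0.001`, or at
`max_iter = 20 000` steps. Gradients of the KL objective with respect to
the embeddings and centroids are analytic and finite-difference-checked;
per-update KL is recorded twice — against the freshly sharpened target
(which is non-monotone by construction, since each new `P` measures how
far `Q` still is from one-hot) and within each fixed-target interval,
where gradient descent must not increase it. The latter is the
monotonicity the tests assert.

`k` is always supplied by the caller; no model-selection procedure is
included. Density-based and weightless-network alternatives can be
plugged in by the caller on the same latent features but are not
implemented here.

## Evaluation

NMI uses the geometric-mean normalization (the convention is not fixed
by the source tables; on well-separated fixtures the choice is
immaterial) with natural logarithms; ARI is the chance-corrected Rand
index; cluster accuracy is the maximum fraction correct over one-to-one
cluster→class mappings, solved as a maximum-weight bipartite matching.
All three are cross-checked in the tests against brute-force oracles
(direct entropy summation, pair counting, exhaustive `k!` mapping for
`k ≤ 5`).

## Visualization

Latent features are summarized as an exact Euclidean kNN graph
(tie-break by lower index) reduced to a minimum spanning forest
(Kruskal with lexicographic `(weight, i, j)` tie-break — deterministic),
exported as GraphML with true and cluster labels as node attributes.
Exactness replaces the approximate-MST machinery that large-scale
tree-map layouts need; at desk scale (hundreds of windows) it is
cheaper and reproducible. `transition_adjacency_fraction` measures how
many transition-labeled nodes are tree-adjacent to their flanking
activities — the tree-level signature of transition windows bridging
two activity clusters.

## Pipeline

`run_pipeline` chains simulate → preprocess → train → extract → cluster
→ evaluate → visualize under one schema-validated config (unknown keys
rejected by name) and a single global seed; every artifact is written to
the run directory and SHA-256-checksummed into a manifest that fully
re-describes the run. Splits are stratified 64/16/20 by window.

## Problem sizes and numerical choices

The study-scale experiments use 6 activities × 120 s × 200 Hz → 239
windows of 200 × 9, 20 training epochs; the separable unit-test fixture
uses 3 activities × 60 s × 50 Hz with 64-sample windows (label-pure
windows only). DEC demonstrations use 600 points in 10-D with three
moderately overlapping Gaussian blobs, a (64, 64)→5 autoencoder, and
`update_interval = 50`. These sizes were chosen so the full study reruns
in minutes on one CPU while leaving every qualitative behaviour intact;
scaling up is a matter of config values.

Degenerate cases are defined, not special-cased away: constant channels
scale to the range minimum; identical centroids give uniform soft
assignments; `KL` uses the `0·log 0 = 0` convention and returns `inf`
with a warning when `Q` lacks support where `P` has mass; duplicate
points produce zero-weight kNN edges; argmax ties resolve to the lowest
index everywhere.

## Known limitations

* The simulator's sinusoidal signatures are linearly separable given
  enough capacity; real inter-class confusion (e.g. walking upstairs vs
  downstairs) is harder than anything tested here.
* The numpy engine is single-threaded and eager; it is sized for
  hundreds-to-thousands of windows, not for full benchmark corpora.
* Autoencoder-trained features are tested for mechanics and training
  dynamics, not for clustering quality parity with supervised features.
* `cnn2d` fixes one particular 2-D arrangement of the nine channels
  (3 × 3 sensor-triple grid per time step); other layouts are plausible
  and would need a different reshape.
* Full-sequence (unsegmented) training is out of scope; the readers and
  extractors operate on fixed-length windows only.
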