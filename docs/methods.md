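# Methods

`mgtcn` implements a dual-graph transformer/GCN pipeline for EEG-based
emotion recognition end to end, together with a synthetic EEG generator so
every stage is testable without access-restricted recordings. This note
documents the models, the numerical choices, and what the synthetic
experiments do and do not show.

## Pipeline

Raw input is a set of trials, each a channel × time matrix at sampling rate
`fs`, with one class label per trial. The stages, in order:

1. **Band-pass filter** 1–50 Hz, 4th-order Butterworth applied
   forward–backward (`sosfiltfilt`), so the filter is zero-phase and the
   waveform timing the nonlinear features depend on is preserved. The filter
   family and order are a package choice; a 4th-order zero-phase design
   attenuates a 60 Hz tone to roughly 7 % amplitude at `fs` = 200 Hz.
2. **Imputation and z-scoring**, per trial and channel: NaN samples are
   replaced by the channel's within-trial mean of the observed samples,
   *then* the channel is standardized to mean 0 / sd 1. Channels with
   sd below `zscore_eps` (default 1e-8) map to zeros rather than dividing by
   ~0. A channel that is entirely missing is an error.
3. **Windowing and baseline correction.** Trials are cut into consecutive
   non-overlapping windows of `window_len` seconds (trailing remainder
   dropped; overlap is not used because no stride is part of the published
   protocol). Within each window the first `baseline_len` seconds are the
   resting epoch; its per-channel mean is subtracted from the *entire*
   window. The baseline samples are retained — the window is re-centered, not
   truncated — and the operation is idempotent. Two bundled profiles:
   `seed` (8 s window, 2 s baseline) and `deap` (2 s window, 1 s baseline).
4. **Features**, per segment and channel (7 columns per channel,
   channel-major order):
   - *Higuchi fractal dimension*: average curve length L(k) over the k offset
     subsequences for k = 1..`hfd_kmax` (default 10; the source protocol does
     not state a value), HFD = least-squares slope of log L(k) on log(1/k).
     A straight line gives 1, white noise ≈ 2. A constant signal has zero
     curve length at every k; it returns 1.0 by convention with a warning.
   - *Histogram entropy* (nats): Shannon entropy of the amplitude histogram
     over `entropy_bins` (default 100) equal-width bins spanning
     [min, max], with 0·log 0 = 0. The conventional minus sign is used
     (H = −Σ pᵢ log pᵢ ≥ 0); a rendering of the formula without the sign
     would be non-positive, which we treat as a typographical artifact.
   - *Differential entropy* per band (delta 1–4, theta 4–8, alpha 8–13,
     beta 13–20, gamma 20–30 Hz): DE = log(var(x_band) + 1e-10), with the
     same Butterworth family as the preprocessing filter. Gamma is capped at
     30 Hz even though the preprocessing filter passes to 50 Hz, matching the
     published band table.
5. **PCA** to `pca_dim` components (default 64) after column
   standardization. The standardization statistics and the principal
   directions are fitted **on training rows only** and applied to all rows,
   so no test information can leak into the projection, even though the
   published description of the feature stage is silent on this point.

## Dual graph

Nodes are segments (samples). The published text describes correlations
"between feature dimensions" while its train/test masks and per-node class
predictions require nodes to be samples; we default to samples-as-nodes
(the only reading under which the whole pipeline type-checks) and ship the
features-as-nodes reading as an experimental secondary mode
(`GraphConfig.node_semantics`).

- **Physical proximity layer**: a complete topology — every ordered pair of
  distinct nodes connected with unit weight, no self-loops, n(n−1) directed
  edges. It is a uniform structural prior, not electrode geometry.
- **Functional connectivity layer**: Pearson correlation between node
  feature vectors, zero diagonal. Entries are thresholded at the mean
  off-diagonal magnitude (`abs_mean`, the default, so strong anticorrelations
  also form edges) or at the mean signed value (`signed_mean`); ties at the
  threshold are kept. The diagonal is excluded from the mean. Retained
  entries become directed edge pairs, with r carried as an (unused by
  default) edge weight. A zero-variance node gets no functional edges.

Graphs are built **within a split**: the train rows form one graph, the test
rows another, each with locally reindexed edges, so no edge ever connects a
train node to a test node and perturbing test rows cannot change any
train-side artifact.

## Network

A weight-shared encoder — two graph-transformer layers then one GCN layer —
is applied to both edge layers; the two 128-d per-node embeddings are
concatenated (256-d) and classified by FC(256 → 256) + batch-norm + ELU +
dropout, then FC(→ n_classes) + log-softmax. Trained with NLL loss.

- **Transformer layer**: per head h (8 heads of d_k = 16 by default),
  logits e_ij = (qᵢ·kⱼ)/√d_k over in-neighbors j of i,
  α_ij = softmax_j(e_ij), output the α-weighted sum of projected neighbor
  features; heads concatenated, then ELU. `qkv` mode (default) uses separate
  query/key/value projections; `shared_w` uses a single matrix for all three
  (the literal single-matrix form of the published equations — text and
  figure disagree, so both are provided). Dropout (default 0.5) is applied
  to α during training only. A node with no in-edges aggregates to zeros.
- **GCN layer**: symmetric degree normalization with self-loops,
  Âᵢⱼ = 1/√(deg i · deg j) on A + I, then batch-norm and ELU. Self-inclusion
  is a package choice (the published normalization constant is described
  only as degree-based).
- **Batch normalization** is transductive: every forward pass processes an
  entire split graph, and normalization always uses the statistics of that
  batch. This matters because attention over a complete topology averages
  over all nodes of the split, so activation variance depends on the split's
  node count; normalizing the test graph with train-graph running statistics
  systematically mis-scales it. Running statistics are still tracked per
  branch (physical/functional) during training, as fitted artifacts and
  diagnostics. The affine parameters are shared, as the weight-shared
  encoder requires.
- **Initialization**: uniform with fan-in scaling, seeded from
  `ModelConfig.seed`. All message passing is computed densely (the α matrix
  is materialized and masked), which is exact and fast for the
  hundreds-of-nodes graphs this package targets.
- **Ablation switches** remove the transformer stack, the GCN layer, or
  either graph branch; a removed branch halves the fused embedding, a
  removed layer type passes dimension-matched features through. Disabling
  both branches or both layer types is a configuration error.

## Training and evaluation

Adam (lr 1e-4, weight decay 5e-4), cosine-annealing schedule by default
(with a reduce-on-plateau alternative — the source describes both; the
experimental-setup section names cosine, so that is the default), at most
300 epochs with early stopping when validation loss has not improved for 10
epochs. The validation set is an internal stratified 10 % split of the
training rows (the published protocol never defines one inside the CV loop).
The best-validation parameters are restored before evaluation.

Evaluation is stratified 5-fold cross-validation. Per fold: accuracy,
per-class precision/recall/F1 from the confusion matrix closed forms
(micro-F1 equals accuracy for single-label data, used as a self-test), macro
aggregates (classes without support excluded, with a warning), and the
confusion matrix in counts and row-normalized percentages. Fold statistics
are reported as sample mean ± sd (ddof = 1). `run_ablation` repeats the CV on
identical folds per variant so comparisons are paired.

## Synthetic data

`generate_recordings` emulates the study conditions: 62 channels at 200 Hz,
balanced class labels, and class-dependent band structure. Each trial is a
sum over the five canonical bands of band-pass-filtered white noise
(4th-order zero-phase Butterworth) normalized to unit sd and scaled by the
trial class's row of `band_gain_table`, plus white noise (`noise_sd`,
default 0.5). Band-limited noise rather than sinusoids keeps HFD and entropy
non-degenerate. Realized band power therefore tracks gain²; the default gain
table separates the three classes by ≥ 2× in alpha and beta. All channels of
a trial share 30 % of each band component's variance (a common source plus
private sources), giving the functional graph non-trivial structure. The
first `baseline_len` seconds of each trial repeat the same process with all
gains halved — a measurable resting epoch for the baseline-correction stage
(the source never characterizes baseline statistics, so this is a package
choice). A per-subject log-normal amplitude factor (sd 0.05) adds mild
between-subject variability.

Not emulated: ocular/muscle artifacts, volume conduction, electrode
geometry, non-stationarity within a trial, and realistic 1/f background.
Passing the synthetic recovery test therefore shows the pipeline and model
are implemented coherently and can exploit band-power class structure; it
does not certify performance on real EEG.

`planted_correlation_features` builds the ablation instance: each class has
a hidden orthonormal template, each row is ± (random symmetric sign) the
template plus isotropic noise. Class-conditional means are zero — a linear
classifier on rows alone performs at chance — while same-class rows are
strongly correlated, so the class structure is recoverable only through the
functional-connectivity graph. The ablation experiment uses `signed_mean`
thresholding so functional neighborhoods are sign-coherent and neighbor
aggregation does not cancel; with `abs_mean` both polarities join the
neighborhood and the aggregated signal vanishes by symmetry.

## Problem sizes and experiment settings

The synthetic experiments run on one CPU. The class-recovery experiment uses
the full study conditions (450 segments, 62 channels) with the published
hyperparameters capped at 100 epochs; the chance control re-runs it with
permuted labels and 20-epoch training (early stopping ends those runs after
~10–20 epochs since there is nothing to learn); the planted-correlation
ablation uses 150 rows × 32 features, a 64-d/8-head model, lr 3e-3,
dropout 0.2, up to 100 epochs. These sizes are the package's chosen
experiment scale and are fixed in the tests and the acceptance script.

## Known limitations

- Dense message passing is quadratic in split size; beyond a few thousand
  nodes a sparse implementation would be needed.
- `features_as_nodes` is experimental plumbing for the alternative reading
  of the graph construction; it is not wired into the training loop.
- The optional per-subject evaluation grouping from the published tables is
  not implemented; pooled segment-level CV (the described protocol) is.
- Checkpointing stores parameters in-memory per fold; there is no on-disk
  checkpoint format beyond the exported metrics/embedding CSVs.
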