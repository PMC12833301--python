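# mgtcn — dual-graph transformer/GCN pipeline for EEG emotion recognition

`mgtcn` classifies emotional states from multichannel EEG by combining two
complementary graph views of the data. Segments of preprocessed EEG are
described by nonlinear and spectral features — Higuchi fractal dimension,
amplitude-histogram entropy, and band-wise differential entropy
DE = log(var(x_band) + ε) over the delta/theta/alpha/beta/gamma bands —
reduced by PCA. Over the resulting feature vectors two graphs are built:

- a **physical proximity** layer: a complete topology (every pair of nodes
  connected), a uniform structural prior;
- a **functional connectivity** layer: Pearson correlations between node
  feature vectors, thresholded at their mean off-diagonal magnitude,
  A_F[i,j] = cov(X_i, X_j) / (σ_i σ_j).

A weight-shared encoder — two graph-transformer layers
(α_ij = softmax_j((q_i·k_j)/√d_k), multi-head, ELU) followed by one GCN layer
(symmetric degree normalization D^{-1/2}(A+I)D^{-1/2}, batch-norm, ELU) — runs
on both graphs; the two embeddings are concatenated and a fully connected
classifier with NLL loss produces per-segment class probabilities. Training
uses Adam (lr 1e-4, weight decay 5e-4), cosine learning-rate annealing, early
stopping on an internal validation split, and stratified 5-fold
cross-validation. PCA, the functional adjacency and all trained statistics
are fitted on training rows only; train and test splits live in separate,
locally indexed graphs, so evaluation is leakage-free and transductive.

The package is aimed at researchers in affective computing / EEG decoding who
want a fully inspectable, CPU-sized reference implementation of this model
family, plus a synthetic EEG generator (band-limited noise with class-dependent
band gains, shared cross-channel sources, a pre-stimulus baseline epoch) so the
entire pipeline can be developed and tested without restricted datasets. The
network is implemented in NumPy on a small reverse-mode autodiff core with
dense masked message passing — exact, deterministic, and dependency-light.

## Worked example

```python
from mgtcn import (MultilayerGTCN, SynthConfig, generate_recordings,
                   FeatureConfig, ModelConfig, TrainConfig)

rec = generate_recordings(SynthConfig(n_trials_per_class=50, n_channels=20, seed=7))
model = MultilayerGTCN.from_recordings(
    rec,
    feature_cfg=FeatureConfig(pca_dim=40),
    model_cfg=ModelConfig(n_classes=3, seed=0),
    train_cfg=TrainConfig(max_epochs=60, seed=0),
)
res = model.fit()
print(res.summary())
```

prints

```
Multilayer graph transformer/GCN cross-validation results
==========================================================
segments: 150   classes: 3   folds: 5
accuracy :  97.33 +/- 4.35 %
macro F1 :  97.29 +/- 4.44 %

per-fold metrics:
 fold  accuracy  macro_f1  macro_precision  macro_recall
    0    0.9667    0.9666           0.9697        0.9667
    1    0.9000    0.8977           0.9231        0.9000
    2    1.0000    1.0000           1.0000        1.0000
    3    1.0000    1.0000           1.0000        1.0000
    4    1.0000    1.0000           1.0000        1.0000

pooled confusion matrix (rows = true class, counts):
    0   1   2
0  46   0   4
1   0  50   0
2   0   0  50
```

The 150 synthetic segments carry three classes whose alpha/beta band gains
differ by ≥ 2×; the model recovers them at 97 % mean cross-validated accuracy
(fold-level mean ± sd, ddof = 1). `res.confusion`, `res.fold_frame`,
`res.export_embeddings(...)` and `model.ablation()` expose the confusion
matrix, per-fold metrics, the fused 256-d pre-classifier embeddings, and the
component-removal study (full model vs. no transformer / no GCN / no physical
graph / no functional graph on identical folds).

The same flow is available from the shell:

```bash
mgtcn simulate  --config cfg.yaml --out data/
mgtcn featurize --profile seed --config cfg.yaml --in data/ --out features.csv
mgtcn train     --features features.csv --config cfg.yaml --out run/
mgtcn ablate    --features features.csv --config cfg.yaml --variants all --out ablation.csv
```

## Layout

- `src/mgtcn/synthetic.py` — synthetic EEG generator + dataset container IO
- `src/mgtcn/preprocess.py` — filtering, z-scoring, windowing, baseline correction
- `src/mgtcn/features.py` — HFD / entropy / band DE, feature table, PCA
- `src/mgtcn/graphs.py` — dual-graph construction and thresholding
- `src/mgtcn/autodiff.py`, `network.py`, `optim.py` — the model and its training machinery
- `src/mgtcn/train_eval.py` — CV loop, metrics, ablation driver
- `src/mgtcn/model.py` — `MultilayerGTCN` / `GTCNResults` front end
- `docs/methods.md` — model assumptions, numerical choices, limitations
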