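# Methods

## Model

`platfuse` treats an expression value as the sum of a platform-independent
component (the sample's biology) and a platform-related component (technical
structure of the measurement technology). The package separates the two in
an unsupervised first stage and predicts binary endpoints in a supervised
second stage.

**Stage 1 — encoding networks.** All three networks share one autoencoder
shape: nine node-bearing layers with widths *p*, 4096, 3072, 2048, 1024,
2048, 3072, 4096, *p* (encoder = first half, 1024-unit bottleneck), tanh on
every hidden layer, sigmoid on the output layer, and dropout (rate 0.2)
after every hidden layer of encoder and decoder, disabled at encode time.
Because the output layer is a sigmoid trained with per-feature binary
cross-entropy, inputs are min–max normalized to [0, 1] first (mean squared
error on unnormalized data is available as a config alternative). The three
variants differ only in what is fed and targeted:

* *ae*: one platform's samples, reconstruction only. One such model is
  trained per platform for the latent diagnostics; the primary platform's
  model contributes the first feature block.
* *pooled*: both platforms' samples pooled row-wise (2n × p) into a single
  autoencoder, so one encoder serves either platform.
* *cross*: both translation directions in one shared-weight network. Each
  row x (from either platform) is scored with
  `L(x̂, x) + λ·L(x̂, pair(x))` where `pair(x)` is the same sample on the
  other platform and λ defaults to 1. At λ = 0 this coincides exactly
  (same seed, same random stream) with the pooled autoencoder; training the
  two directions as separate networks was rejected because two independent
  encoders place the platforms in unrelated latent coordinate systems,
  which destroys the cross-platform latent correlation the network exists
  to produce.

Feature extraction takes the bottleneck activation (dropout off). The
per-sample blocks from ae, pooled and cross are concatenated into the fused
3072-dimensional feature set; block boundaries remain addressable for
ablations.

**Stage 2 — classifier.** A six-layer fully-connected feed-forward network
with widths x, 1024, 512, 256, 128, 2. Each hidden layer is dense →
batch-norm → ReLU; the output is a 2-unit softmax trained with categorical
cross-entropy on one-hot labels, mini-batch size 32. Dropout is kept off
when batch normalization is on (the two regularizers interact poorly).
Baselines reuse the identical classifier on raw genes (`raw`) or on the
genes passing a two-sided Welch t-test at p < 0.05 fitted on training data
only (`fs`); zero-variance columns receive p = 1 and are never selected.

## Evaluation protocol

Cross-validation: stratified 5-fold, repeated 20 times with fold-partition
seeds `base_seed + r`, i.e. 100 sub-models per endpoint, summarized as
mean(sd) AUC. Stratification is the default because imbalanced endpoints at
small n occasionally produce single-class folds under plain random
splitting; plain k-fold is available by flag. External testing retrains on
the full training split under seeds `base_seed + i` (default 100 runs) and
scores a fixed, id-disjoint test split; overlapping sample ids are rejected
outright. AUC is the Mann–Whitney pairwise-concordance statistic (ties 0.5),
computed via scikit-learn and checked in the test suite against a
brute-force pairwise oracle at 1e-12. Ablations evaluate feature-block
subsets on identical fold partitions so comparisons are paired.

## Latent diagnostics

Both platforms' features are stacked and decomposed with a single PCA
(mean-centered, no variance scaling; component signs fixed by forcing the
largest-magnitude loading positive). Two statistics summarize the geometry:
the *PC1 platform separation*, the symmetrized AUC of the PC1 score against
the platform label (1 = platforms fully separated, 0.5 = PC1 platform-free
— the formalization of the usual visual judgement); and the *PC2
cross-platform r²*, the squared Pearson correlation of paired per-sample
PC2 scores, which is high exactly when the second component carries the
same per-sample biology on both platforms. For the ae source the two
platforms' blocks come from two different models, as they would in practice.

## Synthetic cohorts

The generator draws `x_ip = W z_i + V_p u_ip + c_p + baseline + ε` with
shared factors `z_i ~ N(0, I)` expressed through a single loading matrix W
common to both platforms — the mapped gene columns measure the same
transcripts, and with offset 0, no platform factors and no noise the two
matrices coincide. Defaults: n = 200 samples, 300 genes, 5 shared factors
(loading scale 1.8, so shared biological variance clearly dominates the 3
platform-specific factors), platform offset norm 30 (platform identity
dominates the combined covariance, as in real paired cohorts), noise sd
0.5, baseline 8 (log-scale-like positive values). Three endpoints are drawn
from a fixed unit direction w in shared-factor space,
`y ~ Bernoulli(sigmoid(β·w·z))`, with β = 3 / 1.2 / 0 (easy / medium /
hard); the hard endpoint is deliberately unpredictable. The generator
emulates paired samples, a one-to-one gene map, dominant platform variance
and recoverable shared factors; it does not emulate count noise,
heavy-tailed intensities, gene–gene correlation networks, or batch
structure beyond the global offset — passing tests demonstrate mechanism,
not real-data performance.

## Numerical and design choices

* **Engine.** All networks run on a small hand-written numpy engine (dense,
  batch-norm, dropout, tanh/ReLU/sigmoid, Adam, manual backprop) whose
  gradients are verified against finite differences in the test suite.
  Training is bit-reproducible for a fixed seed on a fixed machine; every
  random draw (init, shuffling, dropout) flows from `numpy.random.Generator`.
* **Normalization.** Per-gene min–max fitted on the pooled rows of both
  platforms, so both live in one [0, 1] feature space and genuine
  between-platform shifts survive (per-platform fitting would silently
  remove them). Constant genes map to 0; unseen out-of-range values clip.
* **Optimization.** Adam; encoder defaults lr 1e-4, 200 epochs, batch 32;
  classifier defaults lr 1e-3, 100 epochs, batch 32; no early stopping.
  Softmax is folded into the loss for stability; BCE predictions are
  clipped at 1e-7.
* **Desk scale.** Every layer width scales by one config factor. The test
  suite and the acceptance script use encoder sizes (64, 48, 32, 16) with
  lr 1e-3 and 200 epochs, classifier hidden sizes (64, 32, 16, 8) with 60
  epochs, and 5-fold × 2-repeat CV over ten generator seeds — sizes at
  which the full study runs in minutes on one CPU core while preserving
  every architectural ratio.
* **Seeds.** The four encoding networks train at fixed offsets (0, 101,
  202, 303) from the bundle seed so no two share an initialization; CV
  sub-model seeds derive from `base_seed` via a fixed prime stride.

## Known limitations

* Encoders are trained once on all available expression (they are
  unsupervised and never see labels) and reused across CV folds; held-out
  *expression* therefore participates in representation learning, a
  standard but real caveat of two-stage designs.
* The fused feature set does not always beat the best single block on the
  latent r² diagnostic at desk scale: when the cross block alone reaches
  r² ≈ 0.99, concatenating the unaligned ae block can only dilute it. The
  classifier-side ablation (fused ≥ best single − 0.02) is the meaningful
  comparison and holds.
* With batch normalization, prediction uses running moments; extremely
  short trainings (a few batches) leave them close to their initialization.
* The CLI covers the two-platform case only; ≥3 platforms would need
  pairwise cross networks and a multi-platform gene map.
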