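# Methods

## Problem setting

`psgrn` treats gene-regulatory-network (GRN) inference as supervised pair
classification.  Given a gene × time-point expression matrix and a gold
standard of known TF→target regulations, every ordered (TF, gene) pair is a
sample: label 1 if the regulation is in the gold standard, 0 otherwise.  A
trained classifier then scores all pairs, and the predicted network is read
off the top of the ranking.  Because regulation is sparse (network density =
regulations / (TFs × genes), typically 0.12–0.19), the label distribution is
heavily unbalanced and all evaluation is AUPR-first.

## Preprocessing

1. Genes with mean expression below 1.0 over the time course are removed
   (threshold inclusive: a constant-1.0 gene stays).
2. Candidate regulations with p > 0.01 are removed; the rest are sorted by
   ascending p-value, ties broken lexicographically by (TF, target) so runs
   are reproducible.
3. A sub-dataset is induced from the genes touched by the top-k most credible
   regulations: the gene set is every endpoint of those k edges present in
   the filtered profile, and the edge set is **every** credible edge between
   genes of that set, not only the top k.  This is why an induced dataset can
   hold far more regulations than k.
4. Pair labeling enumerates all n_tfs × n_genes ordered pairs, including
   tf→tf and tf→itself pairs.  The arithmetic is auditable: positives +
   negatives must equal n_tfs × n_genes exactly.

## Feature encoding

Each gene's length-n series x becomes a lagged difference matrix with rows

    row_j = [x[j+1]−x[j], …, x[j+tl]−x[j]],   j = 1 … n−tl−1,

of shape (n−tl−1) × tl; with the default time lag tl = 32 a 107-point course
becomes 74 × 32.  The final time point enters only through row differences;
we implement the row-count formula literally rather than "fixing" the
apparent off-by-one, because the printed shape contract (74 × 32) follows
from it.  Series are z-scored per gene before differencing by default
(configurable: `none`, `zscore`, `log1p_zscore`); differencing makes the
encoding invariant to additive shifts and homogeneous in scale.

## Model

The pair classifier is pseudo-Siamese: two branch encoders of identical
structure but independent parameters (perturbing TF-branch weights provably
leaves the target encoding unchanged; a unit test enforces this).

* **Branch encoders** — GRU by default: reset/update sigmoid gates, tanh
  candidate, convex-combination state update, hidden dimension 128 in the
  full configuration.  The candidate uses `r_t ⊙ h_{t−1}` (the standard
  two-gate form).  Input-to-hidden weights are Kaiming-initialized,
  hidden-to-hidden orthogonal, biases zero.  Vanilla-RNN and LSTM drop-ins
  exist for the ablations, and `branch_type="none"` feeds the difference
  matrices straight to the spatial module.
* **Merge** — row-wise concatenation into one single-channel matrix of
  shape 2·(n−tl−1) × hidden, TF rows first.  The FM-GRU ablation replaces
  this with the scaled product h_tf · h_targetᵀ of the two hidden
  sequences (only valid without a spatial module).
* **Spatial module** — densely connected conv blocks: within a block, layer
  k receives the channel concatenation of the block input and all previous
  layers' outputs (input channels = in + (k−1)·growth); 1×1-conv + 2×2
  average-pool transitions compress channels (factor 0.5) and halve the
  spatial dims; global average pooling produces a fixed-length vector whose
  size depends only on channel bookkeeping.  Conv units are
  conv→batch-norm→ReLU.  The stem is a stride-2 3×3 convolution plus a 2×2
  average pool; for merged matrices narrower than 16 columns the stem only
  downsamples the time axis.  Defaults: 3 blocks × 4 layers, growth 12.
  The originating architecture's exact depth was not recoverable, so these
  are explicit stand-ins, all exposed in `ModelConfig`.  VGG-style and
  residual modules exist for ablations.
* **Head** — fully connected layer (width 32), ReLU, 1-D max-pool, and a
  final linear map to one sigmoid unit: the relatedness coefficient
  α ∈ (0, 1).  The PS-SM ablation replaces the sigmoid with a two-class
  softmax.

Training minimizes mean binary cross-entropy with an adaptive-moment
optimizer (lr 1e−3, batch 64 by default), early-stops on validation AUPR
(patience 10, max 100 epochs), and restores the best-validation checkpoint
(including batch-norm running statistics).  `TrainSchedule.augment_sd`
optionally adds Gaussian noise to training inputs only — a regularizer
against gene-identity memorization that matters on small pair sets; it
defaults to off.  No class reweighting is applied by default.  All
randomness (init, shuffling, augmentation) derives from integer seeds, so
single-device runs are exactly reproducible.

The whole network stack (recurrent cells, convolutions, batch norm, Adam,
backpropagation) is implemented in NumPy inside `psgrn.nn` with explicit
forward/backward passes; every layer is verified against finite-difference
gradients and the recurrent cells against step-by-step evaluations of their
gate equations.

## Evaluation

* **AUPR** is average precision (step interpolation over descending unique
  thresholds), not trapezoidal — the two differ on small sets, and tests
  pin the step definition against a brute-force all-thresholds oracle.
* **AUROC** equals the normalized Mann–Whitney statistic with ties counted
  half.
* **Top-k extraction**: μ is the k-th largest coefficient; the selection
  rule is score ≥ μ, so ties at μ can admit more than k pairs.  Confusion
  counts at μ always satisfy TP+FP+TN+FN = N and TP+FN = positives.
* The 3:1:1 train/test/validation split is stratified per class (floor
  division for the two small splits, remainder to training), so each
  split's prevalence matches the global one to within a pair.

## Synthetic benchmark

The generator emulates the statistical shape of a maize-like input pair: a
sparse directed TF→gene network and a staged expression time course.

* **Network**: exactly round(density × n_tfs × n_genes) distinct ordered
  TF→gene edges sampled uniformly, each with a synthetic p-value below
  0.01.  Defaults: 60 genes, 12 TFs, density 0.15.
* **Baselines**: per-gene mean-reverting random walk around level 5.0
  (AR coefficient 0.5, shock sd 0.5).  The moderate autocorrelation is
  deliberate: it leaves the 107-point course with enough effectively
  independent observations that regulator–target correlations over true
  edges separate from the null over non-edges — the precondition for any
  recovery experiment.  A sinusoid-mixture baseline and a four-segment
  piecewise "developmental stage" drift are available options.
* **Regulation**: TF expression is exogenous — every TF follows its own
  baseline regardless of incoming edges (its drivers are treated as outside
  the modeled panel, the usual convention for master regulators in
  in-silico GRN benchmarks).  Each regulated non-TF gene adds effect_size ×
  (regulator expression, lagged signal_lag = 3 steps) per regulator, plus
  Gaussian observation noise (sd 0.2, i.e. effect well above noise).  A
  smooth softplus floor (sharpness 50) keeps values non-negative without
  distorting realistic magnitudes, so closed-form identities (e.g. a
  noise-free single-regulator target equals its effect-scaled lag-shifted
  TF) hold to float precision and every gene passes the mean ≥ 1.0 filter.
* One consequence of TF exogeneity: TF→TF gold edges carry a label but no
  expression footprint, so ≈ n_tfs/n_genes of the positives are
  irreducibly unlearnable from expression alone — a known ceiling on
  synthetic-recovery AUPR.

What the generator does **not** emulate: read-count noise models, dropout,
heavy-tailed degree distributions of real regulomes, indirect-cascade
correlations, or condition-dependent regulation.  Passing recovery tests
here demonstrates that the pipeline's plumbing, optimization and metrics
behave as designed — not that the architecture would attain its real-data
accuracy on another organism.

## Robustness and ablations

* **Noise condition**: 5% of pairs, chosen uniformly, read a uniformly
  chosen random gene's series on the TF side while keeping the target and
  the label.  We corrupt in place (the alternative reading — appending
  corrupted duplicates — is available via the library); the base dataset is
  never mutated.
* **Incomplete condition**: a label-stratified 70% subsample.
* Experiments repeat 10 times; repeat i derives seed base+i, applies the
  condition, splits, trains, and records the test AUPR; reports carry the
  per-repeat list, mean, and population variance (the spread definition is
  stated because sample variance would differ at n = 10).  All conditions
  and variants at repeat i share the same seed, so comparisons are paired.

## Benchmark-scale protocol and its statistics

CPU-scale verification runs a reduced configuration: hidden 32, 2 dense
blocks × 2 layers, growth 8, initial features 8, with the default
optimization protocol (lr 1e−3, batch 64, at most 30 epochs, patience 5,
no augmentation) on the default 60 × 12 benchmark (720 pairs; 144 test
pairs, ~21 test positives).  The learned-signal check is a paired
permutation test: per seed, the model's test AUPR is compared with the mean
AUPR of models trained and evaluated on independent uniform label
permutations of the same dataset and split.  A single-permutation control
is avoided deliberately: with ~21 test positives the AUPR of even a random
ranking varies widely across draws, so one permutation gives a noisy
reference; averaging permutations tightens the null while keeping the
comparison paired.  The small evaluation set is also why recovery margins
here are modest in absolute terms, and why paired mean comparisons between
nearby conditions can land either way at this scale.

## Known limitations

* The merged-matrix + convolution design localizes TF–target interaction
  learning to receptive fields spanning the concatenation boundary; on very
  small training sets this is sample-inefficient, and the explicit-product
  (FM-GRU) ablation can be competitive there even though it is the weaker
  design at scale.
* Checkpoints store float32 weights; bit-exact reproducibility is
  guaranteed on a single device but not across BLAS implementations.
* The CLI trains CPU-scale models; the full configuration (hidden 128,
  3 × 4 dense layers) on hundreds of genes is hours of CPU time.
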