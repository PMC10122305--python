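# psgrn

Supervised gene-regulatory-network (GRN) inference from time-series
expression data with a pseudo-Siamese pair classifier.

## The problem

A GRN is a directed graph of transcription factors (TFs) regulating target
genes.  Given (a) a gene × time-point expression matrix and (b) a gold
standard of experimentally supported TF→target regulations, `psgrn` frames
inference as binary classification of every ordered (TF, gene) pair: known
regulations are positives, all other pairs negatives.  Because regulation
is sparse — network density = regulations / (TFs × genes), typically
0.12–0.19 — evaluation centers on AUPR (average precision), the metric of
record for heavily unbalanced edge labels.

It is aimed at computational biologists who have a time-course expression
matrix for one tissue or condition and a partial regulatory map (e.g. from
ChIP-seq) for a related one, and want to rank candidate regulations for the
former.

## The model

Each gene's length-*n* expression series *x* becomes a lagged difference
matrix *G′* with rows

    G′_j = [x_{j+1} − x_j,  x_{j+2} − x_j,  …,  x_{j+tl} − x_j],   j = 1 … n − tl − 1,

shape (n − tl − 1) × tl; with the default time lag tl = 32, a 107-point
course becomes a 74 × 32 matrix.  A candidate pair (TF, target) is scored
by a pseudo-Siamese network:

1. two GRU encoders with identical structure but independent weights
   (reset gate r_t = σ(W_r·[h_{t−1}, x_t]), update gate
   z_t = σ(W_z·[h_{t−1}, x_t]), candidate h′_t = tanh(W_h·[r_t ⊙ h_{t−1}, x_t]),
   state h_t = (1 − z_t) ⊙ h_{t−1} + z_t ⊙ h′_t) turn each difference
   matrix into a hidden-state sequence;
2. the two sequences are row-concatenated (TF first) into one
   single-channel matrix;
3. a densely connected convolutional module (dense blocks with transition
   layers, global average pooling) extracts spatial features;
4. a fully connected head with max-pooling and a sigmoid output yields the
   relatedness coefficient α ∈ (0, 1).

Training minimizes binary cross-entropy on a stratified 3:1:1
train/test/validation split.  The predicted network is the set of pairs
with α ≥ μ, where μ is the k-th largest coefficient.  Every ablation
variant from the validation protocol is built in: FM-DN, RNN-DN, LSTM-DN,
FM-GRU, GRU-VGG, GRU-RN and PS-SM.  The full network stack (GRU/RNN/LSTM,
convolutions, batch norm, Adam, backprop) is implemented in NumPy in
`psgrn.nn`, so there is no deep-learning-framework dependency.

A seeded synthetic generator (`psgrn.synthetic_data`) produces maize-like
benchmarks — a sparse uniform TF→gene network plus time courses in which
regulated targets track their TFs with a fixed lag — so the whole pipeline
is testable offline.

## Worked example

```bash
# simulate a small benchmark: 20 genes, 5 TFs, density 0.15, 40 time points
psgrn simulate --genes 20 --tfs 5 --density 0.15 --timepoints 40 --seed 3 --out sim
# -> 15 edges over 4 TFs x 20 genes

# filter + induce the sub-network of the top-5 regulations + label all pairs
psgrn preprocess --expression sim/expression.tsv --edges sim/edges.tsv --top-k 5 --out prep
# -> 3 TFs x 7 genes = 21 pairs, 7 positive

# per-gene lagged difference matrices at tl=8
psgrn featurize --profile prep/expression.tsv --tl 8 --out features.npz
# -> 7 genes featurized, matrix shape 31x8

# train a small model and evaluate the held-out test split
psgrn train --dataset sim --variant PSGRN --tl 8 --hidden-dim 16 --epochs 4 --seed 7 --out run
# -> trained 4 epochs; best validation AUPR 0.2310
psgrn evaluate --model run/model.npz --dataset sim --split test --seed 7 --report report.json
# -> {"split": "test", "aupr": 0.255..., "auroc": 0.487..., "threshold": 0.525...,
#     "confusion": {"tp": 1, "fp": 2, "tn": 11, "fn": 2}}
```

The simulate step prints the realized network (15 edges = round(0.15 × 5 ×
20)).  Preprocess keeps the genes touched by the five most credible
regulations and enumerates every ordered TF–gene pair over them; 7 of the
21 pairs are gold-standard positives.  The evaluate step reports ranking
quality on the test split and the confusion counts at the default top-k
threshold; at this toy scale (4 test positives) the metrics are noisy —
the default benchmark for quantitative checks is larger (60 genes, 12 TFs,
720 pairs; see `tests/test_acceptance.py`).

Robustness and ablation protocols follow the same pattern:

```bash
psgrn robustness --dataset sim --condition noise --repeats 10 --seed 1 --report noise.json
psgrn ablate --dataset sim --variants PSGRN,FM-DN,FM-GRU --repeats 10 --seed 1 --report ablate.json
```

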