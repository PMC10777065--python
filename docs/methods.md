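# Methods

## Problem and model

The package predicts circRNA–miRNA interactions as bipartite link
prediction. Each candidate pair is described by the concatenation of four
vectors — circRNA sequence feature, circRNA structural feature, miRNA
sequence feature, miRNA structural feature — and scored by a
gradient-boosted tree classifier. Only validated positive pairs exist;
the negative class is constructed by uniform sampling from unobserved
pairs (one negative per positive by default), which is statistically
reasonable because true interactions are sparse in the pair space, but
inevitably mislabels any undiscovered interaction it happens to draw.

## Sequence features: masked-LM transformer encoder

Sequences are reverse-transcribed (U→T), tokenized into overlapping
k-mers (stride 1), and chunked into consecutive 510-token segments, each
wrapped `[CLS]…[SEP]` and right-padded to a fixed 512-position window.
Chunks do not overlap. k-mers containing a non-ACGT character become
`[UNK]` so coordinates are preserved. Special token indices are frozen
([PAD]=0, [UNK]=1, [CLS]=2, [SEP]=3, [MASK]=4) for reproducibility.

The encoder is a standard post-norm BERT block (multi-head self-attention
with √d_k score scaling and padding keys excluded from the softmax;
residual + layer norm; GELU feed-forward; residual + layer norm) over
learned token and position embeddings. Defaults: L=2 layers, h=4 heads,
d_model=64, d_ff=128. This is a deliberately small encoder of the
reference architecture, trained from scratch on the task corpus — genome-
scale pretraining is out of scope, and a checkpoint-loading hook
(`EncoderModel.load`) is the extension point for externally trained
weights.

Training is masked language modelling only, the one objective with a
defined loss here: per chunk, disjoint runs of exactly k contiguous
content tokens are replaced by `[MASK]` until ⌊0.15·n/k⌋ runs are placed
(≈15% of content), and the mean cross-entropy of the original tokens at
masked positions is minimized. Masked tokens are always replaced by
`[MASK]`; the 80/10/10 replacement heuristic of standard BERT is
deliberately not used (a documented simplification). Specials are never
masked; masks are redrawn every epoch. Optimization is AdamW
(lr 1e-3, decoupled weight decay 0.01 on weight matrices only, batch 16)
with inverted dropout (p=0.1) on the hidden states feeding the MLM head,
for 3 epochs by default. The full forward/backward pass is hand-written
on numpy arrays; the test suite checks analytic gradients against finite
differences at 1e-4 relative tolerance.

The per-sequence feature is the final-layer [CLS] state of each chunk.
With the default d_out = d_model = 64 the hidden state is used directly
("the last hidden layer is 64-dimensional"); if d_out ≠ d_model a linear
projection head maps onto d_out. Multi-chunk sequences are aggregated by
a content-length-weighted mean of chunk vectors: plain concatenation
cannot give the fixed width the classifier needs, and the weighted mean
treats a 510+10-token sequence sensibly where an unweighted mean would
let the 10-token fragment dominate. Feature extraction is invariant to
the amount of right-padding (attention masking guarantees it; tests
assert it).

## Structural features: HOPE on the interaction graph

The undirected bipartite graph over all circRNA and miRNA nodes (isolated
nodes retained) is built from **training positives only** — in every
cross-validation fold the graph is rebuilt so that no test edge
influences the embedding. High-order proximity is the Katz index
S = Σ_{l≥1} β^l A^l = (I − βA)^{-1} βA with β = 0.5/ρ(A), the canonical
choice: convergence requires β·ρ(A) < 1, and halving the critical decay
balances short- and long-walk contributions. A common-neighbors
proximity (AᵀA) is available as a configuration alternative. At the
scale this package targets (thousands of nodes) S is formed densely and
factorized exactly.

Factorization takes the top-d singular triplets: U_s = U_d √Σ_d,
U_t = V_d √Σ_d, which by Eckart–Young minimizes ‖S − U_s U_tᵀ‖_F² over
rank-d factorizations; the reconstruction error equals √(Σ_{i>d} σ_i²)
and the tests assert both the closed form and superiority over random
factorizations. Each singular vector's sign is fixed by making the
largest-magnitude entry of the left vector positive, so embeddings are
reproducible across linear-algebra backends. The node feature is
[U_s row | U_t row]; with the default d=32 this is 64-dim, mirroring the
sequence-feature width. Nodes isolated in a training fold have an
all-zero proximity row and receive an exactly zero vector.

## Classifier: gradient boosting from first principles

Binary classification uses the binomial deviance (squared loss is kept
for regression-style unit tests). The ensemble is
F(x) = F₀ + Σ_m ν·γ_m·h_m(x) with F₀ the loss-minimizing constant
(log-odds of the positive rate; clamped with a warning if labels are
degenerate), h_m a regression tree fit by exact greedy variance-reduction
splits to the pseudo-residuals y − σ(F), and γ_m a single line-searched
step per tree (closed form for squared loss; safeguarded Newton for the
deviance) — one coefficient per stage, not per leaf, matching the
single-γ formulation. Split thresholds are midpoints between consecutive
distinct feature values; ties in gain resolve to the lowest feature
index, then the lowest threshold, with gains within 1e-9 (relative) of
the maximum treated as exact ties so the rule is robust to floating-point
noise. No row or feature subsampling is used. Because the loss is convex
in the score and 0 < ν ≤ 1, training loss is non-increasing per stage;
the fit asserts this. Defaults: 300 stages, ν=0.1, depth 3, min 5
samples per leaf — standard practice for this family. Tree fits are
validated against an exhaustive split-search oracle on small instances,
and whole-model discrimination against an established boosting
implementation.

## Evaluation

5-fold cross-validation with a seeded shuffle (folds disjoint, sizes
within one); an 80/20 holdout mode mirrors the ablation protocol. The
sequence LM is trained once on the whole unlabelled sequence corpus and
reused across folds — masked-token prediction never sees interaction
labels, so this cannot leak label information; per-fold retraining is
available via `retrain_lm_per_fold`. Per fold, a SHA-256 digest of the
labelled training pairs and graph edges is recorded; the leakage audit
asserts test pairs are absent from the digested inputs.

Metrics are computed from first principles and cross-checked against
scikit-learn to 1e-6 in tests: AUC by the midrank Mann–Whitney statistic
(correct under ties), AUPR by interpolation-free step integration with
tied scores grouped per threshold, and ACC/MCC/F1 from the confusion
matrix at probability threshold 0.5 (natural for balanced classes). MCC
is defined as 0 (with a warning) when a marginal is zero; with
single-class labels the ranking metrics are NaN while threshold metrics
are still returned. Fold variance uses the population formula (divide by
k). ROC and PRC coordinates are exported as TSV.

## Synthetic data

The generator miniaturizes a real interaction compendium (thousands of
molecules, ~1:4 miRNA:circRNA ratio, ~10k validated pairs) to a desk-
scale instance with two independently switchable planted signals: a
block-structured bipartite network (edges Bernoulli(p_in) within a block,
Bernoulli(p_out) across) and block-specific (circ-motif, mir-motif) pairs
implanted into interacting molecules over i.i.d. uniform background.
Defaults: 120 circRNAs × 60 miRNAs, 4 blocks, p_in=0.45, p_out=0.005
(≈850 positive edges), circRNA lengths 100–200, miRNA lengths 20–28,
motif length 12, fidelity 0.9, calibrated once so that the planted
signal is learnable by the full pipeline (combined-feature CV AUC above
0.85) while a label-permuted control sits at chance. Sequence lengths are
chosen so a single implanted motif is a noticeable fraction of the k-mer
stream; long-sequence chunking is exercised separately with generated
70 kb sequences.

What the fixture does *not* emulate: back-splice junction biology, miRNA
seed-pairing thermodynamics, shared k-mer composition biases between
related molecules, the heavy-tailed degree distribution of real
interaction networks, and identifier cross-referencing across circRNA
naming schemes. Passing tests therefore demonstrate that the pipeline
recovers planted network-community and motif signal at desk scale — not
that it attains any particular accuracy on real compendia, which depends
on data volume and on sequence-model pretraining far beyond this
package's scope.

## Numerical choices and degenerate inputs

- All floating-point work is float64; attention softmax excludes padding
  keys exactly (zeroed terms, not a large negative constant), and a row
  with no valid key yields zeros.
- Katz divergence (β·ρ(A) ≥ 1) raises with the computed spectral radius;
  β=0 returns S=0; an empty graph gets β=0.
- MLM with a mask rate too low to place a single k-run raises rather
  than returning an undefined loss; NaN loss aborts training.
- Negative sampling switches from rejection sampling to exact
  without-replacement enumeration when more than half the complement is
  requested; both routes are deterministic under the seed.
- Every stochastic step (fixture generation, negative sampling, fold
  shuffling, masking, dropout, initialization) draws from generators
  seeded via `numpy` SeedSequence derivation from one master seed; two
  runs under the same seed are bit-identical, and the tests assert it.

## Problem sizes used in checks

The shipped evaluation runs use the default fixture scale (180 molecules,
~1,700 labelled pairs) with the default model sizes above; oracle-
equivalence checks run on deliberately tiny instances (≤16-sample trees,
≤10-node graphs, 8–64-wide encoders) where brute-force references are
exact. These sizes are the package's own choice of a desk-scale working
point that keeps every check executable anywhere while exercising every
code path, including multi-chunk sequences at 70 kb.

## Known limitations

- The encoder is trained from scratch on the task corpus; with the
  default 3 epochs it captures corpus k-mer statistics only partially,
  so sequence features are the weaker view on small corpora. Loading
  externally pretrained weights is the intended remedy.
- The 512-position window forces chunked processing of long circRNAs;
  the weighted-mean aggregation discards cross-chunk order.
- Uniformly sampled negatives may contain undiscovered true
  interactions.
- One step size per tree (not per leaf) trades a small amount of
  accuracy for fidelity to the single-coefficient formulation.
- Dense Katz + full SVD scale to roughly 10⁴ nodes; larger graphs would
  need the sparse generalized-SVD machinery deliberately left out here.
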