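# Methods

## Model

`heterolink` scores disease–miRNA association candidates on a heterogeneous
graph with three node types (gene, disease, miRNA) and four edge types.
All information flows through the gene–gene (PPI) backbone: disease and
miRNA nodes carry no intrinsic features and receive representations only by
aggregation over their gene neighbourhoods. The modelling assumptions are
therefore:

1. associations are mediated by genes — a disease and a miRNA that touch
   the same PPI neighbourhood are candidates for association;
2. the PPI graph is unweighted and undirected; input edge weights are
   ignored;
3. disease or miRNA nodes whose annotated genes all fall outside the PPI
   are untrainable and are removed during assembly, together with their
   associations (a node is kept if *any* of its genes is in the PPI — the
   least destructive reading of PPI anchoring).

The forward pass is described in the README. Two points deserve
elaboration:

**Bipartite propagation.** The self-loop trick `A + I` is undefined for a
non-square incidence, so cross-network layers use row normalisation: each
disease/miRNA row is the mean of its gene neighbours' activations. This
keeps the activation scale independent of annotation degree. Raw sums
(`bipartite_norm="none"`) are available for comparison.

**Final embeddings.** Both conventions found in this model family are
implemented: `final_mode="last"` (default; `Z = H^(K)`) and
`final_mode="mean"` (element-wise average of the per-layer cross
activations, which requires equal layer widths).

## Negative sampling

Curated databases record confirmed associations only; an absent pair is
unverified, not negative. The sampler treats distance from the positive
population as a reliability proxy: edge features are concatenations
`[z_d ‖ z_m]` (concatenation preserves endpoint identity; alternatives such
as Hadamard products are pluggable), distances are Euclidean, and the K
unknown pairs farthest beyond the mean positive distance are taken as
negatives, with ties at the K-th distance broken lexicographically by
(disease index, miRNA index) for reproducibility. The sampler is strict —
if fewer than K candidates exceed the threshold it raises — and the trainer
responds by lowering K to the available count (first epoch) or reusing the
previous epoch's set (later epochs), with a warning either way.

By default negatives are drawn **once**, from the embeddings produced by
the initialised (untrained) network. Re-sampling from the current
embeddings every epoch (`neg_refresh="per-epoch"`) is supported but makes
the optimisation target non-stationary; at the fixed 100-epoch budget this
measurably slows convergence of the decoder and increases seed-to-seed
variance, so stationary targets are the default.

## Training

Summed cross entropy over the 2K shuffled samples plus
`weight_decay · Σ‖W‖²` over every trainable matrix (including the decoder).
Full batch, Adam (lr 0.001), 100 epochs, Glorot-uniform initialisation.
The per-edge loss is evaluated in logit space
(`max(g,0) − y·g + log(1+e^−|g|)`) so extreme scores cannot overflow;
the probability-space contract applies p clipped to `[1e-12, 1 − 1e-12]`.
Gradients are hand-derived backpropagation through the sparse propagation
stack; the test suite verifies every parameter matrix against central
finite differences (step 1e-5, relative error < 1e-4) for both hidden
activations and both final modes. Mini-batching was evaluated and gave no
benefit at these problem sizes, so the simpler full-batch step is kept.
No dropout and no early stopping: the final-epoch model is returned.

`weight_decay` defaults to 5e-4 and is the one hyperparameter worth
cross-validating per dataset (the k-fold harness is the intended tool);
a coarse sweep on the synthetic benchmark showed 5e-4 and 5e-3
indistinguishable and 5e-2 harmful.

## Gene features

Raw gene features are node2vec-style embeddings of the PPI backbone:
10 second-order walks per node of length 80 (p = q = 1 defaults, window
10), embedded by skip-gram with 5 negative samples, 5 epochs, sequential
per-pair SGD with linearly decaying learning rate (0.025 → 1e-4). The
inner loop is numba-compiled and fully seeded; identical inputs give
bit-identical embeddings. Feature dimension defaults to 128 (64 and 256
are the usual alternatives; 64 roughly halves embedding time with a small
quality cost at these graph sizes).

As the final step of feature construction the embedding columns are
**standardised** (zero mean, unit variance per dimension). Skip-gram
embeddings carry a large shared mean component; removing it and equalising
column scales conditions the downstream bilinear decoder, which otherwise
spends most of its fixed optimisation budget discovering that common
direction. Row normalisation (L1 or L2) is available via
`normalize_features` — L1 rows are the convention for bag-of-words-style
nonnegative features such as the one-hot baseline (whose rows are already
unit-L1) but measurably mis-scale dense signed embeddings, so the trainer
applies no further normalisation by default (`feature_norm="none"`).

## Evaluation protocol

* **AUROC** — rank/concordance (Mann–Whitney) form, ties ½.
* **AUPRC** — average precision (step integral); trapezoidal interpolation
  in PR space is optimistic and deliberately avoided.
* **Accuracy** — threshold 0.5, ties called positive.
* **k-fold CV** — the 2K-sample universe (K positives + K initial-embedding
  negatives) is randomly partitioned into k mutually exclusive, exhaustive
  folds. Each fold's training run restricts the positive set and the
  negative candidate pool to non-test edges, and recomputes the positive
  centroid from training positives only; an assertion inspects every
  epoch's negative set for test-edge leakage. A single 80/10/10 split
  (`make_split`) is provided as the alternative protocol.
* **Per-disease LOOCV** — each known association is hidden in turn, the
  model retrained, and the hidden miRNA ranked among all miRNAs not known
  to be associated with the disease. Pooled (label, score) pairs across
  rounds give the ROC/PR curves; AP@k (k ∈ {20, 40, 60}) is truncated
  average precision on the pooled ranking. `fast=True` trains once with
  the whole disease hidden — cheaper, slightly pessimistic.
* **Candidate ranking** — all unknown pairs of a disease sorted by decoded
  probability.

## Synthetic benchmark

The generator emulates the structural premise of the method: gene modules
drive associations. Genes are split round-robin into `n_modules` blocks and
wired by a planted-partition model (defaults: 200 genes, 4 modules, intra
0.2, inter 0.01). Each disease (20) and miRNA (30) is assigned a home
module round-robin and linked to 10 distinct genes, each drawn from the
home module with probability `module_fidelity` = 0.8, else uniformly. True
associations connect module-mates; with single home modules the
overlap-threshold rule `θ_ov` degenerates to home-module equality.
Observed labels hide a `label_noise` = 0.2 fraction of true positives —
noise conceals, never fabricates, mirroring the premise that unknown pairs
are unverified rather than negative.

Balanced (round-robin) home assignment is deliberate: it makes every
disease and miRNA association degree equal in expectation, so the
hidden-positive recovery task cannot be solved by node popularity alone and
the degree-preserving null (below) sits at chance. Entities are drawn only
from genes with at least one PPI edge, so assembly never drops nodes and
the observed and true matrices always share an index space.

**Null control.** `degree_preserving_null` randomises the true association
matrix by repeated 2×2 checkerboard swaps — both degree sequences are
preserved exactly while all pair-level structure is destroyed — then
re-hides the same number of positives. (A plain permutation of disease
rows is *not* a null for this model: the permuted labels remain a
deterministic function of disease identity and miRNA module and are
re-learnable; the swap null is not.)

**What passing shows — and does not.** At the reference conditions the
trained model recovers hidden positives with mean AUROC ≈ 0.89 over five
seeds while the null stays at ≈ 0.5, demonstrating that the full pipeline
— walks, embedding, heterogeneous convolution, distance-sampled negatives,
bilinear decoding — extracts gene-mediated association structure end to
end. The generator does not emulate scale-free PPI degree distributions,
overlapping or hierarchical disease modules, miRNA family redundancy, or
annotation biases of real curated databases; performance on real corpora
must be established with the k-fold and LOOCV protocols on real edge lists.

## Numerical and degenerate-input choices

* Sigmoid and cross entropy computed in stable forms; no NaN up to
  |logit| ≈ 1e4 (beyond ~±37 the probability saturates to 0/1 in float64).
* All-zero feature rows pass through row normalisation untouched, with a
  warning.
* Isolated genes cannot occur (the gene universe is defined by the PPI edge
  set); an isolated node in a hand-built `GeneNetwork` receives a self-loop
  weight of 1 under normalisation.
* Gene–gene self-loops in input files are dropped at parse time; the
  convolution adds its own self-loops.
* Ties: negative-sampling ties break lexicographically; ranking ties keep
  the stable sort order; AUROC ties count ½; accuracy ties call positive.
* Determinism: every stochastic stage (walks, skip-gram, initialisation,
  shuffling, simulation, splits) takes an explicit seed and runs
  single-threaded; repeated runs are bit-identical.

## Known limitations

* A single relation type: one decoder matrix `M_r`; multi-relation
  (per-edge-type) decoding is out of scope.
* The one-hot baseline materialises an N×N dense matrix and is only
  sensible at small N.
* LOOCV with per-edge retraining is O(#associations) trainings; use
  `fast=True` beyond toy scale.
* The distance-based sampler can select concealed true associations as
  training negatives (on the synthetic benchmark, roughly 10% of hidden
  positives at any epoch); this is intrinsic to training against unverified
  unknowns and slightly depresses recovery.
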