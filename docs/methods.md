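# Methods

## Problem and model

`vgaedti` predicts drug–target interactions (DTIs) by embedding a
heterogeneous drug–target–disease network and classifying candidate
(target, drug) pairs. The model has three stages.

**1. Similarity layers.** Drug–drug similarity is the cosine similarity of
binary structure fingerprints, `S_r(i,j) = F_i·F_j / (‖F_i‖‖F_j‖)`;
additional binary-profile channels (side-effect or protein-domain
profiles) can be fused in by a weighted elementwise mean (uniform by
default). Target–target similarity starts from Smith–Waterman local
alignment scores `sw(i,j)`, row-normalized as
`S_p(i,j) = (sw(i,j) − min(sw_i)) / (max(sw_i) − min(sw_i))`. The row
extrema exclude the diagonal by default (`include_diagonal=False`):
self-alignment scores are much larger than any cross score and would
compress the informative range. Row normalization is asymmetric, so the
matrix is symmetrized by averaging with its transpose; the
pre-symmetrization matrix is available via `normalize_sw(...,
symmetrize=False)`. Alignment scoring defaults to BLOSUM62 with affine
gaps (open 10, extend 1), the standard protein local-alignment setting; a
simple match/mismatch/linear-gap mode exists for exact oracle testing.

**2. Graph autoencoders under variational EM.** The five blocks assemble
into one symmetric adjacency over targets, drugs and diseases (in that
node order):

    H = [ S_p     A_pr    A_dp^T ]
        [ A_pr^T  S_r     A_dr^T ]
        [ A_dp    A_dr    0      ]

Every node's feature vector is its row of H, and every graph-convolution
layer propagates over the same normalized operator
`D̃^{-1/2}(H + I)D̃^{-1/2}`. Passing messages over the single full
network (rather than per-space subgraphs) is a deliberate design choice:
the per-space adjacency sums that motivated subgraphs do not typecheck
dimensionally, while the full-H formulation is well defined and lets
disease nodes mediate information flow between the two entity classes.
The drug view and target view differ only in which latent rows are read
out.

Two encoder families are co-trained:

* **VGAE (feature inference).** Per view: a shared GCN hidden layer
  (leaky ReLU), parallel linear GCN heads for μ and log σ, a
  reparameterized sample `Z = μ + σ⊙ε` with ε ~ N(0, I), and a dense
  linear decoder back to feature space. Losses: Gaussian reconstruction
  `½‖X − X̂‖²_F` on the view's rows and the standard Gaussian KL
  `½Σ(μ² + σ² − 1 − log σ²)`. The total VGAE objective is
  `α·L_pVGAE + (1−α)·L_rVGAE + β·L_KL` with α = β = 0.5 by default; the
  KL is kept out of the per-space terms so β weights it exactly once.
* **GAE (label propagation).** Two stacked GCN layers (leaky ReLU, then
  linear) produce deterministic embeddings; the decoder scores pair (i, j)
  as `logistic(⟨Z'_p[i], Z'_r[j]⟩)` and is trained with full binary
  cross-entropy against the known association block. (A
  `positive_only_ce` flag restricts the loss to its positive terms; the
  full form is the numerically sane default.) With this single shared
  inner-product decoder the drug-space reconstruction error coincides
  with the target-space one, so the α-weighted GAE total reduces to the
  common value.

Training alternates **E-steps** (variational encoders updated, GAE
frozen) and **M-steps** (GAE updated, variational latents frozen), every
epoch by default. Both steps add the alignment penalty
`½‖Z − Z'‖²_F` per space (weight 1.0), which is what couples the two
encoders: feature inference is pulled toward the label-propagation
geometry and vice versa. With co-training enabled, a
reconstruction-consistency term `½‖dec(Y_p) − X_p‖² + ½‖dec(Y_r) − X_r‖²`
is added, where `Y` is the fused embedding (mean of the VGAE μ and the
GAE embedding) mapped through the view's decoder — the fused
representation must still explain the raw features. Final embeddings use
the VGAE means (not samples), averaged with the GAE embeddings
(`embedding_source="mean"`, also `"vgae"`/`"gae"`).

**3. Random-forest scorer.** A (target, drug) pair is featurized by
concatenating the two embedding vectors (an elementwise-sum encoding is
available). CART trees are grown on with-replacement bootstrap resamples;
splits minimize the size-weighted child Gini impurity `1 − Σ p²` over
candidate thresholds (midpoints of consecutive sorted unique values)
within a random subset of ⌈√d⌉ features; trees grow to purity by default.
A pair's score is the mean positive-class leaf proportion over trees.
Known interactions are the positives; all unknown pairs are negatives by
default (`neg_ratio` subsamples them).

## Hyperparameters

| parameter | default | notes |
| --- | --- | --- |
| epochs | 500 | or early stop: objective change < 1e-6 for 20 epochs |
| learning rate (Adam) | 0.1 | see numerical notes below |
| weight decay | 1e-8 | L2, folded into the gradient |
| hidden size | 256 | GCN hidden width, both encoder families |
| latent dim | 64 | shared by VGAE and GAE so latents are alignable |
| α, β | 0.5, 0.5 | space balance / KL weight, each in (0,1) |
| alignment weight | 1.0 | coupling strength of the EM penalty |
| forest | 100 trees, unlimited depth, ⌈√d⌉ features/split | |

## Numerical choices

* Losses follow the sum (not mean) reduction of their defining formulas.
  On desk-scale graphs (~170 nodes) these sums make Adam's default-scale
  steps at learning rate 0.1 overshoot and oscillate; all synthetic-
  fixture runs in the tests and the acceptance script therefore use
  learning rate 0.01. The 0.1 default is retained in `TrainConfig` as the
  reference setting for larger corpora.
* Hidden layers use leaky ReLU (slope 0.01). The GCN inputs are
  nonnegative (similarities and binary associations), and plain ReLU
  reproducibly collapses here: one aggressive early step drives a
  hidden column's pre-activations all-negative, its gradient becomes
  exactly zero, and the unit never recovers (observed as the GAE loss
  frozen at the logistic(0) plateau). Plain ReLU remains available via
  `hidden_activation="relu"`.
* Probabilities inside logarithms are clipped to [1e-7, 1 − 1e-7];
  log σ is clamped to [−10, 10] before exponentiation.
* Glorot-uniform initialization; one `numpy` generator seeded from the
  config drives initialization, ε draws, bootstraps and fold shuffles, so
  a run is bit-reproducible from its seed.
* Benchmark and acceptance runs use 200 trees instead of the default
  100: bootstrap averaging only reduces score variance, and the larger
  ensemble stabilizes the reported metrics across seeds.
* Row-wise min–max normalization of a constant alignment-score row is
  undefined; such rows are zeroed with a warning rather than raised.
* Split search excludes degenerate splits (an empty child); impurity
  ties resolve to the lowest feature index, then the lowest threshold.

## Synthetic data: what it emulates and what it does not

`synthgen.generate` plants a shared low-rank structure. Latent factors
U (targets × r), V (drugs × r), W (diseases × r) are standard Gaussian;
each association block is sampled `Bernoulli(sigmoid(s·FG^T/√r + b))`
with b bisected so the realized density hits the target. The logit scale
s (`signal_strength`, default 8) controls how cleanly the planted
structure separates interacting from non-interacting pairs; the default
makes the oracle ranking (true logits) nearly perfect, emulating the
high predictability of curated DTI benchmarks, which is the regime the
recovery tests probe. Surface data carry the same signal: fingerprint
bits are Bernoulli draws of a fixed random projection of V (so cosine
similarity tracks latent proximity), and protein sequences are generated
by mutating per-cluster ancestor strings at a rate growing with a
target's distance from its cluster centre (so alignment similarity does
too). Label noise (`noise_flip_rate`) flips entries of the *observed*
association blocks only; the clean sample is kept as ground truth for
evaluation, and flips never touch held-out cells, so noise cannot leak a
masked positive back into training.

The reference recovery fixture is 60 drugs × 80 targets × 30 diseases,
rank 8, density 0.08, 2% flips, fixed seed, with 20% of true interactions
masked out; evaluation ranks the masked positives against all pairs
unknown in both truth and training. `null_benchmark` overwrites every
association block with pure coin flips as a no-signal control.

What passing these tests shows: the pipeline recovers planted low-rank
association structure from multi-view evidence at realistic sparsity and
does not hallucinate structure from noise. What it does not show: the
generator reproduces none of the marginal statistics of real compound
libraries or proteomes (fingerprint bit correlations, sequence family
structure, hub drugs/targets, biased negative sampling), so absolute
metric values do not transfer to DrugBank-scale corpora.

## Problem sizes used by tests and the acceptance script

Reference recovery: the fixture above, 500 epochs, 200 trees. Ablation:
the same fixture, 300 epochs and 60 trees, three seeds, co-training on
vs off. Null control: 30 targets × 25 drugs × 10 diseases, 5-fold CV
with 80 epochs, width-64/latent-16 encoders and 20 trees over five
seeds. These sizes are the package's canonical desk-scale settings;
results at these sizes are what the README quotes.

## Known limitations

* Dense full-graph linear algebra throughout; intended for desk-scale
  networks (hundreds of nodes), not genome-scale corpora.
* The two VGAE views share no parameters; exact drug/target exchange
  symmetry holds structurally but not across independently initialized
  weights.
* The GAE's shared decoder makes the two per-space reconstruction losses
  coincide, so the α weight is inert in the GAE total (it is active in
  the VGAE total and in which latents the alignment couples).
* No minibatching, GPU path, or sparse-matrix support; no automatic
  hyperparameter search beyond what the CLI exposes.
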