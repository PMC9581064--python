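# Methods

## Model

The package implements a drug-response regressor whose first two layers are
sparsity-constrained by biological connectivity. The input for one
(drug, cell line) pair is a vector `X ∈ R^{Kn}` holding `K = 3` features per
gene in gene-major order: expression (FPKM), copy number (integer GISTIC
score in {-2..2}), and the binary `is_target_of_Drug` flag. Two fixed binary
masks define which connections exist:

* `C_XG ∈ {0,1}^{Kn×n}` wires each gene's K features exclusively to that
  gene's node: `c_{i,j} = 1` iff `i = K(j-1)+m`, `m = 1..K` (1-based). Every
  row has exactly one nonzero and every column exactly K.
* `C_GP ∈ {0,1}^{n×s}` wires gene nodes to the signaling pathways they
  belong to (many-to-many membership).

The forward pass is

    G = (C_XG ∘ W_XG)ᵀ X,    P = (C_GP ∘ W_GP)ᵀ G,

with `∘` the element-wise product, followed by a densely connected head
(ReLU layers of 256/128/32 units, then a linear output `ŷ`, the predicted
AUC). The loss is mean squared error. At the real-data scale the model is
instantiated with K = 3, n = 929 genes and s = 46 signaling pathways; the
synthetic benchmark uses n = 200, s = 10.

The masked-tier equations carry no bias and no nonlinearity, so the default
is linear, bias-free tiers; `gene_pathway_activation="relu"` and
`use_bias_masked_layers=True` are opt-in flags.

Masking is enforced structurally, not approximately: the effective weight is
`mask * W` on every forward pass and the weight gradient is multiplied by
the mask on every backward pass. Combined with zero initialization at masked
positions and the fact that Adam maps zero gradients to zero updates, a
masked-out weight is exactly 0.0 (bit-for-bit) at every step of training.
The test suite audits this invariant on every mini-batch of a training run.

### Numerical core

No automatic-differentiation backend is part of the dependency set; the
layers (masked/dense linear, ReLU, LeakyReLU, inverted dropout) implement
their own forward/backward passes in numpy, and the optimizer is Adam with
default moments (β₁=0.9, β₂=0.999, ε=1e-8). The forward pass is validated
against an independent brute-force oracle (explicit per-gene / per-pathway /
per-unit summation loops) on random small architectures to 1e-6 relative
tolerance, and training determinism is tested to bitwise equality.

Choices the architecture description leaves open, fixed here:

* **Optimizer**: Adam — the training protocol prescribes a hand-staged
  learning-rate schedule, which Adam tolerates well. Recorded in every run's
  resolved config.
* **Initialization**: seeded Glorot-uniform (scaled by fan-in/fan-out);
  masked positions forced to 0.
* **Batch size**: 256 by default, configurable.
* **Dropout in the main model's head**: none (only the comparators specify
  dropout).
* **Gene ordering**: lexicographic after alignment, fixed once per dataset;
  masks, sample vectors and checkpoints all carry the same ordering and are
  cross-checked at model-build time.

## Comparator architectures

* **DNN**: the same K·n input through two 256-unit LeakyReLU (α = 0.3)
  layers with dropout 0.1, then 256/128/32 ReLU layers and a linear output.
  Uses its own staged schedule (below).
* **Path-DNN**: expression + is_target features per gene (no CNV), one
  masked layer to the s pathway nodes (each gene's two features inherit that
  gene's pathway connectivity), then 512/32 ReLU layers and a linear output.
* **PASNet**: expression only through the gene→pathway mask, one 100-unit
  ReLU hidden layer with dropout 0.1, linear output; L2 penalty 0.01 on the
  hidden and output layers. The hidden width is not pinned down by the
  protocol description; 100 units follows the original PASNet architecture.

## Training protocol

Five-fold cross-validation: a seeded uniform permutation cut into k
contiguous blocks, remainder samples appended to the last fold(s)
largest-last, so 16,761 records give test folds of 3352/3352/3352/3352/3353.
Each fold trains for 100 epochs under a staged learning-rate schedule:

| model | epochs 1–30 | 31–40 | 41–50 | 51–70 | 71–100 |
|---|---|---|---|---|---|
| pathway-constrained | 1e-3 | 1e-4 | 5e-5 | 1e-5 | 1e-6 |

| DNN | epochs 1–15 | 16–30 | 31–50 | 51–70 | 71–100 |
|---|---|---|---|---|---|
| rates | 1e-3 | 1e-4 | 5e-5 | 1e-5 | 1e-6 |

No early stopping. Metrics are per-fold and averaged train/test MSE and
Pearson r; Pearson on a constant vector is reported as an error, never
silently 0.

### Permutation null

Significance is assessed by retraining from scratch on label-shuffled data:
10 permutations per fold by default (a flag switches to one global set of
permutations), identical protocol and fold split. The empirical p-value per
fold is `#{null r ≥ observed r} / n_perm` — the plain ECDF convention, which
yields p = 0 when the observed correlation exceeds every null draw; the
`(r+1)/(n+1)` add-one correction is available as a flag. FDR across the five
folds uses Benjamini–Hochberg (statsmodels).

## SmoothGrad pathway attribution

The attribution target is the pathway tier: the gradient of `ŷ` with respect
to the s pathway activations says how strongly each pathway drives the
predicted response at a given input. SmoothGrad averages this gradient over
`n_noisy = 50` copies of the input perturbed with Gaussian noise of standard
deviation `noise_scale × (per-dimension input range)`, `noise_scale = 0.10`.
Design choices where the procedure is genuinely open:

* noise is injected at the **input layer** while gradients are taken at the
  pathway layer (a flag moves the perturbation to the pathway activations);
* per-dimension input ranges are computed on the **training split only** (no
  test-set leakage);
* **signed** gradients are pooled (importance distributions legitimately
  span negative and positive values); absolute-value pooling is a flag.

Per-sample scores from all five test folds are pooled into per-pathway
distribution summaries (min, quartiles, max, mean, mean |score|).

## Synthetic benchmark

The generator emulates the five input tables: zero-inflated log-normal
expression (log-scale σ = 1, 10% zeros — enough to exercise the
over-one-third-zeros gene filter machinery without dropping genes at 100
cell lines), GISTIC scores drawn from a multinomial with mode 0
(probabilities 0.05/0.15/0.60/0.15/0.05), each gene assigned to 1–3 of the
s pathways uniformly (pathways topped up to at least one member), and 1–3
target genes per drug.

The planted response model is linear in pathway activities:

    activity_t = mean_{g ∈ pathway t} [ a·expr(g,c) + b·cnv(g,c) + u·is_target(d,g) ]
    AUC(d,c)   = sigmoid( gain · standardize( Σ_t β_t · activity_t ) ) + ε

with fixed generator coefficients a = 1, b = 0.5, u = 1, gain = 2 and
ε ~ N(0, noise_sd²), noise_sd = 0.01 by default; responses are clipped to
[0, 1]. The pre-squash signal is standardized across the generated samples
so the logistic squash spreads responses over (0, 1) like real AUC values
regardless of the arbitrary expression units; all intermediate quantities
(activities, pre-squash signal, noiseless responses) are recorded in
`SyntheticTruth`, so linear-recovery checks remain exact. With all β_t = 0
the responses are pure noise around 0.5. A `quadratic` coefficient adds a
pathway-interaction term (the squared activity for a single active
pathway) to the planted signal, stressing the head's capacity beyond the
linear-in-activities default.

Default scale: 200 genes × 100 cell lines, 10 pathways, 20 drugs, all
drug × cell-line pairs measured → exactly 2,000 response records, one
active pathway (β = 1). One 100-epoch training takes a few seconds on one
CPU, so the full protocol (5-fold CV + 10 permutations per fold) runs in
minutes. Twenty drugs at 100 cell lines were chosen because all pairs then
give the intended ~2,000-record benchmark in one pass, close to the
real-data ratio of two dozen drugs across hundreds of cell lines.

### What the benchmark does and does not show

Because the planted signal is a linear function of pathway activities passed
through a smooth squash, a correctly implemented masked network recovers it
almost perfectly (test r > 0.99 at noise_sd = 0.01) — the benchmark
validates the machinery (masking, alignment, training, attribution), not
performance on real data. Real GDSC/CCLE responses are noisier, the true
response surface is not linear in pathway means, and expression marginals
are only coarsely matched (log-normal with zero inflation; no
gene–gene correlation structure, no batch effects). Headline correlations
from the real-data study (train/test r ≈ 0.98/0.85) depend on the external
dataset and original seeds and are context, not targets, here.

Attribution recovery is assessed over the full five-fold pooled importance:
individual fold models can route credit through pathways whose activities
correlate with the active one (genes belong to several pathways, so pathway
activities overlap), but pooling the five independently initialized fold
models makes the truly active pathway the top-ranked one by mean |score| in
at least 9 of 10 seeded replicates at default conditions.

## Degenerate inputs and tie-breaks

* Gene filter boundary: a gene with exactly one-third zeros is kept
  ("over" read strictly).
* Alignment errors (empty gene/cell-line/drug intersections) raise rather
  than silently producing empty datasets; cell-line matching is exact string
  equality, never fuzzy.
* Duplicate (drug, cell line) response pairs are an input error.
* A pathway with no member gene after alignment is an error (its node could
  never activate).
* Non-finite training loss aborts with the epoch/batch position.

## Known limitations

* Single-CPU numpy training: fine at desk scale, not intended for the
  full 929-gene × 16,761-sample problem at 100 epochs × 55 retrainings.
* The permutation null retrains the full model per shuffle; its cost
  dominates the protocol (50 retrainings at default settings).
* No chemical-structure drug features: drugs are encoded solely through
  target-gene flags, so two drugs with identical target sets are
  indistinguishable by construction.
* No hierarchical ontology masks, no gene-level attribution.
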