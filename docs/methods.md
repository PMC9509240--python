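# Methods

## Problem setting

Given three gene × sample matrices (mRNA expression, DNA methylation, copy
number) over one cohort and a binary drug-response label per sample, the
package predicts response by (i) scoring genes, (ii) finding drug-associated
connected subpathways, (iii) summarizing each subpathway per omics layer per
patient, and (iv) classifying. The clinical dichotomization is fixed:
complete and partial response are responders, stable and progressive disease
are non-responders.

Omics encodings are deliberately unconstrained: any real-valued matrix is
accepted (beta- or M-values for methylation, log-ratios or integer calls for
CNV), because every downstream step works on per-gene standardized values.
Gene identifiers are opaque strings matched exactly across files; no ID
mapping is performed.

## Gene scoring

Each gene is screened per layer with a one-covariate logistic regression of
the label on the gene's values, standardized to mean 0 / sd 1 so the
coefficient is per-SD and comparable across layers. Significance is a
two-sided Wald test; the Wald/LRT distinction is immaterial at screening
scale and Wald is cheaper over thousands of genes. No multiple-testing
correction is applied: the p-values feed a ranking, not a decision
threshold.

The composite score is `S_g = Σ_o −log10 p_{g,o}` over layers where the gene
is measured, with p floored at 1e−300 before the log. The log base only
rescales all scores, so any consumer of the ranking is base-invariant.
Degenerate fits are flagged, never fatal: constant genes get p = 1, perfect
separation gets the floor p with a `separation` flag, non-convergence gets a
flag and p = 1.

**Known limitation.** The 1e−300 floor turns perfectly separated genes into
extreme weight outliers (score 300 against a background of ~1). In small
cohorts at large effect sizes this inflates the global score sd and can
collapse the annealer's incentive to grow modules around such a gene. At the
default study scale (130 samples, unit effect size) separation is rare; for
small-n use the flags should be inspected.

## Subpathway search

Pathways are undirected node-weighted graphs (edge direction from source
files is discarded — connectivity is all the search uses). A module M is
scored by the standardized sum
`Z(M) = (Σ w_g − k μ_w) / (σ_w √k)`,
where μ_w, σ_w are the mean and sd of *all* composite scores; the √k
denominator makes Z size-neutral so the optimizer is not rewarded for
growing indiscriminately.

The optimizer is Metropolis simulated annealing over connected node
subsets. A move adds a node adjacent to the current set or removes a
non-articulation member, drawn uniformly over all legal moves; worsening
moves are accepted with probability exp(ΔZ/T) under geometric cooling
T_t = T₀·r^t (defaults T₀ = 1, r = 0.995, 10 000 iterations, 3 restarts —
the first restart starts at the heaviest node, the rest at random nodes).
The best state ever visited is returned. One module is reported per pathway
(the best), keeping the retained set interpretable as "pathway X's drug-
associated core". Articulation points are recomputed each step with an
iterative lowlink pass, so each iteration is O(k + edges); the inner loop is
numba-compiled.

Significance is a permutation test: node weights are shuffled within the
pathway B = 1000 times and the search re-run at a reduced budget
(iterations/10, one restart); p = (1 + #{Z_perm ≥ Z_obs}) / (B + 1).
The reduced budget is a tractability compromise and biases the null
*downward* (under-optimized permuted scores), i.e. the p-values are
anticonservative at the default budget ratio; with the ratio set to 1
(`perm_budget_divisor=1`) the test is an exact permutation test, which the
test suite verifies under a global null. Screening keeps modules with ≥ 3
genes and p ≤ 0.05, ranks them by Z and retains the top K = 17 (configurable;
if fewer survive, all survivors are kept and downstream shapes adapt).

Screening is re-run inside every cross-validation training fold by default.
A `half-split` mode instead screens once on a stratified random half of the
cohort and reuses those modules in every fold.

## Feature construction

Each retained subpathway × omics layer pair yields one feature per patient:
the mean of the member genes' z-scored values, with z statistics estimated
on the training fold only and reused verbatim on held-out samples. Mean
aggregation balances layers with different units; `median` and `pc1` are
available as config options but mean is the tested default. A subpathway
with no genes measured in a layer contributes 0 there (logged). The K × 3
matrix is flattened subpathway-major to a 3K vector (51 at K = 17); the
network's first layer inverts this exact order.

## Classifiers

**Random forest**: scikit-learn, 500 trees, default depth, seeded, on the
flattened vectors.

**1D CNN** (NumPy implementation with hand-derived gradients, verified
against finite differences in the test suite): reshape 3K → K × 3 → 100
convolution filters of kernel height 1 spanning the 3 omics channels (ReLU)
→ max-pool of size 3 → dropout 0.5 → flatten (100K = 1700 at K = 17) →
dense 512 (ReLU) → dense 256 (ReLU) → dense 2 softmax. The pooling uses
stride 1 with same-length padding so the 17 × 100 map, and hence the
1700-length flatten consumed by the first dense layer, is preserved; a
stride-3 ("one-third length") variant is available via `pool_stride=3` but
is not the default because the downstream dense layer consumes length 1700.

**Attention CNN**: identical stack with an additive-attention layer between
dropout and flatten. Position i (a 100-dim feature vector y_i) is scored
against a learnable 100-dim context vector c by
`e_i = v_aᵀ tanh(W_a c + U_a y_i)` (attention dim 32), α = softmax(e), and
the sequence is re-weighted as `ŷ_i = K α_i y_i`. The K-scaling makes
uniform attention (α_i = 1/K, e.g. v_a = 0) the exact identity, so the
attention model nests the plain CNN — a property the tests assert
parameter-for-parameter. The context vector is learnable; `c = mean_i y_i`
is the documented alternative. The attention is single-query: one score per
position, not position-pair self-attention.

**Training** (all invented plumbing, centralized in `TrainConfig`): Adam at
lr 1e−3, batch size 16, up to 100 epochs, early stopping on validation loss
with patience 10 and best-weights restore, categorical cross-entropy. A
stratified 20% of each training fold serves as the validation split. Runs
are bit-deterministic given the seed.

## Evaluation

Stratified 5-fold cross-validation (stratification is required for stable
minority representation at cohort sizes near 100). Per fold, the entire
pipeline — scoring, screening, feature standardization, fitting — sees the
training samples only; the suite asserts by interception that no fit or
screen call ever receives held-out indices. Metrics are accuracy at the 0.5
probability threshold and rank-based ROC AUC (equivalent to the normalized
Mann–Whitney U; verified against a brute-force all-pairs count). AUC is
computed for all three models. The master seed fans out to per-stage
substreams via named seed sequences, so changing one stage's options does
not perturb another's randomness.

## Synthetic study conditions

The generator emulates the statistical structure the pipeline assumes, at
the scale of a ~130-patient cohort: defaults are 130 samples, 600 genes, 20
pathways of 15–40 nodes (random tree + ~n/2 extra edges), 17 planted
connected modules of 3–8 genes, responder fraction 0.5 assigned by fixed
count, effect size δ = 1.0 (between-class mean shift of planted genes, in
noise-sd units, present in all three layers), noise sd 1.0, and cross-omics
noise correlation ρ = 0.5 through a shared per-gene latent factor. Labels
are drawn first and molecular values generated conditionally (a planted
mean-shift model), which keeps δ directly interpretable and the ground
truth exact. 17 planted modules make the default pipeline output a 17 × 3
feature matrix.

What the generator does **not** emulate: real expression/methylation/CNV
marginal distributions, batch effects, pathway overlap structure beyond
random sharing of background genes, label noise, or class imbalance.
Passing tests therefore demonstrate that the machinery recovers the
structure it assumes — not that the assumed structure describes any real
cohort. At the default δ = 1.0 the planted signal is strong enough that all
three classifiers approach perfect held-out accuracy; the comparison
becomes discriminative only as δ shrinks toward the noise floor.

## Numerical choices and problem sizes

- p floor 1e−300; score arithmetic in float64 throughout.
- SA ties: among equal-Z states the first visited is kept (best-ever only
  replaced on strict improvement); pathways smaller than `min_genes` are
  skipped; an empty survivor set is a hard error advising threshold
  relaxation rather than a silent empty feature matrix.
- Permutation p-values live in [1/(B+1), 1] by construction.
- The acceptance script runs the recovery experiment at the full default
  annealing budget and the five-fold comparison at a reduced budget
  (2 000 iterations, 200 permutations per pathway per fold), the package's
  chosen balance between Monte-Carlo resolution and a five-fold re-screen;
  the suite's cross-validation tests use similarly reduced budgets and
  smaller cohorts, with the exact sizes stated in each test.
- The null-calibration check disables the p ≤ 0.05 screen (threshold 1.0):
  under a zero effect size the filter correctly rejects everything, and the
  check's purpose is to verify the *classifiers* stay at chance on noise
  features.

## Design decisions that were genuinely open

- **Objective, cooling, move set, null.** None are dictated by the problem
  statement; the standardized-sum objective with within-pathway weight
  permutation is the field-standard active-subnetwork recipe, and every
  constant is exposed in `SAConfig`.
- **One module per pathway.** Keeps K interpretable; enumerating multiple
  overlapping modules per pathway is deliberately out of scope.
- **Undirected edges.** The search needs adjacency only; direction would
  add modeling the rest of the pipeline never consumes.
- **No imputation across layers.** Genes absent from a layer simply
  contribute nothing there; imputing would inject unstated structure.
- **Composite via −log10 with no weighting.** Layer weighting and p-value
  dependence corrections (the three layers of one gene are correlated when
  the underlying signal is shared) are known refinements left out to keep
  the score transparent; the test suite demonstrates the dependence effect
  under the null (it shifts rank distributions without creating false
  top-ranked genes).
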