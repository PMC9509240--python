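# pathdrp — pathway-aware drug response prediction

`pathdrp` predicts whether a cancer patient will respond to a drug from
three omics layers — gene expression, DNA methylation and copy number —
by routing the molecular evidence through pathway topology instead of
treating genes as independent markers. It is aimed at computational
biologists working with cohort-scale multi-omics plus clinical response
labels (e.g. responder vs non-responder under temozolomide in low-grade
glioma), where a few hundred patients rule out gene-level deep models but
pathway-level features remain learnable.

The pipeline has four stages:

1. **Gene scoring.** Clinical response categories are dichotomized
   (complete/partial response → 1, stable/progressive disease → 0). Each
   gene *g* is screened in each omics layer *o* by univariate logistic
   regression of the label on its standardized values, and evidence is
   combined into a composite score
   `S_g = Σ_o −log10 p_{g,o}`,
   which lets a gene strongly supported in a single layer outrank one
   mediocre everywhere.
2. **Subpathway discovery.** Composite scores become node weights on each
   pathway graph. Simulated annealing searches connected gene sets *M*
   maximizing the standardized-sum score
   `Z(M) = (Σ_{g∈M} w_g − k·μ_w) / (σ_w √k)`, `k = |M|`,
   accepting worsening moves with probability `exp(ΔZ/T)` under geometric
   cooling. Each pathway's best module gets a permutation p-value
   (weights shuffled within the pathway, search re-run); modules with
   ≥ 3 genes and p ≤ 0.05 survive, and the top *K* = 17 by Z are retained.
3. **Feature construction.** For each patient, each retained subpathway
   contributes one activity score per omics layer (mean of train-fold
   z-scored member-gene values), giving a K × 3 matrix flattened to a
   3K-vector (51 at the default K = 17).
4. **Classification.** Three models are compared under stratified 5-fold
   cross-validation, with scoring and screening re-run inside every
   training fold: a 500-tree random forest, a 1D CNN
   (reshape → 100 conv filters of height 1 → max-pool 3 → dropout 0.5 →
   dense 512 → 256 → softmax 2), and the same CNN with an additive
   attention layer over the K subpathway positions:
   `e_i = v_aᵀ tanh(W_a c + U_a y_i)`, `α = softmax(e)`,
   re-weighting position *i* by `K·α_i` so uniform attention is exactly
   the plain CNN.

Real cohorts with response labels are access-restricted, so the package
ships a first-class synthetic-data module that plants connected
high-signal subpathways inside random pathway graphs and generates
correlated three-layer omics plus labels from them — every stage is
testable end to end without any download.

## Worked example

`python examples/find_subpathways.py` simulates an 80-patient cohort with
5 planted subpathways among 8 pathways, scores all genes, and screens:

```
rank  pathway   k      Z       p     jaccard_vs_truth
   0  path001   8    6.70  0.0233  1.00
   1  path002   6    6.08  0.0100  1.00
   2  path003   5    5.89  0.0033  1.00
   3  path004   6    5.64  0.0033  1.00
   4  path000   3    4.36  0.0266  1.00
```

Each row is one pathway's best connected module: `k` genes whose summed
composite score sits `Z` standard units above what a random size-`k` set
would carry, with permutation significance `p`. Jaccard 1.00 against the
generator's ground truth means every planted module was recovered exactly.
The other examples cover fixture generation (`simulate_fixture.py`), gene
scoring (`score_genes.py`), training and inspecting the attention CNN
(`train_attention_cnn.py`), and the cross-validated model comparison
(`crossvalidate.py`).

A thin CLI wires the same stages for shell use:

```bash
pathdrp simulate --out fixtures --seed 1
pathdrp cv --data-dir fixtures --out results
pathdrp report results/report.json
```

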