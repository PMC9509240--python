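"""Screen every gene for drug association and combine evidence across omics.

Each gene is tested per layer by univariate logistic regression of the
binary response on its (standardized) values; the composite score sums
-log10(p) over layers, so genes supported by several layers — or strongly
by one — rise to the top. Printed: the five highest-scoring genes and
whether they were planted signal genes.
"""

from pathdrp import SimulationConfig, score_all_genes, simulate

config = SimulationConfig(n_samples=80, n_genes=200, n_pathways=8,
                          n_planted_subpathways=5, delta=1.5, seed=2)
dataset, pathways, truth = simulate(config)
scores = score_all_genes(dataset)
signal = truth.all_signal_genes()

top = scores.sort_values("score", ascending=False).head(5)
print("gene    composite S   p(mRNA)   p(Methyl)  p(CNV)    planted?")
for gene, row in top.iterrows():
    print(f"{gene}  {row['score']:10.2f}   {row['p_mRNA']:.2e}  "
          f"{row['p_Methyl']:.2e}  {row['p_CNV']:.2e}  "
          f"{gene in signal}")
print(
    "\nComposite S = sum over layers of -log10(p); a gene at S ~ 9 carries "
    "roughly p ~ 1e-3 of evidence in each of the three layers."
)
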