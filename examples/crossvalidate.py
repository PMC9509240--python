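"""Cross-validated comparison: random forest vs 1D CNN vs attention CNN.

Inside each of 5 stratified folds the full pipeline is re-run on the
training samples only (gene scoring, subpathway screening, feature
standardization), then each model is fit and evaluated on the held-out
fold. Printed: mean +/- sd accuracy and AUC per model.
"""

from pathdrp import SAConfig, SimulationConfig, TrainConfig, run_cv, simulate

config = SimulationConfig(n_samples=80, n_genes=200, n_pathways=8,
                          pathway_size_range=(15, 25),
                          n_planted_subpathways=5, delta=1.2, seed=8)
dataset, pathways, _ = simulate(config)
report = run_cv(
    dataset, pathways,
    SAConfig(iterations=1500, permutations=150, max_subpathways=5),
    TrainConfig(max_epochs=40),
    n_folds=5, seed=8,
)
print(report.comparison_table().round(3).to_string(index=False))
print(
    "\nAccuracies are means over the five held-out folds; with planted "
    "signal subpathways all models should sit well above the 0.5 chance "
    "rate, and the feature construction is what makes the problem easy."
)
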