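"""Per-gene drug-sensitivity screening and composite scoring.

Each gene is screened within each omics layer by a univariate logistic
regression of the binary response on the (standardized) gene value, yielding
a coefficient and a two-sided Wald p-value.  Evidence is then combined across
layers into a composite score

    S_g = sum over layers of -log10(p_{g,o})

so that a gene strongly significant in a single layer can outrank a gene
that is mediocre everywhere — the composite highlights complementary
information between expression, methylation and copy number.  p-values are
floored at 1e-300 before the log; no multiple-testing correction is applied
because the scores feed a ranking, not a hard cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datasets import OmicsDataset

P_FLOOR = 1e-300


@dataclass
class GeneOmicsStat:
    """Univariate logistic fit of one gene in one omics layer."""

    gene: str
    omics_name: str
    beta: float          # log-odds per SD of the gene's value
    p_value: float       # two-sided Wald test of beta = 0
    flag: str = ""       # "", "constant", "separation", "nonconverged"


@dataclass
class CompositeScore:
    gene: str
    score: float
    n_layers_present: int
    flags: tuple[str, ...] = ()


def fit_univariate_logistic(
    x: np.ndarray, y: np.ndarray, gene: str = "", omics_name: str = ""
) -> GeneOmicsStat:
    """Maximum-likelihood logistic fit P(y=1) = sigmoid(b0 + b·x).

    ``x`` is standardized to mean 0, sd 1 before fitting so coefficients are
    per-SD and comparable across omics layers.  Perfect separation gives a
    floored p-value (1e-300) with a flag; constant ``x`` gives p=1, beta=0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, int)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("y must contain both classes 0 and 1")
    if np.bincount(y, minlength=2).min() < 2:
        raise ValueError("need >= 2 samples per class")
    sd = x.std()
    if not np.isfinite(sd) or sd == 0:
        return GeneOmicsStat(gene, omics_name, 0.0, 1.0, "constant")
    xz = (x - x.mean()) / sd
    # perfect separation: the classes occupy disjoint value ranges
    if xz[y == 1].min() > xz[y == 0].max() or xz[y == 1].max() < xz[y == 0].min():
        return GeneOmicsStat(
            gene, omics_name, np.sign(xz[y == 1].mean()) * np.inf, P_FLOOR,
            "separation",
        )
    X = sm.add_constant(xz)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=50)
        except Exception:
            return GeneOmicsStat(gene, omics_name, np.nan, 1.0, "nonconverged")
    beta = float(res.params[1])
    p = float(res.pvalues[1])
    flag = ""
    if not np.isfinite(beta) or not np.isfinite(p):
        # quasi-separation drives |beta| to huge values with p -> 0
        beta = np.nan if not np.isfinite(beta) else beta
        p = P_FLOOR if not np.isfinite(p) else p
        flag = "nonconverged"
    return GeneOmicsStat(gene, omics_name, beta, max(p, P_FLOOR), flag)


def composite_score(stats: list[GeneOmicsStat]) -> CompositeScore:
    """Combine one gene's per-layer p-values into S = sum of -log10 p."""
    if not stats:
        raise ValueError("composite_score needs at least one layer")
    gene = stats[0].gene
    s = float(sum(-np.log10(max(st.p_value, P_FLOOR)) for st in stats))
    flags = tuple(st.flag for st in stats if st.flag)
    return CompositeScore(gene, s, len(stats), flags)


def score_all_genes(
    dataset: OmicsDataset, sample_idx: np.ndarray | list[int] | None = None
) -> pd.DataFrame:
    """Screen every gene in every layer on the given (training) samples.

    Returns a DataFrame indexed by gene with per-layer ``p_<omics>`` and
    ``beta_<omics>`` columns, the composite ``score``, ``n_layers`` and a
    semicolon-joined ``flags`` column.  Per-gene failures are flagged, never
    abort the sweep.
    """
    sub = dataset if sample_idx is None else dataset.subset(list(sample_idx))
    y = sub.labels
    per_gene: dict[str, list[GeneOmicsStat]] = {}
    for name in sub.omics_names:
        mat = sub.omics[name]
        vals = mat.to_numpy(float)
        for i, gene in enumerate(mat.index):
            x = vals[i]
            mask = np.isfinite(x)
            if mask.sum() < 4 or len(np.unique(y[mask])) < 2:
                st = GeneOmicsStat(gene, name, np.nan, 1.0, "insufficient")
            else:
                st = fit_univariate_logistic(x[mask], y[mask], gene, name)
            per_gene.setdefault(gene, []).append(st)

    rows = []
    for gene, stats in per_gene.items():
        comp = composite_score(stats)
        row: dict[str, object] = {
            "gene": gene,
            "score": comp.score,
            "n_layers": comp.n_layers_present,
            "flags": ";".join(f"{st.omics_name}:{st.flag}" for st in stats if st.flag),
        }
        for st in stats:
            row[f"p_{st.omics_name}"] = st.p_value
            row[f"beta_{st.omics_name}"] = st.beta
        rows.append(row)
    df = pd.DataFrame(rows).set_index("gene")
    return df


def scores_as_weights(scores: pd.DataFrame) -> dict[str, float]:
    """Gene → composite score mapping for pathway node weighting."""
    return scores["score"].to_dict()


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index_label="gene")
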