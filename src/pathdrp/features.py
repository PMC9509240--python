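"""Turn retained subpathways into the per-sample (K x 3) feature matrix.

For each subpathway and omics layer, the feature is the mean over member
genes of the gene's z-scored value, with z-scoring statistics (per-gene
mean/sd) computed on the training samples only and reused verbatim for test
samples — the standard guard against information leaking from the held-out
fold.  A subpathway with no member gene measured in a layer contributes 0
for that layer (recorded as a warning).

The model consumes a flat vector: the K x 3 matrix is flattened
subpathway-major (row-major), giving length 3K — 51 at the default K = 17 —
and the network's first layer reshapes it back.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import OmicsDataset
from .subpathways import Subpathway

logger = logging.getLogger(__name__)


@dataclass
class FeatureTensor:
    """Per-sample subpathway x omics activity scores.

    ``values`` has shape (n_samples, K, n_omics); rows are ordered by the
    subpathway retained-rank, columns by the dataset's omics order.
    """

    sample_ids: list[str]
    subpathway_ids: list[str]
    omics_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        expect = (len(self.sample_ids), len(self.subpathway_ids), len(self.omics_names))
        if self.values.shape != expect:
            raise ValueError(f"values shape {self.values.shape} != {expect}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature tensor contains non-finite values")

    @property
    def K(self) -> int:
        return len(self.subpathway_ids)

    def flattened(self) -> np.ndarray:
        """(n_samples, 3K) row-major flatten; the model reshape inverts it."""
        n = len(self.sample_ids)
        return self.values.reshape(n, -1)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"{sp}|{om}"
            for sp in self.subpathway_ids
            for om in self.omics_names
        ]
        return pd.DataFrame(self.flattened(), index=self.sample_ids, columns=cols)


@dataclass
class _GeneStandardizer:
    """Per-gene train-fold mean/sd for one omics layer."""

    mean: pd.Series
    sd: pd.Series

    @classmethod
    def fit(cls, mat: pd.DataFrame, train_cols: list[str]) -> "_GeneStandardizer":
        sub = mat.loc[:, train_cols]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=0).replace(0.0, 1.0).fillna(1.0)
        return cls(mean, sd)

    def transform(self, mat: pd.DataFrame) -> pd.DataFrame:
        mu = self.mean.reindex(mat.index).fillna(0.0)
        sd = self.sd.reindex(mat.index).fillna(1.0)
        return mat.sub(mu, axis=0).div(sd, axis=0)


def subpathway_omics_score(
    subpathway: Subpathway,
    omics_matrix: pd.DataFrame,
    standardizer: _GeneStandardizer,
) -> np.ndarray:
    """Per-sample mean of train-z-scored member-gene values in one layer."""
    members = [g for g in subpathway.genes if g in omics_matrix.index]
    if not members:
        logger.warning(
            "subpathway %s has no genes in this omics layer; feature set to 0",
            subpathway.pathway_id,
        )
        return np.zeros(omics_matrix.shape[1])
    z = standardizer.transform(omics_matrix.loc[members])
    return np.nan_to_num(z.to_numpy(float)).mean(axis=0)


def build_feature_tensor(
    dataset: OmicsDataset,
    subpathways: list[Subpathway],
    train_idx,
    test_idx=None,
    aggregation: str = "mean",
) -> tuple[FeatureTensor, FeatureTensor | None]:
    """Train and (optionally) test tensors sharing train-fold statistics.

    ``aggregation`` supports ``mean`` (default), ``median`` and ``pc1``
    (first principal component loading-weighted mean of z-scored members).
    """
    if not subpathways:
        raise ValueError("no subpathways to build features from (K = 0)")
    if aggregation not in {"mean", "median", "pc1"}:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    train_idx = list(train_idx)
    train_cols = [dataset.sample_ids[i] for i in train_idx]
    standardizers = {
        name: _GeneStandardizer.fit(dataset.omics[name], train_cols)
        for name in dataset.omics_names
    }

    def _tensor(idx) -> FeatureTensor:
        cols = [dataset.sample_ids[i] for i in idx]
        vals = np.zeros((len(cols), len(subpathways), len(dataset.omics_names)))
        for o, name in enumerate(dataset.omics_names):
            mat = dataset.omics[name].loc[:, cols]
            std = standardizers[name]
            for s, sub in enumerate(subpathways):
                members = [g for g in sub.genes if g in mat.index]
                if not members:
                    continue
                z = np.nan_to_num(std.transform(mat.loc[members]).to_numpy(float))
                if aggregation == "mean":
                    vals[:, s, o] = z.mean(axis=0)
                elif aggregation == "median":
                    vals[:, s, o] = np.median(z, axis=0)
                else:  # pc1
                    if z.shape[0] == 1:
                        vals[:, s, o] = z[0]
                    else:
                        u, sv, vt = np.linalg.svd(z - z.mean(axis=1, keepdims=True),
                                                  full_matrices=False)
                        load = u[:, 0]
                        if load.sum() < 0:
                            load = -load
                        vals[:, s, o] = load @ z / np.abs(load).sum()
        return FeatureTensor(
            sample_ids=cols,
            subpathway_ids=[s.pathway_id for s in subpathways],
            omics_names=tuple(dataset.omics_names),
            values=vals,
        )

    train_tensor = _tensor(train_idx)
    test_tensor = _tensor(list(test_idx)) if test_idx is not None else None
    return train_tensor, test_tensor
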