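"""Stratified cross-validated comparison of the three classifiers.

The whole pipeline is re-run inside each training fold — gene scoring,
subpathway screening, feature standardization and model fitting all see the
training samples only — so the held-out fold's labels never reach any fit or
screen call.  The report carries per-fold and aggregate accuracy and AUC for
each model plus the fold assignments, seeds and config snapshot, and is
serializable to JSON/TSV.

An alternative "half-split" screening mode discovers the subpathways once on
a stratified random half of the cohort and reuses them in every fold.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .datasets import OmicsDataset, PathwayGraph
from .features import build_feature_tensor
from .models import TrainConfig, build_cnn, random_forest_baseline, train_model
from .scoring import score_all_genes
from .subpathways import SAConfig, Subpathway, screen_subpathways

MODEL_NAMES = ("random_forest", "cnn", "attention_cnn")


def roc_auc(probabilities: np.ndarray, labels: np.ndarray):
    """Trapezoidal AUC over the empirical ROC (rank-based, ties averaged —
    equivalent to the normalized Mann–Whitney U statistic).

    Returns (auc, fpr, tpr)."""
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC/AUC needs both classes present")
    auc = float(roc_auc_score(labels, probabilities))
    fpr, tpr, _ = roc_curve(labels, probabilities)
    return auc, fpr, tpr


@dataclass
class FoldResult:
    fold: int
    test_idx: list[int]
    metrics: dict[str, dict]  # model -> {accuracy, auc, confusion, probs}


@dataclass
class CVReport:
    folds: list[FoldResult]
    aggregate: dict[str, dict]  # model -> {mean_accuracy, sd_accuracy, ...}
    fold_assignments: list[int]
    seed: int
    config: dict

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config,
            "fold_assignments": self.fold_assignments,
            "folds": [
                {
                    "fold": f.fold,
                    "test_idx": f.test_idx,
                    "metrics": f.metrics,
                }
                for f in self.folds
            ],
            "aggregate": self.aggregate,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def comparison_table(self) -> pd.DataFrame:
        rows = [
            {
                "model": m,
                "mean_accuracy": self.aggregate[m]["mean_accuracy"],
                "sd_accuracy": self.aggregate[m]["sd_accuracy"],
                "mean_auc": self.aggregate[m]["mean_auc"],
                "sd_auc": self.aggregate[m]["sd_auc"],
            }
            for m in self.aggregate
        ]
        return pd.DataFrame(rows)


def _derive(seed: int, *tags: int) -> int:
    return int(np.random.SeedSequence([seed, *tags]).generate_state(1)[0] % (2**31))


def _fit_and_score(
    name: str,
    x_train: np.ndarray, y_train: np.ndarray,
    x_test: np.ndarray, y_test: np.ndarray,
    K: int,
    train_config: TrainConfig,
    seed: int,
) -> dict:
    if name == "random_forest":
        clf = random_forest_baseline(x_train, y_train, seed=seed)
        probs = clf.predict_proba(x_test)[:, 1]
    else:
        xa, xv, ya, yv = train_test_split(
            x_train, y_train, test_size=0.2, stratify=y_train, random_state=seed
        )
        model = build_cnn(K, with_attention=(name == "attention_cnn"), seed=seed)
        train_model(model, xa, ya, xv, yv, replace(train_config, seed=seed))
        probs = model.predict_proba(x_test)[:, 1]
    pred = (probs >= 0.5).astype(int)
    acc = float((pred == y_test).mean())
    auc, _, _ = roc_auc(probs, y_test)
    return {
        "accuracy": acc,
        "auc": auc,
        "confusion": confusion_matrix(y_test, pred).tolist(),
        "probs": [float(p) for p in probs],
    }


def run_cv(
    dataset: OmicsDataset,
    pathways: list[PathwayGraph],
    sa_config: SAConfig | None = None,
    train_config: TrainConfig | None = None,
    model_names: tuple[str, ...] = MODEL_NAMES,
    n_folds: int = 5,
    seed: int = 0,
    aggregation: str = "mean",
    screen_mode: str = "per-fold",
) -> CVReport:
    """Cross-validate the pipeline end to end.

    ``screen_mode='per-fold'`` (default) re-runs gene scoring and subpathway
    screening inside every training fold; ``'half-split'`` screens once on a
    stratified random half of the samples and reuses those subpathways.
    """
    sa_config = sa_config or SAConfig()
    train_config = train_config or TrainConfig()
    if n_folds < 2:
        raise ValueError("cross-validation needs at least 2 folds")
    unknown = set(model_names) - set(MODEL_NAMES)
    if unknown:
        raise ValueError(f"unknown models: {sorted(unknown)}")
    y = dataset.labels
    if len(np.unique(y)) < 2:
        raise ValueError("dataset labels contain a single class")

    fixed_subs: list[Subpathway] | None = None
    if screen_mode == "half-split":
        half_idx, _ = train_test_split(
            np.arange(dataset.n_samples), test_size=0.5, stratify=y,
            random_state=_derive(seed, 31),
        )
        scores = score_all_genes(dataset, half_idx)
        fixed_subs = screen_subpathways(
            pathways, scores, replace(sa_config, seed=_derive(seed, 32))
        )
    elif screen_mode != "per-fold":
        raise ValueError(f"unknown screen_mode {screen_mode!r}")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=_derive(seed, 1))
    assignments = np.empty(dataset.n_samples, int)
    folds: list[FoldResult] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignments[test_idx] = fold
        y_train, y_test = y[train_idx], y[test_idx]
        if len(np.unique(y_test)) < 2:
            raise ValueError(
                f"fold {fold} holds a single class; change the master seed"
            )
        if fixed_subs is None:
            scores = score_all_genes(dataset, train_idx)
            subs = screen_subpathways(
                pathways, scores, replace(sa_config, seed=_derive(seed, 2, fold))
            )
        else:
            subs = fixed_subs
        tr_tensor, te_tensor = build_feature_tensor(
            dataset, subs, train_idx, test_idx, aggregation=aggregation
        )
        x_train = tr_tensor.flattened()
        x_test = te_tensor.flattened()
        metrics = {
            name: _fit_and_score(
                name, x_train, y_train, x_test, y_test, tr_tensor.K,
                train_config, _derive(seed, 3, fold, i),
            )
            for i, name in enumerate(model_names)
        }
        folds.append(FoldResult(fold, [int(i) for i in test_idx], metrics))

    aggregate: dict[str, dict] = {}
    for name in model_names:
        accs = np.array([f.metrics[name]["accuracy"] for f in folds])
        aucs = np.array([f.metrics[name]["auc"] for f in folds])
        aggregate[name] = {
            "mean_accuracy": float(accs.mean()),
            "sd_accuracy": float(accs.std()),
            "mean_auc": float(aucs.mean()),
            "sd_auc": float(aucs.std()),
        }
    config_snapshot = {
        "sa": dataclasses.asdict(sa_config),
        "train": dataclasses.asdict(train_config),
        "n_folds": n_folds,
        "aggregation": aggregation,
        "screen_mode": screen_mode,
        "models": list(model_names),
    }
    return CVReport(
        folds=folds,
        aggregate=aggregate,
        fold_assignments=[int(a) for a in assignments],
        seed=seed,
        config=config_snapshot,
    )
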