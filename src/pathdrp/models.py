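"""The three classifiers: random forest, plain 1D CNN, and attention CNN.

The CNNs consume the flattened (K x 3) subpathway feature vector (length
3K, 51 at K = 17), reshape it, extract 100 convolutional features per
subpathway position, max-pool, drop out, optionally reweight positions by
additive attention, and classify through 512 -> 256 -> 2(softmax) dense
layers.  Training uses Adam with early stopping on validation loss; all
hyperparameters live in :class:`TrainConfig` and every run is deterministic
given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .nn import Adam, ConvAttentionNet


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 100
    patience: int = 10           # early stopping on validation loss
    seed: int = 0

    def validate(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.patience) <= 0:
            raise ValueError("all training hyperparameters must be positive")


def build_cnn(K: int, with_attention: bool, pool_stride: int = 1,
              seed: int = 0, **kwargs) -> ConvAttentionNet:
    """Construct the (attention) CNN for K subpathway positions.

    At K = 17: conv output (17, 100), flatten length 1700, dense sizes
    512/256, softmax over 2 classes.
    """
    return ConvAttentionNet(K=K, with_attention=with_attention,
                            pool_stride=pool_stride, seed=seed, **kwargs)


def _onehot(y: np.ndarray, n_classes: int = 2) -> np.ndarray:
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), y] = 1.0
    return out


def train_model(
    model: ConvAttentionNet,
    x_train: np.ndarray, y_train: np.ndarray,
    x_val: np.ndarray, y_val: np.ndarray,
    config: TrainConfig | None = None,
) -> dict:
    """Early-stopped Adam fit; returns the per-epoch history.

    The model is updated in place; the weights giving the best validation
    loss are restored at the end.  A NaN loss aborts with diagnostics.
    """
    config = config or TrainConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params, lr=config.learning_rate)
    y1 = _onehot(np.asarray(y_train, int))
    yv = np.asarray(y_val, int)
    yv1 = _onehot(yv)
    n = len(x_train)
    history: dict[str, list[float]] = {
        "loss": [], "val_loss": [], "accuracy": [], "val_accuracy": []
    }
    best_val = np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    stale = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, config.batch_size):
            idx = order[s : s + config.batch_size]
            loss, grads = model.loss_and_grads(x_train[idx], y1[idx], rng=rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {s // config.batch_size}; "
                    f"lr={config.learning_rate}, batch={config.batch_size}"
                )
            opt.step(model.params, grads)
            losses.append(loss)
        probs_tr = model.predict_proba(x_train)
        probs_v = model.predict_proba(x_val)
        val_loss = float(-(yv1 * np.log(probs_v + 1e-12)).sum() / len(yv))
        history["loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        history["accuracy"].append(
            float((probs_tr.argmax(1) == np.asarray(y_train, int)).mean()))
        history["val_accuracy"].append(float((probs_v.argmax(1) == yv).mean()))
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    model.params = best_params
    return history


def random_forest_baseline(
    x: np.ndarray, y: np.ndarray, seed: int = 0, n_estimators: int = 500
) -> RandomForestClassifier:
    """The flat-feature baseline: a 500-tree random forest."""
    clf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1, oob_score=True
    )
    clf.fit(np.asarray(x), np.asarray(y, int))
    return clf
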