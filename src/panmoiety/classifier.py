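"""Per-family deep binary classifiers and their evaluation.

One feed-forward network per kinase family maps the 238-bit moiety vector to
the probability that a compound is an active family inhibitor.  Defaults
follow the tuned configuration: four hidden layers of 1024/768/512/256 ReLU
units with batch normalization and 20% dropout, trained with Adam
(lr 0.001, batch size 32) on binary cross entropy, with stratified 80/20
train/validation splits.  Experiments are repeated over independently seeded
splits and initializations and metrics averaged.

Evaluation reports the confusion counts at a 0.5 threshold, accuracy,
Matthews correlation coefficient, and ROC AUC (trapezoidal area under the
ROC curve).  A historical half-sum variant (TPR+FPR)/2 is additionally
reported as ``auc_half_sum`` for transparency; it is not an area under any curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split

from .nn import Adam, DenseNet, binary_cross_entropy

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "Metrics",
    "RepeatResult",
    "init_model",
    "train_model",
    "evaluate",
    "repeat_experiments",
]


@dataclass(frozen=True)
class ModelSpec:
    """Network shape: widths of the hidden stack over the moiety inputs."""

    n_inputs: int = 238
    hidden_sizes: tuple[int, ...] = (1024, 768, 512, 256)
    dropout_rate: float = 0.2
    batch_norm: bool = True

    def validate(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        if len(self.hidden_sizes) < 1 or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be a non-empty tuple of positive ints")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    split_fraction: float = 0.8
    n_repeats: int = 100
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10  # early stopping on validation loss
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass(frozen=True)
class Metrics:
    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    auc: float
    mcc: float
    tpr: float
    fpr: float
    auc_half_sum: float

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "ACC": self.acc, "AUC": self.auc, "MCC": self.mcc,
            "TPR": self.tpr, "FPR": self.fpr, "auc_half_sum": self.auc_half_sum,
        }


def init_model(spec: ModelSpec, seed: int = 0) -> DenseNet:
    """Seeded network construction (He-initialized weights)."""
    spec.validate()
    return DenseNet(
        n_inputs=spec.n_inputs,
        hidden_sizes=spec.hidden_sizes,
        dropout_rate=spec.dropout_rate,
        batch_norm=spec.batch_norm,
        seed=seed,
    )


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y.astype(float)


def train_model(
    model: DenseNet,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
) -> tuple[DenseNet, Metrics]:
    """Train on a stratified random split and return validation metrics.

    Minimizes mean binary cross entropy with Adam over shuffled mini-batches.
    Training stops early when the validation loss has not improved for
    ``cfg.patience`` epochs; the best-validation-loss parameters are
    restored.  Fully deterministic for a given config seed.
    """
    cfg.validate()
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    X_tr, X_va, y_tr, y_va = train_test_split(
        X,
        y,
        train_size=cfg.split_fraction,
        random_state=cfg.seed % (2**32),
        stratify=y,
    )
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training split contains a single class")

    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xB47C)))
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    best_loss = math.inf
    best_state = model.state_dict()
    stale = 0
    n = len(y_tr)
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            _, cache = model.forward(X_tr[idx], training=True, rng=rng)
            grads = model.backward(cache, y_tr[idx])
            optimizer.step(grads)
        val_loss = binary_cross_entropy(model.predict_proba(X_va), y_va)
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_state = model.state_dict()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    model.load_state_dict(best_state)
    return model, evaluate(model.predict_proba(X_va), y_va)


def evaluate(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> Metrics:
    """Confusion counts at the threshold plus ACC, MCC and ROC AUC.

    MCC is 0 when any factor of its denominator vanishes.  AUC is the
    trapezoidal area under the ROC curve over all score thresholds; with a
    single label class it is undefined and reported as NaN.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size == 0:
        raise ValueError("evaluate requires at least one sample")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    tn = int(np.sum(~pred & ~pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n
    denom = (tp + fp) * (tp + fn) * (tn + fn) * (tn + fp)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    tpr = tp / (tp + fn) if (tp + fn) else 0.0
    fpr = fp / (fp + tn) if (fp + tn) else 0.0
    if pos.all() or (~pos).all():
        auc = float("nan")
    else:
        fpr_curve, tpr_curve, _ = roc_curve(labels, scores)
        auc = float(np.trapezoid(tpr_curve, fpr_curve))
    return Metrics(tp, tn, fp, fn, acc, auc, mcc, tpr, fpr, (tpr + fpr) / 2.0)


@dataclass
class RepeatResult:
    """Averaged metrics over repeated splits, plus the trained models."""

    metrics: list[Metrics]
    models: list[DenseNet]
    mean: dict = field(init=False)
    std: dict = field(init=False)

    def __post_init__(self) -> None:
        keys = ("ACC", "AUC", "MCC")
        values = {k: np.array([m.as_dict()[k] for m in self.metrics]) for k in keys}
        self.mean = {k: float(np.nanmean(v)) for k, v in values.items()}
        self.std = {k: float(np.nanstd(v)) for k, v in values.items()}


def repeat_experiments(
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    spec: ModelSpec | None = None,
) -> RepeatResult:
    """Re-train from scratch over ``cfg.n_repeats`` independent splits.

    Each repeat derives its own split and initialization seed from
    ``cfg.seed``, so the whole experiment is reproducible end to end.
    """
    cfg.validate()
    if spec is None:
        spec = ModelSpec(n_inputs=np.asarray(X).shape[1])
    seeds = np.random.SeedSequence(cfg.seed).generate_state(2 * cfg.n_repeats) % (2**31)
    metrics = []
    models = []
    for r in range(cfg.n_repeats):
        model = init_model(spec, seed=int(seeds[2 * r]))
        repeat_cfg = TrainConfig(
            split_fraction=cfg.split_fraction,
            n_repeats=1,
            learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size,
            max_epochs=cfg.max_epochs,
            patience=cfg.patience,
            seed=int(seeds[2 * r + 1]),
        )
        model, m = train_model(model, X, y, repeat_cfg)
        metrics.append(m)
        models.append(model)
    return RepeatResult(metrics, models)
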