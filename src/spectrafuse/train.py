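"""Training loop, learning-rate schedule, model selection and evaluation.

The protocol: minibatch SGD (batch 128) for 500 epochs with a scheduled
learning rate starting at 0.005 and cut to one tenth every 100 epochs;
after every epoch the training and validation accuracies are recorded and
the parameter snapshot with the highest validation accuracy (earliest
epoch on ties) is the returned model.  Test accuracy is computed once, on
that selected snapshot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import DatasetSplit, labels_of
from .nn import SGD


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule hyperparameters.

    Defaults mirror the full protocol (500 epochs, base lr 0.005 decayed
    x0.1 every 100 epochs, batch 128, plain SGD); tests and examples pass
    smaller epoch counts.
    """

    epochs: int = 500
    base_lr: float = 0.005
    lr_decay: float = 0.1
    decay_every: int = 100
    batch_size: int = 128
    seed: int = 0
    optimizer: str = "sgd"
    momentum: float = 0.0
    select_by: str = "accuracy"  # or "loss"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.select_by not in ("accuracy", "loss"):
            raise ValueError("select_by must be 'accuracy' or 'loss'")
        if self.optimizer not in ("sgd", "sgd_momentum"):
            raise ValueError("optimizer must be 'sgd' or 'sgd_momentum'")


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Learning rate at a 1-based epoch: base_lr * decay^floor((epoch-1)/100)."""
    if not 1 <= epoch <= cfg.epochs:
        raise ValueError(f"epoch must be in 1..{cfg.epochs}, got {epoch}")
    return cfg.base_lr * cfg.lr_decay ** ((epoch - 1) // cfg.decay_every)


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    loss: float
    train_acc: float
    val_acc: float


@dataclass
class TrainResult:
    model: object
    history: list[EpochRecord]
    best_epoch: int
    best_val_acc: float


def _accuracy(model, X, y) -> float:
    proba = model.predict_proba(X)
    return float(np.mean(proba.argmax(axis=1) == y))


def _val_loss(model, X, y) -> float:
    proba = model.predict_proba(X)
    n = len(y)
    return float(-np.mean(np.log(np.maximum(proba[np.arange(n), y], 1e-12))))


def _slice_inputs(X, idx):
    if isinstance(X, list):
        return [x[idx] for x in X]
    return X[idx]


def train(model, split: DatasetSplit, cfg: TrainConfig = TrainConfig()) -> TrainResult:
    """Train a model on a split and return the best-validation snapshot.

    ``model`` is any object with the protocol used throughout the
    package: ``inputs(records)``, ``loss_and_grads(X, y)``,
    ``predict_proba(X)``, ``parameters()``, ``get_state()/set_state()``.
    Deterministic for a fixed (model seed, cfg.seed, data) triple in
    single-threaded execution.
    """
    if not split.train or not split.validation:
        raise ValueError("train and validation sets must be nonempty")
    Xtr = model.inputs(split.train)
    ytr = labels_of(split.train)
    Xval = model.inputs(split.validation)
    yval = labels_of(split.validation)
    n = len(ytr)
    batch = cfg.batch_size
    if batch > n:
        warnings.warn(
            f"batch_size {batch} exceeds training-set size {n}; shrinking",
            stacklevel=2,
        )
        batch = n

    opt = SGD(model.parameters(), momentum=cfg.momentum if cfg.optimizer == "sgd_momentum" else 0.0)
    rng = np.random.default_rng(cfg.seed)
    history: list[EpochRecord] = []
    best_state = model.get_state()
    best_val = -np.inf
    best_epoch = 0

    for epoch in range(1, cfg.epochs + 1):
        lr = lr_at(epoch, cfg)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            opt.zero_grad()
            losses.append(model.loss_and_grads(_slice_inputs(Xtr, idx), ytr[idx]))
            opt.step(lr)
        if hasattr(model, "recalibrate"):
            # exponential BN averages lag when an epoch has few batches;
            # re-estimate inference statistics at the current parameters
            model.recalibrate(Xtr)
        train_acc = _accuracy(model, Xtr, ytr)
        val_acc = _accuracy(model, Xval, yval)
        history.append(EpochRecord(epoch, lr, float(np.mean(losses)), train_acc, val_acc))
        score = val_acc if cfg.select_by == "accuracy" else -_val_loss(model, Xval, yval)
        if score > best_val:
            best_val = score
            best_state = model.get_state()
            best_epoch = epoch

    model.set_state(best_state)
    best_val_acc = (
        best_val if cfg.select_by == "accuracy" else _accuracy(model, Xval, yval)
    )
    return TrainResult(model=model, history=history, best_epoch=best_epoch,
                       best_val_acc=float(best_val_acc))


@dataclass
class EvalReport:
    """Accuracy plus a 5x5 confusion matrix (rows = true, cols = predicted)."""

    accuracy: float
    confusion: np.ndarray


def evaluate(model, records) -> EvalReport:
    """Evaluate on a record list: argmax predictions (ties -> smallest index)."""
    if not records:
        raise ValueError("record list must be nonempty")
    X = model.inputs(records)
    y = labels_of(records)
    preds = model.predict_proba(X).argmax(axis=1)
    n_classes = 5
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y, preds):
        confusion[t, p] += 1
    accuracy = float(np.trace(confusion) / confusion.sum())
    return EvalReport(accuracy=accuracy, confusion=confusion)


def evaluate_all(model, split: DatasetSplit) -> dict[str, EvalReport]:
    """Per-split evaluation (train / validation / test)."""
    out = {}
    for name, recs in (("train", split.train), ("validation", split.validation), ("test", split.test)):
        if recs:
            out[name] = evaluate(model, recs)
    return out
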