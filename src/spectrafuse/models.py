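"""Base classifiers: the gated-attention 1D CNN (CNN-S) and an RBF-SVM.

CNN-S processes one 1-D input vector (a reflectance spectrum, a kinetic
curve, or a concatenation of several) through:

1. an attention layer, Y = ReLU(W1 · ReLU(W2 · X + b1) + b2) ⊙ X;
2. a convolution block of three 1-D convolutions (kernel 3, stride 1,
   ReLU) with one max-pooling (size 2, stride 2) after the first;
3. three dense layers of 512, 128 and 5 neurons (ReLU on the first two,
   softmax on the last);

with batch normalization before every convolution and dense layer and a
softmax cross-entropy loss.  The 128-unit activation feeding the last
dense layer is the "deep feature" used by the feature-level fusion
models.

The RBF-SVM is the conventional reference classifier: a grid search over
C and gamma in {10^-8 .. 10^8} (289 pairs) selected on validation
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from . import nn
from .data import FusionStrategy, SINGLE_MODALITY_STRATEGIES, assemble
from .nn import DTYPE, softmax

N_CLASSES = 5


# ---------------------------------------------------------------------------
# attention layer (functional form)


@dataclass
class AttentionParams:
    """Weights of the attention gate: W1 (d x h), W2 (h x d), b1 (h), b2 (d)."""

    W1: np.ndarray
    W2: np.ndarray
    b1: np.ndarray
    b2: np.ndarray

    def __post_init__(self):
        W1, W2 = np.asarray(self.W1, float), np.asarray(self.W2, float)
        b1, b2 = np.asarray(self.b1, float), np.asarray(self.b2, float)
        d, h = W1.shape
        if W2.shape != (h, d) or b1.shape != (h,) or b2.shape != (d,):
            raise ValueError(
                f"inconsistent attention shapes: W1 {W1.shape}, W2 {W2.shape}, "
                f"b1 {b1.shape}, b2 {b2.shape}"
            )
        self.W1, self.W2, self.b1, self.b2 = W1, W2, b1, b2

    @property
    def d(self) -> int:
        return self.W1.shape[0]

    @property
    def h(self) -> int:
        return self.W1.shape[1]


def attention_forward(x: np.ndarray, p: AttentionParams) -> np.ndarray:
    """Apply the multiplicative ReLU attention gate to a vector or batch."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xb = x[None, :] if single else x
    if xb.shape[-1] != p.d:
        raise ValueError(f"input length {xb.shape[-1]} != attention d {p.d}")
    inner = np.maximum(xb @ p.W2.T + p.b1, 0.0)
    gate = np.maximum(inner @ p.W1.T + p.b2, 0.0)
    out = gate * xb
    return out[0] if single else out


# ---------------------------------------------------------------------------
# CNN-S


@dataclass(frozen=True)
class CNNSConfig:
    """Architecture hyperparameters of the CNN-S base classifier.

    Kernel/stride/pool values and the dense widths are the cited design;
    the convolution channel counts and the attention hidden width are the
    open choices (defaults: 16/32/32 channels, hidden width = input
    length).
    """

    input_length: int
    conv_channels: tuple[int, int, int] = (16, 32, 32)
    kernel_size: int = 3
    stride: int = 1
    pool_size: int = 2
    pool_stride: int = 2
    dense_sizes: tuple[int, int, int] = (512, 128, 5)
    attention_hidden: int | None = None
    batch_norm: bool = True

    def __post_init__(self):
        if self.input_length < self.pool_size:
            raise ValueError("input_length too short")
        if self.dense_sizes[-1] != N_CLASSES:
            raise ValueError(f"dense_sizes must end in {N_CLASSES}")
        if self.pool_size != self.pool_stride:
            raise ValueError("only non-overlapping pooling is supported")

    @property
    def hidden(self) -> int:
        return self.attention_hidden if self.attention_hidden is not None else self.input_length

    @property
    def flatten_width(self) -> int:
        pooled = self.input_length // self.pool_size
        return self.conv_channels[2] * pooled


def _build_cnns_layers(cfg: CNNSConfig, rng: np.random.Generator):
    """Build (trunk, head) layer lists; trunk ends at the 128-d feature."""
    c1, c2, c3 = cfg.conv_channels
    d1, d2, d3 = cfg.dense_sizes
    k = cfg.kernel_size
    bn = cfg.batch_norm

    def maybe_bn(n, conv):
        return [nn.BatchNorm(n, conv=conv)] if bn else []

    trunk: list[nn.Layer] = [
        nn.AttentionGate(cfg.input_length, cfg.hidden, rng),
        nn.Reshape1d(),
        *maybe_bn(1, True),
        nn.Conv1d(1, c1, k, rng, stride=cfg.stride),
        nn.ReLU(),
        nn.MaxPool1d(cfg.pool_size),
        *maybe_bn(c1, True),
        nn.Conv1d(c1, c2, k, rng, stride=cfg.stride),
        nn.ReLU(),
        *maybe_bn(c2, True),
        nn.Conv1d(c2, c3, k, rng, stride=cfg.stride),
        nn.ReLU(),
        nn.Flatten(),
        *maybe_bn(cfg.flatten_width, False),
        nn.Dense(cfg.flatten_width, d1, rng),
        nn.ReLU(),
        *maybe_bn(d1, False),
        nn.Dense(d1, d2, rng),
        nn.ReLU(),
    ]
    head: list[nn.Layer] = [
        *maybe_bn(d2, False),
        nn.Dense(d2, d3, rng),
    ]
    return trunk, head


def _collect_state(layers: Sequence[nn.Layer]) -> list[np.ndarray]:
    state = []
    for layer in layers:
        for p in layer.parameters():
            state.append(p.value.copy())
        if isinstance(layer, nn.BatchNorm):
            state.append(layer.running_mean.copy())
            state.append(layer.running_var.copy())
    return state


def _recalibrate_layers(layers, forward_fn, X, batch: int = 1024) -> None:
    """Re-estimate all batch-norm running statistics over a dataset.

    Runs training-mode forwards in calibration mode so each batch-norm
    layer replaces its exponential running averages with the exact
    population moments of the current activations.
    """
    bns = [l for l in layers if isinstance(l, nn.BatchNorm)]
    if not bns:
        return
    for b in bns:
        b.begin_calibration()
    n = X[0].shape[0] if isinstance(X, list) else X.shape[0]
    for i in range(0, n, batch):
        if isinstance(X, list):
            forward_fn([x[i : i + batch] for x in X])
        else:
            forward_fn(X[i : i + batch])
    for b in bns:
        b.end_calibration()


def _restore_state(layers: Sequence[nn.Layer], state: Sequence[np.ndarray]) -> None:
    it = iter(state)
    for layer in layers:
        for p in layer.parameters():
            p.value = next(it).copy()
        if isinstance(layer, nn.BatchNorm):
            layer.running_mean = next(it).copy()
            layer.running_var = next(it).copy()


class CNNSModel:
    """The CNN-S base classifier bound to a modality subset.

    ``strategy`` determines which modality vectors (concatenated in the
    fixed order) the model consumes; a single-modality strategy gives the
    plain base classifier, a multi-modality one the raw-concatenation
    (low-level fusion) variant.
    """

    def __init__(self, cfg: CNNSConfig, seed: int = 0, strategy: FusionStrategy | None = None):
        self.cfg = cfg
        self.seed = seed
        self.strategy = strategy
        rng = np.random.default_rng(seed)
        self.trunk, self.head = _build_cnns_layers(cfg, rng)
        self._all = nn.Sequential(list(self.trunk) + list(self.head))

    # -- model protocol -----------------------------------------------------

    def parameters(self) -> list[nn.Parameter]:
        return self._all.parameters()

    def inputs(self, records) -> np.ndarray:
        if self.strategy is None:
            raise ValueError("model has no bound strategy; pass arrays directly")
        return assemble(records, self.strategy, "stacked").astype(DTYPE)

    def _check(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.cfg.input_length:
            raise ValueError(
                f"input length {x.shape[1]} != configured {self.cfg.input_length}"
            )
        return x

    def forward_logits(self, x: np.ndarray, training: bool) -> np.ndarray:
        return self._all.forward(self._check(x), training)

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray) -> float:
        logits = self.forward_logits(x, training=True)
        loss, g = nn.softmax_cross_entropy(logits, y)
        self._all.backward(g)
        return loss

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        x = self._check(x)
        out = [
            softmax(self._all.forward(x[i : i + batch], training=False))
            for i in range(0, x.shape[0], batch)
        ]
        return np.concatenate(out, axis=0)

    def penultimate_features(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        """The 128-d activation feeding the final dense layer (inference mode)."""
        x = self._check(x)
        trunk = nn.Sequential(list(self.trunk))
        out = [trunk.forward(x[i : i + batch], training=False) for i in range(0, x.shape[0], batch)]
        return np.concatenate(out, axis=0)

    def head_forward(self, features: np.ndarray) -> np.ndarray:
        """Apply the final BN + dense + softmax to given 128-d features."""
        z = np.ascontiguousarray(features, dtype=DTYPE)
        for layer in self.head:
            z = layer.forward(z, training=False)
        return softmax(z)

    def recalibrate(self, x: np.ndarray, batch: int = 1024) -> None:
        """Replace BN running statistics with population moments over ``x``."""
        x = self._check(x)
        _recalibrate_layers(self._all.layers, lambda xb: self._all.forward(xb, True), x, batch)

    def get_state(self) -> list[np.ndarray]:
        return _collect_state(self._all.layers)

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        _restore_state(self._all.layers, state)

    def save(self, path) -> None:
        """Write a binary checkpoint (.npz) plus a JSON config sidecar."""
        import dataclasses
        import json
        from pathlib import Path

        path = Path(path)
        state = self.get_state()
        np.savez(path.with_suffix(".npz"), **{f"arr_{i}": a for i, a in enumerate(state)})
        sidecar = {
            "config": dataclasses.asdict(self.cfg),
            "seed": int(self.seed) if np.isscalar(self.seed) else None,
            "strategy": self.strategy.name if self.strategy is not None else None,
            "n_arrays": len(state),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "CNNSModel":
        """Rebuild a model from :meth:`save` output."""
        import json
        from pathlib import Path

        from .data import FUSION_STRATEGIES, SINGLE_MODALITY_STRATEGIES

        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg_dict = sidecar["config"]
        for key in ("conv_channels", "dense_sizes"):
            cfg_dict[key] = tuple(cfg_dict[key])
        strategy = None
        if sidecar["strategy"] is not None:
            named = {s.name: s for s in FUSION_STRATEGIES.values()}
            named.update(SINGLE_MODALITY_STRATEGIES)
            strategy = named[sidecar["strategy"]]
        model = cls(CNNSConfig(**cfg_dict), seed=sidecar["seed"] or 0, strategy=strategy)
        with np.load(path.with_suffix(".npz")) as data:
            model.set_state([data[f"arr_{i}"] for i in range(sidecar["n_arrays"])])
        return model


def single_modality_model(modality: str, length: int, seed: int = 0,
                          cfg: CNNSConfig | None = None) -> CNNSModel:
    """Convenience constructor: CNN-S bound to one modality."""
    if cfg is None:
        cfg = CNNSConfig(input_length=length)
    elif cfg.input_length != length:
        raise ValueError("cfg.input_length disagrees with modality length")
    return CNNSModel(cfg, seed=seed, strategy=SINGLE_MODALITY_STRATEGIES[modality])


# ---------------------------------------------------------------------------
# RBF-SVM reference classifier


def _decade_grid() -> tuple[float, ...]:
    return tuple(float(10.0**e) for e in range(-8, 9))


@dataclass(frozen=True)
class SVMGridConfig:
    """RBF-SVM search grid: C and gamma over decades 10^-8 .. 10^8."""

    kernel: str = "rbf"
    C_grid: tuple[float, ...] = field(default_factory=_decade_grid)
    g_grid: tuple[float, ...] = field(default_factory=_decade_grid)

    def __post_init__(self):
        if not self.C_grid or not self.g_grid:
            raise ValueError("grids must be nonempty")
        if any(v <= 0 for v in self.C_grid) or any(v <= 0 for v in self.g_grid):
            raise ValueError("grid values must be positive")


def svm_train_select(
    train_X: np.ndarray,
    train_y: np.ndarray,
    val_X: np.ndarray,
    val_y: np.ndarray,
    grid: SVMGridConfig = SVMGridConfig(),
):
    """Train an RBF-SVM per (C, gamma) pair and select on validation accuracy.

    Returns ``(classifier, (C, gamma), validation_accuracy)``; ties go to
    the smallest C, then the smallest gamma.
    """
    train_y = np.asarray(train_y)
    if np.unique(train_y).size < 2:
        raise ValueError("training set must contain at least two classes")
    best = None
    for C in sorted(grid.C_grid):
        for g in sorted(grid.g_grid):
            clf = SVC(kernel=grid.kernel, C=C, gamma=g)
            clf.fit(train_X, train_y)
            acc = float(np.mean(clf.predict(val_X) == val_y))
            if best is None or acc > best[2]:
                best = (clf, (C, g), acc)
    return best
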