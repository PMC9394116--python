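"""Multimodal fusion architectures over the CNN-S base classifier.

Three fusion levels are provided, all trainable end to end:

* **low level** — the selected modality vectors are concatenated into one
  long vector and fed to a single CNN-S;
* **middle level** — one CNN-S trunk (the network minus its final dense
  layer) per modality produces a 128-d deep feature; each feature passes
  through a trainable per-branch linear map with ReLU, the results are
  concatenated and a dense softmax head classifies, with one
  cross-entropy on the fused output;
* **high level (decision fusion)** — one complete CNN-S per modality
  outputs class probabilities; the probability vectors are concatenated
  (length 5m) and fed to a dense softmax head.  The joint loss
  ``L = ce(y, y_F) + sum_i ce(y, y_i)`` simultaneously drives the fused
  output and every submodel toward the true class, so the concatenated
  inputs stay genuine probability distributions and the head performs a
  learned decision fusion.

Two conventional two-stage baselines are included for comparison: middle
level with separately trained frozen extractors plus a fresh classifier
on the concatenated 128m-d features, and high level as plain averaging of
separately trained submodels' probability vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .data import FusionStrategy, SINGLE_MODALITY_STRATEGIES, assemble
from .models import (
    CNNSConfig,
    CNNSModel,
    N_CLASSES,
    _build_cnns_layers,
    _collect_state,
    _recalibrate_layers,
    _restore_state,
)
from .nn import DTYPE, softmax

DEFAULT_MODALITY_LENGTHS = {
    "l_visnir": 396,
    "s_visnir": 396,
    "l_fkc": 286,
    "s_fkc": 286,
}

_EPS = 1e-12


def _branch_cfg(length: int, overrides: dict | None) -> CNNSConfig:
    return CNNSConfig(input_length=length, **(overrides or {}))


# ---------------------------------------------------------------------------
# low-level fusion


def low_level_model(
    strategy: FusionStrategy,
    modality_lengths: dict[str, int] | None = None,
    seed: int = 0,
    cfg_overrides: dict | None = None,
) -> CNNSModel:
    """CNN-S consuming the raw concatenation of the selected modalities."""
    lengths = modality_lengths or DEFAULT_MODALITY_LENGTHS
    total = sum(lengths[m] for m in strategy.modalities)
    cfg = _branch_cfg(total, cfg_overrides)
    return CNNSModel(cfg, seed=seed, strategy=strategy)


# ---------------------------------------------------------------------------
# middle-level fusion (end-to-end)


class _ScalarScale(nn.Layer):
    """y = w * x with a single trainable scalar (scalar fusion-weight mode)."""

    def __init__(self):
        self.w = nn.Parameter(np.ones(1))
        self._x = None

    def parameters(self):
        return [self.w]

    def forward(self, x, training):
        self._x = x if training else None
        return self.w.value * x

    def backward(self, g):
        self.w.grad += np.array([(g * self._x).sum()], dtype=DTYPE)
        return self.w.value * g


class MiddleFusionModel:
    """End-to-end feature-level fusion.

    Per selected modality: a CNN-S trunk to a 128-d deep feature, a
    trainable fusion weight (a 128x128 linear map by default, a scalar if
    ``scalar_weights``) and a ReLU; the weighted features are concatenated
    and classified by a dense softmax head, trained with a single
    cross-entropy on the fused output.
    """

    def __init__(
        self,
        strategy: FusionStrategy,
        modality_lengths: dict[str, int] | None = None,
        seed: int = 0,
        cfg_overrides: dict | None = None,
        scalar_weights: bool = False,
    ):
        if strategy.n_modalities < 2:
            raise ValueError("middle-level fusion needs at least two modalities")
        self.strategy = strategy
        lengths = modality_lengths or DEFAULT_MODALITY_LENGTHS
        rng = np.random.default_rng(seed)
        self.branch_cfgs = [_branch_cfg(lengths[m], cfg_overrides) for m in strategy.modalities]
        feat = self.branch_cfgs[0].dense_sizes[1]
        self.feature_width = feat
        self.trunks = []
        self.branch_maps = []
        self.branch_relus = []
        for cfg in self.branch_cfgs:
            trunk, _ = _build_cnns_layers(cfg, rng)
            self.trunks.append(nn.Sequential(trunk))
            self.branch_maps.append(
                _ScalarScale() if scalar_weights else nn.Dense(feat, feat, rng)
            )
            self.branch_relus.append(nn.ReLU())
        m = strategy.n_modalities
        self.head = nn.Dense(feat * m, N_CLASSES, rng)
        self._layers = (
            [l for t in self.trunks for l in t.layers]
            + self.branch_maps
            + self.branch_relus
            + [self.head]
        )

    # -- model protocol -----------------------------------------------------

    def parameters(self):
        return [p for layer in self._layers for p in layer.parameters()]

    def inputs(self, records) -> list[np.ndarray]:
        return [m.astype(DTYPE) for m in assemble(records, self.strategy, "per_modality")]

    def _check(self, xs) -> list[np.ndarray]:
        if len(xs) != len(self.trunks):
            raise ValueError(
                f"expected {len(self.trunks)} modality inputs, got {len(xs)}"
            )
        out = []
        for x, cfg in zip(xs, self.branch_cfgs):
            x = np.ascontiguousarray(x, dtype=DTYPE)
            if x.ndim == 1:
                x = x[None, :]
            if x.shape[1] != cfg.input_length:
                raise ValueError("modality input length mismatch")
            out.append(x)
        return out

    def forward_logits(self, xs, training: bool) -> np.ndarray:
        xs = self._check(xs)
        hs = []
        for x, trunk, wmap, relu in zip(xs, self.trunks, self.branch_maps, self.branch_relus):
            f = trunk.forward(x, training)
            hs.append(relu.forward(wmap.forward(f, training), training))
        z = np.concatenate(hs, axis=1)
        return self.head.forward(z, training)

    def loss_and_grads(self, xs, y) -> float:
        logits = self.forward_logits(xs, training=True)
        loss, g = nn.softmax_cross_entropy(logits, y)
        dz = self.head.backward(g)
        f = self.feature_width
        for i, (trunk, wmap, relu) in enumerate(
            zip(self.trunks, self.branch_maps, self.branch_relus)
        ):
            dh = dz[:, i * f : (i + 1) * f]
            trunk.backward(wmap.backward(relu.backward(dh)))
        return loss

    def predict_proba(self, xs, batch: int = 256) -> np.ndarray:
        xs = self._check(xs)
        n = xs[0].shape[0]
        out = []
        for i in range(0, n, batch):
            sl = [x[i : i + batch] for x in xs]
            out.append(softmax(self.forward_logits(sl, training=False)))
        return np.concatenate(out, axis=0)

    def recalibrate(self, xs, batch: int = 1024) -> None:
        """Replace BN running statistics with population moments over ``xs``."""
        xs = self._check(xs)
        _recalibrate_layers(self._layers, lambda sl: self.forward_logits(sl, True), xs, batch)

    def get_state(self):
        return _collect_state(self._layers)

    def set_state(self, state):
        _restore_state(self._layers, state)


# ---------------------------------------------------------------------------
# high-level (decision) fusion, end-to-end with the joint loss


@dataclass
class HighFusionOutput:
    """Fused prediction plus the per-submodel probability vectors."""

    y_F: np.ndarray
    y_subs: list[np.ndarray]


def joint_loss(out: HighFusionOutput, y: int) -> float:
    """Joint cross-entropy: ce(y, y_F) + sum_i ce(y, y_i) for one sample.

    Probabilities are floored at 1e-12 before the log for numerical
    safety.
    """
    terms = [out.y_F] + list(out.y_subs)
    return float(sum(-np.log(max(float(v[y]), _EPS)) for v in terms))


class HighFusionModel:
    """End-to-end decision fusion over complete CNN-S submodels.

    Each selected modality runs through a full CNN-S (softmax output);
    the m probability vectors are concatenated (length 5m) and a dense
    layer with 5 neurons plus softmax produces the fused prediction.
    Training backpropagates the joint loss through the head *and* all
    submodels in one stage.
    """

    def __init__(
        self,
        strategy: FusionStrategy,
        modality_lengths: dict[str, int] | None = None,
        seed: int = 0,
        cfg_overrides: dict | None = None,
    ):
        if strategy.n_modalities < 2:
            raise ValueError("high-level fusion needs at least two modalities")
        self.strategy = strategy
        lengths = modality_lengths or DEFAULT_MODALITY_LENGTHS
        seeds = np.random.SeedSequence(seed).spawn(strategy.n_modalities + 1)
        self.submodels = [
            CNNSModel(
                _branch_cfg(lengths[m], cfg_overrides),
                seed=s,
                strategy=SINGLE_MODALITY_STRATEGIES[m],
            )
            for m, s in zip(strategy.modalities, seeds[:-1])
        ]
        m = strategy.n_modalities
        self.head = nn.Dense(N_CLASSES * m, N_CLASSES, np.random.default_rng(seeds[-1]))
        # Initialize the decision head at probability averaging (stacked
        # identity blocks / m): the fused output starts as the mean of the
        # submodel distributions and training refines the combination.
        self.head.W.value = np.tile(np.eye(N_CLASSES, dtype=DTYPE), (m, 1)) / m
        self.head.b.value = np.zeros(N_CLASSES, dtype=DTYPE)

    # -- model protocol -----------------------------------------------------

    def parameters(self):
        return [p for s in self.submodels for p in s.parameters()] + self.head.parameters()

    def inputs(self, records) -> list[np.ndarray]:
        return [m.astype(DTYPE) for m in assemble(records, self.strategy, "per_modality")]

    def _forward(self, xs, training: bool):
        if len(xs) != len(self.submodels):
            raise ValueError(f"expected {len(self.submodels)} modality inputs, got {len(xs)}")
        probs = [softmax(sm.forward_logits(x, training)) for sm, x in zip(self.submodels, xs)]
        fused_in = np.concatenate(probs, axis=1).astype(DTYPE)
        u = self.head.forward(fused_in, training)
        return softmax(u), probs

    def forward_output(self, xs) -> HighFusionOutput:
        """Inference on a single sample (vectors) or batch; returns all heads."""
        xs = [np.asarray(x, dtype=DTYPE) for x in xs]
        single = xs[0].ndim == 1
        if single:
            xs = [x[None, :] for x in xs]
        y_F, probs = self._forward(xs, training=False)
        if single:
            return HighFusionOutput(y_F=y_F[0], y_subs=[p[0] for p in probs])
        return HighFusionOutput(y_F=y_F, y_subs=probs)

    def loss_and_grads(self, xs, y) -> float:
        n = xs[0].shape[0]
        y = np.asarray(y)
        y_F, probs = self._forward(xs, training=True)
        idx = np.arange(n)
        loss = -np.mean(np.log(np.maximum(y_F[idx, y], _EPS)))
        for p in probs:
            loss += -np.mean(np.log(np.maximum(p[idx, y], _EPS)))

        onehot = np.zeros_like(y_F)
        onehot[idx, y] = 1.0
        du = ((y_F - onehot) / n).astype(DTYPE)
        dfused = self.head.backward(du)
        for i, (sm, p) in enumerate(zip(self.submodels, probs)):
            dp = dfused[:, i * N_CLASSES : (i + 1) * N_CLASSES]
            # gradient into the submodel logits: the head path through the
            # softmax Jacobian plus this submodel's own cross-entropy term
            dz = nn.softmax_vjp(p, dp) + (p - onehot) / n
            sm._all.backward(dz.astype(DTYPE))
        return float(loss)

    def predict_proba(self, xs, batch: int = 256) -> np.ndarray:
        xs = [np.ascontiguousarray(x, dtype=DTYPE) for x in xs]
        n = xs[0].shape[0]
        out = []
        for i in range(0, n, batch):
            y_F, _ = self._forward([x[i : i + batch] for x in xs], training=False)
            out.append(y_F)
        return np.concatenate(out, axis=0)

    def recalibrate(self, xs, batch: int = 1024) -> None:
        """Replace BN running statistics with population moments over ``xs``."""
        layers = [l for sm in self.submodels for l in sm._all.layers]
        _recalibrate_layers(layers, lambda sl: self._forward(sl, True), xs, batch)

    def get_state(self):
        state = []
        for sm in self.submodels:
            state.extend(sm.get_state())
        state.extend(_collect_state([self.head]))
        return state

    def set_state(self, state):
        it = list(state)
        pos = 0
        for sm in self.submodels:
            k = len(sm.get_state())
            sm.set_state(it[pos : pos + k])
            pos += k
        _restore_state([self.head], it[pos:])


# ---------------------------------------------------------------------------
# two-stage baselines


class TwoStageMiddleModel:
    """Stage-2 classifier over frozen stage-1 deep-feature extractors.

    ``inputs`` maps records to the concatenated 128-d penultimate features
    of the (already trained, frozen) extractors; only the stage-2 CNN-S
    parameters are exposed for training, so stage-1 parameters cannot
    change.
    """

    def __init__(self, extractors: dict[str, CNNSModel], seed: int = 0,
                 cfg_overrides: dict | None = None):
        self.extractors = dict(extractors)
        self.modalities = tuple(self.extractors)
        feat = next(iter(self.extractors.values())).cfg.dense_sizes[1]
        width = feat * len(self.extractors)
        self.classifier = CNNSModel(_branch_cfg(width, cfg_overrides), seed=seed)
        self.strategy = None

    def parameters(self):
        return self.classifier.parameters()

    def inputs(self, records) -> np.ndarray:
        feats = []
        for mod in self.modalities:
            ext = self.extractors[mod]
            X = assemble(records, SINGLE_MODALITY_STRATEGIES[mod], "stacked").astype(DTYPE)
            feats.append(ext.penultimate_features(X))
        return np.concatenate(feats, axis=1)

    def loss_and_grads(self, x, y):
        return self.classifier.loss_and_grads(x, y)

    def predict_proba(self, x, batch: int = 256):
        return self.classifier.predict_proba(x, batch)

    def recalibrate(self, x, batch: int = 1024):
        self.classifier.recalibrate(x, batch)

    def get_state(self):
        return self.classifier.get_state()

    def set_state(self, state):
        self.classifier.set_state(state)


def two_stage_middle(
    split,
    strategy: FusionStrategy,
    train_cfg,
    seed: int = 0,
    modality_lengths: dict[str, int] | None = None,
    cfg_overrides: dict | None = None,
):
    """Two-stage feature-level fusion: m extractors + 1 fused classifier.

    Stage 1 trains an independent CNN-S per selected modality; stage 2
    freezes them, extracts and concatenates their 128-d features and
    trains a fresh CNN-S on the fused feature table.  Trains exactly
    m + 1 models.  Returns ``(model, histories)`` where model is the
    trained :class:`TwoStageMiddleModel`.
    """
    from .train import train  # deferred: train imports this module's types

    lengths = modality_lengths or DEFAULT_MODALITY_LENGTHS
    seeds = np.random.SeedSequence(seed).spawn(strategy.n_modalities + 1)
    extractors = {}
    histories = {}
    for mod, s in zip(strategy.modalities, seeds[:-1]):
        model = CNNSModel(
            _branch_cfg(lengths[mod], cfg_overrides),
            seed=s,
            strategy=SINGLE_MODALITY_STRATEGIES[mod],
        )
        result = train(model, split, train_cfg)
        extractors[mod] = result.model
        histories[mod] = result.history
    fused = TwoStageMiddleModel(extractors, seed=seeds[-1], cfg_overrides=cfg_overrides)
    result = train(fused, split, train_cfg)
    histories["fused"] = result.history
    return result.model, histories


def two_stage_high(prob_vectors) -> tuple[int, np.ndarray]:
    """Decision by averaging probability vectors: argmax of the mean.

    Ties break toward the smallest class index.  Returns
    ``(class_index, mean_vector)``.
    """
    vecs = [np.asarray(v, dtype=float) for v in prob_vectors]
    if not vecs:
        raise ValueError("need at least one probability vector")
    mean = np.mean(vecs, axis=0)
    return int(np.argmax(mean)), mean
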