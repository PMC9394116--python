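"""Low/middle/high fusion architectures and the two-stage baselines."""

import numpy as np
import pytest

from spectrafuse import SyntheticConfig, generate_dataset, stratified_split
from spectrafuse.data import FUSION_STRATEGIES
from spectrafuse.fusion import (
    HighFusionModel,
    HighFusionOutput,
    MiddleFusionModel,
    joint_loss,
    low_level_model,
    two_stage_high,
    two_stage_middle,
)
from spectrafuse.models import CNNSModel
from spectrafuse.train import TrainConfig


TINY = dict(conv_channels=(2, 3, 3), dense_sizes=(16, 8, 5), attention_hidden=4)
TINY_LENGTHS = {"l_visnir": 24, "s_visnir": 24, "l_fkc": 16, "s_fkc": 16}


class TestLowLevel:
    def test_fusion5_input_length(self):
        m = low_level_model(FUSION_STRATEGIES[5], seed=0, cfg_overrides=dict(conv_channels=(1, 1, 1), dense_sizes=(8, 4, 5), attention_hidden=2))
        assert m.cfg.input_length == 1364

    def test_fusion1_input_length(self):
        m = low_level_model(FUSION_STRATEGIES[1], seed=0, cfg_overrides=dict(conv_channels=(1, 1, 1), dense_sizes=(8, 4, 5), attention_hidden=2))
        assert m.cfg.input_length == 792

    def test_forward_on_simplex(self, rng):
        m = low_level_model(FUSION_STRATEGIES[2], TINY_LENGTHS, seed=0, cfg_overrides=TINY)
        p = m.predict_proba(rng.normal(size=(4, 32)))
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestMiddleFusion:
    @pytest.fixture()
    def model(self):
        return MiddleFusionModel(FUSION_STRATEGIES[5], TINY_LENGTHS, seed=0, cfg_overrides=TINY)

    def test_output_on_simplex(self, model, rng):
        xs = [rng.normal(size=(3, TINY_LENGTHS[m])) for m in model.strategy.modalities]
        p = model.predict_proba(xs)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_branch_count_mismatch_rejected(self, model, rng):
        with pytest.raises(ValueError):
            model.predict_proba([rng.normal(size=(3, 24))])

    def test_single_modality_rejected(self):
        from spectrafuse.data import SINGLE_MODALITY_STRATEGIES

        with pytest.raises(ValueError):
            MiddleFusionModel(SINGLE_MODALITY_STRATEGIES["l_fkc"], TINY_LENGTHS)

    def test_identity_branch_weights_concatenate_relu_features(self):
        """With identity branch maps, the fused vector is the concatenation
        of the rectified branch features."""
        model = MiddleFusionModel(
            FUSION_STRATEGIES[1],
            TINY_LENGTHS,
            seed=0,
            cfg_overrides=TINY,
        )
        feat = model.feature_width
        for wmap in model.branch_maps:
            wmap.W.value = np.eye(feat, dtype=np.float32)
            wmap.b.value = np.zeros(feat, dtype=np.float32)
        rng = np.random.default_rng(0)
        xs = [rng.normal(size=(2, 24)).astype(np.float32) for _ in range(2)]
        f1 = model.trunks[0].forward(xs[0], False)
        f2 = model.trunks[1].forward(xs[1], False)
        expected = np.concatenate([np.maximum(f1, 0), np.maximum(f2, 0)], axis=1)
        hs = []
        for x, trunk, wmap, relu in zip(xs, model.trunks, model.branch_maps, model.branch_relus):
            hs.append(relu.forward(wmap.forward(trunk.forward(x, False), False), False))
        np.testing.assert_allclose(np.concatenate(hs, axis=1), expected, atol=1e-6)

    def test_scalar_weight_mode(self, rng):
        model = MiddleFusionModel(
            FUSION_STRATEGIES[2], TINY_LENGTHS, seed=0, cfg_overrides=TINY,
            scalar_weights=True,
        )
        xs = [rng.normal(size=(3, 16)) for _ in range(2)]
        p = model.predict_proba(xs)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestHighFusion:
    @pytest.fixture()
    def model(self):
        return HighFusionModel(FUSION_STRATEGIES[5], TINY_LENGTHS, seed=0, cfg_overrides=TINY)

    def test_fused_input_width_is_5m(self, model):
        assert model.head.W.value.shape == (20, 5)

    def test_output_heads_on_simplex(self, model, rng):
        xs = [rng.normal(size=(TINY_LENGTHS[m],)) for m in model.strategy.modalities]
        out = model.forward_output(xs)
        assert isinstance(out, HighFusionOutput)
        assert len(out.y_subs) == 4
        for v in [out.y_F] + out.y_subs:
            assert v.shape == (5,)
            assert (v >= 0).all()
            assert v.sum() == pytest.approx(1.0, abs=1e-6)

    def test_head_selecting_one_submodel_reproduces_it(self, rng):
        """Head weights that copy submodel 1's probability block (scaled)
        make the fused argmax equal submodel 1's argmax."""
        model = HighFusionModel(FUSION_STRATEGIES[5], TINY_LENGTHS, seed=2, cfg_overrides=TINY)
        W = np.zeros((20, 5), dtype=np.float32)
        W[0:5, :] = 20.0 * np.eye(5)  # monotone map of submodel 1's probs
        model.head.W.value = W
        model.head.b.value = np.zeros(5, dtype=np.float32)
        xs = [rng.normal(size=(6, TINY_LENGTHS[m])) for m in model.strategy.modalities]
        out = model.forward_output(xs)
        np.testing.assert_array_equal(
            out.y_F.argmax(axis=1), out.y_subs[0].argmax(axis=1)
        )


class TestJointLoss:
    def _onehot(self, k):
        v = np.zeros(5)
        v[k] = 1.0
        return v

    def test_zero_when_all_heads_correct(self):
        out = HighFusionOutput(y_F=self._onehot(2), y_subs=[self._onehot(2)] * 4)
        assert joint_loss(out, 2) == pytest.approx(0.0, abs=1e-9)

    def test_all_uniform_gives_five_ln_five(self):
        u = np.full(5, 0.2)
        out = HighFusionOutput(y_F=u, y_subs=[u] * 4)
        assert joint_loss(out, 0) == pytest.approx(5 * np.log(5), rel=1e-9)

    def test_one_uniform_submodel_gives_ln_five(self):
        u = np.full(5, 0.2)
        out = HighFusionOutput(
            y_F=self._onehot(1),
            y_subs=[self._onehot(1), self._onehot(1), self._onehot(1), u],
        )
        assert joint_loss(out, 1) == pytest.approx(np.log(5), rel=1e-9)

    def test_lower_bounded_by_fused_term(self, rng):
        for _ in range(10):
            probs = [rng.dirichlet(np.ones(5)) for _ in range(5)]
            out = HighFusionOutput(y_F=probs[0], y_subs=probs[1:])
            y = int(rng.integers(5))
            assert joint_loss(out, y) >= -np.log(max(probs[0][y], 1e-12)) - 1e-12

    def test_zero_probability_floored(self):
        v = np.zeros(5)
        v[0] = 1.0
        out = HighFusionOutput(y_F=v, y_subs=[v] * 4)
        loss = joint_loss(out, 1)  # true class has probability 0 everywhere
        assert np.isfinite(loss)


class TestTwoStageHigh:
    def test_unanimous_vectors(self):
        v = np.array([1.0, 0, 0, 0, 0])
        cls, mean = two_stage_high([v] * 4)
        assert cls == 0
        np.testing.assert_array_equal(mean, v)

    def test_printed_toy_vectors(self):
        vecs = [
            [0.6, 0.4, 0, 0, 0],
            [0.2, 0.8, 0, 0, 0],
            [0.5, 0.5, 0, 0, 0],
            [0.1, 0.9, 0, 0, 0],
        ]
        cls, mean = two_stage_high(vecs)
        np.testing.assert_allclose(mean, [0.35, 0.65, 0, 0, 0])
        assert cls == 1

    def test_tie_breaks_to_smallest_index(self):
        vecs = [[0.5, 0.5, 0, 0, 0], [0.5, 0.5, 0, 0, 0]]
        cls, _ = two_stage_high(vecs)
        assert cls == 0

    def test_mean_stays_on_simplex(self, rng):
        vecs = [rng.dirichlet(np.ones(5)) for _ in range(4)]
        _, mean = two_stage_high(vecs)
        assert (mean >= 0).all()
        assert mean.sum() == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            two_stage_high([])


class TestTwoStageMiddle:
    def test_structure_and_frozen_extractors(self):
        cfg = SyntheticConfig(
            n_per_class=(8,) * 5, n_bands=24, n_timepoints=16,
            noise_sd=0.01, seed=0,
        )
        recs = generate_dataset(cfg)
        split = stratified_split(recs, seed=0)
        tc = TrainConfig(epochs=2, batch_size=16, seed=0)
        lengths = {"l_visnir": 24, "s_visnir": 24, "l_fkc": 16, "s_fkc": 16}
        model, histories = two_stage_middle(
            split, FUSION_STRATEGIES[5], tc, seed=0,
            modality_lengths=lengths, cfg_overrides=TINY,
        )
        # trains exactly m + 1 = 5 models
        assert len(histories) == 5
        # stage-2 classifier consumes the concatenated deep features
        feat = next(iter(model.extractors.values())).cfg.dense_sizes[1]
        assert model.classifier.cfg.input_length == feat * 4
        # frozen extractors: stage-2 training left stage-1 parameters intact
        states_before = {m: e.get_state() for m, e in model.extractors.items()}
        X = model.inputs(split.train)
        assert X.shape[1] == feat * 4
        for m, e in model.extractors.items():
            for a, b in zip(states_before[m], e.get_state()):
                np.testing.assert_array_equal(a, b)

    def test_default_feature_width_gives_512_for_fusion5(self):
        # with the standard 128-d deep feature, 4 branches fuse to width 512
        from spectrafuse.fusion import DEFAULT_MODALITY_LENGTHS, TwoStageMiddleModel
        from spectrafuse.models import CNNSConfig

        slim = dict(conv_channels=(1, 1, 1), dense_sizes=(8, 128, 5), attention_hidden=2)
        extractors = {
            m: CNNSModel(CNNSConfig(input_length=n, **slim), seed=0)
            for m, n in DEFAULT_MODALITY_LENGTHS.items()
        }
        ts = TwoStageMiddleModel(extractors, seed=0, cfg_overrides=slim)
        assert ts.classifier.cfg.input_length == 512
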