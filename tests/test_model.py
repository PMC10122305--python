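import math

import numpy as np
import pytest

from psgrn import (
    ModelConfig,
    PSGRNModel,
    bce_loss,
    build_variant,
    encode_branch,
    merge_branches,
    predict_pair,
    spatial_module,
)
from psgrn.datasets_io import ValidationError
from psgrn.feature_extraction import FeatureMatrix
from psgrn.nn import GRU
from psgrn.nn.spatial import DenseNetModule, ValidationError as SpatialError
from psgrn.nn.core import DTYPE

RNG = np.random.default_rng(0)


def gru_step_oracle(Wx, Wh, b, h_prev, x):
    """One GRU step evaluated directly from the gate equations."""
    H = h_prev.size

    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    pre = x @ Wx + b
    r = sig(pre[:H] + h_prev @ Wh[:, :H])
    z = sig(pre[H : 2 * H] + h_prev @ Wh[:, H : 2 * H])
    c = np.tanh(pre[2 * H :] + (r * h_prev) @ Wh[:, 2 * H :])
    return (1 - z) * h_prev + z * c


class TestGRUBranch:
    def test_single_step_matches_hand_evaluation(self):
        # scalar hidden state with hand-set weights, one time step
        gru = GRU(np.random.default_rng(1), in_dim=1, hidden_dim=1)
        gru.Wx.value[...] = 0.5
        gru.Wh.value[...] = [[0.2, -0.3, 0.7]]
        gru.b.value[...] = [0.1, -0.1, 0.05]
        x = 0.8
        # by calculator: h0 = 0, r = sigma(0.5*0.8+0.1), z = sigma(0.5*0.8-0.1),
        # c = tanh(0.5*0.8+0.05), h1 = z*c
        r = 1 / (1 + math.exp(-0.5))
        z = 1 / (1 + math.exp(-0.3))
        c = math.tanh(0.45)
        expected = z * c
        out = gru.forward(np.array([[[x]]], dtype=DTYPE))
        assert out[0, 0, 0] == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_multi_step_matches_equation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        gru = GRU(rng, in_dim=3, hidden_dim=4)
        x = rng.normal(size=(1, 6, 3)).astype(DTYPE)
        out = gru.forward(x)
        h = np.zeros(4)
        for t in range(6):
            h = gru_step_oracle(
                gru.Wx.value.astype(float),
                gru.Wh.value.astype(float),
                gru.b.value.astype(float),
                h,
                x[0, t].astype(float),
            )
            np.testing.assert_allclose(out[0, t], h, atol=1e-5)

    def test_zero_input_is_fixed_point(self):
        gru = GRU(np.random.default_rng(2), in_dim=3, hidden_dim=5)
        gru.b.value[...] = 0
        out = gru.forward(np.zeros((2, 7, 3), dtype=DTYPE))
        np.testing.assert_array_equal(out, 0)

    def test_hidden_states_bounded(self):
        # h_t is a convex combination of h_{t-1} and a tanh candidate
        gru = GRU(np.random.default_rng(3), in_dim=4, hidden_dim=6)
        x = 10 * np.random.default_rng(4).normal(size=(3, 20, 4)).astype(DTYPE)
        out = gru.forward(x)
        assert np.all(out >= -1) and np.all(out <= 1)

    def test_output_shape_contract(self):
        gru = GRU(np.random.default_rng(5), in_dim=32, hidden_dim=128)
        out = gru.forward(np.zeros((1, 74, 32), dtype=DTYPE))
        assert out.shape == (1, 74, 128)


SMALL = ModelConfig(
    tl=8,
    hidden_dim=8,
    dense_blocks=2,
    layers_per_block=2,
    growth_rate=4,
    num_init_features=4,
    seed=0,
)


def _features(rng, n=2):
    return [rng.normal(size=(31, 8)).astype(DTYPE) for _ in range(n)]


class TestPairModel:
    def test_branches_have_independent_parameters(self):
        model = PSGRNModel(SMALL)
        model.build(31, 8)
        x_tf, x_tg = _features(np.random.default_rng(1))
        before = model.forward(x_tf[None], x_tg[None])[0]
        # perturbing the TF branch must leave the target encoding unchanged
        h_tg_before = model.target_branch.forward(x_tg[None]).copy()
        model.tf_branch.Wx.value += 0.5
        h_tg_after = model.target_branch.forward(x_tg[None])
        np.testing.assert_array_equal(h_tg_before, h_tg_after)
        after = model.forward(x_tf[None], x_tg[None])[0]
        assert before != after  # but the joint score does change

    def test_scores_strictly_inside_unit_interval(self):
        model = PSGRNModel(SMALL)
        rng = np.random.default_rng(2)
        x_tf, x_tg = _features(rng)
        score = model.forward(x_tf[None], x_tg[None])[0]
        assert 0.0 < score < 1.0

    def test_evaluation_mode_is_deterministic(self):
        model = PSGRNModel(SMALL)
        rng = np.random.default_rng(3)
        x_tf, x_tg = _features(rng)
        model.forward(x_tf[None], x_tg[None])
        model.set_training(False)
        s1 = model.forward(x_tf[None], x_tg[None])[0]
        s2 = model.forward(x_tf[None], x_tg[None])[0]
        assert s1 == s2

    def test_direction_sensitivity(self):
        model = PSGRNModel(SMALL)
        rng = np.random.default_rng(4)
        x_tf, x_tg = _features(rng)
        model.forward(x_tf[None], x_tg[None])
        model.set_training(False)
        fwd = model.forward(x_tf[None], x_tg[None])[0]
        rev = model.forward(x_tg[None], x_tf[None])[0]
        assert fwd != rev

    def test_predict_pair_wraps_score(self):
        model = PSGRNModel(SMALL)
        model.build(31, 8)
        model.set_training(False)
        rng = np.random.default_rng(5)
        fm_tf = FeatureMatrix(rng.normal(size=(31, 8)), tl=8, gene_id="tfA")
        fm_tg = FeatureMatrix(rng.normal(size=(31, 8)), tl=8, gene_id="g9")
        ps = predict_pair(model, fm_tf, fm_tg)
        assert ps.tf_id == "tfA" and ps.gene_id == "g9"
        assert 0 < ps.score < 1

    def test_unbuilt_model_predict_raises(self):
        model = PSGRNModel(SMALL)
        fm = FeatureMatrix(np.zeros((31, 8)), tl=8)
        with pytest.raises(RuntimeError, match="not built"):
            predict_pair(model, fm, fm)

    def test_shape_mismatch_rejected(self):
        model = PSGRNModel(SMALL)
        model.build(31, 8)
        with pytest.raises(ValidationError):
            model.forward(np.zeros((1, 30, 8)), np.zeros((1, 30, 8)))

    def test_checkpoint_round_trip(self, tmp_path):
        model = PSGRNModel(SMALL)
        rng = np.random.default_rng(6)
        x_tf, x_tg = _features(rng)
        model.forward(x_tf[None], x_tg[None])
        model.set_training(False)
        score = model.forward(x_tf[None], x_tg[None])[0]
        path = tmp_path / "model.npz"
        model.save(path)
        back = PSGRNModel.load(path)
        assert back.forward(x_tf[None], x_tg[None])[0] == pytest.approx(score, abs=1e-7)


class TestModuleSurface:
    def test_encode_branch_shape_and_independence(self):
        model = PSGRNModel(SMALL)
        model.build(31, 8)
        x = np.random.default_rng(11).normal(size=(31, 8))
        h_tf = encode_branch(model, x, "tf_branch")
        h_tg = encode_branch(model, x, "target_branch")
        assert h_tf.shape == (31, 8)
        # unshared weights: the same input encodes differently per branch
        assert not np.allclose(h_tf, h_tg)
        with pytest.raises(ValidationError):
            encode_branch(model, x, "middle_branch")

    def test_merge_branches_concat_and_multiply(self):
        rng = np.random.default_rng(12)
        h_tf = rng.normal(size=(5, 4))
        h_tg = rng.normal(size=(5, 4))
        merged = merge_branches(h_tf, h_tg, "concat_rows")
        assert merged.shape == (10, 4)
        np.testing.assert_array_equal(merged[:5], h_tf)  # TF rows first
        corr = merge_branches(h_tf, h_tf, "multiply")
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)  # symmetric
        with pytest.raises(ValidationError):
            merge_branches(h_tf, h_tg[:3], "concat_rows")

    def test_spatial_module_returns_fixed_length_vector(self):
        model = PSGRNModel(SMALL)
        model.build(31, 8)
        model.set_training(False)
        rng = np.random.default_rng(13)
        a = spatial_module(model, rng.normal(size=(62, 8)))
        b = spatial_module(model, rng.normal(size=(62, 8)))
        assert a.shape == b.shape == (model.spatial.out_dim,)


class TestMerge:
    def test_concat_rows_shape_and_order(self):
        cfg = ModelConfig(
            tl=8, hidden_dim=8, spatial_type="none", merge="concat_rows", seed=0
        )
        model = PSGRNModel(cfg)
        rng = np.random.default_rng(7)
        x_tf, x_tg = _features(rng)
        model.forward(x_tf[None], x_tg[None])
        model.set_training(False)
        fwd = model.forward(x_tf[None], x_tg[None])[0]
        swapped = model.forward(x_tg[None], x_tf[None])[0]
        assert fwd != swapped  # TF rows come first

    def test_multiply_symmetric_for_identical_inputs(self):
        cfg = build_variant("FM-GRU", SMALL)
        model = PSGRNModel(cfg)
        rng = np.random.default_rng(8)
        x = rng.normal(size=(1, 31, 8)).astype(DTYPE)
        model.forward(x, x)
        h_tf = model.tf_branch.forward(x)
        h_tg = model.target_branch.forward(x)
        corr = np.einsum("bth,bsh->bts", h_tf, h_tf) / cfg.hidden_dim
        np.testing.assert_allclose(corr[0], corr[0].T, atol=1e-6)


class TestSpatialModule:
    def test_dense_connectivity_bookkeeping(self):
        mod = DenseNetModule(
            np.random.default_rng(0), n_blocks=1, layers_per_block=4, growth=3, num_init=5
        )
        block = mod.blocks[0]
        # layer k receives input_channels + (k-1) * growth_rate channels
        assert block.layer_input_channels == [5, 8, 11, 14]

    def test_output_length_matches_channel_count(self):
        mod = DenseNetModule(
            np.random.default_rng(0),
            n_blocks=3,
            layers_per_block=4,
            growth=12,
            num_init=16,
            compression=0.5,
        )
        # block1: 16+48=64 -> transition 32; block2: 32+48=80 -> 40; block3: 88
        assert mod.out_dim == 88
        x = np.random.default_rng(1).normal(size=(2, 1, 148, 128)).astype(DTYPE)
        out = mod.forward(x)
        assert out.shape == (2, 88)

    def test_output_length_independent_of_input_size(self):
        mod = DenseNetModule(
            np.random.default_rng(0), n_blocks=2, layers_per_block=2, growth=4, num_init=4
        )
        rng = np.random.default_rng(2)
        a = mod.forward(rng.normal(size=(1, 1, 62, 8)).astype(DTYPE))
        b = mod.forward(rng.normal(size=(1, 1, 148, 32)).astype(DTYPE))
        assert a.shape[1] == b.shape[1]

    def test_too_small_input_names_minimum(self):
        mod = DenseNetModule(
            np.random.default_rng(0), n_blocks=2, layers_per_block=2, growth=4, num_init=4
        )
        with pytest.raises(SpatialError, match=str(mod.min_input)):
            mod.forward(np.zeros((1, 1, 4, 4), dtype=DTYPE))


class TestBCELoss:
    def test_perfect_prediction_near_zero(self):
        assert bce_loss([1], [1 - 1e-7]) == pytest.approx(0.0, abs=1e-6)

    def test_uninformative_prediction_is_ln2(self):
        assert bce_loss([1, 0], [0.5, 0.5]) == pytest.approx(math.log(2), abs=1e-12)

    def test_label_symmetry(self):
        assert bce_loss([0], [0.5]) == bce_loss([1], [0.5])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            bce_loss([1, 0], [0.5])

    def test_extreme_probs_clamped_finite(self):
        assert np.isfinite(bce_loss([1, 0], [0.0, 1.0]))


class TestVariants:
    def test_default_is_gru_densenet_sigmoid(self):
        cfg = build_variant("PSGRN")
        assert (cfg.branch_type, cfg.spatial_type, cfg.head) == (
            "gru",
            "densenet",
            "sigmoid",
        )

    @pytest.mark.parametrize(
        "name,field,value",
        [
            ("FM-DN", "branch_type", "none"),
            ("RNN-DN", "branch_type", "rnn"),
            ("LSTM-DN", "branch_type", "lstm"),
            ("GRU-VGG", "spatial_type", "vgg"),
            ("GRU-RN", "spatial_type", "resnet"),
            ("PS-SM", "head", "softmax"),
        ],
    )
    def test_variant_table(self, name, field, value):
        assert getattr(build_variant(name), field) == value

    def test_softmax_variant_differs_only_in_head(self):
        a, b = build_variant("PSGRN"), build_variant("PS-SM")
        assert a.branch_type == b.branch_type and a.spatial_type == b.spatial_type
        assert (a.head, b.head) == ("sigmoid", "softmax")

    def test_fm_gru_removes_spatial_and_multiplies(self):
        cfg = build_variant("FM-GRU")
        assert (cfg.spatial_type, cfg.merge) == ("none", "multiply")

    def test_unknown_name_lists_valid_ones(self):
        with pytest.raises(ValidationError, match="PSGRN"):
            build_variant("GRU-Transformer")

    def test_invalid_config_combination_rejected(self):
        with pytest.raises(ValidationError):
            ModelConfig(merge="multiply", spatial_type="densenet")

    @pytest.mark.parametrize("name", ["FM-DN", "FM-GRU", "GRU-VGG", "GRU-RN", "PS-SM"])
    def test_each_variant_scores_in_unit_interval(self, name):
        cfg = build_variant(name, SMALL)
        model = PSGRNModel(cfg)
        rng = np.random.default_rng(9)
        x_tf, x_tg = _features(rng)
        score = model.forward(x_tf[None], x_tg[None])[0]
        assert 0.0 < score < 1.0
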