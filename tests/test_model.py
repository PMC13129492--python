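"""Model core: LSTM recursion, convolution, head, loss, gradients, serialization."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fedherd as fh
from fedherd.model import PARAM_HEADER_BYTES, ParamVector, params_from_bytes, params_to_bytes


def zero_params(cfg: fh.ModelConfig) -> ParamVector:
    return fh.init_params(cfg).zeros_like()


class TestInitParams:
    def test_four_gate_parameter_count(self):
        # hidden 4, 10 features, no CNN, head directly on h_T:
        # 4 gates × (4×(10+4) weights + 4 biases) + (4 head weights + 1 bias)
        cfg = fh.ModelConfig(n_features=10, window_len=4, cnn_enabled=False,
                             lstm_hidden=4, dense_hidden=0)
        assert fh.init_params(cfg).n_params == 4 * (4 * (10 + 4) + 4) + (4 + 1) == 245

    def test_seeded_determinism(self):
        cfg = fh.ModelConfig(seed=5)
        assert fh.init_params(cfg).equal(fh.init_params(fh.ModelConfig(seed=5)))
        assert not fh.init_params(cfg).equal(fh.init_params(fh.ModelConfig(seed=6)))

    def test_biases_zero_weights_bounded(self, tiny_model_cfg):
        params = fh.init_params(tiny_model_cfg)
        for name, arr in params.items():
            if name.split(".")[-1].startswith("b"):
                assert (arr == 0).all()
            else:
                assert (np.abs(arr) <= tiny_model_cfg.init_scale).all()

    def test_budget_exceeded_raises(self):
        cfg = fh.ModelConfig(max_param_bytes=1000)
        with pytest.raises(fh.ConfigError, match="budget"):
            fh.init_params(cfg)

    def test_shipped_default_within_one_to_two_mb(self):
        params = fh.init_params(fh.ModelConfig())
        size = fh.param_size_bytes(params)
        assert 1 * 2**20 <= size <= 2 * 2**20


class TestLstmStep:
    def test_zero_parameter_closed_form(self):
        cfg = fh.ModelConfig(n_features=3, window_len=2, cnn_enabled=False,
                             lstm_hidden=4, dense_hidden=0)
        params = zero_params(cfg)
        c_prev = np.array([0.4, -1.0, 2.0, 0.0])
        state = fh.lstm_step(np.ones(3), fh.CellState(h=np.zeros(4), c=c_prev), params)
        np.testing.assert_allclose(state.c, 0.5 * c_prev, rtol=0, atol=0)
        np.testing.assert_allclose(state.h, 0.5 * np.tanh(0.5 * c_prev), rtol=0, atol=0)

    def test_scalar_oracle_transcription(self):
        # independent scalar transcription of the gate recursion
        w = 0.1
        z = [0.0, 1.0]  # [h_prev, x]
        a = w * z[0] + w * z[1]
        sig = lambda v: 1.0 / (1.0 + math.exp(-v))
        i = f = o = sig(a)
        g = math.tanh(a)
        c_expect = f * 0.0 + i * g
        h_expect = o * math.tanh(c_expect)

        cfg = fh.ModelConfig(n_features=1, window_len=1, cnn_enabled=False,
                             lstm_hidden=1, dense_hidden=0)
        params = zero_params(cfg)
        for gate in "ifoc":
            params[f"lstm.w_{gate}"] = np.full((1, 2), w)
        state = fh.lstm_step(np.array([1.0]), fh.CellState(h=np.zeros(1), c=np.zeros(1)), params)
        assert state.c[0] == pytest.approx(c_expect, abs=1e-12)
        assert state.h[0] == pytest.approx(h_expect, abs=1e-12)

    def test_zero_carry_ignores_forget_gate(self):
        cfg = fh.ModelConfig(n_features=2, window_len=1, cnn_enabled=False,
                             lstm_hidden=3, dense_hidden=0, seed=1, init_scale=0.5)
        params = fh.init_params(cfg)
        x = np.array([0.3, -0.2])
        s1 = fh.lstm_step(x, fh.CellState(h=np.zeros(3), c=np.zeros(3)), params)
        altered = params.copy()
        altered["lstm.w_f"] = altered["lstm.w_f"] + 10.0
        s2 = fh.lstm_step(x, fh.CellState(h=np.zeros(3), c=np.zeros(3)), altered)
        np.testing.assert_array_equal(s1.c, s2.c)

    def test_hidden_state_bounded(self):
        cfg = fh.ModelConfig(n_features=2, window_len=1, cnn_enabled=False,
                             lstm_hidden=5, dense_hidden=0, seed=2, init_scale=3.0)
        params = fh.init_params(cfg)
        state = fh.CellState(h=np.zeros(5), c=np.zeros(5))
        for _ in range(20):
            state = fh.lstm_step(np.array([5.0, -5.0]), state, params)
        assert (np.abs(state.h) < 1.0).all()

    def test_shape_mismatch(self):
        cfg = fh.ModelConfig(n_features=3, window_len=1, cnn_enabled=False,
                             lstm_hidden=4, dense_hidden=0)
        params = zero_params(cfg)
        with pytest.raises(fh.StructuralError):
            fh.lstm_step(np.ones(5), fh.CellState(h=np.zeros(4), c=np.zeros(4)), params)


class TestCnnExtract:
    def _cfg(self, **kw):
        base = dict(n_features=1, window_len=4, cnn_enabled=True,
                    cnn_channels=1, cnn_kernel=3, lstm_hidden=2, dense_hidden=0)
        base.update(kw)
        return fh.ModelConfig(**base)

    def test_zero_input_zero_bias(self):
        cfg = self._cfg()
        params = fh.init_params(cfg)
        out = fh.cnn_extract(np.zeros((4, 1)), params, cfg)
        assert out.shape == (2, 1)
        np.testing.assert_array_equal(out, 0.0)

    def test_hand_convolution(self):
        cfg = self._cfg()
        params = zero_params(cfg)
        params["cnn.w"] = np.array([1.0, 0.0, -1.0]).reshape(1, 3, 1)
        window = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1)
        # valid conv: [1-3, 2-4] = [-2, -2]; ReLU clamps to [0, 0]
        out = fh.cnn_extract(window, params, cfg)
        np.testing.assert_array_equal(out[:, 0], [0.0, 0.0])
        params["cnn.w"] = -params["cnn.w"]
        out = fh.cnn_extract(window, params, cfg)
        np.testing.assert_array_equal(out[:, 0], [2.0, 2.0])

    def test_large_negative_bias_clamps(self):
        cfg = self._cfg()
        params = fh.init_params(cfg)
        params["cnn.b"] = np.array([-1e6])
        out = fh.cnn_extract(np.random.default_rng(0).random((4, 1)), params, cfg)
        np.testing.assert_array_equal(out, 0.0)

    def test_kernel_longer_than_window(self):
        cfg = self._cfg()
        params = fh.init_params(cfg)
        with pytest.raises(fh.ConfigError):
            fh.cnn_extract(np.zeros((2, 1)), params, cfg)
        with pytest.raises(fh.ConfigError):
            fh.ModelConfig(window_len=2, cnn_kernel=3).validate()


class TestForward:
    def test_zero_params_give_half(self, tiny_model_cfg):
        params = zero_params(tiny_model_cfg)
        w = np.random.default_rng(1).random((8, 8))
        assert fh.forward(w, params, tiny_model_cfg) == 0.5

    def test_head_bias_saturation(self, tiny_model_cfg):
        params = zero_params(tiny_model_cfg)
        params["head.b"] = np.array([30.0])
        w = np.random.default_rng(2).random((8, 8))
        assert fh.forward(w, params, tiny_model_cfg) > 0.999999

    def test_straight_line_reimplementation(self):
        # tiny config, fixed weights: compare against an independent
        # start-to-finish transcription of the forward pass
        cfg = fh.ModelConfig(n_features=2, window_len=3, cnn_enabled=False,
                             lstm_hidden=2, dense_hidden=0)
        params = zero_params(cfg)
        params["lstm.w_i"] = np.array([[0.1, -0.2, 0.3, 0.0], [0.2, 0.1, -0.1, 0.4]])
        params["lstm.w_f"] = np.array([[-0.3, 0.2, 0.1, 0.1], [0.0, 0.3, 0.2, -0.2]])
        params["lstm.w_o"] = np.array([[0.2, 0.0, -0.3, 0.2], [0.1, -0.1, 0.0, 0.3]])
        params["lstm.w_c"] = np.array([[0.4, 0.1, 0.2, -0.1], [-0.2, 0.2, 0.1, 0.0]])
        params["lstm.b_i"] = np.array([0.01, -0.02])
        params["head.w"] = np.array([0.7, -0.5])
        params["head.b"] = np.array([0.1])
        window = np.array([[0.2, 0.8], [0.5, 0.5], [0.9, 0.1]])

        sig = lambda v: 1.0 / (1.0 + np.exp(-v))
        h = np.zeros(2)
        c = np.zeros(2)
        for t in range(3):
            z = np.concatenate([h, window[t]])
            i = sig(params["lstm.w_i"] @ z + params["lstm.b_i"])
            f = sig(params["lstm.w_f"] @ z)
            o = sig(params["lstm.w_o"] @ z)
            g = np.tanh(params["lstm.w_c"] @ z)
            c = f * c + i * g
            h = o * np.tanh(c)
        expected = sig(params["head.w"] @ h + 0.1)

        assert fh.forward(window, params, cfg) == pytest.approx(expected, abs=1e-10)

    def test_nonfinite_input_rejected(self, tiny_model_cfg):
        params = zero_params(tiny_model_cfg)
        w = np.zeros((8, 8))
        w[0, 0] = np.nan
        with pytest.raises(fh.DataError):
            fh.forward(w, params, tiny_model_cfg)

    @given(st.integers(0, 2**31 - 1))
    def test_probability_strictly_inside_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        cfg = fh.ModelConfig(n_features=3, window_len=5, cnn_channels=2,
                             cnn_kernel=2, lstm_hidden=3, dense_hidden=2,
                             seed=seed % 1000, init_scale=2.0)
        params = fh.init_params(cfg)
        p = fh.forward(rng.normal(0, 3, (5, 3)), params, cfg)
        assert 0.0 < p < 1.0

    def test_sigmoid_equals_two_class_softmax(self, tiny_model_cfg):
        from scipy.special import softmax

        params = zero_params(tiny_model_cfg)
        w = np.zeros((8, 8))
        for u in np.linspace(-25, 25, 21):
            params["head.b"] = np.array([u])
            p = fh.forward(w, params, tiny_model_cfg)
            assert p == pytest.approx(softmax([0.0, u])[1], abs=1e-12)

    def test_order_sensitivity_and_pooled_ablation(self):
        cfg = fh.ModelConfig(n_features=4, window_len=6, cnn_enabled=False,
                             lstm_hidden=6, dense_hidden=4, seed=3, init_scale=0.8)
        params = fh.init_params(cfg)
        w = np.random.default_rng(4).random((6, 4))
        assert fh.forward(w, params, cfg) != fh.forward(w[::-1], params, cfg)

        pooled_cfg = fh.ModelConfig(n_features=4, window_len=6, cnn_enabled=True,
                                    cnn_channels=5, cnn_kernel=1, lstm_enabled=False,
                                    dense_hidden=4, seed=3, init_scale=0.8)
        pooled_params = fh.init_params(pooled_cfg)
        a = fh.forward(w, pooled_params, pooled_cfg)
        b = fh.forward(w[::-1], pooled_params, pooled_cfg)
        assert a == pytest.approx(b, abs=1e-12)


class TestLoss:
    def test_bce_hand_values(self):
        assert fh.binary_cross_entropy([0.5, 0.5], [1, 0]) == pytest.approx(math.log(2), abs=1e-12)
        assert fh.binary_cross_entropy([0.9, 0.2], [1, 0]) == pytest.approx(
            -(math.log(0.9) + math.log(0.8)) / 2, abs=1e-12)
        # clipping floor: a perfectly confident correct prediction
        assert fh.binary_cross_entropy([1.0], [1]) == pytest.approx(1e-7, rel=1e-3)

    def test_local_loss_at_chance_is_ln2(self, tiny_model_cfg, small_windows):
        params = zero_params(tiny_model_cfg)
        assert fh.local_loss(params, small_windows, tiny_model_cfg) == pytest.approx(
            math.log(2), abs=1e-12)

    def test_local_loss_empty_rejected(self, tiny_model_cfg, small_windows):
        params = zero_params(tiny_model_cfg)
        with pytest.raises(fh.DataError):
            fh.local_loss(params, small_windows.subset(np.zeros(0, dtype=int)), tiny_model_cfg)

    def test_gradient_matches_finite_differences(self):
        cfg = fh.ModelConfig(n_features=2, window_len=3, cnn_enabled=False,
                             lstm_hidden=2, dense_hidden=2, seed=7, init_scale=0.4)
        params = fh.init_params(cfg)
        assert params.n_params == 49
        rng = np.random.default_rng(0)
        X = rng.random((5, 3, 2))
        y = np.array([1, 0, 1, 1, 0])
        _, grad = fh.loss_and_grad(params, X, y, cfg)
        flat, gflat = params.to_flat(), grad.to_flat()
        eps = 1e-6
        num = np.empty_like(flat)
        for i in range(flat.size):
            up, down = flat.copy(), flat.copy()
            up[i] += eps
            down[i] -= eps
            num[i] = (fh.local_loss(params.with_flat(up), (X, y), cfg)
                      - fh.local_loss(params.with_flat(down), (X, y), cfg)) / (2 * eps)
        rel = np.abs(num - gflat) / np.maximum(1e-8, np.abs(num) + np.abs(gflat))
        assert rel.max() <= 1e-4

    def test_gradient_with_cnn_branch(self):
        cfg = fh.ModelConfig(n_features=2, window_len=4, cnn_enabled=True,
                             cnn_channels=2, cnn_kernel=2, lstm_hidden=2,
                             dense_hidden=0, seed=8, init_scale=0.4)
        params = fh.init_params(cfg)
        rng = np.random.default_rng(1)
        X = rng.random((4, 4, 2))
        y = np.array([0, 1, 0, 1])
        _, grad = fh.loss_and_grad(params, X, y, cfg)
        flat, gflat = params.to_flat(), grad.to_flat()
        eps = 1e-6
        num = np.empty_like(flat)
        for i in range(flat.size):
            up, down = flat.copy(), flat.copy()
            up[i] += eps
            down[i] -= eps
            num[i] = (fh.local_loss(params.with_flat(up), (X, y), cfg)
                      - fh.local_loss(params.with_flat(down), (X, y), cfg)) / (2 * eps)
        rel = np.abs(num - gflat) / np.maximum(1e-8, np.abs(num) + np.abs(gflat))
        assert rel.max() <= 1e-4


class TestSerialization:
    def test_round_trip_bit_exact(self, tiny_model_cfg):
        params = fh.init_params(tiny_model_cfg)
        blob = params_to_bytes(params, config_hash=tiny_model_cfg.hash())
        loaded, manifest = params_from_bytes(blob)
        assert manifest["config_hash"] == tiny_model_cfg.hash()
        assert loaded.names() == params.names()
        # float32 quantization is applied once; a second pass is exact
        assert params_to_bytes(loaded, config_hash=tiny_model_cfg.hash()) == blob
        for name in params.names():
            np.testing.assert_array_equal(
                loaded[name], params[name].astype(np.float32).astype(np.float64))

    def test_file_round_trip(self, tiny_model_cfg, tmp_path):
        params = fh.init_params(tiny_model_cfg)
        fh.save_params(params, tmp_path / "p.bin")
        loaded, _ = fh.load_params(tmp_path / "p.bin")
        assert loaded.names() == params.names()

    def test_size_accounting(self):
        from collections import OrderedDict

        empty = ParamVector(OrderedDict())
        assert fh.param_size_bytes(empty) == PARAM_HEADER_BYTES
        cfg = fh.ModelConfig(n_features=10, window_len=4, cnn_enabled=False,
                             lstm_hidden=4, dense_hidden=0)
        toy = fh.init_params(cfg)
        assert fh.param_size_bytes(toy) == 245 * 4 + PARAM_HEADER_BYTES
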