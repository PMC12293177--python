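"""Multimodal teacher: frontend, encoder, attention, forward, pretraining."""

import numpy as np
import pytest

from conftest import SMALL_TEACHER, TOY_TEACHER, fd_grad_entries, pick_entries, toy_batch
from emokd.models import (
    ConfigurationError,
    EncoderConfig,
    FrontendConfig,
    conv_frontend,
    encode_stream,
    frontend_out_len,
    init_encoder,
    init_frontend,
    load_params,
    save_params,
)
from emokd.nn import Tensor, grad, no_grad, scaled_dot_attention
from emokd.teacher import (
    TeacherConfig,
    evaluate_teacher,
    init_teacher,
    pretrain_teacher,
    teacher_forward,
)
from emokd.distill import loss_ce


class TestFrontend:
    CFG = FrontendConfig(n_channels=3, fs=16.0, n_temporal_maps=2, d_model=8, dropout=0.0)

    def test_output_shape_follows_stride_arithmetic(self):
        rng = np.random.default_rng(0)
        params = init_frontend(self.CFG, rng, "fe")
        x = rng.standard_normal((4, 3, 64))
        out = conv_frontend(x, params, "fe", self.CFG)
        assert out.shape == (4, frontend_out_len(64, self.CFG), 8)
        assert frontend_out_len(64, self.CFG) == 8  # 64 samples / (fs/2 = 8)

    def test_default_config_segment_shape(self):
        cfg = FrontendConfig(n_channels=32, fs=128.0, n_temporal_maps=2, d_model=16, dropout=0.0)
        params = init_frontend(cfg, np.random.default_rng(0), "fe")
        out = conv_frontend(np.zeros((2, 32, 512)), params, "fe", cfg)
        assert out.shape == (2, 8, 16)  # 4 s at 128 Hz -> 8 half-second steps

    def test_zero_input_zero_output_under_biasfree_params(self):
        params = init_frontend(self.CFG, np.random.default_rng(1), "fe")
        params["fe.b1"].data[:] = 0.0
        params["fe.b2"].data[:] = 0.0
        out = conv_frontend(np.zeros((2, 3, 64)), params, "fe", self.CFG)
        assert np.array_equal(out.data, np.zeros_like(out.data))

    def test_positive_homogeneity_with_zero_biases(self):
        # relu-conv stack with zero biases: doubling input doubles output
        rng = np.random.default_rng(2)
        params = init_frontend(self.CFG, rng, "fe")
        params["fe.b1"].data[:] = 0.0
        params["fe.b2"].data[:] = 0.0
        x = rng.standard_normal((2, 3, 64))
        a = conv_frontend(x, params, "fe", self.CFG).data
        b = conv_frontend(2 * x, params, "fe", self.CFG).data
        assert np.allclose(b, 2 * a, rtol=1e-12)

    def test_too_short_input_rejected(self):
        params = init_frontend(self.CFG, np.random.default_rng(0), "fe")
        with pytest.raises(ConfigurationError, match="shorter"):
            conv_frontend(np.zeros((1, 3, 4)), params, "fe", self.CFG)


class TestAttention:
    def test_single_position_returns_v_exactly(self):
        rng = np.random.default_rng(3)
        q = Tensor(rng.standard_normal((1, 4)))
        k = Tensor(rng.standard_normal((1, 4)))
        v = Tensor(rng.standard_normal((1, 4)))
        out = scaled_dot_attention(q, k, v)
        assert np.array_equal(out.data, v.data)

    def test_zero_query_gives_row_mean_of_v(self):
        rng = np.random.default_rng(4)
        k = Tensor(rng.standard_normal((5, 4)))
        v = Tensor(rng.standard_normal((5, 4)))
        out = scaled_dot_attention(Tensor(np.zeros((5, 4))), k, v)
        assert np.allclose(out.data, np.tile(v.data.mean(axis=0), (5, 1)), atol=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        q, k, v = (rng.standard_normal((4, 3)) for _ in range(3))
        out = scaled_dot_attention(Tensor(q), Tensor(k), Tensor(v)).data
        # brute-force: explicit loops over positions
        expected = np.zeros((4, 3))
        for i in range(4):
            logits = np.array([q[i] @ k[j] / np.sqrt(3) for j in range(4)])
            w = np.exp(logits - logits.max())
            w /= w.sum()
            expected[i] = sum(w[j] * v[j] for j in range(4))
        assert np.allclose(out, expected, atol=1e-6)

    def test_attention_rows_sum_to_one_at_every_layer_and_head(self):
        rng = np.random.default_rng(6)
        x = toy_batch(rng, n=3)
        params = init_teacher(TOY_TEACHER, rng)
        out = teacher_forward(params, x[0], x[1], TOY_TEACHER, collect_attention=True)
        assert set(out.attention) == {"eeg", "eog"}
        for mod, layers in out.attention.items():
            assert len(layers) == TOY_TEACHER.n_layers
            for a in layers:
                assert np.allclose(a.sum(axis=-1), 1.0, atol=1e-6)


class TestEncoder:
    CFG = EncoderConfig(d_model=8, n_layers=3, n_heads=2, d_ff=8)

    def test_output_list_length_equals_layers(self):
        rng = np.random.default_rng(7)
        params = init_encoder(self.CFG, rng, "enc")
        outs = encode_stream(Tensor(rng.standard_normal((2, 5, 8))), params, "enc", self.CFG)
        assert len(outs) == 3

    def test_single_head_degeneracy(self):
        # h=1 must agree with manually composing one attention head with W^O
        cfg = EncoderConfig(d_model=6, n_layers=1, n_heads=1, d_ff=6, use_positions=False)
        rng = np.random.default_rng(8)
        params = init_encoder(cfg, rng, "enc")
        x = rng.standard_normal((1, 4, 6))
        out = encode_stream(Tensor(x), params, "enc", cfg)[0]

        from emokd.nn import layer_norm, linear, relu as _relu

        seq = Tensor(x)
        q = linear(seq, params["enc.l0.wq"], params["enc.l0.bq"])
        k = linear(seq, params["enc.l0.wk"], params["enc.l0.bk"])
        v = linear(seq, params["enc.l0.wv"], params["enc.l0.bv"])
        att = linear(scaled_dot_attention(q, k, v), params["enc.l0.wo"], params["enc.l0.bo"])
        h = layer_norm(seq + att, params["enc.l0.ln1.g"], params["enc.l0.ln1.b"])
        ff = linear(_relu(linear(h, params["enc.l0.ff.w1"], params["enc.l0.ff.b1"])),
                    params["enc.l0.ff.w2"], params["enc.l0.ff.b2"])
        ref = layer_norm(h + ff, params["enc.l0.ln2.g"], params["enc.l0.ln2.b"])
        assert np.allclose(out.data, ref.data, atol=1e-10)

    def test_permutation_equivariance_without_positions(self):
        cfg = EncoderConfig(d_model=8, n_layers=2, n_heads=2, d_ff=8, use_positions=False)
        rng = np.random.default_rng(9)
        params = init_encoder(cfg, rng, "enc")
        x = rng.standard_normal((1, 6, 8))
        perm = rng.permutation(6)
        out = encode_stream(Tensor(x), params, "enc", cfg)[-1].data
        out_p = encode_stream(Tensor(x[:, perm]), params, "enc", cfg)[-1].data
        assert np.allclose(out_p, out[:, perm], atol=1e-10)

    def test_positions_break_equivariance(self):
        cfg = EncoderConfig(d_model=8, n_layers=1, n_heads=2, d_ff=8, use_positions=True)
        rng = np.random.default_rng(10)
        params = init_encoder(cfg, rng, "enc")
        x = rng.standard_normal((1, 6, 8))
        perm = np.roll(np.arange(6), 1)
        out = encode_stream(Tensor(x), params, "enc", cfg)[-1].data
        out_p = encode_stream(Tensor(x[:, perm]), params, "enc", cfg)[-1].data
        assert not np.allclose(out_p, out[:, perm])


class TestTeacherForward:
    def test_probabilities_are_simplex_length_two(self):
        rng = np.random.default_rng(11)
        eeg, eog, _ = toy_batch(rng, n=5)
        params = init_teacher(TOY_TEACHER, rng)
        out = teacher_forward(params, eeg, eog, TOY_TEACHER)
        assert out.probabilities.shape == (5, 2)
        assert np.allclose(out.probabilities.data.sum(axis=-1), 1.0, atol=1e-6)
        assert all(t.shape == (5, 8) for t in out.taps.values())
        assert out.fused.shape == (5, 16)

    def test_evaluation_mode_deterministic(self):
        rng = np.random.default_rng(12)
        eeg, eog, _ = toy_batch(rng, n=3)
        params = init_teacher(TOY_TEACHER, rng)
        a = teacher_forward(params, eeg, eog, TOY_TEACHER, rng=None)
        b = teacher_forward(params, eeg, eog, TOY_TEACHER, rng=None)
        assert np.array_equal(a.logits.data, b.logits.data)

    def test_missing_modality_rejected(self):
        params = init_teacher(TOY_TEACHER, np.random.default_rng(0))
        with pytest.raises(ValueError, match="multimodal"):
            teacher_forward(params, None, np.zeros((1, 2, 64)), TOY_TEACHER)

    def test_single_layer_teacher_rejected(self):
        with pytest.raises(ConfigurationError):
            TeacherConfig(n_layers=1)

    def test_fusion_path_drives_logits(self, small_cohort, small_data):
        # zeroing the fused feature must change the logits of a trained model
        eeg, eog, y = small_data.arrays("train", "unit-test")
        params, _ = pretrain_teacher(
            (eeg[:48], eog[:48], y[:48]), (eeg[48:64], eog[48:64], y[48:64]),
            SMALL_TEACHER, epochs=2, batch_size=16, seed=0,
        )
        out = teacher_forward(params, eeg[:4], eog[:4], SMALL_TEACHER)
        ablated = (Tensor(np.zeros_like(out.fused.data)) @ params["head.w"] + params["head.b"]).data
        assert not np.allclose(out.logits.data, ablated)

    def test_end_to_end_gradient_check(self):
        rng = np.random.default_rng(13)
        eeg, eog, y = toy_batch(rng, n=4)
        params = init_teacher(TOY_TEACHER, rng)

        def f(p):
            out = teacher_forward(p, eeg, eog, TOY_TEACHER)
            return loss_ce(y, out.probabilities)

        names = sorted(params)
        analytic = dict(zip(names, grad(f(params), [params[k] for k in names])))
        entries = pick_entries(rng, params, 32)
        numeric = fd_grad_entries(f, params, entries)
        got = np.array([analytic[k].data.reshape(-1)[i] for k, i in entries])
        denom = np.maximum(np.abs(numeric), 1e-4)
        assert np.max(np.abs(got - numeric) / denom) < 1e-4


class TestPretraining:
    def test_learns_separable_cohort(self, small_data):
        eeg, eog, y = small_data.arrays("train", "unit-test")
        va = small_data.arrays("val", "unit-test")
        params, history = pretrain_teacher(
            (eeg, eog, y), va, SMALL_TEACHER, epochs=6, batch_size=32, seed=3,
        )
        assert history[-1]["train_loss"] < history[0]["train_loss"]
        _, acc = evaluate_teacher(params, va, SMALL_TEACHER)
        assert acc >= 0.5

    def test_checkpoint_reload_reproduces_val_loss(self, small_data, tmp_path):
        eeg, eog, y = small_data.arrays("train", "unit-test")
        va = small_data.arrays("val", "unit-test")
        params, _ = pretrain_teacher((eeg, eog, y), va, SMALL_TEACHER, epochs=2, batch_size=32, seed=1)
        loss_a, acc_a = evaluate_teacher(params, va, SMALL_TEACHER)
        save_params(params, tmp_path / "t.npz")
        reloaded = load_params(tmp_path / "t.npz")
        loss_b, acc_b = evaluate_teacher(reloaded, va, SMALL_TEACHER)
        assert abs(loss_a - loss_b) < 1e-6
        assert acc_a == acc_b

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError):
            pretrain_teacher(
                (np.zeros((0, 3, 64)), np.zeros((0, 2, 64)), np.zeros(0)),
                (np.zeros((0, 3, 64)), np.zeros((0, 2, 64)), np.zeros(0)),
                TOY_TEACHER, epochs=1,
            )
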