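import math

import numpy as np
import pytest

from eegtcn.models import (AttentionInput, ModelConfig, ResidualBlock,
                           attention_weights, build_baseline, build_model,
                           causal_dilated_conv, count_parameters,
                           parameter_count_formula, receptive_span,
                           self_attention, total_receptive_field)
from eegtcn.nn.autograd import Tensor

REFERENCE = ModelConfig()  # 19 x 200 input, 2 levels, k=4, width 164


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def conv_oracle(x, w, d):
    """Direct-summation causal dilated convolution with left zero padding."""
    c_out, c_in, k = w.shape
    T = x.shape[1]
    pad = d * (k - 1)
    xp = np.concatenate([np.zeros((c_in, pad)), x], axis=1)
    y = np.zeros((c_out, T))
    for o in range(c_out):
        for t in range(T):
            acc = 0.0
            for c in range(c_in):
                for j in range(k):
                    acc += w[o, c, j] * xp[c, t + j * d]
            y[o, t] = acc
    return y


def attention_oracle(Q, M, V):
    """Brute-force scaled dot-product attention, elementwise math only."""
    n, d_m = Q.shape
    out = np.zeros_like(V)
    for i in range(n):
        scores = [sum(Q[i, a] * M[j, a] for a in range(d_m)) / math.sqrt(d_m)
                  for j in range(n)]
        mx = max(scores)
        exp = [math.exp(s - mx) for s in scores]
        z = sum(exp)
        for j in range(n):
            out[i] += (exp[j] / z) * V[j]
    return out


# ---------------------------------------------------------------------------
# receptive span (single layer)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("d,k,expected", [(3, 2, 3), (1, 1, 0), (8, 4, 24)])
def test_receptive_span(d, k, expected):
    assert receptive_span(d, k) == expected


def test_receptive_span_rejects_nonpositive():
    with pytest.raises(ValueError):
        receptive_span(0, 2)
    with pytest.raises(ValueError):
        receptive_span(2, 0)


# ---------------------------------------------------------------------------
# causal dilated convolution
# ---------------------------------------------------------------------------

class TestCausalDilatedConv:
    def test_frozen_example(self):
        # kernel [1, 1], d=1, x=[1,2,3] -> [1, 3, 5]
        out = causal_dilated_conv(np.array([[1.0, 2.0, 3.0]]),
                                  np.array([[[1.0, 1.0]]]), 1)
        np.testing.assert_allclose(out, [[1.0, 3.0, 5.0]])

    def test_pointwise_identity(self, rng):
        x = rng.standard_normal((1, 7))
        out = causal_dilated_conv(x, np.array([[[1.0]]]), 1)
        np.testing.assert_allclose(out, x)

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(25):
            T = int(rng.integers(1, 33))
            d = int(rng.integers(1, 9))
            k = int(rng.integers(1, 5))
            c_in = int(rng.integers(1, 4))
            c_out = int(rng.integers(1, 4))
            x = rng.standard_normal((c_in, T))
            w = rng.standard_normal((c_out, c_in, k))
            np.testing.assert_allclose(
                causal_dilated_conv(x, w, d), conv_oracle(x, w, d), atol=1e-10
            )

    def test_causality_under_future_perturbation(self, rng):
        x = rng.standard_normal((2, 20))
        w = rng.standard_normal((3, 2, 3))
        base = causal_dilated_conv(x, w, 2)
        t = 8
        x2 = x.copy()
        x2[:, t + 1:] += rng.standard_normal(x2[:, t + 1:].shape)
        np.testing.assert_array_equal(
            causal_dilated_conv(x2, w, 2)[:, : t + 1], base[:, : t + 1]
        )

    def test_invalid_dilation(self):
        with pytest.raises(ValueError):
            causal_dilated_conv(np.zeros((1, 4)), np.zeros((1, 1, 2)), 0)


# ---------------------------------------------------------------------------
# residual block
# ---------------------------------------------------------------------------

class TestResidualBlock:
    def _block(self, c_in=1, c_out=1, k=2, d=1, seed=0):
        return ResidualBlock(c_in, c_out, k, d, dropout_p=0.0,
                             activation="relu", rng=np.random.default_rng(seed))

    def test_zero_f_is_identity_on_nonnegative(self, rng):
        block = self._block()
        for conv in (block.conv1, block.conv2):
            conv.weight_v.data[:] = 0.1
            conv.gain.data[:] = 0.0  # effective weight = 0
            conv.bias.data[:] = 0.0
        x = np.abs(rng.standard_normal((1, 1, 8)))
        out = block(Tensor(x))
        np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_length_preserved(self, rng):
        block = self._block(c_in=3, c_out=5, k=4, d=2)
        out = block(Tensor(rng.standard_normal((2, 3, 200))))
        assert out.shape == (2, 5, 200)

    def test_hand_computed_forward(self):
        # 1 channel, T=3, k=2, all conv weights 0.5, biases 0:
        #   conv1([1,2,3]) = [0.5, 1.5, 2.5]; conv2 -> [0.25, 1.0, 2.0]
        #   relu(x + F(x)) = [1.25, 3.0, 5.0]
        block = self._block()
        for conv in (block.conv1, block.conv2):
            conv.weight_v.data[:] = 0.5
            conv.gain.data[:] = np.sqrt((conv.weight_v.data ** 2).sum())
            conv.bias.data[:] = 0.0
        out = block(Tensor(np.array([[[1.0, 2.0, 3.0]]])))
        np.testing.assert_allclose(out.data, [[[1.25, 3.0, 5.0]]], atol=1e-12)


# ---------------------------------------------------------------------------
# self-attention
# ---------------------------------------------------------------------------

class TestSelfAttention:
    def test_single_row_passthrough(self, rng):
        v = rng.standard_normal((1, 3))
        a = AttentionInput(M=rng.standard_normal((1, 3)), V=v,
                           Q=rng.standard_normal((1, 3)))
        np.testing.assert_allclose(self_attention(a), v)

    def test_identical_keys_give_uniform_weights(self, rng):
        n, d_m = 5, 4
        m = np.tile(rng.standard_normal((1, d_m)), (n, 1))
        v = rng.standard_normal((n, d_m))
        a = AttentionInput(M=m, V=v, Q=rng.standard_normal((n, d_m)))
        np.testing.assert_allclose(attention_weights(a), 1.0 / n)
        np.testing.assert_allclose(
            self_attention(a), np.tile(v.mean(axis=0), (n, 1))
        )

    def test_identity_example_matches_oracle(self):
        eye = np.eye(2)
        a = AttentionInput(M=eye, V=eye, Q=eye)
        np.testing.assert_allclose(
            self_attention(a), attention_oracle(eye, eye, eye), atol=1e-12
        )

    def test_random_inputs_match_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 9))
            d_m = int(rng.integers(1, 6))
            q, m, v = (rng.standard_normal((n, d_m)) for _ in range(3))
            a = AttentionInput(M=m, V=v, Q=q)
            np.testing.assert_allclose(
                self_attention(a), attention_oracle(q, m, v), atol=1e-8
            )

    def test_rows_sum_to_one(self, rng):
        a = AttentionInput(*(rng.standard_normal((6, 3)) for _ in range(3)))
        np.testing.assert_allclose(attention_weights(a).sum(axis=1), 1.0,
                                   atol=1e-6)

    def test_permutation_equivariance_of_key_value_rows(self, rng):
        n, d_m = 6, 4
        q, m, v = (rng.standard_normal((n, d_m)) for _ in range(3))
        perm = rng.permutation(n)
        out = self_attention(AttentionInput(M=m, V=v, Q=q))
        out_p = self_attention(AttentionInput(M=m[perm], V=v[perm], Q=q))
        np.testing.assert_allclose(out, out_p, atol=1e-10)

    def test_zero_dm_rejected(self):
        with pytest.raises(ValueError):
            AttentionInput(M=np.zeros((2, 0)), V=np.zeros((2, 0)),
                           Q=np.zeros((2, 0)))


# ---------------------------------------------------------------------------
# full model and baselines
# ---------------------------------------------------------------------------

SMALL = ModelConfig(hidden_width=8, in_channels=4, in_length=40)


class TestBuildModel:
    def test_probability_rows_sum_to_one(self, rng):
        model = build_model(SMALL, seed=0)
        probs = model.predict_proba(rng.random((5, 4, 40)))
        assert probs.shape == (5, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_output_width_two(self, rng):
        model = build_model(SMALL, seed=0)
        logits = model.logits(Tensor(rng.random((3, 4, 40))))
        assert logits.shape == (3, 2)

    def test_reference_parameter_count(self):
        model = build_model(REFERENCE, seed=0)
        assert count_parameters(model) == 420_662
        assert round(count_parameters(model) / 1e6, 2) == 0.42

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(kernel_size=0)
        with pytest.raises(ValueError):
            ModelConfig(attention_dim=10, hidden_width=20)
        with pytest.raises(ValueError):
            ModelConfig(n_classes=3)


class TestCountParameters:
    def test_lone_linear_layer(self, rng):
        from eegtcn.nn.layers import Linear, Module

        class Lone(Module):
            def __init__(self):
                super().__init__()
                self.lin = Linear(164, 2, rng)

        assert count_parameters(Lone()) == 330

    def test_reference_per_tensor_breakdown(self):
        # block-1 conv1 + conv2 + shortcut, block-2 conv1 + conv2, Q/K/V, head
        parts = [12_628, 107_748, 3_280, 107_748, 107_748, 81_180, 330]
        assert sum(parts) == 420_662 == parameter_count_formula(REFERENCE)

    @pytest.mark.parametrize("n_levels", [1, 2, 3])
    @pytest.mark.parametrize("k", [1, 2, 4])
    @pytest.mark.parametrize("width", [3, 8])
    def test_matches_closed_form_on_grid(self, n_levels, k, width):
        cfg = ModelConfig(n_levels=n_levels, kernel_size=k, hidden_width=width,
                          in_channels=4, in_length=16)
        model = build_model(cfg, seed=0)
        assert count_parameters(model) == parameter_count_formula(cfg)


class TestBaselines:
    @pytest.mark.parametrize("kind", ["tcnsa", "tcn", "sa", "cnn"])
    def test_probability_contract(self, kind, rng):
        model = build_baseline(kind, SMALL, seed=1)
        probs = model.predict_proba(rng.random((4, 4, 40)))
        assert np.isfinite(probs).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_tcn_has_no_attention_parameters(self):
        tcn = build_baseline("tcn", SMALL, seed=0)
        tcnsa = build_baseline("tcnsa", SMALL, seed=0)
        attn = 3 * (SMALL.hidden_width ** 2 + SMALL.hidden_width)
        assert count_parameters(tcnsa) - count_parameters(tcn) == attn

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            build_baseline("rnn", SMALL)

    def test_nineteen_channel_input_accepted(self, rng):
        cfg = ModelConfig(hidden_width=8)
        for kind in ("tcnsa", "tcn", "sa", "cnn"):
            model = build_baseline(kind, cfg, seed=0)
            probs = model.predict_proba(rng.random((2, 19, 200)))
            assert np.isfinite(probs).all()


class TestCausalityAndReceptiveField:
    def test_tcn_stack_is_causal(self, rng):
        model = build_baseline("tcn", SMALL, seed=3)
        model.eval_mode()
        x = rng.random((1, 4, 40))
        base = model.feature_sequence(Tensor(x)).data
        for _ in range(20):
            t = int(rng.integers(0, 39))
            x2 = x.copy()
            x2[:, :, t + 1:] += rng.standard_normal(x2[:, :, t + 1:].shape)
            out = model.feature_sequence(Tensor(x2)).data
            np.testing.assert_array_equal(out[:, :, : t + 1], base[:, :, : t + 1])

    @pytest.mark.parametrize("n_levels,k", [(1, 2), (2, 2), (2, 4), (3, 3)])
    def test_receptive_field_closed_form_vs_probe(self, n_levels, k, rng):
        cfg = ModelConfig(n_levels=n_levels, kernel_size=k, hidden_width=4,
                          in_channels=1, in_length=64)
        rf = total_receptive_field(cfg)
        model = build_baseline("tcn", cfg, seed=5)
        model.eval_mode()
        # make the block nonlinearities transparent so the probe sees all taps
        for block in model.blocks:
            for conv in (block.conv1, block.conv2):
                conv.weight_v.data[:] = 1.0
                conv.gain.data[:] = np.sqrt((conv.weight_v.data ** 2).sum(axis=(1, 2)))
                conv.bias.data[:] = 1.0
        x = np.zeros((1, 1, 64))
        base = model.feature_sequence(Tensor(x)).data[0, :, -1]
        affected = []
        for t in range(64):
            xp = x.copy()
            xp[0, 0, t] = 1.0
            out = model.feature_sequence(Tensor(xp)).data[0, :, -1]
            if not np.allclose(out, base):
                affected.append(t)
        assert 64 - min(affected) == min(rf, 64)
        assert max(affected) == 63
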