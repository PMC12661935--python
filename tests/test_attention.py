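"""SE, Coordinate Attention, AFT and CAAFT against brute-force loop oracles."""

import numpy as np
import pytest

from tflos import nn
from tflos.attention import (AFT, CAAFT, CoordAtt, SELayer, aft_forward,
                             ca_pool, ca_reweight, caaft_forward, se_forward)

# ---------------------------------------------------------------------------
# loop oracles
# ---------------------------------------------------------------------------

def se_oracle(x, layer):
    """Per-channel rescale by the gate vector, computed with loops."""
    out = np.zeros_like(x)
    g = layer.gates(nn.Tensor(x)).data
    for b in range(x.shape[0]):
        for c in range(x.shape[1]):
            out[b, c] = x[b, c] * g[b, c]
    return out


def ca_pool_oracle(x):
    B, C, H, W = x.shape
    z_h = np.zeros((B, C, H, 1))
    z_w = np.zeros((B, C, 1, W))
    for b in range(B):
        for c in range(C):
            for h in range(H):
                z_h[b, c, h, 0] = sum(x[b, c, h, i] for i in range(W)) / W
            for w in range(W):
                z_w[b, c, 0, w] = sum(x[b, c, j, w] for j in range(H)) / H
    return z_h, z_w


def ca_reweight_oracle(x, a_h, a_w):
    out = np.zeros_like(x)
    B, C, H, W = x.shape
    for b in range(B):
        for c in range(C):
            for h in range(H):
                for w in range(W):
                    out[b, c, h, w] = x[b, c, h, w] * a_h[b, c, h, 0] * a_w[b, c, 0, w]
    return out


def aft_oracle(x, layer):
    """Elementwise AFT: Y_t = sigmoid(Q'_t) * sum_s softmax(K')_s * V'_s."""
    wq, wk, wv = layer.w_q, layer.w_k, layer.w_v
    T, d = x.shape
    q = x @ wq.weight.data + wq.bias.data
    k = x @ wk.weight.data + wk.bias.data
    v = x @ wv.weight.data + wv.bias.data
    y = np.zeros((T, d))
    for j in range(d):
        ek = np.exp(k[:, j] - k[:, j].max())
        sk = ek / ek.sum()
        pooled = sum(sk[s] * v[s, j] for s in range(T))
        for t in range(T):
            y[t, j] = (1 / (1 + np.exp(-q[t, j]))) * pooled
    return y


# ---------------------------------------------------------------------------
# SE
# ---------------------------------------------------------------------------

class TestSE:
    def test_zero_input_maps_to_zero(self):
        layer = SELayer(8)
        out = layer(np.zeros((1, 8, 4, 4), np.float32))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_saturated_gate_is_identity(self, rng):
        layer = SELayer(8)
        layer.fc2.bias.data[...] = 50.0     # sigmoid saturates to 1
        x = rng.standard_normal((2, 8, 5, 5)).astype(np.float32)
        np.testing.assert_allclose(se_forward(x, layer).data, x, atol=1e-6)

    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            c = int(rng.integers(2, 12))
            layer = SELayer(c, reduction_ratio=4,
                            rng=np.random.default_rng(int(rng.integers(1e6))))
            x = rng.standard_normal((2, c, 4, 6))
            np.testing.assert_allclose(layer(x).data, se_oracle(x, layer),
                                       atol=1e-6)

    def test_gates_strictly_inside_unit_interval(self, rng):
        layer = SELayer(16)
        g = layer.gates(nn.Tensor(rng.standard_normal((3, 16, 4, 4)))).data
        assert np.all(g > 0) and np.all(g < 1)

    def test_shape_preserved_and_bad_channels_rejected(self, rng):
        layer = SELayer(8)
        assert layer(rng.standard_normal((2, 8, 3, 7))).shape == (2, 8, 3, 7)
        with pytest.raises(ValueError):
            layer(rng.standard_normal((2, 4, 3, 3)))


# ---------------------------------------------------------------------------
# Coordinate Attention
# ---------------------------------------------------------------------------

class TestCA:
    def test_constant_input_pools_to_constant(self):
        z_h, z_w = ca_pool(np.full((1, 2, 3, 5), 7.0))
        np.testing.assert_allclose(z_h.data, 7.0)
        np.testing.assert_allclose(z_w.data, 7.0)

    def test_single_impulse_pools_to_inverse_extent(self):
        x = np.zeros((1, 1, 4, 8))
        x[0, 0, 2, 5] = 1.0
        z_h, z_w = ca_pool(x)
        assert z_h.data[0, 0, 2, 0] == pytest.approx(1 / 8)
        assert z_w.data[0, 0, 0, 5] == pytest.approx(1 / 4)
        assert z_h.data.sum() == pytest.approx(1 / 8)
        assert z_w.data.sum() == pytest.approx(1 / 4)

    def test_pool_matches_loop_oracle_on_random_instances(self, rng):
        for _ in range(100):
            shape = (int(rng.integers(1, 3)), int(rng.integers(1, 5)),
                     int(rng.integers(1, 7)), int(rng.integers(1, 7)))
            x = rng.standard_normal(shape)
            z_h, z_w = ca_pool(x)
            oh, ow = ca_pool_oracle(x)
            np.testing.assert_allclose(z_h.data, oh, atol=1e-6)
            np.testing.assert_allclose(z_w.data, ow, atol=1e-6)

    def test_reweight_identity_zero_and_oracle(self, rng):
        x = rng.standard_normal((2, 3, 4, 5))
        ones_h = np.ones((2, 3, 4, 1))
        ones_w = np.ones((2, 3, 1, 5))
        np.testing.assert_allclose(ca_reweight(x, ones_h, ones_w).data, x,
                                   atol=1e-7)
        np.testing.assert_allclose(
            ca_reweight(x, 0 * ones_h, ones_w).data, 0.0)
        for _ in range(100):
            shape = (1, int(rng.integers(1, 4)), int(rng.integers(1, 6)),
                     int(rng.integers(1, 6)))
            x = rng.standard_normal(shape)
            a_h = rng.uniform(0, 1, (1, shape[1], shape[2], 1))
            a_w = rng.uniform(0, 1, (1, shape[1], 1, shape[3]))
            np.testing.assert_allclose(ca_reweight(x, a_h, a_w).data,
                                       ca_reweight_oracle(x, a_h, a_w),
                                       atol=1e-6)

    def test_reweight_rejects_mismatched_descriptors(self, rng):
        x = rng.standard_normal((1, 2, 3, 4))
        with pytest.raises(ValueError):
            ca_reweight(x, np.ones((1, 2, 4, 1)), np.ones((1, 2, 1, 4)))

    def test_full_block_gates_in_unit_interval(self, rng):
        block = CoordAtt(8)
        a_h, a_w = block.attentions(nn.Tensor(rng.standard_normal((1, 8, 6, 6))))
        for a in (a_h.data, a_w.data):
            assert np.all(a > 0) and np.all(a < 1)


# ---------------------------------------------------------------------------
# AFT
# ---------------------------------------------------------------------------

class TestAFT:
    def test_closed_output_gate_silences_output(self, rng):
        layer = AFT(4)
        layer.w_q.weight.data[...] = 0.0
        layer.w_q.bias.data[...] = -60.0    # sigmoid -> 0
        y = layer(rng.standard_normal((5, 4)))
        np.testing.assert_allclose(y.data, 0.0, atol=1e-20)

    def test_single_element_sequence_reduces_to_gated_value(self, rng):
        # T=1: softmax over one element is 1, so Y = sigmoid(Q') * V'
        layer = AFT(3)
        x = rng.standard_normal((1, 3))
        q = x @ layer.w_q.weight.data + layer.w_q.bias.data
        v = x @ layer.w_v.weight.data + layer.w_v.bias.data
        np.testing.assert_allclose(layer(x).data, 1 / (1 + np.exp(-q)) * v,
                                   atol=1e-6)

    def test_matches_loop_oracle_on_random_instances(self, rng):
        for _ in range(100):
            d = int(rng.integers(2, 6))
            T = int(rng.integers(1, 8))
            layer = AFT(d, rng=np.random.default_rng(int(rng.integers(1e6))))
            x = rng.standard_normal((T, d))
            np.testing.assert_allclose(aft_forward(x, layer).data,
                                       aft_oracle(x, layer), atol=1e-6)

    def test_pooled_accumulation_order_invariance(self, rng):
        # summing the pooled terms in reverse order changes nothing (1e-6)
        layer = AFT(4)
        x = rng.standard_normal((6, 4))
        y1 = layer(x).data
        y2 = layer(x[::-1].copy()).data[::-1]
        # softmax-sum pooling is permutation invariant, so outputs match
        np.testing.assert_allclose(y1, y2, atol=1e-6)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            AFT(4)(rng.standard_normal((5, 3)))

    def test_no_quadratic_attention_matrix(self, rng):
        # memory contract: output plus pooled context only, O(T*d)
        layer = AFT(8)
        x = rng.standard_normal((512, 8))
        y = layer(x)
        assert y.shape == (512, 8)


# ---------------------------------------------------------------------------
# CAAFT
# ---------------------------------------------------------------------------

class TestCAAFT:
    def test_shape_preserved(self, rng):
        block = CAAFT(8)
        assert block(rng.standard_normal((2, 8, 16, 16))).shape == (2, 8, 16, 16)

    def test_forced_identity_pathway(self, rng):
        block = CAAFT(8)
        # open the CA gates fully and close the AFT residual gate
        block.ca.conv_h.bias.data[...] = 60.0
        block.ca.conv_h.weight.data[...] = 0.0
        block.ca.conv_w.bias.data[...] = 60.0
        block.ca.conv_w.weight.data[...] = 0.0
        block.aft.w_q.weight.data[...] = 0.0
        block.aft.w_q.bias.data[...] = -60.0
        x = rng.standard_normal((1, 8, 5, 5)).astype(np.float32)
        np.testing.assert_allclose(block(x).data, x, atol=1e-5)

    def test_matches_composition_of_oracles(self, rng):
        for _ in range(10):
            block = CAAFT(4, rng=np.random.default_rng(int(rng.integers(1e6))))
            x = rng.standard_normal((1, 4, 3, 4))
            # oracle composition: CA block, flatten, AFT oracle, residual
            a_h, a_w = block.ca.attentions(nn.Tensor(x))
            m = ca_reweight_oracle(x, a_h.data, a_w.data)
            seq = m[0].reshape(4, -1).T                     # (T, C)
            y = aft_oracle(seq, block.aft)
            expected = m + y.T.reshape(1, 4, 3, 4)
            np.testing.assert_allclose(caaft_forward(x, block).data, expected,
                                       atol=1e-6)
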