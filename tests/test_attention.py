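"""The cross-channel attention unit against a literal loop oracle, the
baseline units' structural properties, and the negative channel-permutation
test that separates convolutional gates from pointwise ones."""

import numpy as np
import pytest

from ccanet.attention import (CCAParams, CCAUnit, CBAMUnit, ECAUnit, SEUnit,
                              build_attention, cca_forward, conv_gate,
                              eca_forward, fc_gate, gap, rescale, se_forward)
from ccanet.nn import Tensor


def loop_cca_oracle(x, p):
    """Naive per-element implementation of the four CCA steps."""
    B, C, H, W = x.shape
    out = np.empty_like(x, dtype=np.float64)
    k = len(p.conv_kernel)
    half = (k - 1) // 2
    for b in range(B):
        z = [sum(x[b, c, i, j] for i in range(H) for j in range(W)) / (H * W)
             for c in range(C)]
        hidden = []
        for row in range(p.W1.shape[0]):
            acc = sum(p.W1[row, c] * z[c] for c in range(C))
            hidden.append(max(acc, 0.0))
        s = []
        for c in range(C):
            acc = sum(p.W2[c, r] * hidden[r] for r in range(len(hidden)))
            s.append(1.0 / (1.0 + np.exp(-acc)))
        omega = []
        for c in range(C):
            acc = 0.0
            for t in range(k):
                src = c + t - half
                if 0 <= src < C:
                    acc += p.conv_kernel[t] * s[src]
            if p.conv_bias is not None:
                acc += p.conv_bias
            omega.append(1.0 / (1.0 + np.exp(-acc)))
        for c in range(C):
            out[b, c] = x[b, c] * omega[c]
    return out


class TestGap:
    def test_constant_map(self):
        x = np.full((1, 4, 3, 3), 3.0)
        np.testing.assert_allclose(gap(x), 3.0)

    def test_known_small_value(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2)
        assert gap(x)[0, 0] == pytest.approx(2.5, abs=1e-12)

    def test_matches_double_loop(self, rng):
        x = rng.normal(size=(2, 8, 5, 7))
        ref = np.array([[sum(x[b, c, i, j] for i in range(5) for j in range(7))
                         / 35 for c in range(8)] for b in range(2)])
        np.testing.assert_allclose(gap(x), ref, atol=1e-6)


class TestGates:
    def test_zero_fc_weights_give_half(self):
        p = CCAParams(W1=np.zeros((2, 4)), W2=np.zeros((4, 2)),
                      conv_kernel=np.zeros(5), r=2)
        np.testing.assert_allclose(fc_gate(np.ones((1, 4)), p), 0.5)

    def test_fc_gate_matrix_vector_oracle(self):
        W1 = np.array([[1.0, -1.0, 0.0, 2.0], [0.5, 0.0, 1.0, 0.0]])
        W2 = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [-1.0, 0.5]])
        p = CCAParams(W1=W1, W2=W2, conv_kernel=np.zeros(5), r=2)
        z = np.array([1.0, 0.0, 0.0, 0.0])
        hidden = np.maximum(W1 @ z, 0)
        expected = 1 / (1 + np.exp(-(W2 @ hidden)))
        np.testing.assert_allclose(fc_gate(z, p)[0], expected, atol=1e-12)

    def test_outputs_strictly_inside_unit_interval(self, rng):
        p = CCAParams.random(16, seed=3)
        s = fc_gate(rng.normal(size=(4, 16)) * 10, p)
        w = conv_gate(s, p)
        for arr in (s, w):
            assert (arr > 0).all() and (arr < 1).all()

    def test_zero_conv_kernel_gives_half(self):
        p = CCAParams(W1=np.zeros((1, 4)), W2=np.zeros((4, 1)),
                      conv_kernel=np.zeros(5), conv_bias=0.0, r=4)
        np.testing.assert_allclose(conv_gate(np.ones((2, 4)), p), 0.5)

    def test_identity_kernel_is_sigmoid(self, rng):
        p = CCAParams(W1=np.zeros((1, 6)), W2=np.zeros((6, 1)),
                      conv_kernel=np.array([0, 0, 1.0, 0, 0]),
                      conv_bias=0.0, r=6)
        s = rng.normal(size=(1, 6))
        np.testing.assert_allclose(conv_gate(s, p),
                                   1 / (1 + np.exp(-s)), atol=1e-12)

    def test_box_kernel_sliding_window_oracle(self):
        p = CCAParams(W1=np.zeros((1, 6)), W2=np.zeros((6, 1)),
                      conv_kernel=np.ones(5), conv_bias=0.0, r=6)
        s = np.zeros((1, 6))
        s[0, 2] = 1.0
        # pre-sigmoid sums: one-hot smeared over a +/-2 window
        expected = 1 / (1 + np.exp(-np.array([1, 1, 1, 1, 1, 0.0])))
        np.testing.assert_allclose(conv_gate(s, p)[0], expected, atol=1e-12)


class TestRescale:
    def test_half_weight_halves_channel(self):
        x = np.full((1, 1, 2, 2), 4.0)
        np.testing.assert_allclose(rescale(x, np.array([0.5])), 2.0)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            rescale(rng.normal(size=(1, 4, 2, 2)), np.ones(3))


class TestCCAForward:
    def test_matches_loop_oracle(self, rng):
        worst = 0.0
        for trial in range(20):
            c = int(rng.choice([16, 32]))
            x = rng.normal(size=(2, c, int(rng.integers(1, 6)),
                                 int(rng.integers(1, 6))))
            p = CCAParams.random(c, r=16, k=5, seed=trial)
            dev = np.abs(cca_forward(x, p) - loop_cca_oracle(x, p)).max()
            worst = max(worst, dev)
        assert worst < 1e-5

    def test_attenuation_in_every_norm(self, rng):
        x = rng.normal(size=(1, 16, 4, 4))
        for fwd in (cca_forward, se_forward, eca_forward):
            out = fwd(x, CCAParams.random(16, seed=1))
            assert (np.abs(out) <= np.abs(x)).all()

    def test_batch_permutation_equivariance(self, rng):
        x = rng.normal(size=(4, 16, 3, 3))
        p = CCAParams.random(16, seed=2)
        perm = np.array([2, 0, 3, 1])
        np.testing.assert_allclose(cca_forward(x[perm], p),
                                   cca_forward(x, p)[perm], atol=1e-12)

    def test_channel_permutation_breaks_conv_gate_only(self, rng):
        """gap/rescale are channel-permutation equivariant; the 1-D conv
        across channels is not — channel order is information it uses."""
        p = CCAParams.random(16, seed=5)
        s = rng.normal(size=(1, 16))
        perm = rng.permutation(16)
        x = rng.normal(size=(1, 16, 2, 2))
        np.testing.assert_allclose(gap(x[:, perm]), gap(x)[:, perm])
        np.testing.assert_allclose(rescale(x[:, perm], s[0, perm]),
                                   rescale(x, s[0])[:, perm])
        assert not np.allclose(conv_gate(s[:, perm], p),
                               conv_gate(s, p)[:, perm])


class TestUnits:
    @pytest.mark.parametrize("variant", ["none", "se", "eca", "cbam", "cca"])
    def test_shape_preserved(self, variant, rng):
        unit = build_attention(variant, 16, r=4)
        unit.eval()
        x = rng.normal(size=(2, 16, 4, 4)).astype(np.float32)
        assert unit(Tensor(x)).shape == x.shape

    def test_se_zero_weights_give_uniform_half_scaling(self, rng):
        unit = SEUnit(8, r=4)
        unit.fc1.weight.data[...] = 0
        unit.fc2.weight.data[...] = 0
        x = rng.normal(size=(1, 8, 3, 3)).astype(np.float64)
        np.testing.assert_allclose(unit(Tensor(x)).data, 0.5 * x, atol=1e-7)

    def test_cca_unit_matches_functional_form(self, rng):
        unit = CCAUnit(16, r=4, k=5, rng=np.random.default_rng(8))
        unit.eval()
        x = rng.normal(size=(2, 16, 4, 4))
        np.testing.assert_allclose(unit(Tensor(x)).data,
                                   cca_forward(x, unit.params()), atol=1e-6)

    def test_eca_is_cca_without_fc_gate(self, rng):
        """Structural check: routing gap straight into the shared conv gate
        reproduces the efficient-channel-attention unit."""
        cca = CCAUnit(16, r=4, k=5, rng=np.random.default_rng(9))
        eca = ECAUnit(16, k=5, rng=np.random.default_rng(10))
        eca.conv.weight.data = cca.conv.weight.data.copy()
        eca.conv.bias.data = cca.conv.bias.data.copy()
        x = rng.normal(size=(1, 16, 3, 3))
        p = cca.params()
        np.testing.assert_allclose(eca(Tensor(x)).data,
                                   eca_forward(x, p), atol=1e-6)

    def test_cbam_gates_bounded(self, rng):
        unit = CBAMUnit(16, r=4)
        unit.eval()
        x = np.abs(rng.normal(size=(1, 16, 4, 4)))
        out = unit(Tensor(x)).data
        assert (np.abs(out) <= np.abs(x)).all()

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            build_attention("bogus", 16)

    def test_indivisible_reduction_rejected(self):
        with pytest.raises(ValueError):
            CCAUnit(10, r=4)
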