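"""SCConv invariants: gating algebra, cross reconstruction, shapes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scdiff.autodiff as ad
from scdiff.errors import ConfigurationError, DegenerateWeightsError
from scdiff.nn import GroupNorm
from scdiff.scconv import (
    CRUParams,
    ChannelReconstructionUnit,
    SCConv,
    SRUParams,
    SpatialReconstructionUnit,
    binary_gates,
    importance_weights,
)


class TestGroupNormalize:
    def test_constant_input_maps_to_shift(self):
        gn = GroupNorm(2, 4)
        x = ad.tensor(np.full((2, 4, 3, 3), 7.0))
        out = gn(x)
        assert np.allclose(out.data, 0.0, atol=1e-2)  # sigma=0 stabilized by eps
        gn.gamma.data[:] = 0.0
        gn.shift.data[:] = 5.0
        assert np.allclose(gn(x).data, 5.0)

    def test_moments_match_loop_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(2.0, 3.0, (2, 4, 8, 8))
        gn = GroupNorm(2, 4)
        normed = gn.normalize(ad.tensor(x)).data
        for b in range(2):
            for g in range(2):
                vals = []
                for c in range(g * 2, (g + 1) * 2):
                    for i in range(8):
                        for j in range(8):
                            vals.append(normed[b, c, i, j])
                vals = np.asarray(vals)
                assert abs(vals.mean()) < 1e-6
                assert abs(vals.var() - 1.0) < 1e-4

    def test_indivisible_groups_rejected(self):
        with pytest.raises(ConfigurationError):
            GroupNorm(3, 4)


class TestImportanceWeights:
    def test_uniform_scales(self):
        assert np.allclose(importance_weights([1, 1, 1, 1]), 0.25)

    def test_direct_values(self):
        assert np.allclose(importance_weights([2, 0]), [1.0, 0.0])
        assert np.allclose(importance_weights([3, 1, 1]), [0.6, 0.2, 0.2])

    def test_negative_scales_use_magnitude(self):
        assert np.allclose(importance_weights([-3, 1, 1]), [0.6, 0.2, 0.2])

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            w = importance_weights(rng.normal(size=8))
            assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateWeightsError):
            importance_weights(np.zeros(4))


class TestBinaryGates:
    def test_sigmoid_threshold_behaviour(self):
        w1, w2 = binary_gates(np.array([1.0, 0.0]), 0.5)
        assert list(w1) == [1, 0]
        assert list(w2) == [0, 1]

    def test_complementarity(self):
        rng = np.random.default_rng(2)
        w1, w2 = binary_gates(rng.uniform(0, 1, 16), 0.5)
        assert np.array_equal(w1 + w2, np.ones(16))

    def test_all_positive_weights_gate_on(self):
        # sigmoid of any positive importance exceeds 0.5 -> all informative
        w1, _ = binary_gates(np.array([0.6, 0.2, 0.2]), 0.5)
        assert np.array_equal(w1, np.ones(3))


class TestSRU:
    def test_gated_streams_sum_to_normalized_feature(self):
        rng = np.random.default_rng(3)
        sru = SpatialReconstructionUnit(8, SRUParams(num_groups=2))
        sru.gn.gamma.data[:] = rng.normal(size=8).astype(np.float32)
        x = ad.tensor(rng.normal(size=(2, 8, 4, 4)).astype(np.float32))
        f = sru.gn(x)
        w1, w2 = sru.gates()
        f1 = w1.reshape(1, 8, 1, 1) * f.data
        f2 = w2.reshape(1, 8, 1, 1) * f.data
        assert np.allclose(f1 + f2, f.data, atol=1e-6)

    def test_all_informative_output_is_channel_permutation(self):
        rng = np.random.default_rng(4)
        sru = SpatialReconstructionUnit(4, SRUParams(num_groups=2))
        x = ad.tensor(rng.normal(size=(1, 4, 3, 3)).astype(np.float32))
        out = sru(x)
        f = sru.gn(x).data
        # default gamma=1: all channels informative, redundant stream zero;
        # cross reconstruction then only reorders the channel halves
        assert np.allclose(np.sort(out.data.ravel()), np.sort(f.ravel()), atol=1e-6)

    def test_odd_channels_rejected(self):
        with pytest.raises(ConfigurationError):
            SpatialReconstructionUnit(5, SRUParams(num_groups=1))


class TestCRU:
    def test_shape_preserved(self):
        rng = np.random.default_rng(5)
        cru = ChannelReconstructionUnit(8, rng)
        x = ad.tensor(rng.normal(size=(1, 8, 8, 8)).astype(np.float32))
        assert cru(x).shape == (1, 8, 8, 8)

    def test_attention_weights_sum_to_one(self):
        rng = np.random.default_rng(6)
        y1 = ad.tensor(rng.normal(size=(2, 8, 4, 4)))
        y2 = ad.tensor(rng.normal(size=(2, 8, 4, 4)))
        b1, b2 = ChannelReconstructionUnit.attention_weights(y1, y2)
        assert np.allclose(b1 + b2, 1.0, atol=1e-12)

    def test_zeroed_upper_path_leaves_weighted_lower_path(self):
        rng = np.random.default_rng(7)
        cru = ChannelReconstructionUnit(8, rng)
        cru.gwc.weight.data[:] = 0.0
        cru.pwc_up.weight.data[:] = 0.0
        x = ad.tensor(rng.normal(size=(1, 8, 6, 6)).astype(np.float32))
        x_low = cru.squeeze_low(x[:, cru.up:])
        y2 = ad.concat([cru.pwc_low(x_low), x_low], axis=1)
        y1 = ad.tensor(np.zeros_like(y2.data))
        expected = cru.fuse(y1, y2)
        assert np.allclose(cru(x).data, expected.data, atol=1e-6)


class TestSCConvComposite:
    @settings(max_examples=50, deadline=None)
    @given(
        batch=st.integers(1, 3),
        channels=st.sampled_from([8, 16]),
        size=st.integers(4, 12),
    )
    def test_shape_preservation_randomized(self, batch, channels, size):
        rng = np.random.default_rng(channels * 100 + size)
        block = SCConv(channels, np.random.default_rng(0))
        x = ad.tensor(rng.normal(size=(batch, channels, size, size)).astype(np.float32))
        out = block(x)
        assert out.shape == x.shape
        assert np.all(np.isfinite(out.data))

    def test_batch_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        block = SCConv(8, np.random.default_rng(1))
        x = rng.normal(size=(3, 8, 5, 5)).astype(np.float32)
        out = block(ad.tensor(x)).data
        perm = [2, 0, 1]
        out_perm = block(ad.tensor(x[perm])).data
        assert np.allclose(out[perm], out_perm, atol=1e-5)

    def test_gradient_reaches_gn_scale(self):
        block = SCConv(8, np.random.default_rng(2))
        x = ad.tensor(np.random.default_rng(9).normal(size=(1, 8, 4, 4)).astype(np.float32))
        loss = ad.tmean(ad.mul(block(x), block(x)))
        loss.backward()
        assert block.sru.gn.gamma.grad is not None
        assert np.any(block.sru.gn.gamma.grad != 0)
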