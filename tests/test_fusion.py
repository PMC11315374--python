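"""Unit and property tests for the AFF, HMU and HMUFF fusion blocks."""

import numpy as np
import pytest

from lgnet.errors import ConfigurationError, ShapeMismatchError
from lgnet.fusion import (AFF, HMU, HMUFF, HMUConfig, aff_forward, aff_weights,
                          difference_matrix, flatten_spatial, hmu_forward,
                          hmuff_forward)
from lgnet.tensor import Tensor

import oracles

F64 = np.float64


def make_aff(channels, seed=0):
    return AFF(channels, rng=np.random.default_rng(seed), dtype=F64)


def rand_map(rng, c, h, w, batch=None):
    shape = (c, h, w) if batch is None else (batch, c, h, w)
    return Tensor(rng.standard_normal(shape))


# ---------------------------------------------------------------------- AFF

class TestAFF:
    def test_zero_conv_gives_half_weights(self, rng):
        aff = make_aff(3)
        aff.conv.weight.data[...] = 0
        aff.conv.bias.data[...] = 0
        xl, xg = rand_map(rng, 3, 4, 4), rand_map(rng, 3, 4, 4)
        w = aff_weights(xl, xg, aff)
        assert np.allclose(w.data, 0.5)

    def test_weights_sum_to_one_everywhere(self, rng):
        for seed in range(5):
            aff = make_aff(4, seed=seed)
            xl, xg = rand_map(rng, 4, 5, 3), rand_map(rng, 4, 5, 3)
            w = aff_weights(xl, xg, aff)
            assert w.shape == (2, 5, 3)
            assert np.allclose(w.data.sum(axis=0), 1.0, atol=1e-12)
            assert (w.data >= 0).all() and (w.data <= 1).all()

    def test_scalar_case_matches_brute_force(self):
        # C=1, 1x1 spatial: concat -> conv -> two-way softmax by hand
        aff = make_aff(1, seed=7)
        xl = Tensor(np.array([[[2.0]]]))
        xg = Tensor(np.array([[[-1.0]]]))
        w = aff_weights(xl, xg, aff)
        _, w_ref = oracles.aff_loops(xl.data, xg.data,
                                     aff.conv.weight.data, aff.conv.bias.data)
        assert np.allclose(w.data, w_ref, atol=1e-12)

    def test_identical_inputs_pass_through(self, rng):
        aff = make_aff(2, seed=3)
        x = rand_map(rng, 2, 3, 3)
        out = aff_forward(x, x, aff)
        assert np.allclose(out.data, x.data, atol=1e-12)

    def test_zero_conv_gives_mean(self, rng):
        aff = make_aff(2)
        aff.conv.weight.data[...] = 0
        aff.conv.bias.data[...] = 0
        xl, xg = rand_map(rng, 2, 4, 4), rand_map(rng, 2, 4, 4)
        out = aff_forward(xl, xg, aff)
        assert np.allclose(out.data, (xl.data + xg.data) / 2, atol=1e-12)

    def test_forward_matches_loop_oracle(self, rng):
        aff = make_aff(4, seed=11)
        xl, xg = rand_map(rng, 4, 8, 8), rand_map(rng, 4, 8, 8)
        out = aff_forward(xl, xg, aff)
        ref, _ = oracles.aff_loops(xl.data, xg.data,
                                   aff.conv.weight.data, aff.conv.bias.data)
        assert np.abs(out.data - ref).max() <= 1e-5

    def test_output_is_pointwise_convex(self, rng):
        for seed in range(5):
            aff = make_aff(3, seed=seed)
            xl, xg = rand_map(rng, 3, 6, 6), rand_map(rng, 3, 6, 6)
            out = aff_forward(xl, xg, aff).data
            lo = np.minimum(xl.data, xg.data)
            hi = np.maximum(xl.data, xg.data)
            assert (out >= lo - 1e-12).all() and (out <= hi + 1e-12).all()

    def test_shape_mismatch_reports_both_shapes(self, rng):
        aff = make_aff(3)
        with pytest.raises(ShapeMismatchError, match=r"3, 4, 4.*3, 5, 4"):
            aff_forward(rand_map(rng, 3, 4, 4), rand_map(rng, 3, 5, 4), aff)

    def test_channel_permutation_equivariance(self, rng):
        # permuting both inputs' channels permutes the output channels, when
        # the fusion conv's weights are permuted to match
        c = 4
        perm = np.array([2, 0, 3, 1])
        aff = make_aff(c, seed=5)
        aff_p = make_aff(c, seed=5)
        w = aff.conv.weight.data            # (2, 2C, 3, 3)
        aff_p.conv.weight.data = np.concatenate(
            [w[:, :c][:, perm], w[:, c:][:, perm]], axis=1)
        xl, xg = rand_map(rng, c, 5, 5), rand_map(rng, c, 5, 5)
        base = aff_forward(xl, xg, aff).data
        permuted = aff_forward(Tensor(xl.data[perm]), Tensor(xg.data[perm]), aff_p).data
        assert np.allclose(permuted, base[perm], atol=1e-10)


# ---------------------------------------------------------------------- HMU

class TestHMU:
    def test_expanded_width_rounding(self):
        cfg = HMUConfig(groups=4, expansion=2.0)
        assert cfg.expanded_width(16) == 36        # smallest multiple of 12 >= 32
        assert cfg.expanded_width(6) == 12
        assert HMUConfig(groups=2).expanded_width(3) == 6

    def test_invalid_pinned_width_raises(self):
        cfg = HMUConfig(groups=4, expanded_channels=32)
        with pytest.raises(ConfigurationError, match="32"):
            cfg.expanded_width(16)

    def test_output_shape_preserved(self, rng):
        hmu = HMU(6, HMUConfig(groups=2), rng=np.random.default_rng(0), dtype=F64)
        x = rand_map(rng, 6, 3, 5)
        assert hmu_forward(x, hmu).shape == x.shape

    def test_zeroed_projection_is_identity(self, rng):
        hmu = HMU(8, rng=np.random.default_rng(1), dtype=F64)
        hmu.zero_output_branch()
        x = rand_map(rng, 8, 4, 4)
        assert np.allclose(hmu_forward(x, hmu).data, x.data, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_unrolled_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cfg = HMUConfig(groups=2)
        hmu = HMU(6, cfg, rng=np.random.default_rng(seed + 100), dtype=F64)
        hmu.eval()
        x = Tensor(rng.standard_normal((6, 2, 2)))
        out = hmu_forward(x, hmu)
        ref = oracles.hmu_loops(x.data, hmu)
        assert np.abs(out.data - ref).max() <= 1e-5

    def test_relu_residual_variant(self, rng):
        cfg = HMUConfig(residual_activation="relu")
        hmu = HMU(4, cfg, rng=np.random.default_rng(2), dtype=F64)
        hmu.zero_output_branch()
        x = rand_map(rng, 4, 3, 3)
        assert np.allclose(hmu_forward(x, hmu).data, np.maximum(x.data, 0))


# ---------------------------------------------------- flatten and difference

class TestFlattenAndDifference:
    def test_row_major_order(self):
        x = Tensor(np.array([[[1.0, 2.0], [3.0, 4.0]]]))
        fh = flatten_spatial(x)
        assert fh.values.data.tolist() == [[1, 2, 3, 4]]
        assert fh.positions == 4

    def test_round_trip(self, rng):
        x = rand_map(rng, 3, 5, 7)
        fh = flatten_spatial(x)
        assert fh.values.shape == (3, 35)
        assert np.array_equal(fh.unflatten().data, x.data)

    def test_single_position_matrix_is_one(self, rng):
        fh1 = flatten_spatial(rand_map(rng, 2, 1, 1))
        fh2 = flatten_spatial(rand_map(rng, 2, 1, 1))
        md = difference_matrix(fh1, fh2)
        assert md.values.data.shape == (1, 1)
        assert np.allclose(md.values.data, 1.0)

    def test_zero_features_give_uniform_matrix(self, rng):
        fh1 = flatten_spatial(rand_map(rng, 2, 2, 2))
        fh2 = flatten_spatial(Tensor(np.zeros((2, 1, 3))))
        md = difference_matrix(fh1, fh2, "rows")
        assert np.allclose(md.values.data, 1.0 / 3.0)

    def test_hand_computed_log2_example(self):
        # choose C=2 features whose Gram matrix is [[0, ln2], [ln2, 0]];
        # row softmax of its negation is [[2/3, 1/3], [1/3, 2/3]]
        ln2 = np.log(2.0)
        fh1 = flatten_spatial(Tensor(np.eye(2).reshape(2, 1, 2)))
        fh2 = flatten_spatial(Tensor(np.array([[0.0, ln2], [ln2, 0.0]]).reshape(2, 1, 2)))
        md = difference_matrix(fh1, fh2, "rows")
        expected = np.array([[2 / 3, 1 / 3], [1 / 3, 2 / 3]])
        assert np.allclose(md.values.data, expected, atol=1e-12)

    @pytest.mark.parametrize("axis,sum_axis", [("rows", -1), ("cols", -2)])
    def test_stochastic_along_normalised_axis(self, rng, axis, sum_axis):
        fh1 = flatten_spatial(rand_map(rng, 4, 3, 2))
        fh2 = flatten_spatial(rand_map(rng, 4, 2, 2))
        md = difference_matrix(fh1, fh2, axis)
        assert (md.values.data > 0).all()
        assert np.allclose(md.values.data.sum(axis=sum_axis), 1.0, atol=1e-6)

    def test_channel_mismatch_raises(self, rng):
        fh1 = flatten_spatial(rand_map(rng, 3, 2, 2))
        fh2 = flatten_spatial(rand_map(rng, 4, 2, 2))
        with pytest.raises(ShapeMismatchError):
            difference_matrix(fh1, fh2)


# -------------------------------------------------------------------- HMUFF

class TestHMUFF:
    def test_shapes_preserved(self, rng):
        hm = HMUFF(6, HMUConfig(groups=2), rng=np.random.default_rng(0), dtype=F64)
        x1, x2 = rand_map(rng, 6, 4, 4), rand_map(rng, 6, 2, 3)
        x12, x21 = hmuff_forward(x1, x2, hm)
        assert x12.shape == x1.shape and x21.shape == x2.shape

    def test_identity_hmu_with_zero_second_input(self, rng):
        hm = HMUFF(4, rng=np.random.default_rng(1), dtype=F64)
        hm.hmu1.zero_output_branch()
        hm.hmu2.zero_output_branch()
        x1 = rand_map(rng, 4, 3, 3)
        x2 = Tensor(np.zeros((4, 2, 2)))
        x12, x21 = hmuff_forward(x1, x2, hm)
        assert np.allclose(x12.data, x1.data, atol=1e-12)
        spatial_mean = x1.data.mean(axis=(1, 2))
        assert np.allclose(x21.data, spatial_mean[:, None, None], atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        hm = HMUFF(6, HMUConfig(groups=2), rng=np.random.default_rng(seed + 50),
                   dtype=F64)
        hm.eval()
        x1 = Tensor(rng.standard_normal((6, 1, 2)))
        x2 = Tensor(rng.standard_normal((6, 1, 3)))
        x12, x21 = hmuff_forward(x1, x2, hm)
        ref12, ref21 = oracles.hmuff_loops(x1.data, x2.data, hm)
        assert np.abs(x12.data - ref12).max() <= 1e-5
        assert np.abs(x21.data - ref21).max() <= 1e-5

    def test_channel_mismatch_raises(self, rng):
        hm = HMUFF(4, rng=np.random.default_rng(0), dtype=F64)
        with pytest.raises(ShapeMismatchError):
            hmuff_forward(rand_map(rng, 3, 2, 2), rand_map(rng, 4, 2, 2), hm)


# ----------------------------------------------------------- differentiability

def test_all_blocks_receive_gradients(rng):
    """Every learnable parameter of each block gets a finite, nonzero
    gradient from a scalar loss on seeded inputs."""
    aff = make_aff(4, seed=9)
    hm = HMUFF(4, rng=np.random.default_rng(9), dtype=F64)
    xl = rand_map(rng, 4, 4, 4, batch=2)
    xg = rand_map(rng, 4, 4, 4, batch=2)
    x2 = rand_map(rng, 4, 2, 2, batch=2)
    fused = aff(xl, xg)
    a, b = hm(fused, x2)
    loss = (a * a).sum() + (b * b).sum()
    loss.backward()
    for module in (aff, hm):
        for name, p in module.named_parameters():
            assert p.grad is not None, name
            assert np.isfinite(p.grad).all(), name
            assert np.abs(p.grad).max() > 0, name
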