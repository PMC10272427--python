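"""Attention block: pooling oracles, branch behaviour, composition."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gabnet.attention import (
    AttentionMaps,
    GabParams,
    GlobalAttentionBlock,
    channel_attention,
    gab_apply,
    gab_param_count,
    height_attention,
    pool_channel_global,
    pool_height,
    pool_width,
    width_attention,
)
from gabnet.nn import Tensor


# ------------------------------------------------------------ loop oracles
def pool_loop(t, axis_kind, mode):
    """Naive triple-loop pooling reference."""
    m, n, k = t.shape
    red = np.mean if mode == "avg" else np.max
    if axis_kind == "height":
        out = np.zeros((1, n, k))
        for j in range(n):
            for c in range(k):
                out[0, j, c] = red([t[i, j, c] for i in range(m)])
    elif axis_kind == "width":
        out = np.zeros((m, 1, k))
        for i in range(m):
            for c in range(k):
                out[i, 0, c] = red([t[i, j, c] for j in range(n)])
    else:
        out = np.zeros((1, 1, k))
        for c in range(k):
            out[0, 0, c] = red([t[i, j, c] for i in range(m) for j in range(n)])
    return out


def make_block(k, r=2, seed=0, **kwargs) -> GlobalAttentionBlock:
    blk = GlobalAttentionBlock(k, GabParams(reduction_ratio=r, **kwargs),
                               rng=np.random.default_rng(seed))
    blk.eval()
    return blk


class TestPooling:
    def test_hand_worked_examples(self):
        assert pool_height(np.array([1.0, 3.0]).reshape(2, 1, 1), "avg")[0, 0, 0] == 2.0
        t = np.array([2.0, 6.0]).reshape(1, 2, 1)
        assert pool_width(t, "avg")[0, 0, 0] == 4.0
        assert pool_width(t, "max")[0, 0, 0] == 6.0
        q = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(2, 2, 1)
        assert pool_channel_global(q, "avg")[0, 0, 0] == 2.5
        assert pool_channel_global(q, "max")[0, 0, 0] == 4.0

    def test_constant_map_pools_to_constant(self):
        t = np.full((4, 5, 3), 7.25)
        for mode in ("avg", "max"):
            assert np.allclose(pool_height(t, mode), 7.25)
            assert np.allclose(pool_width(t, mode), 7.25)
            assert np.allclose(pool_channel_global(t, mode), 7.25)

    @pytest.mark.parametrize("mode", ["avg", "max"])
    def test_matches_loop_oracle(self, rng, mode):
        t = rng.normal(size=(5, 4, 3))
        assert np.allclose(pool_height(t, mode), pool_loop(t, "height", mode), atol=1e-12)
        assert np.allclose(pool_width(t, mode), pool_loop(t, "width", mode), atol=1e-12)
        t2 = rng.normal(size=(7, 5, 4))
        assert np.allclose(
            pool_channel_global(t2, mode), pool_loop(t2, "channel", mode), atol=1e-12
        )

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            pool_height(np.zeros((0, 3, 2)))
        with pytest.raises(ValueError):
            pool_width(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            pool_height(np.zeros((2, 2, 2)), mode="median")
        with pytest.raises(ValueError):
            pool_height(np.full((2, 2, 2), np.nan))


class TestBranches:
    def test_shape_contracts(self, rng):
        t = rng.normal(size=(8, 16, 32))
        blk = make_block(32, r=8)
        assert height_attention(t, blk).shape == (1, 16, 32)
        assert width_attention(t, blk).shape == (8, 1, 32)
        assert channel_attention(t, blk).shape == (1, 1, 32)

    def test_zeroed_transform_gives_half(self, rng):
        """If f's output is forced to zero pre-sigmoid, spatial weights are 0.5."""
        blk = make_block(6, r=2)
        blk.f.steps[0].weight.data[:] = 0.0
        blk.f.steps[1].freeze_identity()
        t = rng.normal(size=(4, 5, 6))
        assert np.allclose(height_attention(t, blk), 0.5, atol=1e-7)
        assert np.allclose(width_attention(t, blk), 0.5, atol=1e-7)

    def test_zeroed_mlp_gives_unit_channel_weights(self, rng):
        """W0 = W1 = 0 makes every channel weight sigmoid(0)+sigmoid(0) = 1."""
        blk = make_block(6, r=2)
        for layer in (blk.w0, blk.w1):
            layer.weight.data[:] = 0.0
            layer.bias.data[:] = 0.0
        t = rng.normal(size=(4, 5, 6))
        assert np.allclose(channel_attention(t, blk), 1.0, atol=1e-7)

    def test_channel_weights_in_open_interval_0_2(self, rng):
        blk = make_block(8, r=4, seed=3)
        for _ in range(20):
            c = channel_attention(rng.normal(size=(5, 6, 8)), blk)
            assert np.all(c > 0) and np.all(c < 2)

    def test_cbam_style_channel_range(self, rng):
        blk = make_block(8, r=4, cbam_style_channel=True)
        c = channel_attention(rng.normal(size=(5, 6, 8)), blk)
        assert np.all(c > 0) and np.all(c < 1)

    def test_channel_branch_manual_composition(self, rng):
        """Hand-set W0/W1 weights reproduce explicit matrix arithmetic."""
        blk = make_block(4, r=2, seed=7)
        w0 = rng.normal(size=(4, 2)).astype(np.float32)
        b0 = rng.normal(size=2).astype(np.float32)
        w1 = rng.normal(size=(2, 4)).astype(np.float32)
        b1 = rng.normal(size=4).astype(np.float32)
        blk.w0.weight.data, blk.w0.bias.data = w0, b0
        blk.w1.weight.data, blk.w1.bias.data = w1, b1
        t = rng.normal(size=(3, 5, 4)).astype(np.float32)

        def mlp(v):
            hidden = np.maximum(v @ w0 + b0, 0)
            return 1 / (1 + np.exp(-(hidden @ w1 + b1)))

        expected = mlp(t.mean(axis=(0, 1))) + mlp(t.max(axis=(0, 1)))
        assert np.allclose(channel_attention(t, blk).ravel(), expected, atol=1e-5)

    def test_spatial_branch_manual_composition(self, rng):
        """Hand-set d/f weights with identity BN reproduce the pipeline by hand."""
        blk = make_block(3, r=1, seed=5)
        dw = rng.normal(size=(6, 3)).astype(np.float32)
        fw = rng.normal(size=(3, 3)).astype(np.float32)
        blk.d.steps[0].weight.data = dw
        blk.f.steps[0].weight.data = fw
        blk.d.steps[1].freeze_identity()
        blk.f.steps[1].freeze_identity()
        t = rng.normal(size=(4, 5, 3)).astype(np.float32)
        pooled = np.concatenate(
            [t.mean(axis=0, keepdims=True), t.max(axis=0, keepdims=True)], axis=2
        )
        hidden = np.maximum(pooled @ dw, 0)
        expected = 1 / (1 + np.exp(-np.maximum(hidden @ fw, 0)))
        assert np.allclose(height_attention(t, blk), expected, atol=1e-5)

    def test_channel_mismatch_raises(self, rng):
        blk = make_block(8)
        with pytest.raises(ValueError):
            height_attention(rng.normal(size=(4, 4, 5)), blk)


class _UnitMapsBlock(GlobalAttentionBlock):
    """Attention block with all three maps forced to one (identity limit)."""

    def height_branch(self, x):
        return Tensor(np.ones((x.shape[0], 1, x.shape[2], x.shape[3])))

    def width_branch(self, x):
        return Tensor(np.ones((x.shape[0], x.shape[1], 1, x.shape[3])))

    def channel_branch(self, x):
        return Tensor(np.ones((x.shape[0], 1, 1, x.shape[3])))


class TestGabApply:
    def test_output_is_product_of_branch_maps(self, rng):
        t = rng.normal(size=(6, 5, 8))
        blk = make_block(8, r=4, seed=2)
        maps = gab_apply(t, blk)
        h = height_attention(t, blk)
        w = width_attention(t, blk)
        c = channel_attention(t, blk)
        assert np.allclose(maps.output, t * h * w * c, atol=1e-6)
        assert np.allclose(maps.height_map, h) and np.allclose(maps.width_map, w)

    def test_unit_maps_reproduce_input(self, rng):
        blk = _UnitMapsBlock(5, GabParams(), rng=np.random.default_rng(0))
        blk.eval()
        t = rng.normal(size=(7, 4, 5))
        maps = gab_apply(t, blk)
        assert np.allclose(maps.output, t, atol=1e-6)

    def test_zero_map_annihilates(self, rng):
        t = rng.normal(size=(4, 4, 3))
        blk = make_block(3, r=1)
        maps = gab_apply(t, blk)
        assert np.allclose(t * maps.height_map * maps.width_map * 0.0, 0.0)

    @settings(max_examples=30, deadline=None)
    @given(
        m=st.integers(1, 9),
        n=st.integers(1, 9),
        k=st.integers(1, 12),
        seed=st.integers(0, 100),
    )
    def test_shape_preserved_and_bounded(self, m, n, k, seed):
        rng = np.random.default_rng(seed)
        blk = GlobalAttentionBlock(k, GabParams(reduction_ratio=4),
                                   rng=np.random.default_rng(seed + 1))
        blk.eval()
        t = rng.normal(size=(m, n, k))
        maps = gab_apply(t, blk)
        assert maps.output.shape == (m, n, k)
        assert np.all(maps.height_map > 0) and np.all(maps.height_map < 1)
        assert np.all(maps.width_map > 0) and np.all(maps.width_map < 1)
        assert np.all(maps.channel_map > 0) and np.all(maps.channel_map < 2)
        assert np.all(np.abs(maps.output) <= 2 * np.abs(t) + 1e-9)


class TestParamCount:
    @pytest.mark.parametrize("k,r", [(32, 8), (8, 2), (5, 3), (1, 1), (64, 64)])
    def test_matches_introspection(self, k, r):
        blk = GlobalAttentionBlock(k, GabParams(reduction_ratio=r),
                                   rng=np.random.default_rng(0))
        assert gab_param_count(k, r) == blk.num_parameters()

    def test_monotone_in_channels(self):
        counts = [gab_param_count(k, 8) for k in range(1, 65)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_maximal_reduction_is_smaller(self):
        for k in (8, 32, 128):
            assert gab_param_count(k, k) < gab_param_count(k, 1)
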