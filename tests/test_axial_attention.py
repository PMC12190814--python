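"""Axial attention: folding, oracle equivalences, complexity accounting."""

import numpy as np
import pytest

from wiafnet.axial_attention import (AXES, AxialAttentionParams, IAFAttention,
                                     IAFTBlock, IAFTBlockParams, TokenSequence,
                                     attention_mac_count, axial_mhsa,
                                     fold_axis, full_mhsa_oracle,
                                     iaf_attention, iaft_block, unfold_axis)
from wiafnet.autodiff import Tensor


class TestFolding:
    def test_height_fold_shape_matches_contract(self, rng):
        t = TokenSequence(rng.normal(size=(1, 24, 5)), (2, 3, 4))
        assert fold_axis(t, "H").shape == (12, 2, 5)

    def test_depth_fold_matches_reindexing_oracle(self, rng):
        t = TokenSequence(rng.normal(size=(1, 24, 5)), (2, 3, 4))
        grid = t.data.reshape(1, 2, 3, 4, 5)
        fd = fold_axis(t, "D")
        assert fd.shape == (6, 4, 5)
        m = 0
        for h in range(2):
            for w in range(3):
                np.testing.assert_array_equal(fd[m], grid[0, h, w])
                m += 1

    @pytest.mark.parametrize("axis", AXES)
    def test_fold_unfold_roundtrip(self, axis, rng):
        t = TokenSequence(rng.normal(size=(2, 60, 3)), (3, 4, 5))
        back = unfold_axis(fold_axis(t, axis), axis, t.dims, 2)
        np.testing.assert_array_equal(back.data, t.data)

    def test_invalid_axis_raises(self, rng):
        t = TokenSequence(rng.normal(size=(1, 8, 2)), (2, 2, 2))
        with pytest.raises(ValueError):
            fold_axis(t, "X")

    def test_dims_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            TokenSequence(rng.normal(size=(1, 9, 2)), (2, 2, 2))


class TestAxialMHSA:
    def test_singleton_axis_is_value_output_projection(self, rng):
        p = AxialAttentionParams.create(4, 2, rng)
        x = rng.normal(size=(3, 1, 4))
        want = (x @ p.WV.T + p.bV) @ p.WO.T + p.bO
        np.testing.assert_allclose(axial_mhsa(x, p), want, atol=1e-12)

    def test_constant_values_collapse_to_common_row(self, rng):
        # softmax rows are convex weights; identical V rows pass through
        p = AxialAttentionParams.create(4, 1, rng)
        p.WV[:] = 0.0
        p.bV[:] = rng.normal(size=4)
        x = rng.normal(size=(2, 5, 4))
        out = axial_mhsa(x, p)
        want = np.broadcast_to(p.bV @ p.WO.T + p.bO, out.shape)
        np.testing.assert_allclose(out, want, atol=1e-10)

    def test_matches_dense_hand_rolled_oracle(self, rng):
        p = AxialAttentionParams.create(4, 1, rng)
        x = rng.normal(size=(1, 3, 4))
        q, k, v = x @ p.WQ.T, x @ p.WK.T, x @ p.WV.T
        s = q @ k.transpose(0, 2, 1) / np.sqrt(4)
        e = np.exp(s - s.max(-1, keepdims=True))
        a = e / e.sum(-1, keepdims=True)
        want = (a @ v) @ p.WO.T
        np.testing.assert_allclose(axial_mhsa(x, p), want, atol=1e-6)

    def test_multihead_matches_per_head_dense_computation(self, rng):
        C, h = 6, 2
        p = AxialAttentionParams.create(C, h, rng)
        x = rng.normal(size=(1, 4, C))
        got = axial_mhsa(x, p)
        q = (x @ p.WQ.T).reshape(1, 4, h, 3).transpose(0, 2, 1, 3)
        k = (x @ p.WK.T).reshape(1, 4, h, 3).transpose(0, 2, 1, 3)
        v = (x @ p.WV.T).reshape(1, 4, h, 3).transpose(0, 2, 1, 3)
        s = q @ k.transpose(0, 1, 3, 2) / np.sqrt(3)
        e = np.exp(s - s.max(-1, keepdims=True))
        a = e / e.sum(-1, keepdims=True)
        want = (a @ v).transpose(0, 2, 1, 3).reshape(1, 4, C) @ p.WO.T
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_head_divisibility_enforced(self, rng):
        with pytest.raises(ValueError):
            AxialAttentionParams.create(5, 2, rng)


class TestIAFAttention:
    def test_zero_value_projection_is_identity(self, rng):
        params = {}
        for ax in AXES:
            p = AxialAttentionParams.create(4, 1, rng)
            p.WV[:] = 0.0
            params[ax] = p
        t = TokenSequence(rng.normal(size=(1, 8, 4)), (2, 2, 2))
        for mode in ("sequential", "summed"):
            out = iaf_attention(t, params, mode, 1)
            np.testing.assert_array_equal(out.data, t.data)

    def test_degenerate_grid_equals_full_attention_oracle(self, rng):
        params = {ax: AxialAttentionParams.create(6, 2, rng) for ax in AXES}
        t = TokenSequence(rng.normal(size=(1, 7, 6)), (1, 1, 7))

        def silu(x):
            return x / (1 + np.exp(-x))

        for mode in ("sequential", "summed"):
            got = iaf_attention(t, params, mode, 1).data
            # manual composition: H and W passes degenerate to per-token maps
            z = t.data
            if mode == "sequential":
                for ax in AXES:
                    if ax == "D":
                        a = full_mhsa_oracle(TokenSequence(z, t.dims),
                                             params[ax]).data
                    else:
                        a = axial_mhsa(z.reshape(7, 1, 6),
                                       params[ax]).reshape(1, 7, 6)
                    z = z + silu(a)
            else:
                total = np.zeros_like(z)
                for ax in AXES:
                    if ax == "D":
                        total += full_mhsa_oracle(TokenSequence(z, t.dims),
                                                  params[ax]).data
                    else:
                        total += axial_mhsa(z.reshape(7, 1, 6),
                                            params[ax]).reshape(1, 7, 6)
                z = z + silu(total)
            np.testing.assert_allclose(got, z, atol=1e-6)

    def test_sequential_and_summed_modes_differ(self, rng):
        params = {ax: AxialAttentionParams.create(6, 2, rng) for ax in AXES}
        t = TokenSequence(rng.normal(size=(1, 8, 6)), (2, 2, 2))
        a = iaf_attention(t, params, "sequential", 1).data
        b = iaf_attention(t, params, "summed", 1).data
        assert np.abs(a - b).max() > 0

    def test_iterations_must_be_positive(self, rng):
        params = {ax: AxialAttentionParams.create(4, 1, rng) for ax in AXES}
        t = TokenSequence(rng.normal(size=(1, 8, 4)), (2, 2, 2))
        with pytest.raises(ValueError):
            iaf_attention(t, params, "sequential", 0)

    def test_deterministic_given_parameters(self, rng):
        params = {ax: AxialAttentionParams.create(4, 2, rng) for ax in AXES}
        t = TokenSequence(rng.normal(size=(1, 27, 4)), (3, 3, 3))
        a = iaf_attention(t, params, "sequential", 2).data
        b = iaf_attention(t, params, "sequential", 2).data
        np.testing.assert_array_equal(a, b)


class TestIAFTBlock:
    def test_all_zero_parameters_give_identity(self, rng):
        p = IAFTBlockParams.create(4, 1, 2.0, rng=rng)
        for ax in AXES:
            for name in ("WQ", "WK", "WV", "WO"):
                getattr(p.attn[ax], name)[:] = 0.0
        p.ln1_gamma[:] = 0.0
        p.ln2_gamma[:] = 0.0
        p.mlp_W1[:] = 0.0
        p.mlp_W2[:] = 0.0
        t = TokenSequence(rng.normal(size=(1, 8, 4)), (2, 2, 2))
        out = iaft_block(t, p)
        np.testing.assert_allclose(out.data, t.data, atol=1e-12)

    def test_shape_preserved_and_finite(self, rng):
        p = IAFTBlockParams.create(6, 2, 2.0, rng=rng)
        t = TokenSequence(rng.normal(size=(2, 24, 6)), (2, 3, 4))
        out = iaft_block(t, p)
        assert out.data.shape == t.data.shape
        assert np.all(np.isfinite(out.data))

    def test_module_block_matches_functional_block(self, rng):
        """The trainable Module path and the NumPy path agree numerically."""
        C = 4
        blk = IAFTBlock(C, 2, mlp_ratio=2.0, rng=rng)
        p = IAFTBlockParams.create(C, 2, 2.0, rng=rng)
        # copy Module weights into the functional parameter set
        for ax, mod in zip(AXES, (blk.iaf.attn_h, blk.iaf.attn_w,
                                  blk.iaf.attn_d)):
            p.attn[ax].WQ = mod.q.weight.data.astype(np.float64)
            p.attn[ax].WK = mod.k.weight.data.astype(np.float64)
            p.attn[ax].WV = mod.v.weight.data.astype(np.float64)
            p.attn[ax].WO = mod.o.weight.data.astype(np.float64)
            p.attn[ax].bQ = mod.q.bias.data.astype(np.float64)
            p.attn[ax].bK = mod.k.bias.data.astype(np.float64)
            p.attn[ax].bV = mod.v.bias.data.astype(np.float64)
            p.attn[ax].bO = mod.o.bias.data.astype(np.float64)
        p.mlp_W1 = blk.fc1.weight.data.astype(np.float64)
        p.mlp_b1 = blk.fc1.bias.data.astype(np.float64)
        p.mlp_W2 = blk.fc2.weight.data.astype(np.float64)
        p.mlp_b2 = blk.fc2.bias.data.astype(np.float64)
        x = rng.normal(size=(1, 8, C)).astype(np.float32)
        got = blk(Tensor(x), (2, 2, 2)).data
        want = iaft_block(TokenSequence(x.astype(np.float64), (2, 2, 2)), p).data
        np.testing.assert_allclose(got, want, atol=1e-5)


class TestFullOracle:
    def test_single_token_is_value_projection(self, rng):
        p = AxialAttentionParams.create(4, 1, rng)
        t = TokenSequence(rng.normal(size=(1, 1, 4)), (1, 1, 1))
        out = full_mhsa_oracle(t, p)
        want = (t.data @ p.WV.T + p.bV) @ p.WO.T + p.bO
        np.testing.assert_allclose(out.data, want, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        p = AxialAttentionParams.create(4, 2, rng)
        t = TokenSequence(rng.normal(size=(1, 6, 4)), (1, 1, 6))
        perm = rng.permutation(6)
        out = full_mhsa_oracle(t, p).data
        out_p = full_mhsa_oracle(
            TokenSequence(t.data[:, perm], t.dims), p).data
        np.testing.assert_allclose(out_p, out[:, perm], atol=1e-10)

    def test_guard_on_token_count(self, rng):
        p = AxialAttentionParams.create(2, 1, rng)
        t = TokenSequence(np.zeros((1, 8, 2)), (2, 2, 2))
        with pytest.raises(ValueError, match="guard"):
            full_mhsa_oracle(t, p, max_tokens=4)

    def test_softmax_rows_sum_to_one_convex_hull(self, rng):
        # outputs lie in the convex hull of value rows per head
        p = AxialAttentionParams.create(4, 1, rng)
        p.WO[:] = np.eye(4)
        p.bO[:] = 0.0
        x = rng.normal(size=(1, 5, 4))
        v = x @ p.WV.T + p.bV
        out = full_mhsa_oracle(TokenSequence(x, (1, 1, 5)), p).data
        assert np.all(out[0].min(axis=0) >= v[0].min(axis=0) - 1e-9)
        assert np.all(out[0].max(axis=0) <= v[0].max(axis=0) + 1e-9)


class TestMacCount:
    def test_cube_doubling_ratios(self):
        a8 = attention_mac_count((8, 8, 8), 16, 1, "axial")
        a16 = attention_mac_count((16, 16, 16), 16, 1, "axial")
        assert a16.score_value / a8.score_value == 16          # 8^(4/3)
        f8 = attention_mac_count((8, 8, 8), 16, 1, "full")
        f16 = attention_mac_count((16, 16, 16), 16, 1, "full")
        assert f16.score_value / f8.score_value == 64          # N^2

    def test_degenerate_line_grid_counts_coincide(self):
        a = attention_mac_count((1, 1, 9), 16, 1, "axial")
        f = attention_mac_count((1, 1, 9), 16, 1, "full")
        assert a.score_value == f.score_value

    def test_loglog_exponent_four_thirds(self):
        sides = [4, 8, 16, 32]
        sv = [attention_mac_count((s, s, s), 16, 1, "axial").score_value
              for s in sides]
        n = [s ** 3 for s in sides]
        slope = np.polyfit(np.log(n), np.log(sv), 1)[0]
        assert abs(slope - 4 / 3) < 4 / 3 * 0.01

    def test_heads_do_not_change_totals(self):
        a = attention_mac_count((4, 4, 4), 16, 1, "axial")
        b = attention_mac_count((4, 4, 4), 16, 4, "axial")
        assert a == b
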