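"""Wavelet front end: filter values, transform oracles, gating, HDF5 I/O."""

import itertools

import numpy as np
import pytest

from wiafnet.wavelet_frontend import (BAND_ORDER, FilterBank, GateParams,
                                      MultiChannelVolume, SubbandStack,
                                      awdfd_forward, dwt3, gate_weights,
                                      haar_analysis_filters, idwt3,
                                      load_filter_bank, recalibrate,
                                      save_filter_bank)

SQRT2 = np.sqrt(2.0)


def brute_force_dwt3(x, low, high):
    """Direct (non-separable) 8-filter 3D convolution + stride-2 decimation."""
    C, H, W, D = x.shape
    out = np.zeros((8 * C, H // 2, W // 2, D // 2))
    filters = list(itertools.product([low, high], repeat=3))
    for c in range(C):
        for bi, (fa, fb, fc) in enumerate(filters):
            kern = np.einsum("p,q,r->pqr", fa, fb, fc)
            for i in range(H // 2):
                for j in range(W // 2):
                    for k in range(D // 2):
                        out[8 * c + bi, i, j, k] = np.sum(
                            kern * x[c, 2 * i:2 * i + 2, 2 * j:2 * j + 2,
                                     2 * k:2 * k + 2])
    return out


class TestFilters:
    def test_orthonormal_haar_values(self):
        fb = haar_analysis_filters()
        np.testing.assert_allclose(fb.low, [0.7071068, 0.7071068], atol=1e-7)
        np.testing.assert_allclose(fb.high, [0.7071068, -0.7071068], atol=1e-7)
        assert abs(np.dot(fb.low, fb.high)) < 1e-15
        assert abs(np.dot(fb.low, fb.low) - 1) < 1e-15

    def test_filter_bank_rejects_bad_length(self):
        with pytest.raises(ValueError):
            FilterBank(low=np.ones(3), high=np.ones(3))


class TestDWT:
    def test_constant_volume_has_only_lll(self):
        sub = dwt3(MultiChannelVolume(np.ones((1, 2, 2, 2))))
        assert sub.data[0, 0, 0, 0] == pytest.approx(2 * SQRT2, abs=1e-12)
        assert np.abs(sub.data[1:]).max() == 0.0

    def test_impulse_matches_brute_force_oracle(self):
        x = np.zeros((1, 2, 2, 2))
        x[0, 0, 0, 0] = 1.0
        fb = haar_analysis_filters()
        got = dwt3(MultiChannelVolume(x)).data
        want = brute_force_dwt3(x, fb.low, fb.high)
        np.testing.assert_allclose(got, want, atol=1e-12)
        # every band sees a single coefficient of magnitude (1/sqrt 2)^3
        np.testing.assert_allclose(np.abs(got).max(axis=(1, 2, 3)),
                                   (1 / SQRT2) ** 3, atol=1e-12)

    def test_matches_oracle_on_random_volumes(self, rng):
        fb = haar_analysis_filters()
        for _ in range(5):
            x = rng.normal(size=(2, 4, 4, 4))
            got = dwt3(MultiChannelVolume(x)).data
            want = brute_force_dwt3(x, fb.low, fb.high)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_parseval_energy_conservation(self, rng):
        x = rng.normal(size=(2, 4, 4, 4))
        sub = dwt3(MultiChannelVolume(x))
        rel = abs((sub.data ** 2).sum() - (x ** 2).sum()) / (x ** 2).sum()
        assert rel < 1e-6

    def test_odd_dimension_raises(self):
        with pytest.raises(ValueError, match="even"):
            dwt3(MultiChannelVolume(np.ones((1, 3, 4, 4))))

    def test_agrees_with_pywavelets(self, rng):
        pywt = pytest.importorskip("pywt")
        x = rng.normal(size=(6, 8, 10))
        got = dwt3(MultiChannelVolume(x[None])).data
        coeffs = pywt.dwtn(x, "haar", axes=(0, 1, 2))
        key = {"L": "a", "H": "d"}
        for bi, band in enumerate(BAND_ORDER):
            want = coeffs["".join(key[ch] for ch in band)]
            np.testing.assert_allclose(got[bi], want, atol=1e-10)


class TestIDWT:
    def test_roundtrip_identity(self, rng):
        x = rng.normal(size=(1, 4, 4, 4))
        back = idwt3(dwt3(MultiChannelVolume(x)))
        np.testing.assert_allclose(back.data, x, atol=1e-6)

    def test_zero_stack_gives_zero_volume(self):
        out = idwt3(SubbandStack(np.zeros((8, 2, 2, 2))))
        assert np.abs(out.data).max() == 0.0

    def test_single_lll_coefficient_spreads_constant_block(self):
        y = np.zeros((8, 2, 2, 2))
        y[0, 0, 0, 0] = 1.0
        out = idwt3(SubbandStack(y)).data
        np.testing.assert_allclose(out[0, :2, :2, :2], 1 / (2 * SQRT2),
                                   atol=1e-12)
        assert np.abs(out[0, 2:]).max() == 0.0

    def test_malformed_channel_count_raises(self):
        with pytest.raises(ValueError, match="8C"):
            SubbandStack(np.zeros((6, 2, 2, 2)))


class TestGate:
    def test_zero_params_give_half_weights(self, rng):
        sub = dwt3(MultiChannelVolume(rng.normal(size=(1, 4, 4, 4))))
        p = GateParams(W1=np.zeros((2, 8)), b1=np.zeros(2),
                       W2=np.zeros((8, 2)), b2=np.zeros(8))
        np.testing.assert_allclose(gate_weights(sub, p), 0.5, atol=1e-15)

    def test_weights_strictly_in_unit_interval(self, rng):
        sub = dwt3(MultiChannelVolume(rng.normal(size=(2, 4, 4, 4)) * 50))
        p = GateParams.create(16, reduction_ratio=4, rng=rng)
        w = gate_weights(sub, p)
        assert w.shape == (16,)
        assert np.all(w > 0) and np.all(w < 1)

    def test_invariant_to_spatial_permutation(self, rng):
        data = rng.normal(size=(8, 2, 2, 2))
        p = GateParams.create(8, reduction_ratio=4, rng=rng)
        w1 = gate_weights(SubbandStack(data), p)
        perm = rng.permutation(8)  # permute voxels within each channel
        shuffled = data.reshape(8, -1)[:, perm].reshape(data.shape)
        w2 = gate_weights(SubbandStack(shuffled), p)
        np.testing.assert_allclose(w1, w2, atol=1e-12)

    def test_expansion_hidden_width(self, rng):
        p = GateParams.create(8, hidden=20, rng=rng)
        assert p.W1.shape == (20, 8)
        assert p.n_params == 20 * 8 + 20 + 8 * 20 + 8


class TestRecalibrate:
    def test_identity_and_annihilation(self, rng):
        sub = SubbandStack(rng.normal(size=(8, 2, 2, 2)))
        np.testing.assert_array_equal(
            recalibrate(sub, np.ones(8)).data, sub.data)
        assert np.abs(recalibrate(sub, np.zeros(8)).data).max() == 0.0

    def test_channel_means_scale_elementwise(self):
        data = np.stack([np.full((2, 2, 2), 1.0), np.full((2, 2, 2), 2.0)])
        out = recalibrate(SubbandStack(np.tile(data, (4, 1, 1, 1))),
                          np.tile([0.25, 0.5], 4))
        means = out.data.mean(axis=(1, 2, 3))
        np.testing.assert_allclose(means, np.tile([0.25, 1.0], 4), atol=1e-12)

    def test_length_mismatch_raises(self, rng):
        sub = SubbandStack(rng.normal(size=(8, 2, 2, 2)))
        with pytest.raises(ValueError):
            recalibrate(sub, np.ones(7))


class TestAWDFD:
    def test_output_shape_halves_spatial_dims(self, rng):
        vol = MultiChannelVolume(rng.normal(size=(4, 16, 16, 16)))
        gate = GateParams.create(32, rng=rng)
        proj = rng.normal(size=(12, 32))
        out = awdfd_forward(vol, gate, proj, np.zeros(12))
        assert out.data.shape == (12, 8, 8, 8)

    def test_zero_input_zero_bias_gives_zero(self, rng):
        vol = MultiChannelVolume(np.zeros((4, 8, 8, 8)))
        gate = GateParams.create(32, rng=rng)
        out = awdfd_forward(vol, gate, rng.normal(size=(6, 32)))
        assert np.abs(out.data).max() == 0.0


class TestSerialization:
    def test_hdf5_roundtrip_reproduces_dwt_bit_identically(self, tmp_path, rng):
        path = tmp_path / "haar.h5"
        save_filter_bank(path)
        fb = load_filter_bank(path)
        x = MultiChannelVolume(rng.normal(size=(2, 4, 4, 4)))
        a = dwt3(x, haar_analysis_filters()).data
        b = dwt3(x, fb).data
        np.testing.assert_array_equal(a, b)
        assert fb.normalization == "orthonormal"
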