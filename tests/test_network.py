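"""Model assembly: pyramid shapes, variants, budget accounting."""

import numpy as np
import pytest

from wiafnet import budgets
from wiafnet.autodiff import Tensor
from wiafnet.config import DecoderConfig, ModelConfig
from wiafnet.network import (WIAF, FeaturePyramid, build_variant, count_macs,
                             count_params, encoder_forward, msffd_forward,
                             wiaf_forward)
from wiafnet.pipeline import _one_hot, training_loss

VARIANTS = ("full", "B", "B+MSFFD", "B+MSFFD+IAFT")


@pytest.fixture(scope="module")
def tiny_model(request):
    return WIAF(ModelConfig.desk(), seed=0)


class TestEncoder:
    def test_pyramid_shapes_halve_per_level(self, tiny_model, rng):
        x = rng.normal(size=(4, 32, 32, 32)).astype(np.float32)
        pyr = encoder_forward(tiny_model, x)
        shapes = [f.shape for f in pyr.features]
        c = tiny_model.cfg.stage_channels
        assert shapes == [(c[0], 16, 16, 16), (c[1], 8, 8, 8),
                          (c[2], 4, 4, 4), (c[3], 2, 2, 2)]

    def test_indivisible_dims_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="divisible by 16"):
            tiny_model.encode(Tensor(np.zeros((1, 4, 24, 24, 24),
                                              dtype=np.float32)))

    def test_encoder_is_deterministic(self, tiny_model, rng):
        x = rng.normal(size=(4, 32, 32, 32)).astype(np.float32)
        a = encoder_forward(tiny_model, x).features
        b = encoder_forward(tiny_model, x).features
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_feature_pyramid_validates_halving(self, rng):
        good = [rng.normal(size=(2, 8, 8, 8)), rng.normal(size=(2, 4, 4, 4)),
                rng.normal(size=(2, 2, 2, 2)), rng.normal(size=(2, 1, 1, 1))]
        FeaturePyramid(good)
        bad = list(good)
        bad[1] = rng.normal(size=(2, 5, 4, 4))
        with pytest.raises(ValueError):
            FeaturePyramid(bad)


class TestForward:
    def test_logits_shape_matches_input(self, tiny_model, rng):
        x = rng.normal(size=(4, 32, 32, 32)).astype(np.float32)
        logits = wiaf_forward(tiny_model, x)
        assert logits.shape == (4, 32, 32, 32)

    def test_softmax_over_classes_sums_to_one(self, tiny_model, rng):
        x = rng.normal(size=(4, 32, 32, 32)).astype(np.float32)
        logits = wiaf_forward(tiny_model, x)
        e = np.exp(logits - logits.max(axis=0))
        p = e / e.sum(axis=0)
        np.testing.assert_allclose(p.sum(axis=0), 1.0, atol=1e-5)

    def test_two_passes_bit_identical(self, tiny_model, rng):
        x = rng.normal(size=(4, 32, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(wiaf_forward(tiny_model, x),
                                      wiaf_forward(tiny_model, x))

    def test_decoder_runs_from_pyramid(self, tiny_model, rng):
        x = rng.normal(size=(4, 32, 32, 32)).astype(np.float32)
        pyr = encoder_forward(tiny_model, x)
        logits = msffd_forward(tiny_model, pyr)
        assert logits.shape == (4, 32, 32, 32)


class TestVariants:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_all_variants_share_io_contract(self, variant, rng):
        model = build_variant(ModelConfig.desk(), variant, seed=0)
        x = rng.normal(size=(4, 16, 16, 16)).astype(np.float32)
        assert wiaf_forward(model, x).shape == (4, 16, 16, 16)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            build_variant(ModelConfig.desk(), "B+XYZ")

    def test_full_equals_default_model_parameter_for_parameter(self):
        cfg = ModelConfig.desk()
        a = WIAF(cfg, seed=3).state_dict()
        b = build_variant(cfg, "full", seed=3).state_dict()
        assert a.keys() == b.keys()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_wavelet_stem_parameter_delta(self):
        """params(full) - params(B+MSFFD+IAFT) = gate + projection - conv stem."""
        cfg = ModelConfig.desk()
        full = count_params(WIAF(cfg, seed=0))[0]
        var = count_params(build_variant(cfg, "B+MSFFD+IAFT", seed=0))[0]
        c1 = cfg.stage_channels[0]
        h = cfg.resolved_gate_hidden
        gate = 65 * h + 32
        proj = 32 * c1 + c1
        stem_conv = 27 * 4 * c1 + c1
        assert full - var == gate + proj - stem_conv


class TestBudgets:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_analytic_params_match_walked_arrays_desk(self, variant):
        cfg = ModelConfig.desk(variant)
        total, breakdown = count_params(WIAF(cfg, seed=0))
        analytic = budgets.params_breakdown(cfg)
        assert breakdown == analytic
        assert total == sum(analytic.values())

    def test_analytic_params_match_walked_arrays_reference(self):
        cfg = ModelConfig.reference()
        total, breakdown = count_params(WIAF(cfg, seed=0))
        assert breakdown == budgets.params_breakdown(cfg)

    def test_pointwise_map_macs_closed_form(self):
        # a 1x1x1 channel map m->n over V voxels costs m*n*V MACs
        cfg = ModelConfig.desk()
        _, bd = count_macs(cfg, (4, 32, 32, 32))
        m = 8 * cfg.in_channels
        v = 16 ** 3
        stem = bd["stem"]
        expected_proj = m * cfg.stage_channels[0] * v
        assert stem - expected_proj == 6 * 4 * 32 ** 3 + 2 * m * \
            cfg.resolved_gate_hidden + m * v

    def test_halving_input_divides_conv_macs_by_eight(self):
        cfg = ModelConfig.desk()
        big = count_macs(cfg, (4, 32, 32, 32))[1]
        small = count_macs(cfg, (4, 16, 16, 16))[1]
        assert big["down2"] == 8 * small["down2"]
        assert big["down4"] == 8 * small["down4"]

    def test_component_macs_sum_to_total(self):
        cfg = ModelConfig.reference()
        total, bd = count_macs(cfg, (4, 128, 128, 128))
        assert total == sum(bd.values())


class TestTraining:
    def test_gradients_reach_every_parameter(self, rng):
        # 32-cube input keeps every stage's axes longer than 1 voxel, so
        # even the deepest attention scores carry gradient
        model = WIAF(ModelConfig.desk(), seed=1)
        x = rng.normal(size=(1, 4, 32, 32, 32)).astype(np.float32)
        labels = (rng.integers(0, 3, size=(32, 32, 32)) * 2).astype(np.int16)
        labels[labels == 6] = 4
        loss, _, _ = training_loss(model(Tensor(x)), _one_hot(labels)[None])
        loss.backward()
        dead = [n for n, p in model.named_parameters()
                if p.grad is None or not np.any(p.grad)]
        assert dead == []

    def test_state_dict_roundtrip_preserves_forward(self, rng):
        cfg = ModelConfig.desk()
        a = WIAF(cfg, seed=5)
        b = WIAF(cfg, seed=6)
        b.load_state_dict(a.state_dict())
        x = rng.normal(size=(4, 16, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(wiaf_forward(a, x), wiaf_forward(b, x))


class TestConfig:
    def test_nondecreasing_channels_enforced(self):
        with pytest.raises(ValueError, match="nondecreasing"):
            ModelConfig(stage_channels=(16, 8, 32, 64))

    def test_heads_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(stage_channels=(9, 16, 32, 64),
                        num_heads=(2, 4, 4, 8))

    def test_yaml_roundtrip(self, tmp_path):
        cfg = ModelConfig.reference()
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        again = ModelConfig.from_yaml(path)
        assert again.to_dict() == cfg.to_dict()

    def test_reference_config_is_committed_and_loadable(self):
        cfg = ModelConfig.reference()
        assert cfg.variant == "full"
        assert DecoderConfig(**cfg.decoder.__dict__)  # well-formed
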