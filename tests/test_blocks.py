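"""Building-block semantics: SE gating, wavelet bottlenecks, C3k2 stages,
SPPF, attention and the detection head."""

import numpy as np
import pytest

import giwtnet.autograd as ag
from giwtnet.autograd import Tensor
from giwtnet.blocks import (
    C2PSA,
    C3K2_WT,
    BlockSpec,
    Bottleneck,
    BottleneckWT,
    C3k2,
    Detect,
    SEConfig,
    SPPF,
    SqueezeExcite,
    calibrate_wtconv_config,
    se_forward,
)
from giwtnet.wavelet_conv import WTConvConfig


def test_blockspec_validation():
    BlockSpec("c3k2", 32, 64, flags={"e": 0.25})
    with pytest.raises(ValueError, match="unknown block kind"):
        BlockSpec("swin", 32, 64)
    with pytest.raises(ValueError, match="expansion"):
        BlockSpec("c3k2", 32, 64, flags={"e": 0.3})


class TestSqueezeExcite:
    def test_zero_second_layer_scales_by_half(self, rng):
        se = SqueezeExcite(SEConfig(8, 4))
        se.fc2.weight.data[:] = 0
        se.fc2.bias.data[:] = 0
        x = rng.normal(size=(2, 8, 4, 4)).astype(np.float32)
        assert np.allclose(_run(se, x), 0.5 * x, atol=1e-6)

    def test_functional_wrapper_returns_array(self, rng):
        x = rng.normal(size=(1, 8, 4, 4)).astype(np.float32)
        out = se_forward(x, SEConfig(8, 4), rng=rng)
        assert isinstance(out, np.ndarray) and out.shape == x.shape

    def test_output_bounded_by_input(self, rng):
        se = SqueezeExcite(SEConfig(16, 4), rng=rng)
        x = rng.normal(size=(1, 16, 6, 6)).astype(np.float32)
        out = _run(se, x)
        assert (np.abs(out) <= np.abs(x) + 1e-6).all()

    def test_param_count_512_r16(self):
        assert SqueezeExcite(SEConfig(512, 16)).param_count() == 33312

    def test_channel_mismatch_rejected(self, rng):
        se = SqueezeExcite(SEConfig(8, 4))
        with pytest.raises(ValueError, match="expected 8"):
            _run(se, rng.normal(size=(1, 4, 4, 4)).astype(np.float32))

    def test_reduction_must_divide(self):
        with pytest.raises(ValueError):
            SEConfig(10, 4)


def _run(module, x):
    module.eval()
    with ag.no_grad():
        return module(Tensor(x)).data


class TestWaveletBottleneck:
    def test_zero_kernels_leave_shortcut_only(self, rng):
        b = BottleneckWT(8, WTConvConfig(8, 3, 1), rng=rng)
        for name, p in b.named_parameters():
            if name.endswith("kernel"):
                p.data[:] = 0
        x = rng.normal(size=(2, 8, 8, 8)).astype(np.float32)
        assert np.allclose(_run(b, x), x, atol=1e-6)

    def test_shape_preserved(self, rng):
        b = BottleneckWT(32, rng=rng)
        x = rng.normal(size=(1, 32, 16, 16)).astype(np.float32)
        assert _run(b, x).shape == x.shape

    def test_param_count_default_cfg(self):
        assert BottleneckWT(32).param_count() == 2 * (4160 + 64)

    def test_second_only_variant_keeps_one_standard_conv(self):
        both = BottleneckWT(32, replace="both").param_count()
        second = BottleneckWT(32, replace="second").param_count()
        standard_conv = 32 * 32 * 9 + 64
        wt_block = 4160 + 64
        assert second - both == standard_conv - wt_block


class TestC3k2:
    def test_baseline_stage1_parameter_count(self):
        assert C3k2(64, 128, 1, False, 0.25).param_count() == 35328
        assert C3k2(64, 128, 1, False, 0.25).param_count() == 4224 + 18560 + 12544

    def test_output_shape(self, rng):
        block = C3K2_WT(16, 32, 1, True, 0.5, rng=rng)
        x = rng.normal(size=(1, 16, 8, 8)).astype(np.float32)
        assert _run(block, x).shape == (1, 32, 8, 8)

    def test_zeroed_wavelet_units_act_as_identity_passthrough(self, rng):
        """With zero wavelet kernels and the shortcut on, each inner unit is
        the identity, so the block equals its inner-units-removed analogue."""
        block = C3K2_WT(16, 16, 1, False, 0.5, rng=np.random.default_rng(5))
        for name, p in block.named_parameters():
            if "wt" in name and name.endswith("kernel"):
                p.data[:] = 0
        x = rng.normal(size=(1, 16, 8, 8)).astype(np.float32)
        got = _run(block, x)
        # manual identity-unit evaluation with the same cv1/cv2 parameters
        with ag.no_grad():
            y = block.cv1(Tensor(x))
            c = block.c
            ref = block.cv2(ag.concat([y[:, :c], y[:, c:], y[:, c:]], axis=1)).data
        assert np.allclose(got, ref, atol=1e-5)

    def test_structural_vs_flat_param_enumeration(self):
        block = C3K2_WT(32, 64, 1, True, 0.5)
        parts = block.cv1.param_count() + block.cv2.param_count() + sum(
            u.param_count() for u in block.units
        )
        assert parts == block.param_count()

    def test_bad_expansion_rejected(self):
        with pytest.raises(ValueError, match="hidden"):
            C3k2(8, 2, 1, False, 0.25)


class TestSPPFAndC2PSA:
    def test_sppf_table_count_and_shape(self, rng):
        assert SPPF(512, 512).param_count() == 656896
        sppf = SPPF(32, 32, rng=rng)
        x = rng.normal(size=(1, 32, 8, 8)).astype(np.float32)
        assert _run(sppf, x).shape == x.shape

    def test_sppf_impulse_produces_nested_plateaus(self):
        """Chained 5x5 stride-1 pools have effective windows 5/9/13."""
        from giwtnet.nn import MaxPool2d

        x = np.zeros((1, 1, 21, 21), dtype=np.float32)
        x[0, 0, 10, 10] = 1.0
        pool = MaxPool2d(5, 1, 2)
        with ag.no_grad():
            p1 = pool(Tensor(x))
            p2 = pool(p1)
            p3 = pool(p2)
        for p, width in ((p1, 5), (p2, 9), (p3, 13)):
            rows = np.where(p.data[0, 0].max(axis=1) == 1.0)[0]
            assert rows.size == width

    def test_c2psa_table_count_and_shape(self, rng):
        assert C2PSA(512, 512, 1).param_count() == 990976
        block = C2PSA(64, 64, 1, rng=rng)
        x = rng.normal(size=(1, 64, 8, 8)).astype(np.float32)
        assert _run(block, x).shape == x.shape


class TestDetect:
    def test_forward_shapes_and_score_range(self, rng):
        head = Detect(6, (16, 32, 64), rng=rng)
        feats = [Tensor(rng.normal(size=(2, c, s, s)).astype(np.float32))
                 for c, s in ((16, 8), (32, 4), (64, 2))]
        head.eval()
        with ag.no_grad():
            outs = head(feats)
        for (box, cls), s in zip(outs, (8, 4, 2)):
            assert box.data.shape == (2, 64, s, s)
            assert cls.data.shape == (2, 6, s, s)
            boxes, scores = head.decode_scale(box.data, cls.data, 8)
            assert ((scores > 0) & (scores < 1)).all()

    def test_scale_count_mismatch_rejected(self, rng):
        head = Detect(6, (16, 32, 64), rng=rng)
        with pytest.raises(ValueError, match="expected 3"):
            head([Tensor(np.zeros((1, 16, 8, 8), dtype=np.float32))])

    def test_one_hot_distribution_decodes_to_bin_times_stride(self):
        head = Detect(6, (16, 32, 64))
        H = W = 2
        stride = 8
        box_logits = np.zeros((1, 64, H, W), dtype=np.float32)
        cls_logits = np.zeros((1, 6, H, W), dtype=np.float32)
        for side, b in ((0, 2), (1, 5), (2, 3), (3, 7)):
            box_logits[0, side * 16 + b] = 60.0  # delta distribution on bin b
        boxes, _ = head.decode_scale(box_logits, cls_logits, stride)
        cx = cy = 0.5 * stride  # cell (0, 0)
        np.testing.assert_allclose(
            boxes[0, 0],
            [cx - 2 * stride, cy - 5 * stride, cx + 3 * stride, cy + 7 * stride],
            atol=1e-4,
        )


class TestCalibration:
    def test_report_structure_and_baseline_row(self):
        report = calibrate_wtconv_config()
        assert report["targets"] == [26080, 103360, 293632, 1127936]
        baseline = report["rows"][0]
        assert baseline["stage_counts"][0] == 35328
        for row in report["rows"]:
            assert len(row["stage_counts"]) == 4
            assert len(row["abs_deviation"]) == 4
        # deterministic across calls
        again = calibrate_wtconv_config()
        assert [r["stage_counts"] for r in again["rows"]] == [
            r["stage_counts"] for r in report["rows"]
        ]
        assert "not adopted" in report["note"]

    def test_no_candidate_matches_targets_exactly(self):
        report = calibrate_wtconv_config()
        assert all(any(d != 0 for d in row["abs_deviation"])
                   for row in report["rows"])
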