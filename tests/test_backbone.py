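"""Residual blocks, stage shapes, skip concatenation, montage export."""

import numpy as np
import pytest

from granulenet.backbone import (BackboneSpec, BlockWeights, ResidualBlockSpec,
                                 build_backbone, concat_flatten,
                                 convolutional_block, export_feature_maps,
                                 extract_features, identity_block)
from granulenet.errors import ParameterError, ShapeError, StateError
from granulenet.layers import BatchNorm, Conv2D, conv2d, max_pool
from granulenet.synthetic import POSITIVE, SynthParams, generate_image

from _helpers import naive_conv2d


def _zero_block_weights(spec: ResidualBlockSpec, cin: int) -> BlockWeights:
    w = BlockWeights.random(spec, cin, np.random.default_rng(0))
    for conv in w.convs:
        conv.w = np.zeros_like(conv.w)
    return w


class TestBlocks:
    def test_identity_block_passthrough_with_zero_residual(self, rng):
        """Zero residual branch + nonnegative input => H(x) = ReLU(0 + x) = x."""
        spec = ResidualBlockSpec("identity", (2, 2, 3))
        weights = _zero_block_weights(spec, 3)
        x = rng.uniform(0.0, 2.0, size=(4, 4, 3))
        out = identity_block(x, spec, weights)
        np.testing.assert_array_equal(out, x)

    def test_identity_block_preserves_full_scale_stage2_shape(self, rng):
        spec = ResidualBlockSpec("identity", (64, 64, 256))
        weights = BlockWeights.random(spec, 256, rng)
        x = rng.standard_normal((56, 56, 256)) * 0.1
        assert identity_block(x, spec, weights).shape == (56, 56, 256)

    def test_identity_block_channel_mismatch_names_stage(self, rng):
        spec = ResidualBlockSpec("identity", (2, 2, 8), name="stage2_id1")
        weights = BlockWeights.random(spec, 8, rng)
        with pytest.raises(ShapeError, match="stage2_id1"):
            identity_block(rng.standard_normal((4, 4, 5)), spec, weights)

    def test_conv_block_downsamples_stage3_shape(self, rng):
        spec = ResidualBlockSpec("convolutional", (128, 128, 512), stride=2)
        weights = BlockWeights.random(spec, 256, rng)
        x = rng.standard_normal((56, 56, 256)) * 0.05
        assert convolutional_block(x, spec, weights).shape == (28, 28, 512)

    def test_conv_block_shortcut_projection_with_zero_main_path(self, rng):
        """F = 0 => H(x) = ReLU(Ws x): pure channel projection of the input."""
        spec = ResidualBlockSpec("convolutional", (2, 2, 4), stride=1)
        weights = _zero_block_weights(spec, 2)
        # Shortcut 1x1 kernel copying input channels into the first outputs.
        ws = np.zeros((1, 1, 2, 4))
        ws[0, 0, 0, 0] = 1.0
        ws[0, 0, 1, 1] = 1.0
        weights.shortcut_conv = Conv2D(w=ws, stride=1)
        weights.shortcut_bn = BatchNorm.identity(4)
        x = rng.uniform(0.0, 1.0, size=(3, 3, 2))
        out = convolutional_block(x, spec, weights)
        np.testing.assert_allclose(out[:, :, :2], x, atol=0)
        np.testing.assert_array_equal(out[:, :, 2:], 0.0)

    @pytest.mark.parametrize("kind,stride", [("identity", 1),
                                             ("convolutional", 1),
                                             ("convolutional", 2)])
    def test_blocks_match_direct_convolution_oracle(self, kind, stride, rng):
        """On <= 4x4x2 toys with seeded weights both block types agree with a
        loop-based convolution oracle to 1e-5 relative error."""
        spec = ResidualBlockSpec(kind, (2, 3, 2), stride=stride)
        weights = BlockWeights.random(spec, 2, rng)
        x = rng.standard_normal((4, 4, 2))
        if kind == "identity":
            got = identity_block(x, spec, weights)
        else:
            got = convolutional_block(x, spec, weights)

        def bn(h, layer):
            return h * weights.bns[layer].scale + weights.bns[layer].shift

        def naive_main(x):
            h = np.maximum(bn(naive_conv2d(x, weights.convs[0].w, stride), 0), 0)
            h = np.maximum(bn(naive_conv2d(h, weights.convs[1].w), 1), 0)
            return bn(naive_conv2d(h, weights.convs[2].w), 2)

        if kind == "identity":
            want = np.maximum(naive_main(x) + x, 0)
        else:
            short = naive_conv2d(x, weights.shortcut_conv.w, stride)
            short = short * weights.shortcut_bn.scale + weights.shortcut_bn.shift
            want = np.maximum(naive_main(x) + short, 0)
        np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-10)

    def test_single_pixel_toy_matches_hand_arithmetic(self):
        """1x1 spatial, single channel, hand-set kernels, batch-norm disabled:
        H(x) = ReLU(w3*ReLU(w2*ReLU(w1*x)) + x)."""
        spec = ResidualBlockSpec("identity", (1, 1, 1))
        mk = lambda k, v: Conv2D(w=np.full((k, k, 1, 1), v))
        weights = BlockWeights(
            convs=[mk(1, 2.0), mk(3, -0.5), mk(1, 3.0)],
            bns=[BatchNorm.identity(1)] * 3)
        x = np.array([[[0.7]]])
        # conv2 sees a single padded pixel: 3x3 kernel center contributes.
        expected = max(3.0 * max(-0.5 * max(2.0 * 0.7, 0), 0) + 0.7, 0)
        out = identity_block(x, spec, weights)
        assert out.shape == (1, 1, 1)
        assert abs(float(out[0, 0, 0]) - expected) < 1e-6


class TestLayerPrimitives:
    def test_same_padding_conv_output_grid(self, rng):
        x = rng.standard_normal((224, 224, 3))
        w = rng.standard_normal((7, 7, 3, 4)) * 0.01
        assert conv2d(x, w, stride=2).shape == (112, 112, 4)

    def test_max_pool_halves_grid(self, rng):
        x = rng.standard_normal((112, 112, 4))
        assert max_pool(x, kernel=3, stride=2).shape == (56, 56, 4)

    def test_conv_channel_mismatch_raises(self, rng):
        with pytest.raises(ShapeError):
            conv2d(rng.standard_normal((4, 4, 3)),
                   rng.standard_normal((1, 1, 2, 5)))


class TestBackbone:
    def test_tiny_flat_vector_matches_shape_arithmetic(self, tiny_extractor):
        img = generate_image(POSITIVE, SynthParams.tiny(), seed=1)
        fm = extract_features(tiny_extractor, img)
        shapes = [f.shape for f in fm.stages]
        assert shapes == [(16, 16, 8), (16, 16, 32), (8, 8, 64), (4, 4, 128),
                          (2, 2, 256)]
        expected_len = 16 * 16 * 32 + 2 * 2 * 256
        assert fm.flat.shape == (expected_len,)
        assert tiny_extractor.flat_dim == expected_len

    def test_extraction_is_deterministic(self, tiny_extractor):
        img = generate_image(POSITIVE, SynthParams.tiny(), seed=5)
        f1 = extract_features(tiny_extractor, img).flat
        f2 = extract_features(tiny_extractor, img).flat
        np.testing.assert_array_equal(f1, f2)

    def test_feature_vector_independent_of_dataset_order(self, tiny_extractor):
        imgs = [generate_image(POSITIVE, SynthParams.tiny(), seed=s)
                for s in (1, 2, 3)]
        fwd = [extract_features(tiny_extractor, im).flat for im in imgs]
        rev = [extract_features(tiny_extractor, im).flat for im in reversed(imgs)]
        for a, b in zip(fwd, reversed(rev)):
            np.testing.assert_array_equal(a, b)

    def test_concat_order_is_stage2_then_stage5(self, tiny_extractor):
        img = generate_image(POSITIVE, SynthParams.tiny(), seed=9)
        fm = extract_features(tiny_extractor, img)
        np.testing.assert_array_equal(
            fm.flat, concat_flatten(fm.stage2, fm.stage5))
        np.testing.assert_array_equal(fm.flat[:fm.stage2.size],
                                      fm.stage2.ravel(order="C"))

    def test_grayscale_any_size_is_resized_and_replicated(self, tiny_extractor):
        img = np.random.default_rng(0).uniform(size=(100, 80))
        prepared = tiny_extractor.prepare(img)
        assert prepared.shape == (64, 64, 3)
        np.testing.assert_array_equal(prepared[:, :, 0], prepared[:, :, 2])

    def test_pretrained_init_unavailable_raises(self):
        with pytest.raises(StateError, match="random"):
            build_backbone(BackboneSpec.tiny(), init="pretrained")

    def test_unknown_scale_rejected(self):
        with pytest.raises(ParameterError):
            BackboneSpec.from_scale("medium")

    def test_full_spec_matches_printed_filters(self):
        spec = BackboneSpec.full()
        assert spec.stem_filters == 64
        assert [s[1] for s in spec.stages] == [
            (64, 64, 256), (128, 128, 512), (256, 256, 1024), (512, 512, 2048)]
        assert [s[0] + 1 for s in spec.stages] == [3, 4, 6, 3]  # blocks/stage


class TestExportFeatureMaps:
    def test_montage_tile_grids(self, tiny_extractor, tmp_path):
        from PIL import Image
        img = generate_image(POSITIVE, SynthParams.tiny(), seed=2)
        fm = extract_features(tiny_extractor, img)
        paths = export_feature_maps(fm, tmp_path)
        assert len(paths) == 5
        # Stage 1 at tiny scale: 8 channels of 16x16 -> 3x3 grid of tiles.
        m1 = Image.open(paths[0])
        assert m1.size == (3 * 16, 3 * 16)
        assert m1.mode == "L"
        # Stage 5: 256 channels of 2x2 -> 16x16 grid.
        assert Image.open(paths[4]).size == (32, 32)

    def test_full_scale_stage1_montage_tiles_64_patches(self, full_extractor,
                                                        tmp_path):
        from PIL import Image
        img = generate_image(POSITIVE, SynthParams(), seed=2)
        fm = extract_features(full_extractor, img)
        paths = export_feature_maps(fm, tmp_path)
        # Stage 1: 64 patches of 56x56 on an 8x8 grid.
        assert Image.open(paths[0]).size == (8 * 56, 8 * 56)
        # Stage 5: 2048 patches of 7x7 (46-column grid, 45 rows).
        assert Image.open(paths[4]).size == (46 * 7, 45 * 7)
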