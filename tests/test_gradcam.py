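"""Grad-CAM weights, maps, upsampling and rendering against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikecam import (
    CamMap,
    ChannelWeights,
    InputError,
    LayerActivation,
    channel_weights,
    gradcam_map,
    render_heatmap,
    upsample_cam,
)


def make_activation(values, gradients, layer_id="medium", stride=16):
    return LayerActivation(layer_id=layer_id, values=np.asarray(values, float),
                           gradients=np.asarray(gradients, float), stride=stride)


def weights_oracle(gradients):
    """Explicit double loop over Eq.-style spatial sums."""
    k, h, w = gradients.shape
    out = np.zeros(k)
    for c in range(k):
        s = 0.0
        for i in range(h):
            for j in range(w):
                s += gradients[c, i, j]
        out[c] = s / (h * w)
    return out


def cam_oracle(values, alphas):
    """Per-pixel triple loop: sum_k alpha_k A^k_ij then clip at zero."""
    k, h, w = values.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            s = 0.0
            for c in range(k):
                s += alphas[c] * values[c, i, j]
            out[i, j] = max(0.0, s)
    return out


class TestChannelWeights:
    def test_zero_gradients_zero_weights(self):
        act = make_activation(np.ones((3, 2, 2)), np.zeros((3, 2, 2)))
        assert not channel_weights(act).weights.any()

    def test_constant_gradient_equals_itself(self):
        grads = np.stack([np.full((4, 5), 2.5), np.full((4, 5), -1.0)])
        act = make_activation(np.zeros_like(grads), grads)
        np.testing.assert_allclose(channel_weights(act).weights, [2.5, -1.0])

    def test_random_case_matches_double_loop(self, rng):
        grads = rng.normal(size=(3, 2, 2))
        act = make_activation(rng.normal(size=(3, 2, 2)), grads)
        np.testing.assert_allclose(channel_weights(act).weights, weights_oracle(grads),
                                   atol=1e-14)

    def test_empty_layer_rejected(self):
        act = make_activation(np.zeros((2, 0, 3)), np.zeros((2, 0, 3)))
        with pytest.raises(InputError):
            channel_weights(act)


class TestGradcamMap:
    def test_relu_clips_negative_sums(self):
        act = make_activation([[[-1.0, 2.0], [0.0, -3.0]]], np.zeros((1, 2, 2)))
        w = ChannelWeights(layer_id="medium", weights=[1.0])
        np.testing.assert_array_equal(gradcam_map(act, w).values, [[0.0, 2.0], [0.0, 0.0]])

    def test_zero_weights_zero_map(self, rng):
        act = make_activation(rng.normal(size=(4, 3, 3)), np.zeros((4, 3, 3)))
        w = ChannelWeights(layer_id="medium", weights=np.zeros(4))
        assert not gradcam_map(act, w).values.any()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k, h, w = rng.integers(1, 9, size=3)
        values = rng.normal(size=(k, h, w))
        grads = rng.normal(size=(k, h, w))
        act = make_activation(values, grads)
        alphas = channel_weights(act)
        got = gradcam_map(act, alphas).values
        np.testing.assert_allclose(got, cam_oracle(values, alphas.weights), atol=1e-12)

    def test_channel_mismatch_rejected(self):
        act = make_activation(np.zeros((3, 2, 2)), np.zeros((3, 2, 2)))
        with pytest.raises(InputError):
            gradcam_map(act, ChannelWeights(layer_id="medium", weights=[1.0, 2.0]))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 100.0))
    def test_gradient_scaling_scales_map(self, seed, c):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(3, 4, 4))
        grads = rng.normal(size=(3, 4, 4))
        base = gradcam_map(make_activation(values, grads),
                           channel_weights(make_activation(values, grads)))
        scaled_act = make_activation(values, c * grads)
        scaled = gradcam_map(scaled_act, channel_weights(scaled_act))
        np.testing.assert_allclose(scaled.values, c * base.values, rtol=1e-9, atol=1e-12)

    def test_zero_gradients_give_empty_attention_downstream(self):
        from spikecam import attention_mask

        act = make_activation(np.abs(np.random.default_rng(0).normal(size=(2, 4, 4))),
                              np.zeros((2, 4, 4)))
        cam = gradcam_map(act, channel_weights(act))
        mask = attention_mask(upsample_cam(cam, (8, 8)), image_id="img")
        assert not mask.grid.any()


class TestUpsample:
    def test_single_pixel_becomes_constant_grid(self):
        cam = CamMap(layer_id="large", resolution_tag="layer", values=[[3.5]])
        for method in ("bilinear", "nearest"):
            up = upsample_cam(cam, (5, 7), method)
            assert up.values.shape == (5, 7)
            np.testing.assert_array_equal(up.values, np.full((5, 7), 3.5))

    def test_nearest_replicates_blocks(self):
        cam = CamMap(layer_id="l", resolution_tag="layer",
                     values=[[1.0, 2.0], [3.0, 4.0]])
        up = upsample_cam(cam, (4, 4), "nearest")
        expected = np.array([[1, 1, 2, 2], [1, 1, 2, 2], [3, 3, 4, 4], [3, 3, 4, 4]], float)
        np.testing.assert_array_equal(up.values, expected)
        assert sorted(set(up.values.ravel())) == [1.0, 2.0, 3.0, 4.0]

    def test_bilinear_2x2_to_4x4_closed_form(self):
        # pixel-center aligned, edge clamped; worked out by hand for [[0,1],[1,0]]
        cam = CamMap(layer_id="l", resolution_tag="layer", values=[[0.0, 1.0], [1.0, 0.0]])
        expected = np.array(
            [
                [0.0, 0.25, 0.75, 1.0],
                [0.25, 0.375, 0.625, 0.75],
                [0.75, 0.625, 0.375, 0.25],
                [1.0, 0.75, 0.25, 0.0],
            ]
        )
        np.testing.assert_allclose(upsample_cam(cam, (4, 4), "bilinear").values, expected,
                                   atol=1e-12)

    def test_downsampling_rejected(self):
        cam = CamMap(layer_id="l", resolution_tag="layer", values=np.ones((4, 4)))
        with pytest.raises(InputError):
            upsample_cam(cam, (2, 8))

    @pytest.mark.parametrize("method", ["bilinear", "nearest"])
    def test_non_negativity_preserved(self, rng, method):
        cam = CamMap(layer_id="l", resolution_tag="layer",
                     values=np.abs(rng.normal(size=(3, 5))))
        up = upsample_cam(cam, (12, 20), method)
        assert up.values.min() >= 0.0
        assert up.resolution_tag == "image"


class TestRenderHeatmap:
    def test_all_zero_cam_returns_base_image(self, rng):
        image = (rng.uniform(0, 1, (6, 6, 3)) * 255).astype(np.uint8)
        cam = CamMap(layer_id="l", resolution_tag="image", values=np.zeros((6, 6)))
        for opacity in (0.0, 0.5, 1.0):
            np.testing.assert_array_equal(render_heatmap(cam, image, opacity), image)

    def test_constant_positive_cam_full_opacity_is_top_ramp_color(self):
        from matplotlib import colormaps

        image = np.zeros((4, 4, 3), dtype=np.uint8)
        cam = CamMap(layer_id="l", resolution_tag="image", values=np.full((4, 4), 2.0))
        out = render_heatmap(cam, image, opacity=1.0, cmap="jet")
        top = (np.array(colormaps["jet"](1.0)[:3]) * 255 + 0.5).astype(np.uint8)
        assert (out == top).all()

    def test_two_level_cam_gives_two_blended_colors(self):
        image = np.full((4, 4, 3), 100, dtype=np.uint8)
        values = np.zeros((4, 4))
        values[:2] = 5.0
        cam = CamMap(layer_id="l", resolution_tag="image", values=values)
        out = render_heatmap(cam, image, opacity=0.7)
        colors = {tuple(px) for px in out.reshape(-1, 3)}
        assert len(colors) == 2
        assert (100, 100, 100) in colors  # unattended pixels untouched

    def test_resolution_mismatch_rejected(self):
        cam = CamMap(layer_id="l", resolution_tag="image", values=np.ones((4, 4)))
        with pytest.raises(InputError):
            render_heatmap(cam, np.zeros((5, 5, 3), dtype=np.uint8))
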