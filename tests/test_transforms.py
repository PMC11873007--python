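"""Transform vocabulary: matrices, shapes, randomness, inverses."""

import math

import numpy as np
import pytest

from lazyresample import (
    DispatchClass,
    NotInvertibleError,
    TraceRecord,
    add_noise,
    apply_all,
    classify,
    compose_affine,
    crop_patch,
    flip,
    invert_record,
    make_meta_image,
    rand_flip,
    rand_rotate,
    rand_zoom,
    resize,
    rotate,
    rotate90,
    spacing,
    translate,
    zoom,
)
from lazyresample.core import effective_shape


def _img2d(rng, shape=(8, 8)):
    return make_meta_image(rng.random((1, *shape)).astype(np.float32))


class TestRotate:
    def test_zero_angle_is_identity(self, rng):
        out = rotate(_img2d(rng), 0.0)
        assert out.pending[0].operation.is_identity()

    def test_quarter_pi_pull_block_closed_form(self, rng):
        theta = math.pi / 4
        out = rotate(_img2d(rng), theta)
        c, s = math.cos(theta), math.sin(theta)
        expected = np.array([[c, s], [-s, c]])
        assert np.allclose(out.pending[0].operation.spatial, expected, atol=1e-12)

    def test_opposite_rotations_compose_to_identity(self, rng):
        deg45 = math.radians(45)
        out = rotate(rotate(_img2d(rng), deg45), -deg45)
        composed = compose_affine(out.pending[0].operation, out.pending[1].operation)
        assert np.abs(composed.values - np.eye(3)).max() < 1e-6

    def test_wrong_angle_count_rejected(self, rng):
        with pytest.raises(ValueError, match="angle"):
            rotate(_img2d(rng), (0.1, 0.2))


class TestRotate90:
    def test_zero_turns_identity(self, rng):
        out = rotate90(_img2d(rng), 0)
        assert out.pending[0].operation.is_identity()

    def test_half_turn_keeps_shape(self, rng):
        out = rotate90(_img2d(rng, (4, 6)), 2)
        assert out.pending[0].output_shape == (4, 6)

    def test_quarter_turn_swaps_extents(self, rng):
        out = rotate90(_img2d(rng, (4, 6)), 1)
        assert out.pending[0].output_shape == (6, 4)

    def test_invalid_plane_rejected(self, rng):
        with pytest.raises(ValueError, match="plane"):
            rotate90(_img2d(rng), 1, plane=(0, 0))

    def test_lazy_apply_matches_numpy_rot90(self, rng):
        img = _img2d(rng, (4, 6))
        for k in range(4):
            out = apply_all(rotate90(img, k))
            assert np.array_equal(out.data[0], np.rot90(img.data[0], k))


class TestFlip:
    def test_empty_axis_set_is_identity(self, rng):
        out = flip(_img2d(rng), ())
        assert out.pending[0].operation.is_identity()

    def test_double_flip_composes_to_identity_bit_exact(self, rng):
        img = _img2d(rng)
        out = apply_all(flip(flip(img, (0,)), (0,)))
        assert np.array_equal(out.data, img.data)

    def test_flip_matches_direct_reversal(self):
        img = make_meta_image(np.array([[[1.0], [2.0], [3.0]]], dtype=np.float32))
        out = apply_all(flip(img, (0,)))
        assert np.array_equal(out.data[0, :, 0], [3.0, 2.0, 1.0])

    def test_lazy_apply_bit_equal_numpy_flip(self, rng):
        img = _img2d(rng, (5, 7))
        out = apply_all(flip(img, (0, 1)))
        assert np.array_equal(out.data[0], np.flip(img.data[0], (0, 1)))


class TestZoomResizeSpacing:
    def test_unit_factor_identity(self, rng):
        out = zoom(_img2d(rng), 1.0)
        assert out.pending[0].operation.is_identity()
        assert out.pending[0].output_shape == (8, 8)

    def test_factor_two_doubles_extents(self, rng):
        assert zoom(_img2d(rng), 2.0).pending[0].output_shape == (16, 16)

    def test_six_fifths_roundtrip_restores_shape_and_data(self, rng):
        img = _img2d(rng, (64, 64))
        out = zoom(zoom(img, 6 / 5), 5 / 6)
        assert effective_shape(out) == (64, 64)
        assert np.array_equal(apply_all(out).data, img.data)

    def test_nonpositive_factor_rejected(self, rng):
        with pytest.raises(ValueError, match="> 0"):
            zoom(_img2d(rng), 0.0)

    def test_resize_equivalent_to_zoom_with_override(self, rng):
        img = _img2d(rng)
        r = resize(img, (16, 16)).pending[0]
        z = zoom(img, 2.0).pending[0]
        assert r.output_shape == z.output_shape == (16, 16)
        assert np.allclose(r.operation.values, z.operation.values)

    def test_resize_anisotropic_factors(self, rng):
        img = make_meta_image(rng.random((1, 34, 53, 24)).astype(np.float32))
        op = resize(img, (40, 56, 40)).pending[0]
        assert op.output_shape == (40, 56, 40)
        diag = 1.0 / np.diag(op.operation.spatial)
        assert np.allclose(diag, (40 / 34, 56 / 53, 40 / 24))

    def test_spacing_identity_when_target_matches(self, rng):
        img = make_meta_image(rng.random((1, 8, 8)).astype(np.float32), spacing=(2, 2))
        out = spacing(img, (2.0, 2.0))
        assert out.pending[0].operation.is_identity()

    def test_spacing_halving_doubles_extent(self, rng):
        img = make_meta_image(rng.random((1, 10, 10)).astype(np.float32), spacing=(2, 2))
        op = spacing(img, (1.0, 1.0)).pending[0]
        assert op.output_shape == (20, 20)
        assert np.allclose(np.diag(op.operation.spatial), 0.5)

    def test_spacing_anisotropic_volume(self, rng):
        img = make_meta_image(
            np.zeros((1, 240, 240, 78), dtype=np.float32), spacing=(1, 1, 2)
        )
        op = spacing(img, (1.0, 1.0, 1.0)).pending[0]
        assert op.output_shape == (240, 240, 156)


class TestTranslateAndCrop:
    def test_zero_offset_identity(self, rng):
        assert translate(_img2d(rng), (0, 0)).pending[0].operation.is_identity()

    def test_lazy_shift_and_return_bit_equal(self, rng):
        img = _img2d(rng)
        out = apply_all(translate(translate(img, (5, 0)), (-5, 0)))
        assert np.array_equal(out.data, img.data)

    def test_eager_shift_and_return_zeroes_edge(self, rng):
        img = make_meta_image((np.arange(64) + 1.0).reshape(1, 8, 8).astype(np.float32))
        out = translate(translate(img, (5, 0), lazy=False), (-5, 0), lazy=False)
        assert np.all(out.data[0, 3:, :] == 0)
        assert np.array_equal(out.data[0, :3, :], img.data[0, :3, :])

    def test_full_extent_crop_is_identity(self, ramp2d):
        op = crop_patch(ramp2d, (0, 0), (4, 4)).pending[0]
        assert op.operation.is_identity()
        assert op.output_shape == (4, 4)

    def test_centre_crop_hand_trace(self, ramp2d):
        out = apply_all(crop_patch(ramp2d, (1, 1), (2, 2)))
        assert np.array_equal(out.data[0], [[5.0, 6.0], [9.0, 10.0]])

    def test_lazy_crop_then_rotate_recovers_outside_data(self, rng):
        img = _img2d(rng, (16, 16))
        deg40 = math.radians(40)
        lazy_out = apply_all(rotate(crop_patch(img, (4, 4), (8, 8)), deg40))
        eager_out = rotate(
            crop_patch(img, (4, 4), (8, 8), lazy=False), deg40, lazy=False
        )
        # same viewport, but the lazy path sampled from the uncropped volume
        assert lazy_out.spatial_shape == eager_out.spatial_shape == (8, 8)
        assert not np.allclose(lazy_out.data, eager_out.data)
        # oracle: one resample of the full image through the composed matrix
        composed = apply_all(rotate(crop_patch(img, (4, 4), (8, 8)), deg40))
        assert np.array_equal(lazy_out.data, composed.data)

    def test_nonpositive_size_rejected(self, ramp2d):
        with pytest.raises(ValueError, match="size"):
            crop_patch(ramp2d, (0, 0), (0, 2))


class TestRandomTransforms:
    def test_zero_probability_is_identity_behaviour(self, rng):
        img = _img2d(rng)
        out = rand_rotate(img, 0.5, prob=0.0, rng=np.random.default_rng(0))
        assert out is img

    def test_same_seed_same_pending_matrix(self, rng):
        img = _img2d(rng)
        a = rand_rotate(img, 0.5, prob=1.0, rng=np.random.default_rng(7))
        b = rand_rotate(img, 0.5, prob=1.0, rng=np.random.default_rng(7))
        assert np.array_equal(a.pending[0].operation.values, b.pending[0].operation.values)

    def test_lazy_and_eager_share_drawn_parameters(self, rng):
        img = _img2d(rng)
        lazy_out = rand_zoom(img, 0.9, 1.1, prob=1.0, rng=np.random.default_rng(3), lazy=True)
        eager_out = rand_zoom(img, 0.9, 1.1, prob=1.0, rng=np.random.default_rng(3), lazy=False)
        applied = apply_all(lazy_out)
        assert np.array_equal(applied.data, eager_out.data)

    def test_rand_flip_draws_axes_independently(self, rng):
        img = _img2d(rng)
        out = rand_flip(img, prob=1.0, rng=np.random.default_rng(0))
        diag = np.diag(out.pending[0].operation.spatial)
        assert np.array_equal(diag, [-1.0, -1.0])

    def test_invalid_range_rejected(self, rng):
        with pytest.raises(ValueError):
            rand_zoom(_img2d(rng), 1.1, 0.9, prob=1.0, rng=np.random.default_rng(0))


class TestAddNoise:
    def test_sigma_zero_keeps_data(self, rng):
        img = _img2d(rng)
        out = add_noise(img, 0.0, np.random.default_rng(0))
        assert np.array_equal(out.data, img.data)

    def test_fixed_seed_reproducible(self, rng):
        img = _img2d(rng)
        a = add_noise(img, 0.1, np.random.default_rng(5))
        b = add_noise(img, 0.1, np.random.default_rng(5))
        assert np.array_equal(a.data, b.data)

    def test_applies_pending_before_noise(self, rng):
        img = _img2d(rng)
        out = add_noise(flip(img, (0,)), 0.0, np.random.default_rng(0))
        assert not out.pending
        assert np.array_equal(out.data[0], np.flip(img.data[0], 0))


class TestInvertRecord:
    def _record(self, img):
        return apply_all(img).trace[0]

    def test_identity_record_inverts_to_identity(self, rng):
        rec = self._record(flip(_img2d(rng), ()))
        assert invert_record(rec).operation.is_identity()

    def test_rotation_inverts_to_opposite_angle(self, rng):
        theta = math.radians(45)
        rec = self._record(rotate(_img2d(rng), theta))
        expected = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        assert np.allclose(invert_record(rec).operation.spatial, expected, atol=1e-12)

    def test_zoom_inverts_with_swapped_shapes(self, rng):
        rec = self._record(zoom(_img2d(rng, (60, 60)), 6 / 5))
        inv = invert_record(rec)
        assert inv.input_shape == (72, 72)
        assert inv.output_shape == (60, 60)
        # inverse is a zoom by 5/6, whose PULL matrix scales by 6/5
        assert np.allclose(np.diag(inv.operation.spatial), 6 / 5)
        assert inv.interpolation_mode == rec.pending.interpolation_mode

    def test_grid_record_not_invertible(self, rng):
        from lazyresample import PendingOp, VectorGrid

        grid_op = PendingOp(
            operation=VectorGrid(np.zeros((4, 4, 2))),
            input_shape=(4, 4),
            input_dtype="float32",
            output_shape=(4, 4),
            output_dtype="float32",
        )
        with pytest.raises(NotInvertibleError):
            invert_record(TraceRecord(grid_op, {}))


class TestModeDefaults:
    def test_float_images_default_to_linear(self, rng):
        assert rotate(_img2d(rng), 0.3).pending[0].interpolation_mode == "linear"

    def test_integer_labels_default_to_nearest(self, rng):
        lab = make_meta_image(rng.integers(0, 3, (1, 8, 8)).astype(np.int16))
        assert rotate(lab, 0.3).pending[0].interpolation_mode == "nearest"

    def test_eager_single_transform_equals_lazy_then_apply(self, rng):
        img = _img2d(rng)
        eager = rotate(img, 0.3, lazy=False)
        lazy_applied = apply_all(rotate(img, 0.3, lazy=True))
        assert np.array_equal(eager.data, lazy_applied.data)
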