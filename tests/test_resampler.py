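"""Composition, dispatch classification and the universal resampler."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lazyresample import (
    AffineMatrix,
    DispatchClass,
    PendingOp,
    VectorGrid,
    apply_all,
    apply_exact,
    build_groups,
    classify,
    compose_affine,
    make_meta_image,
    resample,
)
from lazyresample.resampler import ComposedGroup
from lazyresample.transforms import rotation_matrix
from lazyresample import flip, rotate, spacing, translate, zoom


def _op(matrix, in_shape, out_shape=None, interp="linear", pad="zeros", dtype="float32", name=""):
    return PendingOp(
        operation=AffineMatrix(matrix) if isinstance(matrix, np.ndarray) else matrix,
        input_shape=in_shape,
        input_dtype=dtype,
        output_shape=out_shape or in_shape,
        output_dtype=dtype,
        interpolation_mode=interp,
        padding_mode=pad,
        source_name=name,
    )


class TestCompose:
    def test_identity_is_neutral(self):
        a = AffineMatrix(rotation_matrix(2, [0.7]))
        assert compose_affine(AffineMatrix.identity(2), a) == a
        assert compose_affine(a, AffineMatrix.identity(2)) == a

    def test_rotation_angles_add(self):
        r30 = AffineMatrix(rotation_matrix(2, [math.radians(30)]))
        r60 = AffineMatrix(rotation_matrix(2, [math.radians(60)]))
        r90 = rotation_matrix(2, [math.radians(90)])
        assert np.allclose(compose_affine(r30, r60).values, r90, atol=1e-12)

    def test_identity_chain_from_worked_example(self):
        # Rotate(45) Zoom(1.25) Rotate(22) Rotate(-22) Zoom(0.8) Rotate(-45)
        deg = math.radians
        mats = [
            rotation_matrix(2, [deg(45)]),
            np.diag([1 / 1.25, 1 / 1.25, 1.0]),
            rotation_matrix(2, [deg(22)]),
            rotation_matrix(2, [deg(-22)]),
            np.diag([1 / 0.8, 1 / 0.8, 1.0]),
            rotation_matrix(2, [deg(-45)]),
        ]
        total = AffineMatrix.identity(2)
        for m in mats:
            total = compose_affine(total, AffineMatrix(m))
        assert np.abs(total.values - np.eye(3)).max() < 1e-6

    @given(
        st.lists(
            st.tuples(
                st.floats(-1.0, 1.0), st.floats(0.5, 2.0), st.floats(-3.0, 3.0)
            ),
            min_size=3,
            max_size=3,
        )
    )
    def test_composition_associative(self, params):
        mats = []
        for angle, scale, shift in params:
            m = rotation_matrix(2, [angle])
            m[:2, :2] *= scale
            m[:2, 2] = shift
            mats.append(AffineMatrix(m))
        a, b, c = mats
        left = compose_affine(compose_affine(a, b), c)
        right = compose_affine(a, compose_affine(b, c))
        assert np.allclose(left.values, right.values, rtol=1e-12, atol=1e-12)


class TestBuildGroups:
    def test_compatible_ops_merge_into_one(self):
        ops = [
            _op(rotation_matrix(2, [0.3]), (8, 8), name="a"),
            _op(np.diag([0.5, 0.5, 1.0]), (8, 8), (16, 16), name="b"),
            _op(rotation_matrix(2, [-0.3]), (16, 16), name="c"),
        ]
        groups = build_groups(ops)
        assert len(groups) == 1
        assert groups[0].in_shape == (8, 8)
        assert groups[0].out_shape == (16, 16)
        assert len(groups[0].members) == 3

    def test_interpolation_mode_change_splits(self):
        ops = [
            _op(np.eye(3), (8, 8), interp="linear"),
            _op(np.eye(3), (8, 8), interp="nearest"),
        ]
        assert len(build_groups(ops)) == 2

    def test_grids_never_merge(self, rng):
        grid = VectorGrid(np.zeros((8, 8, 2)))
        ops = [
            _op(np.eye(3), (8, 8)),
            _op(grid, (8, 8)),
            _op(np.eye(3), (8, 8)),
        ]
        assert len(build_groups(ops)) == 3


class TestClassify:
    def test_identity_is_exact(self):
        assert classify(AffineMatrix.identity(2), (8, 8), (8, 8)) is DispatchClass.EXACT_OP

    def test_rotation_needs_full_resample(self):
        m = AffineMatrix(rotation_matrix(2, [math.radians(45)]))
        assert classify(m, (8, 8), (8, 8)) is DispatchClass.FULL_RESAMPLE

    def test_flip_with_integer_translate_is_exact(self):
        m = np.diag([-1.0, 1.0, 1.0])
        m[:2, 2] = [3.0, -2.0]
        assert classify(AffineMatrix(m), (8, 8), (8, 8)) is DispatchClass.EXACT_OP

    def test_fractional_zoom_is_axis_interp(self):
        m = np.diag([5.0 / 6.0, 5.0 / 6.0, 1.0])
        assert classify(AffineMatrix(m), (60, 60), (72, 72)) is DispatchClass.AXIS_INTERP

    def test_quarter_turn_between_uneven_extents_is_exact(self):
        # centre offsets are half-integers, but the index map is integral
        from lazyresample import rotate90

        img = make_meta_image(np.zeros((1, 4, 7), dtype=np.float32))
        out = rotate90(img, 1)
        op = out.pending[0]
        assert op.output_shape == (7, 4)
        assert classify(op.operation, op.input_shape, op.output_shape) is DispatchClass.EXACT_OP

    def test_near_identity_within_tolerance_snaps_exact(self):
        wobble = np.eye(3)
        wobble[0, 0] = 1.0 + 1e-6
        assert classify(AffineMatrix(wobble), (8, 8), (8, 8)) is DispatchClass.EXACT_OP


def _random_exact_group(rng, shape, interp):
    n = len(shape)
    perm = rng.permutation(n)
    signs = rng.choice([-1.0, 1.0], size=n)
    s = np.zeros((n, n))
    out = [0] * n
    for r, c in enumerate(perm):
        s[r, c] = signs[r]
        out[c] = int(shape[r])  # output axis c sources input axis r
    out_shape = tuple(out)
    # integer index-space shift, folded back into centre-coordinate translation
    t_idx = rng.integers(-3, 4, size=n).astype(float)
    c_in = (np.asarray(shape) - 1.0) / 2.0
    c_out = (np.asarray(out_shape) - 1.0) / 2.0
    t = t_idx + s @ c_out - c_in
    m = np.eye(n + 1)
    m[:n, :n] = s
    m[:n, n] = t
    op = _op(m, shape, out_shape, interp=interp)
    return build_groups([op])[0]


class TestExactPath:
    def test_rot90_group_transposes_and_reverses(self):
        img = make_meta_image(np.arange(24, dtype=np.float32).reshape(1, 4, 6))
        from lazyresample import rotate90

        out = apply_all(rotate90(img, 1))
        assert out.spatial_shape == (6, 4)
        assert np.array_equal(out.data[0], np.rot90(img.data[0]))

    @pytest.mark.parametrize("interp", ["nearest", "linear"])
    def test_exact_gather_matches_general_resampler(self, rng, interp):
        data = rng.random((1, 16, 16, 16)).astype(np.float32)
        for _ in range(40):
            group = _random_exact_group(rng, (16, 16, 16), interp)
            cls = classify(group.operation, group.in_shape, group.out_shape)
            assert cls is DispatchClass.EXACT_OP
            exact = apply_exact(data, group)
            general = resample(data, group)
            assert np.array_equal(exact, general)

    def test_pure_permutation_preserves_value_multiset(self, rng):
        data = rng.random((1, 6, 7, 8)).astype(np.float32)
        perm_group = _random_exact_group(rng, (6, 7, 8), "nearest")
        # choose the translation so every index maps in-bounds (no padding):
        # identity axes shift by 0, reversed axes by extent-1
        m = perm_group.operation.values.copy()
        s = m[:3, :3]
        c_in = (np.asarray(perm_group.in_shape) - 1.0) / 2.0
        c_out = (np.asarray(perm_group.out_shape) - 1.0) / 2.0
        t_idx = np.where(s.sum(axis=1) < 0, np.asarray(perm_group.in_shape) - 1.0, 0.0)
        m[:3, 3] = t_idx + s @ c_out - c_in
        perm_group.operation = AffineMatrix(m)
        out = apply_exact(data, perm_group)
        assert sorted(out.ravel()) == sorted(data.ravel())


class TestResample:
    def test_identity_matrix_returns_input_values(self, rng):
        data = rng.random((2, 9, 9)).astype(np.float32)
        group = build_groups([_op(np.eye(3), (9, 9))])[0]
        out = resample(data, group)
        assert np.allclose(out, data, atol=1e-7)

    def test_nearest_double_upsample_duplicates_samples(self):
        data = np.array([[[1.0, 2.0]]], dtype=np.float32)  # row (a, b)
        m = np.diag([1.0, 0.5, 1.0])
        group = build_groups([_op(m, (1, 2), (1, 4), interp="nearest")])[0]
        out = resample(data, group)
        assert np.array_equal(out[0, 0], [1.0, 1.0, 2.0, 2.0])

    def test_nearest_output_values_subset_of_input(self, rng):
        labels = rng.integers(0, 4, size=(1, 10, 10, 10)).astype(np.int16)
        for _ in range(10):
            angles = rng.uniform(-0.6, 0.6, size=3)
            m = rotation_matrix(3, angles)
            m[:3, 3] = rng.uniform(-2, 2, size=3)
            group = build_groups([_op(m, (10, 10, 10), interp="nearest", dtype="int16")])[0]
            out = resample(labels, group)
            assert set(np.unique(out)) <= set(np.unique(labels))

    def test_checkerboard_rescale_creates_intermediate_values(self):
        from lazyresample import checkerboard

        board = checkerboard((64, 64), 1)[np.newaxis]
        m = np.diag([5.0 / 6.0, 5.0 / 6.0, 1.0])
        group = build_groups([_op(m, (64, 64), (77, 77))])[0]
        out = resample(board, group)
        new_vals = np.setdiff1d(np.unique(out), np.unique(board))
        assert new_vals.size > 0
        assert np.all((new_vals > 0) & (new_vals < 1))

    def test_vector_grid_identity_passthrough(self, rng):
        data = rng.random((1, 5, 6)).astype(np.float32)
        # grid holding each output voxel's own centred input coordinate
        coords = np.indices((5, 6), dtype=np.float64)
        centred = coords - ((np.array([5, 6]) - 1.0) / 2.0)[:, None, None]
        grid = VectorGrid(np.moveaxis(centred, 0, -1))
        group = build_groups([_op(grid, (5, 6), (5, 6), interp="nearest")])[0]
        out = resample(data, group)
        assert np.array_equal(out, data)


class TestPaddingModes:
    def test_border_clamps_to_edge(self):
        img = make_meta_image(np.array([[[1.0], [2.0], [3.0]]], dtype=np.float32))
        out = translate(img, (2, 0), lazy=False, padding_mode="border")
        assert np.array_equal(out.data[0, :, 0], [1.0, 1.0, 1.0])

    def test_reflection_mirrors_without_edge_repeat(self):
        img = make_meta_image(np.array([[[1.0], [2.0], [3.0]]], dtype=np.float32))
        out = translate(img, (2, 0), lazy=False, padding_mode="reflection")
        assert np.array_equal(out.data[0, :, 0], [3.0, 2.0, 1.0])

    def test_zeros_fills_constant(self):
        img = make_meta_image(np.array([[[1.0], [2.0], [3.0]]], dtype=np.float32))
        out = translate(img, (2, 0), lazy=False, padding_mode="zeros")
        assert np.array_equal(out.data[0, :, 0], [0.0, 0.0, 1.0])


class TestApplyAll:
    def test_empty_pending_is_noop(self, random_volume):
        assert apply_all(random_volume) is random_volume

    def test_worked_identity_chain_is_bit_exact(self, rng):
        img = make_meta_image(rng.random((1, 32, 32)).astype(np.float32))
        deg = math.radians
        out = rotate(img, deg(45))
        out = zoom(out, 1.25)
        out = rotate(out, deg(22))
        out = rotate(out, deg(-22))
        out = zoom(out, 0.8)
        out = rotate(out, deg(-45))
        applied = apply_all(out)
        assert np.array_equal(applied.data, img.data)
        assert applied.trace[-1].extra["dispatch"] == "exact_op"

    def test_whole_volume_chain_uses_single_interpolation(self, rng):
        from lazyresample import Instrumentation, rotate90

        img = make_meta_image(
            rng.random((1, 16, 16, 16)).astype(np.float32), spacing=(1, 1, 1.25)
        )
        out = spacing(img, (1, 1, 1))
        out = flip(out, (0,))
        out = rotate90(out, 1)
        out = zoom(out, 1.1)
        out = rotate(out, (0.2, 0.1, 0.05))
        counters = Instrumentation()
        applied = apply_all(out, counters=counters)
        assert counters.interpolation_events == 1
        assert counters.exact_events == 0
        assert len(applied.trace) == 1

    def test_world_affine_and_spacing_track_apply(self, rng):
        img = make_meta_image(
            rng.random((1, 10, 10)).astype(np.float32), spacing=(2.0, 2.0)
        )
        out = apply_all(spacing(img, (1.0, 1.0)))
        assert out.spatial_shape == (20, 20)
        assert np.allclose(out.voxel_spacing, (1.0, 1.0))
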