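"""Compose pending operations and execute them with the cheapest correct path.

Given an image's pending-op list, :func:`build_groups` greedily merges
compatible matrix ops (same interpolation mode, padding mode and output
dtype; vector grids never merge) into :class:`ComposedGroup` instances by
matrix product.  Each group is then dispatched by :func:`classify`:

``exact_op``
    The composed map is a signed permutation of the axes with integer
    translation — executed bit-exactly by axis permutation / reversal /
    integer slicing and padding, with no arithmetic on the values.
``axis_interp``
    Axis-aligned but with non-integer scale or translation — interpolation
    along the axes is required.  Executed through the general resampler
    (a separable fast path would change cost, not output).
``full_resample``
    Anything with a rotated/sheared orientation — full resample.

Index mapping convention (pull, centre-origin):
``i = S @ (o - c_out) + t + c_in`` where ``o`` is the integer output index,
``c = (extent - 1) / 2`` per axis, and ``[S | t]`` is the homogeneous matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import (
    AffineMatrix,
    MetaImage,
    PendingOp,
    SUPPORTED_DTYPES,
    TraceRecord,
    VectorGrid,
    validate_chain,
)

__all__ = [
    "MATRIX_TOL",
    "DispatchClass",
    "ComposedGroup",
    "compose_affine",
    "build_groups",
    "classify",
    "apply_exact",
    "resample",
    "apply_all",
]

#: Absolute tolerance on matrix entries for orthogonality/integrality tests.
#: Wide enough that float parameter round-trips (e.g. 6/5 x 5/6) still
#: classify as exact.
MATRIX_TOL = 1e-5

_SCIPY_PAD_MODE = {
    "zeros": "grid-constant",
    "border": "nearest",
    "reflection": "mirror",  # mirror: edge sample not repeated
}


class DispatchClass(Enum):
    EXACT_OP = "exact_op"
    AXIS_INTERP = "axis_interp"
    FULL_RESAMPLE = "full_resample"


@dataclass
class ComposedGroup:
    """A run of compatible pending ops collapsed to one operation."""

    operation: AffineMatrix | VectorGrid
    in_shape: tuple[int, ...]
    out_shape: tuple[int, ...]
    interpolation_mode: str
    padding_mode: str
    in_dtype: str
    out_dtype: str
    members: tuple[PendingOp, ...]

    @property
    def is_matrix(self) -> bool:
        return isinstance(self.operation, AffineMatrix)


def compose_affine(a: AffineMatrix, b: AffineMatrix) -> AffineMatrix:
    """Compose two pull matrices: result == apply ``a`` then ``b``.

    With pull matrices (output -> input) pipeline order reads left to right
    under right-multiplication: the final output coordinate passes through
    ``b`` to reach ``a``'s output space, then through ``a``.
    """
    return AffineMatrix(a.values @ b.values)


def build_groups(pending: Sequence[PendingOp]) -> list[ComposedGroup]:
    """Greedy left-to-right grouping of a shape-chained pending list.

    A matrix op merges into the open group when interpolation mode, padding
    mode and output dtype are unchanged; anything else (including any vector
    grid) closes the group and opens a new one.
    """
    groups: list[ComposedGroup] = []
    current: ComposedGroup | None = None
    for op in pending:
        compatible = (
            current is not None
            and current.is_matrix
            and op.is_matrix
            and op.interpolation_mode == current.interpolation_mode
            and op.padding_mode == current.padding_mode
            and op.output_dtype == current.out_dtype
        )
        if compatible:
            assert current is not None
            current.operation = compose_affine(current.operation, op.operation)
            current.out_shape = op.output_shape
            current.out_dtype = op.output_dtype
            current.members = current.members + (op,)
        else:
            if current is not None:
                groups.append(current)
            current = ComposedGroup(
                operation=op.operation,
                in_shape=op.input_shape,
                out_shape=op.output_shape,
                interpolation_mode=op.interpolation_mode,
                padding_mode=op.padding_mode,
                in_dtype=op.input_dtype,
                out_dtype=op.output_dtype,
                members=(op,),
            )
    if current is not None:
        groups.append(current)
    return groups


def _centre(shape: Sequence[int]) -> np.ndarray:
    return (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0


def index_affine(
    matrix: AffineMatrix, in_shape: Sequence[int], out_shape: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(S, t_idx)`` of the index-space map ``i = S @ o + t_idx``."""
    s = matrix.spatial
    t = matrix.translation
    t_idx = -s @ _centre(out_shape) + t + _centre(in_shape)
    return s, t_idx


def classify(
    matrix: AffineMatrix,
    in_shape: Sequence[int],
    out_shape: Sequence[int],
    tol: float = MATRIX_TOL,
) -> DispatchClass:
    """Dispatch class of a composed matrix for the given shape pair.

    ``exact_op`` requires a signed permutation spatial block and an integer
    effective index-space translation; ``axis_interp`` requires the spatial
    block to be a permutation-with-scales (axis-aligned); everything else is
    a full resample.
    """
    s, t_idx = index_affine(matrix, in_shape, out_shape)
    n = s.shape[0]
    absent = np.abs(s)
    nonzero = absent > tol
    axis_aligned = bool(
        np.all(nonzero.sum(axis=0) == 1) and np.all(nonzero.sum(axis=1) == 1)
    )
    if not axis_aligned:
        return DispatchClass.FULL_RESAMPLE
    unit_entries = bool(np.all(np.abs(absent[nonzero] - 1.0) <= tol))
    integer_shift = bool(np.all(np.abs(t_idx - np.round(t_idx)) <= tol))
    if unit_entries and integer_shift:
        return DispatchClass.EXACT_OP
    return DispatchClass.AXIS_INTERP


def _fold_indices(idx: np.ndarray, n: int, padding_mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Map raw integer indices into [0, n) per padding mode.

    Returns (indices, oob_mask); for ``zeros`` the mask marks positions to be
    overwritten with 0 after the gather.
    """
    oob = (idx < 0) | (idx >= n)
    if padding_mode == "zeros":
        return np.clip(idx, 0, n - 1), oob
    if padding_mode == "border":
        return np.clip(idx, 0, n - 1), np.zeros_like(oob)
    if padding_mode == "reflection":
        if n == 1:
            return np.zeros_like(idx), np.zeros_like(oob)
        period = 2 * (n - 1)
        m = np.mod(idx, period)
        m = np.where(m >= n, period - m, m)
        return m, np.zeros_like(oob)
    raise ValueError(f"unknown padding mode {padding_mode!r}")


def apply_exact(data: np.ndarray, group: ComposedGroup) -> np.ndarray:
    """Execute an ``exact_op`` group by pure axis gather — bit-exact.

    No arithmetic touches the values: each output axis indexes one input axis
    (possibly reversed and shifted), with out-of-range indices handled per
    padding mode (zeros are written after the gather).
    """
    assert group.is_matrix
    s, t_idx = index_affine(group.operation, group.in_shape, group.out_shape)
    n = s.shape[0]
    t_int = np.round(t_idx).astype(np.int64)
    # input axis r is sourced from output axis col(r); invert to per-output-axis
    col_of_row = [int(np.argmax(np.abs(s[r]))) for r in range(n)]
    row_of_col = [col_of_row.index(a) for a in range(n)]

    # reorder input spatial axes so input axis row_of_col[a] sits at output slot a
    arr = np.transpose(data, (0,) + tuple(1 + r for r in row_of_col))
    masks: list[np.ndarray | None] = []
    for a in range(n):
        r = row_of_col[a]
        sign = 1 if s[r, col_of_row[r]] > 0 else -1
        raw = sign * np.arange(group.out_shape[a], dtype=np.int64) + t_int[r]
        idx, oob = _fold_indices(raw, group.in_shape[r], group.padding_mode)
        arr = np.take(arr, idx, axis=1 + a)
        masks.append(oob if oob.any() else None)
    out = np.ascontiguousarray(arr)
    for a, oob in enumerate(masks):
        if oob is not None:
            sl: list = [slice(None)] * out.ndim
            sl[1 + a] = oob
            out[tuple(sl)] = 0
    return out.astype(SUPPORTED_DTYPES[group.out_dtype], copy=False)


def _pull_coords(group: ComposedGroup) -> np.ndarray:
    """Input index coordinates, shape ``(N, *out_shape)``, float64."""
    n = len(group.out_shape)
    if group.is_matrix:
        s, t_idx = index_affine(group.operation, group.in_shape, group.out_shape)
        o = np.indices(group.out_shape, dtype=np.float64)
        coords = np.tensordot(s, o.reshape(n, -1), axes=1) + t_idx[:, None]
        return coords.reshape((n, *group.out_shape))
    # vector grid: centred input coords per output voxel
    grid = np.moveaxis(group.operation.vectors, -1, 0)
    return grid + _centre(group.in_shape).reshape((n,) + (1,) * n)


def _gather_nearest(
    channel: np.ndarray, coords: np.ndarray, padding_mode: str
) -> np.ndarray:
    """Nearest-neighbour gather; half-way ties resolve to the lower index."""
    idx = np.ceil(coords - 0.5).astype(np.int64)
    n = channel.ndim
    folded = []
    oob_any = np.zeros(coords.shape[1:], dtype=bool)
    for a in range(n):
        fa, oob = _fold_indices(idx[a], channel.shape[a], padding_mode)
        folded.append(fa)
        oob_any |= oob
    out = channel[tuple(folded)]
    if oob_any.any():
        out = out.copy()
        out[oob_any] = 0
    return out


def resample(data: np.ndarray, group: ComposedGroup) -> np.ndarray:
    """Universal resampler: sample the input at matrix/grid-mapped coordinates.

    Linear interpolation runs in float64 through ``scipy.ndimage``; nearest
    mode is a pure gather so the output value set is a subset of the input's.
    """
    coords = _pull_coords(group)
    out_dtype = SUPPORTED_DTYPES[group.out_dtype]
    channels = []
    for c in range(data.shape[0]):
        channel = data[c]
        if group.interpolation_mode == "nearest":
            channels.append(_gather_nearest(channel, coords, group.padding_mode))
        elif group.interpolation_mode == "linear":
            sampled = ndimage.map_coordinates(
                channel.astype(np.float64, copy=False),
                coords,
                order=1,
                mode=_SCIPY_PAD_MODE[group.padding_mode],
                cval=0.0,
                prefilter=False,
            )
            if out_dtype.kind in "iu":
                sampled = np.rint(sampled)
            channels.append(sampled)
        else:  # pragma: no cover - PendingOp validation rejects earlier
            raise ValueError(f"unsupported interpolation mode {group.interpolation_mode!r}")
    return np.stack(channels).astype(out_dtype, copy=False)


def _index_homogeneous(group: ComposedGroup) -> np.ndarray:
    s, t_idx = index_affine(group.operation, group.in_shape, group.out_shape)
    n = s.shape[0]
    mat = np.eye(n + 1)
    mat[:n, :n] = s
    mat[:n, n] = t_idx
    return mat


def apply_all(img: MetaImage, counters=None) -> MetaImage:
    """Apply all pending ops: group, classify, dispatch; trace one record per group.

    The world affine is updated by each applied matrix group (grid groups
    leave it untouched — their map is not expressible as an affine), and the
    voxel spacing is recomputed from the updated affine's column norms.
    """
    if not img.pending:
        return img
    validate_chain(img)
    groups = build_groups(img.pending)
    data = img.data
    world = img.world_affine
    records: list[TraceRecord] = []
    for group in groups:
        if group.is_matrix:
            cls = classify(group.operation, group.in_shape, group.out_shape)
        else:
            cls = DispatchClass.FULL_RESAMPLE
        if cls is DispatchClass.EXACT_OP:
            data = apply_exact(data, group)
            if counters is not None:
                counters.record("exact_op", shape=group.out_shape)
        else:
            data = resample(data, group)
            if counters is not None:
                counters.record("resample", dispatch=cls.value, shape=group.out_shape)
        if group.is_matrix:
            world = AffineMatrix(world.values @ _index_homogeneous(group))
        composed = PendingOp(
            operation=group.operation,
            input_shape=group.in_shape,
            input_dtype=group.in_dtype,
            output_shape=group.out_shape,
            output_dtype=group.out_dtype,
            interpolation_mode=group.interpolation_mode,
            padding_mode=group.padding_mode,
            source_name="+".join(m.source_name for m in group.members),
        )
        records.append(TraceRecord(composed, {"dispatch": cls.value}))
    spacing = tuple(
        float(np.linalg.norm(world.spatial[:, j])) for j in range(world.ndim)
    )
    return replace(
        img,
        data=data,
        world_affine=world,
        pending=(),
        trace=img.trace + tuple(records),
        voxel_spacing=spacing,
    )
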