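"""The transform vocabulary: each spatial op emits a pending description.

Every deterministic spatial operation shares one contract: build a pull
matrix plus output shape, append it to the image's pending list, and — when
``lazy=False`` — immediately apply everything pending.  Randomised variants
draw their parameters first, from a caller-supplied generator, so that lazy
and traditional executions of the same seed see identical draws.

Two API layers are provided:

* plain functions (``rotate``, ``zoom``, ...) for direct use;
* thin :class:`Transform` classes wrapping them, which is what the pipeline
  compiler consumes (they carry the per-instance ``lazy`` flag and the
  capability flags the compiler dispatches on).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .core import (
    AffineMatrix,
    MetaImage,
    NotInvertibleError,
    PendingOp,
    TraceRecord,
    dtype_tag,
    effective_dtype,
    effective_shape,
    is_integer_tag,
    push_pending,
)
from .resampler import apply_all

__all__ = [
    "rotate",
    "rotate90",
    "flip",
    "zoom",
    "translate",
    "spacing",
    "crop_patch",
    "resize",
    "rand_rotate",
    "rand_zoom",
    "rand_flip",
    "add_noise",
    "invert_record",
    "rotation_matrix",
    "Transform",
    "Rotate",
    "Rotate90",
    "Flip",
    "Zoom",
    "Translate",
    "Spacing",
    "CropPatch",
    "Resize",
    "RandRotate",
    "RandZoom",
    "RandFlip",
    "AddNoise",
    "MultiCrop",
]

#: rotation planes, in application order, for 3 angles in 3D
_PLANES_3D = ((0, 1), (0, 2), (1, 2))


def _round_extent(value: float) -> int:
    """Round half away from zero, minimum extent 1."""
    return max(1, int(math.floor(abs(value) + 0.5)))


def _default_interp(img: MetaImage, override: str | None) -> str:
    if override is not None:
        return override
    return "nearest" if is_integer_tag(effective_dtype(img)) else "linear"


def _matrix_op(
    img: MetaImage,
    matrix: np.ndarray,
    out_shape: Sequence[int],
    name: str,
    interpolation_mode: str | None,
    padding_mode: str,
) -> PendingOp:
    tag = effective_dtype(img)
    return PendingOp(
        operation=AffineMatrix(matrix),
        input_shape=effective_shape(img),
        input_dtype=tag,
        output_shape=tuple(int(s) for s in out_shape),
        output_dtype=tag,
        interpolation_mode=_default_interp(img, interpolation_mode),
        padding_mode=padding_mode,
        source_name=name,
    )


def _finish(img: MetaImage, op: PendingOp, lazy: bool, counters=None) -> MetaImage:
    img = push_pending(img, op)
    if lazy:
        return img
    return apply_all(img, counters=counters)


def _embed_plane(n: int, plane: tuple[int, int], block: np.ndarray) -> np.ndarray:
    mat = np.eye(n + 1)
    a, b = plane
    mat[a, a], mat[a, b] = block[0, 0], block[0, 1]
    mat[b, a], mat[b, b] = block[1, 0], block[1, 1]
    return mat


def rotation_matrix(ndim: int, angles: Sequence[float]) -> np.ndarray:
    """Pull homogeneous matrix for a centre rotation.

    2D takes one angle; 3D takes three, applied as plane rotations in the
    order (0,1), (0,2), (1,2).  The pull block for angle theta is
    ``[[cos, sin], [-sin, cos]]`` (inverse of the content rotation).
    """
    angles = [float(a) for a in np.atleast_1d(angles)]
    if ndim == 2:
        if len(angles) != 1:
            raise ValueError(f"2D rotation takes 1 angle, got {len(angles)}")
        planes = [(0, 1)]
    elif ndim == 3:
        if len(angles) != 3:
            raise ValueError(f"3D rotation takes 3 angles, got {len(angles)}")
        planes = list(_PLANES_3D)
    else:
        raise ValueError(f"rotation supports 2 or 3 spatial dims, got {ndim}")
    mat = np.eye(ndim + 1)
    for theta, plane in zip(angles, planes):
        c, s = math.cos(theta), math.sin(theta)
        pull = np.array([[c, s], [-s, c]])
        mat = mat @ _embed_plane(ndim, plane, pull)
    return mat


# ---------------------------------------------------------------------------
# deterministic ops
# ---------------------------------------------------------------------------


def rotate(
    img: MetaImage,
    angles: float | Sequence[float],
    *,
    lazy: bool = True,
    interpolation_mode: str | None = None,
    padding_mode: str = "zeros",
    counters=None,
) -> MetaImage:
    """Rotate about the array centre; output extents equal input extents."""
    n = img.spatial_ndim if not img.pending else len(effective_shape(img))
    mat = rotation_matrix(n, angles)
    op = _matrix_op(img, mat, effective_shape(img), "rotate", interpolation_mode, padding_mode)
    return _finish(img, op, lazy, counters)


def rotate90(
    img: MetaImage,
    k: int,
    plane: tuple[int, int] = (0, 1),
    *,
    lazy: bool = True,
    interpolation_mode: str | None = None,
    padding_mode: str = "zeros",
    counters=None,
) -> MetaImage:
    """Quarter-turn rotation in a spatial plane; exactly orthogonal matrix.

    Orientation matches ``np.rot90(data, k, axes=plane)`` on the spatial axes.
    Odd ``k`` swaps the two extents of the plane.
    """
    shape = effective_shape(img)
    n = len(shape)
    if k not in (0, 1, 2, 3):
        raise ValueError(f"k must be in 0..3, got {k}")
    a, b = plane
    if not (0 <= a < n and 0 <= b < n) or a == b:
        raise ValueError(f"invalid rotation plane {plane} for {n} spatial dims")
    # pull block of one CCW quarter turn (out[i,j] = in[j, W-1-i])
    step = np.array([[0.0, 1.0], [-1.0, 0.0]])
    block = np.linalg.matrix_power(step, k)
    mat = _embed_plane(n, plane, block)
    out_shape = list(shape)
    if k % 2 == 1:
        out_shape[a], out_shape[b] = shape[b], shape[a]
    op = _matrix_op(img, mat, out_shape, f"rotate90(k={k})", interpolation_mode, padding_mode)
    return _finish(img, op, lazy, counters)


def flip(
    img: MetaImage,
    axes: int | Sequence[int],
    *,
    lazy: bool = True,
    interpolation_mode: str | None = None,
    padding_mode: str = "zeros",
    counters=None,
) -> MetaImage:
    """Reverse the given spatial axes (lossless diagonal +/-1 matrix)."""
    shape = effective_shape(img)
    n = len(shape)
    axes = tuple(np.atleast_1d(axes).astype(int)) if axes is not None else ()
    if any(not 0 <= a < n for a in axes):
        raise ValueError(f"flip axes {axes} out of range for {n} spatial dims")
    mat = np.eye(n + 1)
    for a in set(axes):
        mat[a, a] = -1.0
    op = _matrix_op(img, mat, shape, "flip", interpolation_mode, padding_mode)
    return _finish(img, op, lazy, counters)


def zoom(
    img: MetaImage,
    factors: float | Sequence[float],
    *,
    keep_size: bool = False,
    lazy: bool = True,
    interpolation_mode: str | None = None,
    padding_mode: str = "zeros",
    counters=None,
) -> MetaImage:
    """Scale about the centre; output extents are ``round(extent * factor)``.

    With ``keep_size=True`` the extents stay fixed and content zooms about
    the centre within the same field of view.
    """
    shape = effective_shape(img)
    n = len(shape)
    f = np.broadcast_to(np.asarray(factors, dtype=np.float64), (n,)).copy()
    if np.any(f <= 0):
        raise ValueError(f"zoom factors must be > 0, got {tuple(f)}")
    mat = np.eye(n + 1)
    mat[range(n), range(n)] = 1.0 / f
    out_shape = shape if keep_size else tuple(_round_extent(s * fi) for s, fi in zip(shape, f))
    op = _matrix_op(img, mat, out_shape, "zoom", interpolation_mode, padding_mode)
    return _finish(img, op, lazy, counters)


def translate(
    img: MetaImage,
    offsets: float | Sequence[float],
    *,
    lazy: bool = True,
    interpolation_mode: str | None = None,
    padding_mode: str = "zeros",
    counters=None,
) -> MetaImage:
    """Shift content by ``offsets`` voxels (pull translation is ``-offsets``)."""
    shape = effective_shape(img)
    n = len(shape)
    off = np.broadcast_to(np.asarray(offsets, dtype=np.float64), (n,))
    if not np.all(np.isfinite(off)):
        raise ValueError(f"offsets must be finite, got {tuple(off)}")
    mat = np.eye(n + 1)
    mat[:n, n] = -off
    op = _matrix_op(img, mat, shape, "translate", interpolation_mode, padding_mode)
    return _finish(img, op, lazy, counters)


def spacing(
    img: MetaImage,
    target_spacing: float | Sequence[float],
    *,
    lazy: bool = True,
    interpolation_mode: str | None = None,
    padding_mode: str = "zeros",
    counters=None,
) -> MetaImage:
    """Resample to a target physical spacing (mm per voxel).

    The per-axis scale factor is ``current / target``; the voxel-spacing
    metadata is updated when the pending ops are applied (via the world
    affine).
    """
    shape = effective_shape(img)
    n = len(shape)
    current = np.asarray(img.voxel_spacing, dtype=np.float64)
    if current.size != n or np.any(current <= 0):
        raise ValueError(f"current voxel spacing unknown or invalid: {img.voxel_spacing}")
    target = np.broadcast_to(np.asarray(target_spacing, dtype=np.float64), (n,))
    if np.any(target <= 0):
        raise ValueError(f"target spacing must be > 0, got {tuple(target)}")
    factors = current / target
    mat = np.eye(n + 1)
    mat[range(n), range(n)] = 1.0 / factors
    out_shape = tuple(_round_extent(s * fi) for s, fi in zip(shape, factors))
    op = _matrix_op(img, mat, out_shape, "spacing", interpolation_mode, padding_mode)
    return _finish(img, op, lazy, counters)


def crop_patch(
    img: MetaImage,
    start: Sequence[int],
    size: Sequence[int],
    *,
    lazy: bool = True,
    interpolation_mode: str | None = None,
    padding_mode: str = "zeros",
    counters=None,
) -> MetaImage:
    """Take a viewport of extents ``size`` starting at voxel ``start``.

    Lazily this is a pure translation with a changed output shape: no data is
    destroyed until the pending ops are applied, so later transforms can
    still recover content outside the window.  The window may extend past
    the array; padding covers the remainder at apply time.
    """
    shape = effective_shape(img)
    n = len(shape)
    start = np.broadcast_to(np.asarray(start, dtype=np.float64), (n,))
    size = tuple(int(s) for s in np.broadcast_to(np.asarray(size, dtype=np.int64), (n,)))
    if any(s < 1 for s in size):
        raise ValueError(f"patch size must be >= 1 per axis, got {size}")
    mat = np.eye(n + 1)
    mat[:n, n] = (
        start + (np.asarray(size) - 1.0) / 2.0 - (np.asarray(shape) - 1.0) / 2.0
    )
    op = _matrix_op(img, mat, size, "crop_patch", interpolation_mode, padding_mode)
    return _finish(img, op, lazy, counters)


def resize(
    img: MetaImage,
    target_shape: Sequence[int],
    *,
    lazy: bool = True,
    interpolation_mode: str | None = None,
    padding_mode: str = "zeros",
    counters=None,
) -> MetaImage:
    """Scale each axis to hit ``target_shape`` exactly (zoom with shape override)."""
    shape = effective_shape(img)
    n = len(shape)
    target = tuple(int(s) for s in np.broadcast_to(np.asarray(target_shape, dtype=np.int64), (n,)))
    if any(s < 1 for s in target):
        raise ValueError(f"target extents must be >= 1, got {target}")
    factors = np.asarray(target, dtype=np.float64) / np.asarray(shape, dtype=np.float64)
    mat = np.eye(n + 1)
    mat[range(n), range(n)] = 1.0 / factors
    op = _matrix_op(img, mat, target, "resize", interpolation_mode, padding_mode)
    return _finish(img, op, lazy, counters)


# ---------------------------------------------------------------------------
# randomised ops — parameters are drawn BEFORE the lazy branch so that lazy
# and traditional runs of the same stream see identical transforms
# ---------------------------------------------------------------------------


def rand_rotate(
    img: MetaImage,
    angle_range: float | Sequence[float],
    prob: float,
    rng: np.random.Generator,
    **kwargs,
) -> MetaImage:
    """Rotate by angles drawn uniformly from ``[-range, range]`` per plane."""
    n = len(effective_shape(img))
    n_angles = 1 if n == 2 else 3
    ranges = np.broadcast_to(np.asarray(angle_range, dtype=np.float64), (n_angles,))
    if np.any(ranges < 0):
        raise ValueError("angle ranges must be non-negative")
    angles = rng.uniform(-ranges, ranges)
    fire = rng.random() < prob
    if not fire:
        return img
    return rotate(img, angles, **kwargs)


def rand_zoom(
    img: MetaImage,
    low: float,
    high: float,
    prob: float,
    rng: np.random.Generator,
    **kwargs,
) -> MetaImage:
    """Isotropic zoom with factor drawn uniformly from ``[low, high]``."""
    if not 0 < low <= high:
        raise ValueError(f"invalid zoom range ({low}, {high})")
    factor = rng.uniform(low, high)
    fire = rng.random() < prob
    if not fire:
        return img
    return zoom(img, factor, **kwargs)


def rand_flip(
    img: MetaImage,
    prob: float,
    rng: np.random.Generator,
    axes: Sequence[int] | None = None,
    **kwargs,
) -> MetaImage:
    """Flip each candidate axis independently with probability ``prob``."""
    n = len(effective_shape(img))
    candidates = tuple(range(n)) if axes is None else tuple(axes)
    chosen = tuple(a for a in candidates if rng.random() < prob)
    if not chosen:
        return img
    return flip(img, chosen, **kwargs)


def add_noise(
    img: MetaImage,
    sigma: float,
    rng: np.random.Generator,
    *,
    counters=None,
    **_ignored,
) -> MetaImage:
    """Additive Gaussian intensity noise — deliberately NON-lazy.

    Noise must act on concrete voxel values, so any pending spatial ops are
    applied first (in a compiled pipeline the compiler inserts the apply
    stage explicitly before this transform).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if img.pending:
        img = apply_all(img, counters=counters)
    if sigma == 0:
        return img
    noisy = img.data.astype(np.float64) + rng.normal(0.0, sigma, img.data.shape)
    from dataclasses import replace

    return replace(img, data=noisy.astype(img.data.dtype, copy=False))


def invert_record(rec: TraceRecord) -> PendingOp:
    """Inverse description of an applied operation.

    The matrix is inverted and input/output shapes (and dtypes) swap; the
    interpolation and padding modes of the forward op are preserved.  Grid
    operations and singular matrices raise :class:`NotInvertibleError`.
    """
    op = rec.pending
    if not op.is_matrix:
        raise NotInvertibleError("vector-grid operations are not invertible")
    inverse = op.operation.inverse()  # raises NotInvertibleError when singular
    return PendingOp(
        operation=inverse,
        input_shape=op.output_shape,
        input_dtype=op.output_dtype,
        output_shape=op.input_shape,
        output_dtype=op.input_dtype,
        interpolation_mode=op.interpolation_mode,
        padding_mode=op.padding_mode,
        source_name=f"inverse({op.source_name})",
    )


# ---------------------------------------------------------------------------
# Transform classes — the surface the pipeline compiler consumes
# ---------------------------------------------------------------------------


class Transform:
    """Base class: a named, optionally lazy pipeline stage.

    ``lazy`` of ``None`` defers to the pipeline's default; the compiler reads
    ``is_lazy_capable`` / ``is_multi_sample`` / ``requires_rng`` to decide
    where apply stages go and which stages get a random stream.
    """

    name: str = "transform"
    lazy: bool | None = None
    is_lazy_capable: bool = True
    is_multi_sample: bool = False
    requires_rng: bool = False

    def __call__(
        self, img: MetaImage, lazy: bool | None = None, rng=None, counters=None
    ) -> MetaImage:
        raise NotImplementedError

    def _effective_lazy(self, lazy: bool | None) -> bool:
        if lazy is not None:
            return lazy
        return True if self.lazy is None else self.lazy

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}(name={self.name!r}, lazy={self.lazy})"


class _FunctionalTransform(Transform):
    _func = None  # staticmethod set by subclass

    def __init__(
        self,
        *,
        lazy: bool | None = None,
        interpolation_mode: str | None = None,
        padding_mode: str = "zeros",
        **params,
    ) -> None:
        self.lazy = lazy
        self.interpolation_mode = interpolation_mode
        self.padding_mode = padding_mode
        self.params = params

    def __call__(self, img, lazy=None, rng=None, counters=None):
        kwargs = dict(
            self.params,
            lazy=self._effective_lazy(lazy),
            interpolation_mode=self.interpolation_mode,
            padding_mode=self.padding_mode,
            counters=counters,
        )
        if self.requires_rng:
            if rng is None:
                raise ValueError(f"{self.name} needs an rng stream")
            kwargs["rng"] = rng
        return type(self)._func(img, **kwargs)


def _make_class(name, func, *, requires_rng=False, lazy_capable=True):
    return type(
        name,
        (_FunctionalTransform,),
        {
            "name": func.__name__,
            "_func": staticmethod(func),
            "requires_rng": requires_rng,
            "is_lazy_capable": lazy_capable,
        },
    )


Rotate = _make_class("Rotate", rotate)
Rotate90 = _make_class("Rotate90", rotate90)
Flip = _make_class("Flip", flip)
Zoom = _make_class("Zoom", zoom)
Translate = _make_class("Translate", translate)
Spacing = _make_class("Spacing", spacing)
CropPatch = _make_class("CropPatch", crop_patch)
Resize = _make_class("Resize", resize)
RandRotate = _make_class("RandRotate", rand_rotate, requires_rng=True)
RandZoom = _make_class("RandZoom", rand_zoom, requires_rng=True)
RandFlip = _make_class("RandFlip", rand_flip, requires_rng=True)


class AddNoise(Transform):
    """Gaussian noise stage; cannot run lazily (forces an intermediate apply)."""

    name = "add_noise"
    is_lazy_capable = False
    requires_rng = True

    def __init__(self, sigma: float) -> None:
        self.sigma = sigma

    def __call__(self, img, lazy=None, rng=None, counters=None):
        if rng is None:
            raise ValueError("add_noise needs an rng stream")
        return add_noise(img, self.sigma, rng, counters=counters)


class MultiCrop(Transform):
    """Multi-sample patch transform: yields one lazy crop per patch.

    With ``starts`` given the patch positions are fixed; otherwise
    ``n_samples`` positions are drawn uniformly from the valid start range
    (patches stay inside the volume when it is large enough).
    """

    name = "multi_crop"
    is_multi_sample = True
    requires_rng = True

    def __init__(
        self,
        size: Sequence[int],
        n_samples: int | None = None,
        starts: Sequence[Sequence[int]] | None = None,
        *,
        lazy: bool | None = None,
    ) -> None:
        if (n_samples is None) == (starts is None):
            raise ValueError("give exactly one of n_samples or starts")
        self.size = tuple(int(s) for s in size)
        self.n_samples = n_samples
        self.starts = None if starts is None else [tuple(int(v) for v in s) for s in starts]
        self.lazy = lazy

    def sample_starts(self, img: MetaImage, rng) -> list[tuple[int, ...]]:
        if self.starts is not None:
            return list(self.starts)
        shape = effective_shape(img)
        highs = [max(0, s - p) for s, p in zip(shape, self.size)]
        return [
            tuple(int(rng.integers(0, h + 1)) for h in highs)
            for _ in range(int(self.n_samples))
        ]

    def sample_iter(self, img: MetaImage, rng, lazy: bool = True, counters=None):
        for start in self.sample_starts(img, rng):
            yield crop_patch(img, start, self.size, lazy=lazy, counters=counters)

    def __call__(self, img, lazy=None, rng=None, counters=None):  # pragma: no cover
        raise RuntimeError("MultiCrop must be executed inside a compiled pipeline")
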