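"""Metadata-carrying images and pending-transform descriptions.

The central idea borrowed from graphics pipelines: a spatial transform is a
*description* — a homogeneous matrix acting in voxel space, or a grid of
per-voxel sampling targets — that can be composed with other descriptions.
An image carries the ordered list of descriptions that have not yet been
executed (``pending``) plus a trace of the ones that have (``trace``), so a
whole chain of rotations, zooms, crops and flips can later be collapsed into
a single resample.

Conventions
-----------
* Arrays are channel-first, ``(C, *spatial)``, with 2 or 3 spatial dims.
* Matrices use the **pull** convention: a pending op's matrix maps OUTPUT
  voxel coordinates to INPUT voxel coordinates.  Resampling iterates output
  voxels, and composition reads left-to-right in pipeline order with
  right-multiplication (see :mod:`lazyresample.resampler`).
* Voxel coordinates are centred: index ``i`` maps to ``i - (extent - 1)/2``,
  so rotations and zooms act about the array centre.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "AffineMatrix",
    "VectorGrid",
    "PendingOp",
    "TraceRecord",
    "MetaImage",
    "NotInvertibleError",
    "ShapeChainError",
    "make_meta_image",
    "push_pending",
    "effective_shape",
    "effective_dtype",
    "validate_chain",
    "dtype_tag",
    "load_nifti",
    "save_nifti",
]

#: dtype tags supported for image payloads; labels must use an integer tag.
SUPPORTED_DTYPES: dict[str, np.dtype] = {
    "float32": np.dtype(np.float32),
    "float64": np.dtype(np.float64),
    "uint8": np.dtype(np.uint8),
    "int16": np.dtype(np.int16),
    "int32": np.dtype(np.int32),
    "int64": np.dtype(np.int64),
}

INTERPOLATION_MODES = ("linear", "nearest")
PADDING_MODES = ("zeros", "border", "reflection")

_LAST_ROW_TOL = 1e-9


class NotInvertibleError(ValueError):
    """A transform description cannot be inverted (singular matrix or grid)."""


class ShapeChainError(ValueError):
    """The pending-op shape chain is broken."""


def dtype_tag(dtype: Any) -> str:
    """Return the canonical tag for a supported dtype, else raise."""
    dt = np.dtype(dtype)
    for tag, candidate in SUPPORTED_DTYPES.items():
        if dt == candidate:
            return tag
    raise ValueError(
        f"unsupported dtype {dt!r}; supported: {sorted(SUPPORTED_DTYPES)}"
    )


def is_integer_tag(tag: str) -> bool:
    return SUPPORTED_DTYPES[tag].kind in "iu"


# ---------------------------------------------------------------------------
# transform descriptions
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class AffineMatrix:
    """A homogeneous (N+1)x(N+1) matrix over N in {2, 3} spatial dims.

    The last row must be ``[0, ..., 0, 1]``; the spatial block plus the
    translation column encode any affine map of voxel space.
    """

    values: np.ndarray

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AffineMatrix):
            return NotImplemented
        return np.array_equal(self.values, other.values)

    def __hash__(self) -> int:
        return hash(self.values.tobytes())

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValueError(f"affine matrix must be square, got {vals.shape}")
        n = vals.shape[0] - 1
        if n not in (2, 3):
            raise ValueError(f"affine matrix must be 3x3 or 4x4, got {vals.shape}")
        expected = np.zeros(n + 1)
        expected[-1] = 1.0
        if not np.allclose(vals[-1], expected, atol=_LAST_ROW_TOL):
            raise ValueError(f"last row must be {expected}, got {vals[-1]}")
        object.__setattr__(self, "values", vals)

    @property
    def ndim(self) -> int:
        """Number of spatial dimensions."""
        return self.values.shape[0] - 1

    @property
    def spatial(self) -> np.ndarray:
        return self.values[: self.ndim, : self.ndim]

    @property
    def translation(self) -> np.ndarray:
        return self.values[: self.ndim, self.ndim]

    @classmethod
    def identity(cls, ndim: int) -> "AffineMatrix":
        return cls(np.eye(ndim + 1))

    def is_identity(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.values, np.eye(self.ndim + 1), atol=tol))

    def inverse(self) -> "AffineMatrix":
        det = np.linalg.det(self.spatial)
        if abs(det) < 1e-12:
            raise NotInvertibleError(f"singular spatial block (det={det:.3e})")
        return AffineMatrix(np.linalg.inv(self.values))


@dataclass(frozen=True, eq=False)
class VectorGrid:
    """Per-output-voxel sampling targets, shape ``(*spatial, N)``.

    ``vectors[..., k]`` gives the centred INPUT voxel coordinate sampled for
    each output voxel along spatial axis ``k`` (pull form, like the matrices).
    """

    vectors: np.ndarray

    def __post_init__(self) -> None:
        vec = np.asarray(self.vectors, dtype=np.float64)
        if vec.ndim < 2 or vec.shape[-1] != vec.ndim - 1:
            raise ValueError(
                f"vector grid must have shape (*spatial, N); got {vec.shape}"
            )
        if vec.ndim - 1 not in (2, 3):
            raise ValueError("vector grid must be 2D or 3D")
        object.__setattr__(self, "vectors", vec)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VectorGrid):
            return NotImplemented
        return np.array_equal(self.vectors, other.vectors)

    def __hash__(self) -> int:
        return hash(self.vectors.tobytes())

    @property
    def ndim(self) -> int:
        return self.vectors.ndim - 1

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.vectors.shape[:-1]


@dataclass(frozen=True)
class PendingOp:
    """One lazily recorded spatial operation plus the metadata needed to run it."""

    operation: AffineMatrix | VectorGrid
    input_shape: tuple[int, ...]
    input_dtype: str
    output_shape: tuple[int, ...]
    output_dtype: str
    interpolation_mode: str = "linear"
    padding_mode: str = "zeros"
    source_name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "input_shape", tuple(int(s) for s in self.input_shape))
        object.__setattr__(self, "output_shape", tuple(int(s) for s in self.output_shape))
        for shape in (self.input_shape, self.output_shape):
            if len(shape) != self.operation.ndim:
                raise ValueError(
                    f"shape {shape} does not match operation ndim {self.operation.ndim}"
                )
            if any(s < 1 for s in shape):
                raise ValueError(f"all extents must be >= 1, got {shape}")
        if self.interpolation_mode not in INTERPOLATION_MODES:
            raise ValueError(f"unknown interpolation mode {self.interpolation_mode!r}")
        if self.padding_mode not in PADDING_MODES:
            raise ValueError(f"unknown padding mode {self.padding_mode!r}")
        for tag in (self.input_dtype, self.output_dtype):
            if tag not in SUPPORTED_DTYPES:
                raise ValueError(f"unknown dtype tag {tag!r}")
        if isinstance(self.operation, VectorGrid):
            if self.operation.spatial_shape != self.output_shape:
                raise ValueError(
                    "vector grid spatial shape "
                    f"{self.operation.spatial_shape} != output shape {self.output_shape}"
                )

    @property
    def is_matrix(self) -> bool:
        return isinstance(self.operation, AffineMatrix)

    # -- JSON round-trip (matrices row-major) --------------------------------

    def to_dict(self) -> dict[str, Any]:
        if self.is_matrix:
            op = {"kind": "matrix", "values": self.operation.values.tolist()}
        else:
            op = {"kind": "grid", "vectors": self.operation.vectors.tolist()}
        return {
            "operation": op,
            "input_shape": list(self.input_shape),
            "input_dtype": self.input_dtype,
            "output_shape": list(self.output_shape),
            "output_dtype": self.output_dtype,
            "interpolation_mode": self.interpolation_mode,
            "padding_mode": self.padding_mode,
            "source_name": self.source_name,
        }

    @classmethod
    def from_dict(cls, payload: dict[str, Any]) -> "PendingOp":
        op_payload = payload["operation"]
        if op_payload["kind"] == "matrix":
            operation: AffineMatrix | VectorGrid = AffineMatrix(
                np.asarray(op_payload["values"], dtype=np.float64)
            )
        elif op_payload["kind"] == "grid":
            operation = VectorGrid(np.asarray(op_payload["vectors"], dtype=np.float64))
        else:
            raise ValueError(f"unknown operation kind {op_payload['kind']!r}")
        return cls(
            operation=operation,
            input_shape=tuple(payload["input_shape"]),
            input_dtype=payload["input_dtype"],
            output_shape=tuple(payload["output_shape"]),
            output_dtype=payload["output_dtype"],
            interpolation_mode=payload["interpolation_mode"],
            padding_mode=payload["padding_mode"],
            source_name=payload.get("source_name", ""),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "PendingOp":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class TraceRecord:
    """Record of an applied (executed) operation, enabling inversion.

    ``pending`` is the operation as actually applied — for a lazily merged
    group this is the single composed matrix, so the inverse pass costs at
    most as many resamples as the forward pass.  ``extra`` holds bookkeeping
    such as the dispatch class used.
    """

    pending: PendingOp
    extra: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {"pending": self.pending.to_dict(), "extra": dict(self.extra)}

    @classmethod
    def from_dict(cls, payload: dict[str, Any]) -> "TraceRecord":
        return cls(PendingOp.from_dict(payload["pending"]), dict(payload["extra"]))


# ---------------------------------------------------------------------------
# the image container
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class MetaImage:
    """Channel-first array plus world affine, pending ops and applied trace."""

    data: np.ndarray
    world_affine: AffineMatrix
    pending: tuple[PendingOp, ...] = ()
    trace: tuple[TraceRecord, ...] = ()
    voxel_spacing: tuple[float, ...] = ()

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return tuple(self.data.shape[1:])

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_ndim(self) -> int:
        return self.data.ndim - 1

    @property
    def dtype_tag(self) -> str:
        return dtype_tag(self.data.dtype)


def _spacing_from_affine(affine: AffineMatrix) -> tuple[float, ...]:
    return tuple(float(np.linalg.norm(affine.spatial[:, j])) for j in range(affine.ndim))


def make_meta_image(
    data: np.ndarray,
    world_affine: AffineMatrix | np.ndarray | None = None,
    spacing: Sequence[float] | None = None,
) -> MetaImage:
    """Wrap a channel-first array into a :class:`MetaImage`.

    ``data`` must have at least one channel axis followed by 2 or 3 spatial
    dimensions.  When ``world_affine`` is omitted it is built from ``spacing``
    (default 1 mm isotropic); when both are given they must agree.
    """
    arr = np.asarray(data)
    ndim_spatial = arr.ndim - 1
    if ndim_spatial not in (2, 3):
        raise ValueError(
            f"expected (C, *spatial) with 2 or 3 spatial dims, got array ndim {arr.ndim}"
        )
    if arr.shape[0] < 1:
        raise ValueError("data must have at least one channel")
    dtype_tag(arr.dtype)  # reject unsupported payloads early

    if world_affine is None:
        sp = tuple(float(s) for s in (spacing or (1.0,) * ndim_spatial))
        if len(sp) != ndim_spatial:
            raise ValueError(f"spacing {sp} does not match {ndim_spatial} spatial dims")
        mat = np.eye(ndim_spatial + 1)
        mat[range(ndim_spatial), range(ndim_spatial)] = sp
        world = AffineMatrix(mat)
    else:
        world = world_affine if isinstance(world_affine, AffineMatrix) else AffineMatrix(world_affine)
        if world.ndim != ndim_spatial:
            raise ValueError(
                f"world affine ndim {world.ndim} != spatial ndim {ndim_spatial}"
            )
        derived = _spacing_from_affine(world)
        if spacing is not None and not np.allclose(spacing, derived, rtol=1e-6):
            raise ValueError(
                f"spacing {tuple(spacing)} inconsistent with affine column norms {derived}"
            )
    return MetaImage(
        data=arr,
        world_affine=world,
        pending=(),
        trace=(),
        voxel_spacing=_spacing_from_affine(world),
    )


def effective_shape(img: MetaImage) -> tuple[int, ...]:
    """Spatial shape the image will have once pending ops are applied."""
    if img.pending:
        return img.pending[-1].output_shape
    return img.spatial_shape


def effective_dtype(img: MetaImage) -> str:
    if img.pending:
        return img.pending[-1].output_dtype
    return img.dtype_tag


def push_pending(img: MetaImage, op: PendingOp) -> MetaImage:
    """Append one pending op; the data array is untouched (same object)."""
    current = effective_shape(img)
    if op.input_shape != current:
        raise ShapeChainError(
            f"op {op.source_name or '<unnamed>'} expects input shape {op.input_shape}, "
            f"but the current effective shape is {current}"
        )
    return replace(img, pending=img.pending + (op,))


def validate_chain(img: MetaImage) -> None:
    """Raise :class:`ShapeChainError` if the pending shape chain is broken."""
    if not img.pending:
        return
    if img.pending[0].input_shape != img.spatial_shape:
        raise ShapeChainError(
            f"first pending op input {img.pending[0].input_shape} != data shape "
            f"{img.spatial_shape}"
        )
    for i in range(len(img.pending) - 1):
        a, b = img.pending[i], img.pending[i + 1]
        if a.output_shape != b.input_shape:
            raise ShapeChainError(
                f"pending[{i}].output_shape {a.output_shape} != "
                f"pending[{i + 1}].input_shape {b.input_shape}"
            )


# ---------------------------------------------------------------------------
# NIfTI-1 I/O
# ---------------------------------------------------------------------------


def load_nifti(path: str) -> MetaImage:
    """Load a NIfTI-1 file as a channel-first :class:`MetaImage`.

    3D volumes gain a singleton channel axis; 4D volumes are treated as
    spatial-first with the 4th axis moved to the channel position.
    """
    img = nib.load(path)
    arr = np.asarray(img.dataobj)
    if arr.ndim == 3:
        arr = arr[np.newaxis]
    elif arr.ndim == 4:
        arr = np.moveaxis(arr, -1, 0)
    else:
        raise ValueError(f"expected a 3D or 4D NIfTI volume, got ndim {arr.ndim}")
    affine = np.asarray(img.affine, dtype=np.float64)
    return make_meta_image(arr, world_affine=AffineMatrix(affine))


def save_nifti(img: MetaImage, path: str) -> None:
    """Write a 3D :class:`MetaImage` (single- or multi-channel) to NIfTI-1."""
    if img.spatial_ndim != 3:
        raise ValueError("NIfTI output requires 3 spatial dimensions")
    if img.pending:
        raise ValueError("apply pending ops before saving")
    arr = img.data
    arr = arr[0] if arr.shape[0] == 1 else np.moveaxis(arr, 0, -1)
    nib.save(nib.Nifti1Image(arr, img.world_affine.values), path)
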