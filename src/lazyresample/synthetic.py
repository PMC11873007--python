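"""Synthetic test inputs: checkerboards and labelled 3D phantoms.

The checkerboard maximises moire/aliasing artifacts under incommensurate
rescaling, which is what makes interpolation loss visible at a glance.  The
phantom volumes emulate the statistical structure of volumetric MRI
segmentation data: a smooth anatomical background, a handful of ellipsoidal
foreground structures per class occupying a small volume fraction, and a
high-frequency intensity texture.  The texture matters: a piecewise-constant
phantom would understate interpolation loss, whereas a near-uniform marginal
intensity distribution starts at near-maximal binned entropy, so every
linear resample measurably concentrates it.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import MetaImage, make_meta_image, save_nifti

__all__ = [
    "PhantomSpec",
    "checkerboard",
    "phantom_volume",
    "write_fixture_set",
    "read_fixture_manifest",
]

#: Foreground-fraction ranges of the two volumetric MRI segmentation datasets
#: the phantoms emulate (fraction of a volume, per class).
BRAIN_TUMOUR_FG_RANGE = (0.000816, 0.0357)
HIPPOCAMPUS_FG_RANGE = (0.0376, 0.0748)


def checkerboard(shape: Sequence[int], cell: int, dtype=np.float32) -> np.ndarray:
    """Binary 2D checkerboard with square cells of ``cell`` pixels."""
    if cell < 1:
        raise ValueError("cell size must be >= 1")
    h, w = (int(s) for s in shape)
    ii, jj = np.indices((h, w))
    return (((ii // cell) + (jj // cell)) % 2).astype(dtype)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one labelled phantom volume."""

    shape: tuple[int, int, int] = (64, 64, 64)
    n_classes: int = 3
    fg_fraction_range: tuple[float, float] = HIPPOCAMPUS_FG_RANGE
    n_blobs: int = 3
    seed: int = 0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.25)
    #: amplitudes of the smooth background, per-class offset step and
    #: high-frequency uniform texture, in arbitrary intensity units
    background_amp: float = 0.5
    class_offset: float = 0.4
    texture_amp: float = 1.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "PhantomSpec":
        payload = dict(payload)
        for key in ("shape", "fg_fraction_range", "spacing"):
            payload[key] = tuple(payload[key])
        return cls(**payload)


def _ellipsoid_mask(shape, centre, radii) -> np.ndarray:
    grids = np.indices(shape, dtype=np.float64)
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, r in zip(grids, centre, radii):
        acc += ((g - c) / r) ** 2
    return acc <= 1.0


def phantom_volume(spec: PhantomSpec) -> tuple[MetaImage, MetaImage]:
    """Generate one (image, labels) phantom pair, reproducible from the seed.

    Labels are non-overlapping axis-aligned ellipsoids (``n_blobs`` per
    class); earlier classes keep priority where placements would collide.
    The achieved per-class volume fraction lands inside
    ``fg_fraction_range`` up to one blob's discretisation error.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    total = float(np.prod(shape))
    labels = np.zeros(shape, dtype=np.int16)

    lo, hi = spec.fg_fraction_range
    if not 0 < lo <= hi < 1:
        raise ValueError(f"invalid foreground fraction range ({lo}, {hi})")
    for cls in range(1, spec.n_classes + 1):
        # draw inside the inner 80% of the range: keeps the achieved fraction
        # within the stated bounds despite voxelisation of the ellipsoids
        margin = 0.1 * (hi - lo)
        target_frac = rng.uniform(lo + margin, hi - margin)
        target_vox = target_frac * total
        per_blob = target_vox / spec.n_blobs
        placed = 0
        for _ in range(spec.n_blobs):
            base_r = (per_blob * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
            for _attempt in range(1000):
                aniso = rng.uniform(0.75, 1.35, size=3)
                aniso *= (base_r**3 / np.prod(base_r * aniso)) ** (1.0 / 3.0)
                radii = np.maximum(1.5, base_r * aniso)
                if np.any(2 * radii + 2 >= np.asarray(shape)):
                    raise ValueError(
                        f"blob of radii {tuple(radii)} cannot fit in shape {shape}"
                    )
                centre = [
                    rng.uniform(r + 1, s - r - 2) for r, s in zip(radii, shape)
                ]
                mask = _ellipsoid_mask(shape, centre, radii)
                if not np.any(mask & (labels > 0)):
                    labels[mask] = cls
                    placed += int(mask.sum())
                    break
            else:
                raise ValueError(
                    f"could not place blob {spec.n_blobs} of class {cls} without overlap"
                )
        blob_vol = per_blob
        if not (lo * total - blob_vol) <= placed <= (hi * total + blob_vol):
            raise ValueError(
                f"achieved fraction {placed / total:.5f} for class {cls} outside range"
            )

    background = ndimage.gaussian_filter(rng.normal(size=shape), sigma=6.0)
    background /= max(np.abs(background).max(), 1e-12)
    image = spec.background_amp * background
    image += spec.class_offset * labels.astype(np.float64)
    image += spec.texture_amp * rng.uniform(-0.5, 0.5, size=shape)

    img = make_meta_image(image[np.newaxis].astype(np.float32), spacing=spec.spacing)
    lab = make_meta_image(labels[np.newaxis], spacing=spec.spacing)
    return img, lab


def write_fixture_set(directory: str, specs: Sequence[PhantomSpec]) -> dict:
    """Write NIfTI image/label pairs plus a JSON manifest; returns the manifest."""
    os.makedirs(directory, exist_ok=True)
    entries = []
    for i, spec in enumerate(specs):
        img, lab = phantom_volume(spec)
        image_path = f"phantom_{i:03d}_image.nii"
        label_path = f"phantom_{i:03d}_label.nii"
        save_nifti(img, os.path.join(directory, image_path))
        save_nifti(lab, os.path.join(directory, label_path))
        entries.append({"image": image_path, "label": label_path, "spec": spec.to_dict()})
    manifest = {"fixtures": entries}
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_fixture_manifest(directory: str) -> list[PhantomSpec]:
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    return [PhantomSpec.from_dict(e["spec"]) for e in manifest["fixtures"]]
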