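"""Declarative pipeline configuration (YAML/JSON).

A pipeline file is a mapping with a ``transforms`` list plus optional
``lazy_default`` and ``master_seed``.  Each transform entry names a
registered transform and passes its parameters, e.g.::

    lazy_default: true
    master_seed: 7
    transforms:
      - {name: spacing, target_spacing: [1, 1, 1]}
      - {name: rand_flip, prob: 0.5}
      - {name: rotate90, k: 1}
      - {name: rand_zoom, low: 0.9, high: 1.1, prob: 1.0}
      - {name: rotate, angles_deg: [15], lazy: true, mode: linear, padding: zeros}

Angles are accepted in degrees in config files (``angles_deg`` /
``angle_range_deg``); the programmatic API uses radians throughout.
"""

from __future__ import annotations

import json
import math
from typing import Any

import yaml

from . import transforms as T

__all__ = ["TRANSFORM_REGISTRY", "build_transform", "build_pipeline_config", "load_pipeline_config"]

TRANSFORM_REGISTRY = {
    "rotate": T.Rotate,
    "rotate90": T.Rotate90,
    "flip": T.Flip,
    "zoom": T.Zoom,
    "translate": T.Translate,
    "spacing": T.Spacing,
    "crop_patch": T.CropPatch,
    "resize": T.Resize,
    "rand_rotate": T.RandRotate,
    "rand_zoom": T.RandZoom,
    "rand_flip": T.RandFlip,
    "add_noise": T.AddNoise,
    "multi_crop": T.MultiCrop,
}

_DEG_KEYS = {"angles_deg": "angles", "angle_range_deg": "angle_range"}
_MODE_KEYS = {"mode": "interpolation_mode", "padding": "padding_mode"}
_LIST_TO_TUPLE_KEYS = {"target_spacing", "target_shape", "size", "offsets", "axes", "plane", "factors", "angles", "start"}


def build_transform(entry: dict[str, Any]) -> T.Transform:
    entry = dict(entry)
    try:
        name = entry.pop("name")
    except KeyError:
        raise ValueError(f"transform entry missing 'name': {entry}") from None
    try:
        cls = TRANSFORM_REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown transform {name!r}; known: {sorted(TRANSFORM_REGISTRY)}"
        ) from None
    params: dict[str, Any] = {}
    for key, value in entry.items():
        if key in _DEG_KEYS:
            vals = value if isinstance(value, (list, tuple)) else [value]
            converted = [math.radians(v) for v in vals]
            params[_DEG_KEYS[key]] = converted if len(converted) > 1 else converted[0]
        elif key in _MODE_KEYS:
            params[_MODE_KEYS[key]] = value
        elif key in _LIST_TO_TUPLE_KEYS and isinstance(value, list):
            params[key] = tuple(value)
        else:
            params[key] = value
    return cls(**params)


def build_pipeline_config(payload: dict[str, Any]) -> tuple[list[T.Transform], bool, int]:
    """Return (transforms, lazy_default, master_seed) from a config mapping."""
    entries = payload.get("transforms")
    if not entries:
        raise ValueError("config must contain a non-empty 'transforms' list")
    transforms = [build_transform(e) for e in entries]
    return (
        transforms,
        bool(payload.get("lazy_default", True)),
        int(payload.get("master_seed", 0)),
    )


def load_pipeline_config(path: str) -> tuple[list[T.Transform], bool, int]:
    with open(path) as fh:
        if path.endswith(".json"):
            payload = json.load(fh)
        else:
            payload = yaml.safe_load(fh)
    return build_pipeline_config(payload)
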