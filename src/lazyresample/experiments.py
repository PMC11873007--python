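"""Desk-scale experiment drivers: lazy vs traditional A/B comparisons.

Each driver builds its own synthetic inputs, runs a pipeline in lazy and/or
traditional mode with shared random draws, and returns plain dicts or
DataFrames.  These functions back the command-line interface, the example
scripts and the acceptance checks.

The "whole-volume" pipeline is the reference augmentation chain
Spacing → Flip → Rotate90 → Zoom → Rotate.  The random parameter ranges
(rotation ±15°, zoom 0.9–1.1, flip p=0.5 per axis) are package defaults —
visible, overridable config, not values quoted from any dataset protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import MetaImage, make_meta_image
from .metrics import (
    count_events,
    dice_report,
    histogram_divergence,
    shannon_entropy,
)
from .pipeline import (
    CompiledPipeline,
    Instrumentation,
    MultiSampler,
    compile_pipeline,
    execute,
    invert_trace,
)
from .resampler import DispatchClass, build_groups, classify
from .synthetic import BRAIN_TUMOUR_FG_RANGE, HIPPOCAMPUS_FG_RANGE, PhantomSpec, checkerboard, phantom_volume
from .transforms import (
    Flip,
    MultiCrop,
    RandFlip,
    RandRotate,
    RandZoom,
    Rotate,
    Rotate90,
    Spacing,
    Translate,
    Zoom,
    rotate,
    translate,
    zoom,
)

__all__ = [
    "whole_volume_pipeline",
    "deterministic_whole_volume_pipeline",
    "lossless_pipeline",
    "run_identity_chain",
    "run_moire",
    "run_translate_return",
    "run_forward",
    "run_roundtrip",
    "run_event_audit",
    "run_multisampler_check",
]

DEFAULT_ROTATE_RANGE = math.radians(15.0)
DEFAULT_ZOOM_RANGE = (0.9, 1.1)
DEFAULT_FLIP_PROB = 0.5


def whole_volume_pipeline(
    *,
    target_spacing: Sequence[float] = (1.0, 1.0, 1.0),
    rotate_range: float = DEFAULT_ROTATE_RANGE,
    zoom_range: tuple[float, float] = DEFAULT_ZOOM_RANGE,
    flip_prob: float = DEFAULT_FLIP_PROB,
):
    """Randomised Spacing → Flip → Rotate90 → Zoom → Rotate transform list."""
    return [
        Spacing(target_spacing=tuple(target_spacing)),
        RandFlip(prob=flip_prob),
        Rotate90(k=1, plane=(0, 1)),
        RandZoom(low=zoom_range[0], high=zoom_range[1], prob=1.0),
        RandRotate(angle_range=rotate_range, prob=1.0),
    ]


def deterministic_whole_volume_pipeline(
    *,
    target_spacing: Sequence[float] = (1.0, 1.0, 1.0),
    zoom_factor: float = 1.1,
    angles: Sequence[float] = (0.2, 0.1, 0.05),
):
    """Fixed-parameter whole-volume pipeline (for exact event-count audits)."""
    return [
        Spacing(target_spacing=tuple(target_spacing)),
        Flip(axes=(0,)),
        Rotate90(k=1, plane=(0, 1)),
        Zoom(factors=zoom_factor),
        Rotate(angles=tuple(angles)),
    ]


def lossless_pipeline(offsets: Sequence[int] = (3, -2, 1)):
    """Flip → Rotate90 → integer Translate: every stage is exact."""
    return [
        Flip(axes=(1,)),
        Rotate90(k=1, plane=(0, 1)),
        Translate(offsets=tuple(int(o) for o in offsets)),
    ]


# ---------------------------------------------------------------------------
# identity chain
# ---------------------------------------------------------------------------


def run_identity_chain(shape: tuple[int, int] = (64, 64), seed: int = 0) -> dict:
    """Rotate(45°), Zoom(1.25), Rotate(22°), Rotate(−22°), Zoom(0.8), Rotate(−45°).

    Lazily composed, this six-transform chain collapses to the identity: the
    composed matrix deviates from I only by float round-off, dispatch picks
    the exact path, and the output is bit-equal to the input with zero
    interpolation events.
    """
    rng = np.random.default_rng(seed)
    img = make_meta_image(rng.random((1, *shape)).astype(np.float32))
    deg = math.radians
    out = img
    for step in (
        lambda im: rotate(im, deg(45)),
        lambda im: zoom(im, 1.25),
        lambda im: rotate(im, deg(22)),
        lambda im: rotate(im, deg(-22)),
        lambda im: zoom(im, 0.8),
        lambda im: rotate(im, deg(-45)),
    ):
        out = step(out)
    groups = build_groups(out.pending)
    assert len(groups) == 1
    matrix = groups[0].operation
    max_dev = float(np.abs(matrix.values - np.eye(3)).max())
    dispatch = classify(matrix, groups[0].in_shape, groups[0].out_shape)
    counters = Instrumentation()
    from .resampler import apply_all

    applied = apply_all(out, counters=counters)
    return {
        "max_abs_deviation": max_dev,
        "dispatch": dispatch.value,
        "bit_equal": bool(np.array_equal(applied.data, img.data)),
        "interpolation_events": counters.interpolation_events,
        "n_pending_composed": len(out.pending),
    }


# ---------------------------------------------------------------------------
# moire round trip
# ---------------------------------------------------------------------------


def run_moire(
    cells: Sequence[int] = (1, 2, 4),
    shape: tuple[int, int] = (64, 64),
    factor: float = 6.0 / 5.0,
    keep_images: bool = False,
) -> list[dict]:
    """Scale a checkerboard by 6/5 then 5/6, lazily and traditionally.

    Lazily the two zooms compose to the identity and the round trip is
    bit-exact; traditionally each zoom linearly resamples, the intermediate
    image shows moire patterning and the round trip invents intensities that
    never existed in the binary input.
    """
    results = []
    for cell in cells:
        board = checkerboard(shape, cell)
        img = make_meta_image(board[np.newaxis])

        lazy_out = zoom(zoom(img, factor, lazy=True), 1.0 / factor, lazy=True)
        from .resampler import apply_all

        lazy_applied = apply_all(lazy_out)

        trad_mid = zoom(img, factor, lazy=False)
        trad_out = zoom(trad_mid, 1.0 / factor, lazy=False)

        original = img.data[0]
        lazy_arr = lazy_applied.data[0]
        trad_arr = trad_out.data[0]
        new_values = np.setdiff1d(np.unique(trad_arr), np.unique(original))
        entry = {
            "cell": int(cell),
            "lazy_bit_equal": bool(np.array_equal(lazy_arr, original)),
            "lazy_divergence": histogram_divergence(original, lazy_arr),
            "traditional_divergence": histogram_divergence(original, trad_arr),
            "traditional_new_values": int(new_values.size),
        }
        if keep_images:
            entry["images"] = {
                "original": original,
                "scaled": trad_mid.data[0],
                "roundtrip_traditional": trad_arr,
                "roundtrip_lazy": lazy_arr,
            }
        results.append(entry)
    return results


# ---------------------------------------------------------------------------
# translate and return
# ---------------------------------------------------------------------------


def run_translate_return(k: int = 5, shape: tuple[int, int] = (16, 16), seed: int = 0) -> dict:
    """Translate +k then −k voxels along axis 0, lazily vs eagerly.

    The lazy composition is the identity (bit-equal round trip); the eager
    pair destroys exactly ``k`` rows, replaced by the zeros padding.
    """
    rng = np.random.default_rng(seed)
    img = make_meta_image(rng.random((1, *shape)).astype(np.float32) + 1.0)
    from .resampler import apply_all

    lazy_out = apply_all(translate(translate(img, (k, 0)), (-k, 0)))
    eager_out = translate(translate(img, (k, 0), lazy=False), (-k, 0), lazy=False)
    destroyed = int(np.sum(np.all(eager_out.data[0] == 0, axis=1)))
    return {
        "k": int(k),
        "lazy_bit_equal": bool(np.array_equal(lazy_out.data, img.data)),
        "eager_destroyed_rows": destroyed,
    }


# ---------------------------------------------------------------------------
# forward-pass entropy comparison
# ---------------------------------------------------------------------------


def run_forward(
    n_samples: int = 50,
    shape: tuple[int, int, int] = (48, 48, 48),
    seed: int = 0,
    bins: int = 256,
    fg_fraction_range: tuple[float, float] = BRAIN_TUMOUR_FG_RANGE,
    modes: Sequence[str] = ("lazy", "traditional"),
) -> pd.DataFrame:
    """Per-sample entropy in/out and event counts for each execution mode.

    Both modes of a sample share one master seed, hence identical random
    augmentation parameters; the only difference is where resamples happen.
    """
    rows = []
    for i in range(n_samples):
        spec = PhantomSpec(
            shape=shape, seed=seed + i, fg_fraction_range=fg_fraction_range, n_classes=3
        )
        img, _ = phantom_volume(spec)
        transforms = whole_volume_pipeline()
        for mode in modes:
            counters = Instrumentation()
            pipeline = compile_pipeline(
                transforms, lazy_default=(mode == "lazy"), master_seed=seed + i
            )
            out = execute(pipeline, img, counters=counters)
            e_in = shannon_entropy(img.data, bins)
            e_out = shannon_entropy(out.data, bins)
            events = count_events(counters)
            rows.append(
                {
                    "sample": i,
                    "mode": mode,
                    "entropy_in": e_in,
                    "entropy_out": e_out,
                    "entropy_delta": e_in - e_out,
                    "resamples": events.resamples,
                    "interpolations": events.interpolations,
                    "exact_ops": events.exact_ops,
                }
            )
    return pd.DataFrame(rows)


def forward_summary(df: pd.DataFrame) -> dict:
    """Mean ± sd of entropy delta per mode plus a paired sign test."""
    summary: dict = {}
    for mode, group in df.groupby("mode"):
        summary[mode] = {
            "entropy_delta_mean": float(group["entropy_delta"].mean()),
            "entropy_delta_sd": float(group["entropy_delta"].std()),
            "interpolations_mean": float(group["interpolations"].mean()),
        }
    if {"lazy", "traditional"} <= set(df["mode"]):
        lazy = df[df["mode"] == "lazy"].set_index("sample")["entropy_delta"]
        trad = df[df["mode"] == "traditional"].set_index("sample")["entropy_delta"]
        diff = (trad - lazy).dropna()
        n_pos = int((diff > 0).sum())
        test = stats.binomtest(n_pos, len(diff), 0.5, alternative="greater")
        summary["paired"] = {
            "n": int(len(diff)),
            "n_traditional_loses_more": n_pos,
            "sign_test_p": float(test.pvalue),
        }
    return summary


# ---------------------------------------------------------------------------
# round-trip label Dice
# ---------------------------------------------------------------------------


def run_roundtrip(
    n_runs: int = 20,
    n_phantoms: int = 10,
    shape: tuple[int, int, int] = (64, 64, 64),
    seed: int = 0,
    fg_fraction_range: tuple[float, float] = HIPPOCAMPUS_FG_RANGE,
    transforms_factory=whole_volume_pipeline,
) -> pd.DataFrame:
    """Forward + inverse label round trip, per class, lazy vs traditional.

    Labels ride the randomised whole-volume pipeline with nearest-neighbour
    interpolation, then back through the inverted trace.  Lazy mode costs
    one resample each way; traditional mode one per lossy stage each way.
    """
    phantoms = [
        phantom_volume(
            PhantomSpec(
                shape=shape,
                seed=seed + i,
                fg_fraction_range=fg_fraction_range,
                n_classes=2,
            )
        )[1]
        for i in range(n_phantoms)
    ]
    rows = []
    for run in range(n_runs):
        lab = phantoms[run % n_phantoms]
        transforms = transforms_factory()
        for mode in ("lazy", "traditional"):
            lazy_mode = mode == "lazy"
            counters = Instrumentation()
            pipeline = compile_pipeline(transforms, lazy_default=lazy_mode, master_seed=seed + run)
            out = execute(pipeline, lab, counters=counters)
            inverse = invert_trace(out.trace, lazy_default=lazy_mode)
            back = execute(inverse, out, counters=counters)
            report = dice_report(lab.data[0], back.data[0])
            events = count_events(counters)
            for cls, coeff in report.per_class.items():
                rows.append(
                    {
                        "run": run,
                        "phantom": run % n_phantoms,
                        "mode": mode,
                        "class": cls,
                        "dice": coeff,
                        "roundtrip_interpolations": events.interpolations,
                    }
                )
    return pd.DataFrame(rows)


def roundtrip_summary(df: pd.DataFrame) -> dict:
    out: dict = {}
    for mode, group in df.groupby("mode"):
        out[mode] = {
            "dice_mean": float(group["dice"].mean()),
            "dice_sd": float(group["dice"].std()),
            "interpolations_mean": float(group["roundtrip_interpolations"].mean()),
        }
    return out


# ---------------------------------------------------------------------------
# event-count audits
# ---------------------------------------------------------------------------


def run_event_audit(shape: tuple[int, int, int] = (24, 24, 24), seed: int = 0) -> dict:
    """Interpolation/apply counts for the reference pipelines in both modes."""
    rng = np.random.default_rng(seed)
    img = make_meta_image(
        rng.random((1, *shape)).astype(np.float32), spacing=(1.0, 1.0, 1.25)
    )
    result: dict = {}
    for mode in ("lazy", "traditional"):
        counters = Instrumentation()
        pipeline = compile_pipeline(
            deterministic_whole_volume_pipeline(), lazy_default=(mode == "lazy"), master_seed=seed
        )
        out = execute(pipeline, img, counters=counters)
        inverse = invert_trace(out.trace, lazy_default=(mode == "lazy"))
        execute(inverse, out, counters=counters)
        events = count_events(counters)
        forward_only = Instrumentation()
        execute(
            compile_pipeline(
                deterministic_whole_volume_pipeline(),
                lazy_default=(mode == "lazy"),
                master_seed=seed,
            ),
            img,
            counters=forward_only,
        )
        result[mode] = {
            "forward_interpolations": count_events(forward_only).interpolations,
            "roundtrip_interpolations": events.interpolations,
            "forward_apply_events": forward_only.apply_events,
        }
    return result


def mixed_pipeline_apply_events(shape: tuple[int, int] = (16, 16), seed: int = 0) -> int:
    """ApplyPending count for a [3 lazy, 1 non-lazy, 3 lazy] pipeline."""
    from .transforms import AddNoise

    rng = np.random.default_rng(seed)
    img = make_meta_image(rng.random((1, *shape)).astype(np.float32))
    transforms = [
        Rotate(angles=0.1),
        Zoom(factors=1.05),
        Rotate(angles=-0.05),
        AddNoise(sigma=0.01),
        Rotate(angles=0.07),
        Zoom(factors=0.95),
        Rotate(angles=-0.02),
    ]
    counters = Instrumentation()
    execute(compile_pipeline(transforms, lazy_default=True, master_seed=seed), img, counters=counters)
    return counters.apply_events


# ---------------------------------------------------------------------------
# multi-sampler
# ---------------------------------------------------------------------------


def run_multisampler_check(
    n_patches: int = 8,
    volume_shape: tuple[int, int, int] = (32, 32, 32),
    patch_size: tuple[int, int, int] = (16, 16, 16),
    seed: int = 0,
) -> dict:
    """Patch sampling with downstream transforms vs naive per-patch execution."""
    rng = np.random.default_rng(seed)
    img = make_meta_image(rng.random((1, *volume_shape)).astype(np.float32))
    sampler = MultiCrop(size=patch_size, n_samples=n_patches)
    downstream = [Flip(axes=(0,)), Rotate(angles=(0.1, 0.0, 0.0))]
    pipeline = compile_pipeline([sampler] + downstream, lazy_default=True, master_seed=seed)
    counters = Instrumentation()
    outputs = list(execute(pipeline, img, counters=counters))

    # naive oracle: re-draw the same starts, run each patch independently
    from .pipeline import _stage_rng
    from .resampler import apply_all
    from .transforms import crop_patch, flip as flip_fn, rotate as rotate_fn

    starts = sampler.sample_starts(img, _stage_rng(seed, 0, 0))
    naive = []
    for start in starts:
        patch = crop_patch(img, start, patch_size, lazy=True)
        patch = flip_fn(patch, (0,), lazy=True)
        patch = rotate_fn(patch, (0.1, 0.0, 0.0), lazy=True)
        naive.append(apply_all(patch))
    matches = [
        bool(np.array_equal(o.data, n.data)) for o, n in zip(outputs, naive)
    ]
    return {
        "n_patches": len(outputs),
        "all_match_naive": all(matches),
        "max_live_samples": counters.max_live_samples,
    }
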