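"""Compile transform lists into executable pipelines and invert their traces.

The compiler mirrors how a language compiler lowers source: it walks the
user's transform list and inserts :class:`ApplyPending` stages wherever the
accumulated pending descriptions must actually be executed —

* before any stage that cannot operate lazily,
* after any lazy-capable stage whose own ``lazy`` flag is ``False``,
* at the end of the pipeline;

and wraps a multi-sample stage plus everything downstream of it in a
:class:`MultiSampler`, which executes depth-first, one sample at a time, so
memory stays constant in the number of samples.

Random streams are keyed by ``(master_seed, transform position in the
ORIGINAL list, sample index)``.  Keying on the original position rather than
the compiled stage index means a lazy and a traditional compilation of the
same list draw identical random parameters — the precondition for any
lazy-vs-traditional comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .core import MetaImage, NotInvertibleError, PendingOp, TraceRecord, push_pending
from .resampler import apply_all
from .transforms import Transform, invert_record

__all__ = [
    "Instrumentation",
    "ApplyPending",
    "MultiSampler",
    "CompiledPipeline",
    "UnsupportedPipelineError",
    "compile_pipeline",
    "execute",
    "apply_pending_stage",
    "invert_trace",
    "InverseOp",
]


class UnsupportedPipelineError(ValueError):
    """The pipeline structure is outside what the compiler supports."""


@dataclass
class Instrumentation:
    """Counter object recording pipeline events.

    Event kinds: ``describe`` (a transform emitted a pending op), ``apply``
    (an ApplyPending stage executed), ``resample`` (a group needed
    interpolation), ``exact_op`` (a group executed losslessly).  Sample
    liveness tracking backs the constant-memory assertion for multi-sample
    runs.
    """

    events: list[dict] = field(default_factory=list)
    live_samples: int = 0
    max_live_samples: int = 0

    def record(self, kind: str, **info) -> None:
        self.events.append({"event": kind, **info})

    def sample_started(self) -> None:
        self.live_samples += 1
        self.max_live_samples = max(self.max_live_samples, self.live_samples)

    def sample_finished(self) -> None:
        self.live_samples -= 1

    def count(self, kind: str) -> int:
        return sum(1 for e in self.events if e["event"] == kind)

    @property
    def describe_events(self) -> int:
        return self.count("describe")

    @property
    def apply_events(self) -> int:
        return self.count("apply")

    @property
    def interpolation_events(self) -> int:
        return self.count("resample")

    @property
    def exact_events(self) -> int:
        return self.count("exact_op")

    def to_jsonl(self, path: str) -> None:
        with open(path, "w") as fh:
            for event in self.events:
                fh.write(json.dumps(event, default=str) + "\n")


class ApplyPending:
    """Pipeline stage that composes and executes all accumulated pending ops."""

    name = "apply_pending"

    def __call__(self, img: MetaImage, counters: Instrumentation | None = None) -> MetaImage:
        if counters is not None:
            counters.record("apply", n_pending=len(img.pending))
        return apply_all(img, counters=counters)


def apply_pending_stage(img: MetaImage, counters: Instrumentation | None = None) -> MetaImage:
    """Apply pending ops now (no-op when the pending list is empty)."""
    return ApplyPending()(img, counters)


@dataclass
class MultiSampler:
    """Container running a multi-sample transform and its downstream stages.

    The downstream list is executed once per sample, depth-first, so at most
    one sample's intermediates are alive at any time.
    """

    sampler: Transform
    sampler_stream: int
    downstream: list
    downstream_streams: list

    @property
    def name(self) -> str:  # pragma: no cover - debugging aid
        return f"multi_sampler({self.sampler.name})"


@dataclass
class CompiledPipeline:
    """Transform sequence after compilation, plus execution defaults.

    ``streams`` holds one entry per stage: the transform's position in the
    original (pre-compilation) list, or ``None`` for inserted ApplyPending
    stages.
    """

    stages: list
    streams: list
    lazy_default: bool = True
    master_seed: int = 0


def _insert_applies(
    transforms: Sequence[Transform], lazy_default: bool, terminal: bool, first_id: int
) -> tuple[list, list]:
    stages: list = []
    ids: list = []
    pending_possible = False
    next_id = first_id
    for t in transforms:
        if not isinstance(t, Transform):
            raise TypeError(f"pipeline entries must be Transform instances, got {t!r}")
        if t.is_lazy_capable:
            effective_lazy = t.lazy if t.lazy is not None else lazy_default
            stages.append(t)
            ids.append(next_id)
            if effective_lazy:
                pending_possible = True
            else:
                stages.append(ApplyPending())
                ids.append(None)
                pending_possible = False
        else:
            if pending_possible:
                stages.append(ApplyPending())
                ids.append(None)
                pending_possible = False
            stages.append(t)
            ids.append(next_id)
        next_id += 1
    if terminal and pending_possible:
        stages.append(ApplyPending())
        ids.append(None)
    return stages, ids


def compile_pipeline(
    transforms: Sequence[Transform] | CompiledPipeline,
    lazy_default: bool = True,
    master_seed: int = 0,
) -> CompiledPipeline:
    """Compile a transform list into an executable stage sequence.

    Compilation is idempotent: compiling a :class:`CompiledPipeline` returns
    it unchanged.  At most one multi-sample transform is supported (nesting
    beyond depth 1 raises :class:`UnsupportedPipelineError`).
    """
    if isinstance(transforms, CompiledPipeline):
        return transforms
    transforms = list(transforms)
    if not transforms:
        raise ValueError("pipeline must contain at least one transform")
    multi_idx = [i for i, t in enumerate(transforms) if getattr(t, "is_multi_sample", False)]
    if len(multi_idx) > 1:
        raise UnsupportedPipelineError("nested multi-samplers beyond depth 1 are unsupported")
    if multi_idx:
        m = multi_idx[0]
        head, head_ids = _insert_applies(transforms[:m], lazy_default, False, 0)
        tail, tail_ids = _insert_applies(transforms[m + 1 :], lazy_default, True, m + 1)
        if not tail:
            tail, tail_ids = [ApplyPending()], [None]
        stages = head + [MultiSampler(transforms[m], m, tail, tail_ids)]
        ids = head_ids + [m]
    else:
        stages, ids = _insert_applies(transforms, lazy_default, True, 0)
    return CompiledPipeline(
        stages=stages, streams=ids, lazy_default=lazy_default, master_seed=master_seed
    )


def _stage_rng(master_seed: int, stream_id: int, sample_index: int) -> np.random.Generator:
    # dedicated per-transform stream: pipeline edits don't shift other draws,
    # and lazy/traditional compilations of one list share identical draws
    return np.random.default_rng([int(master_seed), int(stream_id), int(sample_index)])


def _run_stage(stage, img, counters, rng):
    if isinstance(stage, ApplyPending):
        return stage(img, counters)
    before = len(img.pending)
    img = stage(img, lazy=True if stage.is_lazy_capable else None, rng=rng, counters=counters)
    if counters is not None and len(img.pending) > before:
        counters.record("describe", transform=stage.name)
    return img


def execute(
    pipeline: CompiledPipeline | Sequence[Transform],
    img: MetaImage,
    counters: Instrumentation | None = None,
    sample_index: int = 0,
) -> MetaImage | Iterator[MetaImage]:
    """Run a compiled pipeline on one image.

    Returns a single :class:`MetaImage`, or — when the pipeline contains a
    multi-sample stage — an iterator yielding one image per sample,
    depth-first.
    """
    pipeline = compile_pipeline(pipeline)
    for stage, stream in zip(pipeline.stages, pipeline.streams):
        if isinstance(stage, MultiSampler):
            return _execute_multi(pipeline, stage, img, counters, sample_index)
        rng = None if stream is None else _stage_rng(pipeline.master_seed, stream, sample_index)
        img = _run_stage(stage, img, counters, rng)
    return img


def _execute_multi(pipeline, ms, img, counters, sample_index):
    sampler_rng = _stage_rng(pipeline.master_seed, ms.sampler_stream, sample_index)
    samples = ms.sampler.sample_iter(img, sampler_rng, lazy=True, counters=counters)
    for s_i, sample in enumerate(samples):
        if counters is not None:
            counters.sample_started()
        out = sample
        for stage, stream in zip(ms.downstream, ms.downstream_streams):
            rng = None if stream is None else _stage_rng(pipeline.master_seed, stream, s_i)
            out = _run_stage(stage, out, counters, rng)
        if counters is not None:
            counters.sample_finished()
        yield out


class InverseOp(Transform):
    """A transform that replays a fixed (inverse) pending description."""

    name = "inverse_op"

    def __init__(self, op: PendingOp, lazy: bool | None = None) -> None:
        self.op = op
        self.lazy = lazy
        self.name = op.source_name or "inverse_op"

    def __call__(self, img, lazy=None, rng=None, counters=None):
        img = push_pending(img, self.op)
        if self._effective_lazy(lazy):
            return img
        return apply_all(img, counters=counters)


def invert_trace(
    trace: Sequence[TraceRecord],
    lazy_default: bool = True,
    master_seed: int = 0,
) -> CompiledPipeline:
    """Build the inverse pipeline of an applied-op trace.

    Records are inverted individually (matrix inverse, shapes swapped) and
    replayed in reverse order.  Because the trace holds post-composition
    groups, a lazily merged forward pass inverts with the same number of
    resamples as it took going forward.  The default lazy compilation keeps
    it that way; pass ``lazy_default=False`` to invert a traditional pass
    traditionally.
    """
    inverse_ops = [InverseOp(invert_record(rec)) for rec in reversed(list(trace))]
    if not inverse_ops:
        return CompiledPipeline(
            stages=[], streams=[], lazy_default=lazy_default, master_seed=master_seed
        )
    return compile_pipeline(inverse_ops, lazy_default=lazy_default, master_seed=master_seed)
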