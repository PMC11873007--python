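"""Information-loss and label-degradation metrics.

Shannon entropy of the binned intensity distribution is used as a proxy for
image information content; the Dice similarity coefficient quantifies label
agreement after a forward/inverse round trip; the L1 histogram divergence
exposes the new intermediate intensities that linear interpolation invents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .core import TraceRecord
from .pipeline import Instrumentation

__all__ = [
    "EntropyReport",
    "DiceReport",
    "EventCounts",
    "shannon_entropy",
    "entropy_report",
    "dice",
    "dice_report",
    "histogram_divergence",
    "count_events",
]


@dataclass(frozen=True)
class EntropyReport:
    entropy_in: float
    entropy_out: float
    bins: int

    @property
    def delta(self) -> float:
        """Entropy lost through the pipeline (bits); positive means loss."""
        return self.entropy_in - self.entropy_out


@dataclass(frozen=True)
class DiceReport:
    per_class: Mapping[int, float]

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_class.values())))


class EventCounts(NamedTuple):
    resamples: int
    interpolations: int
    exact_ops: int


def shannon_entropy(
    data: np.ndarray,
    bins: int = 256,
    value_range: tuple[float, float] | None = None,
) -> float:
    """Shannon entropy (bits) of the intensity histogram.

    The array is binned into ``bins`` equal-width bins over its own
    ``[min, max]`` by default (pass ``value_range`` for a fixed global
    range); a constant array occupies a single bin and has entropy 0.
    """
    arr = np.asarray(data).ravel()
    if arr.size == 0:
        raise ValueError("entropy of an empty array is undefined")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    lo, hi = value_range if value_range is not None else (arr.min(), arr.max())
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(arr, bins=bins, range=(float(lo), float(hi)))
    p = counts[counts > 0] / arr.size
    return float(-(p * np.log2(p)).sum())


def entropy_report(before: np.ndarray, after: np.ndarray, bins: int = 256) -> EntropyReport:
    return EntropyReport(shannon_entropy(before, bins), shannon_entropy(after, bins), bins)


def dice(a: np.ndarray, b: np.ndarray, cls: int) -> float:
    """Dice coefficient ``2|A∩B| / (|A|+|B|)`` of one label class.

    Two empty masks agree vacuously (1.0), which keeps per-class means
    defined on sparse synthetic labels.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mask_a = a == cls
    mask_b = b == cls
    total = int(mask_a.sum()) + int(mask_b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((mask_a & mask_b).sum()) / total


def dice_report(
    a: np.ndarray, b: np.ndarray, classes: Iterable[int] | None = None
) -> DiceReport:
    """Per-class Dice over the non-background classes present in either array."""
    if classes is None:
        classes = sorted(set(np.unique(a)) | set(np.unique(b)) - {0})
        classes = [int(c) for c in classes if c != 0]
    return DiceReport({int(c): dice(a, b, int(c)) for c in classes})


def histogram_divergence(a: np.ndarray, b: np.ndarray, bins: int = 256) -> float:
    """L1 distance between normalised histograms over shared bin edges.

    Edges span the combined ``[min, max]`` of both arrays, so the measure is
    0 iff the two binned distributions are identical.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        return 0.0
    ha, _ = np.histogram(a, bins=bins, range=(lo, hi))
    hb, _ = np.histogram(b, bins=bins, range=(lo, hi))
    return float(np.abs(ha / a.size - hb / b.size).sum())


def count_events(
    source: Sequence[TraceRecord] | Instrumentation,
) -> EventCounts:
    """Exact (resamples, interpolations, exact_ops) from a trace or counters.

    ``resamples`` counts every executed group; ``interpolations`` the groups
    that needed interpolation (axis-aligned or full); ``exact_ops`` the
    lossless ones.
    """
    if isinstance(source, Instrumentation):
        interp = source.interpolation_events
        exact = source.exact_events
        return EventCounts(interp + exact, interp, exact)
    interp = exact = 0
    for rec in source:
        if rec.extra.get("dispatch") == "exact_op":
            exact += 1
        else:
            interp += 1
    return EventCounts(interp + exact, interp, exact)
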