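"""Time-series plumbing for pressure and flow signals.

Offset correction, trapezoidal integration, breath segmentation with
hysteresis, and paired test-vs-reference tidal-volume comparison. All
signals live on a shared, strictly increasing time base in seconds;
pressures are cmH2O, flows L/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

from .errors import AlignmentError, BaselineError, InputError

__all__ = [
    "Signal",
    "PressureSignal",
    "FlowSignal",
    "BreathSegment",
    "VolumeComparison",
    "zero_offset_correct",
    "integrate",
    "active_window",
    "detect_breaths",
    "compare_volumes",
]


@dataclass(frozen=True)
class Signal:
    """A sampled signal: time base ``t`` (s, strictly increasing) and samples ``y``."""

    t: np.ndarray
    y: np.ndarray
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise InputError("t and y must be 1-D arrays of equal length")
        if t.size < 2:
            raise InputError("a signal needs at least 2 samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise InputError("non-finite samples in signal")
        if np.any(np.diff(t) <= 0):
            i = int(np.argmax(np.diff(t) <= 0))
            raise InputError(f"time base not strictly increasing at sample {i + 1}")

    def __len__(self) -> int:
        return int(self.t.size)

    def slice(self, start: int, stop: int) -> "Signal":
        """Sub-signal over sample indices [start, stop] inclusive."""
        if stop <= start:
            raise InputError("empty slice")
        return replace(self, t=self.t[start : stop + 1], y=self.y[start : stop + 1])


@dataclass(frozen=True)
class PressureSignal(Signal):
    units: str = "cmH2O"


@dataclass(frozen=True)
class FlowSignal(Signal):
    units: str = "L/s"


@dataclass(frozen=True)
class BreathSegment:
    """One detected inspiration: sample index range and its integrated volume (L)."""

    start: int
    end: int
    volume: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputError("breath segment must span at least two samples")


def zero_offset_correct(
    p: PressureSignal,
    baseline_window: float | tuple[int, int] = 1.0,
    max_baseline_sd: float | None = None,
) -> tuple[PressureSignal, float]:
    """Remove the transducer zero-flow offset estimated from a quiet window.

    Differential-pressure transducers drift: their output at zero flow is a
    nonzero constant that, left in place, integrates into a spurious volume.
    The offset is estimated as the mean over a baseline window known to
    contain no flow and subtracted from the whole record.

    Parameters
    ----------
    p : PressureSignal
    baseline_window : float or (int, int)
        Seconds from the start of the record, or an explicit inclusive
        sample-index range.
    max_baseline_sd : float, optional
        Quiescence guard: if given and the window's sample SD exceeds it,
        the window is judged to contain signal, not baseline, and
        :class:`BaselineError` is raised. A practical choice is 5x the
        expected sensor noise SD.

    Returns
    -------
    (corrected_signal, offset)
    """
    if isinstance(baseline_window, tuple):
        i0, i1 = baseline_window
    else:
        i0 = 0
        i1 = int(np.searchsorted(p.t, p.t[0] + float(baseline_window), side="right")) - 1
    window = p.y[i0 : i1 + 1]
    if window.size < 5:
        raise InputError("baseline window must contain at least 5 samples")
    sd = float(np.std(window))
    if max_baseline_sd is not None and sd > max_baseline_sd:
        raise BaselineError(
            f"no quiescent baseline: window SD {sd:.4g} exceeds {max_baseline_sd:.4g}"
        )
    offset = float(np.mean(window))
    corrected = replace(p, y=p.y - offset)
    return corrected, offset


def integrate(f: Signal, t0: float | None = None, t1: float | None = None) -> float:
    """Trapezoidal time integral of a signal over [t0, t1] (default: all).

    For a FlowSignal in L/s this is the volume in litres. The rule is exact
    for piecewise-linear signals and second-order accurate otherwise, on
    uniform or non-uniform time bases.
    """
    mask = np.ones(len(f), dtype=bool)
    if t0 is not None:
        mask &= f.t >= t0
    if t1 is not None:
        mask &= f.t <= t1
    if mask.sum() < 2:
        raise InputError("integration range contains fewer than 2 samples")
    return float(np.trapezoid(f.y[mask], f.t[mask]))


def active_window(
    p: Signal, threshold: float, margin: float = 0.0
) -> tuple[int, int]:
    """Inclusive index range spanning all samples with |y| > threshold.

    ``margin`` seconds are added on both sides (clamped to the record).
    Used to crop a maneuver record to the part that actually contains flow,
    so baseline noise outside it cannot bias the integrated volume.
    """
    hot = np.flatnonzero(np.abs(p.y) > threshold)
    if hot.size == 0:
        raise InputError(f"no samples exceed threshold {threshold}")
    t_lo = p.t[hot[0]] - margin
    t_hi = p.t[hot[-1]] + margin
    i0 = int(np.searchsorted(p.t, t_lo, side="left"))
    i1 = int(np.searchsorted(p.t, t_hi, side="right")) - 1
    return max(i0, 0), min(i1, len(p) - 1)


def detect_breaths(
    f: FlowSignal, threshold: float = 0.05, min_duration: float = 0.1
) -> list[BreathSegment]:
    """Segment inspirations by flow threshold with hysteresis.

    A segment opens when flow rises to ``threshold`` (L/s) and closes at the
    first sample below ``threshold / 2`` — the hysteresis prevents chatter on
    noise near the threshold. Segments shorter than ``min_duration`` seconds
    are discarded. Each segment's inspiratory volume is the trapezoidal
    integral over its samples.
    """
    if threshold <= 0:
        raise InputError("threshold must be positive")
    y, t = f.y, f.t
    low = threshold / 2.0
    segments: list[BreathSegment] = []
    i = 0
    n = len(f)
    while i < n:
        if y[i] >= threshold:
            start = i
            j = i + 1
            while j < n and y[j] >= low:
                j += 1
            end = min(j, n - 1)  # include the closing sub-threshold sample
            if end > start and t[end] - t[start] >= min_duration:
                vol = float(np.trapezoid(y[start : end + 1], t[start : end + 1]))
                segments.append(BreathSegment(start, end, vol))
            i = j + 1
        else:
            i += 1
    return segments


@dataclass(frozen=True)
class VolumeComparison:
    """Per-breath paired volumes from a test and a reference flow signal."""

    test_volumes: tuple[float, ...]
    reference_volumes: tuple[float, ...]
    relative_errors_pct: tuple[float, ...]

    @property
    def mean_abs_error_pct(self) -> float:
        return float(np.mean(self.relative_errors_pct))

    @property
    def max_abs_error_pct(self) -> float:
        return float(np.max(self.relative_errors_pct))

    @property
    def n_breaths(self) -> int:
        return len(self.test_volumes)


def compare_volumes(
    test: FlowSignal,
    reference: FlowSignal,
    threshold: float = 0.05,
    min_duration: float = 0.1,
) -> VolumeComparison:
    """Pair breaths by order and report per-breath relative volume errors (%).

    Both signals are segmented with the same detector settings; a breath-count
    mismatch raises :class:`AlignmentError` rather than guessing a pairing.
    """
    bt = detect_breaths(test, threshold, min_duration)
    br = detect_breaths(reference, threshold, min_duration)
    if len(bt) != len(br):
        raise AlignmentError(
            f"breath counts differ: test {len(bt)} vs reference {len(br)}"
        )
    if not bt:
        raise InputError("no breaths detected in either signal")
    vt = tuple(b.volume for b in bt)
    vr = tuple(b.volume for b in br)
    errs = tuple(100.0 * abs(a - b) / b for a, b in zip(vt, vr))
    return VolumeComparison(vt, vr, errs)
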