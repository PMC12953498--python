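"""Systolic-peak / valley detection and valley-to-valley pulse segmentation.

Peaks and valleys are detected with a physiology-bounded moving window:
candidate extrema must be the maximum (minimum) of a window spanning the
minimum credible cardiac period, and must rise above a prominence
threshold expressed as a fraction of the record's amplitude range.  The
window bounds come from the resting heart-rate range 60-100 bpm, i.e.
one cardiac cycle every 0.6-1.0 s.  Valleys delimit complete pulses;
three consecutive pulses are then selected for feature analysis by a
template-correlation quality criterion (earliest window on ties).

Indices are 0-based; pulse intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .records import PPGRecord


class NoPulsesError(ValueError):
    """Raised when a record yields no usable cardiac pulses."""


@dataclass
class SegmentationParams:
    """Physiological bounds for peak/valley detection."""

    min_period_s: float = 0.6
    max_period_s: float = 1.0
    min_prominence_fraction: float = 0.3

    def validate(self) -> None:
        if not 0 < self.min_period_s < self.max_period_s:
            raise ValueError("need 0 < min_period_s < max_period_s")
        if not 0 <= self.min_prominence_fraction <= 1:
            raise ValueError("min_prominence_fraction must lie in [0,1]")


@dataclass
class PulseSegment:
    """One complete valley-to-valley cardiac pulse.

    ``start_index``/``end_index`` index the parent record (half-open);
    ``systolic_peak_index`` is also a parent-record index.
    """

    samples: np.ndarray
    start_index: int
    end_index: int
    systolic_peak_index: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.start_index < self.systolic_peak_index < self.end_index:
            raise ValueError("systolic peak must lie strictly inside the pulse")
        if self.samples.size != self.end_index - self.start_index:
            raise ValueError("samples length must equal end_index - start_index")

    @property
    def duration_samples(self) -> int:
        return self.end_index - self.start_index

    def duration_s(self, fs_hz: float) -> float:
        return self.duration_samples / fs_hz

    @property
    def peak_offset(self) -> int:
        """Systolic peak index relative to the pulse start."""
        return self.systolic_peak_index - self.start_index


def _enforce_alternation(
    x: np.ndarray, peaks: np.ndarray, valleys: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Keep peaks as anchors; between consecutive peaks keep the deepest
    valley, plus the deepest valley before the first / after the last peak."""
    kept: list[int] = []
    bounds = [-1, *peaks.tolist(), x.size]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        cand = valleys[(valleys > lo) & (valleys < hi)]
        if cand.size:
            kept.append(int(cand[np.argmin(x[cand])]))
    return peaks, np.asarray(sorted(kept), dtype=int)


def detect_fiducials(
    record: PPGRecord, params: SegmentationParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Detect systolic peaks and inter-pulse valleys.

    Returns ``(peaks, valleys)`` as strictly increasing sample-index
    arrays whose sorted merge alternates valley/peak.  Peak spacing is
    constrained to at least ``0.8 * min_period_s`` and prominence to
    ``min_prominence_fraction`` of the record's amplitude range, making
    detection invariant to positive amplitude scaling and time shifts.
    """
    params = params or SegmentationParams()
    params.validate()
    x = record.samples
    rng = float(np.max(x) - np.min(x)) if x.size else 0.0
    if rng == 0:
        raise NoPulsesError(f"{record.record_id()}: flat signal, no pulses detected")
    distance = max(1, int(round(0.8 * params.min_period_s * record.fs_hz)))
    prominence = params.min_prominence_fraction * rng
    peaks, _ = sps.find_peaks(x, distance=distance, prominence=prominence)
    valleys, _ = sps.find_peaks(-x, distance=distance, prominence=prominence)
    if peaks.size == 0 or valleys.size < 2:
        raise NoPulsesError(f"{record.record_id()}: fewer than 2 valleys / no peaks detected")
    peaks, valleys = _enforce_alternation(x, peaks, valleys)
    if valleys.size < 2:
        raise NoPulsesError(f"{record.record_id()}: fewer than 2 valleys after alternation")
    return peaks, valleys


def segment_pulses(record: PPGRecord, valleys: np.ndarray) -> list[PulseSegment]:
    """Split the record into complete valley-to-valley pulses.

    Segments tile ``[first valley, last valley)`` with no gaps or
    overlaps; count = number of valleys - 1.  The systolic peak of each
    pulse is its interior argmax.
    """
    valleys = np.asarray(valleys, dtype=int)
    if valleys.size < 2:
        raise NoPulsesError("need at least 2 valleys to form a pulse")
    segments = []
    x = record.samples
    for lo, hi in zip(valleys[:-1], valleys[1:]):
        peak = lo + 1 + int(np.argmax(x[lo + 1 : hi]))
        segments.append(
            PulseSegment(
                samples=x[lo:hi],
                start_index=int(lo),
                end_index=int(hi),
                systolic_peak_index=peak,
            )
        )
    return segments


def _resample(y: np.ndarray, n: int = 100) -> np.ndarray:
    return np.interp(np.linspace(0, 1, n), np.linspace(0, 1, y.size), y)


def select_consecutive(
    segments: list[PulseSegment], k: int = 3, tie_tolerance: float = 5e-3
) -> list[PulseSegment]:
    """Pick the ``k`` consecutive pulses with the most mutually similar shapes.

    Quality of a window = mean pairwise Pearson correlation of the pulses
    resampled to a common length; scores within ``tie_tolerance`` of the
    best count as tied and break to the earliest window.  The default
    tolerance (5e-3) absorbs the ~1e-3 scatter that pulse-length rounding
    and filter edge effects produce even on perfectly periodic records,
    while artifacts depress correlations by well over 1e-2.  With exactly
    ``k`` pulses they are returned as-is.
    """
    if len(segments) < k:
        raise NoPulsesError(f"need at least {k} complete pulses, found {len(segments)}")
    if len(segments) == k:
        return list(segments)
    shapes = [_resample(s.samples) for s in segments]
    scores = []
    for i in range(len(segments) - k + 1):
        cors = []
        for a in range(i, i + k):
            for b in range(a + 1, i + k):
                sa, sb = shapes[a], shapes[b]
                if np.std(sa) == 0 or np.std(sb) == 0:
                    cors.append(0.0)
                else:
                    cors.append(float(np.corrcoef(sa, sb)[0, 1]))
        scores.append(float(np.mean(cors)))
    scores = np.asarray(scores)
    best = int(np.flatnonzero(scores >= scores.max() - tie_tolerance)[0])
    return segments[best : best + k]


def pulse_rate(peaks: np.ndarray, fs_hz: float) -> float:
    """Beats per minute from mean inter-peak interval."""
    peaks = np.asarray(peaks)
    if peaks.size < 2:
        raise ValueError("pulse rate needs at least 2 systolic peaks")
    return float(60.0 / (np.mean(np.diff(peaks)) / fs_hz))


class PulseSegmenter:
    """Convenience wrapper: record -> selected pulse segments.

    Returns ``(segments, peaks, valleys, selected)`` via :meth:`process`.
    """

    def __init__(self, params: SegmentationParams | None = None, k: int = 3):
        self.params = params or SegmentationParams()
        self.k = k

    def process(self, record: PPGRecord):
        peaks, valleys = detect_fiducials(record, self.params)
        segments = segment_pulses(record, valleys)
        selected = select_consecutive(segments, self.k)
        return segments, peaks, valleys, selected
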