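"""Silencer/enhancer element screening.

Repressive-mark peaks are scanned with fixed-width sliding windows; windows
carrying accessibility or TF-binding evidence are scored by a pluggable
scorer, a score cutoff is calibrated from background windows at a target
false-positive rate, and passing windows are merged into elements.

The scorer is an abstract contract (any callable mapping a window interval to
a finite score, higher = more silencer-like); :class:`SignalMeanScorer` scores
a window by its mean mark signal and is the default used on synthetic data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .intervals import Element, GenomicInterval, IntervalIndex, merge_overlapping, sort_intervals
from .io import SignalTrack

__all__ = [
    "ScreeningThreshold",
    "SignalMeanScorer",
    "TableScorer",
    "tile_windows",
    "filter_active",
    "score_windows",
    "calibrate_threshold",
    "call_elements",
    "screen_peaks",
]

Scorer = Callable[[GenomicInterval], float]


@dataclass(frozen=True)
class ScreeningThreshold:
    """Score cutoff ``ts`` calibrated at false-positive rate ``fpr`` on a
    background set whose background:positive composition is ``bg_ratio``."""

    ts: float
    fpr: float = 0.1
    bg_ratio: float = 9.0

    def __post_init__(self):
        if not 0 < self.fpr < 1:
            raise ValueError(f"fpr must be in (0,1), got {self.fpr}")


class SignalMeanScorer:
    """Score a window by the mean mark signal under it."""

    def __init__(self, track: SignalTrack):
        self.track = track

    def __call__(self, window: GenomicInterval) -> float:
        return self.track.summarize(window, stat="mean")


class TableScorer:
    """Score windows from a precomputed (chrom, start, end) -> score table."""

    def __init__(self, scores: dict[tuple[str, int, int], float]):
        self.scores = dict(scores)

    def __call__(self, window: GenomicInterval) -> float:
        return self.scores[(window.chrom, window.start, window.end)]


def tile_windows(peak: GenomicInterval, window: int = 1000, step: int = 100,
                 score_short_peaks: bool = False) -> list[GenomicInterval]:
    """Slide fixed windows across a peak; windows lie fully inside the peak.

    Peaks shorter than the window yield no windows unless
    ``score_short_peaks`` is set, in which case the whole peak becomes the
    single window.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if len(peak) < window:
        return [peak] if score_short_peaks else []
    n = (len(peak) - window) // step + 1
    return [GenomicInterval(peak.chrom, peak.start + i * step, peak.start + i * step + window)
            for i in range(n)]


def filter_active(windows: Iterable[GenomicInterval],
                  activity_peaks: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Keep windows overlapping at least one accessibility/TF peak by >= 1 bp."""
    index = IntervalIndex(activity_peaks)
    return [w for w in windows if index.any_overlap(w.chrom, w.start, w.end)]


def score_windows(windows: Sequence[GenomicInterval], scorer: Scorer) -> np.ndarray:
    scores = np.array([scorer(w) for w in windows], dtype=float)
    if scores.size and not np.all(np.isfinite(scores)):
        raise ValueError("scorer produced non-finite scores")
    return scores


def calibrate_threshold(bg_scores: Sequence[float], fpr: float = 0.1,
                        bg_ratio: float = 9.0) -> ScreeningThreshold:
    """Set ``ts`` as the empirical (1 - fpr) quantile of background scores:
    the smallest background score with at least that fraction of the
    background at or below it."""
    scores = np.asarray(list(bg_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("background score set is empty")
    if not 0 < fpr < 1:
        raise ValueError(f"fpr must be in (0,1), got {fpr}")
    ordered = np.sort(scores)
    idx = math.ceil((1.0 - fpr) * scores.size) - 1
    return ScreeningThreshold(ts=float(ordered[max(idx, 0)]), fpr=fpr, bg_ratio=bg_ratio)


def call_elements(windows: Sequence[GenomicInterval], scores: Sequence[float],
                  threshold: ScreeningThreshold) -> list[Element]:
    """Merge windows scoring strictly above ``ts`` into elements.

    Overlapping and book-ended passing windows merge; each element keeps the
    maximum member-window score (the strongest local evidence).
    """
    scores = np.asarray(scores, dtype=float)
    passing = [(w, s) for w, s in zip(windows, scores) if s > threshold.ts]
    if not passing:
        return []
    merged = merge_overlapping(w for w, _ in passing)
    elements = []
    for iv in merged:
        best = max(s for w, s in passing
                   if w.chrom == iv.chrom and w.start >= iv.start and w.end <= iv.end)
        elements.append(Element(iv, score=best))
    return sort_intervals(elements)


def screen_peaks(peaks: Iterable[GenomicInterval],
                 activity_peaks: Iterable[GenomicInterval],
                 scorer: Scorer,
                 bg_windows: Sequence[GenomicInterval] | None = None,
                 fpr: float = 0.1,
                 window: int = 1000,
                 step: int = 100,
                 threshold: ScreeningThreshold | None = None,
                 score_short_peaks: bool = False) -> tuple[list[Element], ScreeningThreshold]:
    """Full screening pass: tile, activity-filter, score, calibrate, call.

    ``bg_windows`` supply the calibration background; when a precomputed
    ``threshold`` is given it is used directly.
    """
    activity_peaks = list(activity_peaks)
    windows: list[GenomicInterval] = []
    for peak in sort_intervals(peaks):
        windows.extend(tile_windows(peak, window=window, step=step,
                                    score_short_peaks=score_short_peaks))
    windows = filter_active(windows, activity_peaks)
    scores = score_windows(windows, scorer)
    if threshold is None:
        if bg_windows is None:
            raise ValueError("either bg_windows or a threshold is required")
        bg_scores = score_windows(list(bg_windows), scorer)
        threshold = calibrate_threshold(bg_scores, fpr=fpr)
    return call_elements(windows, scores, threshold), threshold
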