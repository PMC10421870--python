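"""Fixation, saccade and blink detection within a window.

Fixations are found with a dispersion-threshold (I-DT) pass: a candidate span
grows while its spatial spread, measured as (max x - min x) + (max y - min y),
stays at or below the threshold, and is emitted once it lasts at least the
minimum fixation duration. Blinks are the blink-flagged missing runs from
preprocessing, bounded in duration. Saccades are derived between consecutive
fixations that are not separated by a blink.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from gazelapse.io import Window, _runs

__all__ = [
    "EventDetectionConfig",
    "Fixation",
    "Saccade",
    "Blink",
    "detect_blinks",
    "detect_fixations",
    "derive_saccades",
    "detect_events",
]


@dataclass(frozen=True)
class EventDetectionConfig:
    dispersion_threshold: float = 30.0  # px
    min_fixation_duration: float = 0.1  # s
    min_blink_duration: float = 0.05  # s
    max_blink_duration: float = 0.5  # s

    def validate(self) -> None:
        if min(self.dispersion_threshold, self.min_fixation_duration,
               self.min_blink_duration, self.max_blink_duration) <= 0:
            raise ValueError("event-detection thresholds must be positive")
        if self.min_blink_duration >= self.max_blink_duration:
            raise ValueError("min_blink_duration must be < max_blink_duration")


@dataclass(frozen=True)
class Fixation:
    x: float
    y: float
    onset: float
    offset: float
    start_sample: int
    end_sample: int  # exclusive

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class Saccade:
    start_point: tuple[float, float]
    end_point: tuple[float, float]
    onset: float
    offset: float
    duration: float

    @property
    def amplitude(self) -> float:
        return math.hypot(self.end_point[0] - self.start_point[0],
                          self.end_point[1] - self.start_point[1])

    @property
    def speed(self) -> float:
        return self.amplitude / self.duration


@dataclass(frozen=True)
class Blink:
    onset: float
    offset: float
    start_sample: int
    end_sample: int

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def detect_blinks(window: Window, cfg: EventDetectionConfig | None = None) -> list[Blink]:
    """Turn blink-flagged runs of valid duration into Blink events."""
    cfg = cfg or EventDetectionConfig()
    fs = window.sample_rate
    out = []
    for i0, i1 in _runs(window.blink_mask):
        dur = (i1 - i0) / fs
        if cfg.min_blink_duration <= dur <= cfg.max_blink_duration:
            onset = float(window.t[i0])
            out.append(Blink(onset=onset, offset=onset + dur,
                             start_sample=i0, end_sample=i1))
    return out


def detect_fixations(window: Window, cfg: EventDetectionConfig | None = None) -> list[Fixation]:
    """Greedy dispersion-threshold (I-DT) fixation detection.

    Blink samples never join a fixation; detection runs independently on each
    maximal eyes-open span. Adjacent detections separated by at most two
    samples whose centroids lie within the dispersion threshold are merged:
    jitter near the threshold otherwise over-segments a single physical
    fixation, and a genuine saccade moves the centroid much further.
    """
    cfg = cfg or EventDetectionConfig()
    fs = window.sample_rate
    min_samples = max(2, int(math.ceil(cfg.min_fixation_duration * fs)))
    x, y = window.x, window.y
    fixations: list[Fixation] = []
    open_mask = ~window.blink_mask
    for r0, r1 in _runs(open_mask):
        i = r0
        while i + min_samples <= r1:
            j = i + min_samples
            seg_x, seg_y = x[i:j], y[i:j]
            if (seg_x.max() - seg_x.min()) + (seg_y.max() - seg_y.min()) > cfg.dispersion_threshold:
                i += 1
                continue
            xmin, xmax = seg_x.min(), seg_x.max()
            ymin, ymax = seg_y.min(), seg_y.max()
            while j < r1:
                nxmin, nxmax = min(xmin, x[j]), max(xmax, x[j])
                nymin, nymax = min(ymin, y[j]), max(ymax, y[j])
                if (nxmax - nxmin) + (nymax - nymin) > cfg.dispersion_threshold:
                    break
                xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
                j += 1
            onset = float(window.t[i])
            dur = (j - i) / fs
            fixations.append(
                Fixation(
                    x=float(x[i:j].mean()), y=float(y[i:j].mean()),
                    onset=onset, offset=onset + dur,
                    start_sample=i, end_sample=j,
                )
            )
            i = j
    return _merge_adjacent(fixations, x, y, window, cfg)


def _merge_adjacent(fixations: list[Fixation], x: np.ndarray, y: np.ndarray,
                    window: Window, cfg: EventDetectionConfig) -> list[Fixation]:
    if len(fixations) < 2:
        return fixations
    fs = window.sample_rate
    merged: list[Fixation] = [fixations[0]]
    for f in fixations[1:]:
        prev = merged[-1]
        gap = f.start_sample - prev.end_sample
        close = math.hypot(f.x - prev.x, f.y - prev.y) <= cfg.dispersion_threshold
        if 0 <= gap <= 2 and close and not window.blink_mask[prev.end_sample:f.start_sample].any():
            i0, i1 = prev.start_sample, f.end_sample
            merged[-1] = Fixation(
                x=float(x[i0:i1].mean()), y=float(y[i0:i1].mean()),
                onset=prev.onset, offset=prev.onset + (i1 - i0) / fs,
                start_sample=i0, end_sample=i1,
            )
        else:
            merged.append(f)
    return merged


def derive_saccades(fixations: list[Fixation], window: Window) -> list[Saccade]:
    """One saccade per consecutive fixation pair not separated by a blink.

    Endpoints are the two fixation centroids; the saccade occupies the
    inter-fixation gap. A gap of zero samples (back-to-back fixations split by
    the dispersion criterion) is assigned one sample period so speed stays
    finite.
    """
    fs = window.sample_rate
    out = []
    for a, b in zip(fixations, fixations[1:]):
        if window.blink_mask[a.end_sample:b.start_sample].any():
            continue
        duration = max(b.onset - a.offset, 1.0 / fs)
        out.append(
            Saccade(
                start_point=a.centroid, end_point=b.centroid,
                onset=a.offset, offset=a.offset + duration, duration=duration,
            )
        )
    return out


def detect_events(
    window: Window, cfg: EventDetectionConfig | None = None
) -> tuple[list[Fixation], list[Saccade], list[Blink]]:
    """Fixations, saccades and blinks of one window."""
    cfg = cfg or EventDetectionConfig()
    fixations = detect_fixations(window, cfg)
    saccades = derive_saccades(fixations, window)
    blinks = detect_blinks(window, cfg)
    return fixations, saccades, blinks
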