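"""Reading, repairing and windowing raw gaze tables.

The raw input is a delimited text table (comma or tab) with columns
``timestamp, x, y, pupil, confidence``. Missing pupil samples caused by
blinking are repaired by linear interpolation between the flanking valid
values; other missing samples ("collection loss") are repaired with the mean
of the valid samples in a small neighbourhood. The repaired stream is cut
into overlapping fixed-length windows (500 samples / 5 s, 100-sample overlap)
which are labelled against annotated forgetting-episode intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("timestamp", "x", "y", "pupil", "confidence")

__all__ = [
    "GazeRecording",
    "Window",
    "read_gaze_table",
    "read_episode_sidecar",
    "classify_missing",
    "fill_blink_gaps",
    "fill_collection_gaps",
    "preprocess",
    "slide_windows",
    "assign_labels",
    "GazeReadError",
]


class GazeReadError(ValueError):
    """Raised when a gaze table cannot be parsed."""


@dataclass
class GazeRecording:
    """A uniformly sampled gaze stream.

    ``blink_mask``/``collection_mask`` are filled in by :func:`classify_missing`
    and carried through the repair steps so that event detection still knows
    where the eyes were closed.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray
    confidence: np.ndarray
    sample_rate: float
    episodes: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    blink_mask: np.ndarray | None = None
    collection_mask: np.ndarray | None = None

    def __len__(self) -> int:
        return self.t.size

    def copy(self) -> "GazeRecording":
        return GazeRecording(
            t=self.t.copy(), x=self.x.copy(), y=self.y.copy(),
            pupil=self.pupil.copy(), confidence=self.confidence.copy(),
            sample_rate=self.sample_rate, episodes=self.episodes.copy(),
            blink_mask=None if self.blink_mask is None else self.blink_mask.copy(),
            collection_mask=(None if self.collection_mask is None
                             else self.collection_mask.copy()),
        )


@dataclass
class Window:
    """A fixed-length slice of a recording — one classification event."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray
    confidence: np.ndarray
    blink_mask: np.ndarray
    start_index: int
    sample_rate: float
    label: int | None = None

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return len(self) / self.sample_rate

    @property
    def t_start(self) -> float:
        return float(self.t[0])

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration


def read_gaze_table(path, episodes_path=None) -> GazeRecording:
    """Read a delimited gaze table (comma or tab, any column order).

    Raises
    ------
    GazeReadError
        If a required column is absent or a timestamp cannot be parsed; the
        message names the offending column or line.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise GazeReadError(f"cannot parse gaze table {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise GazeReadError(
            f"gaze table {path} is missing required column(s): {', '.join(missing)}"
        )
    cols = {c: pd.to_numeric(df[c], errors="coerce").to_numpy(float)
            for c in REQUIRED_COLUMNS}
    bad = np.flatnonzero(~np.isfinite(cols["timestamp"]))
    if bad.size:
        # +2: header line plus 1-based numbering
        raise GazeReadError(
            f"gaze table {path}: unparsable timestamp at line {bad[0] + 2}"
        )
    order = np.argsort(cols["timestamp"], kind="stable")
    if not np.array_equal(order, np.arange(order.size)):
        logger.warning("gaze table %s has out-of-order timestamps; sorting", path)
        cols = {k: v[order] for k, v in cols.items()}
    t = cols["timestamp"]
    if t.size < 2:
        rate = 100.0
    else:
        rate = 1.0 / float(np.median(np.diff(t)))
    episodes = (read_episode_sidecar(episodes_path)
                if episodes_path is not None else np.empty((0, 2)))
    return GazeRecording(
        t=t, x=cols["x"], y=cols["y"], pupil=cols["pupil"],
        confidence=cols["confidence"], sample_rate=rate, episodes=episodes,
    )


def read_episode_sidecar(path) -> np.ndarray:
    """Read annotated episode intervals (two columns: start_s, end_s)."""
    try:
        df = pd.read_csv(path)
        if "start_s" not in df.columns:
            df = pd.read_csv(path, header=None, names=["start_s", "end_s"])
    except Exception as exc:  # noqa: BLE001
        raise GazeReadError(f"cannot parse episode sidecar {path}: {exc}") from exc
    if df.empty:
        return np.empty((0, 2))
    arr = df[["start_s", "end_s"]].to_numpy(float)
    if np.any(arr[:, 1] <= arr[:, 0]):
        raise GazeReadError(f"episode sidecar {path}: end before start")
    return arr[np.argsort(arr[:, 0])]


# ---------------------------------------------------------------------------
# missing-data repair

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean mask as half-open (start, stop) pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def classify_missing(
    rec: GazeRecording,
    min_blink_duration: float = 0.05,
    max_blink_duration: float = 0.5,
) -> GazeRecording:
    """Split missing samples into blink loss and collection loss.

    A missing run counts as blink loss when the pupil is missing with
    confidence 0 throughout and the run lasts between ``min_blink_duration``
    and ``max_blink_duration``; every other missing sample (in any channel)
    is collection loss.
    """
    out = rec.copy()
    n = len(out)
    blink = np.zeros(n, dtype=bool)
    candidate = np.isnan(out.pupil) & (out.confidence == 0)
    for i0, i1 in _runs(candidate):
        dur = (i1 - i0) / out.sample_rate
        if min_blink_duration <= dur <= max_blink_duration:
            blink[i0:i1] = True
    missing_any = (np.isnan(out.x) | np.isnan(out.y) | np.isnan(out.pupil))
    out.blink_mask = blink
    out.collection_mask = missing_any & ~blink
    return out


def fill_blink_gaps(rec: GazeRecording) -> GazeRecording:
    """Linearly interpolate pupil diameter across blink-flagged runs.

    Gaps touching a recording boundary are extended with the nearest valid
    value (logged); x and y are untouched.
    """
    out = rec if rec.blink_mask is not None else classify_missing(rec)
    out = out.copy()
    mask = out.blink_mask
    if not mask.any():
        return out
    valid = ~np.isnan(out.pupil)
    if not valid.any():
        raise GazeReadError("no valid pupil samples to interpolate from")
    idx = np.arange(len(out))
    if mask[0] or mask[-1]:
        logger.info("blink gap touches recording boundary; using nearest value")
    out.pupil[mask] = np.interp(idx[mask], idx[valid], out.pupil[valid])
    return out


def fill_collection_gaps(rec: GazeRecording, radius: int = 10) -> GazeRecording:
    """Replace collection-loss samples with the local mean of valid neighbours.

    For each missing sample the mean of the valid samples within ``radius``
    samples on either side is used; a gap with no valid neighbour in range is
    an error listing the unrecoverable span.
    """
    if radius < 1:
        raise ValueError("radius must be at least 1")
    out = rec if rec.collection_mask is not None else classify_missing(rec)
    out = out.copy()
    mask = out.collection_mask
    if not mask.any():
        return out
    n = len(out)
    for name in ("x", "y", "pupil"):
        ch = getattr(out, name)
        # blink samples in pupil stay for fill_blink_gaps; only repair
        # collection-missing entries of this channel
        todo = mask & np.isnan(ch)
        if name == "pupil":
            todo &= ~out.blink_mask
        for i in np.flatnonzero(todo):
            lo, hi = max(0, i - radius), min(n, i + radius + 1)
            neigh = ch[lo:hi]
            good = neigh[np.isfinite(neigh)]
            if good.size == 0:
                raise GazeReadError(
                    f"channel {name}: samples {lo}-{hi - 1} entirely missing; "
                    f"cannot repair collection loss at index {i}"
                )
            ch[i] = float(good.mean())
    out.collection_mask = np.zeros(n, dtype=bool)
    return out


def preprocess(
    rec: GazeRecording,
    radius: int = 10,
    min_blink_duration: float = 0.05,
    max_blink_duration: float = 0.5,
) -> GazeRecording:
    """classify_missing -> fill_collection_gaps -> fill_blink_gaps."""
    out = classify_missing(rec, min_blink_duration, max_blink_duration)
    out = fill_collection_gaps(out, radius=radius)
    out = fill_blink_gaps(out)
    return out


# ---------------------------------------------------------------------------
# windowing and labelling

def slide_windows(
    rec: GazeRecording, window_length: int = 500, overlap: int = 100
) -> list[Window]:
    """Cut the stream into fixed-length windows with the given overlap.

    Windows start at multiples of ``window_length - overlap``; a trailing
    remainder shorter than ``window_length`` is discarded.
    """
    if overlap < 0 or window_length <= overlap:
        raise ValueError("require window_length > overlap >= 0")
    n = len(rec)
    if n < window_length:
        return []
    stride = window_length - overlap
    blink = (rec.blink_mask if rec.blink_mask is not None
             else np.zeros(n, dtype=bool))
    windows = []
    for start in range(0, n - window_length + 1, stride):
        sl = slice(start, start + window_length)
        windows.append(
            Window(
                t=rec.t[sl], x=rec.x[sl], y=rec.y[sl], pupil=rec.pupil[sl],
                confidence=rec.confidence[sl], blink_mask=blink[sl],
                start_index=start, sample_rate=rec.sample_rate,
            )
        )
    return windows


def assign_labels(
    windows: list[Window],
    episodes: np.ndarray,
    min_overlap: float = 0.5,
) -> list[Window]:
    """Label a window `forgetting` (1) when episode overlap reaches the
    stated fraction of the window duration, else `normal` (0)."""
    episodes = np.asarray(episodes, dtype=float).reshape(-1, 2)
    out = []
    for w in windows:
        ov = 0.0
        for s, e in episodes:
            ov += max(0.0, min(w.t_end, e) - max(w.t_start, s))
        label = 1 if ov >= min_overlap * w.duration else 0
        out.append(replace(w, label=label))
    return out
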