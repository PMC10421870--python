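"""The 44 per-window eye-movement metrics, normalization and sequences.

Each 5-second window yields 23 time-related metrics (counts, totals, rates —
quantities that accumulate with time) and 21 time-independent metrics
(medians, ranges, moments and spatial statistics of the window's events).
All metrics are finite for any window: empty event lists fall back to zero,
and third/fourth moments fall back to zero below three observations.

Metric conventions (the terms are named but not defined in the source
tables; the definitions below are frozen in the exported name manifests):

* population (n-denominator) standard deviations, Fisher skewness, excess
  kurtosis;
* "gaze width" is the maximum pairwise centroid distance, "gaze density" the
  fixation count per centroid bounding-box area (floored at 1 px^2);
* blink "depth" is read as blink duration;
* "noting"/"returning" count novel-cell visits and refixations on a 4x4
  screen grid;
* the "global/local ratio" compares saccades above vs below a 100 px
  amplitude threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from gazelapse.events import EventDetectionConfig, detect_events
from gazelapse.io import Window

__all__ = [
    "FeatureConfig",
    "MinMaxParams",
    "TIME_RELATED_NAMES",
    "TIME_INDEPENDENT_NAMES",
    "FEATURE_NAMES",
    "N_TIME_RELATED",
    "N_TIME_INDEPENDENT",
    "compute_time_related",
    "compute_time_independent",
    "compute_features",
    "windows_to_features",
    "fit_minmax",
    "apply_minmax",
    "assemble_sequences",
    "write_feature_table",
    "read_feature_table",
]

TIME_RELATED_NAMES = [
    "fixation_count",
    "fixations_per_second",
    "mean_fixation_duration",
    "gaze_width",
    "nearest_neighbor_distance",
    "total_fixation_time",
    "max_fixation_duration",
    "gaze_density",
    "blink_count",
    "blink_rate",
    "longest_blink_duration",
    "latest_blink_duration",
    "closed_eye_time",
    "saccade_count",
    "total_saccade_length",
    "max_saccade_amplitude",
    "mean_saccade_amplitude",
    "total_saccade_time",
    "mean_saccade_duration",
    "max_saccade_duration",
    "mean_saccade_speed",
    "overall_saccade_speed",
    "mean_pupil_diameter",
]

TIME_INDEPENDENT_NAMES = [
    "median_fixation_duration",
    "fixation_time_ratio",
    "fixation_scatter",
    "horizontal_range",
    "fixation_duration_sd",
    "fixation_duration_skewness",
    "fixation_duration_kurtosis",
    "first_fixation_offcenter",
    "blink_count_per_second_sd",
    "noting",
    "returning",
    "mean_gaze_offcenter",
    "weighted_fixation_offcenter",
    "vertical_range",
    "median_saccade_amplitude",
    "saccade_amplitude_sd",
    "saccade_amplitude_skewness",
    "saccade_amplitude_kurtosis",
    "scanpath_length",
    "global_local_ratio",
    "saccade_dispersion",
]

FEATURE_NAMES = TIME_RELATED_NAMES + TIME_INDEPENDENT_NAMES
N_TIME_RELATED = len(TIME_RELATED_NAMES)
N_TIME_INDEPENDENT = len(TIME_INDEPENDENT_NAMES)
assert N_TIME_RELATED == 23 and N_TIME_INDEPENDENT == 21


@dataclass(frozen=True)
class FeatureConfig:
    screen_extent: tuple[float, float] = (1920.0, 1080.0)
    grid: tuple[int, int] = (4, 4)
    global_local_threshold: float = 100.0  # px

    @property
    def center(self) -> tuple[float, float]:
        return (self.screen_extent[0] / 2.0, self.screen_extent[1] / 2.0)


def _sd(values: np.ndarray) -> float:
    return float(np.std(values)) if values.size else 0.0


def _skew(values: np.ndarray) -> float:
    if values.size < 3 or np.std(values) == 0:
        return 0.0
    with warnings.catch_warnings():
        # near-identical values legitimately occur; the finite check below
        # handles the degenerate outcome
        warnings.simplefilter("ignore", RuntimeWarning)
        v = float(_stats.skew(values, bias=True))
    return v if np.isfinite(v) else 0.0


def _kurt(values: np.ndarray) -> float:
    if values.size < 3 or np.std(values) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        v = float(_stats.kurtosis(values, fisher=True, bias=True))
    return v if np.isfinite(v) else 0.0


def compute_time_related(window, fixations, saccades, blinks,
                         cfg: FeatureConfig | None = None) -> np.ndarray:
    """The 23 time-related metrics in manifest order."""
    cfg = cfg or FeatureConfig()
    T = window.duration
    fdur = np.array([f.duration for f in fixations])
    cx = np.array([f.x for f in fixations])
    cy = np.array([f.y for f in fixations])
    samp = np.array([s.amplitude for s in saccades])
    sdur = np.array([s.duration for s in saccades])
    bdur = np.array([b.duration for b in blinks])

    nf = len(fixations)
    if nf >= 2:
        dx = cx[:, None] - cx[None, :]
        dy = cy[:, None] - cy[None, :]
        dist = np.hypot(dx, dy)
        gaze_width = float(dist.max())
        np.fill_diagonal(dist, np.inf)
        nn_dist = float(dist.min(axis=1).mean())
    else:
        gaze_width = 0.0
        nn_dist = 0.0
    if nf:
        area = max((cx.max() - cx.min()) * (cy.max() - cy.min()), 1.0)
        density = nf / area
    else:
        density = 0.0

    total_sacc_time = float(sdur.sum()) if sdur.size else 0.0
    total_sacc_len = float(samp.sum()) if samp.size else 0.0

    return np.array([
        float(nf),
        nf / T,
        float(fdur.mean()) if nf else 0.0,
        gaze_width,
        nn_dist,
        float(fdur.sum()) if nf else 0.0,
        float(fdur.max()) if nf else 0.0,
        density,
        float(len(blinks)),
        len(blinks) / T,
        float(bdur.max()) if bdur.size else 0.0,
        float(bdur[-1]) if bdur.size else 0.0,
        float(bdur.sum()) if bdur.size else 0.0,
        float(len(saccades)),
        total_sacc_len,
        float(samp.max()) if samp.size else 0.0,
        float(samp.mean()) if samp.size else 0.0,
        total_sacc_time,
        float(sdur.mean()) if sdur.size else 0.0,
        float(sdur.max()) if sdur.size else 0.0,
        float((samp / sdur).mean()) if samp.size else 0.0,
        total_sacc_len / total_sacc_time if total_sacc_time > 0 else 0.0,
        float(np.nanmean(window.pupil)) if np.isfinite(window.pupil).any() else 0.0,
    ])


def compute_time_independent(window, fixations, saccades, blinks,
                             cfg: FeatureConfig | None = None) -> np.ndarray:
    """The 21 time-independent metrics in manifest order."""
    cfg = cfg or FeatureConfig()
    T = window.duration
    ctr = np.array(cfg.center)
    fdur = np.array([f.duration for f in fixations])
    cx = np.array([f.x for f in fixations])
    cy = np.array([f.y for f in fixations])
    samp = np.array([s.amplitude for s in saccades])
    nf = len(fixations)

    if nf:
        mean_c = np.array([cx.mean(), cy.mean()])
        scatter = float(np.sqrt(np.mean((cx - mean_c[0]) ** 2
                                        + (cy - mean_c[1]) ** 2)))
        first_off = float(np.hypot(cx[0] - ctr[0], cy[0] - ctr[1]))
        hrange = float(cx.max() - cx.min())
        vrange = float(cy.max() - cy.min())
        wmean = np.array([np.average(cx, weights=fdur),
                          np.average(cy, weights=fdur)])
        weighted_off = float(np.hypot(*(wmean - ctr)))
    else:
        scatter = first_off = hrange = vrange = weighted_off = 0.0

    # per-second blink counts over the window's 1 s bins
    n_bins = max(1, int(round(T)))
    counts = np.zeros(n_bins)
    for b in blinks:
        k = min(int((b.onset - window.t_start) // 1.0), n_bins - 1)
        counts[max(k, 0)] += 1
    blink_sd = _sd(counts)

    # noting / returning over a grid of screen cells
    gx, gy = cfg.grid
    w, h = cfg.screen_extent
    noting = returning = 0
    if nf:
        cells = list(zip(
            np.clip((cx / w * gx).astype(int), 0, gx - 1),
            np.clip((cy / h * gy).astype(int), 0, gy - 1),
        ))
        seen: set = set()
        prev = None
        for c in cells:
            if c not in seen:
                noting += 1
                seen.add(c)
            elif prev is not None and c != prev:
                returning += 1
            prev = c
    # raw scanpath and mean-gaze statistics on the eyes-open samples
    open_mask = np.isfinite(window.x) & np.isfinite(window.y)
    xs, ys = window.x[open_mask], window.y[open_mask]
    if xs.size:
        spl = float(np.sum(np.hypot(np.diff(xs), np.diff(ys))))
        mean_off = float(np.hypot(xs.mean() - ctr[0], ys.mean() - ctr[1]))
    else:
        spl = mean_off = 0.0

    if samp.size:
        thr = cfg.global_local_threshold
        glratio = float((samp > thr).sum()) / max(1, int((samp <= thr).sum()))
        ex = np.array([[s.end_point[0], s.end_point[1]] for s in saccades])
        ec = ex.mean(axis=0)
        dispersion = float(np.sqrt(np.mean(np.sum((ex - ec) ** 2, axis=1))))
    else:
        glratio = dispersion = 0.0

    return np.array([
        float(np.median(fdur)) if nf else 0.0,
        (float(fdur.sum()) / T) if nf else 0.0,
        scatter,
        hrange,
        _sd(fdur),
        _skew(fdur),
        _kurt(fdur),
        first_off,
        blink_sd,
        float(noting),
        float(returning),
        mean_off,
        weighted_off,
        vrange,
        float(np.median(samp)) if samp.size else 0.0,
        _sd(samp),
        _skew(samp),
        _kurt(samp),
        spl,
        glratio,
        dispersion,
    ])


def compute_features(window: Window,
                     cfg: FeatureConfig | None = None,
                     event_cfg: EventDetectionConfig | None = None) -> np.ndarray:
    """All 44 metrics of one window (events detected internally)."""
    cfg = cfg or FeatureConfig()
    fixations, saccades, blinks = detect_events(window, event_cfg)
    tc = compute_time_related(window, fixations, saccades, blinks, cfg)
    tic = compute_time_independent(window, fixations, saccades, blinks, cfg)
    out = np.concatenate([tc, tic])
    if not np.all(np.isfinite(out)):
        bad = [FEATURE_NAMES[i] for i in np.flatnonzero(~np.isfinite(out))]
        raise AssertionError(f"non-finite feature(s): {bad}")
    return out


def windows_to_features(
    windows: list[Window],
    cfg: FeatureConfig | None = None,
    event_cfg: EventDetectionConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feature matrix (n, 44), labels and start indices for a window list."""
    F = np.empty((len(windows), len(FEATURE_NAMES)))
    labels = np.full(len(windows), -1, dtype=int)
    starts = np.empty(len(windows), dtype=int)
    for i, w in enumerate(windows):
        F[i] = compute_features(w, cfg, event_cfg)
        labels[i] = -1 if w.label is None else w.label
        starts[i] = w.start_index
    return F, labels, starts


# ---------------------------------------------------------------------------
# min-max normalization (x' = (x - min X) / (max X - min X))

@dataclass
class MinMaxParams:
    min_: np.ndarray
    max_: np.ndarray

    @property
    def degenerate(self) -> np.ndarray:
        """Features whose training range collapsed to a point."""
        return self.max_ <= self.min_


def fit_minmax(train_matrix: np.ndarray) -> MinMaxParams:
    """Per-feature min/max learned from the training rows only."""
    train_matrix = np.asarray(train_matrix, dtype=float)
    if train_matrix.ndim != 2 or train_matrix.shape[0] == 0:
        raise ValueError("fit_minmax needs a non-empty 2-D training matrix")
    return MinMaxParams(min_=train_matrix.min(axis=0),
                        max_=train_matrix.max(axis=0))


def apply_minmax(matrix: np.ndarray, params: MinMaxParams) -> np.ndarray:
    """Map each feature through the learned range, clipping into [0, 1].

    Degenerate features (max == min in training) map to 0.
    """
    matrix = np.asarray(matrix, dtype=float)
    span = params.max_ - params.min_
    safe = np.where(span > 0, span, 1.0)
    with np.errstate(over="ignore"):
        # a subnormal training span can overflow the quotient; the clip
        # below maps those values to the correct endpoint anyway
        out = (matrix - params.min_) / safe
    out[..., params.degenerate] = 0.0
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# sequence assembly

def assemble_sequences(
    matrix: np.ndarray,
    labels: np.ndarray,
    length: int = 6,
    stride: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Group consecutive windows of one recording into event sequences.

    Returns ``X`` of shape (m, length, 44) and ``y`` of shape (m,), where the
    sequence label is the label of its final window. Fewer than ``length``
    windows yield an empty result.
    """
    if length < 1 or stride < 1:
        raise ValueError("length and stride must be positive")
    matrix = np.asarray(matrix)
    labels = np.asarray(labels)
    n = matrix.shape[0]
    if n < length:
        return (np.empty((0, length, matrix.shape[1])), np.empty(0, dtype=int))
    offs = range(0, n - length + 1, stride)
    X = np.stack([matrix[o:o + length] for o in offs])
    y = np.array([labels[o + length - 1] for o in offs], dtype=int)
    return X, y


# ---------------------------------------------------------------------------
# plain-text feature tables

def write_feature_table(path, matrix, labels, starts, recording_ids=None) -> None:
    import pandas as pd

    df = pd.DataFrame(matrix, columns=FEATURE_NAMES)
    df.insert(0, "start_index", starts)
    df.insert(0, "label", labels)
    if recording_ids is not None:
        df.insert(0, "recording", recording_ids)
    df.to_csv(path, index=False)


def read_feature_table(path):
    import pandas as pd

    df = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing[:3]} ...")
    return df
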