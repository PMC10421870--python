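"""Seeded scanpath simulator with annotated forgetting episodes.

Emulates what a head-mounted eye tracker records during a radar-monitoring
task: a fixation/saccade scanpath over a screen, blinks appearing as runs of
missing pupil samples, pupil diameter with slow noise, and occasional
single-sample collection dropouts. Forgetting episodes are annotated time
intervals during which the generating distributions shift (longer fixations,
larger saccades, more blinks, dilated pupil); with all multipliers at 1 and a
zero pupil shift the generator is exactly null — the drawn sample stream is
bit-identical to a run without episodes, so episode-overlapping windows carry
no class signal by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from gazelapse.io import GazeRecording

__all__ = [
    "ScanpathParams",
    "ForgettingEpisodeParams",
    "PlannedFixation",
    "SimulatedRecording",
    "simulate_recording",
    "null_signal_check",
    "NullSignalSummary",
    "write_gaze_table",
    "write_episode_sidecar",
]


@dataclass(frozen=True)
class ScanpathParams:
    """Generating distributions of the baseline (non-episode) scanpath.

    Durations in seconds, positions/velocities in screen pixels, pupil in mm.
    Defaults describe a plausible 100 Hz monitoring scanpath: ~0.3 s median
    fixations, saccadic peak velocity of ~18000 px/s (roughly 500 deg/s at a
    typical viewing geometry), 15 blinks/min of 0.1-0.3 s.
    """

    n_targets: int = 12
    fixation_duration_log_mean: float = math.log(0.3)
    fixation_duration_log_sd: float = 0.35
    saccade_peak_velocity: float = 18000.0
    blink_rate: float = 15.0  # blinks per minute
    blink_duration_range: tuple[float, float] = (0.1, 0.3)
    pupil_baseline: float = 3.5
    pupil_noise_sd: float = 0.1
    position_noise_sd: float = 2.0
    screen_extent: tuple[float, float] = (1920.0, 1080.0)
    sample_rate: float = 100.0
    collection_dropout_rate: float = 0.0005  # per-sample single dropouts

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.n_targets < 2:
            raise ValueError("n_targets must be at least 2")
        if self.fixation_duration_log_sd <= 0:
            raise ValueError("fixation_duration_log_sd must be positive")
        if self.saccade_peak_velocity <= 0:
            raise ValueError("saccade_peak_velocity must be positive")
        if self.blink_rate < 0:
            raise ValueError("blink_rate must be non-negative")
        lo, hi = self.blink_duration_range
        if not (0 < lo < hi):
            raise ValueError("blink_duration_range must satisfy 0 < min < max")
        if self.pupil_baseline <= 0:
            raise ValueError("pupil_baseline must be positive")
        if min(self.screen_extent) <= 0:
            raise ValueError("screen_extent must be positive")
        if not 0 <= self.collection_dropout_rate < 1:
            raise ValueError("collection_dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class ForgettingEpisodeParams:
    """Rate, duration and oculomotor effect sizes of forgetting episodes.

    Multipliers scale the corresponding generating quantity while the scanpath
    is inside an episode; ``pupil_shift_mm`` is added to the pupil baseline.
    Unit multipliers and zero shift give the null (no-signal) generator.
    """

    episode_rate: float = 6.0  # episodes per hour
    episode_duration_range: tuple[float, float] = (20.0, 60.0)
    fixation_duration_multiplier: float = 2.0
    saccade_amplitude_multiplier: float = 2.0
    blink_rate_multiplier: float = 2.0
    pupil_shift_mm: float = 0.5

    def validate(self) -> None:
        if self.episode_rate < 0:
            raise ValueError("episode_rate must be non-negative")
        lo, hi = self.episode_duration_range
        if not (0 < lo < hi):
            raise ValueError("episode_duration_range must satisfy 0 < min < max")
        for name in (
            "fixation_duration_multiplier",
            "saccade_amplitude_multiplier",
            "blink_rate_multiplier",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def is_null(self) -> bool:
        return (
            self.fixation_duration_multiplier == 1.0
            and self.saccade_amplitude_multiplier == 1.0
            and self.blink_rate_multiplier == 1.0
            and self.pupil_shift_mm == 0.0
        )


def null_params(**overrides) -> ForgettingEpisodeParams:
    """Episode parameters with all effects switched off.

    Keyword overrides (e.g. ``episode_rate``) are forwarded; the four effect
    strengths stay at their neutral values.
    """
    return ForgettingEpisodeParams(
        fixation_duration_multiplier=1.0,
        saccade_amplitude_multiplier=1.0,
        blink_rate_multiplier=1.0,
        pupil_shift_mm=0.0,
        **overrides,
    )


@dataclass(frozen=True)
class PlannedFixation:
    onset: float
    offset: float
    x: float
    y: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class SimulatedRecording:
    """A generated gaze stream plus its ground truth.

    ``episodes`` are the annotated forgetting intervals; ``planned_fixations``
    are the fixations the scanpath actually executed (used as the recovery
    oracle for the event detector).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray
    confidence: np.ndarray
    sample_rate: float
    episodes: list[tuple[float, float]]
    planned_fixations: list[PlannedFixation]
    seed: int
    params: ScanpathParams
    episode_params: ForgettingEpisodeParams

    def __len__(self) -> int:
        return self.t.size

    def to_recording(self) -> GazeRecording:
        """View as the generic recording type the pipeline consumes."""
        episodes = (
            np.asarray(self.episodes, dtype=float).reshape(-1, 2)
            if self.episodes
            else np.empty((0, 2))
        )
        return GazeRecording(
            t=self.t.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            pupil=self.pupil.copy(),
            confidence=self.confidence.copy(),
            sample_rate=self.sample_rate,
            episodes=episodes,
        )


def _draw_episodes(
    rng: np.random.Generator, epi: ForgettingEpisodeParams, duration: float
) -> list[tuple[float, float]]:
    """Non-overlapping episode intervals from exponential inter-arrival gaps."""
    if epi.episode_rate == 0:
        return []
    out: list[tuple[float, float]] = []
    mean_gap = 3600.0 / epi.episode_rate
    t = 0.0
    lo, hi = epi.episode_duration_range
    while True:
        t += rng.exponential(mean_gap)
        if t >= duration:
            break
        end = min(t + rng.uniform(lo, hi), duration)
        out.append((t, end))
        t = end
    return out


def _in_episode(t: float, episodes: list[tuple[float, float]]) -> bool:
    for s, e in episodes:
        if s <= t < e:
            return True
        if s > t:
            break
    return False


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on tau in [0, 1]."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def simulate_recording(
    params: ScanpathParams,
    episodes: ForgettingEpisodeParams,
    duration: float = 5400.0,
    seed: int = 0,
) -> SimulatedRecording:
    """Generate one annotated gaze recording.

    Parameters
    ----------
    params : ScanpathParams
        Baseline scanpath distributions.
    episodes : ForgettingEpisodeParams
        Episode rate, durations and effect sizes.
    duration : float
        Recording length in seconds (default 5400 s = 90 min).
    seed : int
        Fully determines the output: the same seed gives a bit-identical
        recording.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    params.validate()
    episodes.validate()

    rng = np.random.default_rng(seed)
    fs = params.sample_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.empty(n)
    y = np.empty(n)

    epi_list = _draw_episodes(rng, episodes, duration)

    w, h = params.screen_extent
    targets = np.column_stack([rng.uniform(0, w, params.n_targets),
                               rng.uniform(0, h, params.n_targets)])
    cur_idx = int(rng.integers(params.n_targets))
    cur = targets[cur_idx].copy()

    planned: list[PlannedFixation] = []
    tc = 0.0
    min_dur = 2.0 / fs

    def seg(i0_time: float, i1_time: float) -> tuple[int, int]:
        i0 = int(np.ceil(i0_time * fs - 1e-9))
        i1 = int(np.ceil(i1_time * fs - 1e-9))
        return max(i0, 0), min(i1, n)

    while tc < duration:
        # fixation
        dur = rng.lognormal(params.fixation_duration_log_mean,
                            params.fixation_duration_log_sd)
        if _in_episode(tc, epi_list):
            dur *= episodes.fixation_duration_multiplier
        dur = max(dur, min_dur)
        i0, i1 = seg(tc, tc + dur)
        x[i0:i1] = cur[0]
        y[i0:i1] = cur[1]
        planned.append(PlannedFixation(tc, min(tc + dur, duration), cur[0], cur[1]))
        tc += dur
        if tc >= duration:
            break
        # saccade to the next target (Markov re-selection among the others)
        nxt = int(rng.integers(params.n_targets - 1))
        if nxt >= cur_idx:
            nxt += 1
        jump = targets[nxt] - cur
        if _in_episode(tc, epi_list):
            jump = jump * episodes.saccade_amplitude_multiplier
        land = np.clip(cur + jump, [0.0, 0.0], [w, h])
        dist = float(np.hypot(*(land - cur)))
        sdur = max(1.875 * dist / params.saccade_peak_velocity, min_dur)
        i0, i1 = seg(tc, tc + sdur)
        if i1 > i0:
            tau = (t[i0:i1] - tc) / sdur
            prof = _min_jerk(np.clip(tau, 0.0, 1.0))
            x[i0:i1] = cur[0] + prof * (land[0] - cur[0])
            y[i0:i1] = cur[1] + prof * (land[1] - cur[1])
        tc += sdur
        cur = land
        cur_idx = nxt

    # measurement jitter on gaze position
    x += rng.normal(0.0, params.position_noise_sd, n)
    y += rng.normal(0.0, params.position_noise_sd, n)
    np.clip(x, 0.0, w, out=x)
    np.clip(y, 0.0, h, out=y)

    # pupil: baseline + episode shift + AR(1) noise (slow drift-like)
    phi = 0.95
    innov = rng.normal(0.0, params.pupil_noise_sd * math.sqrt(1 - phi**2), n)
    noise = _signal.lfilter([1.0], [1.0, -phi], innov)
    pupil = params.pupil_baseline + noise
    if episodes.pupil_shift_mm != 0.0 and epi_list:
        shift = np.zeros(n)
        for s, e in epi_list:
            shift[(t >= s) & (t < e)] = episodes.pupil_shift_mm
        pupil = pupil + shift

    confidence = np.ones(n)

    # blinks: runs of missing pupil with confidence 0
    if params.blink_rate > 0:
        mean_gap = 60.0 / params.blink_rate
        bt = 0.0
        lo, hi = params.blink_duration_range
        while True:
            g = rng.exponential(mean_gap)
            if _in_episode(bt, epi_list):
                g /= episodes.blink_rate_multiplier
            bt += g
            if bt >= duration:
                break
            bdur = rng.uniform(lo, hi)
            i0, i1 = seg(bt, bt + bdur)
            pupil[i0:i1] = np.nan
            confidence[i0:i1] = 0.0
            bt += bdur

    # isolated collection dropouts (all channels missing for one sample)
    if params.collection_dropout_rate > 0:
        drop = rng.random(n) < params.collection_dropout_rate
        drop &= ~np.isnan(pupil)  # keep blink runs as pure blink loss
        # avoid extending a blink run: clear dropouts adjacent to blinks
        blinked = np.isnan(pupil)
        adjacent = np.zeros(n, dtype=bool)
        adjacent[1:] |= blinked[:-1]
        adjacent[:-1] |= blinked[1:]
        drop &= ~adjacent
        x[drop] = np.nan
        y[drop] = np.nan
        pupil[drop] = np.nan
        confidence[drop] = 0.0

    return SimulatedRecording(
        t=t, x=x, y=y, pupil=pupil, confidence=confidence,
        sample_rate=fs, episodes=epi_list, planned_fixations=planned,
        seed=seed, params=params, episode_params=episodes,
    )


# ---------------------------------------------------------------------------
# plain-text writers (same table the reader consumes)

def write_gaze_table(rec: SimulatedRecording, path) -> None:
    """Write the gaze stream as a CSV with the five canonical columns."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "timestamp": rec.t,
            "x": rec.x,
            "y": rec.y,
            "pupil": rec.pupil,
            "confidence": rec.confidence,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def write_episode_sidecar(rec: SimulatedRecording, path) -> None:
    """Write annotated episode intervals, one `start_s,end_s` pair per line."""
    with open(path, "w") as fh:
        fh.write("start_s,end_s\n")
        for s, e in rec.episodes:
            fh.write(f"{s:.6f},{e:.6f}\n")


# ---------------------------------------------------------------------------
# null-signal diagnostic

@dataclass
class NullSignalSummary:
    """Per-feature two-sample test of episode vs non-episode windows."""

    feature_names: list[str]
    p_values: np.ndarray
    adjusted_p: np.ndarray
    alpha: float
    n_positive: int
    n_negative: int

    @property
    def n_rejections(self) -> int:
        return int(np.sum(self.adjusted_p < self.alpha))

    def rejected_features(self) -> list[str]:
        return [n for n, p in zip(self.feature_names, self.adjusted_p)
                if p < self.alpha]


def null_signal_check(
    n_recordings: int,
    seed: int,
    params: ScanpathParams | None = None,
    episode_params: ForgettingEpisodeParams | None = None,
    duration: float = 120.0,
    alpha: float = 0.01,
) -> NullSignalSummary:
    """Compare each of the 44 features between episode and non-episode windows.

    With the null episode parameters no feature should separate the classes;
    with a genuine effect (for example ``fixation_duration_multiplier=2``) the
    touched features should reject. Uses Mann-Whitney U per feature with Holm
    multiplicity adjustment.
    """
    from gazelapse import features as feats
    from gazelapse import io as gio

    if params is None:
        params = ScanpathParams()
    if episode_params is None:
        episode_params = null_params()
    # episodes must actually occur within short recordings
    if episode_params.episode_rate * duration / 3600.0 < 1:
        episode_params = replace(episode_params,
                                 episode_rate=max(episode_params.episode_rate, 60.0))

    fcfg = feats.FeatureConfig(screen_extent=params.screen_extent)
    pos_rows, neg_rows = [], []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_recordings) % (2**31)
    for s in child_seeds:
        rec = simulate_recording(params, episode_params, duration, int(s))
        g = gio.preprocess(rec.to_recording())
        windows = gio.slide_windows(g)
        windows = gio.assign_labels(windows, g.episodes)
        F, labels, _ = feats.windows_to_features(windows, fcfg)
        pos_rows.append(F[labels == 1])
        neg_rows.append(F[labels == 0])
    pos = np.vstack(pos_rows)
    neg = np.vstack(neg_rows)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both episode and non-episode windows; "
                         "increase duration or episode rate")

    pvals = np.ones(pos.shape[1])
    for j in range(pos.shape[1]):
        a, b = pos[:, j], neg[:, j]
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals[j] = 1.0
        else:
            pvals[j] = _stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    # Holm step-down adjustment
    order = np.argsort(pvals)
    m = pvals.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return NullSignalSummary(
        feature_names=list(feats.FEATURE_NAMES),
        p_values=pvals,
        adjusted_p=adj,
        alpha=alpha,
        n_positive=len(pos),
        n_negative=len(neg),
    )
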