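import numpy as np
import pytest

from gazelapse import io as gio
from gazelapse import simulate as sim
from gazelapse.model import HybridConfig


@pytest.fixture(scope="session")
def short_recording() -> sim.SimulatedRecording:
    """60 s recording with a high episode rate so both classes appear."""
    return sim.simulate_recording(
        sim.ScanpathParams(),
        sim.ForgettingEpisodeParams(episode_rate=120.0,
                                    episode_duration_range=(10.0, 20.0)),
        duration=60.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def preprocessed(short_recording) -> gio.GazeRecording:
    return gio.preprocess(short_recording.to_recording())


@pytest.fixture(scope="session")
def labeled_windows(preprocessed):
    return gio.assign_labels(gio.slide_windows(preprocessed),
                             preprocessed.episodes)


@pytest.fixture()
def tiny_model_cfg() -> HybridConfig:
    """Width-reduced architecture in float64 for numerical checks."""
    return HybridConfig(tc_features=5, tic_features=4, sequence_length=3,
                        conv_channels=3, lstm_hidden=4, dtype=np.float64)


def make_window(x, y, pupil=None, blink=None, fs=100.0, start=0) -> gio.Window:
    """Hand-built window for unit tests."""
    x = np.asarray(x, dtype=float)
    n = x.size
    y = np.asarray(y, dtype=float)
    if pupil is None:
        pupil = np.full(n, 3.5)
    if blink is None:
        blink = np.zeros(n, dtype=bool)
    return gio.Window(
        t=np.arange(start, start + n) / fs,
        x=x, y=y, pupil=np.asarray(pupil, dtype=float),
        confidence=np.ones(n), blink_mask=np.asarray(blink, dtype=bool),
        start_index=start, sample_rate=fs,
    )
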