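"""Closed-form checks of the 44 window metrics, normalization and sequences."""

import numpy as np
import pytest

from gazelapse import events as ev
from gazelapse import features as feats

from conftest import make_window


def _idx(name):
    return feats.FEATURE_NAMES.index(name)


def _three_fixation_window():
    """500 samples, 100 Hz: dwells at (200,200), (500,200), (500,500)."""
    x = np.concatenate([np.full(160, 200.0), np.full(170, 500.0),
                        np.full(170, 500.0)])
    y = np.concatenate([np.full(160, 200.0), np.full(170, 200.0),
                        np.full(170, 500.0)])
    return make_window(x, y)


def test_manifest_sizes_and_disjointness():
    assert len(feats.TIME_RELATED_NAMES) == 23
    assert len(feats.TIME_INDEPENDENT_NAMES) == 21
    assert len(feats.FEATURE_NAMES) == 44
    assert len(set(feats.FEATURE_NAMES)) == 44


def test_time_related_metrics_closed_form():
    w = _three_fixation_window()
    v = feats.compute_features(w)
    assert v[_idx("fixation_count")] == 3
    assert v[_idx("fixations_per_second")] == pytest.approx(3 / 5.0)
    assert v[_idx("total_fixation_time")] == pytest.approx(5.0)
    assert v[_idx("mean_fixation_duration")] == pytest.approx(5.0 / 3)
    assert v[_idx("max_fixation_duration")] == pytest.approx(1.7)
    # centroids (200,200), (500,200), (500,500): widest pair is the diagonal
    assert v[_idx("gaze_width")] == pytest.approx(np.hypot(300, 300))
    # every centroid's nearest neighbour is 300 px away
    assert v[_idx("nearest_neighbor_distance")] == pytest.approx(300.0)
    assert v[_idx("gaze_density")] == pytest.approx(3 / (300.0 * 300.0))
    assert v[_idx("saccade_count")] == 2
    assert v[_idx("total_saccade_length")] == pytest.approx(600.0)
    assert v[_idx("mean_saccade_amplitude")] == pytest.approx(300.0)
    assert v[_idx("mean_pupil_diameter")] == pytest.approx(3.5)
    assert v[_idx("blink_count")] == 0
    assert v[_idx("closed_eye_time")] == 0.0


def test_time_independent_metrics_closed_form():
    w = _three_fixation_window()
    v = feats.compute_features(w)
    assert v[_idx("median_fixation_duration")] == pytest.approx(1.7)
    assert v[_idx("fixation_time_ratio")] == pytest.approx(1.0)
    assert v[_idx("horizontal_range")] == pytest.approx(300.0)
    assert v[_idx("vertical_range")] == pytest.approx(300.0)
    # first fixation (200,200) against the 1920x1080 screen centre
    assert v[_idx("first_fixation_offcenter")] == pytest.approx(
        np.hypot(200 - 960, 200 - 540))
    # population SD of durations [1.6, 1.7, 1.7]
    assert v[_idx("fixation_duration_sd")] == pytest.approx(
        np.std([1.6, 1.7, 1.7]))
    assert v[_idx("median_saccade_amplitude")] == pytest.approx(300.0)
    assert v[_idx("saccade_amplitude_sd")] == pytest.approx(0.0)
    # instantaneous jumps: raw scanpath length equals the two 300 px legs
    assert v[_idx("scanpath_length")] == pytest.approx(600.0)
    # both saccades exceed the 100 px global/local threshold
    assert v[_idx("global_local_ratio")] == pytest.approx(2.0)


def test_noting_and_returning_on_grid():
    # cells on the 4x4 grid of a 1920x1080 screen: A, B, A, B
    xs = [100.0, 700.0, 100.0, 700.0]
    x = np.concatenate([np.full(20, v) for v in xs])
    y = np.full(x.size, 100.0)
    v = feats.compute_features(make_window(x, y))
    assert v[_idx("fixation_count")] == 4
    assert v[_idx("noting")] == 2  # two novel cells
    assert v[_idx("returning")] == 2  # each cell revisited once


def test_blink_metrics():
    n = 500
    blink = np.zeros(n, dtype=bool)
    blink[100:110] = True  # 0.10 s
    blink[300:330] = True  # 0.30 s
    w = make_window(np.full(n, 400.0), np.full(n, 400.0), blink=blink)
    v = feats.compute_features(w)
    assert v[_idx("blink_count")] == 2
    assert v[_idx("blink_rate")] == pytest.approx(2 / 5.0)
    assert v[_idx("longest_blink_duration")] == pytest.approx(0.3)
    assert v[_idx("latest_blink_duration")] == pytest.approx(0.3)
    assert v[_idx("closed_eye_time")] == pytest.approx(0.4)
    assert v[_idx("blink_count_per_second_sd")] == pytest.approx(
        np.std([0, 1, 0, 1, 0]))


def test_empty_window_yields_all_zero_event_metrics():
    # pure drift: no dwell ever satisfies the dispersion criterion
    x = np.linspace(0.0, 1800.0, 500)
    v = feats.compute_features(make_window(x, x.copy()))
    assert v[_idx("fixation_count")] == 0
    assert v[_idx("saccade_count")] == 0
    assert v[_idx("mean_fixation_duration")] == 0.0
    assert v[_idx("fixation_duration_skewness")] == 0.0
    assert np.all(np.isfinite(v))


def test_moment_fallbacks_below_three_observations():
    # exactly two fixations: SD is defined, skewness/kurtosis fall back to 0
    x = np.concatenate([np.full(200, 200.0), np.full(300, 600.0)])
    v = feats.compute_features(make_window(x, np.full(500, 200.0)))
    assert v[_idx("fixation_count")] == 2
    assert v[_idx("fixation_duration_sd")] > 0
    assert v[_idx("fixation_duration_skewness")] == 0.0
    assert v[_idx("fixation_duration_kurtosis")] == 0.0


def test_features_finite_on_simulated_windows(labeled_windows):
    F, labels, starts = feats.windows_to_features(labeled_windows)
    assert F.shape == (len(labeled_windows), 44)
    assert np.all(np.isfinite(F))
    assert set(labels) <= {0, 1}
    assert starts.tolist() == sorted(starts.tolist())


# --- normalization -------------------------------------------------------

def test_minmax_endpoints_and_interior():
    train = np.array([[0.0, 10.0], [4.0, 30.0], [2.0, 20.0]])
    p = feats.fit_minmax(train)
    z = feats.apply_minmax(train, p)
    assert z.min(axis=0).tolist() == [0.0, 0.0]
    assert z.max(axis=0).tolist() == [1.0, 1.0]
    assert z[2, 0] == pytest.approx(0.5)
    assert z[2, 1] == pytest.approx(0.5)


def test_minmax_degenerate_feature_maps_to_zero():
    train = np.array([[7.0, 1.0], [7.0, 2.0]])
    p = feats.fit_minmax(train)
    z = feats.apply_minmax(np.array([[7.0, 1.5], [9.0, 2.0]]), p)
    assert z[:, 0].tolist() == [0.0, 0.0]
    assert z[0, 1] == pytest.approx(0.5)


def test_minmax_clips_out_of_range_test_rows():
    p = feats.fit_minmax(np.array([[0.0], [10.0]]))
    z = feats.apply_minmax(np.array([[-5.0], [15.0]]), p)
    assert z.ravel().tolist() == [0.0, 1.0]


def test_fit_minmax_rejects_empty():
    with pytest.raises(ValueError):
        feats.fit_minmax(np.empty((0, 3)))


# --- sequence assembly ---------------------------------------------------

def test_assemble_sequences_shapes_and_labels():
    m = np.arange(20 * 44, dtype=float).reshape(20, 44)
    labels = np.arange(20) % 2
    X, y = feats.assemble_sequences(m, labels, length=6, stride=1)
    assert X.shape == (15, 6, 44)
    np.testing.assert_array_equal(X[0], m[0:6])
    np.testing.assert_array_equal(X[14], m[14:20])
    # sequence label = final window's label
    np.testing.assert_array_equal(y, labels[5:])


def test_assemble_sequences_short_input_is_empty():
    X, y = feats.assemble_sequences(np.ones((5, 44)), np.zeros(5), length=6)
    assert X.shape == (0, 6, 44) and y.size == 0


def test_assemble_sequences_stride():
    X, y = feats.assemble_sequences(np.ones((20, 44)), np.zeros(20),
                                    length=6, stride=6)
    assert X.shape[0] == 3


def test_feature_table_round_trip(tmp_path, labeled_windows):
    F, labels, starts = feats.windows_to_features(labeled_windows)
    p = tmp_path / "features.csv"
    feats.write_feature_table(p, F, labels, starts,
                              recording_ids=np.zeros(len(labels), dtype=int))
    df = feats.read_feature_table(p)
    np.testing.assert_allclose(df[feats.FEATURE_NAMES].to_numpy(), F,
                               rtol=1e-12, atol=1e-12)
    np.testing.assert_array_equal(df["label"].to_numpy(), labels)


def test_custom_event_config_propagates():
    w = _three_fixation_window()
    strict = ev.EventDetectionConfig(min_fixation_duration=1.65)
    v = feats.compute_features(w, event_cfg=strict)
    assert v[_idx("fixation_count")] == 2  # the 1.6 s dwell now falls short
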