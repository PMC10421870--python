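"""Cross-validation protocol, baselines and the benchmark dataset builder."""

import numpy as np
import pytest

from gazelapse import features as feats
from gazelapse import simulate as sim
from gazelapse import train as tr
from gazelapse.model import HybridConfig


SMALL_CFG = HybridConfig(conv_channels=8, lstm_hidden=8)  # full 44-feature input


def _separable(m=60, seed=0, gap=0.6):
    """(m, 6, 44) sequences where feature 0's level encodes the class."""
    rng = np.random.default_rng(seed)
    X = rng.random((m, 6, 44)) * 0.4
    y = (np.arange(m) % 2).astype(int)
    X[:, :, 0] += gap * y[:, None]
    return X, y


# --- folds ---------------------------------------------------------------

def test_make_folds_partitions_everything_once():
    folds = tr.make_folds(23, 5, seed=1)
    assert len(folds) == 5
    all_idx = np.concatenate(folds)
    assert sorted(all_idx.tolist()) == list(range(23))
    sizes = sorted(len(f) for f in folds)
    assert sizes == [4, 4, 5, 5, 5]


def test_make_folds_deterministic_in_seed():
    a = tr.make_folds(40, 5, seed=3)
    b = tr.make_folds(40, 5, seed=3)
    c = tr.make_folds(40, 5, seed=4)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)
    assert any(not np.array_equal(x, y) for x, y in zip(a, c))


def test_make_folds_rejects_too_few_samples():
    with pytest.raises(ValueError):
        tr.make_folds(3, 5, seed=0)


def test_group_folds_never_split_a_recording():
    groups = np.repeat(np.arange(8), 10)  # 8 recordings, 10 sequences each
    folds = tr.make_group_folds(groups, 5, seed=0)
    all_idx = np.concatenate(folds)
    assert sorted(all_idx.tolist()) == list(range(80))
    fold_of = np.empty(80, dtype=int)
    for k, f in enumerate(folds):
        fold_of[f] = k
    # every sequence of one recording lands in the same fold
    for g in range(8):
        assert len(set(fold_of[groups == g])) == 1


def test_group_folds_require_enough_recordings():
    with pytest.raises(ValueError, match="recordings"):
        tr.make_group_folds(np.repeat(np.arange(3), 5), 5, seed=0)


def test_run_methods_with_groups_keeps_overlap_out_of_validation():
    X, y = _separable(m=60, seed=4)
    groups = np.repeat(np.arange(6), 10)
    cfg = tr.TrainConfig(learning_rate=0.01, epochs=3, batch_size=16,
                         seed=0, folds=3)
    report = tr.run_methods(X, y, cfg, methods=("logistic",), groups=groups)
    assert len(report.entries) == 1
    folds = tr.make_group_folds(groups, 3, seed=0)
    assert report.entries[0].fold_checksum == tr._fold_checksum(folds)


def test_train_config_validation():
    with pytest.raises(ValueError):
        tr.TrainConfig(epochs=0).validate()
    with pytest.raises(ValueError):
        tr.TrainConfig(folds=1).validate()
    tr.TrainConfig().validate()


# --- training and evaluation --------------------------------------------

def test_adam_train_reduces_loss_and_fits_separable_data():
    X, y = _separable()
    cfg = tr.TrainConfig(learning_rate=0.01, epochs=15, batch_size=16, seed=0)
    from gazelapse.model import build_model

    model = build_model("hybrid", SMALL_CFG, seed=0)
    trace = tr.adam_train(model, X, y, cfg)
    assert len(trace) == 15
    assert trace[-1] < trace[0]
    assert tr.evaluate_accuracy(model, X, y) > 0.9


def test_evaluate_accuracy_rejects_empty():
    from gazelapse.model import build_model

    model = build_model("hybrid", SMALL_CFG, seed=0)
    with pytest.raises(ValueError):
        tr.evaluate_accuracy(model, np.empty((0, 6, 44)), np.empty(0))


def test_five_fold_cv_protocol():
    X, y = _separable(m=50)
    cfg = tr.TrainConfig(learning_rate=0.01, epochs=10, batch_size=16,
                         seed=1, folds=5)
    results, entry = tr.five_fold_cv(X, y, cfg, "conv_only", SMALL_CFG)
    assert len(results) == 5
    assert len(entry.fold_accuracies) == 5
    # every sample is validated exactly once
    assert sum(r.n_val for r in results) == 50
    assert all(r.n_train + r.n_val == 50 for r in results)
    assert entry.mean_accuracy == pytest.approx(
        np.mean([r.val_accuracy for r in results]))
    assert entry.mean_accuracy > 0.8


def test_logistic_baseline_fits_linearly_separable_data():
    X, y = _separable(m=80, seed=2)
    cfg = tr.TrainConfig(seed=0, folds=5)
    entry = tr.train_logistic_baseline(X, y, cfg)
    assert entry.name == "logistic"
    assert entry.mean_accuracy > 0.9


def test_run_methods_shares_folds_and_reports():
    X, y = _separable(m=40, seed=3)
    cfg = tr.TrainConfig(learning_rate=0.01, epochs=5, batch_size=16,
                         seed=2, folds=4)
    report = tr.run_methods(X, y, cfg, methods=("conv_only", "logistic"),
                            model_cfg=SMALL_CFG)
    assert {e.name for e in report.entries} == {"conv_only", "logistic"}
    assert len({e.fold_checksum for e in report.entries}) == 1
    table = report.to_table()
    assert "conv_only" in table and "logistic" in table
    # JSON round trip preserves every entry
    back = tr.ComparisonReport.from_json(report.to_json())
    assert {e.name: e.fold_accuracies for e in back.entries} == {
        e.name: e.fold_accuracies for e in report.entries}


def test_comparison_report_rejects_mismatched_folds():
    a = tr.MethodResult("hybrid", [0.9], seed=0, fold_checksum="aaa")
    b = tr.MethodResult("logistic", [0.8], seed=0, fold_checksum="bbb")
    with pytest.raises(ValueError, match="fold assignments"):
        tr.comparison_report([a, b])


def test_run_methods_rejects_unknown_method():
    X, y = _separable(m=20)
    with pytest.raises(ValueError, match="unknown method"):
        tr.run_methods(X, y, tr.TrainConfig(folds=2), methods=("svm",))


def test_normalization_fitted_on_train_split_only():
    """A validation outlier must clip to 1 rather than stretch the scale."""
    train = np.array([[0.0], [1.0], [2.0]])
    params = feats.fit_minmax(train)
    val = feats.apply_minmax(np.array([[50.0]]), params)
    assert val[0, 0] == 1.0


# --- benchmark dataset ---------------------------------------------------

@pytest.fixture(scope="module")
def benchmark_small():
    epi = sim.ForgettingEpisodeParams(episode_rate=60.0,
                                      episode_duration_range=(20.0, 40.0))
    return tr.make_benchmark_dataset(2, 300.0, seed=9, episode_params=epi)


def test_benchmark_dataset_shape_and_balance(benchmark_small):
    X, y = benchmark_small
    assert X.ndim == 3 and X.shape[1:] == (6, 44)
    assert set(y) == {0, 1}
    assert (y == 0).sum() == (y == 1).sum()  # balanced by construction
    assert np.all(np.isfinite(X))


def test_benchmark_dataset_group_ids():
    epi = sim.ForgettingEpisodeParams(episode_rate=60.0,
                                      episode_duration_range=(20.0, 40.0))
    X, y, groups = tr.make_benchmark_dataset(2, 300.0, seed=9,
                                             episode_params=epi,
                                             return_groups=True)
    assert groups.shape == y.shape
    assert set(groups) == {0, 1}


def test_benchmark_dataset_deterministic():
    epi = sim.ForgettingEpisodeParams(episode_rate=60.0,
                                      episode_duration_range=(20.0, 40.0))
    X1, y1 = tr.make_benchmark_dataset(1, 300.0, seed=5, episode_params=epi)
    X2, y2 = tr.make_benchmark_dataset(1, 300.0, seed=5, episode_params=epi)
    np.testing.assert_array_equal(X1, X2)
    np.testing.assert_array_equal(y1, y2)


def test_benchmark_dataset_requires_both_classes():
    epi = sim.ForgettingEpisodeParams(episode_rate=0.0)
    with pytest.raises(ValueError, match="both classes"):
        tr.make_benchmark_dataset(1, 300.0, seed=0, episode_params=epi)
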