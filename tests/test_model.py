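"""Architecture dimensions, layer mechanics and numerical oracles."""

import numpy as np
import pytest

from gazelapse import diagnostics as diag
from gazelapse import nn
from gazelapse.model import (
    ConvOnlyModel,
    HybridConfig,
    HybridModel,
    RecurrentOnlyModel,
    build_model,
    softmax,
    softmax_cross_entropy,
    splice_features,
)


# --- architecture dimensions --------------------------------------------

def test_default_dimension_ladder():
    cfg = HybridConfig()
    assert (cfg.tc_features, cfg.tic_features) == (23, 21)
    assert cfg.sequence_length == 6
    assert cfg.conv_channels == 64
    assert cfg.spliced_width == 87
    assert cfg.lstm_hidden == 128
    assert cfg.head_width == 2

    model = HybridModel(seed=0)
    tc = np.random.default_rng(0).random((4, 6, 23), dtype=np.float32)
    tic = np.random.default_rng(1).random((4, 6, 21), dtype=np.float32)

    deep = model.conv_branch_forward(tc)
    assert deep.shape == (4, 6, 64)
    spliced = splice_features(deep, tc)
    assert spliced.shape == (4, 6, 87)
    np.testing.assert_array_equal(spliced[..., 64:], tc)  # raw block intact
    hs = model.lstm_forward(spliced)
    assert hs.shape == (4, 6, 128)

    tc_out = model._tc_forward(tc, training=False)
    tic_out = model.tic_branch_forward(tic)
    assert tc_out.shape == (4, 2) and tic_out.shape == (4, 2)
    logits = model.forward(tc, tic)
    assert logits.shape == (4, 2)
    probs = model.predict_proba(tc, tic)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)


def test_conv_is_causal():
    """Changing a late event never alters earlier conv outputs."""
    rng = np.random.default_rng(2)
    conv = nn.TemporalConv(5, 3, rng, kernel=2, dtype=np.float64)
    x = rng.random((2, 6, 5))
    base = conv.forward(x)
    x2 = x.copy()
    x2[:, 4, :] += 1.0
    out = conv.forward(x2)
    np.testing.assert_array_equal(out[:, :4, :], base[:, :4, :])
    assert not np.allclose(out[:, 4, :], base[:, 4, :])


def test_ablations_share_the_tic_branch_shape(tiny_model_cfg):
    for cls in (HybridModel, ConvOnlyModel, RecurrentOnlyModel):
        model = cls(tiny_model_cfg, seed=1)
        tc = np.random.default_rng(3).random((5, 3, 5))
        tic = np.random.default_rng(4).random((5, 3, 4))
        assert model.forward(tc, tic).shape == (5, 2)
        assert model.n_parameters() > 0


def test_shape_validation_rejects_wrong_widths():
    model = build_model("hybrid", seed=0)
    with pytest.raises(ValueError, match="23"):
        model.forward(np.zeros((2, 6, 22)), np.zeros((2, 6, 21)))
    with pytest.raises(ValueError, match="21"):
        model.forward(np.zeros((2, 6, 23)), np.zeros((2, 6, 20)))
    with pytest.raises(ValueError):
        build_model("transformer")


def test_same_seed_same_init_different_seed_differs(tiny_model_cfg):
    a = HybridModel(tiny_model_cfg, seed=5)
    b = HybridModel(tiny_model_cfg, seed=5)
    c = HybridModel(tiny_model_cfg, seed=6)
    ka = a.lstm.params["W0"]
    np.testing.assert_array_equal(ka, b.lstm.params["W0"])
    assert not np.array_equal(ka, c.lstm.params["W0"])


# --- formula oracles -----------------------------------------------------

def test_batch_norm_training_output_is_standardized():
    rng = np.random.default_rng(7)
    bn = nn.BatchNorm(6, dtype=np.float64)
    x = rng.normal(3.0, 4.0, (64, 6))
    z = bn.forward(x, training=True)
    np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-10)
    np.testing.assert_allclose(z.var(axis=0), 1.0, atol=1e-4)  # eps shrinkage
    # 3-D input: statistics pool batch and sequence positions
    x3 = rng.normal(-1.0, 2.0, (16, 6, 6))
    z3 = bn.forward(x3, training=True)
    np.testing.assert_allclose(z3.mean(axis=(0, 1)), 0.0, atol=1e-10)
    np.testing.assert_allclose(z3.var(axis=(0, 1)), 1.0, atol=1e-4)


def test_batch_norm_inference_uses_running_stats():
    bn = nn.BatchNorm(3, dtype=np.float64)
    rng = np.random.default_rng(8)
    x = rng.normal(5.0, 2.0, (32, 3))
    for _ in range(200):
        bn.forward(x, training=True)
    z = bn.forward(x, training=False)
    assert abs(z.mean()) < 0.05 and abs(z.var() - 1.0) < 0.05
    with pytest.raises(ValueError):
        bn.forward(x[:1], training=True)


def test_lstm_matches_hand_stepped_recurrence():
    assert diag.lstm_forward_error(seed=0) <= 1e-6
    assert diag.lstm_forward_error(seed=1, num_layers=1, hidden=8) <= 1e-6


def test_cross_entropy_matches_direct_evaluation():
    assert diag.cross_entropy_error(seed=0) <= 1e-8
    assert diag.cross_entropy_error(seed=5, batch=64) <= 1e-8


def test_cross_entropy_gradient_is_softmax_minus_onehot():
    logits = np.array([[2.0, -1.0], [0.5, 0.5], [-3.0, 1.0]])
    labels = np.array([0, 1, 1])
    loss, d = softmax_cross_entropy(logits, labels)
    p = softmax(logits)
    expected = p.copy()
    expected[np.arange(3), labels] -= 1.0
    np.testing.assert_allclose(d, expected / 3, atol=1e-12)
    assert loss > 0


def test_class_weights_reweight_the_loss():
    logits = np.array([[2.0, -1.0], [-1.0, 2.0]])
    labels = np.array([0, 1])
    base, _ = softmax_cross_entropy(logits, labels)
    # equal per-sample losses: any weighting keeps the same mean
    w, _ = softmax_cross_entropy(logits, labels, class_weights=np.array([3.0, 1.0]))
    assert w == pytest.approx(base)
    # unequal per-sample losses shift toward the upweighted class
    logits2 = np.array([[2.0, -1.0], [2.0, -1.0]])  # second sample mislabeled
    labels2 = np.array([0, 1])
    unweighted, _ = softmax_cross_entropy(logits2, labels2)
    upweighted, _ = softmax_cross_entropy(logits2, labels2,
                                          class_weights=np.array([1.0, 3.0]))
    assert upweighted > unweighted


def test_adam_matches_hand_stepped_updates():
    assert diag.adam_update_error() <= 1e-8


def test_adam_first_step_size_is_learning_rate():
    """With bias correction the first update is ~lr * sign(gradient)."""

    class OneParam(nn.Layer):
        def __init__(self):
            super().__init__()
            self._register("theta", np.array([1.0]))

    layer = OneParam()
    opt = nn.Adam([layer], lr=0.01)
    layer.grads["theta"][0] = 7.3
    opt.step()
    assert layer.params["theta"][0] == pytest.approx(1.0 - 0.01, abs=1e-6)


@pytest.mark.parametrize("name", ["hybrid", "conv_only", "recurrent_only"])
def test_analytic_gradients_match_finite_differences(name, tiny_model_cfg):
    model = build_model(name, tiny_model_cfg, seed=0)
    assert diag.gradient_check(model, seed=0) < 1e-4


def test_splice_rejects_mismatched_leading_dims():
    with pytest.raises(ValueError):
        splice_features(np.zeros((2, 6, 3)), np.zeros((2, 5, 4)))


def test_relu_and_last_step_mechanics():
    x = np.array([[[-1.0, 2.0], [3.0, -4.0]]])
    r = nn.ReLU()
    np.testing.assert_array_equal(r.forward(x), [[[0.0, 2.0], [3.0, 0.0]]])
    np.testing.assert_array_equal(r.backward(np.ones_like(x)),
                                  [[[0.0, 1.0], [1.0, 0.0]]])
    ls = nn.LastStep()
    np.testing.assert_array_equal(ls.forward(x), [[3.0, -4.0]])
    back = ls.backward(np.array([[1.0, 1.0]]))
    np.testing.assert_array_equal(back, [[[0.0, 0.0], [1.0, 1.0]]])
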