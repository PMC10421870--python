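"""Independent numerical checks of the model and pipeline.

These helpers re-derive quantities along a second, deliberately naive code
path — literal per-gate recurrence stepping, central finite differences,
hand-stepped optimizer updates — and measure how far the production
implementation deviates. They back the package's correctness tests and the
reproduction script.
"""

from __future__ import annotations

import math

import numpy as np

from gazelapse.model import DualBranchModel, softmax_cross_entropy

__all__ = [
    "reference_lstm_forward",
    "lstm_forward_error",
    "gradient_check",
    "adam_update_error",
    "cross_entropy_error",
    "fixation_recovery_rate",
]


def reference_lstm_forward(params: dict, x: np.ndarray,
                           num_layers: int, hidden: int) -> np.ndarray:
    """Literal per-step, per-gate evaluation of the stacked LSTM recurrence.

    Written independently of the production layer: gates are sliced and
    evaluated one by one with plain ``math``-style formulas.
    """
    B, T, _ = x.shape
    H = hidden
    inp = x.astype(np.float64)
    for layer in range(num_layers):
        W = np.asarray(params[f"W{layer}"], dtype=np.float64)
        U = np.asarray(params[f"U{layer}"], dtype=np.float64)
        b = np.asarray(params[f"b{layer}"], dtype=np.float64)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        outs = np.zeros((B, T, H))
        for t in range(T):
            a = inp[:, t, :] @ W + h @ U + b
            i_gate = 1.0 / (1.0 + np.exp(-a[:, 0:H]))
            f_gate = 1.0 / (1.0 + np.exp(-a[:, H:2 * H]))
            o_gate = 1.0 / (1.0 + np.exp(-a[:, 2 * H:3 * H]))
            cand = np.tanh(a[:, 3 * H:4 * H])
            c = f_gate * c + i_gate * cand
            h = o_gate * np.tanh(c)
            outs[:, t, :] = h
        inp = outs
    return inp


def lstm_forward_error(seed: int = 0, batch: int = 3, steps: int = 6,
                       width: int = 7, hidden: int = 5,
                       num_layers: int = 3) -> float:
    """Max |production LSTM - reference recurrence| on random inputs."""
    from gazelapse import nn

    rng = np.random.default_rng(seed)
    lstm = nn.LSTM(width, hidden, num_layers, rng, dtype=np.float64)
    for k in lstm.params:  # non-zero biases exercise every term
        lstm.params[k] = rng.normal(0, 0.5, lstm.params[k].shape)
    x = rng.normal(0, 1, (batch, steps, width))
    got = lstm.forward(x)
    want = reference_lstm_forward(lstm.params, x, num_layers, hidden)
    return float(np.max(np.abs(got - want)))


def gradient_check(model: DualBranchModel, seed: int = 0, batch: int = 4,
                   samples_per_param: int = 4, eps: float = 1e-6) -> float:
    """Max guarded relative error between analytic and central-difference
    gradients of the training loss, sampled over every parameter array.

    The model must be built with float64. The relative error is guarded as
    |num - ana| / max(|num| + |ana|, 1e-4): with a loss of order one and
    eps = 1e-6, the central difference quotient carries roughly 1e-10 to
    1e-8 of rounding noise, so gradients smaller than about 1e-4 cannot be
    resolved in relative terms and would otherwise register that noise.
    """
    cfg = model.cfg
    if cfg.dtype is not np.float64:
        raise ValueError("gradient_check requires a float64 model")
    rng = np.random.default_rng(seed)
    tc = rng.random((batch, cfg.sequence_length, cfg.tc_features))
    tic = rng.random((batch, cfg.sequence_length, cfg.tic_features))
    y = rng.integers(0, cfg.n_classes, batch)

    def loss() -> float:
        return softmax_cross_entropy(model.forward(tc, tic, training=True), y)[0]

    model.zero_grads()
    l0, dl = softmax_cross_entropy(model.forward(tc, tic, training=True), y)
    model.backward(dl)
    worst = 0.0
    for layer in model.layers():
        for key, P in layer.params.items():
            g = layer.grads[key]
            k = min(samples_per_param, P.size)
            flat = rng.choice(P.size, size=k, replace=False)
            for f in flat:
                ii = np.unravel_index(f, P.shape)
                old = P[ii]
                P[ii] = old + eps
                lp = loss()
                P[ii] = old - eps
                lm = loss()
                P[ii] = old
                num = (lp - lm) / (2 * eps)
                rel = abs(num - g[ii]) / max(abs(num) + abs(g[ii]), 1e-4)
                worst = max(worst, rel)
    return worst


def adam_update_error(n_steps: int = 50, lr: float = 0.05,
                      theta0: float = 3.0) -> float:
    """Max |production Adam - hand-stepped Adam| on a 1-parameter quadratic.

    Minimizes f(theta) = 0.5 theta^2 (gradient = theta) and steps a scalar
    replica of the update equations alongside the production optimizer.
    """
    from gazelapse import nn

    class OneParam(nn.Layer):
        def __init__(self):
            super().__init__()
            self._register("theta", np.array([theta0]))

    layer = OneParam()
    opt = nn.Adam([layer], lr=lr)

    theta = theta0
    m = v = 0.0
    b1, b2, eps = 0.9, 0.999, 1e-8
    worst = 0.0
    for t in range(1, n_steps + 1):
        layer.zero_grads()
        layer.grads["theta"][0] = layer.params["theta"][0]
        opt.step()
        g = theta
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        mhat = m / (1 - b1**t)
        vhat = v / (1 - b2**t)
        theta = theta - lr * mhat / (math.sqrt(vhat) + eps)
        worst = max(worst, abs(float(layer.params["theta"][0]) - theta))
    return worst


def cross_entropy_error(seed: int = 0, batch: int = 16,
                        n_classes: int = 2) -> float:
    """|production loss - direct log-sum-exp evaluation| on random logits."""
    rng = np.random.default_rng(seed)
    logits = rng.normal(0, 2, (batch, n_classes))
    labels = rng.integers(0, n_classes, batch)
    loss, _ = softmax_cross_entropy(logits, labels)
    direct = 0.0
    for row, cls in zip(logits, labels):
        direct += -math.log(math.exp(row[cls]) / sum(math.exp(v) for v in row))
    return abs(loss - direct / batch)


def fixation_recovery_rate(
    n_seeds: int = 10,
    duration: float = 120.0,
    seed: int = 0,
    scan_params=None,
    episode_params=None,
) -> tuple[float, int]:
    """Fraction of windows whose detected fixation count is within +-1 of the
    simulator's planted count; returns (fraction, n_windows).

    The planted count per window is the number of *detectable* planned
    fixation fragments: each planned fixation span is intersected with the
    window and with the eyes-open samples (a blink interrupting a fixation
    splits it, exactly as the detector sees it), and fragments at least the
    minimum fixation duration long are counted.
    """
    from gazelapse import events as ev
    from gazelapse import io as gio
    from gazelapse import simulate as sim

    scan_params = scan_params or sim.ScanpathParams()
    episode_params = episode_params or sim.null_params()
    cfg = ev.EventDetectionConfig()
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    hits = total = 0
    for s in seeds:
        rec = sim.simulate_recording(scan_params, episode_params, duration, int(s))
        g = gio.preprocess(rec.to_recording())
        fs = g.sample_rate
        # per-sample planned fixation id (-1 during saccades)
        fix_id = np.full(len(g), -1, dtype=int)
        for k, f in enumerate(rec.planned_fixations):
            i0 = max(int(np.ceil(f.onset * fs - 1e-9)), 0)
            i1 = min(int(np.ceil(f.offset * fs - 1e-9)), len(g))
            fix_id[i0:i1] = k
        min_samples = max(2, int(np.ceil(cfg.min_fixation_duration * fs)))
        for w in gio.slide_windows(g):
            ids = fix_id[w.start_index:w.start_index + len(w)].copy()
            ids[w.blink_mask] = -1
            planted = _count_runs(ids, min_samples)
            detected = len(ev.detect_fixations(w, cfg))
            hits += abs(detected - planted) <= 1
            total += 1
    return hits / total, total


def _count_runs(ids: np.ndarray, min_len: int) -> int:
    """Number of maximal constant runs of non-negative ids of length >= min_len."""
    count = 0
    run_val, run_len = -1, 0
    for v in ids:
        if v == run_val:
            run_len += 1
        else:
            if run_val >= 0 and run_len >= min_len:
                count += 1
            run_val, run_len = v, 1
    if run_val >= 0 and run_len >= min_len:
        count += 1
    return count
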