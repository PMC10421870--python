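"""Minimal NumPy layers with hand-written forward/backward passes.

The classifier is small and fixed (temporal convolutions over length-6 event
sequences, batch normalization, a 3-layer LSTM, dense heads), so the layers
here implement exactly what it needs: each layer caches its forward
activations and produces analytic input/parameter gradients on ``backward``.
Gradient correctness is validated against central finite differences in the
test suite.

Weight initialization is He/Kaiming (normal with variance 2/fan_in) for every
weight matrix; biases and batch-norm shifts start at zero, batch-norm scales
at one.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "TemporalConv",
    "BatchNorm",
    "ReLU",
    "LSTM",
    "LastStep",
    "Flatten",
    "Sequential",
    "Adam",
    "kaiming_normal",
]


def kaiming_normal(rng: np.random.Generator, shape, fan_in: int, dtype):
    """He-initialized weights: Normal(0, sqrt(2 / fan_in))."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


class Layer:
    """Base class: parameters and their gradients live in parallel dicts."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def _register(self, name: str, value: np.ndarray) -> None:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)

    def zero_grads(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine map on the last axis: y = x W + b."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self._register("W", kaiming_normal(rng, (in_dim, out_dim), in_dim, dtype))
        self._register("b", np.zeros(out_dim, dtype=dtype))

    def forward(self, x, training=False):
        if x.shape[-1] != self.in_dim:
            raise ValueError(f"Dense expected width {self.in_dim}, got {x.shape[-1]}")
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        x = self._x
        x2 = x.reshape(-1, self.in_dim)
        d2 = dout.reshape(-1, self.out_dim)
        self.grads["W"] += x2.T @ d2
        self.grads["b"] += d2.sum(axis=0)
        return dout @ self.params["W"].T


class TemporalConv(Layer):
    """1-D convolution along the sequence axis with causal same-padding.

    Input (B, T, C_in) -> output (B, T, C_out). The kernel spans ``kernel``
    consecutive events and the full feature width; K-1 zero steps are padded
    at the sequence start so event t never sees t+1 and T is preserved.
    No bias: every convolution here is immediately batch-normalized.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 kernel: int = 2, dtype=np.float32):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self._register(
            "W", kaiming_normal(rng, (kernel, in_ch, out_ch), kernel * in_ch, dtype)
        )

    def forward(self, x, training=False):
        if x.shape[-1] != self.in_ch:
            raise ValueError(
                f"TemporalConv expected {self.in_ch} channels, got {x.shape[-1]}"
            )
        B, T, _ = x.shape
        K = self.kernel
        xpad = np.zeros((B, T + K - 1, self.in_ch), dtype=x.dtype)
        xpad[:, K - 1:, :] = x
        self._xpad, self._T = xpad, T
        W = self.params["W"]
        out = xpad[:, 0:T, :] @ W[0]
        for k in range(1, K):
            out += xpad[:, k:k + T, :] @ W[k]
        return out

    def backward(self, dout):
        xpad, T, K = self._xpad, self._T, self.kernel
        W = self.params["W"]
        dxpad = np.zeros_like(xpad)
        d2 = dout.reshape(-1, self.out_ch)
        for k in range(K):
            xk = xpad[:, k:k + T, :].reshape(-1, self.in_ch)
            self.grads["W"][k] += xk.T @ d2
            dxpad[:, k:k + T, :] += dout @ W[k].T
        return dxpad[:, K - 1:, :]


class BatchNorm(Layer):
    """Per-feature batch normalization: z = gamma (x - mu)/sqrt(var + eps) + beta.

    Statistics are computed over every axis except the last (batch x sequence
    positions for 3-D input); running estimates are kept for inference mode.
    Training mode requires at least two rows.
    """

    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1, dtype=np.float32):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self._register("gamma", np.ones(num_features, dtype=dtype))
        self._register("beta", np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)

    def forward(self, x, training=False):
        if x.shape[-1] != self.num_features:
            raise ValueError(
                f"BatchNorm expected {self.num_features} features, got {x.shape[-1]}"
            )
        axes = tuple(range(x.ndim - 1))
        if training:
            if x.shape[0] < 2:
                raise ValueError("training-mode batch norm needs batch size >= 2")
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(
                self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._xhat, self._inv_std, self._training = xhat, inv_std, training
        self._N = int(np.prod(x.shape[:-1]))
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        axes = tuple(range(dout.ndim - 1))
        xhat, inv_std = self._xhat, self._inv_std
        self.grads["beta"] += dout.sum(axis=axes)
        self.grads["gamma"] += (dout * xhat).sum(axis=axes)
        dxhat = dout * self.params["gamma"]
        if not self._training:
            return dxhat * inv_std
        N = self._N
        return (inv_std / N) * (
            N * dxhat
            - dxhat.sum(axis=axes)
            - xhat * (dxhat * xhat).sum(axis=axes)
        )


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LastStep(Layer):
    """Select the final event's representation: (B, T, H) -> (B, H)."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x[:, -1, :]

    def backward(self, dout):
        dx = np.zeros(self._shape, dtype=dout.dtype)
        dx[:, -1, :] = dout
        return dx


class Flatten(Layer):
    """(B, T, C) -> (B, T*C)."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


def _sigmoid(a):
    from scipy.special import expit

    return expit(a)


class LSTM(Layer):
    """Stacked LSTM returning the top layer's hidden state at every step.

    Gate equations per step (gate order i, f, o, g in the packed matrices):

        i_t = sigmoid(x_t Wi + h_{t-1} Ui + bi)
        f_t = sigmoid(x_t Wf + h_{t-1} Uf + bf)
        o_t = sigmoid(x_t Wo + h_{t-1} Uo + bo)
        g_t = tanh  (x_t Wc + h_{t-1} Uc + bc)     (candidate / instant state)
        c_t = f_t * c_{t-1} + i_t * g_t
        h_t = o_t * tanh(c_t)

    States start at zero. Input (B, T, D) -> output (B, T, H).
    """

    def __init__(self, input_size: int, hidden_size: int, num_layers: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.input_size, self.hidden_size = input_size, hidden_size
        self.num_layers = num_layers
        H = hidden_size
        for layer in range(num_layers):
            D = input_size if layer == 0 else H
            self._register(f"W{layer}", kaiming_normal(rng, (D, 4 * H), D, dtype))
            self._register(f"U{layer}", kaiming_normal(rng, (H, 4 * H), H, dtype))
            self._register(f"b{layer}", np.zeros(4 * H, dtype=dtype))

    def forward(self, x, training=False):
        if x.shape[-1] != self.input_size:
            raise ValueError(
                f"LSTM expected input width {self.input_size}, got {x.shape[-1]}"
            )
        B, T, _ = x.shape
        H = self.hidden_size
        self._cache = []
        inp = x
        for layer in range(self.num_layers):
            W = self.params[f"W{layer}"]
            U = self.params[f"U{layer}"]
            b = self.params[f"b{layer}"]
            ax = inp.reshape(B * T, -1) @ W  # input contribution, all steps
            ax = ax.reshape(B, T, 4 * H) + b
            h = np.zeros((B, H), dtype=ax.dtype)
            c = np.zeros((B, H), dtype=ax.dtype)
            steps = []
            hs = np.empty((B, T, H), dtype=ax.dtype)
            for t in range(T):
                a = ax[:, t, :] + h @ U
                i = _sigmoid(a[:, 0 * H:1 * H])
                f = _sigmoid(a[:, 1 * H:2 * H])
                o = _sigmoid(a[:, 2 * H:3 * H])
                g = np.tanh(a[:, 3 * H:4 * H])
                c_prev, h_prev = c, h
                c = f * c_prev + i * g
                tc = np.tanh(c)
                h = o * tc
                hs[:, t, :] = h
                steps.append((i, f, o, g, c_prev, h_prev, tc))
            self._cache.append((inp, steps))
            inp = hs
        return inp

    def backward(self, dout):
        H = self.hidden_size
        dtop = dout
        for layer in range(self.num_layers - 1, -1, -1):
            inp, steps = self._cache[layer]
            B, T, D = inp.shape
            W = self.params[f"W{layer}"]
            U = self.params[f"U{layer}"]
            dW = self.grads[f"W{layer}"]
            dU = self.grads[f"U{layer}"]
            db = self.grads[f"b{layer}"]
            dx = np.empty_like(inp)
            dh_next = np.zeros((B, H), dtype=dout.dtype)
            dc_next = np.zeros((B, H), dtype=dout.dtype)
            for t in range(T - 1, -1, -1):
                i, f, o, g, c_prev, h_prev, tc = steps[t]
                dh = dtop[:, t, :] + dh_next
                do = dh * tc
                dc = dh * o * (1.0 - tc * tc) + dc_next
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dc_next = dc * f
                da = np.concatenate(
                    [
                        di * i * (1.0 - i),
                        df * f * (1.0 - f),
                        do * o * (1.0 - o),
                        dg * (1.0 - g * g),
                    ],
                    axis=1,
                )
                dW += inp[:, t, :].T @ da
                dU += h_prev.T @ da
                db += da.sum(axis=0)
                dx[:, t, :] = da @ W.T
                dh_next = da @ U.T
            dtop = dx
        return dtop


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grads(self):
        for layer in self.layers:
            layer.zero_grads()

    def all_layers(self):
        out = []
        for layer in self.layers:
            out.extend(layer.all_layers() if isinstance(layer, Sequential)
                       else [layer])
        return out


class Adam(object):
    """Adam with bias correction.

    Keeps exponential moving averages of gradients (m) and squared gradients
    (v) per parameter and scales the step by the bias-corrected ratio.
    """

    def __init__(self, layers: list[Layer], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in layer.params.items()}
            for layer in layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in layer.params.items()}
            for layer in layers
        ]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * (g * g)
                mhat = m[k] / bc1
                vhat = v[k] / bc2
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()
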