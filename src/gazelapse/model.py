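"""The dual-branch convolutional + recurrent lapse classifier.

Time-related branch: three temporal convolutions (kernel length 2 over the
event axis, 64 channels, each Conv -> BatchNorm -> ReLU) extract deep
features from the (6, 23) event sequence; the deep features are spliced with
the raw features to width 87, batch-normalized, passed through a 3-layer
LSTM with hidden width 128, and the final step's hidden state is mapped to a
length-2 vector. Time-independent branch: the same convolution stack on the
(6, 21) matrix, flattened and mapped to a length-2 vector. The two length-2
outputs are concatenated (width 4), passed through a final dense layer and a
softmax, giving the probability pair (normal, forgetting).

Ablations keep everything identical except the removed stage: ``ConvOnly``
drops the recurrent encoder (splice -> flatten -> head), ``RecurrentOnly``
feeds the 23 raw features straight into the LSTM.

Dimension ladder of the full model for a batch B:
(B,6,23) -> conv (B,6,64) -> splice (B,6,87) -> LSTM (B,6,128) -> head (B,2);
(B,6,21) -> conv (B,6,64) -> flatten (B,384) -> head (B,2); fused (B,4) -> (B,2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gazelapse import nn

__all__ = [
    "HybridConfig",
    "DualBranchModel",
    "HybridModel",
    "ConvOnlyModel",
    "RecurrentOnlyModel",
    "splice_features",
    "softmax",
    "softmax_cross_entropy",
    "build_model",
]


@dataclass(frozen=True)
class HybridConfig:
    tc_features: int = 23
    tic_features: int = 21
    sequence_length: int = 6
    conv_channels: int = 64
    conv_layers: int = 3
    kernel: int = 2
    lstm_hidden: int = 128
    lstm_layers: int = 3
    head_width: int = 2
    n_classes: int = 2
    bn_eps: float = 1e-5
    dtype: type = np.float32

    @property
    def spliced_width(self) -> int:
        return self.conv_channels + self.tc_features


def splice_features(deep: np.ndarray, original: np.ndarray) -> np.ndarray:
    """Per-event concatenation [deep, original] along the feature axis.

    The original features pass through unchanged, so slicing the last block
    of the result recovers them exactly.
    """
    if deep.shape[:-1] != original.shape[:-1]:
        raise ValueError(
            f"batch/sequence dims differ: {deep.shape[:-1]} vs {original.shape[:-1]}"
        )
    return np.concatenate([deep, original], axis=-1)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray,
    labels: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy -log softmax(y)[class] and its logit gradient.

    ``class_weights``, when given, reweight each sample's term by its class
    weight (weighted mean).
    """
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= logits.shape[-1]:
        raise ValueError("labels outside the valid class range")
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    logp = np.log(np.clip(p[np.arange(n), labels], 1e-300, None))
    if class_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(class_weights, dtype=float)[labels]
    wsum = w.sum()
    loss = float(-(w * logp).sum() / wsum)
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits.astype(logits.dtype)


def _conv_branch(in_features: int, cfg: HybridConfig,
                 rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    ch_in = in_features
    for _ in range(cfg.conv_layers):
        layers.append(nn.TemporalConv(ch_in, cfg.conv_channels, rng,
                                      kernel=cfg.kernel, dtype=cfg.dtype))
        layers.append(nn.BatchNorm(cfg.conv_channels, eps=cfg.bn_eps,
                                   dtype=cfg.dtype))
        layers.append(nn.ReLU())
        ch_in = cfg.conv_channels
    return nn.Sequential(layers)


class DualBranchModel:
    """Common skeleton: a tc branch, a tic branch and the fusion head."""

    name = "dual"

    def __init__(self, cfg: HybridConfig | None = None, seed: int = 0):
        self.cfg = cfg or HybridConfig()
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._build(self.cfg, rng)
        self.fuse = nn.Dense(2 * self.cfg.head_width, self.cfg.n_classes,
                             rng, dtype=self.cfg.dtype)

    # subclasses fill in the tc path
    def _build(self, cfg: HybridConfig, rng: np.random.Generator) -> None:
        raise NotImplementedError

    def _tc_forward(self, tc: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def _tc_backward(self, dout: np.ndarray) -> None:
        raise NotImplementedError

    def _build_tic(self, cfg: HybridConfig, rng: np.random.Generator) -> None:
        self.conv_tic = _conv_branch(cfg.tic_features, cfg, rng)
        self.flat_tic = nn.Flatten()
        self.tic_head = nn.Dense(cfg.sequence_length * cfg.conv_channels,
                                 cfg.head_width, rng, dtype=cfg.dtype)

    def tic_branch_forward(self, tic: np.ndarray, training: bool = False) -> np.ndarray:
        h = self.conv_tic.forward(tic, training=training)
        return self.tic_head.forward(self.flat_tic.forward(h))

    def _tic_backward(self, dout: np.ndarray) -> None:
        d = self.tic_head.backward(dout)
        self.conv_tic.backward(self.flat_tic.backward(d))

    def fuse_and_classify(self, tc_out: np.ndarray, tic_out: np.ndarray) -> np.ndarray:
        """Concatenate the two length-2 branch outputs, map to final logits."""
        fused = np.concatenate([tc_out, tic_out], axis=-1)
        return self.fuse.forward(fused)

    def forward(self, tc: np.ndarray, tic: np.ndarray,
                training: bool = False) -> np.ndarray:
        cfg = self.cfg
        if tc.shape[1:] != (cfg.sequence_length, cfg.tc_features):
            raise ValueError(
                f"tc batch must be (B, {cfg.sequence_length}, {cfg.tc_features}); "
                f"got {tc.shape}"
            )
        if tic.shape[1:] != (cfg.sequence_length, cfg.tic_features):
            raise ValueError(
                f"tic batch must be (B, {cfg.sequence_length}, {cfg.tic_features}); "
                f"got {tic.shape}"
            )
        tc = np.ascontiguousarray(tc, dtype=cfg.dtype)
        tic = np.ascontiguousarray(tic, dtype=cfg.dtype)
        tc_out = self._tc_forward(tc, training)
        tic_out = self.tic_branch_forward(tic, training)
        return self.fuse_and_classify(tc_out, tic_out)

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.fuse.backward(dlogits)
        hw = self.cfg.head_width
        self._tc_backward(dfused[:, :hw])
        self._tic_backward(dfused[:, hw:])

    def predict_proba(self, tc: np.ndarray, tic: np.ndarray) -> np.ndarray:
        """Probability pairs (rows sum to 1); inference mode."""
        return softmax(self.forward(tc, tic, training=False))

    def layers(self) -> list[nn.Layer]:
        out = self._tc_layers() + self.conv_tic.all_layers()
        out += [self.tic_head, self.fuse]
        return out

    def _tc_layers(self) -> list[nn.Layer]:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for layer in self.layers():
            layer.zero_grads()

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers() for p in layer.params.values())


class HybridModel(DualBranchModel):
    """Full model: conv extractor + splice + batch norm + LSTM on the tc side."""

    name = "hybrid"

    def _build(self, cfg, rng):
        self.conv_tc = _conv_branch(cfg.tc_features, cfg, rng)
        self.bn_splice = nn.BatchNorm(cfg.spliced_width, eps=cfg.bn_eps,
                                      dtype=cfg.dtype)
        self.lstm = nn.LSTM(cfg.spliced_width, cfg.lstm_hidden,
                            cfg.lstm_layers, rng, dtype=cfg.dtype)
        self.last = nn.LastStep()
        self.tc_head = nn.Dense(cfg.lstm_hidden, cfg.head_width, rng,
                                dtype=cfg.dtype)
        self._build_tic(cfg, rng)

    def conv_branch_forward(self, tc: np.ndarray, training: bool = False) -> np.ndarray:
        """Deep feature extractor: (B, 6, 23) -> (B, 6, 64)."""
        return self.conv_tc.forward(tc, training=training)

    def lstm_forward(self, spliced: np.ndarray, training: bool = False) -> np.ndarray:
        """(B, 6, 87) -> hidden states of the top layer, (B, 6, 128)."""
        return self.lstm.forward(spliced, training=training)

    def _tc_forward(self, tc, training):
        deep = self.conv_branch_forward(tc, training)
        spliced = splice_features(deep, tc)
        z = self.bn_splice.forward(spliced, training=training)
        hs = self.lstm_forward(z, training)
        return self.tc_head.forward(self.last.forward(hs))

    def _tc_backward(self, dout):
        dhs = self.last.backward(self.tc_head.backward(dout))
        dz = self.lstm.backward(dhs)
        dspliced = self.bn_splice.backward(dz)
        ddeep = dspliced[..., : self.cfg.conv_channels]
        self.conv_tc.backward(np.ascontiguousarray(ddeep))

    def _tc_layers(self):
        return self.conv_tc.all_layers() + [self.bn_splice, self.lstm,
                                            self.last, self.tc_head]


class ConvOnlyModel(DualBranchModel):
    """Hybrid with the recurrent encoder removed: conv -> splice -> flatten."""

    name = "conv_only"

    def _build(self, cfg, rng):
        self.conv_tc = _conv_branch(cfg.tc_features, cfg, rng)
        self.bn_splice = nn.BatchNorm(cfg.spliced_width, eps=cfg.bn_eps,
                                      dtype=cfg.dtype)
        self.flat_tc = nn.Flatten()
        self.tc_head = nn.Dense(cfg.sequence_length * cfg.spliced_width,
                                cfg.head_width, rng, dtype=cfg.dtype)
        self._build_tic(cfg, rng)

    def _tc_forward(self, tc, training):
        deep = self.conv_tc.forward(tc, training=training)
        z = self.bn_splice.forward(splice_features(deep, tc), training=training)
        return self.tc_head.forward(self.flat_tc.forward(z))

    def _tc_backward(self, dout):
        dz = self.flat_tc.backward(self.tc_head.backward(dout))
        dspliced = self.bn_splice.backward(dz)
        self.conv_tc.backward(
            np.ascontiguousarray(dspliced[..., : self.cfg.conv_channels]))

    def _tc_layers(self):
        return self.conv_tc.all_layers() + [self.bn_splice, self.flat_tc,
                                            self.tc_head]


class RecurrentOnlyModel(DualBranchModel):
    """Hybrid with the conv extractor removed: LSTM on the 23 raw features."""

    name = "recurrent_only"

    def _build(self, cfg, rng):
        self.lstm = nn.LSTM(cfg.tc_features, cfg.lstm_hidden,
                            cfg.lstm_layers, rng, dtype=cfg.dtype)
        self.last = nn.LastStep()
        self.tc_head = nn.Dense(cfg.lstm_hidden, cfg.head_width, rng,
                                dtype=cfg.dtype)
        self._build_tic(cfg, rng)

    def _tc_forward(self, tc, training):
        hs = self.lstm.forward(tc, training=training)
        return self.tc_head.forward(self.last.forward(hs))

    def _tc_backward(self, dout):
        dhs = self.last.backward(self.tc_head.backward(dout))
        self.lstm.backward(dhs)

    def _tc_layers(self):
        return [self.lstm, self.last, self.tc_head]


MODEL_CLASSES = {
    "hybrid": HybridModel,
    "conv_only": ConvOnlyModel,
    "recurrent_only": RecurrentOnlyModel,
}


def build_model(name: str, cfg: HybridConfig | None = None,
                seed: int = 0) -> DualBranchModel:
    try:
        cls = MODEL_CLASSES[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; expected one of {sorted(MODEL_CLASSES)}"
        ) from None
    return cls(cfg, seed=seed)
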