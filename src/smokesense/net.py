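"""The CNN-LSTM smoking classifier.

Architecture: three convolution blocks (conv -> batch-norm -> ReLU -> 2x2
max-pool), each conv's filter spanning half of its own input's spatial
dimensions, with feature-map depths 128/64/32; a fully connected layer
reducing to 32 features per window; 0.5 dropout; two LSTM layers of cell size
64 consuming sequences of consecutive-window features (default 6 windows,
about 35 s of context); and a single sigmoid output unit giving the smoking
probability of the sequence's final window.  Trained with Adam (learning rate
1e-2, mini-batch 64, 5 epochs) on binary cross-entropy.

The LSTM consumes per-window FC features rather than intra-window time bins:
the convolutional stack summarizes each window, the recurrence models the
dynamics across neighboring windows.  Mini-batches are contiguous blocks of
sequences (block order shuffled each epoch) so the CNN pass of a window shared
by several overlapping sequences in a batch is computed once and its feature
gradient accumulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._layers import (
    LSTM,
    Adam,
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    MaxPool2D,
    ReLU,
    bce_with_logits,
    sigmoid,
)

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "ConfigurationError",
    "build_model",
    "SequenceSet",
    "make_sequences",
    "CnnLstm",
]


class ConfigurationError(ValueError):
    """An architecture that cannot be realized for the given input shape."""


@dataclass(frozen=True)
class ModelConfig:
    conv_feature_maps: tuple[int, int, int] = (128, 64, 32)
    filter_fraction: float = 0.5
    pool_size: int = 2
    fc_units: int = 32
    dropout_rate: float = 0.5
    lstm_cell_size: int = 64
    n_lstm_layers: int = 2
    sequence_length: int = 6

    def __post_init__(self) -> None:
        if any(m < 1 for m in self.conv_feature_maps):
            raise ValueError("conv_feature_maps must be positive")
        if not (0 < self.filter_fraction <= 1):
            raise ValueError("filter_fraction must be in (0, 1]")
        for name in ("pool_size", "fc_units", "lstm_cell_size", "n_lstm_layers",
                     "sequence_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-2
    batch_size: int = 64
    n_epochs: int = 5
    seed: int = 0
    loss: str = "bce"

    def __post_init__(self) -> None:
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if self.loss.lower() != "bce":
            raise ValueError("only binary cross-entropy is supported")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.n_epochs < 1:
            raise ValueError("batch_size and n_epochs must be >= 1")


def build_model(
    input_shape: tuple[int, int, int], cfg: ModelConfig | None = None
) -> list[dict]:
    """Enumerate the layer stack for a given (freq, time, channels) input.

    Pure shape arithmetic: no parameters are allocated.  Each conv filter's
    spatial dims are ``max(1, floor(filter_fraction * input_dim))``; pooling
    is non-overlapping with trailing partial windows kept.  Raises
    :class:`ConfigurationError`, naming the offending layer, if a spatial
    dimension would collapse below 1.
    """
    cfg = cfg or ModelConfig()
    F, T, C = input_shape
    if F < 2 or T < 2:
        raise ConfigurationError("input spatial dims must each be >= 2")
    if C < 1:
        raise ConfigurationError("input needs at least one channel")
    layers: list[dict] = []
    h, w, cin = F, T, C
    p = cfg.pool_size
    for bi, fmaps in enumerate(cfg.conv_feature_maps, start=1):
        fh = max(1, math.floor(cfg.filter_fraction * h))
        fw = max(1, math.floor(cfg.filter_fraction * w))
        oh, ow = h - fh + 1, w - fw + 1
        if oh < 1 or ow < 1:
            raise ConfigurationError(
                f"conv{bi}: filter ({fh}, {fw}) exceeds its input ({h}, {w})"
            )
        layers.append(
            {"layer": "conv", "name": f"conv{bi}", "feature_maps": fmaps,
             "filter": (fh, fw), "input": (h, w, cin), "output": (oh, ow, fmaps)}
        )
        layers.append({"layer": "batch_norm", "name": f"bn{bi}", "features": fmaps})
        layers.append({"layer": "relu", "name": f"relu{bi}"})
        ph, pw = MaxPool2D.out_dim(oh, p), MaxPool2D.out_dim(ow, p)
        if ph < 1 or pw < 1:
            raise ConfigurationError(f"pool{bi}: output collapses below 1")
        layers.append(
            {"layer": "max_pool", "name": f"pool{bi}", "size": p,
             "output": (ph, pw, fmaps)}
        )
        h, w, cin = ph, pw, fmaps
    flat = h * w * cin
    layers.append({"layer": "dense", "name": "fc", "units": cfg.fc_units, "input": flat})
    layers.append({"layer": "dropout", "name": "dropout", "rate": cfg.dropout_rate})
    for li in range(1, cfg.n_lstm_layers + 1):
        layers.append(
            {"layer": "lstm", "name": f"lstm{li}", "cells": cfg.lstm_cell_size,
             "input": cfg.fc_units if li == 1 else cfg.lstm_cell_size}
        )
    layers.append(
        {"layer": "dense", "name": "output", "units": 1, "activation": "sigmoid",
         "input": cfg.lstm_cell_size}
    )
    return layers


@dataclass
class SequenceSet:
    """Overlapping runs of consecutive windows feeding the LSTM.

    One sequence ends at every window, so each window receives exactly one
    prediction; sequences never mix recordings.  Prefix sequences at a
    recording start are padded by repeating the first window and flagged.
    ``indices`` indexes into the global window/tensor array; ``final_index``
    maps each sequence to the window it predicts.
    """

    indices: np.ndarray  # (n_seq, L) int
    labels: np.ndarray  # (n_seq,)
    padded: np.ndarray  # (n_seq,) bool
    final_index: np.ndarray  # (n_seq,) int

    def __len__(self) -> int:
        return len(self.labels)


def make_sequences(
    subject_ids: np.ndarray | list[str],
    labels: np.ndarray,
    sequence_length: int = 6,
) -> SequenceSet:
    """Build LSTM input sequences from windows ordered by start within subject.

    ``subject_ids`` marks recording membership per window (windows of one
    recording must be contiguous and time-ordered).  The sequence label is the
    label of its final window.
    """
    subject_ids = np.asarray(subject_ids)
    labels = np.asarray(labels)
    n = len(labels)
    if n == 0:
        return SequenceSet(
            indices=np.empty((0, sequence_length), dtype=np.int64),
            labels=np.empty(0, dtype=labels.dtype),
            padded=np.empty(0, dtype=bool),
            final_index=np.empty(0, dtype=np.int64),
        )
    if len(subject_ids) != n:
        raise ValueError("subject_ids and labels must align")
    L = sequence_length
    idx = np.empty((n, L), dtype=np.int64)
    padded = np.zeros(n, dtype=bool)
    boundaries = np.flatnonzero(np.r_[True, subject_ids[1:] != subject_ids[:-1], True])
    for g0, g1 in zip(boundaries[:-1], boundaries[1:]):
        for i in range(g0, g1):
            first = max(g0, i - L + 1)
            run = np.arange(first, i + 1)
            if len(run) < L:
                run = np.r_[np.full(L - len(run), g0), run]
                padded[i] = True
            idx[i] = run
    return SequenceSet(
        indices=idx, labels=labels.copy(), padded=padded,
        final_index=np.arange(n, dtype=np.int64),
    )


class CnnLstm:
    """The CNN-LSTM classifier, parameterized and trainable.

    ``fit`` consumes a standardized window-tensor stack plus a
    :class:`SequenceSet`; ``predict`` returns one smoking probability (and a
    0.5-thresholded label) per sequence, i.e. per final window.  Given a fixed
    seed, training is deterministic within one environment.
    """

    def __init__(
        self,
        input_shape: tuple[int, int, int],
        cfg: ModelConfig | None = None,
        seed: int = 0,
    ):
        self.cfg = cfg or ModelConfig()
        self.input_shape = tuple(input_shape)
        self.seed = seed
        self.description = build_model(self.input_shape, self.cfg)
        rng = np.random.default_rng(seed)
        self.conv_blocks: list[tuple[Conv2D, BatchNorm, ReLU, MaxPool2D]] = []
        for spec in self.description:
            if spec["layer"] == "conv":
                fh, fw = spec["filter"]
                _, _, cin = spec["input"]
                conv = Conv2D(fh, fw, cin, spec["feature_maps"], rng)
                self.conv_blocks.append(
                    (conv, BatchNorm(spec["feature_maps"]), ReLU(), MaxPool2D(self.cfg.pool_size))
                )
        fc_spec = next(s for s in self.description if s.get("name") == "fc")
        self.fc = Dense(fc_spec["input"], self.cfg.fc_units, rng)
        self.dropout = Dropout(self.cfg.dropout_rate)
        self.lstms = [
            LSTM(self.cfg.fc_units if i == 0 else self.cfg.lstm_cell_size,
                 self.cfg.lstm_cell_size, rng)
            for i in range(self.cfg.n_lstm_layers)
        ]
        self.head = Dense(self.cfg.lstm_cell_size, 1, rng)
        self.train_config: TrainConfig | None = None
        self.loss_history: list[float] = []
        self.fold_id: str | None = None

    # ---- parameter plumbing -------------------------------------------
    def _layers_with_params(self):
        for conv, bn, _, _ in self.conv_blocks:
            yield conv
            yield bn
        yield self.fc
        yield from self.lstms
        yield self.head

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._layers_with_params() for p in layer.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self._layers_with_params() for g in layer.grads()]

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All learnable parameters plus batch-norm running statistics."""
        out: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            out[f"param_{i:03d}"] = p
        for j, (_, bn, _, _) in enumerate(self.conv_blocks):
            out[f"bn_{j}_running_mean"] = bn.running_mean
            out[f"bn_{j}_running_var"] = bn.running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p[...] = state[f"param_{i:03d}"]
        for j, (_, bn, _, _) in enumerate(self.conv_blocks):
            bn.running_mean[...] = state[f"bn_{j}_running_mean"]
            bn.running_var[...] = state[f"bn_{j}_running_var"]

    # ---- forward / backward -------------------------------------------
    def _cnn_forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = x
        for conv, bn, relu, pool in self.conv_blocks:
            h = pool.forward(relu.forward(bn.forward(conv.forward(h, train), train)))
        self._flat_shape = h.shape
        return self.fc.forward(h.reshape(h.shape[0], -1), train)

    def _cnn_backward(self, dfeats: np.ndarray) -> None:
        dh = self.fc.backward(dfeats).reshape(self._flat_shape)
        for conv, bn, relu, pool in reversed(self.conv_blocks):
            dh = conv.backward(bn.backward(relu.backward(pool.backward(dh))))

    def _sequence_forward(
        self, X: np.ndarray, seq_idx: np.ndarray, train: bool,
        rng: np.random.Generator | None,
    ) -> tuple[np.ndarray, tuple]:
        B, L = seq_idx.shape
        uniq, inv = np.unique(seq_idx.ravel(), return_inverse=True)
        feats = self._cnn_forward(X[uniq], train)
        feats = self.dropout.forward(feats, train, rng)
        seq = feats[inv].reshape(B, L, -1)
        h = seq
        for lstm in self.lstms:
            h = lstm.forward(h, train)
        logits = self.head.forward(h[:, -1, :], train)[:, 0]
        cache = (uniq, inv, (B, L), feats.shape, h.shape)
        return logits, cache

    def _sequence_backward(self, dlogits: np.ndarray, cache: tuple) -> None:
        uniq, inv, (B, L), feat_shape, h_shape = cache
        dh_last = self.head.backward(dlogits[:, None])
        dhs = np.zeros(h_shape)
        dhs[:, -1, :] = dh_last
        for lstm in reversed(self.lstms):
            dhs = lstm.backward(dhs)
        dfeats = np.zeros(feat_shape)
        np.add.at(dfeats, inv, dhs.reshape(B * L, -1))
        dfeats = self.dropout.backward(dfeats)
        self._cnn_backward(dfeats)

    # ---- public API ----------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        sequences: SequenceSet,
        train_cfg: TrainConfig | None = None,
        fold_id: str | None = None,
    ) -> "CnnLstm":
        """Train on a (n_windows, F, T, C) stack with its sequence set.

        Raises ``ValueError`` for a single-class training set.
        """
        cfg = train_cfg or TrainConfig()
        y = np.asarray(sequences.labels, dtype=np.float64)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        rng = np.random.default_rng(cfg.seed)
        opt = Adam(self.parameters(), lr=cfg.learning_rate)
        n_seq = len(sequences)
        starts = np.arange(0, n_seq, cfg.batch_size)
        self.loss_history = []
        for _epoch in range(cfg.n_epochs):
            order = rng.permutation(len(starts))
            epoch_losses = []
            for bi in order:
                s = starts[bi]
                e = min(s + cfg.batch_size, n_seq)
                logits, cache = self._sequence_forward(
                    X, sequences.indices[s:e], train=True, rng=rng
                )
                loss, dlogits = bce_with_logits(logits, y[s:e])
                self._sequence_backward(dlogits, cache)
                opt.step(self.gradients())
                epoch_losses.append(loss)
            self.loss_history.append(float(np.mean(epoch_losses)))
        self.train_config = cfg
        self.fold_id = fold_id
        return self

    def evaluate_loss(self, X: np.ndarray, sequences: SequenceSet) -> float:
        """Mean BCE over the set with the current parameters (no training)."""
        probs = self.predict_proba(X, sequences)
        y = np.asarray(sequences.labels, dtype=np.float64)
        eps = 1e-12
        return float(-np.mean(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)))

    def predict_proba(
        self, X: np.ndarray, sequences: SequenceSet, chunk: int = 512
    ) -> np.ndarray:
        """One probability per sequence (hence per final window), in order."""
        if X.shape[1:] != tuple(self.input_shape):
            raise ValueError(
                f"window tensors of shape {X.shape[1:]} do not match the model "
                f"input {self.input_shape}"
            )
        out = np.empty(len(sequences))
        for s in range(0, len(sequences), chunk):
            e = min(s + chunk, len(sequences))
            logits, _ = self._sequence_forward(
                X, sequences.indices[s:e], train=False, rng=None
            )
            out[s:e] = sigmoid(logits)
        return out

    def predict(
        self, X: np.ndarray, sequences: SequenceSet, threshold: float = 0.5
    ) -> tuple[np.ndarray, np.ndarray]:
        """(probabilities, binary labels at the 0.5 operating point)."""
        probs = self.predict_proba(X, sequences)
        return probs, (probs >= threshold).astype(np.int8)
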