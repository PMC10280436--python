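"""The five TSS sequence-classifier architectures.

All take a one-hot window (length x 4) and end in a single sigmoid unit:

cnn        3 x [conv1d(32 filters, width 5, stride 1, ReLU) -> maxpool(4)]
           -> flatten -> dense(1024) -> dropout 0.2 -> dense(512)
           -> dropout 0.2 -> dense(128) -> dropout 0.2 -> dense(1, sigmoid)
lstm       LSTM(128) -> dense(64) -> dropout 0.5 -> dense(1, sigmoid)
blstm      BLSTM(128 per direction) -> dense(64) -> dropout 0.5 -> dense(1, sigmoid)
cnn_lstm   conv1d(64 filters, width 3, ReLU) -> maxpool(3) -> dropout 0.25
           -> LSTM(64) -> dropout 0.8 -> dense(1, sigmoid)
cnn_blstm  same with BLSTM(64 per direction)

Convolutions use valid padding; pooling stride equals pool size; recurrent
layers return only their final state; hidden activations are ReLU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError
from .core import (
    Bidirectional,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    LSTM,
    MaxPool1D,
    Network,
)

ARCHITECTURE_NAMES = ("cnn", "lstm", "blstm", "cnn_lstm", "cnn_blstm")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Structural description of an architecture (layer-by-layer)."""

    name: str
    input_length: int
    layers: tuple  # tuple of dicts: kind plus its hyperparameters


def _spec_layers(name: str) -> list[dict]:
    if name == "cnn":
        layers: list[dict] = []
        for _ in range(3):
            layers.append({"kind": "conv1d", "filters": 32, "width": 5, "stride": 1, "activation": "relu"})
            layers.append({"kind": "maxpool", "size": 4})
        layers.append({"kind": "flatten"})
        for units in (1024, 512, 128):
            layers.append({"kind": "dense", "units": units, "activation": "relu"})
            layers.append({"kind": "dropout", "rate": 0.2})
        layers.append({"kind": "dense", "units": 1, "activation": "sigmoid"})
        return layers
    if name in ("lstm", "blstm"):
        recurrent = {"kind": "lstm" if name == "lstm" else "blstm", "units": 128}
        return [
            recurrent,
            {"kind": "dense", "units": 64, "activation": "relu"},
            {"kind": "dropout", "rate": 0.5},
            {"kind": "dense", "units": 1, "activation": "sigmoid"},
        ]
    if name in ("cnn_lstm", "cnn_blstm"):
        recurrent = {"kind": "lstm" if name == "cnn_lstm" else "blstm", "units": 64}
        return [
            {"kind": "conv1d", "filters": 64, "width": 3, "stride": 1, "activation": "relu"},
            {"kind": "maxpool", "size": 3},
            {"kind": "dropout", "rate": 0.25},
            recurrent,
            {"kind": "dropout", "rate": 0.8},
            {"kind": "dense", "units": 1, "activation": "sigmoid"},
        ]
    raise ConfigurationError(
        f"unknown architecture {name!r}; expected one of {ARCHITECTURE_NAMES}"
    )


def build_architecture(
    name: str, input_length: int = 1003, seed: int = 0
) -> tuple[ArchitectureSpec, Network]:
    """Instantiate an architecture for a given window length.

    Returns the structural spec and a trainable :class:`Network`. Raises a
    configuration error for unknown names or inputs too short for the stack.
    """
    spec_layers = _spec_layers(name)
    spec = ArchitectureSpec(name=name, input_length=input_length, layers=tuple(spec_layers))
    rng = np.random.default_rng(seed)

    layers = []
    length, channels = input_length, 4
    features = None  # set once the stack goes 1-D
    for entry in spec_layers:
        kind = entry["kind"]
        if kind == "conv1d":
            layers.append(Conv1D(channels, entry["filters"], entry["width"], rng, entry["activation"]))
            length = length - entry["width"] + 1
            channels = entry["filters"]
            if length < 1:
                raise ConfigurationError(
                    f"input_length {input_length} too short for architecture {name!r}"
                )
        elif kind == "maxpool":
            length = length // entry["size"]
            if length < 1:
                raise ConfigurationError(
                    f"input_length {input_length} too short for architecture {name!r}"
                )
            layers.append(MaxPool1D(entry["size"]))
        elif kind == "flatten":
            layers.append(Flatten())
            features = length * channels
        elif kind == "lstm":
            layers.append(LSTM(channels, entry["units"], rng))
            features = entry["units"]
        elif kind == "blstm":
            layers.append(Bidirectional(channels, entry["units"], rng))
            features = 2 * entry["units"]
        elif kind == "dropout":
            layers.append(Dropout(entry["rate"], rng))
        elif kind == "dense":
            if features is None:
                raise ConfigurationError("dense layer before any flattening stage")
            activation = "relu" if entry["activation"] == "relu" else None
            layers.append(Dense(features, entry["units"], rng, activation))
            features = entry["units"]
        else:  # pragma: no cover - exhaustive by construction
            raise ConfigurationError(f"unknown layer kind {kind!r}")
    return spec, Network(layers)
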