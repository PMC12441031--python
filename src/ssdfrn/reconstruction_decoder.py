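"""Splice-and-decode head for disturbing-feature reconstruction.

The encoder's projected representation (length L−W, a "residual skeleton":
its first P entries stand for the features before the disturbed window, the
rest for the features after it) is spliced with the auxiliary data at the
disturbance position, giving a length-L decoder input.  A small cascade of
valid 1-D convolution + pooling blocks, a flatten and a linear output layer
map it back to a full-length reconstructed feature vector.  The output layer
is linear because targets are standardized features of either sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Conv1d, Linear, Param, Pool1d, ReLU, conv_output_length
from .mvcnn_encoder import ShapeConfigError


@dataclass(frozen=True)
class DecoderConfig:
    conv_blocks: tuple[tuple[int, int, int], ...] = ((16, 3, 1), (32, 3, 1))
    """(kernel count K, kernel size, stride) per block."""
    pool_window: int = 2
    pool_stride: int = 2
    pool_mode: str = "max"
    output_width: int = 22

    def __post_init__(self) -> None:
        if not self.conv_blocks:
            raise ValueError("decoder needs at least one conv block")


def decoder_stage_lengths(input_length: int, config: DecoderConfig) -> list[int]:
    """Length after each conv and each pool, in order; validates the config."""
    lengths = []
    n = input_length
    for i, (_, kernel, stride) in enumerate(config.conv_blocks):
        try:
            n = conv_output_length(n, kernel, stride)
            lengths.append(n)
            n = conv_output_length(n, config.pool_window, config.pool_stride)
            lengths.append(n)
        except ValueError as exc:
            raise ShapeConfigError(f"decoder stage {i} underflows: {exc}") from exc
    return lengths


def splice_decoder_input(
    hidden: np.ndarray, auxiliary: np.ndarray, position: int
) -> np.ndarray:
    """hidden[0:P] ++ auxiliary ++ hidden[P:], total length L.

    The disturbance position is honoured: the auxiliary data occupy exactly
    the slots of the original shuffle window.
    """
    if position < 0 or position > hidden.shape[0]:
        raise ValueError(f"position {position} out of range for hidden length {hidden.shape[0]}")
    return np.concatenate([hidden[:position], auxiliary, hidden[position:]])


def split_decoder_input(
    x_de: np.ndarray, position: int, window_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`splice_decoder_input`: recover (hidden, auxiliary)."""
    aux = x_de[position : position + window_length]
    hidden = np.concatenate([x_de[:position], x_de[position + window_length :]])
    return hidden, aux


class Decoder:
    """Cascaded conv+pool blocks, flatten, linear layer to ``output_width``."""

    def __init__(self, config: DecoderConfig, input_length: int, rng: np.random.Generator):
        self.config = config
        self.input_length = input_length
        final_len = decoder_stage_lengths(input_length, config)[-1]
        self.layers: list = []
        in_ch = 1
        for k, kernel, stride in config.conv_blocks:
            self.layers.append(Conv1d(in_ch, k, kernel, stride, rng))
            self.layers.append(ReLU())
            self.layers.append(Pool1d(config.pool_window, config.pool_stride, config.pool_mode))
            in_ch = k
        self.flatten_width = final_len * in_ch
        self.output = Linear(self.flatten_width, config.output_width, rng)
        self._map_shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, 1, input_length) → (N, output_width), linear output."""
        h = x
        for layer in self.layers:
            h = layer.forward(h)
        self._map_shape = h.shape
        return self.output.forward(h.reshape(h.shape[0], -1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.output.backward(dy).reshape(self._map_shape)
        for layer in reversed(self.layers):
            dh = layer.backward(dh)
        return dh

    def parameters(self) -> list[Param]:
        params: list[Param] = []
        for layer in self.layers:
            params.extend(layer.parameters())
        return params + self.output.parameters()


def reconstruction_loss(reconstructed: np.ndarray, target: np.ndarray) -> float:
    """Mean square over all M×L entries — disturbed and undisturbed positions alike."""
    reconstructed = np.asarray(reconstructed, dtype=float)
    target = np.asarray(target, dtype=float)
    if reconstructed.shape != target.shape:
        raise ValueError(f"shape mismatch: {reconstructed.shape} vs {target.shape}")
    return float(np.mean((reconstructed - target) ** 2))


def masked_reconstruction_loss(
    reconstructed: np.ndarray,
    target: np.ndarray,
    positions: np.ndarray,
    window_length: int,
) -> float:
    """Experimental variant: mean square over the disturbed window slots only."""
    if reconstructed.shape != target.shape:
        raise ValueError(f"shape mismatch: {reconstructed.shape} vs {target.shape}")
    total = 0.0
    for j, p in enumerate(positions):
        diff = reconstructed[j, p : p + window_length] - target[j, p : p + window_length]
        total += float(np.sum(diff**2))
    return total / (len(positions) * window_length)
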