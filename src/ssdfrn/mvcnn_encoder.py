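"""Multi-view cascaded convolution encoder (MVCNN).

The multi-view cascaded convolution module (MVCCM) runs three parallel branches
with sliding strides S1..S3.  Each branch applies a small-kernel convolution,
then a medium-kernel convolution on its output, concatenates the two feature
maps along the LENGTH axis, and passes the result through a large-kernel
convolution; the three branch outputs are again concatenated along the length
axis, so the channel count stays at K throughout.  The encoder alternates
MVCCMs with pooling layers, flattens the final map, and linearly projects it to
a fixed-width hidden representation (default L−W = 18).

All convolutions are valid (no padding): length-axis concatenation is only
well-defined when branch outputs may have different lengths, which rules out
same-padding with channel concatenation for strides 2 and 3.  ReLU follows
every convolution; the final projection is linear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._nn import Conv1d, Linear, Param, Pool1d, ReLU, conv_output_length


class ShapeConfigError(ValueError):
    """A convolution/pooling stage would collapse to zero length."""


@dataclass(frozen=True)
class MVCCMConfig:
    """One multi-view cascaded convolution module.

    ``kernel_sizes`` are the small/medium/large kernel widths, ``strides`` the
    three branch strides, ``kernels`` the number K of convolution kernels used
    by every convolution in the module.
    """

    kernel_sizes: tuple[int, int, int] = (2, 3, 4)
    strides: tuple[int, int, int] = (1, 2, 3)
    kernels: int = 16

    def __post_init__(self) -> None:
        v1, v2, v3 = self.kernel_sizes
        if not (v1 < v2 < v3):
            warnings.warn("kernel sizes are usually increasing (small < medium < large)")
        if len(set(self.strides)) != len(self.strides) or min(self.strides) < 1:
            raise ValueError("strides must be positive and distinct")
        if self.kernels < 1:
            raise ValueError("kernels must be >= 1")


@dataclass(frozen=True)
class PlainConvConfig:
    """Single-branch convolution block used by the encoder-ablation variant."""

    kernel_size: int = 3
    stride: int = 1
    kernels: int = 16


BlockConfig = MVCCMConfig | PlainConvConfig


@dataclass(frozen=True)
class EncoderConfig:
    modules: tuple[BlockConfig, ...] = (
        MVCCMConfig(kernels=16),
        MVCCMConfig(kernels=32),
    )
    pool_window: int = 2
    pool_stride: int = 2
    pool_mode: str = "max"
    projection_width: int = 18

    def __post_init__(self) -> None:
        if not self.modules:
            raise ValueError("encoder needs at least one module")
        if self.pool_window < 1 or self.pool_stride < 1 or self.projection_width < 1:
            raise ValueError("pool window/stride and projection width must be >= 1")


# ---------------------------------------------------------------------------
# Shape arithmetic (used for build-time validation and parameter counting)
# ---------------------------------------------------------------------------


def mvccm_branch_lengths(n: int, config: MVCCMConfig) -> list[dict[str, int]]:
    """Per-branch lengths (small, medium, concatenated, big) for input length n."""
    v1, v2, v3 = config.kernel_sizes
    out = []
    for s in config.strides:
        try:
            small = conv_output_length(n, v1, s)
            medium = conv_output_length(small, v2, s)
            cat = small + medium
            big = conv_output_length(cat, v3, s)
        except ValueError as exc:
            raise ShapeConfigError(f"branch with stride {s} collapses: {exc}") from exc
        out.append({"small": small, "medium": medium, "cat": cat, "big": big})
    return out


def block_output_length(n: int, config: BlockConfig) -> int:
    if isinstance(config, MVCCMConfig):
        return sum(b["big"] for b in mvccm_branch_lengths(n, config))
    return conv_output_length(n, config.kernel_size, config.stride)


def encoder_stage_lengths(input_length: int, config: EncoderConfig) -> list[int]:
    """Length after each module and each pooling layer, in order."""
    lengths = []
    n = input_length
    for i, mod in enumerate(config.modules):
        try:
            n = block_output_length(n, mod)
            lengths.append(n)
            n = conv_output_length(n, config.pool_window, config.pool_stride)
            lengths.append(n)
        except ValueError as exc:
            raise ShapeConfigError(f"stage {i} underflows: {exc}") from exc
    return lengths


def flatten_width(input_length: int, config: EncoderConfig) -> int:
    final_len = encoder_stage_lengths(input_length, config)[-1]
    return final_len * config.modules[-1].kernels


def count_parameters(config: EncoderConfig, input_length: int | None = None) -> int:
    """Trainable scalars in the encoder.

    With ``input_length=None`` only the convolutional blocks are counted (a
    quantity independent of input length, by weight sharing); otherwise the
    flatten projection for that input length is included.
    """
    total = 0
    in_ch = 1
    for mod in config.modules:
        k = mod.kernels
        if isinstance(mod, MVCCMConfig):
            v1, v2, v3 = mod.kernel_sizes
            total += 3 * (k * in_ch * v1 + k)
            total += 3 * (k * k * v2 + k)
            total += 3 * (k * k * v3 + k)
        else:
            total += k * in_ch * mod.kernel_size + k
        in_ch = k
    if input_length is not None:
        fw = flatten_width(input_length, config)
        total += fw * config.projection_width + config.projection_width
    return total


# ---------------------------------------------------------------------------
# Built network
# ---------------------------------------------------------------------------


class MVCCM:
    """Built three-branch module; channel count K is preserved across Θ."""

    def __init__(self, in_channels: int, config: MVCCMConfig, rng: np.random.Generator):
        self.config = config
        self.out_channels = config.kernels
        v1, v2, v3 = config.kernel_sizes
        k = config.kernels
        self.branches = []
        for s in config.strides:
            self.branches.append(
                {
                    "small": Conv1d(in_channels, k, v1, s, rng),
                    "relu_s": ReLU(),
                    "medium": Conv1d(k, k, v2, s, rng),
                    "relu_m": ReLU(),
                    "big": Conv1d(k, k, v3, s, rng),
                    "relu_b": ReLU(),
                }
            )
        self._split: list[tuple[int, int]] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        outs = []
        self._split = []
        for br in self.branches:
            small = br["relu_s"].forward(br["small"].forward(x))
            medium = br["relu_m"].forward(br["medium"].forward(small))
            cat = np.concatenate([small, medium], axis=2)
            big = br["relu_b"].forward(br["big"].forward(cat))
            self._split.append((small.shape[2], big.shape[2]))
            outs.append(big)
        return np.concatenate(outs, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = None
        offset = 0
        for br, (small_len, big_len) in zip(self.branches, self._split):
            d_big = dy[:, :, offset : offset + big_len]
            offset += big_len
            d_cat = br["big"].backward(br["relu_b"].backward(d_big))
            d_small = d_cat[:, :, :small_len].copy()
            d_medium = d_cat[:, :, small_len:]
            d_small += br["medium"].backward(br["relu_m"].backward(d_medium))
            d_in = br["small"].backward(br["relu_s"].backward(d_small))
            dx = d_in if dx is None else dx + d_in
        return dx

    def parameters(self) -> list[Param]:
        params: list[Param] = []
        for br in self.branches:
            for layer in (br["small"], br["medium"], br["big"]):
                params.extend(layer.parameters())
        return params


class PlainConvBlock:
    """conv+ReLU block standing in for an MVCCM in the encoder ablation."""

    def __init__(self, in_channels: int, config: PlainConvConfig, rng: np.random.Generator):
        self.config = config
        self.out_channels = config.kernels
        self.conv = Conv1d(in_channels, config.kernels, config.kernel_size, config.stride, rng)
        self.relu = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.relu.forward(self.conv.forward(x))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.relu.backward(dy))

    def parameters(self) -> list[Param]:
        return self.conv.parameters()


def _build_block(in_channels: int, cfg: BlockConfig, rng: np.random.Generator):
    if isinstance(cfg, MVCCMConfig):
        return MVCCM(in_channels, cfg, rng)
    return PlainConvBlock(in_channels, cfg, rng)


class MVCNNEncoder:
    """Alternating conv modules and pooling, flatten, and a linear projection.

    Built for a fixed input length; `rebuild_for_length` shares the (length
    agnostic) convolution blocks but re-instantiates the flatten projection,
    which is how the pretrained encoder is reused on full-length undisturbed
    feature vectors at fine-tune time.
    """

    def __init__(
        self,
        config: EncoderConfig,
        input_length: int,
        rng: np.random.Generator,
        _shared_blocks: list | None = None,
    ):
        self.config = config
        self.input_length = input_length
        encoder_stage_lengths(input_length, config)  # validates, raises early
        if _shared_blocks is None:
            blocks = []
            in_ch = 1
            for mod in config.modules:
                blocks.append(_build_block(in_ch, mod, rng))
                in_ch = mod.kernels
            self.blocks = blocks
        else:
            self.blocks = _shared_blocks
        self.pools = [
            Pool1d(config.pool_window, config.pool_stride, config.pool_mode)
            for _ in config.modules
        ]
        self.flatten_width = flatten_width(input_length, config)
        self.projection = Linear(self.flatten_width, config.projection_width, rng)
        self._map_shape: tuple | None = None

    def rebuild_for_length(self, input_length: int, rng: np.random.Generator) -> "MVCNNEncoder":
        return MVCNNEncoder(self.config, input_length, rng, _shared_blocks=self.blocks)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, 1, input_length) → (N, projection_width)."""
        if x.shape[2] != self.input_length:
            raise ValueError(
                f"encoder built for length {self.input_length}, got {x.shape[2]}"
            )
        h = x
        for block, pool in zip(self.blocks, self.pools):
            h = pool.forward(block.forward(h))
        self._map_shape = h.shape
        flat = h.reshape(h.shape[0], -1)
        return self.projection.forward(flat)

    def backward(self, d_hidden: np.ndarray) -> np.ndarray:
        d_flat = self.projection.backward(d_hidden)
        dh = d_flat.reshape(self._map_shape)
        for block, pool in zip(reversed(self.blocks), reversed(self.pools)):
            dh = block.backward(pool.backward(dh))
        return dh

    def conv_parameters(self) -> list[Param]:
        params: list[Param] = []
        for block in self.blocks:
            params.extend(block.parameters())
        return params

    def parameters(self) -> list[Param]:
        return self.conv_parameters() + self.projection.parameters()
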