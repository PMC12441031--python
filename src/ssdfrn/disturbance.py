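"""Self-supervised view generation: shuffle-window disturbance of feature vectors.

A window of W consecutive features (in schema order) is picked at a random
position P, its entries are permuted and masked with additive Gaussian noise
("auxiliary data"), while the remaining L−W features are concatenated in order
("residual data").  The pair (residual, auxiliary) plus the original vector is
one pretraining view; the number of views is not limited by the sample count.

Indexing is 0-based with half-open windows: the window starting at P covers
features P..P+W−1, and P is drawn uniformly from {1, …, L−W−1}, so the first
and last features always stay in the residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schema_io import FeatureTable


@dataclass(frozen=True)
class DisturbanceConfig:
    window_length: int = 4
    noise_sigma: float = 1.0
    views_per_sample: int = 1

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.views_per_sample < 1:
            raise ValueError("views_per_sample must be >= 1")

    def validate_for(self, n_features: int) -> None:
        if self.window_length > n_features - 2:
            raise ValueError(
                f"window_length {self.window_length} leaves no valid positions "
                f"for {n_features} features (need W <= L-2)"
            )


@dataclass
class DisturbanceRecord:
    """One pretraining view of one sample."""

    sample_id: str
    position: int
    permutation: np.ndarray
    auxiliary: np.ndarray
    residual: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        n_total = self.target.shape[0]
        window = self.auxiliary.shape[0]
        assert self.residual.shape[0] == n_total - window
        assert 1 <= self.position <= n_total - window - 1


def sample_window_position(
    n_features: int, window_length: int, rng: np.random.Generator
) -> int:
    """Uniform draw of the window start P from {1, …, L−W−1} inclusive."""
    high = n_features - window_length - 1
    if high < 1:
        raise ValueError(
            f"no valid window positions for L={n_features}, W={window_length}"
        )
    return int(rng.integers(1, high + 1))


def make_auxiliary(
    x: np.ndarray,
    position: int,
    config: DisturbanceConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Permute the window entries and add i.i.d. Gaussian(0, sigma²) noise.

    Returns (auxiliary vector of length W, permutation applied).
    """
    w = config.window_length
    window = x[position : position + w]
    perm = rng.permutation(w)
    noise = rng.normal(0.0, config.noise_sigma, size=w)
    return noise + window[perm], perm


def make_residual(x: np.ndarray, position: int, window_length: int) -> np.ndarray:
    """The L−W features outside the window, order preserved."""
    return np.concatenate([x[:position], x[position + window_length :]])


def splice_back(
    residual: np.ndarray, window: np.ndarray, position: int
) -> np.ndarray:
    """Inverse of window removal: reinsert the window values at ``position``."""
    return np.concatenate([residual[:position], window, residual[position:]])


def generate_views(
    table: FeatureTable,
    config: DisturbanceConfig,
    rng: np.random.Generator,
) -> list[DisturbanceRecord]:
    """Draw M × views_per_sample fresh disturbance records (fresh every call).

    The table is expected to be standardized so the Gaussian mask operates on a
    common unit scale.
    """
    config.validate_for(table.schema.n_features)
    records: list[DisturbanceRecord] = []
    for _ in range(config.views_per_sample):
        for j in range(table.n_samples):
            x = table.values[j]
            pos = sample_window_position(
                table.schema.n_features, config.window_length, rng
            )
            aux, perm = make_auxiliary(x, pos, config, rng)
            records.append(
                DisturbanceRecord(
                    sample_id=table.sample_ids[j],
                    position=pos,
                    permutation=perm,
                    auxiliary=aux,
                    residual=make_residual(x, pos, config.window_length),
                    target=x.copy(),
                )
            )
    return records
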