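"""Two-stage training: self-supervised reconstruction pretraining, then
fine-tuning a two-layer biomass estimator on the encoder representation.

Stage 1 draws fresh disturbance views every epoch, encodes the residual data,
splices the projected representation with the auxiliary data at the disturbed
position, decodes, and minimises the mean-square reconstruction error over all
feature positions.  Stage 2 rebuilds the encoder for full-length undisturbed
input vectors (convolution kernels are length-agnostic and are reused; only
the flatten projection is re-instantiated and always trained), attaches a
two-layer fully connected regression head, and minimises the mean-square
biomass error.  By default the convolutional encoder is frozen in stage 2;
a flag allows joint updates.

All randomness flows from a single integer seed through separate spawned
streams for initialisation, disturbance draws and minibatch shuffling, so a
run is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ._nn import Adam, Linear, Param, ReLU
from .disturbance import DisturbanceConfig, generate_views
from .mvcnn_encoder import EncoderConfig, MVCCMConfig, MVCNNEncoder, PlainConvConfig
from .reconstruction_decoder import Decoder, DecoderConfig, splice_decoder_input
from .schema_io import FeatureSchema, FeatureTable, StandardizationStats


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 20
    learning_rate: float = 1e-4
    epochs_stage1: int = 1000
    epochs_stage2: int = 1000
    seed: int = 0
    freeze_encoder_in_stage2: bool = True
    estimator_hidden_width: int = 200
    standardize_target: bool = False
    masked_loss_only: bool = False

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs_stage1 < 1 or self.epochs_stage2 < 1:
            raise ValueError("batch size and epoch counts must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")


@dataclass
class LossHistory:
    stage1_losses: list[float] = field(default_factory=list)
    stage2_losses: list[float] = field(default_factory=list)


def estimation_loss(estimated: np.ndarray, actual: np.ndarray) -> float:
    """Mean-square biomass estimation error (1/M) Σ (ŷ_j − y_j)²."""
    estimated = np.asarray(estimated, dtype=float).ravel()
    actual = np.asarray(actual, dtype=float).ravel()
    if estimated.shape != actual.shape:
        raise ValueError(f"shape mismatch: {estimated.shape} vs {actual.shape}")
    return float(np.mean((estimated - actual) ** 2))


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


@dataclass
class PretrainResult:
    encoder: MVCNNEncoder
    decoder: Decoder
    history: LossHistory


def pretrain(
    table: FeatureTable,
    disturbance: DisturbanceConfig,
    encoder_config: EncoderConfig | None = None,
    decoder_config: DecoderConfig | None = None,
    train: TrainConfig | None = None,
) -> PretrainResult:
    """Stage-1 self-supervised pretraining on a standardized feature table."""
    train = train or TrainConfig()
    n_features = table.schema.n_features
    encoder_config = encoder_config or EncoderConfig(projection_width=n_features - disturbance.window_length)
    decoder_config = decoder_config or DecoderConfig(output_width=n_features)
    if table.stats is None:
        import warnings

        warnings.warn("table carries no standardization stats; pretraining expects z-scored features")
    if table.n_samples < train.batch_size:
        import warnings

        warnings.warn(
            f"table has {table.n_samples} rows, fewer than batch size {train.batch_size}"
        )
    init_rng, dist_rng, batch_rng = _rngs(train.seed, 3)
    residual_len = n_features - disturbance.window_length
    encoder = MVCNNEncoder(encoder_config, residual_len, init_rng)
    decoder = Decoder(decoder_config, n_features, init_rng)
    params = encoder.parameters() + decoder.parameters()
    opt = Adam(params, lr=train.learning_rate)
    history = LossHistory()
    w = disturbance.window_length
    for epoch in range(train.epochs_stage1):
        records = generate_views(table, disturbance, dist_rng)
        epoch_loss = 0.0
        for idx in _batches(len(records), train.batch_size, batch_rng):
            batch = [records[i] for i in idx]
            residuals = np.stack([r.residual for r in batch])[:, None, :]
            targets = np.stack([r.target for r in batch])
            positions = [r.position for r in batch]
            hidden = encoder.forward(residuals)
            x_de = np.stack(
                [
                    splice_decoder_input(hidden[j], batch[j].auxiliary, positions[j])
                    for j in range(len(batch))
                ]
            )[:, None, :]
            recon = decoder.forward(x_de)
            diff = recon - targets
            if train.masked_loss_only:
                mask = np.zeros_like(diff)
                for j, p in enumerate(positions):
                    mask[j, p : p + w] = 1.0
                loss = float(np.sum(mask * diff**2) / mask.sum())
                d_recon = 2.0 * mask * diff / mask.sum()
            else:
                loss = float(np.mean(diff**2))
                d_recon = 2.0 * diff / diff.size
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite reconstruction loss at epoch {epoch}: {loss}"
                )
            opt.zero_grad()
            d_xde = decoder.backward(d_recon)[:, 0, :]
            d_hidden = np.empty_like(hidden)
            for j, p in enumerate(positions):
                d_hidden[j, :p] = d_xde[j, :p]
                d_hidden[j, p:] = d_xde[j, p + w :]
            encoder.backward(d_hidden)
            opt.step()
            epoch_loss += loss * len(batch)
        history.stage1_losses.append(epoch_loss / len(records))
    return PretrainResult(encoder=encoder, decoder=decoder, history=history)


class BiomassEstimator:
    """Two fully connected layers (ReLU hidden, linear scalar output)."""

    def __init__(
        self,
        in_width: int,
        hidden_width: int,
        rng: np.random.Generator,
        output_bias: float = 0.0,
    ):
        self.fc1 = Linear(in_width, hidden_width, rng)
        self.relu = ReLU()
        self.fc2 = Linear(hidden_width, 1, rng)
        # starting the scalar output at the training-target mean keeps the
        # head well-conditioned for unstandardized biomass targets
        self.fc2.bias.value[:] = output_bias

    def forward(self, hidden: np.ndarray) -> np.ndarray:
        return self.fc2.forward(self.relu.forward(self.fc1.forward(hidden)))[:, 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.fc1.backward(self.relu.backward(self.fc2.backward(dy[:, None])))

    def parameters(self) -> list[Param]:
        return self.fc1.parameters() + self.fc2.parameters()


@dataclass
class SSDFRNModel:
    """Fine-tuned model bundle: schema, scaling stats, encoder and estimator."""

    schema: FeatureSchema
    stats: StandardizationStats
    encoder: MVCNNEncoder
    estimator: BiomassEstimator
    target_mean: float = 0.0
    target_std: float = 1.0

    def predict_standardized(self, values: np.ndarray) -> np.ndarray:
        hidden = self.encoder.forward(values[:, None, :])
        yhat = self.estimator.forward(hidden)
        return yhat * self.target_std + self.target_mean

    def predict(self, raw_values: np.ndarray) -> np.ndarray:
        """Estimate biomass for raw (unstandardized) feature rows."""
        raw_values = np.atleast_2d(np.asarray(raw_values, dtype=float))
        if raw_values.shape[1] != self.schema.n_features:
            raise ValueError(
                f"expected {self.schema.n_features} features, got {raw_values.shape[1]}"
            )
        z = (raw_values - self.stats.mean) / self.stats.std
        return self.predict_standardized(z)

    def predict_table(self, table: FeatureTable) -> np.ndarray:
        if table.schema.content_hash() != self.schema.content_hash():
            raise ValueError("feature schema of the table does not match the model")
        values = table.values if table.stats is None else None
        if values is None:
            return self.predict_standardized(table.values)
        return self.predict(values)


@dataclass
class FinetuneResult:
    model: SSDFRNModel
    history: LossHistory


def finetune(
    table: FeatureTable,
    encoder: MVCNNEncoder | None,
    encoder_config: EncoderConfig | None = None,
    train: TrainConfig | None = None,
) -> FinetuneResult:
    """Stage-2 supervised fine-tuning on a standardized, biomass-labelled table.

    ``encoder`` is the stage-1 pretrained encoder (its convolution kernels are
    reused on the full-length input); pass ``None`` for the no-pretraining
    ablation, in which case a randomly initialised encoder is built from
    ``encoder_config``.
    """
    train = train or TrainConfig()
    if table.biomass is None:
        raise ValueError("fine-tuning requires a biomass column")
    if table.stats is None:
        raise ValueError("fine-tuning expects a standardized table (stats present)")
    n_features = table.schema.n_features
    init_rng, batch_rng = _rngs(train.seed + 1, 2)
    if encoder is not None:
        full_encoder = encoder.rebuild_for_length(n_features, init_rng)
    else:
        if encoder_config is None:
            raise ValueError("encoder_config required when no pretrained encoder is given")
        full_encoder = MVCNNEncoder(encoder_config, n_features, init_rng)

    y = table.biomass.astype(float)
    if train.standardize_target:
        target_mean, target_std = float(y.mean()), float(y.std() or 1.0)
    else:
        target_mean, target_std = 0.0, 1.0
    y_scaled = (y - target_mean) / target_std

    estimator = BiomassEstimator(
        full_encoder.config.projection_width,
        train.estimator_hidden_width,
        init_rng,
        output_bias=float(y_scaled.mean()),
    )
    params = full_encoder.projection.parameters() + estimator.parameters()
    if not train.freeze_encoder_in_stage2:
        params = full_encoder.conv_parameters() + params
    opt = Adam(params, lr=train.learning_rate)
    history = LossHistory()
    x = table.values
    for epoch in range(train.epochs_stage2):
        epoch_loss = 0.0
        for idx in _batches(table.n_samples, train.batch_size, batch_rng):
            xb = x[idx][:, None, :]
            yb = y_scaled[idx]
            hidden = full_encoder.forward(xb)
            yhat = estimator.forward(hidden)
            diff = yhat - yb
            loss = float(np.mean(diff**2))
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite estimation loss at epoch {epoch}: {loss}")
            opt.zero_grad()
            d_hidden = estimator.backward(2.0 * diff / diff.size)
            full_encoder.backward(d_hidden)
            opt.step()
            epoch_loss += loss * len(idx)
        history.stage2_losses.append(epoch_loss / table.n_samples)
    model = SSDFRNModel(
        schema=table.schema,
        stats=table.stats,
        encoder=full_encoder,
        estimator=estimator,
        target_mean=target_mean,
        target_std=target_std,
    )
    return FinetuneResult(model=model, history=history)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def _encoder_config_to_dict(config: EncoderConfig) -> dict:
    mods = []
    for m in config.modules:
        if isinstance(m, MVCCMConfig):
            mods.append(
                {
                    "type": "mvccm",
                    "kernel_sizes": list(m.kernel_sizes),
                    "strides": list(m.strides),
                    "kernels": m.kernels,
                }
            )
        else:
            mods.append(
                {
                    "type": "plain",
                    "kernel_size": m.kernel_size,
                    "stride": m.stride,
                    "kernels": m.kernels,
                }
            )
    return {
        "modules": mods,
        "pool_window": config.pool_window,
        "pool_stride": config.pool_stride,
        "pool_mode": config.pool_mode,
        "projection_width": config.projection_width,
    }


def _encoder_config_from_dict(doc: dict) -> EncoderConfig:
    mods: list = []
    for m in doc["modules"]:
        if m["type"] == "mvccm":
            mods.append(
                MVCCMConfig(
                    kernel_sizes=tuple(m["kernel_sizes"]),
                    strides=tuple(m["strides"]),
                    kernels=m["kernels"],
                )
            )
        else:
            mods.append(
                PlainConvConfig(
                    kernel_size=m["kernel_size"], stride=m["stride"], kernels=m["kernels"]
                )
            )
    return EncoderConfig(
        modules=tuple(mods),
        pool_window=doc["pool_window"],
        pool_stride=doc["pool_stride"],
        pool_mode=doc["pool_mode"],
        projection_width=doc["projection_width"],
    )


def save_pretrained(
    result: PretrainResult,
    schema: FeatureSchema,
    stats: StandardizationStats,
    path: str,
) -> None:
    """Serialize the stage-1 artifact (encoder + decoder, marked pretrained-only)."""
    arrays = {}
    for i, p in enumerate(result.encoder.parameters()):
        arrays[f"enc_{i}"] = p.value
    for i, p in enumerate(result.decoder.parameters()):
        arrays[f"dec_{i}"] = p.value
    arrays["stats_mean"] = stats.mean
    arrays["stats_std"] = stats.std
    meta = {
        "stage": "pretrained",
        "schema_names": list(schema.feature_names),
        "schema_hash": schema.content_hash(),
        "encoder_config": _encoder_config_to_dict(result.encoder.config),
        "input_length": result.encoder.input_length,
        "decoder_config": {
            "conv_blocks": [list(b) for b in result.decoder.config.conv_blocks],
            "pool_window": result.decoder.config.pool_window,
            "pool_stride": result.decoder.config.pool_stride,
            "pool_mode": result.decoder.config.pool_mode,
            "output_width": result.decoder.config.output_width,
        },
        "stage1_losses": result.history.stage1_losses,
    }
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_pretrained(
    path: str, schema: FeatureSchema | None = None
) -> tuple[MVCNNEncoder, Decoder, FeatureSchema, StandardizationStats]:
    with np.load(path) as blob:
        meta = json.loads(bytes(blob["meta"]).decode())
        arrays = {k: blob[k] for k in blob.files if k != "meta"}
    if meta["stage"] != "pretrained":
        raise ValueError(f"checkpoint stage is {meta['stage']!r}, expected 'pretrained'")
    saved_schema = FeatureSchema(feature_names=tuple(meta["schema_names"]))
    if schema is not None and schema.content_hash() != meta["schema_hash"]:
        raise ValueError("checkpoint was trained against a different feature schema")
    rng = np.random.default_rng(0)
    encoder = MVCNNEncoder(
        _encoder_config_from_dict(meta["encoder_config"]), meta["input_length"], rng
    )
    for i, p in enumerate(encoder.parameters()):
        p.value[...] = arrays[f"enc_{i}"]
    dc = meta["decoder_config"]
    decoder = Decoder(
        DecoderConfig(
            conv_blocks=tuple(tuple(b) for b in dc["conv_blocks"]),
            pool_window=dc["pool_window"],
            pool_stride=dc["pool_stride"],
            pool_mode=dc["pool_mode"],
            output_width=dc["output_width"],
        ),
        dc["output_width"],
        rng,
    )
    for i, p in enumerate(decoder.parameters()):
        p.value[...] = arrays[f"dec_{i}"]
    stats = StandardizationStats(mean=arrays["stats_mean"], std=arrays["stats_std"])
    return encoder, decoder, saved_schema, stats


def save_model(model: SSDFRNModel, path: str) -> None:
    """Serialize a fine-tuned model (parameters + config + schema hash)."""
    arrays = {}
    for i, p in enumerate(model.encoder.parameters()):
        arrays[f"enc_{i}"] = p.value
    for i, p in enumerate(model.estimator.parameters()):
        arrays[f"est_{i}"] = p.value
    arrays["stats_mean"] = model.stats.mean
    arrays["stats_std"] = model.stats.std
    meta = {
        "stage": "finetuned",
        "schema_names": list(model.schema.feature_names),
        "schema_hash": model.schema.content_hash(),
        "encoder_config": _encoder_config_to_dict(model.encoder.config),
        "input_length": model.encoder.input_length,
        "estimator_hidden_width": model.estimator.fc1.out_features,
        "target_mean": model.target_mean,
        "target_std": model.target_std,
    }
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str, schema: FeatureSchema | None = None) -> SSDFRNModel:
    with np.load(path) as blob:
        meta = json.loads(bytes(blob["meta"]).decode())
        arrays = {k: blob[k] for k in blob.files if k != "meta"}
    saved_schema = FeatureSchema(feature_names=tuple(meta["schema_names"]))
    if schema is not None and schema.content_hash() != meta["schema_hash"]:
        raise ValueError("checkpoint was trained against a different feature schema")
    config = _encoder_config_from_dict(meta["encoder_config"])
    rng = np.random.default_rng(0)
    encoder = MVCNNEncoder(config, meta["input_length"], rng)
    for i, p in enumerate(encoder.parameters()):
        p.value[...] = arrays[f"enc_{i}"]
    estimator = BiomassEstimator(
        config.projection_width, meta["estimator_hidden_width"], rng
    )
    for i, p in enumerate(estimator.parameters()):
        p.value[...] = arrays[f"est_{i}"]
    stats = StandardizationStats(mean=arrays["stats_mean"], std=arrays["stats_std"])
    return SSDFRNModel(
        schema=saved_schema,
        stats=stats,
        encoder=encoder,
        estimator=estimator,
        target_mean=meta["target_mean"],
        target_std=meta["target_std"],
    )
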