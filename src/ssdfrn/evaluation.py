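"""Error metrics, data splits and the ablation harness.

Provides absolute error / MAE / RMSE, the 70/30 holdout (40/18 for the 58-plot
study layout) and fivefold cross-validation splits, and a three-task ablation
grid: T1 = pretraining + multi-view encoder, T2 = pretraining + plain
single-branch convolutional encoder, T3 = multi-view encoder without
pretraining.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .disturbance import DisturbanceConfig
from .mvcnn_encoder import EncoderConfig, MVCCMConfig, PlainConvConfig
from .schema_io import FeatureTable, apply_standardization, fit_standardization
from .training import TrainConfig, finetune, pretrain


def absolute_errors(actual: np.ndarray, estimated: np.ndarray) -> np.ndarray:
    actual = np.asarray(actual, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if actual.shape != estimated.shape:
        raise ValueError(f"length mismatch: {actual.shape} vs {estimated.shape}")
    return np.abs(estimated - actual)


def mae(actual: np.ndarray, estimated: np.ndarray) -> float:
    errors = absolute_errors(actual, estimated)
    if errors.size == 0:
        raise ValueError("cannot compute MAE of empty input")
    return float(errors.mean())


def rmse(actual: np.ndarray, estimated: np.ndarray) -> float:
    actual = np.asarray(actual, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if actual.shape != estimated.shape:
        raise ValueError(f"length mismatch: {actual.shape} vs {estimated.shape}")
    if actual.size == 0:
        raise ValueError("cannot compute RMSE of empty input")
    return float(np.sqrt(np.mean((estimated - actual) ** 2)))


@dataclass
class EvaluationReport:
    per_sample_ae: np.ndarray
    mae: float
    rmse: float
    n: int
    split_id: str = ""

    @classmethod
    def from_predictions(
        cls, actual: np.ndarray, estimated: np.ndarray, split_id: str = ""
    ) -> "EvaluationReport":
        errors = absolute_errors(actual, estimated)
        return cls(
            per_sample_ae=errors,
            mae=mae(actual, estimated),
            rmse=rmse(actual, estimated),
            n=errors.size,
            split_id=split_id,
        )


def load_reference_test_pairs() -> pd.DataFrame:
    """The 18 published actual/estimated test-set biomass pairs (fixture CSV)."""
    with importlib.resources.files("ssdfrn").joinpath(
        "data/table5_test_pairs.csv"
    ).open() as fh:
        return pd.read_csv(fh)


@dataclass
class SplitPlan:
    mode: str
    folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int


def make_split(n: int, mode: str = "holdout", seed: int = 0) -> SplitPlan:
    """Seeded 70/30 holdout (floor on the training share) or fivefold CV.

    Fivefold folds are a seeded shuffle followed by contiguous blocking; the
    first ``n % 5`` folds get the extra samples, so n=58 gives test-fold sizes
    (12, 12, 12, 11, 11).
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    if mode == "holdout":
        n_train = int(np.floor(0.7 * n))
        folds = [(np.sort(order[:n_train]), np.sort(order[n_train:]))]
    elif mode == "kfold":
        if n < 5:
            raise ValueError("fivefold split needs at least 5 samples")
        sizes = [n // 5 + (1 if i < n % 5 else 0) for i in range(5)]
        folds = []
        start = 0
        for size in sizes:
            test = np.sort(order[start : start + size])
            train = np.sort(np.concatenate([order[:start], order[start + size :]]))
            folds.append((train, test))
            start += size
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    return SplitPlan(mode=mode, folds=folds, seed=seed)


ABLATION_TASKS = ("T1", "T2", "T3")


def _plain_encoder_config(reference: EncoderConfig) -> EncoderConfig:
    """Single-branch substitute encoder with matched depth and kernel counts."""
    modules = tuple(
        PlainConvConfig(kernel_size=3, stride=1, kernels=m.kernels)
        for m in reference.modules
    )
    return replace(reference, modules=modules)


def evaluate_once(
    table: FeatureTable,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    task: str,
    disturbance: DisturbanceConfig,
    encoder_config: EncoderConfig,
    train_config: TrainConfig,
    split_id: str = "",
) -> EvaluationReport:
    """Train one ablation task on the given split and score the held-out rows."""
    train_raw = table.subset(train_idx)
    test_raw = table.subset(test_idx)
    stats = fit_standardization(train_raw)
    train_table = apply_standardization(train_raw, stats)
    if task == "T2":
        encoder_config = _plain_encoder_config(encoder_config)
    if task in ("T1", "T2"):
        pre = pretrain(train_table, disturbance, encoder_config, train=train_config)
        result = finetune(train_table, pre.encoder, train=train_config)
    elif task == "T3":
        result = finetune(train_table, None, encoder_config=encoder_config, train=train_config)
    else:
        raise ValueError(f"unknown ablation task {task!r}")
    predictions = result.model.predict(test_raw.values)
    return EvaluationReport.from_predictions(test_raw.biomass, predictions, split_id)


def run_ablation(
    table: FeatureTable,
    seeds: list[int],
    disturbance: DisturbanceConfig | None = None,
    encoder_config: EncoderConfig | None = None,
    train_config: TrainConfig | None = None,
    tasks: tuple[str, ...] = ABLATION_TASKS,
) -> pd.DataFrame:
    """Run the ablation grid on seeded 70/30 splits shared across tasks.

    Returns one row per (task, seed) with columns task/seed/mae/rmse.
    """
    if table.biomass is None:
        raise ValueError("ablation requires a biomass column")
    disturbance = disturbance or DisturbanceConfig()
    encoder_config = encoder_config or EncoderConfig(
        modules=(MVCCMConfig(kernels=16), MVCCMConfig(kernels=32)),
        projection_width=table.schema.n_features - disturbance.window_length,
    )
    train_config = train_config or TrainConfig()
    rows = []
    for seed in seeds:
        plan = make_split(table.n_samples, "holdout", seed=seed)
        train_idx, test_idx = plan.folds[0]
        cfg = replace(train_config, seed=seed)
        for task in tasks:
            report = evaluate_once(
                table,
                train_idx,
                test_idx,
                task,
                disturbance,
                encoder_config,
                cfg,
                split_id=f"holdout-{seed}",
            )
            rows.append(
                {"task": task, "seed": seed, "mae": report.mae, "rmse": report.rmse}
            )
    return pd.DataFrame(rows)
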