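"""Feature schema, CSV table I/O, standardization and the allometric biomass law.

The default schema describes the 22 per-plot predictors used for mangrove
aboveground-biomass estimation: seven Landsat-8 band values, six vegetation
indices derived from them, eight GLCM texture statistics and one topographic
factor.  Feature order is fixed (bands, indices, textures, topography) and is
the order used by the shuffle-window indexing of the disturbance stage.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

BAND_FEATURES = ["COASTAL", "BLUE", "GREEN", "RED", "NIR", "SWIR1", "SWIR2"]
INDEX_FEATURES = ["NDVI", "RVI", "DVI", "SAVI", "EVI", "GNDVI"]
TEXTURE_FEATURES = ["VAR", "HOM", "CON", "HET", "ENT", "ASM", "COR", "MEA"]
TOPO_FEATURES = ["TOF"]

DEFAULT_FEATURE_NAMES = BAND_FEATURES + INDEX_FEATURES + TEXTURE_FEATURES + TOPO_FEATURES

BIOMASS_COLUMN = "biomass"


class SchemaError(ValueError):
    """A table does not conform to the feature schema."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature-name list; ``n_features`` (L) equals its length."""

    feature_names: tuple[str, ...] = tuple(DEFAULT_FEATURE_NAMES)

    def __post_init__(self) -> None:
        if len(set(self.feature_names)) != len(self.feature_names):
            raise SchemaError("feature names must be unique")
        if not self.feature_names:
            raise SchemaError("schema needs at least one feature")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def content_hash(self) -> str:
        """Stable digest used to guard checkpoints against schema mismatch."""
        return hashlib.sha256(",".join(self.feature_names).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str) -> "FeatureSchema":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(feature_names=tuple(doc["feature_names"]))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"feature_names": list(self.feature_names)}, fh)


@dataclass
class StandardizationStats:
    """Per-feature mean/std fitted on training rows (std of constant columns is 1)."""

    mean: np.ndarray
    std: np.ndarray


@dataclass
class FeatureTable:
    """M samples by L features, optionally labelled with observed biomass.

    ``values`` is an (M, L) float array in schema order; ``sample_ids`` keeps the
    source row identity; ``stats`` is set once the table has been standardized
    (or transformed with stats fitted elsewhere) so the mapping can be inverted.
    """

    schema: FeatureSchema
    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    biomass: np.ndarray | None = None
    stats: StandardizationStats | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.schema.n_features:
            raise SchemaError(
                f"values must be (M, {self.schema.n_features}); got {self.values.shape}"
            )
        if self.n_samples < 1:
            raise SchemaError("table needs at least one row")
        if not np.all(np.isfinite(self.values)):
            raise SchemaError("feature values must be finite")
        if not self.sample_ids:
            self.sample_ids = [str(i) for i in range(self.n_samples)]
        if self.biomass is not None:
            self.biomass = np.asarray(self.biomass, dtype=float)
            if self.biomass.shape != (self.n_samples,):
                raise SchemaError("biomass length must equal the number of rows")
            if not np.all(np.isfinite(self.biomass)):
                raise SchemaError("biomass must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def subset(self, indices: np.ndarray) -> "FeatureTable":
        indices = np.asarray(indices, dtype=int)
        return FeatureTable(
            schema=self.schema,
            values=self.values[indices].copy(),
            sample_ids=[self.sample_ids[i] for i in indices],
            biomass=None if self.biomass is None else self.biomass[indices].copy(),
            stats=self.stats,
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(self.schema.feature_names))
        frame.insert(0, "sample_id", self.sample_ids)
        if self.biomass is not None:
            frame[BIOMASS_COLUMN] = self.biomass
        return frame


def read_feature_table(path: str, schema: FeatureSchema | None = None) -> FeatureTable:
    """Read a CSV feature table; a ``biomass`` column is optional.

    Raises :class:`SchemaError` naming any missing feature column, and a parse
    error with the row index for non-numeric cells.
    """
    schema = schema or FeatureSchema()
    frame = pd.read_csv(path)
    missing = [name for name in schema.feature_names if name not in frame.columns]
    if missing:
        raise SchemaError(f"missing feature column(s): {', '.join(missing)}")
    numeric_cols = list(schema.feature_names)
    if BIOMASS_COLUMN in frame.columns:
        numeric_cols.append(BIOMASS_COLUMN)
    numeric = frame[numeric_cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame[numeric_cols].notna() | frame[numeric_cols].isna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy().any(axis=1))[0, 0])
        raise ValueError(f"non-numeric or missing cell in row {row}")
    sample_ids = (
        frame["sample_id"].astype(str).tolist()
        if "sample_id" in frame.columns
        else [str(i) for i in range(len(frame))]
    )
    biomass = numeric[BIOMASS_COLUMN].to_numpy() if BIOMASS_COLUMN in frame.columns else None
    return FeatureTable(
        schema=schema,
        values=numeric[list(schema.feature_names)].to_numpy(),
        sample_ids=sample_ids,
        biomass=biomass,
    )


def write_feature_table(table: FeatureTable, path: str) -> None:
    table.to_frame().to_csv(path, index=False)


def fit_standardization(table: FeatureTable) -> StandardizationStats:
    """Per-feature mean/std over rows; constant columns get std 1 by convention."""
    if table.n_samples < 2:
        raise ValueError("cannot estimate feature spread from a single row")
    mean = table.values.mean(axis=0)
    std = table.values.std(axis=0, ddof=0)
    # constant columns map to exact zeros (std treated as 1)
    constant = table.values.max(axis=0) == table.values.min(axis=0)
    mean[constant] = table.values[0, constant]
    std = np.where(constant, 1.0, np.where(std > 0, std, 1.0))
    return StandardizationStats(mean=mean, std=std)


def apply_standardization(table: FeatureTable, stats: StandardizationStats) -> FeatureTable:
    values = (table.values - stats.mean) / stats.std
    return replace(table, values=values, stats=stats)


def standardize(table: FeatureTable) -> FeatureTable:
    """Z-score each feature using stats fitted on this table; stats are stored."""
    return apply_standardization(table, fit_standardization(table))


def inverse_standardize(table: FeatureTable) -> FeatureTable:
    if table.stats is None:
        raise ValueError("table carries no standardization stats to invert")
    values = table.values * table.stats.std + table.stats.mean
    return replace(table, values=values, stats=None)


@dataclass(frozen=True)
class AllometricParams:
    """Power law y = a · D^b for Kandelia stem biomass from basal branch diameter."""

    coefficient: float = 3.614
    exponent: float = 1.446

    def __post_init__(self) -> None:
        if self.coefficient <= 0 or self.exponent <= 0:
            raise ValueError("allometric coefficient and exponent must be positive")


def biomass_from_diameter(
    diameter: float | np.ndarray, params: AllometricParams | None = None
) -> float | np.ndarray:
    """Total plant biomass from near-ground branch trunk diameter D (power law).

    Strictly increasing in D; D must be non-negative.
    """
    params = params or AllometricParams()
    diameter = np.asarray(diameter, dtype=float)
    if np.any(diameter < 0):
        raise ValueError("diameter must be non-negative")
    result = params.coefficient * diameter**params.exponent
    return float(result) if result.ndim == 0 else result
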