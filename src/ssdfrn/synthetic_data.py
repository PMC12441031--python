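"""Synthetic feature tables with the structure the method assumes.

A latent canopy-density variable c ~ Uniform(0, 1) drives everything: seven
reflectance-like bands are affine in c plus Gaussian noise (visible and
short-wave reflectance decreasing in c, near-infrared increasing — the
spectral behaviour vegetation indices exploit); the six vegetation indices are
computed from the synthetic bands by their standard formulas; the eight
texture statistics are smooth nonlinear transforms of c plus noise; the
topographic factor is weakly correlated noise.  A latent basal stem diameter
is affine in c and is pushed through the allometric power law, plus Gaussian
noise, and affinely anchored to the published test-set biomass span
(roughly 10–29) so error magnitudes are comparable to the reference scale.

This is deliberately a latent-factor emulator, not a radiative-transfer model:
its job is to give the 22 features realistic mutual structure so that
masked-feature reconstruction and the downstream regression are learnable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import make_split
from .schema_io import AllometricParams, FeatureSchema, FeatureTable, biomass_from_diameter

# band reflectance ramps: (intercept, slope in the latent canopy variable)
_BAND_RAMPS = {
    "COASTAL": (0.12, -0.05),
    "BLUE": (0.10, -0.05),
    "GREEN": (0.12, -0.04),
    "RED": (0.22, -0.16),
    "NIR": (0.15, 0.30),
    "SWIR1": (0.28, -0.14),
    "SWIR2": (0.22, -0.12),
}


@dataclass(frozen=True)
class SimConfig:
    n: int = 58
    seed: int = 0
    latent_noise: float = 0.3
    biomass_noise: float = 0.5
    biomass_range: tuple[float, float] = (10.0, 29.0)
    allometric: AllometricParams = field(default_factory=AllometricParams)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.latent_noise < 0 or self.biomass_noise < 0:
            raise ValueError("noise scales must be >= 0")
        lo, hi = self.biomass_range
        if not (0 < lo < hi):
            raise ValueError("biomass_range must be positive and increasing")


def _bands(c: np.ndarray, noise: float, rng: np.random.Generator) -> dict[str, np.ndarray]:
    out = {}
    for name, (intercept, slope) in _BAND_RAMPS.items():
        eps = rng.normal(0.0, noise * abs(slope), size=c.shape)
        out[name] = np.clip(intercept + slope * c + eps, 0.01, None)
    return out


def _indices(b: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    nir, red, blue, green = b["NIR"], b["RED"], b["BLUE"], b["GREEN"]
    return {
        "NDVI": (nir - red) / (nir + red),
        "RVI": nir / red,
        "DVI": nir - red,
        "SAVI": 1.5 * (nir - red) / (nir + red + 0.5),
        "EVI": 2.5 * (nir - red) / (nir + 6.0 * red - 7.5 * blue + 1.0),
        "GNDVI": (nir - green) / (nir + green),
    }


def _textures(c: np.ndarray, noise: float, rng: np.random.Generator) -> dict[str, np.ndarray]:
    def jitter(x: np.ndarray, scale: float) -> np.ndarray:
        return x + rng.normal(0.0, noise * scale, size=c.shape)

    return {
        "VAR": jitter(0.6 * c * (1.0 - c) + 0.1, 0.1),
        "HOM": jitter(0.4 + 0.5 * c**2, 0.15),
        "CON": jitter(0.8 * (1.0 - c) ** 1.5 + 0.1, 0.2),
        "HET": jitter(0.7 * (1.0 - c) + 0.15, 0.15),
        "ENT": jitter(np.log1p(2.0 * c) + 0.5, 0.2),
        "ASM": jitter(0.9 - 0.6 * np.sqrt(c), 0.15),
        "COR": jitter(0.3 + 0.6 * c, 0.15),
        "MEA": jitter(0.2 + 0.6 * c, 0.15),
    }


def simulate(config: SimConfig | None = None, schema: FeatureSchema | None = None) -> FeatureTable:
    """Draw a biomass-labelled synthetic table with the default 22-feature schema."""
    config = config or SimConfig()
    schema = schema or FeatureSchema()
    rng = np.random.default_rng(config.seed)
    c = rng.uniform(0.0, 1.0, size=config.n)

    columns: dict[str, np.ndarray] = {}
    columns.update(_bands(c, config.latent_noise, rng))
    columns.update(_indices(columns))
    columns.update(_textures(c, config.latent_noise, rng))
    columns["TOF"] = 0.2 * c + rng.normal(0.0, 0.3, size=config.n)

    missing = [n for n in schema.feature_names if n not in columns]
    if missing:
        raise ValueError(f"schema features not produced by the simulator: {missing}")
    values = np.column_stack([columns[n] for n in schema.feature_names])

    # latent diameter -> allometric biomass, anchored to the target span
    d_min, d_max = 1.0, 10.0
    diameter = d_min + (d_max - d_min) * c
    raw = biomass_from_diameter(diameter, config.allometric)
    raw = raw + rng.normal(0.0, config.biomass_noise, size=config.n)
    lo, hi = config.biomass_range
    ref_lo = biomass_from_diameter(d_min, config.allometric)
    ref_hi = biomass_from_diameter(d_max, config.allometric)
    biomass = lo + (raw - ref_lo) * (hi - lo) / (ref_hi - ref_lo)
    biomass = np.clip(biomass, 0.1, None)

    return FeatureTable(schema=schema, values=values, biomass=biomass)


def simulate_split(
    config: SimConfig | None = None, schema: FeatureSchema | None = None
) -> tuple[FeatureTable, FeatureTable]:
    """Simulate once and apply the seeded 70/30 holdout (58 → 40/18)."""
    config = config or SimConfig()
    if config.n < 10:
        raise ValueError("simulate_split needs n >= 10")
    table = simulate(config, schema)
    plan = make_split(table.n_samples, "holdout", seed=config.seed)
    train_idx, test_idx = plan.folds[0]
    return table.subset(train_idx), table.subset(test_idx)
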