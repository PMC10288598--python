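"""Synthetic data with known ground truth.

The curated literature table behind the real analysis is not required at
test time: this module emulates its schema and value ranges, planting a
*known* signal (informative features, pairwise interactions, Gaussian
noise) so recovery of drivers, interactions and projections can be checked
against the truth.  Raw labels are generated on the control-relative
percent scale (control = 100), as literature records report them.

A matching raster generator produces spatially smooth environmental layers
(temperatures, illumination, humidity, soil pH, crop mask, planting month)
for the projection stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import GeoMeta, RasterStack
from .schema import (
    CATEGORICAL_FEATURES,
    FEATURES,
    NP_TYPES,
    ONE_HOT_LEVELS,
    QUANTITATIVE_RANGES,
    SHAPE_FEATURE,
    SHAPE_LEVELS,
    TYPE_FEATURE,
)

__all__ = ["EffectSpec", "generate_experiment_table", "generate_raster_stack",
           "CLIMATE_PROFILES"]


# ---------------------------------------------------------------------------
# Experiment-table generator
# ---------------------------------------------------------------------------

@dataclass
class EffectSpec:
    """Ground truth for a synthetic experiment table.

    ``effects`` maps feature name -> signed effect size; ``interactions``
    lists (feature_a, feature_b, effect size) triples.  With
    ``standardize=True`` (default) effect sizes are in label units per
    *normalized* feature unit (features are centred and scaled by their
    population mean/SD before multiplying), which makes effects comparable
    across features of very different ranges; with ``standardize=False``
    effects apply to raw feature units.
    """

    n: int = 200
    effects: dict[str, float] = field(default_factory=dict)
    interactions: list[tuple[str, str, float]] = field(default_factory=list)
    noise_sd: float = 5.0
    label_set: tuple[str, ...] = ("dry_weight",)
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        named = set(self.effects)
        for a, b, _ in self.interactions:
            named.update((a, b))
        unknown = named - set(FEATURES)
        if unknown:
            raise ValueError(
                f"unknown feature name(s) in effect spec: {sorted(unknown)}"
            )
        for f, e in self.effects.items():
            if not np.isfinite(e):
                raise ValueError(f"effect size for {f!r} is not finite")
        for a, b, e in self.interactions:
            if not np.isfinite(e):
                raise ValueError(f"interaction effect for ({a}, {b}) is not finite")


def _feature_signal(records: pd.DataFrame, feature: str, standardize: bool) -> np.ndarray:
    """Numeric carrier of a feature for signal construction.

    Quantitative features use their raw value; categorical features use the
    index of the level in sorted level order.  Standardization uses the
    *population* moments implied by the uniform sampling scheme, so a
    noiseless run is exactly linear in the carrier.
    """
    if feature in QUANTITATIVE_RANGES:
        x = records[feature].to_numpy(dtype=float)
        lo, hi, _ = QUANTITATIVE_RANGES[feature]
        mu = (lo + hi) / 2.0
        sd = (hi - lo) / np.sqrt(12.0)
    else:
        if feature == TYPE_FEATURE:
            levels = sorted(NP_TYPES)
        elif feature == SHAPE_FEATURE:
            levels = sorted(SHAPE_LEVELS)
        else:
            levels = sorted(ONE_HOT_LEVELS[feature])
        idx = {lv: i for i, lv in enumerate(levels)}
        x = np.array([idx[v] for v in records[feature]], dtype=float)
        k = len(levels)
        mu = (k - 1) / 2.0
        sd = np.sqrt((k * k - 1) / 12.0) if k > 1 else 1.0
    if standardize:
        return (x - mu) / sd
    return x


def generate_experiment_table(spec: EffectSpec) -> pd.DataFrame:
    """Draw ``spec.n`` records from the canonical schema.

    Quantitative features are uniform over their documented ranges,
    categorical features uniform over their level sets.  Each requested
    raw label is

    ``100 + sum(effect * carrier) + sum(interaction * carrier_a * carrier_b)
    + N(0, noise_sd)``

    clipped at 0 (raw biological measurements cannot be negative), with
    ``control_<label> = 100``.  Identical seeds give identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    cols: dict[str, np.ndarray | list] = {}

    for feat in FEATURES:
        if feat in QUANTITATIVE_RANGES:
            lo, hi, _ = QUANTITATIVE_RANGES[feat]
            cols[feat] = rng.uniform(lo, hi, size=n)
        elif feat == TYPE_FEATURE:
            cols[feat] = rng.choice(sorted(NP_TYPES), size=n)
        elif feat == SHAPE_FEATURE:
            cols[feat] = rng.choice(sorted(SHAPE_LEVELS), size=n)
        else:
            cols[feat] = rng.choice(sorted(ONE_HOT_LEVELS[feat]), size=n)

    records = pd.DataFrame(cols)

    signal = np.zeros(n)
    for feat, eff in spec.effects.items():
        signal = signal + eff * _feature_signal(records, feat, spec.standardize)
    for a, b, eff in spec.interactions:
        signal = signal + eff * (
            _feature_signal(records, a, spec.standardize)
            * _feature_signal(records, b, spec.standardize)
        )

    for label in spec.label_set:
        noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0
        raw = np.clip(100.0 + signal + noise, 0.0, None)
        records[label] = raw
        records[f"control_{label}"] = 100.0

    return records


# ---------------------------------------------------------------------------
# Raster-stack generator
# ---------------------------------------------------------------------------

#: climate profiles: layer -> (low, high) bounds of the smooth field
CLIMATE_PROFILES: dict[str, dict[str, tuple[float, float]]] = {
    "tropical": {
        "daytime_temperature": (24.0, 38.0),
        "night_temperature": (18.0, 30.0),
        "illumination_intensity": (200.0, 800.0),
        "relative_humidity": (50.0, 95.0),
        "soil_pH": (4.0, 7.5),
    },
    "temperate": {
        "daytime_temperature": (10.0, 28.0),
        "night_temperature": (2.0, 18.0),
        "illumination_intensity": (100.0, 700.0),
        "relative_humidity": (35.0, 90.0),
        "soil_pH": (4.5, 8.5),
    },
    "boreal": {
        "daytime_temperature": (2.0, 18.0),
        "night_temperature": (-5.0, 8.0),
        "illumination_intensity": (0.0, 500.0),
        "relative_humidity": (30.0, 85.0),
        "soil_pH": (4.0, 9.0),
    },
}

_SMOOTH_SIGMA = 3.0  # cells; autocorrelation scale of the synthetic fields
_MISSING_FRACTION = 0.05


def _smooth_field(rng: np.random.Generator, h: int, w: int,
                  lo: float, hi: float) -> np.ndarray:
    """Spatially autocorrelated field rescaled into [lo, hi]."""
    z = rng.standard_normal((h, w))
    z = ndimage.gaussian_filter(z, sigma=_SMOOTH_SIGMA, mode="nearest")
    zmin, zmax = z.min(), z.max()
    if zmax > zmin:
        z = (z - zmin) / (zmax - zmin)
    else:
        z = np.full((h, w), 0.5)
    return lo + z * (hi - lo)


def generate_raster_stack(
    height: int,
    width: int,
    seed: int = 0,
    climate_profile: str = "temperate",
    cellsize_arcmin: float = 30.0,
    origin_lat: float = 60.0,
    origin_lon: float = -10.0,
) -> RasterStack:
    """Synthetic environmental raster stack for projection tests.

    All layers share the grid; about 5 % of cells are masked as missing
    (jointly across layers, mirroring the deletion of incomplete grid
    cells); the crop mask and planting month derive from smooth fields so
    cropped regions are spatially contiguous.
    """
    if height < 1 or width < 1:
        raise ValueError("height and width must be >= 1")
    if climate_profile not in CLIMATE_PROFILES:
        known = ", ".join(sorted(CLIMATE_PROFILES))
        raise ValueError(
            f"unknown climate profile {climate_profile!r}; known profiles: {known}"
        )
    rng = np.random.default_rng(seed)
    bounds = CLIMATE_PROFILES[climate_profile]

    layers: dict[str, np.ndarray] = {}
    for name, (lo, hi) in bounds.items():
        layers[name] = _smooth_field(rng, height, width, lo, hi)

    crop_field = _smooth_field(rng, height, width, 0.0, 1.0)
    layers["crop_mask"] = (crop_field > np.median(crop_field)).astype(float)
    month_field = _smooth_field(rng, height, width, 1.0, 12.999)
    layers["planting_month"] = np.floor(month_field)

    missing = rng.random((height, width)) < _MISSING_FRACTION
    mask = ~missing

    geo = GeoMeta(origin_lat=origin_lat, origin_lon=origin_lon,
                  cellsize_arcmin=cellsize_arcmin)
    return RasterStack(layers=layers, geo=geo, mask=mask)
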