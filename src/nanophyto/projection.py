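"""Geospatial projection of fitted models onto environmental rasters.

Each valid crop cell of a :class:`~nanophyto.raster.RasterStack` is turned
into one experiment-style record — environmental features from the layers
(temperatures, illumination, humidity, soil class from pH), nanoparticle
and crop features from a fixed exposure scenario — encoded with the
*training* normalisation statistics and pushed through the forest.  On top
of per-label response maps the module builds a composite oxidative-stress
risk map (absolute mean of the four indicator responses, normalised to a
maximum of 1, ranked into 20 equal-count levels), temperature-scenario
shifts, and Monte-Carlo refit uncertainty maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import EncodedMatrix, assemble_design_matrix
from .forest import FittedForest, ForestSpec, fit_forest
from .raster import GeoMeta, RasterStack
from .schema import OXIDATIVE_LABELS

__all__ = [
    "classify_soil",
    "build_grid_features",
    "GridFeatures",
    "project_response",
    "ResponseMap",
    "oxidative_risk_levels",
    "RiskLevelMap",
    "ScenarioSpec",
    "apply_scenario",
    "uncertainty_map",
    "UncertaintyMap",
    "DEFAULT_FIXED_CONDITIONS",
]

_REL_UNCERTAINTY_EPS = 1e-9


# ---------------------------------------------------------------------------
# Soil classification
# ---------------------------------------------------------------------------

def classify_soil(ph: float) -> str:
    """Three-way soil class from pH: acid below 6.5, alkaline above 7.5,
    neutral on the closed interval [6.5, 7.5] (both boundaries neutral).
    """
    if not (0.0 <= ph <= 14.0):
        raise ValueError(f"pH must lie in [0, 14], got {ph}")
    if ph < 6.5:
        return "acid"
    if ph > 7.5:
        return "alkaline"
    return "neutral"


_SOIL_TO_CULTURE = {
    "acid": "acidic soil",
    "neutral": "neutral soil",
    "alkaline": "alkaline soil",
}

#: crop photosynthetic category
_CROP_CATEGORY = {"maize": "C4", "bean": "C3", "wheat": "C3"}

#: fixed exposure scenario for projection: dose and duration at the values
#: used for seedling-stage response/uptake maps, root exposure, with
#: nanoparticle physical properties set to representative mid-range values
DEFAULT_FIXED_CONDITIONS: dict[str, object] = {
    "np_shape": "sphere",
    "hollow": 0,
    "size_TEM": 30.0,
    "size_DLS": 150.0,
    "zeta_potential": -20.0,
    "purity": 99.0,
    "plant_growing_state": "seedling",
    "exposure_pathway": "root",
    "measured_tissue": "root",
    "total_dose": 50.0,
    "duration": 21.0,
    "plant_age": 21.0,
    "photoperiod": 12.0,
}


# ---------------------------------------------------------------------------
# Grid feature assembly
# ---------------------------------------------------------------------------

@dataclass
class GridFeatures:
    """Per-cell experiment records plus the grid geometry they came from."""

    records: pd.DataFrame
    rows: np.ndarray            # cell row index per record
    cols: np.ndarray            # cell column index per record
    shape: tuple[int, int]
    mask: np.ndarray            # valid crop cells (True where records exist)
    geo: GeoMeta

    @property
    def n_cells(self) -> int:
        return len(self.records)

    def to_map(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        out = np.full(self.shape, fill)
        out[self.rows, self.cols] = values
        return out


_REQUIRED_LAYERS = (
    "daytime_temperature", "night_temperature", "illumination_intensity",
    "relative_humidity", "soil_pH", "crop_mask",
)


def build_grid_features(
    stack: RasterStack,
    crop: str,
    np_type: str,
    dose: float = 50.0,
    **fixed_overrides,
) -> GridFeatures:
    """One experiment-style record per valid crop cell.

    Environmental features come from the raster layers; the soil pH layer
    is classified into acid/neutral/alkaline and mapped onto the culture
    feature; nanoparticle, crop and experimental-condition features come
    from the fixed exposure scenario (overridable by keyword).
    """
    for name in _REQUIRED_LAYERS:
        if name not in stack.layers:
            raise ValueError(f"raster stack is missing required layer {name!r}")
    valid = stack.mask & (stack.layer("crop_mask") > 0)
    rows, cols = np.where(valid)
    if len(rows) == 0:
        warnings.warn("no valid crop cells in the raster stack", stacklevel=2)

    fixed = {**DEFAULT_FIXED_CONDITIONS, **fixed_overrides,
             "total_dose": dose, "np_type": np_type}
    soil = [
        _SOIL_TO_CULTURE[classify_soil(ph)]
        for ph in stack.layer("soil_pH")[rows, cols]
    ]
    data: dict[str, object] = {
        "np_type": np_type,
        "plant_species": crop,
        "plant_category": _CROP_CATEGORY.get(crop, "C3"),
        "plant_culture": soil,
        "daytime_temperature": stack.layer("daytime_temperature")[rows, cols],
        "night_temperature": stack.layer("night_temperature")[rows, cols],
        "illumination_intensity": stack.layer("illumination_intensity")[rows, cols],
        "relative_humidity": stack.layer("relative_humidity")[rows, cols],
    }
    for key, val in fixed.items():
        data.setdefault(key, val)
    records = pd.DataFrame(data, index=range(len(rows)))
    return GridFeatures(records, rows, cols, stack.shape, valid, stack.geo)


# ---------------------------------------------------------------------------
# Response maps
# ---------------------------------------------------------------------------

@dataclass
class ResponseMap:
    """Per-cell forest predictions on the transformed label scale."""

    values: np.ndarray          # (H, W), nan off the crop mask
    mask: np.ndarray
    label: str
    np_type: str = ""
    dose: float = float("nan")
    crop: str = ""
    geo: GeoMeta | None = None

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def mean(self) -> float:
        return float(np.nanmean(self.valid_values()))


def project_response(
    forest: FittedForest,
    grid: GridFeatures,
    norm_stats: dict[str, tuple[float, float]],
    label: str = "",
) -> ResponseMap:
    """Predict every valid crop cell with a fitted per-label forest.

    Grid records are encoded with the training normalisation statistics;
    a column mismatch with the model's design matrix raises with the
    offending columns named.
    """
    enc = assemble_design_matrix(grid.records, fit_stats=norm_stats)
    model_cols = forest.structure.columns
    if enc.columns != model_cols:
        extra = sorted(set(enc.columns) - set(model_cols))
        miss = sorted(set(model_cols) - set(enc.columns))
        raise ValueError(
            f"encoded grid columns do not match the model: "
            f"unexpected={extra}, missing={miss}"
        )
    preds = forest.predict(enc.X) if grid.n_cells else np.empty(0)
    values = grid.to_map(preds)
    return ResponseMap(values, grid.mask, label or forest.structure.label,
                       str(grid.records["np_type"].iloc[0]) if grid.n_cells else "",
                       float(grid.records["total_dose"].iloc[0]) if grid.n_cells else float("nan"),
                       str(grid.records["plant_species"].iloc[0]) if grid.n_cells else "",
                       grid.geo)


# ---------------------------------------------------------------------------
# Composite oxidative-stress risk levels
# ---------------------------------------------------------------------------

@dataclass
class RiskLevelMap:
    """20-level composite oxidative-stress ranking (level 20 = highest)."""

    levels: np.ndarray          # (H, W) int, 0 off-mask
    composite: np.ndarray       # normalised composite, nan off-mask
    mask: np.ndarray
    area_percentages: pd.Series  # per level, sums to 100 over valid cells

    def percent_high_risk(self, from_level: int = 16) -> float:
        """Area share at the given level or above (default: levels 16-20)."""
        return float(self.area_percentages.loc[from_level:].sum())


def oxidative_risk_levels(
    maps: dict[str, ResponseMap] | list[ResponseMap],
    composite_mode: str = "abs_of_mean",
    binning: str = "equal_count",
) -> RiskLevelMap:
    """Composite oxidative-stress risk from the four indicator maps.

    Per cell the composite is the absolute value of the mean of the four
    transformed indicator responses (APX, H2O2, MDA, SOD)
    (``composite_mode="mean_of_abs"`` averages the absolute values
    instead).  Composites are normalised by their maximum (so the maximum
    is 1), sorted, and split into 20 equal-count levels; ties are broken
    by stable cell order, and ``binning="equal_width"`` uses value bands
    instead of ranks.
    """
    if isinstance(maps, dict):
        missing = [lb for lb in OXIDATIVE_LABELS if lb not in maps]
        if missing:
            raise ValueError(f"missing oxidative indicator maps: {missing}")
        maps = [maps[lb] for lb in OXIDATIVE_LABELS]
    if len(maps) != 4:
        raise ValueError("exactly four oxidative indicator maps are required")
    mask = maps[0].mask
    for m in maps[1:]:
        if m.values.shape != maps[0].values.shape or not np.array_equal(m.mask, mask):
            raise ValueError("indicator maps disagree on grid or mask")

    stackvals = np.stack([m.values for m in maps])
    if composite_mode == "abs_of_mean":
        composite = np.abs(stackvals.mean(axis=0))
    elif composite_mode == "mean_of_abs":
        composite = np.abs(stackvals).mean(axis=0)
    else:
        raise ValueError("composite_mode must be 'abs_of_mean' or 'mean_of_abs'")

    vals = composite[mask]
    n = len(vals)
    levels = np.zeros(maps[0].values.shape, dtype=int)
    norm = np.full(maps[0].values.shape, np.nan)

    if n == 0:
        warnings.warn("no valid cells; empty risk map", stacklevel=2)
        return RiskLevelMap(levels, norm, mask,
                            pd.Series(0.0, index=pd.RangeIndex(1, 21, name="level")))

    vmax = float(vals.max())
    if vmax == 0:
        warnings.warn("composite oxidative stress is zero everywhere; "
                      "all cells assigned level 1", stacklevel=2)
        cell_levels = np.ones(n, dtype=int)
        norm_vals = np.zeros(n)
    else:
        norm_vals = vals / vmax
        if np.ptp(norm_vals) == 0:
            cell_levels = np.full(n, 20, dtype=int)
        elif binning == "equal_count":
            order = np.argsort(norm_vals, kind="stable")
            ranks = np.empty(n, dtype=int)
            ranks[order] = np.arange(n)
            cell_levels = (ranks * 20) // n + 1
        elif binning == "equal_width":
            cell_levels = np.minimum((norm_vals * 20).astype(int) + 1, 20)
        else:
            raise ValueError("binning must be 'equal_count' or 'equal_width'")

    levels[mask] = cell_levels
    norm[mask] = norm_vals
    counts = pd.Series(cell_levels).value_counts().reindex(range(1, 21), fill_value=0)
    pct = counts / n * 100.0
    pct.index.name = "level"
    return RiskLevelMap(levels, norm, mask, pct)


# ---------------------------------------------------------------------------
# Temperature scenarios
# ---------------------------------------------------------------------------

@dataclass
class ScenarioSpec:
    """Future-climate temperature offsets added to the present-day layers.

    Offsets may be scalars or per-cell arrays (degC); named presets follow
    the shared socioeconomic pathway convention (e.g. SSP126 ... SSP585).
    """

    name: str
    daytime_offset: float | np.ndarray = 0.0
    night_offset: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        for off in (self.daytime_offset, self.night_offset):
            if not np.all(np.isfinite(off)):
                raise ValueError("scenario offsets must be finite")


def apply_scenario(stack: RasterStack, scenario: ScenarioSpec) -> RasterStack:
    """Shift the daytime/night temperature layers; all else unchanged."""
    return stack.with_layers(
        daytime_temperature=stack.layer("daytime_temperature") + scenario.daytime_offset,
        night_temperature=stack.layer("night_temperature") + scenario.night_offset,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo uncertainty
# ---------------------------------------------------------------------------

@dataclass
class UncertaintyMap:
    """Per-cell mean, SD and relative uncertainty over repeated refits."""

    mean: np.ndarray
    sd: np.ndarray
    relative: np.ndarray        # SD/mean, nan where |mean| below epsilon
    mask: np.ndarray
    runs: int
    undefined: np.ndarray = field(default=None)  # cells with |mean| < eps

    def __post_init__(self) -> None:
        if self.undefined is None:
            self.undefined = np.zeros(self.mean.shape, dtype=bool)


def uncertainty_map(
    X: EncodedMatrix,
    y: np.ndarray,
    spec: ForestSpec,
    grid: GridFeatures,
    runs: int = 200,
    seed: int = 0,
) -> UncertaintyMap:
    """Refit the forest ``runs`` times with distinct seeds and map the
    spread of per-cell predictions (SD and SD/mean).

    Cells whose mean prediction is within 1e-9 of zero get an undefined
    relative uncertainty (flagged, not infinite).
    """
    if runs < 2:
        raise ValueError("runs must be >= 2")
    y = np.asarray(y, dtype=float)
    enc = assemble_design_matrix(grid.records, fit_stats=X.norm_stats)
    preds = np.empty((runs, grid.n_cells))
    from dataclasses import replace
    for r in range(runs):
        forest = fit_forest(X, y, replace(spec, seed=seed + r))
        preds[r] = forest.predict(enc.X)
    mean = preds.mean(axis=0)
    sd = preds.std(axis=0, ddof=1)
    undefined = np.abs(mean) < _REL_UNCERTAINTY_EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(undefined, np.nan, sd / np.where(undefined, 1.0, mean))

    return UncertaintyMap(
        mean=grid.to_map(mean),
        sd=grid.to_map(sd),
        relative=grid.to_map(rel),
        mask=grid.mask,
        runs=runs,
        undefined=grid.to_map(undefined.astype(float)) == 1.0,
    )
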