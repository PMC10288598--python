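"""Preprocessing: turn raw experiment records into the numeric design matrix.

The encoding follows the nano-QSAR convention used throughout the package:

* nanoparticle **type** is replaced by four class flags (carbide / metal /
  oxide / macromolecular compound) plus the relative atomic masses of its
  first and second components (``com1``, ``com2``);
* nanoparticle **shape** is replaced by three mutually exclusive
  dimensionality flags plus a hollow flag;
* the six remaining discrete features (plant species, plant category,
  growing state, culture, exposure pathway, measured tissue) are one-hot
  encoded;
* quantitative features (and ``com1``/``com2``) are z-scored;

and labels measured relative to an untreated control are mapped to a
unitless effect score in [-1, 1)::

    y' = (y - c) / y   if y > c
    y' = (y - c) / c   if y < c
    y' = 0             if y = c

where ``y`` is the treated-group value and ``c`` the control value.  Ratio
labels (RS_ratio, TF, RCF, SCF) are already unitless and are left raw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (
    CATEGORICAL_FEATURES,
    FEATURES,
    HOLLOW_SHAPES,
    NP_TYPE_REGISTRY,
    ONE_HOT_LEVELS,
    QUANTITATIVE_FEATURES,
    RATIO_LABELS,
    SHAPE_CODE_COLUMNS,
    SHAPE_DIM_REGISTRY,
    SHAPE_FEATURE,
    TYPE_CODE_COLUMNS,
    TYPE_FEATURE,
    ShapeCode,
    TypeCode,
)

__all__ = [
    "encode_np_type",
    "encode_shape",
    "transform_label",
    "transform_label_series",
    "transport_indices",
    "assemble_design_matrix",
    "EncodedMatrix",
    "ColumnMeta",
    "write_registry_csv",
    "read_registry_csv",
]


# ---------------------------------------------------------------------------
# Type / shape coding
# ---------------------------------------------------------------------------

def encode_np_type(type_name: str, registry: dict[str, TypeCode] | None = None) -> TypeCode:
    """Encode a nanoparticle type name with the type-coding method.

    Parameters
    ----------
    type_name
        One of the registered nanoparticle types (e.g. ``"TiO2"``,
        ``"graphene"``).
    registry
        Optional replacement registry (e.g. loaded from an edited CSV).

    Returns
    -------
    TypeCode
        Class flags and component atomic masses (IUPAC weights, 2 d.p.).
    """
    reg = NP_TYPE_REGISTRY if registry is None else registry
    try:
        return reg[type_name]
    except KeyError:
        known = ", ".join(sorted(reg))
        raise KeyError(
            f"unknown nanoparticle type {type_name!r}; known types: {known}"
        ) from None


def encode_shape(shape_name: str, hollow: int = 0) -> ShapeCode:
    """Encode a shape name as dimensionality flags plus a hollow flag.

    ``hollow`` is taken from the record except for intrinsically hollow
    shapes (nanotubes), which force the flag on.
    """
    try:
        dim = SHAPE_DIM_REGISTRY[shape_name]
    except KeyError:
        known = ", ".join(sorted(SHAPE_DIM_REGISTRY))
        raise KeyError(
            f"unknown nanoparticle shape {shape_name!r}; known shapes: {known}"
        ) from None
    h = 1 if shape_name in HOLLOW_SHAPES else int(bool(hollow))
    return ShapeCode(int(dim == 0), int(dim == 1), int(dim == 2), h)


# ---------------------------------------------------------------------------
# Label transformation
# ---------------------------------------------------------------------------

def transform_label(y: float, c: float) -> float:
    """Control-relative effect score on [-1, 1).

    ``(y - c)/y`` when the treated value exceeds control, ``(y - c)/c``
    when it falls below, 0 at equality (both branch limits agree there).

    Raises
    ------
    ValueError
        If ``c <= 0`` or ``y < 0``.
    """
    if c <= 0:
        raise ValueError(f"control value must be positive, got {c}")
    if y < 0:
        raise ValueError(f"label value must be non-negative, got {y}")
    if y > c:
        return (y - c) / y
    if y < c:
        return (y - c) / c
    return 0.0


def transform_label_series(y: np.ndarray | pd.Series, c: np.ndarray | pd.Series | float) -> np.ndarray:
    """Vectorised :func:`transform_label`."""
    y = np.asarray(y, dtype=float)
    c = np.broadcast_to(np.asarray(c, dtype=float), y.shape)
    if np.any(c <= 0):
        raise ValueError("control values must be positive")
    if np.any(y < 0):
        raise ValueError("label values must be non-negative")
    out = np.zeros_like(y)
    hi = y > c
    lo = y < c
    out[hi] = (y[hi] - c[hi]) / y[hi]
    out[lo] = (y[lo] - c[lo]) / c[lo]
    return out


def transport_indices(
    shoot_conc: float | None = None,
    root_conc: float | None = None,
    media_conc: float | None = None,
) -> dict[str, float]:
    """Transport factor and concentration factors from tissue/media levels.

    TF = shoot/root, RCF = root/media, SCF = shoot/media (concentrations in
    mg/kg dry weight for tissues, mg/L or mg/kg for the growth medium).
    An index whose denominator is zero (or whose inputs are missing) is
    reported as ``nan`` rather than silently 0; negative concentrations are
    rejected.
    """
    for name, v in (("shoot", shoot_conc), ("root", root_conc), ("media", media_conc)):
        if v is not None and v < 0:
            raise ValueError(f"{name} concentration must be non-negative, got {v}")

    def ratio(num, den):
        if num is None or den is None or den == 0:
            return float("nan")
        return num / den

    return {
        "TF": ratio(shoot_conc, root_conc),
        "RCF": ratio(root_conc, media_conc),
        "SCF": ratio(shoot_conc, media_conc),
    }


# ---------------------------------------------------------------------------
# Design matrix assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnMeta:
    name: str
    source: str           # raw feature the column derives from
    kind: str             # "numeric" | "one-hot" | "type-code" | "shape-code"
    level: str | None = None   # one-hot level, if any


@dataclass
class EncodedMatrix:
    """n x p numeric design matrix with full column provenance.

    ``norm_stats`` records the mean/SD used for z-scoring so scoring-time
    matrices (grid projections, held-out folds) reuse the fitting-set
    statistics instead of recomputing them.
    """

    values: pd.DataFrame
    column_meta: list[ColumnMeta]
    norm_stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def feature_of(self, column: str) -> str:
        """Raw feature a matrix column derives from."""
        for m in self.column_meta:
            if m.name == column:
                return m.source
        raise KeyError(column)

    def columns_of(self, feature: str) -> list[str]:
        """All matrix columns derived from one raw feature."""
        out = [m.name for m in self.column_meta if m.source == feature]
        if not out:
            raise KeyError(f"no columns derive from feature {feature!r}")
        return out

    def feature_partition(self) -> dict[str, list[str]]:
        """Raw feature -> derived column names (metadata round trip)."""
        part: dict[str, list[str]] = {}
        for m in self.column_meta:
            part.setdefault(m.source, []).append(m.name)
        return part

    # -- persistence ------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.values.to_csv(path, index=False)
        side = {
            "column_meta": [m.__dict__ for m in self.column_meta],
            "norm_stats": {k: list(v) for k, v in self.norm_stats.items()},
        }
        path.with_suffix(".meta.json").write_text(json.dumps(side, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "EncodedMatrix":
        path = Path(path)
        values = pd.read_csv(path)
        side = json.loads(path.with_suffix(".meta.json").read_text())
        meta = [ColumnMeta(**m) for m in side["column_meta"]]
        stats = {k: (v[0], v[1]) for k, v in side["norm_stats"].items()}
        return cls(values, meta, stats)


def _zscore_columns() -> list[str]:
    # quantitative raw features plus the two continuous type-code components
    return list(QUANTITATIVE_FEATURES) + ["com1", "com2"]


def assemble_design_matrix(
    records: pd.DataFrame,
    fit_stats: dict[str, tuple[float, float]] | None = None,
) -> EncodedMatrix:
    """Build the numeric design matrix from a table of raw records.

    Column order is deterministic: canonical raw-feature order, with
    type-code and shape-code columns in their fixed order and one-hot
    levels in lexicographic order.  In fitting mode (``fit_stats=None``)
    z-score statistics are computed from ``records``; in scoring mode the
    supplied statistics are reused and unseen categorical levels raise.
    """
    missing = [f for f in FEATURES if f not in records.columns]
    if missing:
        raise ValueError(f"records are missing canonical features: {missing}")

    cols: dict[str, np.ndarray] = {}
    meta: list[ColumnMeta] = []
    n = len(records)

    for feat in FEATURES:
        if feat == TYPE_FEATURE:
            codes = [encode_np_type(t).as_dict() for t in records[feat]]
            for c in TYPE_CODE_COLUMNS:
                cols[c] = np.array([d[c] for d in codes], dtype=float)
                meta.append(ColumnMeta(c, feat, "type-code"))
        elif feat == SHAPE_FEATURE:
            hollow = records["hollow"] if "hollow" in records.columns else np.zeros(n)
            codes = [
                encode_shape(s, int(h)).as_dict()
                for s, h in zip(records[feat], hollow)
            ]
            for c in SHAPE_CODE_COLUMNS:
                cols[c] = np.array([d[c] for d in codes], dtype=float)
                meta.append(ColumnMeta(c, feat, "shape-code"))
        elif feat in CATEGORICAL_FEATURES:
            levels = sorted(ONE_HOT_LEVELS[feat])
            seen = set(map(str, records[feat]))
            unknown = seen - set(levels)
            if unknown:
                raise ValueError(
                    f"unseen level(s) {sorted(unknown)} for feature {feat!r}"
                )
            for lv in levels:
                name = f"{feat}={lv}"
                cols[name] = (records[feat].astype(str) == lv).to_numpy(dtype=float)
                meta.append(ColumnMeta(name, feat, "one-hot", lv))
        else:
            cols[feat] = records[feat].to_numpy(dtype=float)
            meta.append(ColumnMeta(feat, feat, "numeric"))

    values = pd.DataFrame(cols)
    if values.isna().any().any():
        bad = values.columns[values.isna().any()].tolist()
        raise ValueError(f"missing values in encoded columns: {bad}")

    # z-score quantitative columns (flags stay 0/1)
    stats: dict[str, tuple[float, float]] = {}
    for c in _zscore_columns():
        if fit_stats is not None:
            if c not in fit_stats:
                raise ValueError(f"fit_stats missing column {c!r}")
            mu, sd = fit_stats[c]
        else:
            mu = float(values[c].mean())
            sd = float(values[c].std(ddof=0))
        stats[c] = (mu, sd)
        if sd > 0:
            values[c] = (values[c] - mu) / sd
        else:
            values[c] = values[c] - mu

    return EncodedMatrix(values, meta, stats)


# ---------------------------------------------------------------------------
# Registry CSV round trip (editable registry)
# ---------------------------------------------------------------------------

def write_registry_csv(path: str | Path, registry: dict[str, TypeCode] | None = None) -> None:
    reg = NP_TYPE_REGISTRY if registry is None else registry
    rows = [{"np_type": k, **v.as_dict()} for k, v in reg.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_registry_csv(path: str | Path) -> dict[str, TypeCode]:
    df = pd.read_csv(path)
    return {
        r["np_type"]: TypeCode(
            int(r["carbide"]), int(r["metal"]), int(r["oxide"]),
            int(r["macromolecular_compound"]), float(r["com1"]), float(r["com2"]),
        )
        for _, r in df.iterrows()
    }
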