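"""Canonical schema shared by every stage of the pipeline.

One experiment record = 20 raw features (nanoparticle properties, plant
properties, experimental/environmental conditions) plus up to 13 response
labels measured relative to an untreated control (control = 100 % for
percent-scale labels).  All modules consume this single roster; the column
order defined here is the column order everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

# ---------------------------------------------------------------------------
# Feature roster (order is canonical)
# ---------------------------------------------------------------------------

#: quantitative features with their documented (min, max) ranges and units
QUANTITATIVE_RANGES: dict[str, tuple[float, float, str]] = {
    "size_TEM": (2.5, 2000.0, "nm"),
    "size_DLS": (5.0, 3000.0, "nm"),
    "zeta_potential": (-50.0, 50.0, "mV"),
    "purity": (90.0, 100.0, "%"),
    "total_dose": (0.0, 3000.0, "mg"),
    "duration": (1.0, 60.0, "d"),
    "plant_age": (1.0, 60.0, "d"),
    "daytime_temperature": (10.0, 40.0, "degC"),
    "night_temperature": (-5.0, 30.0, "degC"),
    "illumination_intensity": (0.0, 800.0, "umol m-2 s-1"),
    "photoperiod": (8.0, 16.0, "h"),
    "relative_humidity": (20.0, 95.0, "%"),
}

#: categorical features encoded by one-hot (six discrete features)
ONE_HOT_LEVELS: dict[str, tuple[str, ...]] = {
    "plant_species": ("bean", "cucumber", "lettuce", "maize", "rice", "tomato", "wheat"),
    "plant_category": ("C3", "C4"),
    "plant_growing_state": ("mature", "seed", "seedling", "vegetative"),
    "plant_culture": (
        "acidic soil",
        "alkaline soil",
        "calcareous soil",
        "hydroponic",
        "neutral soil",
    ),
    "exposure_pathway": ("leaf", "root", "seed"),
    "measured_tissue": ("leaf", "plant", "root", "shoot"),
}

#: the two specially coded categorical features
TYPE_FEATURE = "np_type"
SHAPE_FEATURE = "np_shape"

#: canonical raw-feature order (20 features)
FEATURES: tuple[str, ...] = (
    "np_type",
    "np_shape",
    "size_TEM",
    "size_DLS",
    "zeta_potential",
    "purity",
    "plant_species",
    "plant_category",
    "plant_growing_state",
    "plant_culture",
    "exposure_pathway",
    "measured_tissue",
    "total_dose",
    "duration",
    "plant_age",
    "daytime_temperature",
    "night_temperature",
    "illumination_intensity",
    "photoperiod",
    "relative_humidity",
)

QUANTITATIVE_FEATURES: tuple[str, ...] = tuple(QUANTITATIVE_RANGES)
CATEGORICAL_FEATURES: tuple[str, ...] = tuple(ONE_HOT_LEVELS)

#: which broad class each feature belongs to (used to colour network nodes)
FEATURE_CLASSES: dict[str, str] = {
    "np_type": "NP property",
    "np_shape": "NP property",
    "size_TEM": "NP property",
    "size_DLS": "NP property",
    "zeta_potential": "NP property",
    "purity": "NP property",
    "plant_species": "plant property",
    "plant_category": "plant property",
    "plant_growing_state": "plant property",
    "plant_age": "plant property",
    "plant_culture": "experimental condition",
    "exposure_pathway": "experimental condition",
    "measured_tissue": "experimental condition",
    "total_dose": "experimental condition",
    "duration": "experimental condition",
    "daytime_temperature": "experimental condition",
    "night_temperature": "experimental condition",
    "illumination_intensity": "experimental condition",
    "photoperiod": "experimental condition",
    "relative_humidity": "experimental condition",
}

# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

#: 13 response labels: 3 growth, 6 oxidative-stress/photosynthesis, 4 uptake
LABELS: tuple[str, ...] = (
    "length",
    "dry_weight",
    "RS_ratio",
    "APX",
    "H2O2",
    "MDA",
    "SOD",
    "chl_a",
    "chl_b",
    "uptake",
    "TF",
    "RCF",
    "SCF",
)

#: ratio-type labels that bypass the control-relative transformation
RATIO_LABELS: frozenset[str] = frozenset({"RS_ratio", "TF", "RCF", "SCF"})

#: the four oxidative-stress indicators entering the composite risk index
OXIDATIVE_LABELS: tuple[str, ...] = ("APX", "H2O2", "MDA", "SOD")


# ---------------------------------------------------------------------------
# Nanoparticle type registry (type-coding method)
# ---------------------------------------------------------------------------

# IUPAC standard atomic weights, two decimals
_AW = {
    "Ag": 107.87, "Au": 196.97, "Cu": 63.55, "Zn": 65.38, "Fe": 55.85,
    "Ti": 47.87, "Si": 28.09, "Ce": 140.12, "Al": 26.98, "Mg": 24.31,
    "Ni": 58.69, "O": 16.00, "C": 12.01, "H": 1.01,
}


@dataclass(frozen=True)
class TypeCode:
    """Continuous/class encoding of a nanoparticle type.

    Four mutually exclusive class flags plus the relative atomic masses of
    the first and second chemical components (``com2 = 0`` for
    single-element materials).
    """

    carbide: int
    metal: int
    oxide: int
    macromolecular_compound: int
    com1: float
    com2: float

    def __post_init__(self) -> None:
        if self.carbide + self.metal + self.oxide + self.macromolecular_compound > 1:
            raise ValueError("at most one NP class flag may be set")
        if self.com1 <= 0:
            raise ValueError("com1 must be positive")
        if self.com2 < 0:
            raise ValueError("com2 must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {
            "carbide": self.carbide,
            "metal": self.metal,
            "oxide": self.oxide,
            "macromolecular_compound": self.macromolecular_compound,
            "com1": self.com1,
            "com2": self.com2,
        }


def _metal(el: str) -> TypeCode:
    return TypeCode(0, 1, 0, 0, _AW[el], 0.0)


def _oxide(el: str) -> TypeCode:
    return TypeCode(0, 0, 1, 0, _AW[el], _AW["O"])


#: 17 nanoparticle types covered by the registry.  Carbon nanomaterials carry
#: no class flag; polystyrene is the macromolecular compound (nanoplastic)
#: with backbone carbon/hydrogen components.
NP_TYPE_REGISTRY: dict[str, TypeCode] = {
    "Ag": _metal("Ag"),
    "Au": _metal("Au"),
    "Cu": _metal("Cu"),
    "CuO": _oxide("Cu"),
    "ZnO": _oxide("Zn"),
    "Fe2O3": _oxide("Fe"),
    "Fe3O4": _oxide("Fe"),
    "TiO2": _oxide("Ti"),
    "SiO2": _oxide("Si"),
    "CeO2": _oxide("Ce"),
    "Al2O3": _oxide("Al"),
    "MgO": _oxide("Mg"),
    "NiO": _oxide("Ni"),
    "graphene": TypeCode(0, 0, 0, 0, _AW["C"], 0.0),
    "graphene_oxide": TypeCode(0, 0, 0, 0, _AW["C"], _AW["O"]),
    "MWCNT": TypeCode(0, 0, 0, 0, _AW["C"], 0.0),
    "polystyrene": TypeCode(0, 0, 0, 1, _AW["C"], _AW["H"]),
}

TYPE_CODE_COLUMNS: tuple[str, ...] = (
    "carbide", "metal", "oxide", "macromolecular_compound", "com1", "com2",
)


# ---------------------------------------------------------------------------
# Shape registry (shape-coding method)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeCode:
    """Dimensionality encoding of a nanoparticle shape.

    Exactly one of ``dim0`` (granular), ``dim1`` (one-dimensional),
    ``dim2`` (two-dimensional) is set; ``hollow`` is an independent flag.
    """

    dim0: int
    dim1: int
    dim2: int
    hollow: int

    def __post_init__(self) -> None:
        if self.dim0 + self.dim1 + self.dim2 != 1:
            raise ValueError("exactly one dimensionality flag must be set")

    def as_dict(self) -> dict[str, int]:
        return {"dim0": self.dim0, "dim1": self.dim1,
                "dim2": self.dim2, "hollow": self.hollow}


#: shape name -> dimensionality class (0 granular, 1 one-D, 2 two-D);
#: hollowness comes from the record, except tubes which are hollow by
#: construction.
SHAPE_DIM_REGISTRY: dict[str, int] = {
    "sphere": 0,
    "granular": 0,
    "quasi-spherical": 0,
    "cube": 0,
    "nanorod": 1,
    "nanowire": 1,
    "nanotube": 1,
    "nanofiber": 1,
    "nanosheet": 2,
    "nanoplate": 2,
    "film": 2,
}

#: shapes that are intrinsically hollow
HOLLOW_SHAPES: frozenset[str] = frozenset({"nanotube"})

SHAPE_CODE_COLUMNS: tuple[str, ...] = ("dim0", "dim1", "dim2", "hollow")

#: shape levels offered by the synthetic generator
SHAPE_LEVELS: tuple[str, ...] = (
    "sphere", "granular", "nanorod", "nanotube", "nanosheet",
)

NP_TYPES: tuple[str, ...] = tuple(NP_TYPE_REGISTRY)
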