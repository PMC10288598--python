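"""Model/Results front end for the per-label forest analysis.

:class:`PlantResponseForest` is built from a raw experiment table (one of
the 13 response labels at a time); ``fit()`` encodes the table, fits the
forest and returns a :class:`ForestResults` carrying the fitted structure,
goodness-of-fit diagnostics and a ``summary()`` table.  All downstream
analyses — cross-validation, the anti-overfitting battery, the four-way
importance report, interaction and similarity networks, partial
dependence, Shapley drivers and raster projection — hang off the results
object, operating on the raw tree structure the fit froze.

Typical use::

    from nanophyto import EffectSpec, generate_experiment_table
    from nanophyto.model import PlantResponseForest

    table = generate_experiment_table(EffectSpec(n=400, effects={"total_dose": -40.0}))
    model = PlantResponseForest.from_dataframe(table, label="dry_weight")
    res = model.fit()
    print(res.summary())
    imp = res.importance()
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import interpret, projection, validation
from .encoding import EncodedMatrix, assemble_design_matrix, transform_label_series
from .forest import (
    CVReport,
    FittedForest,
    ForestSpec,
    cross_validate,
    fit_comparators,
    fit_forest,
    tune_forest,
)
from .raster import RasterStack
from .schema import FEATURES, LABELS, RATIO_LABELS

__all__ = ["PlantResponseForest", "ForestResults"]


class PlantResponseForest:
    """Forest regression model of one plant-response label.

    Parameters
    ----------
    records
        Raw experiment table on the canonical 20-feature schema, with a
        ``<label>`` column (raw measurement) and, for control-relative
        labels, a ``control_<label>`` column.  Rows missing the label or
        any model input are dropped (with a recorded count), mirroring
        the deletion of incomplete records.
    label
        One of the 13 response labels.  Control-relative labels are
        transformed to the unitless effect score in [-1, 1); ratio labels
        (RS_ratio, TF, RCF, SCF) are used raw.
    spec
        Forest hyperparameters (default: 500 trees, mtry 20).
    """

    def __init__(self, records: pd.DataFrame, label: str,
                 spec: ForestSpec | None = None):
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}; choose one of {LABELS}")
        if label not in records.columns:
            raise ValueError(f"records carry no column for label {label!r}")
        self.label = label
        self.spec = spec or ForestSpec()

        needed = list(FEATURES) + [label]
        control_col = f"control_{label}"
        if label not in RATIO_LABELS:
            if control_col not in records.columns:
                raise ValueError(
                    f"label {label!r} is control-relative but records lack "
                    f"{control_col!r}"
                )
            needed.append(control_col)
        complete = records[needed].notna().all(axis=1)
        self.n_dropped = int((~complete).sum())
        self.records = records.loc[complete].reset_index(drop=True)

        if label in RATIO_LABELS:
            self.y = self.records[label].to_numpy(dtype=float)
        else:
            self.y = transform_label_series(
                self.records[label], self.records[control_col]
            )

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, label: str,
                       spec: ForestSpec | None = None) -> "PlantResponseForest":
        return cls(records, label, spec)

    # -- encoding ---------------------------------------------------------
    def encode(self) -> EncodedMatrix:
        return assemble_design_matrix(self.records)

    # -- fitting ----------------------------------------------------------
    def fit(self, spec: ForestSpec | None = None) -> "ForestResults":
        spec = spec or self.spec
        enc = self.encode()
        forest = fit_forest(enc, self.y, spec, label=self.label)
        return ForestResults(self, forest, enc)

    def tune(self, grid: list[tuple[int, int]], folds: int = 10,
             seed: int | None = None) -> tuple[ForestSpec, pd.DataFrame]:
        enc = self.encode()
        return tune_forest(enc.X, self.y, grid,
                           seed=self.spec.seed if seed is None else seed,
                           folds=folds, base_spec=self.spec)

    def cross_validate(self, learner: str = "forest", folds: int = 10,
                       seed: int | None = None,
                       leakage_free: bool = True) -> CVReport:
        """10-fold shuffle-split CV.

        With ``leakage_free=True`` the encoding (z-score statistics) is
        refit inside each training fold.
        """
        seed = self.spec.seed if seed is None else seed
        if leakage_free:
            return cross_validate(self.records, self.y, learner, self.spec,
                                  folds=folds, seed=seed)
        enc = self.encode()
        return cross_validate(enc.X, self.y, learner, self.spec,
                              folds=folds, seed=seed)

    def compare_learners(self, folds: int = 10, seed: int | None = None,
                         learners: tuple[str, ...] = ("forest", "xgb", "svm", "ann"),
                         ) -> dict[str, CVReport]:
        enc = self.encode()
        return fit_comparators(enc.X, self.y,
                               seed=self.spec.seed if seed is None else seed,
                               spec=self.spec, folds=folds, learners=learners)


@dataclass
class ForestResults:
    """Fitted forest plus every interpretation entry point."""

    model: PlantResponseForest
    forest: FittedForest
    encoded: EncodedMatrix
    _cv: CVReport | None = field(default=None, repr=False)

    # -- basic quantities -------------------------------------------------
    @property
    def label(self) -> str:
        return self.model.label

    @property
    def nobs(self) -> int:
        return len(self.model.y)

    @property
    def spec(self) -> ForestSpec:
        return self.forest.spec

    def predict(self, records: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Predict new raw records (DataFrame) or encoded rows (ndarray)."""
        if isinstance(records, pd.DataFrame):
            enc = assemble_design_matrix(records, fit_stats=self.encoded.norm_stats)
            return self.forest.predict(enc.X)
        return self.forest.predict(np.asarray(records, dtype=float))

    def training_r2(self) -> float:
        return self.forest.training_r2()

    def oob_r2(self) -> float:
        return self.forest.oob_r2()

    def cv(self, folds: int = 10, seed: int | None = None) -> CVReport:
        if self._cv is None:
            self._cv = self.model.cross_validate(folds=folds, seed=seed)
        return self._cv

    def summary(self, cv: bool = False) -> str:
        lines = [
            f"Plant response forest: label = {self.label}",
            "=" * 46,
            f"n observations        {self.nobs}",
            f"n dropped (missing)   {self.model.n_dropped}",
            f"encoded columns       {len(self.encoded.columns)}",
            f"trees / mtry          {self.spec.ntree} / {self.spec.mtry}",
            f"training R2           {self.training_r2():.3f}",
            f"OOB R2                {self.oob_r2():.3f}",
        ]
        if cv:
            rep = self.cv()
            lines.append(
                f"CV R2 (10-fold)       {rep.mean_r2:.3f} +/- {rep.sd_r2:.3f}"
            )
            lines.append(
                f"CV RMSE               {rep.mean_rmse:.3f} +/- {rep.sd_rmse:.3f}"
            )
        return "\n".join(lines)

    # -- validation battery -----------------------------------------------
    def permutation_test(self, **kw) -> validation.PermutationReport:
        return validation.permutation_test(
            self.encoded.X, self.model.y, self.spec, **kw
        )

    def feature_shuffle_test(self, **kw) -> pd.DataFrame:
        return validation.feature_shuffle_test(
            self.encoded.values, self.model.y, self.spec, **kw
        )

    def sbs_select(self, **kw) -> validation.SelectionTrajectory:
        return validation.sbs_select(
            self.encoded.values, self.model.y, self.spec, **kw
        )

    # -- interpretation ---------------------------------------------------
    def importance(self, seed: int = 0, **kw) -> pd.DataFrame:
        return interpret.multiway_importance(self.forest, seed=seed, **kw)

    def interaction_network(self, top_k: int = 50) -> interpret.InteractionNetwork:
        from .schema import FEATURE_CLASSES
        classes = {
            m.name: FEATURE_CLASSES.get(m.source, "unknown")
            for m in self.encoded.column_meta
        }
        return interpret.interaction_network(self.forest, top_k=top_k,
                                             node_classes=classes)

    def similarity_network(self, threshold_multiple: float = 3.0
                           ) -> interpret.ProximitySimilarity:
        return interpret.similarity_network(self.forest,
                                            threshold_multiple=threshold_multiple)

    def partial_dependence(self, features: list[str],
                           grid: list[tuple[float, float, int]],
                           **kw) -> interpret.PDGrid:
        """PD on raw-unit grids (z-scoring handled via the fit statistics)."""
        return interpret.partial_dependence(
            self.forest, features, grid,
            norm_stats=self.encoded.norm_stats, label=self.label, **kw
        )

    def shapley_drivers(self, records: pd.DataFrame | np.ndarray,
                        candidate_features: list[str], **kw) -> pd.DataFrame:
        if isinstance(records, pd.DataFrame):
            enc = assemble_design_matrix(records, fit_stats=self.encoded.norm_stats)
            records = enc.X
        return interpret.shapley_drivers(self.forest, records,
                                         candidate_features, **kw)

    # -- projection -------------------------------------------------------
    def project(self, stack: RasterStack, crop: str, np_type: str,
                dose: float = 50.0, **fixed) -> projection.ResponseMap:
        grid = projection.build_grid_features(stack, crop, np_type, dose, **fixed)
        return projection.project_response(self.forest, grid,
                                           self.encoded.norm_stats,
                                           label=self.label)

    def uncertainty(self, stack: RasterStack, crop: str, np_type: str,
                    dose: float = 50.0, runs: int = 200, seed: int = 0,
                    **fixed) -> projection.UncertaintyMap:
        grid = projection.build_grid_features(stack, crop, np_type, dose, **fixed)
        return projection.uncertainty_map(self.encoded, self.model.y,
                                          self.spec, grid, runs=runs, seed=seed)

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Persist the tree structure as a documented JSON dump."""
        self.forest.structure.to_json(Path(path))

    # -- plotting ---------------------------------------------------------
    def plot_partial_dependence(self, pd_grid: interpret.PDGrid, ax=None):
        """Line (1D) or heat map (2D) of a partial-dependence grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if len(pd_grid.features) == 1:
            ax.plot(pd_grid.axes[0], pd_grid.values)
            ax.set_xlabel(pd_grid.features[0])
            ax.set_ylabel(f"partial dependence ({pd_grid.label})")
        else:
            im = ax.pcolormesh(pd_grid.axes[1], pd_grid.axes[0], pd_grid.values,
                               shading="nearest")
            ax.set_xlabel(pd_grid.features[1])
            ax.set_ylabel(pd_grid.features[0])
            ax.figure.colorbar(im, ax=ax, label=f"PD ({pd_grid.label})")
        return ax

    def plot_map(self, response_map: projection.ResponseMap, ax=None):
        """Raster heat map of a projected response."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(response_map.values, interpolation="nearest")
        ax.figure.colorbar(im, ax=ax, label=response_map.label)
        ax.set_title(
            f"{response_map.label}: {response_map.np_type} "
            f"{response_map.dose:g} mg on {response_map.crop}"
        )
        return ax
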