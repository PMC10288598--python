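"""Random-forest regression with full structural transparency.

Forests are fitted with scikit-learn's ``RandomForestRegressor`` (variance
reduction splits, bootstrap resampling) and then frozen into a plain-array
:class:`ForestStructure`: per node the split column, threshold, children,
depth, impurity and sample weight; per tree the in-bag multiset and
out-of-bag (OOB) row set.  Every interpretability computation in this
package (importance, co-occurrence, minimal depth, proximity, partial
dependence, Shapley drivers) runs on this structure, never on fitted-model
internals, and the structure round-trips through JSON so a persisted model
can be interrogated without the fitting library.

Comparator learners (gradient-boosted trees, RBF support-vector
regression, a two-layer neural network) are evaluated under the identical
10-fold shuffle-split protocol for benchmark tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import ShuffleSplit
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .encoding import EncodedMatrix, assemble_design_matrix
from .schema import FEATURES

__all__ = [
    "ForestSpec",
    "TreeStructure",
    "ForestStructure",
    "FittedForest",
    "fit_forest",
    "oob_fraction",
    "cross_validate",
    "tune_forest",
    "fit_comparators",
    "CVReport",
    "r2_score",
    "rmse",
]


# ---------------------------------------------------------------------------
# Specs and reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForestSpec:
    """Forest hyperparameters.

    ``ntree`` trees, ``mtry`` features tried per split (capped at the
    number of encoded columns), minimum leaf size 1, unlimited depth by
    default.
    """

    ntree: int = 500
    mtry: int = 20
    seed: int = 0
    min_leaf: int = 1
    max_depth: int | None = None

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")


def r2_score(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values are constant; R^2 undefined")
    ss_res = float(np.sum((y_obs - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.sqrt(np.mean((y_obs - y_pred) ** 2)))


@dataclass
class CVReport:
    """Per-fold R^2/RMSE for one learner under the shared fold scheme."""

    learner: str
    fold_r2: list[float]
    fold_rmse: list[float]
    spec: ForestSpec | None = None

    @property
    def n_folds(self) -> int:
        return len(self.fold_r2)

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.fold_r2))

    @property
    def sd_r2(self) -> float:
        return float(np.std(self.fold_r2, ddof=1)) if len(self.fold_r2) > 1 else 0.0

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.fold_rmse))

    @property
    def sd_rmse(self) -> float:
        return float(np.std(self.fold_rmse, ddof=1)) if len(self.fold_rmse) > 1 else 0.0

    def summary(self) -> str:
        return (
            f"{self.learner}: R2 = {self.mean_r2:.3f} +/- {self.sd_r2:.3f}, "
            f"RMSE = {self.mean_rmse:.3f} +/- {self.sd_rmse:.3f} "
            f"({self.n_folds} folds)"
        )


# ---------------------------------------------------------------------------
# Frozen tree/forest structure
# ---------------------------------------------------------------------------

@dataclass
class TreeStructure:
    """One regression tree as flat arrays (node 0 = root, -1 = no child).

    ``feature[i] = -1`` marks a leaf; ``value[i]`` is the leaf prediction
    (mean of in-bag rows reaching the leaf); ``impurity`` is node variance
    and ``n_node`` the (weighted) number of in-bag rows at the node.
    """

    feature: np.ndarray       # int, -1 at leaves
    threshold: np.ndarray     # float
    left: np.ndarray          # int child ids, -1 at leaves
    right: np.ndarray
    value: np.ndarray         # float leaf/node prediction
    impurity: np.ndarray      # float
    n_node: np.ndarray        # float weighted sample count
    depth: np.ndarray = None  # int, computed if absent

    def __post_init__(self) -> None:
        if self.depth is None:
            self.depth = self._compute_depths()

    def _compute_depths(self) -> np.ndarray:
        depth = np.zeros(len(self.feature), dtype=int)
        stack = [(0, 0)]
        while stack:
            node, d = stack.pop()
            depth[node] = d
            if self.left[node] >= 0:
                stack.append((self.left[node], d + 1))
                stack.append((self.right[node], d + 1))
        return depth

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    @property
    def max_depth(self) -> int:
        return int(self.depth.max())

    def is_leaf(self) -> np.ndarray:
        return self.feature < 0

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf index reached by each row (vectorised level-wise descent)."""
        X = np.asarray(X, dtype=float)
        node = np.zeros(len(X), dtype=int)
        while True:
            f = self.feature[node]
            active = f >= 0
            if not active.any():
                return node
            idx = np.where(active)[0]
            fa = f[idx]
            go_left = X[idx, fa] <= self.threshold[node[idx]]
            node[idx] = np.where(go_left, self.left[node[idx]], self.right[node[idx]])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.value[self.apply(X)]

    def split_features(self) -> np.ndarray:
        """Distinct feature indices used for splitting in this tree."""
        return np.unique(self.feature[self.feature >= 0])


@dataclass
class ForestStructure:
    """A forest as a list of :class:`TreeStructure` plus resampling records.

    ``inbag[t]`` is the per-row bootstrap multiplicity for tree ``t``;
    ``oob[t]`` the row indices with multiplicity 0.  Their union is always
    the full row set and their intersection empty.
    """

    trees: list[TreeStructure]
    inbag: list[np.ndarray]   # per-tree multiplicity, shape (n,)
    n_rows: int
    columns: list[str]
    label: str = ""

    @property
    def ntree(self) -> int:
        return len(self.trees)

    def oob(self, t: int) -> np.ndarray:
        return np.where(self.inbag[t] == 0)[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Forest prediction: arithmetic mean of tree predictions."""
        X = np.asarray(X, dtype=float)
        acc = np.zeros(len(X))
        for tree in self.trees:
            acc += tree.predict(X)
        return acc / self.ntree

    def apply(self, X: np.ndarray) -> np.ndarray:
        """(n, ntree) leaf ids."""
        X = np.asarray(X, dtype=float)
        return np.column_stack([t.apply(X) for t in self.trees])

    def oob_predictions(self, X: np.ndarray) -> np.ndarray:
        """Mean over trees for which each row is out of bag (nan if none)."""
        X = np.asarray(X, dtype=float)
        total = np.zeros(len(X))
        count = np.zeros(len(X))
        for t, tree in enumerate(self.trees):
            rows = self.oob(t)
            if len(rows):
                total[rows] += tree.predict(X[rows])
                count[rows] += 1
        with np.errstate(invalid="ignore"):
            return np.where(count > 0, total / np.maximum(count, 1), np.nan)

    # -- persistence ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "label": self.label,
            "columns": self.columns,
            "n_rows": self.n_rows,
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "value": t.value.tolist(),
                    "impurity": t.impurity.tolist(),
                    "n_node": t.n_node.tolist(),
                }
                for t in self.trees
            ],
            "inbag": [b.tolist() for b in self.inbag],
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ForestStructure":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                        and source.strip().endswith(".json")):
            source = Path(source).read_text()
        doc = json.loads(source)
        trees = [
            TreeStructure(
                feature=np.asarray(t["feature"], dtype=int),
                threshold=np.asarray(t["threshold"], dtype=float),
                left=np.asarray(t["left"], dtype=int),
                right=np.asarray(t["right"], dtype=int),
                value=np.asarray(t["value"], dtype=float),
                impurity=np.asarray(t["impurity"], dtype=float),
                n_node=np.asarray(t["n_node"], dtype=float),
            )
            for t in doc["trees"]
        ]
        inbag = [np.asarray(b, dtype=int) for b in doc["inbag"]]
        return cls(trees, inbag, doc["n_rows"], doc["columns"], doc["label"])


@dataclass
class FittedForest:
    """A fitted forest: frozen structure, training data view and spec."""

    structure: ForestStructure
    spec: ForestSpec
    X: np.ndarray
    y: np.ndarray
    column_meta: list = field(default_factory=list)

    @property
    def ntree(self) -> int:
        return self.structure.ntree

    @property
    def columns(self) -> list[str]:
        return self.structure.columns

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.structure.predict(X)

    def training_r2(self) -> float:
        return r2_score(self.y, self.predict(self.X))

    def oob_r2(self) -> float:
        pred = self.structure.oob_predictions(self.X)
        ok = ~np.isnan(pred)
        return r2_score(self.y[ok], pred[ok])


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _as_matrix(X) -> tuple[np.ndarray, list[str], list]:
    if isinstance(X, EncodedMatrix):
        return X.X, X.columns, X.column_meta
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns), []
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])], []


def _freeze_sklearn_forest(rf: RandomForestRegressor, n_rows: int,
                           columns: list[str], label: str) -> ForestStructure:
    trees: list[TreeStructure] = []
    inbag: list[np.ndarray] = []
    for est, samples in zip(rf.estimators_, rf.estimators_samples_):
        t = est.tree_
        feature = t.feature.copy()
        feature[feature < 0] = -1
        trees.append(
            TreeStructure(
                feature=feature.astype(int),
                threshold=t.threshold.copy(),
                left=t.children_left.copy().astype(int),
                right=t.children_right.copy().astype(int),
                value=t.value[:, 0, 0].copy(),
                impurity=t.impurity.copy(),
                n_node=t.weighted_n_node_samples.copy(),
            )
        )
        inbag.append(np.bincount(samples, minlength=n_rows))
    return ForestStructure(trees, inbag, n_rows, columns, label)


def fit_forest(X, y, spec: ForestSpec | None = None, label: str = "") -> FittedForest:
    """Fit a bootstrap forest of variance-reduction trees.

    ``X`` may be an :class:`~nanophyto.encoding.EncodedMatrix`, a numeric
    DataFrame or an ndarray.  ``mtry`` is capped at the column count.
    A constant label yields a warning and a forest of constant leaves.
    """
    spec = spec or ForestSpec()
    Xm, columns, meta = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if len(Xm) != len(y):
        raise ValueError("X and y are not row-aligned")
    if len(y) < 2:
        raise ValueError("need at least 2 rows")
    if np.ptp(y) == 0:
        warnings.warn("label is constant; forest will predict a constant",
                      stacklevel=2)
    p = Xm.shape[1]
    rf = RandomForestRegressor(
        n_estimators=spec.ntree,
        max_features=min(spec.mtry, p),
        min_samples_leaf=spec.min_leaf,
        max_depth=spec.max_depth,
        bootstrap=True,
        random_state=spec.seed,
        n_jobs=1,
    )
    rf.fit(Xm, y)
    structure = _freeze_sklearn_forest(rf, len(y), columns, label)
    return FittedForest(structure, spec, Xm, y, meta)


def oob_fraction(n: int) -> float:
    """Expected out-of-bag fraction ``(1 - 1/n)^n`` for bootstrap size n.

    Converges to 1/e (about 0.368) as n grows.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return float((1.0 - 1.0 / n) ** n)


# ---------------------------------------------------------------------------
# Cross-validation and comparators
# ---------------------------------------------------------------------------

def _is_raw_records(X) -> bool:
    return isinstance(X, pd.DataFrame) and set(FEATURES).issubset(X.columns)


def _make_learner(name: str, spec: ForestSpec, p: int, seed: int):
    if name == "forest":
        return RandomForestRegressor(
            n_estimators=spec.ntree, max_features=min(spec.mtry, p),
            min_samples_leaf=spec.min_leaf, max_depth=spec.max_depth,
            random_state=seed, n_jobs=1,
        )
    if name == "xgb":
        from xgboost import XGBRegressor
        return XGBRegressor(n_estimators=100, random_state=seed,
                            verbosity=0, n_jobs=1)
    if name == "svm":
        return SVR(kernel="rbf", C=1.0)
    if name == "ann":
        # two connected layers; hidden width 2(n-1) with n = feature count
        return MLPRegressor(hidden_layer_sizes=(2 * (p - 1),), solver="adam",
                            max_iter=800, random_state=seed)
    raise ValueError(f"unknown learner {name!r}; choose forest|xgb|svm|ann")


def cross_validate(
    X,
    y,
    learner: str = "forest",
    spec: ForestSpec | None = None,
    folds: int = 10,
    seed: int = 0,
    test_size: float = 0.1,
) -> CVReport:
    """10 random 90/10 shuffle splits with per-fold R^2 and RMSE.

    If ``X`` is a table of raw records, encoding (including z-score
    statistics) is refit inside each training fold so no statistic of a
    test fold leaks into training.
    """
    spec = spec or ForestSpec()
    y = np.asarray(y, dtype=float)
    raw = _is_raw_records(X)
    if not raw:
        Xm, _, _ = _as_matrix(X)
    splitter = ShuffleSplit(n_splits=folds, test_size=test_size, random_state=seed)
    n = len(y)
    if int(np.ceil(n * test_size)) < 2:
        raise ValueError("test folds would have fewer than 2 rows")

    fold_r2: list[float] = []
    fold_rmse: list[float] = []
    for k, (tr, te) in enumerate(splitter.split(np.zeros(n))):
        if raw:
            enc_tr = assemble_design_matrix(X.iloc[tr])
            enc_te = assemble_design_matrix(X.iloc[te], fit_stats=enc_tr.norm_stats)
            Xtr, Xte = enc_tr.X, enc_te.X
        else:
            Xtr, Xte = Xm[tr], Xm[te]
        model = _fit_learner_with_retry(learner, spec, Xtr, y[tr], seed + k)
        pred = model.predict(Xte)
        fold_r2.append(r2_score(y[te], pred))
        fold_rmse.append(rmse(y[te], pred))
    return CVReport(learner, fold_r2, fold_rmse, spec)


def _fit_learner_with_retry(learner: str, spec: ForestSpec,
                            Xtr: np.ndarray, ytr: np.ndarray, seed: int):
    model = _make_learner(learner, spec, Xtr.shape[1], seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xtr, ytr)
    pred = model.predict(Xtr)
    if not np.all(np.isfinite(pred)):
        if learner != "ann":
            raise RuntimeError(f"{learner} produced non-finite predictions")
        model = _make_learner(learner, spec, Xtr.shape[1], seed + 10_007)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xtr, ytr)
        if not np.all(np.isfinite(model.predict(Xtr))):
            raise RuntimeError("ann training diverged twice")
    return model


def tune_forest(
    X,
    y,
    grid: list[tuple[int, int]],
    seed: int = 0,
    folds: int = 10,
    base_spec: ForestSpec | None = None,
) -> tuple[ForestSpec, pd.DataFrame]:
    """Grid search over (ntree, mtry) maximising mean CV R^2.

    Ties are broken toward smaller ntree, then smaller mtry.  Returns the
    winning spec and the full score table.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    base = base_spec or ForestSpec(seed=seed)
    rows = []
    for ntree, mtry in grid:
        spec = replace(base, ntree=ntree, mtry=mtry, seed=seed)
        rep = cross_validate(X, y, "forest", spec, folds=folds, seed=seed)
        rows.append({"ntree": ntree, "mtry": mtry,
                     "mean_r2": rep.mean_r2, "sd_r2": rep.sd_r2,
                     "mean_rmse": rep.mean_rmse})
    table = pd.DataFrame(rows)
    order = table.sort_values(["mean_r2", "ntree", "mtry"],
                              ascending=[False, True, True],
                              kind="mergesort")
    best = order.iloc[0]
    return replace(base, ntree=int(best.ntree), mtry=int(best.mtry), seed=seed), table


def fit_comparators(
    X,
    y,
    seed: int = 0,
    spec: ForestSpec | None = None,
    folds: int = 10,
    learners: tuple[str, ...] = ("forest", "xgb", "svm", "ann"),
) -> dict[str, CVReport]:
    """Benchmark all learners under identical fold splits (shared seed)."""
    return {
        name: cross_validate(X, y, name, spec, folds=folds, seed=seed)
        for name in learners
    }
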