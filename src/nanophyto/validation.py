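"""Anti-overfitting battery for the forest models.

Three complementary diagnostics:

* **y-scrambling (permutation) test** — fractions of the training labels
  (20/40/60/80/100 %) are replaced by uniform draws from the observed
  label range, the model is refit, and the cross-validated Q^2 is
  recorded; over 5 ratios x 10 repetitions x 10 folds this yields 500 Q^2
  values.  Q^2 is regressed on the Pearson correlation between the
  permuted and original training labels; a Y-intercept below 0.05 (the
  model's extrapolated skill at zero label information) indicates the
  model is not fitting chance correlation.
* **feature-value shuffling** — permuting a feature column across rows
  destroys its information while keeping its marginal distribution; the
  drop in CV R^2 measures how much genuine information the feature
  carries.
* **sequential backward selection (SBS)** — greedy removal of the feature
  whose absence most helps (or least hurts) mean CV R^2, never below half
  the feature count; if no subset clearly beats the full set, the full
  set is retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import ShuffleSplit

from .forest import ForestSpec, cross_validate, fit_forest, r2_score

__all__ = [
    "q2_score",
    "permutation_test",
    "PermutationReport",
    "feature_shuffle_test",
    "sbs_select",
    "SelectionTrajectory",
]


def q2_score(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Cross-validated coefficient of determination.

    ``1 - SS_res / SS_tot`` with SS_tot centred on the mean of the
    observed values.  Equals 1 for a perfect predictor and 0 for the
    mean predictor; unbounded below.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_obs) != len(y_pred):
        raise ValueError("y_obs and y_pred lengths differ")
    if len(y_obs) < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(y_obs) == 0:
        raise ValueError("observed labels are constant; Q^2 undefined")
    return r2_score(y_obs, y_pred)


@dataclass
class PermutationReport:
    """All Q^2 draws of the scrambling protocol plus the intercept verdict."""

    entries: pd.DataFrame          # columns: ratio, rep, fold, label_corr, q2
    ratios: tuple[float, ...]
    reps: int
    folds: int
    slope: float
    intercept: float

    @property
    def n_values(self) -> int:
        return len(self.entries)

    @property
    def overfit(self) -> bool:
        return not (self.intercept < 0.05)

    @property
    def verdict(self) -> str:
        return "overfit" if self.overfit else "not-overfit"

    def mean_q2_by_ratio(self) -> pd.Series:
        return self.entries.groupby("ratio")["q2"].mean()


def permutation_test(
    X,
    y,
    spec: ForestSpec | None = None,
    ratios: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0),
    reps: int = 10,
    folds: int = 10,
    seed: int = 0,
    test_size: float = 0.1,
) -> PermutationReport:
    """Y-scrambling protocol: ratios x reps x folds model refits.

    For each (ratio, repetition, fold): the stated fraction of
    training-fold labels is replaced by uniform draws from
    ``[min(y), max(y)]``, the forest refit, and Q^2 computed on the
    held-out fold against the *original* labels.  Q^2 is then regressed
    on the correlation between permuted and original training labels; the
    report's verdict is "not-overfit" iff the Y-intercept is below 0.05.
    """
    spec = spec or ForestSpec()
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("label is constant; permutation test undefined")
    X = np.asarray(X, dtype=float) if not hasattr(X, "X") else X.X
    lo, hi = float(y.min()), float(y.max())
    rng = np.random.default_rng(seed)

    rows = []
    for ratio in ratios:
        for rep in range(reps):
            split_seed = int(rng.integers(0, 2**31 - 1))
            splitter = ShuffleSplit(n_splits=folds, test_size=test_size,
                                    random_state=split_seed)
            for fold, (tr, te) in enumerate(splitter.split(np.zeros(len(y)))):
                y_perm = y[tr].copy()
                k = int(round(ratio * len(tr)))
                idx = rng.choice(len(tr), size=k, replace=False)
                y_perm[idx] = rng.uniform(lo, hi, size=k)
                if np.ptp(y[tr]) > 0 and np.ptp(y_perm) > 0:
                    corr = float(np.corrcoef(y_perm, y[tr])[0, 1])
                else:
                    corr = 0.0
                forest = fit_forest(X[tr], y_perm, spec)
                q2 = q2_score(y[te], forest.predict(X[te]))
                rows.append({"ratio": ratio, "rep": rep, "fold": fold,
                             "label_corr": corr, "q2": q2})

    entries = pd.DataFrame(rows)
    reg = stats.linregress(entries["label_corr"], entries["q2"])
    return PermutationReport(entries, tuple(ratios), reps, folds,
                             float(reg.slope), float(reg.intercept))


def feature_shuffle_test(
    X,
    y,
    spec: ForestSpec | None = None,
    seed: int = 0,
    columns: list | None = None,
    folds: int = 10,
    include_all: bool = True,
    permutation: np.ndarray | None = None,
) -> pd.DataFrame:
    """CV R^2 after destroying one feature (or all features) by shuffling.

    Returns one row per tested column (plus ``__all__`` when
    ``include_all``): baseline mean R^2, shuffled mean R^2 and their
    difference.  ``permutation`` overrides the random row permutation
    (the identity permutation is a useful no-op control).
    """
    spec = spec or ForestSpec()
    Xm = np.asarray(X, dtype=float) if not hasattr(X, "X") else X.X
    names = (list(X.columns) if hasattr(X, "columns")
             else [f"x{i}" for i in range(Xm.shape[1])])
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)

    baseline = cross_validate(Xm, y, "forest", spec, folds=folds, seed=seed).mean_r2
    tested = list(range(Xm.shape[1])) if columns is None else [
        names.index(c) if isinstance(c, str) else c for c in columns
    ]

    rows = []
    for j in tested:
        perm = rng.permutation(len(y)) if permutation is None else permutation
        Xs = Xm.copy()
        Xs[:, j] = Xs[perm, j]
        r2 = cross_validate(Xs, y, "forest", spec, folds=folds, seed=seed).mean_r2
        rows.append({"column": names[j], "baseline_r2": baseline,
                     "shuffled_r2": r2, "delta_r2": r2 - baseline})
    if include_all:
        Xs = Xm.copy()
        for j in range(Xm.shape[1]):
            perm = rng.permutation(len(y)) if permutation is None else permutation
            Xs[:, j] = Xs[perm, j]
        r2 = cross_validate(Xs, y, "forest", spec, folds=folds, seed=seed).mean_r2
        rows.append({"column": "__all__", "baseline_r2": baseline,
                     "shuffled_r2": r2, "delta_r2": r2 - baseline})
    return pd.DataFrame(rows)


@dataclass
class SelectionTrajectory:
    """Backward-elimination path and the chosen feature subset."""

    steps: pd.DataFrame            # removed, remaining_size, mean_r2
    baseline_r2: float
    full_set: list[str]
    chosen: list[str]
    chosen_r2: float

    @property
    def improved(self) -> bool:
        return len(self.chosen) < len(self.full_set)


def sbs_select(
    X,
    y,
    spec: ForestSpec | None = None,
    min_features: int | None = None,
    seed: int = 0,
    folds: int = 10,
    tolerance: float = 0.005,
) -> SelectionTrajectory:
    """Greedy sequential backward selection on mean CV R^2.

    At each step the feature whose removal maximises mean CV R^2 is
    dropped (ties keep the earlier-ordered feature), never going below
    ``min_features`` (default: half the feature count, rounded up).  The
    chosen subset is the trajectory point with the best mean R^2 — unless
    no point beats the full set by more than ``tolerance``, in which case
    the full set is retained so no potentially important property is
    discarded on noise.
    """
    spec = spec or ForestSpec()
    Xm = np.asarray(X, dtype=float) if not hasattr(X, "X") else X.X
    names = (list(X.columns) if hasattr(X, "columns")
             else [f"x{i}" for i in range(Xm.shape[1])])
    y = np.asarray(y, dtype=float)
    p = Xm.shape[1]
    if p < 2:
        raise ValueError("need at least 2 features")
    if min_features is None:
        min_features = math.ceil(p / 2)
    min_features = max(1, min_features)

    baseline = cross_validate(Xm, y, "forest", spec, folds=folds, seed=seed).mean_r2
    remaining = list(range(p))
    steps = []
    best_subset = list(remaining)
    best_r2 = baseline

    while len(remaining) > min_features:
        scores = []
        for j in remaining:
            keep = [c for c in remaining if c != j]
            rep = cross_validate(Xm[:, keep], y, "forest", spec,
                                 folds=folds, seed=seed)
            scores.append((j, rep.mean_r2))
        # tie -> keep the earlier-ordered feature (remove the later one)
        drop, drop_r2 = scores[0]
        for j, r in scores[1:]:
            if r >= drop_r2:
                drop, drop_r2 = j, r
        remaining = [c for c in remaining if c != drop]
        steps.append({"removed": names[drop],
                      "remaining_size": len(remaining),
                      "mean_r2": drop_r2})
        if drop_r2 > best_r2:
            best_r2 = drop_r2
            best_subset = list(remaining)

    steps_df = pd.DataFrame(steps, columns=["removed", "remaining_size", "mean_r2"])
    if best_r2 <= baseline + tolerance:
        chosen, chosen_r2 = list(range(p)), baseline
    else:
        chosen, chosen_r2 = best_subset, best_r2
    return SelectionTrajectory(
        steps=steps_df,
        baseline_r2=baseline,
        full_set=list(names),
        chosen=[names[c] for c in chosen],
        chosen_r2=chosen_r2,
    )
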