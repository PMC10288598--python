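"""Interpretability analytics computed from raw tree structure.

Everything here consumes the frozen :class:`~nanophyto.forest.ForestStructure`
(split columns, thresholds, children, impurities, in-bag/out-of-bag rows)
rather than any fitting-library internals:

* **multiway importance** — four complementary measures per feature
  (out-of-bag permutation MSE increase normalised by its SD, summed
  node-purity increase, mean minimal depth, and a one-sided binomial
  P value on split counts), guarding against the bias of any single
  importance index;
* **interaction network** — the number of trees in which two features are
  both used for splitting, taken as the strength of their interaction;
* **proximity similarity network** — the fraction of trees in which two
  training rows land in the same terminal node, thresholded into a graph
  whose cluster density exposes heterogeneous sub-populations;
* **partial dependence** — model-average prediction over 1D/2D feature
  grids;
* **Shapley drivers** — additive per-record attribution over a small
  candidate feature set (exact coalition enumeration up to 6 candidates,
  permutation sampling above), naming the locally dominant factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .forest import FittedForest, ForestStructure

__all__ = [
    "multiway_importance",
    "interaction_network",
    "InteractionNetwork",
    "similarity_network",
    "ProximitySimilarity",
    "partial_dependence",
    "PDGrid",
    "shapley_drivers",
]


def _structure(forest) -> ForestStructure:
    return forest.structure if isinstance(forest, FittedForest) else forest


# ---------------------------------------------------------------------------
# Multiway importance
# ---------------------------------------------------------------------------

def multiway_importance(
    forest: FittedForest,
    seed: int = 0,
    absent_depth: str = "max_depth_plus_one",
) -> pd.DataFrame:
    """Four importance measures per design-matrix column.

    Returns a DataFrame indexed by column name with:

    ``mse_increase``
        Per tree, OOB MSE after permuting the column minus baseline OOB
        MSE; averaged over trees and divided by the SD of the per-tree
        differences.
    ``node_purity_increase``
        Sum over all splits on the column of the weighted impurity
        decrease (parent minus children).  Summing over columns recovers
        the forest's total impurity reduction.
    ``mean_minimal_depth``
        Tree-averaged depth of the shallowest node splitting the column;
        trees that never use it contribute their maximum depth + 1
        (``absent_depth="skip"`` averages only over trees using it).
    ``p_value``
        One-sided binomial test of the column's total split count against
        uniform selection among the p columns.

    plus ``split_count``, a ``constant`` flag for unpermutable columns,
    and a ``combined_rank`` (mean of the four single-measure ranks,
    smaller = more important).
    """
    if absent_depth not in {"max_depth_plus_one", "skip"}:
        raise ValueError("absent_depth must be 'max_depth_plus_one' or 'skip'")
    st = _structure(forest)
    X, y = forest.X, forest.y
    p = X.shape[1]
    rng = np.random.default_rng(seed)
    constant = np.array([np.ptp(X[:, j]) == 0 for j in range(p)])

    # --- OOB permutation MSE increase ---
    diffs = np.zeros((st.ntree, p))
    for t, tree in enumerate(st.trees):
        rows = st.oob(t)
        if len(rows) < 2:
            continue
        Xo = X[rows]
        base_mse = float(np.mean((y[rows] - tree.predict(Xo)) ** 2))
        for j in range(p):
            if constant[j]:
                continue
            perm = rng.permutation(len(rows))
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            diffs[t, j] = np.mean((y[rows] - tree.predict(Xp)) ** 2) - base_mse
    mean_diff = diffs.mean(axis=0)
    sd_diff = diffs.std(axis=0, ddof=1) if st.ntree > 1 else np.ones(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        mse_increase = np.where(sd_diff > 0, mean_diff / sd_diff, mean_diff)
    mse_increase[constant] = 0.0

    # --- node purity increase, minimal depth, split counts ---
    purity = np.zeros(p)
    split_count = np.zeros(p, dtype=int)
    depth_sum = np.zeros(p)
    depth_trees = np.zeros(p, dtype=int)
    for tree in st.trees:
        internal = ~tree.is_leaf()
        feats = tree.feature[internal]
        dec = (
            tree.n_node[internal] * tree.impurity[internal]
            - tree.n_node[tree.left[internal]] * tree.impurity[tree.left[internal]]
            - tree.n_node[tree.right[internal]] * tree.impurity[tree.right[internal]]
        )
        np.add.at(purity, feats, dec)
        np.add.at(split_count, feats, 1)
        depths = tree.depth[internal]
        mindepth = np.full(p, np.inf)
        np.minimum.at(mindepth, feats, depths)
        used = np.isfinite(mindepth)
        depth_sum[used] += mindepth[used]
        depth_trees[used] += 1
        if absent_depth == "max_depth_plus_one":
            depth_sum[~used] += tree.max_depth + 1
            depth_trees[~used] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_minimal_depth = np.where(depth_trees > 0, depth_sum / np.maximum(depth_trees, 1), np.nan)

    total_splits = int(split_count.sum())
    p_values = np.ones(p)
    if total_splits > 0:
        for j in range(p):
            p_values[j] = stats.binomtest(
                int(split_count[j]), total_splits, 1.0 / p, alternative="greater"
            ).pvalue

    report = pd.DataFrame(
        {
            "mse_increase": mse_increase,
            "node_purity_increase": purity,
            "mean_minimal_depth": mean_minimal_depth,
            "p_value": p_values,
            "split_count": split_count,
            "constant": constant,
        },
        index=pd.Index(st.columns, name="column"),
    )
    ranks = pd.DataFrame(
        {
            "mse": report["mse_increase"].rank(ascending=False),
            "purity": report["node_purity_increase"].rank(ascending=False),
            "depth": report["mean_minimal_depth"].rank(ascending=True),
            "p": report["p_value"].rank(ascending=True),
        }
    )
    report["combined_rank"] = ranks.mean(axis=1)
    return report


# ---------------------------------------------------------------------------
# Interaction (co-occurrence) network
# ---------------------------------------------------------------------------

@dataclass
class InteractionNetwork:
    """Top-k feature pairs by per-tree co-occurrence count."""

    edges: pd.DataFrame        # feature_a, feature_b, count
    ntree: int
    top_k: int
    node_classes: dict[str, str]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for _, r in self.edges.iterrows():
            g.add_edge(r.feature_a, r.feature_b, weight=int(r["count"]))
        nx.set_node_attributes(
            g, {n: self.node_classes.get(n, "unknown") for n in g.nodes}, "feature_class"
        )
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_csv(self, path) -> None:
        self.edges.to_csv(path, index=False)


def interaction_network(
    forest,
    top_k: int = 50,
    node_classes: dict[str, str] | None = None,
) -> InteractionNetwork:
    """Feature-feature interaction strengths from tree co-membership.

    For every unordered pair of columns, counts the number of trees in
    which *both* are used as split variables (presence per tree, not path
    multiplicity).  Pairs are ranked by count; ties at the cut are broken
    by lexicographic pair name so the edge list is reproducible.
    """
    st = _structure(forest)
    counts: dict[tuple[int, int], int] = {}
    for tree in st.trees:
        used = sorted(int(f) for f in tree.split_features())
        for a, b in combinations(used, 2):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    names = st.columns
    rows = [
        {"feature_a": names[a], "feature_b": names[b], "count": c}
        for (a, b), c in counts.items()
    ]
    edges = pd.DataFrame(rows, columns=["feature_a", "feature_b", "count"])
    if len(edges):
        edges = edges.sort_values(
            ["count", "feature_a", "feature_b"],
            ascending=[False, True, True], kind="mergesort",
        ).head(top_k).reset_index(drop=True)
    return InteractionNetwork(edges, st.ntree, top_k, node_classes or {})


# ---------------------------------------------------------------------------
# Proximity similarity network
# ---------------------------------------------------------------------------

@dataclass
class ProximitySimilarity:
    """Row-row proximity matrix and its thresholded similarity graph."""

    proximity: np.ndarray      # (n, n), symmetric, diagonal 1
    edges: pd.DataFrame        # i, j, proximity
    threshold: float
    threshold_multiple: float

    def to_networkx(self, classes: list | None = None) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.proximity)))
        for _, r in self.edges.iterrows():
            g.add_edge(int(r.i), int(r.j), weight=float(r.proximity))
        if classes is not None:
            nx.set_node_attributes(g, dict(enumerate(classes)), "node_class")
        return g

    def cluster_density(self, classes: list) -> pd.DataFrame:
        """Within-class edge fraction per class (network tightness)."""
        classes = list(classes)
        rows = []
        for cls in sorted(set(classes)):
            members = [i for i, c in enumerate(classes) if c == cls]
            if len(members) < 2:
                rows.append({"node_class": cls, "n_nodes": len(members),
                             "density": 0.0})
                continue
            mset = set(members)
            within = sum(
                1 for _, r in self.edges.iterrows()
                if int(r.i) in mset and int(r.j) in mset
            )
            possible = len(members) * (len(members) - 1) / 2
            rows.append({"node_class": cls, "n_nodes": len(members),
                         "density": within / possible})
        return pd.DataFrame(rows)


def similarity_network(
    forest,
    X: np.ndarray | None = None,
    threshold_multiple: float = 3.0,
) -> ProximitySimilarity:
    """Proximity matrix and similarity graph of the fitting rows.

    ``proximity(i, j)`` is the fraction of trees in which rows i and j
    share a terminal node.  Edges connect pairs whose proximity exceeds
    ``threshold_multiple`` times the mean off-diagonal proximity.
    """
    st = _structure(forest)
    if X is None:
        if not isinstance(forest, FittedForest):
            raise ValueError("X is required when passing a bare structure")
        X = forest.X
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 rows")
    leaves = st.apply(X)                       # (n, ntree)
    prox = np.zeros((n, n))
    for t in range(st.ntree):
        col = leaves[:, t]
        prox += col[:, None] == col[None, :]
    prox /= st.ntree

    off = prox[~np.eye(n, dtype=bool)]
    threshold = threshold_multiple * float(off.mean())
    iu, ju = np.triu_indices(n, k=1)
    keep = prox[iu, ju] > threshold
    edges = pd.DataFrame(
        {"i": iu[keep], "j": ju[keep], "proximity": prox[iu, ju][keep]}
    )
    return ProximitySimilarity(prox, edges, threshold, threshold_multiple)


# ---------------------------------------------------------------------------
# Partial dependence
# ---------------------------------------------------------------------------

@dataclass
class PDGrid:
    """Partial-dependence values on a 1D or 2D grid (axes in raw units)."""

    features: tuple[str, ...]
    axes: tuple[np.ndarray, ...]
    values: np.ndarray
    label: str = ""
    n_background: int = 0

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        if len(self.features) == 1:
            return pd.DataFrame({self.features[0]: self.axes[0],
                                 "pd": self.values})
        a, b = np.meshgrid(self.axes[0], self.axes[1], indexing="ij")
        return pd.DataFrame({self.features[0]: a.ravel(),
                             self.features[1]: b.ravel(),
                             "pd": self.values.ravel()})


def _grid_points(lo: float, hi: float, steps: int) -> np.ndarray:
    """``steps`` points starting at ``lo`` with step ``(hi - lo)/steps``.

    E.g. a 0-50 mg dose grid in 100 steps of 0.5 mg gives
    0, 0.5, ..., 49.5 — exactly 100 evaluation points.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    step = (hi - lo) / steps
    return lo + step * np.arange(steps)


def partial_dependence(
    forest,
    features: list[str],
    grid: list[tuple[float, float, int]],
    X: np.ndarray | None = None,
    norm_stats: dict[str, tuple[float, float]] | None = None,
    max_background: int = 500,
    seed: int = 0,
    label: str = "",
) -> PDGrid:
    """Model-average prediction over a 1D or 2D feature grid.

    For each grid point the feature column(s) are overwritten across a
    background sample of training rows and the forest predictions
    averaged.  Grid bounds are given in raw units; ``norm_stats``
    (fitting-set mean/SD per column) converts them to the z-scored design
    scale while the reported axes stay raw.  Two-feature grids are
    evaluated on the full cross product.
    """
    st = _structure(forest)
    if len(features) not in (1, 2) or len(grid) != len(features):
        raise ValueError("give 1 or 2 features with one (min, max, steps) each")
    cols = []
    for f in features:
        if f not in st.columns:
            raise KeyError(f"feature {f!r} is not a model input column")
        cols.append(st.columns.index(f))
    if X is None:
        if not isinstance(forest, FittedForest):
            raise ValueError("X is required when passing a bare structure")
        X = forest.X
    rng = np.random.default_rng(seed)
    if len(X) > max_background:
        X = X[rng.choice(len(X), size=max_background, replace=False)]

    axes_raw = tuple(_grid_points(lo, hi, steps) for lo, hi, steps in grid)

    def to_model_scale(feature: str, vals: np.ndarray) -> np.ndarray:
        if norm_stats and feature in norm_stats:
            mu, sd = norm_stats[feature]
            return (vals - mu) / sd if sd > 0 else vals - mu
        return vals

    axes_model = tuple(to_model_scale(f, a) for f, a in zip(features, axes_raw))

    # evaluate all grid points in one stacked prediction (chunked for memory)
    B = len(X)
    if len(features) == 1:
        points = axes_model[0][:, None]
        out_shape: tuple[int, ...] = (len(axes_model[0]),)
    else:
        a, b = np.meshgrid(axes_model[0], axes_model[1], indexing="ij")
        points = np.column_stack([a.ravel(), b.ravel()])
        out_shape = (len(axes_model[0]), len(axes_model[1]))

    vals = np.empty(len(points))
    chunk = max(1, 500_000 // max(B, 1))
    for start in range(0, len(points), chunk):
        block_pts = points[start:start + chunk]
        work = np.repeat(X[None, :, :], len(block_pts), axis=0)
        for k, c in enumerate(cols):
            work[:, :, c] = block_pts[:, k][:, None]
        preds = st.predict(work.reshape(-1, X.shape[1]))
        vals[start:start + chunk] = preds.reshape(len(block_pts), B).mean(axis=1)
    return PDGrid(tuple(features), axes_raw, vals.reshape(out_shape), label, len(X))


# ---------------------------------------------------------------------------
# Shapley drivers
# ---------------------------------------------------------------------------

def shapley_drivers(
    forest,
    records: np.ndarray,
    candidate_features: list[str],
    background: np.ndarray | None = None,
    max_background: int = 50,
    n_permutations: int = 128,
    seed: int = 0,
) -> pd.DataFrame:
    """Additive Shapley attribution of predictions to candidate features.

    The value of a coalition S is the mean prediction over background
    rows with the S columns replaced by the record's values.  With up to
    6 candidates all 2^k coalitions are enumerated (exact Shapley
    values); above that, permutation sampling is used.  The attributions
    plus the baseline (mean background prediction) sum to the record's
    coalition-complete value; the main driver is the candidate with the
    largest absolute attribution.
    """
    st = _structure(forest)
    if not candidate_features:
        raise ValueError("candidate feature set is empty")
    cols = []
    for f in candidate_features:
        if f not in st.columns:
            raise KeyError(f"candidate {f!r} is not a model input column")
        cols.append(st.columns.index(f))
    if background is None:
        if not isinstance(forest, FittedForest):
            raise ValueError("background is required when passing a bare structure")
        background = forest.X
    rng = np.random.default_rng(seed)
    if len(background) > max_background:
        background = background[
            rng.choice(len(background), size=max_background, replace=False)
        ]
    records = np.atleast_2d(np.asarray(records, dtype=float))
    k = len(cols)

    if k <= 6:
        phi = _exact_shapley(st, records, cols, background)
    else:
        phi = _sampled_shapley(st, records, cols, background, n_permutations, rng)

    baseline = float(st.predict(background).mean())
    # full-coalition value per record, computed directly (so the additive
    # decomposition baseline + sum(phi) = prediction is a checkable axiom)
    full = np.empty(len(records))
    for r, record in enumerate(records):
        work = background.copy()
        for j in cols:
            work[:, j] = record[j]
        full[r] = st.predict(work).mean()
    out = pd.DataFrame(phi, columns=candidate_features)
    out["baseline"] = baseline
    out["prediction"] = full
    out["main_driver"] = [
        candidate_features[int(np.argmax(np.abs(row)))] for row in phi
    ]
    return out


def _coalition_values(st, record, cols, background, subsets) -> dict[frozenset, float]:
    B = len(background)
    stacked = np.empty((len(subsets) * B, background.shape[1]))
    for s, sub in enumerate(subsets):
        block = background.copy()
        for j in sub:
            block[:, j] = record[j]
        stacked[s * B:(s + 1) * B] = block
    preds = st.predict(stacked)
    return {
        frozenset(sub): float(preds[s * B:(s + 1) * B].mean())
        for s, sub in enumerate(subsets)
    }


def _exact_shapley(st, records, cols, background) -> np.ndarray:
    k = len(cols)
    subsets = [tuple(c) for r in range(k + 1) for c in combinations(cols, r)]
    phi = np.zeros((len(records), k))
    for r, record in enumerate(records):
        v = _coalition_values(st, record, cols, background, subsets)
        for jpos, j in enumerate(cols):
            total = 0.0
            for sub in subsets:
                if j in sub:
                    continue
                s = len(sub)
                w = factorial(s) * factorial(k - s - 1) / factorial(k)
                total += w * (v[frozenset(sub + (j,))] - v[frozenset(sub)])
            phi[r, jpos] = total
    return phi


def _sampled_shapley(st, records, cols, background, n_perm, rng) -> np.ndarray:
    k = len(cols)
    phi = np.zeros((len(records), k))
    for r, record in enumerate(records):
        acc = np.zeros(k)
        for _ in range(n_perm):
            order = rng.permutation(k)
            work = background.copy()
            prev = st.predict(work).mean()
            for pos in order:
                work[:, cols[pos]] = record[cols[pos]]
                cur = st.predict(work).mean()
                acc[pos] += cur - prev
                prev = cur
        phi[r] = acc / n_perm
    return phi
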