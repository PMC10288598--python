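"""Shared fixtures: planted synthetic tables and a hand-built oracle forest."""

import numpy as np
import pytest

from nanophyto.forest import ForestSpec, ForestStructure, TreeStructure, fit_forest
from nanophyto.model import PlantResponseForest
from nanophyto.simulate import EffectSpec, generate_experiment_table


@pytest.fixture(scope="session")
def planted_table():
    """Table with a dominant dose effect, a weaker duration effect and a
    dose x duration interaction (standardized effect scale, noise SD 5)."""
    spec = EffectSpec(
        n=400,
        effects={"total_dose": -40.0, "duration": 20.0},
        interactions=[("total_dose", "duration", 15.0)],
        noise_sd=5.0,
        seed=101,
    )
    return generate_experiment_table(spec)


@pytest.fixture(scope="session")
def planted_results(planted_table):
    """Fitted forest on the planted table (small forest for speed)."""
    model = PlantResponseForest.from_dataframe(
        planted_table, "dry_weight", ForestSpec(ntree=60, seed=0)
    )
    return model.fit()


@pytest.fixture(scope="session")
def small_xy():
    """Plain numeric regression problem: 3 informative of 10 features."""
    rng = np.random.default_rng(7)
    n, p = 200, 10
    X = rng.uniform(-1, 1, size=(n, p))
    y = 3.0 * X[:, 0] - 2.0 * X[:, 1] + 1.5 * X[:, 2] + rng.normal(0, 0.3, n)
    return X, y


@pytest.fixture()
def oracle_forest():
    """Hand-built 2-tree forest over 6 rows and 3 features.

    Tree A: root splits x0 at 0.5; its left child splits x1 at 0.5;
    leaves predict -1 (x0<=.5, x1<=.5), +1 (x0<=.5, x1>.5), +2 (x0>.5).
    Tree B: root splits x2 at 0.5; leaves predict 0 (left) and +3 (right).
    Impurities and node sizes are fixed so purity increases are exactly
    enumerable.  All rows are in-bag for both trees.
    """
    tree_a = TreeStructure(
        feature=np.array([0, 1, -1, -1, -1]),
        threshold=np.array([0.5, 0.5, 0.0, 0.0, 0.0]),
        left=np.array([1, 3, -1, -1, -1]),
        right=np.array([2, 4, -1, -1, -1]),
        value=np.array([0.5, -0.33, 2.0, -1.0, 1.0]),
        impurity=np.array([5.0, 2.0, 1.0, 0.5, 0.0]),
        n_node=np.array([6.0, 3.0, 3.0, 2.0, 1.0]),
    )
    tree_b = TreeStructure(
        feature=np.array([2, -1, -1]),
        threshold=np.array([0.5, 0.0, 0.0]),
        left=np.array([1, -1, -1]),
        right=np.array([2, -1, -1]),
        value=np.array([1.0, 0.0, 3.0]),
        impurity=np.array([4.0, 1.0, 0.0]),
        n_node=np.array([6.0, 4.0, 2.0]),
    )
    inbag = [np.ones(6, dtype=int), np.ones(6, dtype=int)]
    structure = ForestStructure(
        [tree_a, tree_b], inbag, 6, ["x0", "x1", "x2"], "oracle"
    )
    X = np.array([
        [0, 0, 0],
        [0, 1, 0],
        [1, 0, 0],
        [1, 1, 1],
        [0, 0, 1],
        [1, 1, 0],
    ], dtype=float)
    return structure, X
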