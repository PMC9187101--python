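"""Bootstrap regression-tree ensemble and OOB permutation importance.

Ranks the four single ecosystem functions by how much each contributes to
predicting multifunctionality.  Trees are CART regression trees fit on
bootstrap resamples with ``mtry`` features considered per split; importance
of a feature is the mean increase in out-of-bag (OOB) mean squared error
after permuting that feature among each tree's OOB rows.  Permutation
importance is used instead of impurity importance because the latter is
biased when features are correlated.

When the response is itself an average of the features (as the MF index
is), importance reflects each function's variance/covariance contribution
to MF, not a causal weight; a log note is emitted in that case by the
pipeline layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

__all__ = ["RegressionForest", "fit_forest", "permutation_importance"]


@dataclass
class RegressionForest:
    trees: list
    oob_indices: list         # per tree, indices never drawn into its bootstrap
    feature_names: tuple
    n_trees: int
    mtry: int
    max_depth: int | None
    min_samples_leaf: int
    seed: int

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.mean([t.predict(X) for t in self.trees], axis=0)

    def oob_prediction(self, X) -> np.ndarray:
        """Per-row prediction from trees whose bootstrap excluded the row (NaN if none)."""
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        total = np.zeros(n)
        count = np.zeros(n)
        for tree, oob in zip(self.trees, self.oob_indices):
            if len(oob) == 0:
                continue
            total[oob] += tree.predict(X[oob])
            count[oob] += 1
        with np.errstate(invalid="ignore"):
            return np.where(count > 0, total / np.maximum(count, 1), np.nan)

    def oob_r2(self, X, y) -> float:
        y = np.asarray(y, dtype=float)
        pred = self.oob_prediction(X)
        ok = ~np.isnan(pred)
        sse = float(np.sum((y[ok] - pred[ok]) ** 2))
        sst = float(np.sum((y[ok] - y[ok].mean()) ** 2))
        return 1.0 - sse / sst


def _as_array(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(map(str, X.columns))
    X = np.asarray(X, dtype=float)
    return X, tuple(f"x{i}" for i in range(X.shape[1]))


def fit_forest(X, y, n_trees: int = 500, mtry: int | None = None, seed: int = 0,
               max_depth: int | None = None, min_samples_leaf: int = 5) -> RegressionForest:
    """Fit the bootstrap ensemble; fully reproducible from ``seed``.

    ``mtry`` defaults to ⌈p/3⌉ (the regression-forest convention).  OOB row
    indices are retained per tree for the permutation-importance step.
    """
    Xa, names = _as_array(X)
    y = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if n != len(y):
        raise ValueError("X and y have different lengths")
    if np.std(y) == 0:
        raise ValueError("constant response; importance is undefined")
    if mtry is None:
        mtry = math.ceil(p / 3)
    mtry = int(min(max(mtry, 1), p))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5f0]))
    trees, oob_sets = [], []
    all_idx = np.arange(n)
    for _ in range(int(n_trees)):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(all_idx, boot, assume_unique=False)
        tree = DecisionTreeRegressor(
            max_features=mtry,
            max_depth=max_depth,
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(Xa[boot], y[boot])
        trees.append(tree)
        oob_sets.append(oob)
    return RegressionForest(trees=trees, oob_indices=oob_sets, feature_names=names,
                            n_trees=int(n_trees), mtry=mtry, max_depth=max_depth,
                            min_samples_leaf=min_samples_leaf, seed=int(seed))


def permutation_importance(forest: RegressionForest, X, y, n_perm: int = 10,
                           seed: int = 0) -> pd.DataFrame:
    """OOB permutation importance and descending-score ranks.

    Importance of feature j = mean over trees and shuffles of the increase
    in that tree's OOB MSE after permuting column j among its OOB rows;
    negative means are floored at 0.  Ties rank in feature-name order.
    """
    Xa, names = _as_array(X)
    if names != forest.feature_names and isinstance(X, pd.DataFrame):
        raise ValueError("feature columns differ from those the forest was fit on")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x13f]))
    p = Xa.shape[1]
    increases = np.zeros(p)
    n_used = 0
    for tree, oob in zip(forest.trees, forest.oob_indices):
        if len(oob) < 2:
            continue
        n_used += 1
        Xo, yo = Xa[oob], y[oob]
        base = float(np.mean((tree.predict(Xo) - yo) ** 2))
        for j in range(p):
            for _ in range(int(n_perm)):
                Xp = Xo.copy()
                Xp[:, j] = Xp[rng.permutation(len(oob)), j]
                increases[j] += float(np.mean((tree.predict(Xp) - yo) ** 2)) - base
    if n_used == 0:
        raise ValueError("no tree has out-of-bag rows; cannot compute OOB importance")
    scores = np.maximum(increases / (n_used * n_perm), 0.0)
    out = pd.DataFrame({"feature": forest.feature_names, "score": scores})
    out = out.sort_values(["score", "feature"], ascending=[False, True], kind="mergesort")
    out["rank"] = np.arange(1, p + 1)
    out = out.reset_index(drop=True)
    out.attrs.update(n_trees=forest.n_trees, mtry=forest.mtry, seed=forest.seed,
                     n_perm=int(n_perm), perm_seed=int(seed))
    return out
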