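"""Balanced random-forest classification with out-of-bag error.

Morphometric sex differences in young tortoises are weak and spread over
many correlated measurements, so a random forest is used rather than a
linear discriminant (the composite features are highly multicollinear).
Sex ratios in the training tables are uneven; to keep the forest from
simply voting the majority class, each tree is grown on a *balanced*
bootstrap: x animals drawn with replacement from each class, where x is
the size of the rarer class (the ``sampsize = c(x, x)`` device).

Out-of-bag (OOB) error is computed per class from the trees that did not
sample a given animal, and variable importance is OOB permutation
importance (mean decrease in accuracy): each feature column is shuffled in
turn and the drop in OOB accuracy recorded.

Trees themselves come from scikit-learn; this module owns the balanced
bagging, the OOB bookkeeping and the importance computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

CLASSES = np.array(["F", "M"])


@dataclass
class RFConfig:
    """Forest settings.

    mtry: features considered per split (5 for combined hormone+morphology
    models, 1 for testosterone-only models).  ntrees defaults to 10^4,
    by which point OOB estimates have stabilised; larger counts are
    available for final runs.  ``balanced`` enables per-tree downsampling
    of the majority class.
    """

    mtry: int = 5
    ntrees: int = 10_000
    balanced: bool = True
    seed: int | None = None


@dataclass
class RFResult:
    oob_overall: float
    oob_female: float
    oob_male: float
    importances: pd.Series | None
    feature_names: list[str]
    trees: list = field(repr=False, default_factory=list)
    sample_indices: list = field(repr=False, default_factory=list)

    @property
    def model(self):
        return self.trees


def _as_matrix(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), list(features.columns)
    arr = np.asarray(features, dtype=float)
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def _oob_errors(votes: np.ndarray, y_idx: np.ndarray) -> tuple[float, float, float]:
    """Per-class and overall error from an (n, 2) OOB vote matrix."""
    seen = votes.sum(axis=1) > 0
    pred = np.argmax(votes, axis=1)  # tie -> class 0 ("F"), deterministic
    wrong = (pred != y_idx) & seen
    err = []
    for c in (0, 1):
        in_c = seen & (y_idx == c)
        err.append(wrong[in_c].sum() / in_c.sum() if in_c.any() else np.nan)
    overall = wrong[seen].sum() / seen.sum()
    return float(overall), float(err[0]), float(err[1])


def fit_rf_oob(
    features,
    labels,
    config: RFConfig | None = None,
    compute_importances: bool = False,
) -> RFResult:
    """Grow a balanced forest and report out-of-bag error rates.

    ``labels`` must contain both "F" and "M".  With ``balanced`` each tree
    draws the rarer-class count with replacement from *each* class, so
    per-tree class frequencies are equal by construction.
    """
    config = config or RFConfig()
    X, names = _as_matrix(features)
    y = np.asarray(labels)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains missing or non-finite values")
    y_idx = np.searchsorted(CLASSES, y)
    if set(np.unique(y)) != {"F", "M"}:
        raise ValueError("labels must contain both classes F and M")
    if not 1 <= config.mtry <= X.shape[1]:
        raise ValueError(f"mtry={config.mtry} outside [1, {X.shape[1]}]")

    idx_f = np.flatnonzero(y_idx == 0)
    idx_m = np.flatnonzero(y_idx == 1)
    x_size = min(idx_f.size, idx_m.size)
    if x_size < 2:
        raise ValueError("need at least 2 animals per class")

    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    votes = np.zeros((n, 2), dtype=np.int32)
    trees, samples = [], []
    tree_seeds = rng.integers(0, 2**31 - 1, size=config.ntrees)

    for b in range(config.ntrees):
        if config.balanced:
            take = np.concatenate([
                rng.choice(idx_f, size=x_size, replace=True),
                rng.choice(idx_m, size=x_size, replace=True),
            ])
        else:
            take = rng.integers(0, n, n)
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[take] = False
        tree = DecisionTreeClassifier(
            max_features=config.mtry, random_state=int(tree_seeds[b])
        )
        tree.fit(X[take], y_idx[take])
        if oob_mask.any():
            pred = tree.predict(X[oob_mask])
            np.add.at(votes, (np.flatnonzero(oob_mask), pred), 1)
        trees.append(tree)
        samples.append(take)

    overall, err_f, err_m = _oob_errors(votes, y_idx)
    result = RFResult(
        oob_overall=overall,
        oob_female=err_f,
        oob_male=err_m,
        importances=None,
        feature_names=names,
        trees=trees,
        sample_indices=samples,
    )
    if compute_importances:
        result.importances = _oob_permutation_importance(result, X, y_idx, rng)
    return result


def _oob_permutation_importance(
    result: RFResult, X: np.ndarray, y_idx: np.ndarray, rng: np.random.Generator
) -> pd.Series:
    """Mean decrease in OOB accuracy when each feature is permuted."""
    n = X.shape[0]

    def oob_accuracy(Xeval):
        votes = np.zeros((n, 2), dtype=np.int32)
        for tree, take in zip(result.trees, result.sample_indices):
            oob = np.ones(n, dtype=bool)
            oob[take] = False
            if oob.any():
                pred = tree.predict(Xeval[oob])
                np.add.at(votes, (np.flatnonzero(oob), pred), 1)
        seen = votes.sum(axis=1) > 0
        return np.mean(np.argmax(votes[seen], axis=1) == y_idx[seen])

    base = oob_accuracy(X)
    drops = {}
    for j, name in enumerate(result.feature_names):
        Xp = X.copy()
        Xp[:, j] = Xp[rng.permutation(n), j]
        drops[name] = base - oob_accuracy(Xp)
    return pd.Series(drops).sort_values(ascending=False)


def predict_sex_rf(result: RFResult, features) -> np.ndarray:
    """Majority-vote sex labels for new animals (columns in training order)."""
    if isinstance(features, pd.DataFrame):
        missing = [c for c in result.feature_names if c not in features.columns]
        extra = [c for c in features.columns if c not in result.feature_names]
        if missing or extra:
            raise ValueError(
                f"feature columns do not match training order; missing: {missing}, "
                f"unexpected: {extra}"
            )
        X = features[result.feature_names].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != len(result.feature_names):
            raise ValueError(
                f"expected {len(result.feature_names)} feature columns, got {X.shape[1]}"
            )
    votes = np.zeros((X.shape[0], 2), dtype=np.int64)
    for tree in result.trees:
        pred = tree.predict(X)
        np.add.at(votes, (np.arange(X.shape[0]), pred), 1)
    return CLASSES[np.argmax(votes, axis=1)]
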