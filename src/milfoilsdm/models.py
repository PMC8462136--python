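"""Random-forest SDM fitting, permutation importance, partial dependence.

Occurrence datasets get a classification forest whose predicted
suitability is the fraction of trees voting presence; the abundance
dataset gets a regression forest predicting frequency of occurrence.
Relative importance is the percent increase in mean-squared error when a
predictor is permuted on held-out rows (Brier-style MSE of predicted
suitability against the 0/1 label for occurrence models).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import train_test_split

from .pseudoabsence import ResponseDataset

__all__ = [
    "RFHyper",
    "FittedSDM",
    "fit_forest",
    "fit_sdm",
    "permutation_importance",
    "partial_dependence",
]


@dataclass(frozen=True)
class RFHyper:
    """Forest hyperparameters. Features per split follow the classic
    defaults: sqrt(p) for classification, p/3 for regression."""

    n_trees: int = 500
    max_features_classify: str | float = "sqrt"
    max_features_regress: float = 1.0 / 3.0
    max_depth: int | None = None
    min_samples_leaf: int = 1


def fit_forest(X, y, task: str, hyper: RFHyper | None = None, seed: int = 0):
    """Fit a seeded random forest on the given rows and return it."""
    hyper = hyper or RFHyper()
    if task == "classify":
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        est = RandomForestClassifier(
            n_estimators=hyper.n_trees,
            max_features=hyper.max_features_classify,
            max_depth=hyper.max_depth,
            min_samples_leaf=hyper.min_samples_leaf,
            random_state=seed,
            n_jobs=1,
        )
    elif task == "regress":
        est = RandomForestRegressor(
            n_estimators=hyper.n_trees,
            max_features=hyper.max_features_regress,
            max_depth=hyper.max_depth,
            min_samples_leaf=hyper.min_samples_leaf,
            random_state=seed,
            n_jobs=1,
        )
    else:
        raise ValueError(f"unknown task {task!r}")
    est.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
    return est


@dataclass
class FittedSDM:
    """A fitted SDM variant with its data split.

    ``predict`` returns suitability in [0, 1] for occurrence models (the
    fraction of trees voting presence) or a frequency-of-occurrence
    estimate for the abundance model.
    """

    kind: str
    includes_autocov: bool
    estimator: object
    feature_names: list[str]
    dataset: ResponseDataset
    train_idx: np.ndarray
    test_idx: np.ndarray
    task: str
    seed: int
    hyper: RFHyper = field(default_factory=RFHyper)

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names]
        X = np.asarray(X, dtype=float)
        if self.task == "classify":
            return self.estimator.predict_proba(X)[:, 1]
        return self.estimator.predict(X)

    @property
    def X(self) -> pd.DataFrame:
        return self.dataset.df[self.feature_names]

    @property
    def y(self) -> np.ndarray:
        return self.dataset.labels


def fit_sdm(
    dataset: ResponseDataset,
    include_autocov: bool = False,
    hyper: RFHyper | None = None,
    seed: int = 0,
    train_fraction: float | None = 0.7,
) -> FittedSDM:
    """Fit one SDM variant on a response dataset.

    Occurrence kinds use a class-stratified 70/30 train/test split by
    default; ``train_fraction=None`` fits on all rows (used for the
    final full-data predictions that feed functional accuracy).
    """
    hyper = hyper or RFHyper()
    features = list(dataset.feature_names)
    if include_autocov:
        if "autocov" not in dataset.df.columns:
            raise ValueError("dataset has no autocovariate column; attach it first")
        if "autocov" not in features:
            features.append("autocov")
    else:
        features = [f for f in features if f != "autocov"]
    task = "classify" if dataset.is_occurrence else "regress"
    y = dataset.labels
    n = len(y)
    idx = np.arange(n)
    if train_fraction is None:
        train_idx, test_idx = idx, np.array([], dtype=int)
    else:
        train_idx, test_idx = train_test_split(
            idx,
            train_size=train_fraction,
            random_state=seed,
            stratify=y if task == "classify" else None,
        )
    est = fit_forest(
        dataset.df.iloc[train_idx][features], y[train_idx], task, hyper, seed
    )
    return FittedSDM(
        kind=dataset.kind,
        includes_autocov=include_autocov,
        estimator=est,
        feature_names=features,
        dataset=dataset,
        train_idx=np.asarray(train_idx),
        test_idx=np.asarray(test_idx),
        task=task,
        seed=seed,
        hyper=hyper,
    )


def permutation_importance(
    model: FittedSDM,
    n_repeats: int = 10,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Percent increase in held-out MSE when each predictor is permuted.

    importance_j = 100 * (MSE_permuted_j - MSE_base) / MSE_base averaged
    over ``n_repeats`` independent permutations of column j among the
    held-out rows. Returns a table with columns covariate, importance,
    rank (1 = most important).
    """
    if len(model.test_idx) == 0:
        raise ValueError("model was fit on all rows; no held-out data for importance")
    rng = rng or np.random.default_rng()
    X = model.X.iloc[model.test_idx].to_numpy(dtype=float)
    y = model.y[model.test_idx]
    base = float(np.mean((model.predict(X) - y) ** 2))
    if base == 0:
        base = np.finfo(float).tiny
    rows = []
    for j, name in enumerate(model.feature_names):
        mses = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(X)), j]
            mses.append(np.mean((model.predict(Xp) - y) ** 2))
        rows.append((name, 100.0 * (np.mean(mses) - base) / base))
    out = pd.DataFrame(rows, columns=["covariate", "importance"])
    out["rank"] = out["importance"].rank(ascending=False, method="first").astype(int)
    return out


def partial_dependence(
    model: FittedSDM, covariate: str, grid_size: int = 50
) -> pd.DataFrame:
    """All-rows substitution partial dependence curve for one predictor.

    The grid spans the observed range of the covariate in the model's
    dataset; at each grid value the covariate column is replaced for every
    row and the mean prediction recorded.
    """
    if covariate not in model.feature_names:
        raise ValueError(f"covariate {covariate!r} not among model features")
    X = model.X.to_numpy(dtype=float)
    j = model.feature_names.index(covariate)
    grid = np.linspace(X[:, j].min(), X[:, j].max(), grid_size)
    response = np.empty(grid_size)
    for k, v in enumerate(grid):
        Xg = X.copy()
        Xg[:, j] = v
        response[k] = model.predict(Xg).mean()
    return pd.DataFrame({"grid": grid, "response": response})
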