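"""Discrimination and functional accuracy of occurrence SDMs.

Discrimination (can the model separate presences from (pseudo)absences?)
is measured by AUC, TSS and Kappa under three evaluation schemes:
nonindependent (repeated random 5-fold CV), quasi-independent (one fixed
70/30 split) and spatially blocked (folds are contiguous spatial blocks).
TSS and Kappa are threshold-dependent; the cutoff is chosen by the
sensitivity-specificity equality rule on the training fold.

Functional accuracy (does predicted suitability track observed
abundance?) is the Pearson/Spearman correlation between predictions and
frequency of occurrence, with and without the zero-abundance lakes, plus
linear quantile regressions of abundance on suitability at the 50th,
75th and 90th percentiles; the 90th-minus-50th slope difference measures
the strength of the wedge-shaped abundance-suitability relation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.quantile_regression import QuantReg

from .models import FittedSDM, RFHyper, fit_forest
from .pseudoabsence import ResponseDataset
from .spatial import assign_blocks, cross_autocovariate

__all__ = [
    "ConfusionCounts",
    "DiscriminationMetrics",
    "FunctionalMetrics",
    "WedgeFit",
    "EvaluationError",
    "roc_auc",
    "equality_threshold",
    "tss",
    "kappa",
    "evaluate_discrimination",
    "functional_accuracy",
    "wedge_quantiles",
    "SCHEMES",
]

SCHEMES = ("nonindependent", "quasi_independent", "spatially_blocked")


class EvaluationError(RuntimeError):
    """Raised when a scheme cannot produce a valid metric estimate."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @classmethod
    def from_predictions(cls, labels, predicted) -> "ConfusionCounts":
        y = np.asarray(labels, dtype=int)
        p = np.asarray(predicted, dtype=int)
        return cls(
            tp=int(((y == 1) & (p == 1)).sum()),
            fp=int(((y == 0) & (p == 1)).sum()),
            fn=int(((y == 1) & (p == 0)).sum()),
            tn=int(((y == 0) & (p == 0)).sum()),
        )

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class DiscriminationMetrics:
    auc: float
    tss: float
    kappa: float
    threshold: float
    scheme: str


@dataclass
class FunctionalMetrics:
    r_all: float
    r_nonzero: float
    rho_all: float
    rho_nonzero: float


@dataclass
class WedgeFit:
    """Quantile-regression slopes/intercepts at fixed taus and the wedge
    strength slope(0.90) - slope(0.50)."""

    taus: tuple[float, ...]
    slopes: dict[float, float]
    intercepts: dict[float, float]

    @property
    def wedge_strength(self) -> float:
        return self.slopes[0.90] - self.slopes[0.50]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tau": list(self.taus),
                "slope": [self.slopes[t] for t in self.taus],
                "intercept": [self.intercepts[t] for t in self.taus],
                "wedge_strength": self.wedge_strength,
            }
        )


def _check_two_classes(labels) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y, y == 1


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie correction."""
    y, pos = _check_two_classes(labels)
    s = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(s)
    n1 = int(pos.sum())
    n0 = len(y) - n1
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _sens_spec(scores, pos, thresholds) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    spos = np.sort(s[pos])
    sneg = np.sort(s[~pos])
    # presence assigned when score exceeds the threshold
    sens = 1.0 - np.searchsorted(spos, thresholds, side="right") / len(spos)
    spec = np.searchsorted(sneg, thresholds, side="right") / len(sneg)
    return sens, spec


def equality_threshold(scores, labels) -> float:
    """Cutoff at which sensitivity and specificity are (nearly) equal.

    Candidates are midpoints of consecutive sorted unique scores plus
    guards below/above the score range; the candidate minimizing
    |sens - spec| wins, ties broken by larger sens + spec, then by the
    lower threshold.
    """
    _, pos = _check_two_classes(labels)
    s = np.asarray(scores, dtype=float)
    u = np.unique(s)
    mids = (u[:-1] + u[1:]) / 2.0 if len(u) > 1 else np.array([])
    cand = np.concatenate([[u[0] - 1.0], mids, [u[-1] + 1.0]])
    sens, spec = _sens_spec(s, pos, cand)
    gap = np.abs(sens - spec)
    total = sens + spec
    best = np.lexsort((cand, -total, gap))[0]
    return float(cand[best])


def tss(counts: ConfusionCounts) -> float:
    """True skill statistic: sensitivity + specificity - 1."""
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise ValueError("TSS undefined: a class margin is empty")
    sens = counts.tp / (counts.tp + counts.fn)
    spec = counts.tn / (counts.tn + counts.fp)
    return sens + spec - 1.0


def kappa(counts: ConfusionCounts) -> float:
    """Cohen's kappa from the 2x2 contingency margins."""
    n = counts.n
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise ValueError("kappa undefined: an observed margin is empty")
    p_o = (counts.tp + counts.tn) / n
    p_yes = ((counts.tp + counts.fn) / n) * ((counts.tp + counts.fp) / n)
    p_no = ((counts.tn + counts.fp) / n) * ((counts.tn + counts.fn) / n)
    p_e = p_yes + p_no
    if p_e == 1.0:
        raise ValueError("kappa undefined: chance agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)


def _fold_metrics(
    X: np.ndarray,
    y: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    hyper: RFHyper,
    seed: int,
    scheme: str,
) -> DiscriminationMetrics:
    est = fit_forest(X[train], y[train], "classify", hyper, seed)
    train_scores = est.predict_proba(X[train])[:, 1]
    test_scores = est.predict_proba(X[test])[:, 1]
    thr = equality_threshold(train_scores, y[train])
    counts = ConfusionCounts.from_predictions(y[test], test_scores > thr)
    return DiscriminationMetrics(
        auc=roc_auc(test_scores, y[test]),
        tss=tss(counts),
        kappa=kappa(counts),
        threshold=thr,
        scheme=scheme,
    )


def evaluate_discrimination(
    dataset: ResponseDataset,
    scheme: str,
    hyper: RFHyper | None = None,
    seed: int = 0,
    n_folds: int = 5,
    n_iterations: int = 50,
    block_side: float = 10.0,
    k_folds: int = 5,
    include_autocov: bool = False,
) -> DiscriminationMetrics:
    """Average AUC/TSS/Kappa of an occurrence dataset under one scheme.

    nonindependent: ``n_iterations`` repeats of stratified ``n_folds``-fold
    CV, metrics per held-out fold then averaged over all folds.
    quasi_independent: a single stratified 70/30 split.
    spatially_blocked: folds from square spatial blocks of side
    ``block_side``; folds whose test part has one class are skipped with a
    warning, and the scheme fails if at least half are skipped.
    """
    from sklearn.model_selection import StratifiedKFold, train_test_split

    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    hyper = hyper or RFHyper()
    features = list(dataset.feature_names)
    if not include_autocov:
        features = [f for f in features if f != "autocov"]
    X = dataset.df[features].to_numpy(dtype=float)
    y = dataset.labels
    if len(np.unique(y)) < 2:
        raise EvaluationError("dataset has a single class")
    rng = np.random.default_rng(seed)
    folds: list[tuple[np.ndarray, np.ndarray]] = []
    if scheme == "nonindependent":
        for it in range(n_iterations):
            skf = StratifiedKFold(
                n_splits=n_folds, shuffle=True,
                random_state=int(rng.integers(2**31)),
            )
            folds.extend(skf.split(X, y))
    elif scheme == "quasi_independent":
        train, test = train_test_split(
            np.arange(len(y)), train_size=0.7,
            random_state=int(rng.integers(2**31)), stratify=y,
        )
        folds.append((train, test))
    else:
        blocks = assign_blocks(dataset.coords, block_side, k_folds, rng)
        fold_ids = blocks.folds
        for f in range(1, k_folds + 1):
            test = np.flatnonzero(fold_ids == f)
            train = np.flatnonzero(fold_ids != f)
            folds.append((train, test))

    results = []
    skipped = 0
    for train, test in folds:
        if len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2:
            skipped += 1
            warnings.warn("fold with a single class skipped")
            continue
        results.append(
            _fold_metrics(X, y, train, test, hyper, int(rng.integers(2**31)), scheme)
        )
    if skipped >= len(folds) / 2.0 or not results:
        raise EvaluationError(
            f"{skipped}/{len(folds)} folds skipped for single-class data"
        )
    return DiscriminationMetrics(
        auc=float(np.mean([m.auc for m in results])),
        tss=float(np.mean([m.tss for m in results])),
        kappa=float(np.mean([m.kappa for m in results])),
        threshold=float(np.mean([m.threshold for m in results])),
        scheme=scheme,
    )


def suitability_on_table(model: FittedSDM, table: pd.DataFrame) -> np.ndarray:
    """Model predictions for all surveyed lakes of a lake table.

    For autocovariate models the spatial-lag value of each surveyed lake
    is computed from the model's own dataset responses (its neighbors'
    labels), using the same inverse-distance band logic.
    """
    surveyed = table[table["surveyed"].astype(bool)]
    feats = [f for f in model.feature_names if f != "autocov"]
    X = surveyed[feats].copy()
    if model.includes_autocov:
        X["autocov"] = cross_autocovariate(
            surveyed[["x", "y"]].to_numpy(dtype=float),
            model.dataset.coords,
            model.dataset.labels,
        )
    return model.predict(X[model.feature_names])


def functional_accuracy(model: FittedSDM, table: pd.DataFrame) -> FunctionalMetrics:
    """Abundance-suitability correlations over the surveyed lakes.

    r_all / rho_all include zero-abundance lakes; r_nonzero / rho_nonzero
    are restricted to invaded lakes (freq_occ > 0) and are NaN when fewer
    than 3 such lakes exist.
    """
    surveyed = table[table["surveyed"].astype(bool)]
    pred = suitability_on_table(model, table)
    freq = surveyed["freq_occ"].to_numpy(dtype=float)
    if len(freq) < 3:
        raise ValueError("need at least 3 surveyed lakes")
    r_all = stats.pearsonr(pred, freq).statistic
    rho_all = stats.spearmanr(pred, freq).statistic
    nz = freq > 0
    if nz.sum() >= 3:
        r_nz = stats.pearsonr(pred[nz], freq[nz]).statistic
        rho_nz = stats.spearmanr(pred[nz], freq[nz]).statistic
    else:
        r_nz = rho_nz = float("nan")
    return FunctionalMetrics(
        r_all=float(r_all), r_nonzero=float(r_nz),
        rho_all=float(rho_all), rho_nonzero=float(rho_nz),
    )


def wedge_quantiles(
    suitability, freq_occ, taus: tuple[float, ...] = (0.50, 0.75, 0.90)
) -> WedgeFit:
    """Linear quantile regression of abundance on predicted suitability.

    Minimizes the check loss at each tau; the difference between the
    90th- and 50th-percentile slopes quantifies the wedge (suitability
    capping the upper abundance quantiles more steeply than the median).
    """
    x = np.asarray(suitability, dtype=float)
    y = np.asarray(freq_occ, dtype=float)
    if len(x) < 20:
        raise ValueError("need at least 20 pairs for quantile regression")
    if x.std() < 1e-12:
        raise ValueError("degenerate suitability variance")
    exog = np.column_stack([np.ones_like(x), x])
    slopes, intercepts = {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tau in taus:
            res = QuantReg(y, exog).fit(q=tau)
            intercepts[tau] = float(res.params[0])
            slopes[tau] = float(res.params[1])
    return WedgeFit(taus=tuple(taus), slopes=slopes, intercepts=intercepts)
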