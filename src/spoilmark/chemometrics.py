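"""Chemometric core: scaling, PCA, PLS, VIP scores and feature selection.

The trend-feature selection in the milk-spoilage workflow rests on three
multivariate tools applied to the samples x features intensity matrix:

* PCA on min-max-scaled data for an exploratory first look,
* PLS-DA on a binarised fresh / past-use-by class target (days 1-4 vs 5-10,
  after the 96 h use-by limit for raw milk), preceded by a VIP > 1.5 filter,
* PLSR against the storage day, preceded by a univariate-F top-k selection,
  followed by VIP ranking of the features.

The PLS fits delegate to scikit-learn's NIPALS ``PLSRegression`` (centred,
unscaled).  The variable-importance-in-projection score of feature *j* in an
A-component model is

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a )

where ``p`` is the number of features, ``w_a`` the a-th X-weight vector and
``SSY_a = q_a^2 * ||t_a||^2`` the Y sum of squares explained by component
*a*.  The mean of the squared VIPs over features is identically 1, so the
conventional "important" cut-offs (1.0, 1.5) are scale-free.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA as _SkPCA
from sklearn.feature_selection import f_regression

from .exceptions import ConfigurationError, DegenerateClassError, DegenerateDataError

__all__ = [
    "ScaledMatrix", "PCAModel", "PLSModel", "SelectionResult", "PLSDAResult",
    "minmax_scale", "pca", "pls_fit", "pls_predict", "vip_scores",
    "f_select", "vip_filter", "split_by_use_by", "train_test_split",
    "evaluate", "choose_components", "plsda", "save_model", "load_model",
]


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

@dataclass
class ScaledMatrix:
    """Min-max-scaled matrix with the per-feature ranges used."""

    values: np.ndarray      # samples x features, in [0, 1]
    mins: np.ndarray        # per-feature minimum of the original data
    maxs: np.ndarray        # per-feature maximum of the original data

    def inverse(self, values: np.ndarray | None = None) -> np.ndarray:
        """Map scaled values back to the original intensity scale."""
        v = self.values if values is None else np.asarray(values, float)
        span = self.maxs - self.mins
        return v * span + self.mins


def minmax_scale(X: np.ndarray) -> ScaledMatrix:
    """Scale each feature onto [0, 1] via ``(x - min) / (max - min)``.

    Constant features map to 0 (their range is degenerate and carries no
    variance information).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ConfigurationError(f"expected a non-empty 2-D matrix, got shape {X.shape}")
    mins = X.min(axis=0)
    maxs = X.max(axis=0)
    span = maxs - mins
    safe = np.where(span > 0, span, 1.0)
    values = (X - mins) / safe
    values[:, span == 0] = 0.0
    return ScaledMatrix(values=values, mins=mins, maxs=maxs)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    loadings: np.ndarray            # features x k, orthonormal columns
    scores: np.ndarray              # samples x k
    explained_variance_ratio: np.ndarray
    mean: np.ndarray                # per-feature mean removed before projection


def pca(X: np.ndarray | ScaledMatrix, k: int = 2) -> PCAModel:
    """Top-``k`` principal components of the mean-centred data.

    Exploratory only in the spoilage workflow: its output never gates later
    stages.  ``scores = (X - mean) @ loadings``.
    """
    if isinstance(X, ScaledMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= k <= min(n - 1, p):
        raise ConfigurationError(
            f"k={k} out of range for {n} samples x {p} features (max {min(n - 1, p)})")
    model = _SkPCA(n_components=k, svd_solver="full").fit(X)
    scores = model.transform(X)
    return PCAModel(loadings=model.components_.T, scores=scores,
                    explained_variance_ratio=model.explained_variance_ratio_,
                    mean=model.mean_)


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """Fitted NIPALS PLS model (single-column response).

    ``x_weights`` columns are unit norm; ``x_scores`` columns are mutually
    orthogonal.  ``ssy`` holds the per-component explained sum of squares of
    the centred response, the weighting used by the VIP score.
    """

    n_components: int
    x_weights: np.ndarray       # p x A
    x_scores: np.ndarray        # n x A
    x_loadings: np.ndarray      # p x A
    y_loadings: np.ndarray      # A
    coef: np.ndarray            # p, regression coefficients on original scale
    intercept: float
    ssy: np.ndarray             # A, per-component explained SS of y
    x_mean: np.ndarray
    y_mean: float
    scaled: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.coef + self.intercept

    def to_dict(self) -> dict:
        """JSON-serialisable form: scalars plus nested lists for every array."""
        out = {"n_components": self.n_components, "intercept": self.intercept,
               "y_mean": self.y_mean, "scaled": self.scaled}
        for name in ("x_weights", "x_scores", "x_loadings", "y_loadings",
                     "coef", "ssy", "x_mean"):
            out[name] = getattr(self, name).tolist()
        return out

    @classmethod
    def from_dict(cls, payload: dict) -> "PLSModel":
        arrays = {name: np.asarray(payload[name], dtype=float)
                  for name in ("x_weights", "x_scores", "x_loadings", "y_loadings",
                               "coef", "ssy", "x_mean")}
        return cls(n_components=int(payload["n_components"]),
                   intercept=float(payload["intercept"]),
                   y_mean=float(payload["y_mean"]),
                   scaled=bool(payload.get("scaled", False)), **arrays)


def _as_response(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).reshape(-1)
    return y


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int,
            scale: bool = False) -> PLSModel:
    """Fit a PLS1 regression (NIPALS, X-deflation, centred).

    With ``scale=True`` the predictors and response are additionally
    standardised to unit variance before the fit (autoscaling), which stops
    high-intensity features from dominating the covariance criterion; the
    returned coefficients and predictions are on the original scale either
    way.  Raises :class:`ConfigurationError` when ``n_components`` exceeds
    the rank of the centred predictor matrix.
    """
    X = np.asarray(X, dtype=float)
    y = _as_response(y)
    if X.shape[0] != y.shape[0]:
        raise ConfigurationError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if not 1 <= n_components <= rank:
        raise ConfigurationError(
            f"n_components={n_components} exceeds rank(X)={rank}")
    if np.ptp(y) == 0:
        raise DegenerateDataError("response y is constant; PLS is undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = PLSRegression(n_components=n_components, scale=scale).fit(X, y)
    t = est.x_scores_
    q = est.y_loadings_.ravel()
    ssy = (q ** 2) * (t ** 2).sum(axis=0)
    return PLSModel(
        n_components=n_components,
        x_weights=est.x_weights_,
        x_scores=t,
        x_loadings=est.x_loadings_,
        y_loadings=q,
        coef=est.coef_.reshape(-1),
        intercept=float(np.asarray(est.intercept_).reshape(-1)[0]),
        ssy=ssy,
        x_mean=X.mean(axis=0),
        y_mean=float(y.mean()),
        scaled=scale,
    )


def pls_predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predicted response, linear in X."""
    return model.predict(X)


def vip_scores(model: PLSModel) -> np.ndarray:
    """Variable importance in projection for every feature of a fitted model."""
    w = model.x_weights
    ssy = model.ssy
    total = ssy.sum()
    if not total > 0:
        raise DegenerateDataError("total explained SS of y is zero; VIP undefined")
    p = w.shape[0]
    wnorm2 = (w ** 2).sum(axis=0)
    wnorm2 = np.where(wnorm2 > 0, wnorm2, 1.0)
    return np.sqrt(p * ((w ** 2 / wnorm2) @ ssy) / total)


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Per-feature statistic plus the retained subset."""

    statistic: np.ndarray           # per input feature (F value or VIP)
    selected: np.ndarray            # indices into the input feature axis
    feature_ids: list[str] | None = None
    threshold: float | None = None
    k: int | None = None

    @property
    def selected_ids(self) -> list[str]:
        if self.feature_ids is None:
            return [str(i) for i in self.selected]
        return [self.feature_ids[i] for i in self.selected]

    def to_frame(self):
        """CSV-ready frame: feature id, statistic, rank, retained flag."""
        import pandas as pd

        order = np.argsort(-self.statistic, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(1, len(order) + 1)
        ids = (self.feature_ids if self.feature_ids is not None
               else [str(i) for i in range(len(self.statistic))])
        retained = np.zeros(len(self.statistic), dtype=bool)
        retained[self.selected] = True
        return pd.DataFrame({"feature_id": ids, "statistic": self.statistic,
                             "rank": rank, "retained": retained})


def f_select(X: np.ndarray, y: np.ndarray, k: int = 1000,
             feature_ids: Sequence[str] | None = None) -> SelectionResult:
    """Keep the top-``k`` features by univariate regression F against ``y``.

    ``F_j = r_j^2 / (1 - r_j^2) * (n - 2)`` with ``r_j`` the Pearson
    correlation between feature *j* and the (continuous) target.  Constant
    features score 0; a feature perfectly correlated with the target scores
    +inf and ranks first.  Ties are broken by column order for determinism.
    """
    X = np.asarray(X, dtype=float)
    y = _as_response(y)
    n, p = X.shape
    if n < 3:
        raise ConfigurationError(f"need at least 3 samples for an F statistic, got {n}")
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if np.ptp(y) == 0:
        raise DegenerateDataError("target y is constant; F statistic undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, _ = f_regression(X, y, force_finite=True)
    F = np.nan_to_num(F, nan=0.0)
    k_eff = min(k, p)
    order = np.argsort(-F, kind="stable")  # stable: ties by column order
    selected = np.sort(order[:k_eff])
    return SelectionResult(statistic=F, selected=selected,
                           feature_ids=list(feature_ids) if feature_ids is not None else None,
                           k=k_eff)


def _binarize(classes: Sequence) -> tuple[np.ndarray, list]:
    labels = sorted(set(classes), key=str)
    if len(labels) < 2:
        raise DegenerateClassError(f"need exactly 2 classes, got {labels}")
    if len(labels) > 2:
        raise ConfigurationError(f"only two-class problems are supported, got {labels}")
    y = np.array([labels.index(c) for c in classes], dtype=float)
    return y, labels


def vip_filter(X: np.ndarray, classes: Sequence, threshold: float = 1.5,
               n_components: int = 2,
               feature_ids: Sequence[str] | None = None,
               scale: bool = False) -> SelectionResult:
    """VIP > ``threshold`` filter from a preliminary two-class PLS-DA.

    A PLS model with ``n_components`` components is fitted on all samples
    against the binarised class labels; features whose VIP exceeds the
    threshold (strict inequality) are retained.
    """
    X = np.asarray(X, dtype=float)
    y, _ = _binarize(classes)
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    A = min(n_components, rank)
    model = pls_fit(X, y, A, scale=scale)
    vip = vip_scores(model)
    selected = np.flatnonzero(vip > threshold)
    return SelectionResult(statistic=vip, selected=selected,
                           feature_ids=list(feature_ids) if feature_ids is not None else None,
                           threshold=threshold)


# ---------------------------------------------------------------------------
# Splits, targets, evaluation
# ---------------------------------------------------------------------------

#: Raw milk must be consumed within 96 h of production; storage days at or
#: below this boundary count as fresh.
USE_BY_BOUNDARY_DAY = 4

FRESH, PAST_USE_BY = "fresh", "past-use-by"


def split_by_use_by(days: Sequence[int], boundary: int = USE_BY_BOUNDARY_DAY) -> np.ndarray:
    """Class labels from storage days: day <= boundary -> fresh, else past-use-by."""
    days = np.asarray(days)
    if days.size < 1:
        raise ConfigurationError("need at least one day")
    return np.where(days <= boundary, FRESH, PAST_USE_BY)


def train_test_split(samples: Sequence, train_frac: float = 0.8,
                     seed: int | None = None) -> tuple[list, list]:
    """Deterministic seeded shuffle split; train size is ``ceil(train_frac * n)``.

    The two parts are disjoint and exhaust the input.
    """
    items = list(samples)
    n = len(items)
    if n < 2:
        raise ConfigurationError(f"need at least 2 samples to split, got {n}")
    if not 0 < train_frac < 1:
        raise ConfigurationError(f"train_frac must be in (0, 1), got {train_frac}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = math.ceil(train_frac * n)
    train = [items[i] for i in order[:n_train]]
    test = [items[i] for i in order[n_train:]]
    return train, test


def evaluate(model: PLSModel, X_test: np.ndarray, y_test: np.ndarray) -> tuple[float, float]:
    """(MSE, R^2) of the model on held-out data.

    ``R^2 = 1 - SS_res / SS_tot``; a constant test target makes R^2
    undefined and raises :class:`DegenerateDataError`.
    """
    y_test = _as_response(y_test)
    pred = model.predict(np.asarray(X_test, dtype=float))
    resid = y_test - pred
    mse = float(np.mean(resid ** 2))
    ss_tot = float(np.sum((y_test - y_test.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateDataError("constant test target: R^2 undefined")
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return mse, r2


def choose_components(X: np.ndarray, y: np.ndarray, a_max: int,
                      train_frac: float = 0.8, seed: int | None = 42,
                      scale: bool = False) -> tuple[int, list[dict]]:
    """Pick the component count maximising held-out R^2 (ties -> smaller A).

    A single seeded train/test split is used; returns the chosen A and the
    per-A records ``{"A", "mse", "r2"}``.
    """
    if a_max < 1:
        raise ConfigurationError(f"a_max must be >= 1, got {a_max}")
    X = np.asarray(X, dtype=float)
    y = _as_response(y)
    train, test = train_test_split(range(len(y)), train_frac=train_frac, seed=seed)
    rank = np.linalg.matrix_rank(X[train] - X[train].mean(axis=0))
    records = []
    for A in range(1, min(a_max, rank) + 1):
        model = pls_fit(X[train], y[train], A, scale=scale)
        mse, r2 = evaluate(model, X[test], y[test])
        records.append({"A": A, "mse": mse, "r2": r2})
    best = max(records, key=lambda r: (r["r2"], -r["A"]))
    return best["A"], records


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class PLSDAResult:
    """Two-class PLS-DA with a held-out confusion matrix."""

    model: PLSModel
    classes: list
    confusion: np.ndarray           # 2 x 2, rows = true class, cols = predicted
    accuracy: float
    train_index: list[int]
    test_index: list[int]

    def predict_classes(self, X: np.ndarray) -> np.ndarray:
        raw = self.model.predict(np.asarray(X, float))
        return np.asarray(self.classes, object)[(raw > 0.5).astype(int)]


def plsda(X: np.ndarray, classes: Sequence, n_components: int = 2,
          train_frac: float = 0.8, seed: int | None = 42,
          scale: bool = False) -> PLSDAResult:
    """Two-class PLS-DA: binarise, fit PLSR on a seeded train split, threshold at 0.5.

    The confusion matrix and accuracy are computed on the held-out part of
    the split.
    """
    X = np.asarray(X, dtype=float)
    y, labels = _binarize(classes)
    train, test = train_test_split(range(len(y)), train_frac=train_frac, seed=seed)
    if len(set(y[train])) < 2:
        raise DegenerateClassError("training split contains a single class")
    rank = np.linalg.matrix_rank(X[train] - X[train].mean(axis=0))
    model = pls_fit(X[train], y[train], min(n_components, rank), scale=scale)
    pred = (model.predict(X[test]) > 0.5).astype(int)
    truth = y[test].astype(int)
    confusion = np.zeros((2, 2), dtype=int)
    for t, p in zip(truth, pred):
        confusion[t, p] += 1
    accuracy = float((truth == pred).mean()) if len(truth) else float("nan")
    return PLSDAResult(model=model, classes=labels, confusion=confusion,
                       accuracy=accuracy, train_index=list(train), test_index=list(test))


def spearman_trend(intensities: np.ndarray, days: Sequence[int]) -> float:
    """Spearman rank correlation between a feature's intensity and the day."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features have no defined trend
        rho = stats.spearmanr(np.asarray(intensities, float), np.asarray(days)).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def save_model(model: PLSModel, path: "str | Path") -> None:
    """Write a fitted PLS model to the documented JSON schema (see to_dict)."""
    Path(path).write_text(json.dumps(model.to_dict()))


def load_model(path: "str | Path") -> PLSModel:
    """Read a PLS model written by :func:`save_model`."""
    return PLSModel.from_dict(json.loads(Path(path).read_text()))
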