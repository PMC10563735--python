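"""Model families for single-sensor and fused feature tables.

Four estimators, all scikit-learn compatible:

* :class:`CVPLSRegressor` - PLS regression whose latent-variable (LV) count
  is chosen by minimum 10-fold cross-validated RMSE.
* :class:`PLSDAClassifier` - PLS discriminant analysis on one-hot dummy
  responses, decoded by argmax; LV chosen by minimum CV RMSE on the dummy
  block.
* :class:`GridPolySVR` / :class:`GridPolySVC` - second-degree polynomial
  kernel support vector machines, ``(gamma * <x, x'> + 1)^2``, with an
  exhaustive grid search over the 25 pairs of penalty ``c`` and kernel
  parameter ``gamma`` in {0.01, 0.1, 1, 10, 100}, selected by the smallest
  10-fold validation RMSE (for classification, RMSE on one-hot class-coded
  predictions).

Feature-level fusion concatenates the 39 e-nose features with the
CARS-selected wavelengths and z-scores every column on the calibration rows
only.  Kernel methods are scale-sensitive, hence the standardization
contract; :class:`GridPolySVR` additionally standardizes the response
internally so the epsilon-tube width is meaningful across attributes with
very different scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold, cross_val_predict
from sklearn.svm import SVC, SVR
from sklearn.utils.validation import check_is_fitted, check_X_y

__all__ = [
    "CVPLSRegressor",
    "PLSDAClassifier",
    "GridPolySVR",
    "GridPolySVC",
    "FusionDataset",
    "PcaSummary",
    "DEFAULT_SV_GRID",
    "fit_plsr",
    "fit_plsda",
    "fit_sv",
    "fuse_features",
    "pca_summary",
    "one_hot",
    "dummy_rmse",
]

DEFAULT_SV_GRID: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)


def one_hot(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Dummy-code labels as unit vectors over ``classes`` (class j -> e_j)."""
    index = {c: j for j, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, index[lab]] = 1.0
    return Y


def dummy_rmse(y_true, y_pred, classes: np.ndarray) -> float:
    """RMSE over the one-hot dummy block.

    ``y_pred`` may be hard labels (one-hot coded before comparison) or an
    already-continuous score matrix of shape (n, K).
    """
    Yt = one_hot(np.asarray(y_true), classes)
    y_pred = np.asarray(y_pred)
    Yp = y_pred if y_pred.ndim == 2 else one_hot(y_pred, classes)
    return float(np.sqrt(np.mean((Yt - Yp) ** 2)))


def _parsimonious_argmin(rmse: np.ndarray, scale: float) -> int:
    """Smallest LV count whose RMSECV matches the minimum to numerical
    tolerance; with any real noise this is the plain argmin."""
    tol = 1e-9 * max(scale, 1e-12)
    return int(np.flatnonzero(rmse <= rmse.min() + tol)[0]) + 1


def _lv_cap(max_lv: int, n_samples: int, n_features: int, folds: int) -> int:
    smallest_train = n_samples - int(np.ceil(n_samples / folds))
    cap = int(min(max_lv, smallest_train - 1, n_features))
    if cap < max_lv:
        warnings.warn(
            f"max_lv={max_lv} exceeds the rank bound; capped at {cap}")
    return max(cap, 1)


class CVPLSRegressor(RegressorMixin, BaseEstimator):
    """PLS regression with the LV count picked by minimum 10-fold RMSECV.

    Set ``n_components`` to an integer to bypass the cross-validated choice.
    Fitted attributes: ``n_components_``, ``rmsecv_per_lv_``, ``coef_``,
    ``intercept_``, ``pls_``.
    """

    def __init__(self, max_lv: int = 20, n_components: int | None = None,
                 folds: int = 10, random_state: int | None = None):
        self.max_lv = max_lv
        self.n_components = n_components
        self.folds = folds
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if np.ptp(y) == 0:
            raise ValueError("constant response: PLS regression is degenerate")
        if self.n_components is not None:
            self.n_components_ = int(self.n_components)
            self.rmsecv_per_lv_ = None
        else:
            cap = _lv_cap(self.max_lv, len(y), X.shape[1], self.folds)
            cv = KFold(self.folds, shuffle=True,
                       random_state=self.random_state)
            rmse = np.empty(cap)
            for a in range(1, cap + 1):
                pred = cross_val_predict(PLSRegression(n_components=a), X, y, cv=cv)
                rmse[a - 1] = np.sqrt(np.mean((pred.ravel() - y) ** 2))
            self.rmsecv_per_lv_ = rmse
            self.n_components_ = _parsimonious_argmin(rmse, float(np.std(y)))
        self.pls_ = PLSRegression(n_components=self.n_components_).fit(X, y)
        self.coef_ = self.pls_.coef_.ravel()
        self.intercept_ = float(self.pls_.intercept_.ravel()[0])
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "pls_")
        return self.pls_.predict(np.asarray(X, dtype=float)).ravel()


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """PLS discriminant analysis: multi-response PLS on one-hot dummies.

    Classes are dummy-coded as unit vectors; prediction decodes the
    continuous dummy predictions by argmax.  The LV count minimizes the
    10-fold cross-validated RMSE on the dummy block.
    """

    def __init__(self, max_lv: int = 20, n_components: int | None = None,
                 folds: int = 10, random_state: int | None = None):
        self.max_lv = max_lv
        self.n_components = n_components
        self.folds = folds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        if counts.min() < 2:
            thin = self.classes_[counts < 2]
            raise ValueError(f"classes with a single member cannot be stratified: {thin}")
        Y = one_hot(y, self.classes_)
        if self.n_components is not None:
            self.n_components_ = int(self.n_components)
            self.rmsecv_per_lv_ = None
        else:
            cap = _lv_cap(self.max_lv, len(y), X.shape[1], self.folds)
            cv = KFold(self.folds, shuffle=True, random_state=self.random_state)
            rmse = np.empty(cap)
            for a in range(1, cap + 1):
                pred = cross_val_predict(PLSRegression(n_components=a), X, Y, cv=cv)
                rmse[a - 1] = np.sqrt(np.mean((pred - Y) ** 2))
            self.rmsecv_per_lv_ = rmse
            self.n_components_ = _parsimonious_argmin(rmse, float(np.std(Y)))
        self.pls_ = PLSRegression(n_components=self.n_components_).fit(X, Y)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "pls_")
        return self.pls_.predict(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


@dataclass
class GridSearchRecord:
    """One evaluated (c, gamma) pair and its validation RMSE."""

    c: float
    gamma: float
    rmse_val: float


class _GridPolySVBase(BaseEstimator):
    """Shared 25-pair grid search machinery for the polynomial SV models."""

    def __init__(self, c_grid: Sequence[float] = DEFAULT_SV_GRID,
                 gamma_grid: Sequence[float] = DEFAULT_SV_GRID,
                 degree: int = 2, coef0: float = 1.0,
                 folds: int = 10, random_state: int | None = None):
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid
        self.degree = degree
        self.coef0 = coef0
        self.folds = folds
        self.random_state = random_state

    def _search(self, X, y, score_one):
        if not len(self.c_grid) or not len(self.gamma_grid):
            raise ValueError("empty hyperparameter grid")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        record = []
        for c in self.c_grid:
            for gamma in self.gamma_grid:
                record.append(GridSearchRecord(float(c), float(gamma),
                                               score_one(X, y, c, gamma)))
        best = min(range(len(record)), key=lambda i: record[i].rmse_val)
        self.grid_record_ = record
        self.best_c_ = record[best].c
        self.best_gamma_ = record[best].gamma
        self.best_rmse_val_ = record[best].rmse_val
        return self.best_c_, self.best_gamma_


class GridPolySVR(RegressorMixin, _GridPolySVBase):
    """Poly-2 SVR with (c, gamma) chosen by smallest 10-fold validation RMSE.

    The response is standardized internally (``epsilon`` is expressed in
    response SD units) and predictions are returned on the original scale.
    """

    def __init__(self, c_grid: Sequence[float] = DEFAULT_SV_GRID,
                 gamma_grid: Sequence[float] = DEFAULT_SV_GRID,
                 degree: int = 2, coef0: float = 1.0, epsilon: float = 0.01,
                 folds: int = 10, random_state: int | None = None):
        super().__init__(c_grid, gamma_grid, degree, coef0, folds, random_state)
        self.epsilon = epsilon

    def _make(self, c, gamma):
        # generous but finite iteration cap: some grid corners are severely
        # ill-conditioned and libsvm would otherwise spin indefinitely
        return SVR(kernel="poly", degree=self.degree, coef0=self.coef0,
                   C=c, gamma=gamma, epsilon=self.epsilon, max_iter=200_000)

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self._y_mean = float(np.mean(y))
        self._y_sd = float(np.std(y))
        if self._y_sd == 0:
            raise ValueError("constant response")
        z = (y - self._y_mean) / self._y_sd
        cv = KFold(min(self.folds, len(y)), shuffle=True, random_state=self.random_state)

        def score_one(X, z, c, gamma):
            pred = cross_val_predict(self._make(c, gamma), X, z, cv=cv)
            return float(np.sqrt(np.mean((pred - z) ** 2))) * self._y_sd

        c, gamma = self._search(X, z, score_one)
        self.svr_ = self._make(c, gamma).fit(X, z)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "svr_")
        return self.svr_.predict(np.asarray(X, dtype=float)) * self._y_sd + self._y_mean


class GridPolySVC(ClassifierMixin, _GridPolySVBase):
    """Poly-2 SVM classifier (one-vs-rest) with (c, gamma) selected by the
    smallest 10-fold validation RMSE on one-hot class-coded predictions."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        cv = KFold(min(self.folds, len(y)), shuffle=True, random_state=self.random_state)

        def make(c, gamma):
            return SVC(kernel="poly", degree=self.degree, coef0=self.coef0,
                       C=c, gamma=gamma, decision_function_shape="ovr",
                       max_iter=200_000)

        def score_one(X, y, c, gamma):
            pred = cross_val_predict(make(c, gamma), X, y, cv=cv)
            return dummy_rmse(y, pred, self.classes_)

        c, gamma = self._search(X, y, score_one)
        self.svc_ = make(c, gamma).fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.predict(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# thin functional wrappers

def fit_plsr(X, y, max_lv: int = 20, folds: int = 10,
             seed: int | None = None) -> CVPLSRegressor:
    return CVPLSRegressor(max_lv=max_lv, folds=folds, random_state=seed).fit(X, y)


def fit_plsda(X, labels, max_lv: int = 20, folds: int = 10,
              seed: int | None = None) -> PLSDAClassifier:
    return PLSDAClassifier(max_lv=max_lv, folds=folds, random_state=seed).fit(X, labels)


def fit_sv(X, target, task: str, grid: Sequence[float] = DEFAULT_SV_GRID,
           folds: int = 10, seed: int | None = None):
    """Fit the grid-searched polynomial SV model for ``task`` in
    {"regression", "classification"}."""
    if task == "regression":
        est = GridPolySVR(c_grid=grid, gamma_grid=grid, folds=folds, random_state=seed)
    elif task == "classification":
        est = GridPolySVC(c_grid=grid, gamma_grid=grid, folds=folds, random_state=seed)
    else:
        raise ValueError(f"unknown task {task!r}")
    return est.fit(X, target)


# ---------------------------------------------------------------------------
# feature-level fusion

@dataclass
class FusionDataset:
    """Concatenated e-nose + selected-wavelength features, z-scored on the
    calibration rows only (means/SDs stored per column)."""

    X: pd.DataFrame                      # all rows, standardized
    provenance: tuple[str, ...]          # "enose" | "spectral" per column
    means: np.ndarray
    sds: np.ndarray
    calibration_ids: tuple[str, ...]


def fuse_features(
    enose_table: pd.DataFrame,
    spectral_table: pd.DataFrame,
    selected_bands: Sequence,
    calibration_ids: Sequence[str],
) -> FusionDataset:
    """Column-wise concatenation (e-nose block first, then the selected
    wavelengths) with calibration-only z-scoring applied to all rows."""
    missing = [i for i in enose_table.index if i not in spectral_table.index]
    missing += [i for i in spectral_table.index if i not in enose_table.index]
    if missing:
        raise KeyError(f"fruit ids missing from one table: {sorted(set(missing))[:10]}")
    selected = list(selected_bands)
    unknown = [b for b in selected if b not in spectral_table.columns]
    if unknown:
        raise KeyError(f"selected bands absent from the spectral table: {unknown[:10]}")
    if not selected:
        warnings.warn("empty wavelength selection: fused table degenerates to e-nose only")
    spectral_block = spectral_table.loc[enose_table.index, selected]
    spectral_block.columns = [f"{float(c):.3f}nm" for c in spectral_block.columns]
    X = pd.concat([enose_table, spectral_block], axis=1)
    provenance = ("enose",) * enose_table.shape[1] + ("spectral",) * len(selected)

    cal = [i for i in calibration_ids if i in X.index]
    if len(cal) != len(calibration_ids):
        raise KeyError("calibration ids missing from the feature tables")
    means = X.loc[cal].mean(axis=0).to_numpy()
    sds = X.loc[cal].std(axis=0, ddof=0).to_numpy()
    sds = np.where(sds == 0, 1.0, sds)
    Z = (X - means) / sds
    return FusionDataset(Z, provenance, means, sds, tuple(calibration_ids))


@dataclass
class PcaSummary:
    """Centered-PCA summary of one e-nose feature block."""

    block_tag: str
    explained_variance_ratio: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray        # components x features, unit-norm rows


def pca_summary(feature_block, block_tag: str = "") -> PcaSummary:
    """Centered (not scaled) PCA of a feature block (e.g. the 13 MSR columns)."""
    X = np.asarray(feature_block, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least a 2 x 2 block")
    if np.allclose(X, X[0]):
        warnings.warn("constant feature block: PCA is degenerate")
    pca = PCA()
    scores = pca.fit_transform(X)
    return PcaSummary(block_tag, pca.explained_variance_ratio_, scores, pca.components_)
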