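"""Competitive Adaptive Reweighted Sampling (CARS) wavelength selection.

CARS runs a fixed number of Monte-Carlo sampling runs.  Each run fits a PLS
regression on a random calibration fraction of the samples using the
currently surviving wavelengths, ranks wavelengths by the magnitude of
their PLS regression coefficients, enforces a retention count given by a
two-point exponential decay function (EDF, from 100% of wavelengths at run
1 down to 2 variables at the last run), and then performs adaptive
reweighted sampling: a with-replacement draw proportional to |coefficient|
whose distinct outcomes survive into the next run.  Each run's surviving
subset is scored by 10-fold cross-validated RMSE of a PLS model on the full
sample set; the subset of the run with the lowest RMSECV is selected.

The run dynamics show two regimes: a fast coarse-selection stage where the
EDF sheds most wavelengths, then a refined-selection stage with a shallow
decline; the RMSECV curve typically falls, flattens, and rises again once
informative wavelengths start being discarded.

The PLS backbone is a deterministic PLS1 that returns the regression
coefficient vector for every component count 1..A in one pass, which makes
the per-run cross-validated latent-variable choice cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted, check_X_y

__all__ = [
    "CarsConfig",
    "CarsRun",
    "CarsResult",
    "CarsSelector",
    "edf_ratio",
    "run_cars",
    "select_best_run",
    "pls1_coefficient_path",
]


class DegenerateResponseError(ValueError):
    """Raised when the response vector is constant."""


def edf_ratio(run_index: int, n_vars: int, n_runs: int) -> float:
    """Fraction of wavelengths retained by the exponential decay function.

    The two-point construction ``r_i = a * exp(-k * i)`` is fixed by the
    boundary conditions ``r_1 = 1`` (all variables survive the first run)
    and ``r_N = 2 / p`` (two variables survive the last run).
    """
    if n_vars < 2:
        raise ValueError("need at least two variables")
    if n_runs < 2:
        raise ValueError("need at least two runs")
    if not 1 <= run_index <= n_runs:
        raise ValueError(f"run index {run_index} outside 1..{n_runs}")
    a = (n_vars / 2.0) ** (1.0 / (n_runs - 1))
    k = np.log(n_vars / 2.0) / (n_runs - 1)
    return float(a * np.exp(-k * run_index))


def pls1_coefficient_path(
    X: np.ndarray, y: np.ndarray, max_components: int
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """PLS1 regression coefficients for every component count 1..A.

    Returns ``(B, x_mean, y_mean, used)`` where column ``a-1`` of ``B``
    (shape p x A) holds the coefficient vector of the ``a``-component model
    on the original (uncentered) scale:
    ``y_hat = (x - x_mean) @ B[:, a-1] + y_mean``.

    Deflation stops early if the residual collapses; ``used`` is the number
    of components actually extracted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    A = int(min(max_components, n - 1, p))
    if A < 1:
        raise ValueError("cannot extract any PLS component")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xr = X - x_mean
    yr = y - y_mean
    eps = 1e-12 * max(1.0, float(np.abs(yr).max(initial=0.0)))
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    used = 0
    for a in range(A):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw <= eps:
            break
        w /= nw
        t = Xr @ w
        tt = float(t @ t)
        if tt <= eps**2:
            break
        pvec = Xr.T @ t / tt
        qa = float(yr @ t) / tt
        Xr = Xr - np.outer(t, pvec)
        yr = yr - qa * t
        W[:, a], P[:, a], q[a] = w, pvec, qa
        used += 1
    if used == 0:
        raise DegenerateResponseError("response carries no covariance with the predictors")
    # R = W (P^T W)^{-1} via the usual recursion; B_a = R[:, :a] @ q[:a]
    R = np.zeros((p, used))
    for a in range(used):
        r = W[:, a].copy()
        for j in range(a):
            r -= (P[:, j] @ W[:, a]) * R[:, j]
        R[:, a] = r
    B = np.cumsum(R * q[:used], axis=1)
    return B, x_mean, y_mean, used


def _rmsecv_path(
    X: np.ndarray, y: np.ndarray, max_components: int, n_splits: int, seed: int
) -> np.ndarray:
    """10-fold (by default) cross-validated RMSE for each component count."""
    n = X.shape[0]
    n_splits = min(n_splits, n)
    cv = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    sq = np.zeros(max_components)
    counts = np.zeros(max_components)
    for train, val in cv.split(X):
        cap = int(min(max_components, len(train) - 1, X.shape[1]))
        B, xm, ym, used = pls1_coefficient_path(X[train], y[train], cap)
        pred = (X[val] - xm) @ B[:, :used] + ym        # n_val x used
        err = (pred - y[val][:, None]) ** 2
        sq[:used] += err.sum(axis=0)
        counts[:used] += len(val)
        if used < max_components:                      # reuse the deepest model
            sq[used:] += err[:, -1].sum()
            counts[used:] += len(val)
    return np.sqrt(sq / counts)


def _subset_rmsecv(
    X: np.ndarray, y: np.ndarray, n_lv: int, folds: int, seed: int
) -> tuple[float, int]:
    """RMSECV of a PLS model with (at most) ``n_lv`` components."""
    cap = int(min(n_lv, X.shape[0] - 1, X.shape[1]))
    path = _rmsecv_path(X, y, cap, folds, seed)
    return float(path[-1]), cap


@dataclass(frozen=True)
class CarsConfig:
    """CARS sampling-run schedule and internal model-selection settings."""

    n_runs: int = 100
    calibration_fraction: float = 0.8
    folds: int = 10
    max_lv: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("n_runs must be at least 2")
        if not 0.0 < self.calibration_fraction < 1.0:
            raise ValueError("calibration fraction must lie in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be at least 2")
        if self.max_lv < 1:
            raise ValueError("max_lv must be positive")


@dataclass
class CarsRun:
    """One Monte-Carlo sampling run: surviving set, its RMSECV and coefficients."""

    retained: np.ndarray          # sorted global wavelength indices
    rmsecv: float
    n_lv: int
    coef: np.ndarray              # |PLS coefficients| used for this run's ranking


@dataclass
class CarsResult:
    """Full CARS trajectory plus the winning wavelength subset."""

    runs: list[CarsRun]
    best_run: int                 # 0-based index of the argmin-RMSECV run
    selected: np.ndarray          # retained set of the best run
    n_vars: int

    @property
    def n_retained_path(self) -> np.ndarray:
        return np.array([len(r.retained) for r in self.runs])

    @property
    def rmsecv_path(self) -> np.ndarray:
        return np.array([r.rmsecv for r in self.runs])


class CarsSelector(SelectorMixin, BaseEstimator):
    """scikit-learn feature selector running the CARS algorithm.

    Parameters
    ----------
    n_runs : number of Monte-Carlo sampling runs (default 100).
    calibration_fraction : fraction of samples drawn (without replacement)
        to fit each run's ranking model (default 0.8).
    folds : cross-validation folds, both for the per-run latent-variable
        choice and for the RMSECV scoring of each surviving subset.
    max_lv : upper bound on PLS components considered.
    random_state : seed controlling Monte-Carlo draws, adaptive reweighted
        sampling and fold shuffling; fixed seed gives identical results.

    Fitted attributes
    -----------------
    support_ : boolean mask of selected wavelengths.
    result_ : :class:`CarsResult` with the full run trajectory.
    """

    def __init__(
        self,
        n_runs: int = 100,
        calibration_fraction: float = 0.8,
        folds: int = 10,
        max_lv: int = 20,
        random_state: int | None = None,
    ):
        self.n_runs = n_runs
        self.calibration_fraction = calibration_fraction
        self.folds = folds
        self.max_lv = max_lv
        self.random_state = random_state

    def fit(self, X, y):
        config = CarsConfig(
            n_runs=self.n_runs,
            calibration_fraction=self.calibration_fraction,
            folds=self.folds,
            max_lv=self.max_lv,
            seed=0 if self.random_state is None else int(self.random_state),
        )
        X, y = check_X_y(X, y, dtype=float)
        result = run_cars(X, y, config)
        self.n_features_in_ = X.shape[1]
        self.result_ = result
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[result.selected] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def run_cars(X: np.ndarray, y: np.ndarray, config: CarsConfig | None = None) -> CarsResult:
    """Run CARS on a samples x wavelengths matrix against a response vector.

    For classification duties pass integer-coded class labels (e.g. storage
    days) as the response; the PLS backbone regresses on them directly.
    """
    config = config or CarsConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y disagree in sample count")
    if n < 2 * config.folds:
        raise ValueError(f"need at least {2 * config.folds} samples for {config.folds}-fold CV")
    if p < 2:
        raise ValueError("need at least two wavelengths")
    if np.ptp(y) == 0:
        raise DegenerateResponseError("constant response")

    rng = np.random.default_rng(config.seed)
    n_cal = max(int(round(config.calibration_fraction * n)), 2)
    # One shared fold split and one fixed component count score every run's
    # subset, so the RMSECV curve compares subsets, not fold draws or model
    # orders; the count is chosen once by CV on the full spectrum.
    score_seed = int(rng.integers(2**31 - 1))
    full_cap = int(min(config.max_lv, n - 1, p))
    full_path = _rmsecv_path(X, y, full_cap, config.folds, score_seed)
    score_lv = int(np.argmin(full_path)) + 1
    retained = np.arange(p)
    runs: list[CarsRun] = []
    for i in range(1, config.n_runs + 1):
        if len(retained) < 2:
            break       # degenerate survivor set; keep the runs recorded so far
        k_target = max(2, int(round(edf_ratio(i, p, config.n_runs) * p)))
        k_keep = min(k_target, len(retained))

        cal = rng.choice(n, size=n_cal, replace=False)
        Xi = X[np.ix_(cal, retained)]
        yi = y[cal]
        if np.ptp(yi) == 0:
            continue    # unlucky draw; skip the run rather than rank on noise
        fold_seed = int(rng.integers(2**31 - 1))
        cap = int(min(config.max_lv, Xi.shape[0] - 1, Xi.shape[1]))
        lv_path = _rmsecv_path(Xi, yi, cap, config.folds, fold_seed)
        n_lv = int(np.argmin(lv_path)) + 1
        B, _, _, used = pls1_coefficient_path(Xi, yi, n_lv)
        coef = np.abs(B[:, used - 1])

        # EDF enforcement: keep the k_keep largest |coefficients|; ties break
        # toward the lower wavelength index.
        order = np.lexsort((retained, -coef))
        survivors_local = np.sort(order[:k_keep])

        # Adaptive reweighted sampling among the EDF survivors: p draws with
        # replacement, proportional to |coefficient|; the distinct outcomes
        # survive.  Drawing p (not k_keep) times makes the EDF schedule, not
        # the draw collapse, govern retention once k_keep << p, which yields
        # the documented sharp-then-shallow retention dynamics.
        weights = coef[survivors_local]
        total = weights.sum()
        probs = np.full(k_keep, 1.0 / k_keep) if total <= 0 else weights / total
        draws = rng.choice(survivors_local, size=p, replace=True, p=probs)
        new_retained = retained[np.unique(draws)]

        rmsecv, used_lv = _subset_rmsecv(
            X[:, new_retained], y, score_lv, config.folds, score_seed)
        runs.append(CarsRun(new_retained, rmsecv, used_lv, coef[survivors_local]))
        retained = new_retained

    if not runs:
        raise RuntimeError("no CARS run completed")
    best = select_best_run_index([r.rmsecv for r in runs])
    return CarsResult(runs, best, runs[best].retained.copy(), p)


def select_best_run_index(rmsecv_curve: Sequence[float]) -> int:
    """0-based index of the first minimum of the RMSECV curve."""
    if len(rmsecv_curve) == 0:
        raise ValueError("no completed runs")
    return int(np.argmin(rmsecv_curve))


def select_best_run(result: CarsResult) -> np.ndarray:
    """Wavelength index set of the run minimizing RMSECV (earliest on ties)."""
    best = select_best_run_index([r.rmsecv for r in result.runs])
    return result.runs[best].retained.copy()
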