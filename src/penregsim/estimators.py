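"""Linear estimators: OLS and penalized least squares (ridge / lasso / elastic net).

The penalized objective is the *unscaled* residual sum of squares plus
separate L1 and L2 penalty weights::

    sum_i (y_i - b0 - x_i' b)^2  +  lambda1 * sum_j |b_j|  +  lambda2 * sum_j b_j^2

with the intercept b0 unpenalized.  There is no 1/n or 1/2 factor in front
of the RSS; tuning-parameter magnitudes throughout the package follow this
convention.  The equivalent mixed form uses ``lambda = lambda1 + lambda2``
and mixing weight ``alpha = lambda2 / (lambda1 + lambda2)``.

Predictors are centered and scaled to unit SD before penalized fitting and
coefficients are transformed back to the original scale; the response is
centered only.  Pure-ridge problems (lambda1 = 0) are solved in closed
form; any lambda1 > 0 is solved by cyclic coordinate descent with
soft-thresholding, which converges to the global minimum of this convex
objective.  Coefficients are exactly zero where soft-thresholding
truncates; "selected" means coefficient != 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import (
    ConvergenceError,
    DegreesOfFreedomError,
    InvalidPenaltyError,
    SingularDesignError,
)

__all__ = [
    "PenaltySpec",
    "FitResult",
    "PenalizedRegression",
    "fit_ols",
    "fit_penalized",
    "regularization_path",
    "penalized_objective",
]

CD_TOL = 1e-8
CD_MAX_ITER = 100_000


@dataclass(frozen=True)
class PenaltySpec:
    """L1 and L2 penalty weights (both on the unscaled-RSS convention)."""

    lambda1: float = 0.0
    lambda2: float = 0.0

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise InvalidPenaltyError(
                f"penalty weights must be nonnegative, got ({self.lambda1}, {self.lambda2})"
            )

    @property
    def lam(self) -> float:
        """Total penalty weight lambda = lambda1 + lambda2."""
        return self.lambda1 + self.lambda2

    @property
    def alpha(self) -> float:
        """Mixing weight alpha = lambda2 / (lambda1 + lambda2); NaN when lambda = 0."""
        return self.lambda2 / self.lam if self.lam > 0 else float("nan")


@dataclass
class FitResult:
    """One fitted linear model: intercept, coefficient vector and training RSS."""

    method: str
    intercept: float
    coefficients: np.ndarray
    rss: float
    penalty: PenaltySpec | None = None
    labels: tuple | None = field(default=None, repr=False)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    def predict(self, X) -> np.ndarray:
        return self.intercept + np.asarray(X) @ self.coefficients

    def to_dict(self) -> dict:
        labels = self.labels or [f"x{j + 1}" for j in range(len(self.coefficients))]
        d = {
            "method": self.method,
            "intercept": float(self.intercept),
            "coefficients": {l: float(b) for l, b in zip(labels, self.coefficients)},
            "rss": float(self.rss),
        }
        if self.penalty is not None:
            d["penalty"] = {
                "lambda1": float(self.penalty.lambda1),
                "lambda2": float(self.penalty.lambda2),
            }
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@njit(cache=False)
def _cd_gram(G, c, beta, lam1, lam2, tol, max_iter):  # pragma: no cover - numba
    """Cyclic coordinate descent on the Gram form of the elastic-net objective.

    Minimizes ``beta' G beta - 2 c' beta + lam1 ||beta||_1 + lam2 ||beta||_2^2``
    in place.  Returns the number of full sweeps, negated if the sweep cap
    was reached before the max coefficient change dropped below ``tol``.
    """
    k = G.shape[0]
    thr = lam1 / 2.0
    last = 0.0
    for it in range(max_iter):
        dmax = 0.0
        for j in range(k):
            gj = 0.0
            for l in range(k):
                gj += G[j, l] * beta[l]
            r = c[j] - gj + G[j, j] * beta[j]
            denom = G[j, j] + lam2
            if denom <= 0.0:
                bnew = 0.0
            else:
                ar = abs(r) - thr
                if ar > 0.0:
                    bnew = (ar if r > 0.0 else -ar) / denom
                else:
                    bnew = 0.0
            d = abs(bnew - beta[j])
            if d > dmax:
                dmax = d
            beta[j] = bnew
        last = dmax
        if dmax < tol:
            return it + 1
    return -max_iter


def _solve_std(G, c, lam1, lam2, beta0=None, tol=CD_TOL, max_iter=CD_MAX_ITER):
    """Solve the standardized-space penalized problem; returns (beta, n_sweeps)."""
    k = G.shape[0]
    if lam1 == 0.0:
        A = G + lam2 * np.eye(k)
        try:
            beta = np.linalg.solve(A, c)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(A, c, rcond=None)
        return beta, 1
    beta = np.zeros(k) if beta0 is None else np.array(beta0, dtype=float)
    n_iter = _cd_gram(G, c, beta, float(lam1), float(lam2), float(tol), int(max_iter))
    if n_iter < 0:
        raise ConvergenceError(
            f"coordinate descent did not converge in {max_iter} sweeps "
            f"(tol {tol})",
        )
    return beta, n_iter


def _center_scale(X, y, standardize):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    mx = X.mean(axis=0)
    my = float(y.mean())
    if standardize:
        sx = X.std(axis=0)
        sx = np.where(sx > 0, sx, 1.0)
    else:
        sx = np.ones(X.shape[1])
    Xs = (X - mx) / sx
    yc = y - my
    return Xs, yc, mx, sx, my


class PenalizedRegression(RegressorMixin, BaseEstimator):
    """Elastic-net penalized linear regression on the unscaled-RSS convention.

    Parameters
    ----------
    lambda1 : float, default 0.0
        L1 penalty weight.  ``lambda1 = lambda2 = 0`` reproduces OLS;
        ``lambda2 = 0`` is the lasso; ``lambda1 = 0`` is ridge (closed form).
    lambda2 : float, default 0.0
        L2 penalty weight.
    standardize : bool, default True
        Center and scale predictors to unit SD before fitting; coefficients
        are reported on the original scale either way.  The response is
        centered only (the intercept is never penalized).
    tol : float, default 1e-8
        Coordinate-descent convergence threshold on the maximum absolute
        coefficient change per sweep.
    max_iter : int, default 100000
        Sweep cap; exceeding it raises :class:`ConvergenceError`.

    Attributes
    ----------
    coef_ : ndarray of shape (k,)
        Coefficients on the original predictor scale.
    intercept_ : float
    rss_ : float
        Residual sum of squares on the training data.
    n_iter_ : int
        Coordinate-descent sweeps used (1 for closed-form paths).
    """

    def __init__(self, lambda1=0.0, lambda2=0.0, standardize=True,
                 tol=CD_TOL, max_iter=CD_MAX_ITER):
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter

    @property
    def penalty_(self) -> PenaltySpec:
        return PenaltySpec(self.lambda1, self.lambda2)

    def fit(self, X, y):
        penalty = PenaltySpec(self.lambda1, self.lambda2)  # validates signs
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per element of y")
        n, k = X.shape
        if n < 2:
            raise ValueError("need at least 2 observations")
        Xs, yc, mx, sx, my = _center_scale(X, y, self.standardize)
        G = Xs.T @ Xs
        c = Xs.T @ yc
        beta_std, self.n_iter_ = _solve_std(
            G, c, penalty.lambda1, penalty.lambda2, tol=self.tol, max_iter=self.max_iter
        )
        self.coef_ = beta_std / sx
        self.intercept_ = my - float(self.coef_ @ mx)
        self.rss_ = float(yc @ yc - 2 * c @ beta_std + beta_std @ G @ beta_std)
        if self.rss_ < 0:  # numerical guard for near-perfect fits
            self.rss_ = 0.0
        self.n_features_in_ = k
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return self.intercept_ + np.asarray(X, dtype=float) @ self.coef_

    def to_result(self, method=None, labels=None) -> FitResult:
        check_is_fitted(self, "coef_")
        if method is None:
            if self.lambda1 == 0 and self.lambda2 == 0:
                method = "OLS"
            elif self.lambda1 == 0:
                method = "Ridge"
            elif self.lambda2 == 0:
                method = "LASSO"
            else:
                method = "Enet"
        return FitResult(
            method=method,
            intercept=float(self.intercept_),
            coefficients=self.coef_.copy(),
            rss=self.rss_,
            penalty=self.penalty_,
            labels=labels,
        )


def penalized_objective(X, y, intercept, coef, penalty: PenaltySpec,
                        standardize: bool = True) -> float:
    """Value of the penalized objective at a given (intercept, coef).

    The penalty applies to the coefficients on the standardized-predictor
    scale when ``standardize`` is true, matching what the solver minimizes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    resid = y - intercept - X @ np.asarray(coef, dtype=float)
    b = np.asarray(coef, dtype=float)
    if standardize:
        sx = X.std(axis=0)
        sx = np.where(sx > 0, sx, 1.0)
        b = b * sx
    return float(
        resid @ resid
        + penalty.lambda1 * np.abs(b).sum()
        + penalty.lambda2 * (b @ b)
    )


def _data_xy(data):
    """Accept a Dataset or an (X, y) pair; return arrays and labels."""
    if hasattr(data, "X") and hasattr(data, "y"):
        labels = getattr(getattr(data, "spec", None), "labels", None)
        return np.asarray(data.X, float), np.asarray(data.y, float), labels
    X, y = data
    return np.asarray(X, float), np.asarray(y, float), None


def fit_ols(data) -> FitResult:
    """Ordinary least squares with rank and degrees-of-freedom checks.

    Requires ``n > k + 1`` and a full-column-rank design (including the
    intercept column).
    """
    X, y, labels = _data_xy(data)
    n, k = X.shape
    if n <= k + 1:
        raise DegreesOfFreedomError(f"OLS needs n > k + 1 = {k + 1}, got n = {n}")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < k + 1:
        raise SingularDesignError("design matrix with intercept is rank deficient")
    coef_full, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef_full
    return FitResult(
        method="OLS",
        intercept=float(coef_full[0]),
        coefficients=coef_full[1:],
        rss=float(resid @ resid),
        penalty=None,
        labels=labels,
    )


def fit_penalized(data, penalty: PenaltySpec, standardize: bool = True) -> FitResult:
    """Fit the elastic-net objective at a fixed penalty; see :class:`PenalizedRegression`."""
    X, y, labels = _data_xy(data)
    est = PenalizedRegression(
        lambda1=penalty.lambda1, lambda2=penalty.lambda2, standardize=standardize
    ).fit(X, y)
    return est.to_result(labels=labels)


def regularization_path(data, penalties, standardize: bool = True) -> list[FitResult]:
    """Fit a sequence of penalties with warm starts.

    Each returned fit equals an independent cold-start ``fit_penalized``
    call to within the solver tolerance; warm starting only speeds up the
    sweep count.
    """
    penalties = list(penalties)
    if not penalties:
        raise ValueError("penalties must be nonempty")
    X, y, labels = _data_xy(data)
    Xs, yc, mx, sx, my = _center_scale(X, y, standardize)
    G = Xs.T @ Xs
    c = Xs.T @ yc
    yty = float(yc @ yc)
    beta = np.zeros(X.shape[1])
    out = []
    for pen in penalties:
        beta, _ = _solve_std(G, c, pen.lambda1, pen.lambda2, beta0=beta)
        coef = beta / sx
        rss = max(0.0, yty - 2 * c @ beta + beta @ G @ beta)
        out.append(
            FitResult(
                method="path",
                intercept=my - float(coef @ mx),
                coefficients=coef,
                rss=float(rss),
                penalty=pen,
                labels=labels,
            )
        )
    return out
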