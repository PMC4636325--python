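"""Stepwise-backward variable selection optimizing AIC or BIC.

The information criteria are, up to additive constants,

    AIC = n * ln(RSS / n) + 2 * k_params
    BIC = n * ln(RSS / n) + k_params * ln(n)

where ``k_params`` counts the fitted slope coefficients plus the intercept.
BIC's penalty per parameter exceeds AIC's as soon as ln(n) > 2, i.e. for
n >= 8, so BIC selects models that are never larger when both search paths
coincide.

The search starts from the full OLS model and greedily applies the single
drop — or, for previously removed variables, single re-entry — that most
decreases the criterion, stopping at a local optimum.  Ties are broken by
lowest variable index; the intercept is never a removal candidate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .estimators import FitResult, _data_xy
from .exceptions import DegenerateFitError, DegreesOfFreedomError, SingularDesignError

__all__ = [
    "CriterionValue",
    "information_criterion",
    "StepwiseRegression",
    "stepwise_backward",
]


@dataclass(frozen=True)
class CriterionValue:
    """An information-criterion value together with its ingredients."""

    criterion: str
    value: float
    n: int
    k_params: int


def information_criterion(rss: float, n: int, k_params: int, criterion: str) -> CriterionValue:
    """AIC or BIC of a Gaussian linear model from its residual sum of squares.

    ``n * ln(rss / n) + penalty`` with penalty ``2 * k_params`` (AIC) or
    ``k_params * ln(n)`` (BIC).  ``k_params`` is the number of fitted
    coefficients including the intercept.
    """
    criterion = criterion.upper()
    if criterion not in ("AIC", "BIC"):
        raise ValueError(f"criterion must be 'AIC' or 'BIC', got {criterion!r}")
    if n <= 0 or k_params < 0:
        raise ValueError("need n > 0 and k_params >= 0")
    if rss <= 0:
        raise DegenerateFitError("rss must be positive for a finite criterion value")
    dev = n * math.log(rss / n)
    pen = 2.0 * k_params if criterion == "AIC" else k_params * math.log(n)
    return CriterionValue(criterion=criterion, value=dev + pen, n=n, k_params=k_params)


class _SubsetOLS:
    """Fast RSS of OLS fits on predictor subsets via the centered Gram matrix."""

    def __init__(self, X, y):
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        self.G = Xc.T @ Xc
        self.c = Xc.T @ yc
        self.yty = float(yc @ yc)
        self.Xc, self.yc = Xc, yc

    def rss(self, subset) -> float:
        subset = list(subset)
        if not subset:
            return self.yty
        Gs = self.G[np.ix_(subset, subset)]
        cs = self.c[subset]
        try:
            b = np.linalg.solve(Gs, cs)
        except np.linalg.LinAlgError:
            b, *_ = np.linalg.lstsq(Gs, cs, rcond=None)
        return max(0.0, self.yty - float(cs @ b))

    def coefs(self, subset):
        subset = list(subset)
        if not subset:
            return np.zeros(0)
        Gs = self.G[np.ix_(subset, subset)]
        cs = self.c[subset]
        return np.linalg.solve(Gs, cs)


class StepwiseRegression(RegressorMixin, BaseEstimator):
    """Stepwise-backward OLS selection minimizing AIC or BIC.

    Parameters
    ----------
    criterion : {"aic", "bic"}, default "aic"
    allow_reentry : bool, default True
        Whether previously dropped variables may re-enter (the
        forward-within-backward combination); pure backward elimination
        when False.

    Attributes
    ----------
    support_ : boolean ndarray of shape (k,), selected variables.
    coef_ : ndarray of shape (k,); zeros for excluded variables.
    intercept_ : float
    criterion_value_ : float, criterion at the final model.
    trace_ : list of (move, variable, value_before, value_after) tuples.
    """

    def __init__(self, criterion: str = "aic", allow_reentry: bool = True):
        self.criterion = criterion
        self.allow_reentry = allow_reentry

    def fit(self, X, y):
        crit = self.criterion.upper()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, k = X.shape
        if n <= k + 1:
            raise DegreesOfFreedomError(f"need n > k + 1 = {k + 1}, got n = {n}")
        design = np.column_stack([np.ones(n), X])
        if np.linalg.matrix_rank(design) < k + 1:
            raise SingularDesignError("design matrix with intercept is rank deficient")

        work = _SubsetOLS(X, y)

        def crit_val(subset):
            rss = work.rss(subset)
            if rss <= 0:
                return -math.inf
            return information_criterion(rss, n, len(subset) + 1, crit).value

        current = list(range(k))
        cur_val = crit_val(current)
        trace = []
        while True:
            best_move = None
            best_val = cur_val
            in_set = set(current)
            for j in current:  # drops, ascending index for deterministic ties
                val = crit_val([v for v in current if v != j])
                if val < best_val - 1e-12:
                    best_val, best_move = val, ("drop", j)
            if self.allow_reentry:
                for j in range(k):
                    if j in in_set:
                        continue
                    val = crit_val(sorted(current + [j]))
                    if val < best_val - 1e-12:
                        best_val, best_move = val, ("add", j)
            if best_move is None:
                break
            move, j = best_move
            trace.append((move, j, cur_val, best_val))
            if move == "drop":
                current = [v for v in current if v != j]
            else:
                current = sorted(current + [j])
            cur_val = best_val

        self.support_ = np.zeros(k, dtype=bool)
        self.support_[current] = True
        self.coef_ = np.zeros(k)
        if current:
            self.coef_[current] = work.coefs(current)
        self.intercept_ = float(y.mean() - self.coef_ @ X.mean(axis=0))
        self.rss_ = work.rss(current)
        self.criterion_value_ = cur_val
        self.trace_ = trace
        self.n_features_in_ = k
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return self.intercept_ + np.asarray(X, dtype=float) @ self.coef_


def stepwise_backward(data, criterion: str = "aic", allow_reentry: bool = True) -> FitResult:
    """Run stepwise-backward selection on a dataset; returns the final OLS fit.

    Excluded variables' coefficients are zero in the returned result.
    """
    X, y, labels = _data_xy(data)
    est = StepwiseRegression(criterion=criterion, allow_reentry=allow_reentry).fit(X, y)
    return FitResult(
        method="sAIC" if criterion.upper() == "AIC" else "sBIC",
        intercept=est.intercept_,
        coefficients=est.coef_.copy(),
        rss=est.rss_,
        penalty=None,
        labels=labels,
    )
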