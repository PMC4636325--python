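"""Correlation-matrix utilities and VIF-targeted synthesis.

The simulation scenarios are defined not by explicit correlation matrices
but by the variance inflation factors (VIFs) each predictor should exhibit.
This module provides the forward map (correlation matrix -> VIF vector) and
an inverse calibration step that searches a structured family of
positive-definite correlation matrices for one whose VIFs match a target
vector.

Two structured families are available:

``banded-serial``
    A (generally non-stationary) first-order Markov chain over serially
    ordered variables: ``corr(i, j) = prod_{l=i}^{j-1} r_l`` for neighbour
    correlations ``r_l`` in (-1, 1).  This emulates repeated measurements
    over time (e.g. a glucose curve), where neighbouring time points are
    most strongly correlated, and is positive definite by construction.

``grouped-block``
    A two-level factor model: each variable loads on one shared factor and
    on one group-specific factor, ``corr(i, j) = a_i a_j + 1{g_i = g_j} c_i c_j``.
    This emulates a panel of assays where summaries of the same analyte
    (fasting, post-load, AUC) are strongly correlated within a group and
    moderately correlated across groups.  Positive definite whenever every
    variable retains unique variance.

Variables whose target VIF is exactly 1 are held orthogonal (zero
correlation with everything) in both families.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .exceptions import CalibrationError, InvalidCorrelationError

__all__ = [
    "validate_correlation",
    "vif_from_correlation",
    "synthesize_correlation",
    "markov_serial_matrix",
    "grouped_factor_matrix",
]

_EIG_TOL = 1e-10


def validate_correlation(R, *, require_pd: bool = True) -> np.ndarray:
    """Validate and return ``R`` as a correlation matrix.

    Checks: square, symmetric, unit diagonal, off-diagonal entries in
    [-1, 1] and (optionally) positive definiteness.

    Raises
    ------
    InvalidCorrelationError
        If any check fails.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise InvalidCorrelationError(f"expected a square matrix, got shape {R.shape}")
    if not np.allclose(R, R.T, atol=1e-12):
        raise InvalidCorrelationError("matrix is not symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-12):
        raise InvalidCorrelationError("diagonal entries must all equal 1")
    off = R[~np.eye(R.shape[0], dtype=bool)]
    if off.size and (np.abs(off) > 1.0 + 1e-12).any():
        raise InvalidCorrelationError("off-diagonal entries must lie in [-1, 1]")
    if require_pd:
        w = np.linalg.eigvalsh(R)
        if w.min() <= _EIG_TOL:
            raise InvalidCorrelationError(
                f"matrix is not positive definite (min eigenvalue {w.min():.3e})"
            )
    return R


def vif_from_correlation(R) -> np.ndarray:
    """Variance inflation factor of every variable of a correlation matrix.

    ``VIF_j = 1 / (1 - R^2_j)`` where ``R^2_j`` is the multiple R-squared of
    variable j regressed on all the others; this equals the j-th diagonal
    entry of ``R^{-1}``.  A VIF of 1 corresponds to an orthogonal system.
    """
    R = validate_correlation(R)
    return np.diag(np.linalg.inv(R)).copy()


def markov_serial_matrix(r) -> np.ndarray:
    """Correlation matrix of a first-order Markov chain with neighbour correlations ``r``.

    ``corr(i, j) = prod(r[i:j])`` for i < j.  Positive definite for all
    ``|r_l| < 1``.
    """
    r = np.asarray(r, dtype=float)
    k = r.size + 1
    R = np.eye(k)
    for i in range(k):
        acc = 1.0
        for j in range(i + 1, k):
            acc *= r[j - 1]
            R[i, j] = R[j, i] = acc
    return R


def grouped_factor_matrix(a, c, groups) -> np.ndarray:
    """Correlation matrix of a two-level (shared + group) factor model.

    Parameters
    ----------
    a : array of shared-factor loadings (one per variable).
    c : array of group-factor loadings (one per variable).
    groups : sequence of hashable group labels, one per variable.
    """
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    groups = np.asarray(groups)
    same = groups[:, None] == groups[None, :]
    R = np.outer(a, a) + same * np.outer(c, c)
    np.fill_diagonal(R, 1.0)
    return R


def _init_markov(targets: np.ndarray) -> np.ndarray:
    """Recursive initial guess for neighbour correlations from the VIF chain identity.

    For a Markov chain the precision diagonal is A_1, A_1 + A_2 - 1, ...,
    A_{k-1} with A_l = 1/(1 - r_l^2); solve the chain forward and clip.
    """
    k = targets.size
    A = np.empty(k - 1)
    A[0] = targets[0]
    for j in range(1, k - 1):
        A[j] = targets[j] + 1.0 - A[j - 1]
    A = np.clip(A, 1.02, 50.0)
    return np.sqrt(1.0 - 1.0 / A)


def _calibrate(residual_fn, x0, bounds, targets, tolerance, seed, build):
    """Shared least-squares driver with seeded random restarts."""
    rng = np.random.default_rng(seed)
    best = None
    best_err = np.inf
    x_try = np.asarray(x0, dtype=float)
    for attempt in range(6):
        sol = least_squares(residual_fn, x_try, bounds=bounds, xtol=1e-12, ftol=1e-12)
        R = build(sol.x)
        achieved = np.diag(np.linalg.inv(R))
        err = np.max(np.abs(achieved - targets)) if targets.size else 0.0
        if err < best_err:
            best, best_err = R, err
        if best_err <= tolerance:
            return best
        lo, hi = bounds
        width = np.where(np.isfinite(hi - lo), hi - lo, 1.0)
        x_try = np.clip(
            np.asarray(x0) + rng.normal(scale=0.1 * width, size=len(x0)), lo + 1e-6, hi - 1e-6
        )
    raise CalibrationError(
        f"VIF calibration failed: max |achieved - target| = {best_err:.4f} "
        f"exceeds tolerance {tolerance}",
        achieved_vifs=np.diag(np.linalg.inv(best)),
    )


def synthesize_correlation(
    target_vifs,
    structure: str = "banded-serial",
    tolerance: float = 0.5,
    seed: int = 0,
    *,
    groups=None,
    matrix=None,
) -> np.ndarray:
    """Build a positive-definite correlation matrix matching a VIF target vector.

    Parameters
    ----------
    target_vifs : array-like of floats >= 1
        Desired VIF per variable.  Variables with target exactly 1.0 are
        made orthogonal to all others.
    structure : {"banded-serial", "grouped-block", "explicit"}
        Family searched.  ``explicit`` passes ``matrix`` through after
        validating it and checking its VIFs against the targets.
    tolerance : float
        Maximum allowed ``|achieved - target|`` per variable.
    seed : int
        Seed for the optimizer's random restarts (the first attempt is a
        deterministic analytic initial guess).
    groups : sequence, required for ``grouped-block``
        Group label per variable.
    matrix : array-like, required for ``explicit``.

    Raises
    ------
    CalibrationError
        If no matrix in the family reaches the tolerance; the error carries
        the best achieved VIFs.
    """
    targets = np.asarray(target_vifs, dtype=float)
    if (targets < 1.0).any():
        raise ValueError("all target VIFs must be >= 1")
    k = targets.size

    if structure == "explicit":
        if matrix is None:
            raise ValueError("structure='explicit' requires a matrix")
        R = validate_correlation(matrix)
        achieved = np.diag(np.linalg.inv(R))
        err = np.max(np.abs(achieved - targets))
        if err > tolerance:
            raise CalibrationError(
                f"explicit matrix misses the VIF targets by {err:.4f} (> {tolerance})",
                achieved_vifs=achieved,
            )
        return R

    orthogonal = targets == 1.0
    active = ~orthogonal
    k_act = int(active.sum())
    if k_act <= 1:
        return np.eye(k)
    t_act = targets[active]

    if structure == "banded-serial":
        def build(r):
            return markov_serial_matrix(r)

        def resid(r):
            return np.diag(np.linalg.inv(markov_serial_matrix(r))) - t_act

        x0 = _init_markov(t_act)
        n_par = k_act - 1
        bounds = (np.full(n_par, -0.995), np.full(n_par, 0.995))
        R_act = _calibrate(resid, x0, bounds, t_act, tolerance, seed, build)
    elif structure == "grouped-block":
        if groups is None:
            raise ValueError("structure='grouped-block' requires groups")
        groups = np.asarray(groups)
        if groups.size != k:
            raise ValueError("groups must have one label per variable")
        g_act = groups[active]
        _, counts = np.unique(g_act, return_counts=True)
        sizes = dict(zip(*np.unique(g_act, return_counts=True)))
        singleton = np.array([sizes[g] == 1 for g in g_act])

        # Parameters: per-variable total loading u in [0, u_max] and, for
        # variables in multi-member groups, a mixing angle t in [0, pi/2]
        # splitting u between the shared factor (a = u cos t) and the group
        # factor (c = u sin t).  Unique variance 1 - u^2 > 0 keeps R PD.
        u_max = np.sqrt(0.995)
        n_angle = int((~singleton).sum())

        def unpack(x):
            u = x[:k_act]
            t = np.zeros(k_act)
            t[~singleton] = x[k_act:]
            a = u * np.cos(t)
            c = u * np.sin(t)
            c[singleton] = 0.0
            return a, c

        def build(x):
            a, c = unpack(x)
            return grouped_factor_matrix(a, c, g_act)

        def resid(x):
            return np.diag(np.linalg.inv(build(x))) - t_act

        u0 = np.sqrt(np.clip(1.0 - 1.0 / t_act, 0.05, u_max**2 * 0.98))
        x0 = np.concatenate([u0, np.full(n_angle, np.pi / 4)])
        lo = np.concatenate([np.zeros(k_act), np.zeros(n_angle)])
        hi = np.concatenate([np.full(k_act, u_max), np.full(n_angle, np.pi / 2)])
        R_act = _calibrate(resid, x0, (lo, hi), t_act, tolerance, seed, build)
    else:
        raise ValueError(f"unknown structure {structure!r}")

    R = np.eye(k)
    idx = np.flatnonzero(active)
    R[np.ix_(idx, idx)] = R_act
    return validate_correlation(R)
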