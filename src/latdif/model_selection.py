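"""BIC-based tuning-parameter and class-number selection.

For each lambda on a descending grid the penalised problem is solved
(warm-started along the path, Lasso style), the nonzero pattern of the DIF
matrix is extracted, and a constrained maximum-likelihood refit with that
support and lambda = 0 is scored by

    BIC = -2 log L(refit) + log(N) * Card,

where Card counts free parameters: 2J item parameters, K free class
proportions, 2K focal means/variances, plus the nonzero DIF entries.  The
refit, not the shrunken penalised solution, is the final estimator; an item
is flagged as DIF when any of its refit DIF entries is nonzero.  The number
of latent classes is chosen by running the whole pipeline per candidate K and
comparing the selected models' BICs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .em_estimator import (
    EMControls,
    FitResult,
    default_init,
    e_step,
    fit_regularized,
    grad_F,
)
from .model_core import (
    ParameterSet,
    ResponseMatrix,
    SupportPattern,
    make_quadrature,
)

__all__ = [
    "SelectionResult",
    "count_free_parameters",
    "bic",
    "default_lambda_grid",
    "select_lambda",
    "select_K",
]


@dataclass
class SelectionResult:
    lambda_grid: np.ndarray
    bic_per_lambda: np.ndarray
    best_lambda: float
    final_fit: FitResult
    dif_items: np.ndarray
    fits_per_lambda: list | None = None

    def __post_init__(self):
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        self.bic_per_lambda = np.asarray(self.bic_per_lambda, dtype=float)


def count_free_parameters(params: ParameterSet, support: SupportPattern,
                          known_classes: bool = False) -> int:
    """Free-parameter count of the support-constrained model.

    2J item parameters + K free proportions + 2K focal-class moments + the
    unconstrained DIF entries.  Under the known-groups (oracle) estimator the
    proportions are not parameters, removing the K term.
    """
    n = 2 * params.J + 2 * params.K + support.n_nonzero
    if not known_classes:
        n += params.K
    return n


def bic(loglik: float, n_free: int, N: int) -> float:
    """Bayesian Information Criterion: -2 log L + log(N) * n_free."""
    if N < 1:
        raise ValueError("N must be positive")
    return -2.0 * loglik + np.log(N) * n_free


def _null_fit(data: ResponseMatrix, K: int, controls: EMControls,
              known_classes=None, init=None) -> FitResult:
    """Constrained fit with delta pinned to zero (no-DIF mixture)."""
    return fit_regularized(data, K, 0.0, controls, init=init,
                           fixed_support=SupportPattern.empty(data.J, K),
                           known_classes=known_classes)


def _bottom_anchor(N: int) -> float:
    """Smallest-lambda anchor of the path.

    Gradients of the summed log-likelihood scale linearly in N, so the anchor
    does too; N/500 sits low enough to keep every plausible DIF effect active
    while still pinning the ability scale to the sparse representative of the
    mean-shift/DIF ridge.
    """
    return max(N / 500.0, 1e-2)


def lambda_max(data: ResponseMatrix, K: int, controls: EMControls,
               known_classes=None) -> float:
    """Smallest lambda at which the fitted DIF matrix is entirely zero,
    found by an ascending warm-started doubling search from the bottom
    anchor."""
    lam, _ = _path_scale(data, K, controls, known_classes)
    return lam


def _path_scale(data: ResponseMatrix, K: int, controls: EMControls,
                known_classes=None):
    """(lambda_max, bottom fit): doubling search upward with warm starts.

    The bottom fit (multistarted, smallest lambda) anchors the path; lambda
    then doubles, each fit warm-started from the previous one, until the
    fitted DIF matrix is entirely zero.
    """
    if K == 0:
        raise ValueError("lambda path is undefined for K = 0")
    lam = _bottom_anchor(data.N)
    bottom = fit_regularized(data, K, lam, controls, known_classes=known_classes)
    if bottom.support.n_nonzero == 0:
        return 2.0 * lam, bottom
    fit = bottom
    for _ in range(25):
        lam *= 2.0
        fit = fit_regularized(data, K, lam, controls, init=fit.params,
                              known_classes=known_classes)
        if fit.support.n_nonzero == 0:
            return lam, bottom
    return lam, bottom


def default_lambda_grid(data: ResponseMatrix, K: int, M: int = 10,
                        controls: EMControls = EMControls(),
                        known_classes=None) -> np.ndarray:
    """M log-spaced penalty weights from lambda_max down two decades, descending."""
    if M < 2:
        raise ValueError("need at least two grid points")
    if K == 0:
        return np.zeros(M)
    lmax = lambda_max(data, K, controls, known_classes)
    return np.geomspace(lmax, lmax / 20.0, M)


def select_lambda(data: ResponseMatrix, K: int, grid=None,
                  controls: EMControls = EMControls(),
                  known_classes=None, keep_fits: bool = False) -> SelectionResult:
    """Full regularisation path with BIC-scored constrained refits.

    The path runs from the largest lambda (all-zero DIF) downward with warm
    starts; each support is refit at lambda = 0 and scored by BIC.  Ties in
    BIC go to the smallest lambda (the latest, least-constrained support on
    the descending path).
    """
    if K == 0:
        fit = _null_fit(data, 0, controls, known_classes)
        n_free = count_free_parameters(fit.params, fit.support,
                                       known_classes is not None)
        b = bic(fit.loglik, n_free, data.N)
        return SelectionResult(np.array([0.0]), np.array([b]), 0.0, fit,
                               np.zeros(data.J, dtype=bool),
                               [fit] if keep_fits else None)
    bottom = None
    if grid is None:
        lmax, bottom = _path_scale(data, K, controls, known_classes)
        grid = np.geomspace(lmax, lmax / 20.0, 10)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    # The path is traversed in ASCENDING lambda order.  At small lambda the
    # penalty pins the ability scale to the sparse representative of the
    # mean-shift/DIF unidentifiability ridge (the DIF-free items dominate),
    # so the support starts clean and thins out as lambda grows.  Descending
    # paths inherit the no-DIF fit's shifted scale, which activates spurious
    # DIF entries with the wrong sign and never recovers.
    order = np.argsort(grid)
    bics = np.empty(grid.size)
    refits: list[FitResult | None] = [None] * grid.size
    # bottom-of-path fit warm-starts from the path-scale anchor when
    # available, otherwise multistarts from scratch
    warm = None if bottom is None else bottom.params
    any_converged = False
    for pos in order:
        lam = grid[pos]
        fit = fit_regularized(data, K, lam, controls, init=warm,
                              known_classes=known_classes)
        warm = fit.params
        refit = fit_regularized(data, K, 0.0, controls, init=fit.params,
                                fixed_support=fit.support,
                                known_classes=known_classes)
        refit.lam = lam
        n_free = count_free_parameters(refit.params, refit.support,
                                       known_classes is not None)
        bics[pos] = bic(refit.loglik, n_free, data.N)
        refits[pos] = refit
        any_converged = any_converged or (fit.converged and refit.converged)
    if not any_converged:
        raise RuntimeError(
            "no (fit, refit) pair converged on the lambda grid; "
            "loosen EMControls (max_iter/tol) or revise the grid")
    # argmin with ties resolved toward the smallest lambda
    best_pos = None
    for pos in order:
        if best_pos is None or bics[pos] < bics[best_pos]:
            best_pos = pos
    final = refits[best_pos]
    return SelectionResult(
        lambda_grid=grid, bic_per_lambda=bics, best_lambda=float(grid[best_pos]),
        final_fit=final, dif_items=final.support.dif_items(),
        fits_per_lambda=refits if keep_fits else None)


def select_K(data: ResponseMatrix, K_candidates, controls: EMControls = EMControls(),
             grid_policy="auto"):
    """Choose the number of focal classes by BIC over full selection pipelines.

    Runs the lambda-selection pipeline per candidate K and compares the BICs
    of the selected refits; ties go to the smaller K.  Returns
    (K_star, bic_per_K, results_per_K).
    """
    K_candidates = sorted(set(int(k) for k in K_candidates))
    if not K_candidates or min(K_candidates) < 0:
        raise ValueError("candidate K values must be distinct non-negative integers")
    bics = []
    results = {}
    for K in K_candidates:
        try:
            grid = None if grid_policy == "auto" else grid_policy
            res = select_lambda(data, K, grid=grid, controls=controls)
        except Exception as exc:  # propagate with context per candidate
            raise RuntimeError(f"selection failed for K={K}: {exc}") from exc
        results[K] = res
        bics.append(res.bic_per_lambda.min() if K > 0 else res.bic_per_lambda[0])
    bics = np.asarray(bics)
    K_star = K_candidates[int(np.argmin(bics))]  # argmin takes first => smaller K
    return K_star, bics, results
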