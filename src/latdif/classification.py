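"""Respondent-level inference: posterior class membership and MAP labels.

The posterior probability that respondent i belongs to latent class k given
their responses follows Bayes' rule with the ability integrated out; MAP
classification takes the row-wise argmax.  Because non-reference classes are
exchangeable (label switching), labels are resolved post hoc by an ordering
convention on the class proportions (or means), or — in simulations where
truth is available — by the permutation minimising classification error.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.stats import rankdata

from .em_estimator import FitResult, e_step
from .model_core import ParameterSet, QuadratureRule, ResponseMatrix

__all__ = [
    "ClassificationResult",
    "posterior_class_probs",
    "map_classify",
    "resolve_labels",
    "permute_classes",
    "match_labels_to_truth",
    "classification_error",
    "auc_one_vs_rest",
]


@dataclass(frozen=True)
class ClassificationResult:
    posterior: np.ndarray
    map_class: np.ndarray

    def __post_init__(self):
        if not np.allclose(self.posterior.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("posterior rows must sum to 1")


def posterior_class_probs(params: ParameterSet, data: ResponseMatrix,
                          quad: QuadratureRule) -> np.ndarray:
    """N x (K+1) matrix of P(xi_i = k | Y_i) under the supplied parameters."""
    return e_step(params, data, quad).class_marginal


def map_classify(posterior: np.ndarray) -> np.ndarray:
    """Row-wise argmax; ties resolved toward the smallest class index."""
    return np.argmax(posterior, axis=1)


def classify(params: ParameterSet, data: ResponseMatrix,
             quad: QuadratureRule) -> ClassificationResult:
    post = posterior_class_probs(params, data, quad)
    return ClassificationResult(posterior=post, map_class=map_classify(post))


def resolve_labels(fit: FitResult | ParameterSet, by: str = "nu") -> np.ndarray:
    """Permutation of the non-reference classes matching an ordering convention.

    Returns ``perm`` such that relabelled class ``i`` (1-based position
    ``i+1``) is old class ``perm[i] + 1``, with classes sorted by ascending
    class proportion (``by='nu'``) or ascending focal mean (``by='mu'``).
    The reference class is never permuted.
    """
    params = fit.params if isinstance(fit, FitResult) else fit
    if params.K < 1:
        raise ValueError("label resolution needs at least one focal class")
    key = {"nu": params.nu[1:], "mu": params.mu[1:]}[by]
    return np.argsort(key, kind="stable")


def permute_classes(params: ParameterSet, perm: np.ndarray) -> ParameterSet:
    """Apply a permutation of the non-reference classes to a ParameterSet."""
    perm = np.asarray(perm, dtype=int)
    full = np.concatenate([[0], perm + 1])
    return params.replace(delta=params.delta[:, perm], nu=params.nu[full],
                          mu=params.mu[full], sigma2=params.sigma2[full])


def match_labels_to_truth(map_class: np.ndarray, truth: np.ndarray,
                          K: int) -> np.ndarray:
    """Best label permutation (min classification error) against known truth.

    Searches all K! permutations of the non-reference classes; used in
    simulations where the generating labels are available.
    """
    best_perm, best_err = None, np.inf
    for perm in permutations(range(K)):
        perm = np.asarray(perm, dtype=int)
        lookup = np.concatenate([[0], perm + 1])
        err = np.mean(lookup[map_class] != truth)
        if err < best_err:
            best_err, best_perm = err, perm
    return best_perm


def classification_error(map_class: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of misclassified respondents (labels assumed resolved)."""
    map_class = np.asarray(map_class)
    truth = np.asarray(truth)
    if map_class.shape != truth.shape:
        raise ValueError("label vectors must have equal length")
    return float(np.mean(map_class != truth))


def auc_one_vs_rest(posterior_col: np.ndarray, truth_indicator: np.ndarray) -> float:
    """Mann-Whitney AUC of a class's posterior probability as a score.

    Ties contribute 1/2 (midrank estimator).  Raises on degenerate truth.
    """
    scores = np.asarray(posterior_col, dtype=float)
    y = np.asarray(truth_indicator).astype(bool)
    if scores.shape != y.shape:
        raise ValueError("scores and truth must have equal length")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined without both positives and negatives")
    ranks = rankdata(scores)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
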