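"""Core objects for the mixture 2-PL latent-DIF model.

The measurement model is a two-parameter logistic IRT model with a
class-specific intercept offset,

    logit P(Y_ij = 1 | theta_i, xi_i = k) = a_j * theta_i + d_j + delta_jk,

where ``a_j`` is the item discrimination, ``d_j`` the item easiness and
``delta_jk`` the DIF effect of latent class ``k`` on item ``j`` (a
log-odds-ratio at equal ability).  Class 0 is the reference class with
``delta_j0 = 0`` for all items.  The structural model is a categorical latent
class ``xi_i`` with proportions ``nu`` and a class-conditional normal ability
``theta_i | xi_i = k ~ N(mu_k, sigma2_k)``; the reference class is pinned at
``mu_0 = 0, sigma2_0 = 1`` for identification.

The marginal likelihood integrates ability out with per-class Gauss-Hermite
quadrature and sums over classes; everything is computed in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit, log_expit, logsumexp

__all__ = [
    "ResponseMatrix",
    "ParameterSet",
    "QuadratureRule",
    "SupportPattern",
    "irf_prob",
    "make_quadrature",
    "log_marginal_likelihood",
    "penalized_objective",
    "apply_identifiability_transform",
]


@dataclass(frozen=True)
class ResponseMatrix:
    """N x J binary item responses with an optional missingness mask.

    ``values`` holds the responses (0/1; entries under a False mask are
    ignored), ``observed`` marks which cells were actually answered.  Missing
    responses are treated as ignorably missing: unobserved items simply drop
    out of a respondent's likelihood product.
    """

    values: np.ndarray
    observed: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if self.observed is None:
            observed = np.ones(values.shape, dtype=bool)
        else:
            observed = np.asarray(self.observed, dtype=bool)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "observed", observed)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if observed.shape != values.shape:
            raise ValueError("observed mask shape must match values")
        n, j = values.shape
        if n < 1 or j < 2:
            raise ValueError("need N >= 1 respondents and J >= 2 items")
        obs_vals = values[observed]
        if not np.all(np.isin(obs_vals, (0.0, 1.0))):
            raise ValueError("observed responses must be exactly 0 or 1")
        if not observed.any(axis=1).all():
            raise ValueError("every respondent needs at least one observed response")

    @classmethod
    def from_values(cls, values, observed=None) -> "ResponseMatrix":
        return cls(np.asarray(values, dtype=float), observed)

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def J(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ParameterSet:
    """All free parameters of the mixture 2-PL latent-DIF model.

    ``delta`` has one column per non-reference class (classes ``1..K``); the
    reference class's DIF column is implicitly zero.  ``nu``, ``mu`` and
    ``sigma2`` have length ``K + 1`` (reference class first) with the
    identification constraints ``mu[0] == 0`` and ``sigma2[0] == 1``.
    """

    a: np.ndarray
    d: np.ndarray
    delta: np.ndarray
    nu: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        d = np.asarray(self.d, dtype=float)
        delta = np.asarray(self.delta, dtype=float)
        nu = np.asarray(self.nu, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        sigma2 = np.asarray(self.sigma2, dtype=float)
        for name, arr in (("a", a), ("d", d), ("delta", delta), ("nu", nu),
                          ("mu", mu), ("sigma2", sigma2)):
            object.__setattr__(self, name, arr)
        j = a.shape[0]
        if d.shape != (j,):
            raise ValueError("a and d must have equal length J")
        if delta.ndim != 2 or delta.shape[0] != j:
            raise ValueError("delta must be J x K")
        k = delta.shape[1]
        if nu.shape != (k + 1,) or mu.shape != (k + 1,) or sigma2.shape != (k + 1,):
            raise ValueError("nu, mu, sigma2 must have length K + 1")
        if not (np.all(nu >= -1e-12) and abs(nu.sum() - 1.0) < 1e-8):
            raise ValueError("nu must lie on the probability simplex")
        if mu[0] != 0.0 or sigma2[0] != 1.0:
            raise ValueError("reference class must have mu[0] = 0, sigma2[0] = 1")
        if not np.all(sigma2 > 0):
            raise ValueError("all class variances must be positive")
        if not all(np.all(np.isfinite(arr)) for arr in (a, d, delta, nu, mu, sigma2)):
            raise ValueError("parameters must be finite")

    @property
    def J(self) -> int:
        return self.a.shape[0]

    @property
    def K(self) -> int:
        return self.delta.shape[1]

    def delta_full(self) -> np.ndarray:
        """DIF matrix including the all-zero reference column, shape J x (K+1)."""
        return np.hstack([np.zeros((self.J, 1)), self.delta])

    def replace(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "a": self.a.tolist(),
            "d": self.d.tolist(),
            "delta": self.delta.tolist(),
            "nu": self.nu.tolist(),
            "mu": self.mu.tolist(),
            "sigma2": self.sigma2.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ParameterSet":
        return cls(
            a=np.asarray(payload["a"], dtype=float),
            d=np.asarray(payload["d"], dtype=float),
            delta=np.asarray(payload["delta"], dtype=float),
            nu=np.asarray(payload["nu"], dtype=float),
            mu=np.asarray(payload["mu"], dtype=float),
            sigma2=np.asarray(payload["sigma2"], dtype=float),
        )


@dataclass(frozen=True)
class QuadratureRule:
    """Per-class Gauss-Hermite rule discretising N(mu_k, sigma2_k).

    ``nodes`` and ``weights`` are (K+1) x Q; each class's weights sum to 1.
    """

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)
        if nodes.shape != weights.shape or nodes.ndim != 2:
            raise ValueError("nodes and weights must be matching 2-D arrays")
        if not np.allclose(weights.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("per-class quadrature weights must sum to 1")

    @property
    def Q(self) -> int:
        return self.nodes.shape[1]

    def log_weights(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.weights)


@dataclass(frozen=True)
class SupportPattern:
    """Boolean J x K pattern marking which DIF parameters are free."""

    nonzero: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "nonzero", np.asarray(self.nonzero, dtype=bool))
        if self.nonzero.ndim != 2:
            raise ValueError("support pattern must be a J x K matrix")

    @classmethod
    def from_delta(cls, delta: np.ndarray) -> "SupportPattern":
        return cls(np.asarray(delta) != 0)

    @classmethod
    def full(cls, J: int, K: int) -> "SupportPattern":
        return cls(np.ones((J, K), dtype=bool))

    @classmethod
    def empty(cls, J: int, K: int) -> "SupportPattern":
        return cls(np.zeros((J, K), dtype=bool))

    @property
    def n_nonzero(self) -> int:
        return int(self.nonzero.sum())

    def dif_items(self) -> np.ndarray:
        """Boolean length-J vector: item flagged if any class has nonzero DIF."""
        return self.nonzero.any(axis=1)


def irf_prob(theta: float, a_j: float, d_j: float, delta_jk: float = 0.0):
    """Item response probability P(Y=1 | theta, class k) = expit(a*theta + d + delta)."""
    eta = np.asarray(a_j) * np.asarray(theta) + np.asarray(d_j) + np.asarray(delta_jk)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite item response function input")
    return expit(eta)


def make_quadrature(mu, sigma2, Q: int = 31) -> QuadratureRule:
    """Gauss-Hermite rule transformed to each class's normal ability law.

    For class k the standard rule (x_q, w_q) for weight exp(-x^2) becomes
    nodes ``mu_k + sqrt(2 sigma2_k) x_q`` with weights ``w_q / sqrt(pi)``,
    which integrate exactly against N(mu_k, sigma2_k) for polynomials up to
    degree 2Q-1.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    sigma2 = np.atleast_1d(np.asarray(sigma2, dtype=float))
    if Q < 2:
        raise ValueError("need at least Q = 2 quadrature points")
    if np.any(sigma2 <= 0):
        raise ValueError("class variances must be positive")
    x, w = np.polynomial.hermite.hermgauss(Q)
    nodes = mu[:, None] + np.sqrt(2.0 * sigma2)[:, None] * x[None, :]
    weights = np.broadcast_to(w / np.sqrt(np.pi), nodes.shape).copy()
    return QuadratureRule(nodes=nodes, weights=weights)


def class_node_log_probs(params: ParameterSet, quad: QuadratureRule):
    """log P(Y=1) and log P(Y=0) at every (class, item, node), (K+1, J, Q)."""
    delta_full = params.delta_full()  # (J, K+1)
    # eta[k, j, q] = a_j * node_kq + d_j + delta_jk
    eta = (params.a[None, :, None] * quad.nodes[:, None, :]
           + params.d[None, :, None] + delta_full.T[:, :, None])
    return log_expit(eta), log_expit(-eta)


def response_class_node_loglik(params: ParameterSet, data: ResponseMatrix,
                               quad: QuadratureRule) -> np.ndarray:
    """log P(Y_i | class k, theta = node_kq) for all i, k, q; shape (N, K+1, Q).

    Unobserved cells drop out of the product (ignorable missingness).
    """
    if params.J != data.J:
        raise ValueError("parameter and data item counts differ")
    logp, log1mp = class_node_log_probs(params, quad)
    ym = np.where(data.observed, data.values, 0.0)          # observed 1s
    zm = np.where(data.observed, 1.0 - data.values, 0.0)    # observed 0s
    kk = params.K + 1
    out = np.empty((data.N, kk, quad.Q))
    for k in range(kk):
        out[:, k, :] = ym @ logp[k] + zm @ log1mp[k]
    return out


def log_marginal_likelihood(params: ParameterSet, data: ResponseMatrix,
                            quad: QuadratureRule) -> float:
    """Quadrature approximation to the marginal log-likelihood.

    log L = sum_i log sum_k nu_k sum_q w_kq P(Y_i | k, node_kq), evaluated
    with log-sum-exp so it is finite for any finite parameters.
    """
    if data.N == 0:
        raise ValueError("empty response matrix")
    ll = response_class_node_loglik(params, data, quad)
    with np.errstate(divide="ignore"):
        log_nu = np.log(params.nu)
    joint = ll + log_nu[None, :, None] + quad.log_weights()[None, :, :]
    return float(logsumexp(joint.reshape(data.N, -1), axis=1).sum())


def penalized_objective(params: ParameterSet, data: ResponseMatrix,
                        lam: float, quad: QuadratureRule) -> float:
    """L1-penalised negative marginal log-likelihood: -log L + lam * ||delta||_1."""
    if lam < 0:
        raise ValueError("penalty weight lambda must be non-negative")
    return -log_marginal_likelihood(params, data, quad) + lam * float(
        np.abs(params.delta).sum())


def apply_identifiability_transform(params: ParameterSet, c) -> ParameterSet:
    """Shift non-reference class means by c and absorb the shift into delta.

    Replacing ``mu_k <- mu_k + c_k`` and ``delta_jk <- delta_jk - a_j c_k``
    (k = 1..K) leaves the marginal likelihood unchanged: it re-expresses the
    same model on a relocated ability scale.  Without anchor items this is an
    unidentified direction; the L1 penalty resolves it by favouring sparse
    delta.  Used for invariance testing.
    """
    c = np.atleast_1d(np.asarray(c, dtype=float))
    if c.shape != (params.K,):
        raise ValueError("shift vector must have length K")
    mu = params.mu.copy()
    mu[1:] = mu[1:] + c
    delta = params.delta - params.a[:, None] * c[None, :]
    return params.replace(mu=mu, delta=delta)
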