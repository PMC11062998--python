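"""Proximal-gradient EM for the L1-regularised mixture 2-PL model.

The estimator minimises  -log L(Delta) + lambda * sum_jk |delta_jk|  subject
to the simplex constraint on the class proportions.  Each EM iteration:

1. E-step: joint responsibilities over (latent class, quadrature node) given
   the current parameters.
2. Closed-form update of the class proportions (the Lagrangian minimiser of
   the D_t block of the surrogate).
3. One line-searched proximal-gradient step on the remaining parameters
   (a, d, delta, mu_1..K, log sigma_1..K): plain gradient steps everywhere,
   soft-thresholding on the DIF parameters — so delta entries are driven to
   *exact* zeros.  The step is scaled per coordinate by a diagonal
   Fisher-type curvature estimate (an adaptive step size); the proximal
   operator in this diagonal metric is still coordinate-wise
   soft-thresholding, and the backtracking test uses the matching weighted
   quadratic upper bound, preserving the descent guarantee.

The M-step only needs to improve the surrogate (generalized EM), which by
Jensen's inequality makes the penalised objective non-increasing.  With
``fixed_support`` and ``lam = 0`` the same engine computes the constrained
maximum likelihood refit used for BIC scoring.  With ``known_classes`` the
class responsibilities are one-hot and the engine computes the known-groups
(oracle) estimator in which the class proportions drop out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .model_core import (
    ParameterSet,
    QuadratureRule,
    ResponseMatrix,
    SupportPattern,
    class_node_log_probs,
    log_marginal_likelihood,
    make_quadrature,
    penalized_objective,
    response_class_node_loglik,
)

__all__ = [
    "PosteriorTable",
    "EMControls",
    "FitResult",
    "e_step",
    "update_class_probs",
    "grad_F",
    "f_t",
    "soft_threshold",
    "proximal_update",
    "line_search",
    "fit_regularized",
    "default_init",
]

_MIN_STEP = 1e-12

# box constraints keeping the EM away from the degenerate ridges of the
# mixture likelihood (vanishing class variance with exploding DIF offsets);
# generous relative to any plausible logit-scale effect
_D_MAX = 8.0
_DELTA_MAX = 6.0
_MU_MAX = 5.0
_LOG_SIG_MIN, _LOG_SIG_MAX = np.log(0.3), np.log(3.0)


@dataclass(frozen=True)
class PosteriorTable:
    """Per-respondent posterior mass over (class, quadrature node).

    ``joint[i, k, q] = P(xi_i = k, theta_i ~ node_kq | Y_i, Delta)``;
    ``class_marginal`` sums the node axis out.
    """

    joint: np.ndarray
    class_marginal: np.ndarray

    def __post_init__(self):
        if not np.allclose(self.joint.reshape(self.joint.shape[0], -1).sum(axis=1),
                           1.0, atol=1e-8):
            raise ValueError("posterior mass must sum to 1 per respondent")


@dataclass(frozen=True)
class EMControls:
    """Knobs of the EM solver.

    tol is the relative change of the penalised objective used to declare
    convergence; step_init seeds the backtracking line search (warm-started
    across iterations); n_starts jittered initialisations guard against the
    local optima of the mixture likelihood.
    """

    max_iter: int = 500
    tol: float = 1e-6
    step_init: float = 1.0
    backtrack_factor: float = 0.5
    armijo_const: float = 1e-4
    n_starts: int = 5
    seed: int = 0
    Q: int = 31
    n_inner: int = 25

    def __post_init__(self):
        if self.max_iter < 1 or self.tol <= 0 or self.step_init <= 0:
            raise ValueError("max_iter, tol, step_init must be positive")
        if not (0 < self.backtrack_factor < 1 and 0 < self.armijo_const < 1):
            raise ValueError("backtrack_factor and armijo_const must be in (0,1)")
        if self.n_starts < 1 or self.Q < 2 or self.n_inner < 1:
            raise ValueError("n_starts, n_inner >= 1 and Q >= 2 required")


@dataclass
class FitResult:
    params: ParameterSet
    objective_trace: list = field(default_factory=list)
    loglik: float = np.nan
    support: SupportPattern | None = None
    converged: bool = False
    n_iter: int = 0
    lam: float = 0.0

    def __post_init__(self):
        if self.support is None:
            self.support = SupportPattern.from_delta(self.params.delta)


def e_step(params: ParameterSet, data: ResponseMatrix, quad: QuadratureRule,
           known_classes: np.ndarray | None = None) -> PosteriorTable:
    """Joint responsibilities r_ikq over (class, node), normalised per respondent.

    With ``known_classes`` the class axis is degenerate at the true label and
    only the within-class node posterior is computed.
    """
    ll = response_class_node_loglik(params, data, quad)
    with np.errstate(divide="ignore"):
        log_nu = np.log(params.nu)
    log_joint = ll + quad.log_weights()[None, :, :]
    if known_classes is None:
        log_joint = log_joint + log_nu[None, :, None]
    else:
        mask = np.full((data.N, params.K + 1), -np.inf)
        mask[np.arange(data.N), known_classes] = 0.0
        log_joint = log_joint + mask[:, :, None]
    norm_c = logsumexp(log_joint.reshape(data.N, -1), axis=1)
    joint = np.exp(log_joint - norm_c[:, None, None])
    return PosteriorTable(joint=joint, class_marginal=joint.sum(axis=2))


def update_class_probs(post: PosteriorTable) -> np.ndarray:
    """Closed-form simplex minimiser of D_t: class-average responsibilities."""
    nu = post.class_marginal.mean(axis=0)
    return nu / nu.sum()


def _log_normal_pdf(x, mu, sigma2):
    return norm.logpdf(x, loc=mu, scale=np.sqrt(sigma2))


def f_t(params: ParameterSet, post: PosteriorTable, data: ResponseMatrix,
        quad: QuadratureRule) -> float:
    """Smooth surrogate block F_t(Delta_2) at fixed expansion-point nodes.

    F_t = - sum_ikq r_ikq [ log P(Y_i | k, x_kq; a, d, delta)
                            + log phi(x_kq | mu_k, sigma2_k) ],
    where the nodes x_kq and responsibilities r come from the E-step at the
    expansion point and stay fixed while Delta_2 varies.
    """
    ll = response_class_node_loglik(params, data, quad)
    bern = float(np.sum(post.joint * ll))
    node_mass = post.joint.sum(axis=0)  # (K+1, Q)
    logphi = _log_normal_pdf(quad.nodes, params.mu[:, None], params.sigma2[:, None])
    return -(bern + float(np.sum(node_mass * logphi)))


def grad_F(params: ParameterSet, post: PosteriorTable, data: ResponseMatrix,
           quad: QuadratureRule) -> dict:
    """Exact gradient of F_t w.r.t. (a, d, delta, mu_1..K, log sigma_1..K).

    The item blocks are weighted logistic-regression scores: for each item,
    sum over (i, k, q) of r_ikq (Y_ij - p_jkq) times d(eta)/d(parameter).
    """
    kk = params.K + 1
    logp, _ = class_node_log_probs(params, quad)
    p = np.exp(logp)  # (K+1, J, Q)
    ym = np.where(data.observed, data.values, 0.0)
    om = data.observed.astype(float)
    g_a = np.zeros(params.J)
    g_d = np.zeros(params.J)
    g_delta = np.zeros((params.J, params.K))
    for k in range(kk):
        r_k = post.joint[:, k, :]                      # (N, Q)
        s1 = ym.T @ r_k                                # (J, Q) sum r * y (observed)
        s0 = om.T @ r_k                                # (J, Q) sum r (observed)
        resid = s1 - p[k] * s0                         # (J, Q)
        g_a -= resid @ quad.nodes[k]
        g_d -= resid.sum(axis=1)
        if k >= 1:
            g_delta[:, k - 1] = -resid.sum(axis=1)
    node_mass = post.joint.sum(axis=0)                 # (K+1, Q)
    g_mu = np.zeros(params.K)
    g_logsig = np.zeros(params.K)
    for k in range(1, kk):
        z = quad.nodes[k] - params.mu[k]
        g_mu[k - 1] = -float(np.sum(node_mass[k] * z)) / params.sigma2[k]
        g_logsig[k - 1] = -float(np.sum(node_mass[k] * (z**2 / params.sigma2[k] - 1.0)))
    return {"a": g_a, "d": g_d, "delta": g_delta, "mu": g_mu, "log_sigma": g_logsig}


def curvature_diag(params: ParameterSet, post: PosteriorTable,
                   data: ResponseMatrix, quad: QuadratureRule) -> dict:
    """Diagonal Fisher-type curvature of F_t, used to precondition the step.

    Item blocks use the Bernoulli information p(1-p) weighted by
    responsibilities; the structural blocks use the normal-model information.
    Floored away from zero so coordinates with vanishing responsibility keep
    a finite step.
    """
    kk = params.K + 1
    logp, log1mp = class_node_log_probs(params, quad)
    pq = np.exp(logp + log1mp)  # p * (1 - p), shape (K+1, J, Q)
    om = data.observed.astype(float)
    c_a = np.zeros(params.J)
    c_d = np.zeros(params.J)
    c_delta = np.zeros((params.J, params.K))
    for k in range(kk):
        s0 = om.T @ post.joint[:, k, :]               # (J, Q)
        info = s0 * pq[k]
        c_a += info @ (quad.nodes[k] ** 2)
        c_d += info.sum(axis=1)
        if k >= 1:
            c_delta[:, k - 1] = info.sum(axis=1)
    node_mass = post.joint.sum(axis=0)
    c_mu = np.zeros(params.K)
    c_logsig = np.zeros(params.K)
    for k in range(1, kk):
        z2 = (quad.nodes[k] - params.mu[k]) ** 2
        c_mu[k - 1] = float(node_mass[k].sum()) / params.sigma2[k]
        c_logsig[k - 1] = 2.0 * float(np.sum(node_mass[k] * z2)) / params.sigma2[k]
    floor = max(1e-6 * max(c_a.max(), c_d.max(), 1.0), 1e-8)
    return {key: np.maximum(val, floor) for key, val in
            (("a", c_a), ("d", c_d), ("delta", c_delta),
             ("mu", c_mu), ("log_sigma", c_logsig))}


def soft_threshold(z, t):
    """Proximal operator of t * |.|: shrink toward zero, snapping to exact 0."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("threshold must be non-negative")
    z = np.asarray(z, dtype=float)
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def _delta2_step(params: ParameterSet, grad: dict, lam: float, step: float,
                 support: np.ndarray | None,
                 precond: dict | None = None) -> ParameterSet:
    """One proximal-gradient update of Delta_2 (class proportions untouched).

    With a diagonal preconditioner W the update is
    x <- x - step * g / W with soft-threshold step * lam / W_delta on the DIF
    block (the proximal operator of the L1 term in the W-metric).
    """
    if precond is None:
        precond = {key: 1.0 for key in ("a", "d", "delta", "mu", "log_sigma")}
    a = params.a - step * grad["a"] / precond["a"]
    d = np.clip(params.d - step * grad["d"] / precond["d"], -_D_MAX, _D_MAX)
    delta = soft_threshold(params.delta - step * grad["delta"] / precond["delta"],
                           step * lam / precond["delta"])
    delta = np.clip(delta, -_DELTA_MAX, _DELTA_MAX)
    if support is not None:
        delta = np.where(support, delta, 0.0)
    mu = params.mu.copy()
    mu[1:] = np.clip(mu[1:] - step * grad["mu"] / precond["mu"], -_MU_MAX, _MU_MAX)
    log_sig = 0.5 * np.log(params.sigma2)
    log_sig[1:] = np.clip(log_sig[1:] - step * grad["log_sigma"] / precond["log_sigma"],
                          _LOG_SIG_MIN, _LOG_SIG_MAX)
    sigma2 = np.exp(2.0 * log_sig)
    sigma2[0] = 1.0
    mu[0] = 0.0
    return params.replace(a=a, d=d, delta=delta, mu=mu, sigma2=sigma2)


def _delta2_diff(new: ParameterSet, old: ParameterSet) -> np.ndarray:
    """Flat difference vector of the Delta_2 coordinates (log-sigma scale)."""
    return np.concatenate([
        new.a - old.a,
        new.d - old.d,
        (new.delta - old.delta).ravel(),
        new.mu[1:] - old.mu[1:],
        0.5 * (np.log(new.sigma2[1:]) - np.log(old.sigma2[1:])),
    ])


def proximal_update(params: ParameterSet, post: PosteriorTable,
                    data: ResponseMatrix, quad: QuadratureRule, lam: float,
                    step: float, support: np.ndarray | None = None,
                    update_nu: bool = True) -> ParameterSet:
    """Single proximal-gradient M-step update at a given step size.

    DIF parameters are soft-thresholded at step*lambda; all other Delta_2
    coordinates take vanilla gradient steps; the class proportions take their
    closed-form update.
    """
    if step <= 0:
        raise ValueError("step size must be positive")
    grad = grad_F(params, post, data, quad)
    new = _delta2_step(params, grad, lam, step, support)
    if update_nu:
        new = new.replace(nu=update_class_probs(post))
    return new


def _flat(grad: dict) -> np.ndarray:
    return np.concatenate([grad["a"], grad["d"], grad["delta"].ravel(),
                           grad["mu"], grad["log_sigma"]])


def line_search(params: ParameterSet, post: PosteriorTable, data: ResponseMatrix,
                quad: QuadratureRule, lam: float, step_init: float,
                controls: EMControls, support: np.ndarray | None = None):
    """Backtracking proximal-gradient step on F_t + G.

    Shrinks the step until the quadratic-upper-bound sufficient-decrease test
    F_t(z) <= F_t(x) + grad'(z-x) + ||z-x||^2 / (2 step) holds, which
    guarantees a strict decrease of F_t + G away from stationary points.
    Returns (step, new_params, stationary).
    """
    fx = f_t(params, post, data, quad)
    grad = grad_F(params, post, data, quad)
    precond = curvature_diag(params, post, data, quad)
    gvec = _flat(grad)
    wvec = _flat(precond)
    g_old = lam * float(np.abs(params.delta).sum())
    step = float(min(step_init, 4.0))
    while step >= _MIN_STEP:
        cand = _delta2_step(params, grad, lam, step, support, precond)
        diff = _delta2_diff(cand, params)
        wsq = float((diff * wvec) @ diff)
        if wsq == 0.0:
            return step, params, True
        lin = float(gvec @ diff)
        f_new = f_t(cand, post, data, quad)
        g_new = lam * float(np.abs(cand.delta).sum())
        upper_ok = f_new <= fx + lin + wsq / (2.0 * step) + 1e-10 * abs(fx)
        decreased = f_new + g_new < fx + g_old
        if upper_ok and decreased:
            return step, cand, False
        step *= controls.backtrack_factor
    return step, params, True


# multipliers applied to the base focal-mean pattern across multistarts: the
# no-DIF mixture likelihood is nearly flat across structural basins, so the
# starts must cover well-separated (and sign-flipped) class configurations
_MU_SCALES = (1.0, 2.0, 3.0, -2.0, 4.0, -3.0, 0.5, 5.0)


def default_init(data: ResponseMatrix, K: int, rng: np.random.Generator | None = None,
                 jitter: float = 0.0, mu_scale: float = 1.0) -> ParameterSet:
    """Symmetry-breaking starting point.

    a = 1, d = logit of observed item means (clipped to +-3), delta = 0,
    uniform class proportions, focal means spread over [0.25, 1] times
    ``mu_scale``, unit variances — plus optional seeded Gaussian jitter.
    Multistarts cycle ``mu_scale`` through a coarse grid of magnitudes and
    signs to reach the separated basins of the mixture likelihood.
    """
    with np.errstate(divide="ignore"):
        means = np.where(data.observed, data.values, np.nan)
        pbar = np.clip(np.nanmean(means, axis=0), 1e-3, 1 - 1e-3)
    d = np.clip(np.log(pbar / (1 - pbar)), -3.0, 3.0)
    a = np.ones(data.J)
    delta = np.zeros((data.J, K))
    nu = np.full(K + 1, 1.0 / (K + 1))
    mu = np.zeros(K + 1)
    if K > 0:
        mu[1:] = np.clip(np.linspace(0.25, 1.0, K) * mu_scale, -_MU_MAX, _MU_MAX)
    sigma2 = np.ones(K + 1)
    if jitter > 0 and rng is not None:
        a = a + jitter * rng.standard_normal(data.J)
        d = d + jitter * rng.standard_normal(data.J)
        if K > 0:
            mu[1:] = mu[1:] + jitter * rng.standard_normal(K)
    return ParameterSet(a=a, d=d, delta=delta, nu=nu, mu=mu, sigma2=sigma2)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def reanchor(params: ParameterSet, lam: float) -> ParameterSet:
    """Exact descent move along the mean-shift/DIF invariance direction.

    Shifting mu_k by c and delta_jk by -a_j c leaves the likelihood unchanged,
    so choosing c_k to minimise the L1 penalty — the weighted median of
    delta_jk / a_j with weights |a_j| — can only decrease the penalised
    objective.  Applied when it strictly shrinks the penalty; keeps the
    estimate anchored at the sparse representative of the ridge.
    """
    if lam <= 0 or params.K == 0:
        return params
    a = params.a
    usable = np.abs(a) > 1e-8
    if usable.sum() < 2:
        return params
    c = np.empty(params.K)
    for k in range(params.K):
        c[k] = _weighted_median(params.delta[usable, k] / a[usable],
                                np.abs(a[usable]))
    if np.all(np.abs(c) < 1e-12):
        return params
    new_delta = params.delta - a[:, None] * c[None, :]
    if np.abs(new_delta).sum() >= np.abs(params.delta).sum() - 1e-12:
        return params
    mu = params.mu.copy()
    mu[1:] = np.clip(mu[1:] + c, -_MU_MAX, _MU_MAX)
    if np.any(mu[1:] != params.mu[1:] + c):  # clip would break invariance
        return params
    return params.replace(mu=mu, delta=new_delta)


def _base_2pl(data: ResponseMatrix, controls: EMControls) -> ParameterSet:
    """Quick plain 2-PL fit (no latent classes) used to seed smart starts."""
    quick = EMControls(max_iter=150, tol=1e-5, n_starts=1, seed=controls.seed,
                       Q=min(controls.Q, 21), n_inner=controls.n_inner)
    fit = _em_single(data, 0.0, quick, default_init(data, 0), None, None)
    return fit.params


def _eap_theta(params: ParameterSet, data: ResponseMatrix, Q: int) -> np.ndarray:
    """Posterior-mean ability under a plain 2-PL with a N(0,1) prior."""
    base = params.replace(delta=np.zeros((params.J, 0)), nu=np.array([1.0]),
                          mu=np.array([0.0]), sigma2=np.array([1.0]))
    quad = make_quadrature(base.mu, base.sigma2, Q)
    post = e_step(base, data, quad)
    return post.joint[:, 0, :] @ quad.nodes[0]


def smart_init(data: ResponseMatrix, K: int, rng: np.random.Generator,
               base: ParameterSet, controls: EMControls) -> ParameterSet:
    """Cluster-seeded start for the latent-DIF mixture.

    Fits abilities under a no-class 2-PL, clusters the respondents' response
    residuals with k-means into K+1 groups (respondents sharing systematic
    residual patterns — the latent-DIF signature — end up together), and
    seeds class proportions, focal means and DIF offsets from the clusters.
    Without such symmetry breaking the EM cannot leave the no-DIF saddle.
    """
    from scipy.cluster.vq import kmeans2

    theta = _eap_theta(base, data, controls.Q)
    eta = base.a[None, :] * theta[:, None] + base.d[None, :]
    resid = np.where(data.observed, data.values - expit(eta), 0.0)
    seed = int(rng.integers(2**31 - 1))
    try:
        _, labels = kmeans2(resid, K + 1, minit="++", seed=seed)
    except Exception:
        return default_init(data, K, rng, jitter=0.2, mu_scale=2.0)
    sizes = np.bincount(labels, minlength=K + 1)
    if (sizes == 0).any():
        return default_init(data, K, rng, jitter=0.2, mu_scale=2.0)
    # biggest cluster plays the reference class
    order = np.argsort(sizes)[::-1]
    relabel = np.empty(K + 1, dtype=int)
    relabel[order] = np.arange(K + 1)
    labels = relabel[labels]
    nu = np.bincount(labels, minlength=K + 1) / data.N
    nu = np.maximum(nu, 0.02)
    nu /= nu.sum()
    theta_bar = np.array([theta[labels == k].mean() for k in range(K + 1)])
    mu = np.zeros(K + 1)
    mu[1:] = np.clip(theta_bar[1:] - theta_bar[0], -_MU_MAX, _MU_MAX)
    # working-response logit offsets per cluster seed the DIF matrix
    pbar = expit(base.d)  # item response scale proxy
    info = np.maximum(pbar * (1 - pbar), 0.1)
    delta = np.zeros((data.J, K))
    for k in range(1, K + 1):
        rbar_k = resid[labels == k].mean(axis=0)
        rbar_0 = resid[labels == 0].mean(axis=0)
        raw = (rbar_k - rbar_0) / info - base.a * mu[k]
        delta[:, k - 1] = np.clip(raw, -2.0, 2.0)
    return ParameterSet(a=base.a, d=base.d, delta=delta, nu=nu, mu=mu,
                        sigma2=np.ones(K + 1))


def _oracle_loglik(params: ParameterSet, data: ResponseMatrix,
                   quad: QuadratureRule, known_classes: np.ndarray) -> float:
    """Known-groups log-likelihood: class proportions drop out."""
    ll = response_class_node_loglik(params, data, quad)
    rows = ll[np.arange(data.N), known_classes, :] + quad.log_weights()[known_classes]
    return float(logsumexp(rows, axis=1).sum())


def _objective(params, data, lam, quad, known_classes):
    if known_classes is None:
        return penalized_objective(params, data, lam, quad)
    return -_oracle_loglik(params, data, quad, known_classes) + lam * float(
        np.abs(params.delta).sum())


def _em_single(data: ResponseMatrix, lam: float, controls: EMControls,
               init: ParameterSet, support: np.ndarray | None,
               known_classes: np.ndarray | None) -> FitResult:
    params = init
    quad = make_quadrature(params.mu, params.sigma2, controls.Q)
    obj = _objective(params, data, lam, quad, known_classes)
    trace = [obj]
    step_ws = controls.step_init
    converged = False
    n_iter = 0
    for n_iter in range(1, controls.max_iter + 1):
        post = e_step(params, data, quad, known_classes)
        if known_classes is None and params.K > 0:
            params = params.replace(nu=update_class_probs(post))
        # M-step: improve the surrogate with up to n_inner line-searched
        # proximal steps at fixed responsibilities (generalized EM)
        new_params, stationary = params, True
        inner_ref = None
        for _ in range(controls.n_inner):
            step, cand, stat = line_search(
                new_params, post, data, quad, lam, step_ws * 2.0, controls,
                support)
            if stat:
                break
            stationary = False
            step_ws = step
            new_params = cand
            fg = f_t(cand, post, data, quad) + lam * float(np.abs(cand.delta).sum())
            if inner_ref is not None and inner_ref - fg < 0.1 * controls.tol * max(
                    1.0, abs(fg)):
                break
            inner_ref = fg
        if stationary:
            converged = True
            break
        if support is None:  # transform would disturb pinned zero constraints
            new_params = reanchor(new_params, lam)
        new_quad = make_quadrature(new_params.mu, new_params.sigma2, controls.Q)
        new_obj = _objective(new_params, data, lam, new_quad, known_classes)
        if new_obj > trace[-1] + 1e-9 * max(1.0, abs(trace[-1])):
            # quadrature refresh can break monotonicity only at convergence
            converged = True
            break
        params, quad = new_params, new_quad
        step_ws = step
        rel = abs(trace[-1] - new_obj) / max(1.0, abs(new_obj))
        trace.append(new_obj)
        if rel < controls.tol:
            converged = True
            break
    if known_classes is None:
        loglik = log_marginal_likelihood(params, data, quad)
    else:
        loglik = _oracle_loglik(params, data, quad, known_classes)
    return FitResult(params=params, objective_trace=trace, loglik=loglik,
                     support=SupportPattern.from_delta(params.delta),
                     converged=converged, n_iter=n_iter, lam=lam)


def fit_regularized(data: ResponseMatrix, K: int, lam: float,
                    controls: EMControls = EMControls(),
                    init: ParameterSet | None = None,
                    fixed_support: SupportPattern | None = None,
                    known_classes: np.ndarray | None = None) -> FitResult:
    """Solve the L1-penalised (or support-constrained) marginal ML problem.

    With ``fixed_support`` given, delta entries outside the support are pinned
    at zero and excluded from updates; combined with ``lam = 0`` this is the
    constrained refit used for BIC scoring.  With ``known_classes`` the latent
    classes are fixed at the given labels (oracle estimator).  When ``init``
    is supplied (warm start) a single run is performed; otherwise
    ``controls.n_starts`` jittered starts are run and the best final objective
    wins.
    """
    if K < 0 or lam < 0:
        raise ValueError("K and lambda must be non-negative")
    support = None if fixed_support is None else fixed_support.nonzero
    if support is not None and support.shape != (data.J, K):
        raise ValueError("fixed_support shape must be J x K")
    if known_classes is not None:
        known_classes = np.asarray(known_classes, dtype=int)
        if known_classes.shape != (data.N,) or known_classes.max(initial=0) > K:
            raise ValueError("known_classes must be length N with labels in 0..K")
    if init is not None:
        starts = [init]
    elif K == 0 or known_classes is not None:
        rng = np.random.default_rng(controls.seed)
        starts = [default_init(data, K, rng, jitter=0.0 if s == 0 else 0.1)
                  for s in range(1 if known_classes is not None else
                                 controls.n_starts)]
    else:
        # default start plus cluster-seeded smart starts: the mixture EM
        # cannot leave the no-DIF saddle from symmetric starts
        rng = np.random.default_rng(controls.seed)
        base = _base_2pl(data, controls)
        starts = [default_init(data, K, rng)]
        starts += [smart_init(data, K, rng, base, controls)
                   for _ in range(max(controls.n_starts - 1, 1))]
    best: FitResult | None = None
    for start in starts:
        if support is not None:
            start = start.replace(delta=np.where(support, start.delta, 0.0))
        fit = _em_single(data, lam, controls, start, support, known_classes)
        if best is None or fit.objective_trace[-1] < best.objective_trace[-1]:
            best = fit
    return best
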