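"""EM engine: E-step, gradients, proximal updates, line search, full fits."""

import numpy as np
import pytest
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit

import latdif as ld
from latdif.em_estimator import (
    EMControls,
    _flat,
    e_step,
    f_t,
    fit_regularized,
    grad_F,
    line_search,
    proximal_update,
    reanchor,
    soft_threshold,
    update_class_probs,
)
from latdif.model_core import (
    ParameterSet,
    ResponseMatrix,
    SupportPattern,
    make_quadrature,
)


class TestEStep:
    def test_no_classes_puts_all_mass_in_reference(self, small_data):
        params = ParameterSet(a=np.ones(4), d=np.zeros(4),
                              delta=np.zeros((4, 0)), nu=np.array([1.0]),
                              mu=np.array([0.0]), sigma2=np.array([1.0]))
        quad = make_quadrature(params.mu, params.sigma2, 21)
        post = e_step(params, small_data, quad)
        np.testing.assert_allclose(post.class_marginal[:, 0], 1.0, atol=1e-12)

    def test_exchangeable_classes_get_equal_mass(self, small_data):
        params = ParameterSet(a=np.ones(4), d=np.zeros(4),
                              delta=np.tile([[0.5]], (4, 2)),
                              nu=np.array([0.4, 0.3, 0.3]),
                              mu=np.array([0.0, 0.2, 0.2]),
                              sigma2=np.array([1.0, 1.1, 1.1]))
        quad = make_quadrature(params.mu, params.sigma2, 21)
        post = e_step(params, small_data, quad)
        np.testing.assert_allclose(post.class_marginal[:, 1],
                                   post.class_marginal[:, 2], atol=1e-12)

    def test_matches_term_by_term_enumeration(self, small_params, small_data):
        quad = make_quadrature(small_params.mu, small_params.sigma2, 25)
        post = e_step(small_params, small_data, quad)
        delta_full = small_params.delta_full()
        manual = np.zeros_like(post.joint)
        for k in range(small_params.K + 1):
            for q in range(25):
                p = expit(small_params.a * quad.nodes[k, q] + small_params.d
                          + delta_full[:, k])
                like = np.where(small_data.observed,
                                np.where(small_data.values == 1,
                                         p[None, :], 1 - p[None, :]), 1.0)
                manual[:, k, q] = (small_params.nu[k] * quad.weights[k, q]
                                   * like.prod(axis=1))
        manual /= manual.sum(axis=(1, 2), keepdims=True)
        np.testing.assert_allclose(post.joint, manual, atol=1e-10)

    def test_posterior_mass_sums_to_one(self, small_params, small_data):
        quad = make_quadrature(small_params.mu, small_params.sigma2, 31)
        post = e_step(small_params, small_data, quad)
        np.testing.assert_allclose(
            post.joint.reshape(small_data.N, -1).sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(post.class_marginal,
                                   post.joint.sum(axis=2), atol=1e-12)


class TestClassProbUpdate:
    def test_uniform_marginals_give_uniform_probs(self, small_params, small_data):
        quad = make_quadrature(small_params.mu, small_params.sigma2, 21)
        post = e_step(small_params, small_data, quad)
        uniform = post.joint * 0 + 1.0 / post.joint[0].size
        from latdif.em_estimator import PosteriorTable
        flat = PosteriorTable(joint=uniform, class_marginal=uniform.sum(axis=2))
        np.testing.assert_allclose(update_class_probs(flat), 1 / 3, atol=1e-12)

    def test_matches_constrained_numerical_minimiser(self, rng):
        # D_t(nu) = -sum_i sum_k m_ik log nu_k minimised on the simplex
        m = rng.random((7, 3))
        m /= m.sum(axis=1, keepdims=True)
        closed = m.mean(axis=0)

        def d_t(v):
            v = np.abs(v) / np.abs(v).sum()
            return -(m * np.log(np.maximum(v, 1e-12))).sum()

        res = minimize(d_t, np.array([1 / 3] * 3), method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-12, maxiter=5000))
        numerical = np.abs(res.x) / np.abs(res.x).sum()
        np.testing.assert_allclose(closed, numerical, atol=1e-6)


class TestGradient:
    def test_matches_central_finite_differences(self, small_params, small_data):
        quad = make_quadrature(small_params.mu, small_params.sigma2, 15)
        post = e_step(small_params, small_data, quad)
        g = _flat(grad_F(small_params, post, small_data, quad))
        J, K = small_params.J, small_params.K

        def pack(p):
            return np.concatenate([p.a, p.d, p.delta.ravel(), p.mu[1:],
                                   0.5 * np.log(p.sigma2[1:])])

        def unpack(v):
            mu = np.concatenate([[0.0], v[2 * J + J * K:2 * J + J * K + K]])
            s2 = np.concatenate([[1.0], np.exp(2 * v[2 * J + J * K + K:])])
            return small_params.replace(
                a=v[:J], d=v[J:2 * J],
                delta=v[2 * J:2 * J + J * K].reshape(J, K), mu=mu, sigma2=s2)

        x0, h = pack(small_params), 1e-5
        for i in range(x0.size):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += h
            xm[i] -= h
            num = (f_t(unpack(xp), post, small_data, quad)
                   - f_t(unpack(xm), post, small_data, quad)) / (2 * h)
            assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-7)

    def test_score_small_at_truth_for_large_sample(self):
        config = ld.get_scenario("two_group_J25_pi0.5_N1000", seed=3)
        ds = ld.generate_dataset(config, 1)
        quad = make_quadrature(ds.true_params.mu, ds.true_params.sigma2, 31)
        post = e_step(ds.true_params, ds.responses, quad)
        g = grad_F(ds.true_params, post, ds.responses, quad)
        # stochastic score: O(sqrt(N * J)) fluctuation around zero
        assert np.abs(g["a"]).max() < 4 * np.sqrt(1000)
        assert np.abs(g["delta"]).max() < 4 * np.sqrt(1000)

    def test_zero_responsibility_class_has_zero_dif_gradient(self, small_data):
        params = ParameterSet(a=np.ones(4), d=np.zeros(4),
                              delta=np.zeros((4, 1)), nu=np.array([1.0, 0.0]),
                              mu=np.array([0.0, 0.5]),
                              sigma2=np.array([1.0, 1.0]))
        quad = make_quadrature(params.mu, params.sigma2, 21)
        post = e_step(params, small_data, quad)
        g = grad_F(params, post, small_data, quad)
        np.testing.assert_allclose(g["delta"], 0.0, atol=1e-12)


class TestSoftThreshold:
    @pytest.mark.parametrize("z,t,expected", [
        (1.0, 0.3, 0.7),
        (-0.2, 0.3, 0.0),
        (0.0, 5.0, 0.0),
        (-1.5, 0.5, -1.0),
    ])
    def test_values(self, z, t, expected):
        out = soft_threshold(z, t)
        assert out == pytest.approx(expected)
        if expected == 0.0:
            assert out == 0.0  # exact zero, no fuzz

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


class TestProximalUpdate:
    def test_huge_lambda_zeroes_all_dif(self, small_params, small_data):
        quad = make_quadrature(small_params.mu, small_params.sigma2, 21)
        post = e_step(small_params, small_data, quad)
        new = proximal_update(small_params, post, small_data, quad,
                              lam=1e9, step=1.0)
        assert np.all(new.delta == 0.0)

    def test_lambda_zero_is_plain_gradient_step(self, small_params, small_data):
        quad = make_quadrature(small_params.mu, small_params.sigma2, 21)
        post = e_step(small_params, small_data, quad)
        a = proximal_update(small_params, post, small_data, quad, 0.0, 0.5,
                            update_nu=False)
        b = proximal_update(small_params, post, small_data, quad, 1e-300, 0.5,
                            update_nu=False)
        np.testing.assert_allclose(a.delta, b.delta, atol=1e-12)
        np.testing.assert_allclose(a.a, b.a, atol=1e-12)

    def test_prox_matches_scalar_surrogate_minimiser(self):
        # prox of t|.| at z solves min_x (x - z)^2 / 2 + t |x|
        for z, t in [(0.9, 0.4), (-1.3, 0.7), (0.2, 0.5)]:
            mine = soft_threshold(z, t)
            res = minimize_scalar(lambda x: 0.5 * (x - z) ** 2 + t * abs(x),
                                  bounds=(-5, 5), method="bounded",
                                  options=dict(xatol=1e-12))
            assert mine == pytest.approx(res.x, abs=1e-8)


class TestLineSearch:
    def test_accepted_step_decreases_surrogate(self, small_params, small_data):
        quad = make_quadrature(small_params.mu, small_params.sigma2, 21)
        post = e_step(small_params, small_data, quad)
        controls = EMControls()
        before = f_t(small_params, post, small_data, quad) \
            + 0.4 * np.abs(small_params.delta).sum()
        step, new, stationary = line_search(
            small_params, post, small_data, quad, 0.4, 1.0, controls)
        assert not stationary
        after = f_t(new, post, small_data, quad) + 0.4 * np.abs(new.delta).sum()
        assert after < before

    def test_reanchor_never_increases_penalty(self, small_params):
        before = np.abs(small_params.delta).sum()
        out = reanchor(small_params, lam=1.0)
        assert np.abs(out.delta).sum() <= before + 1e-12


class TestFitRegularized:
    def test_plain_2pl_parameter_recovery(self):
        # J = 3 pins the latent scale only weakly, so a larger sample keeps
        # the maximum-likelihood noise inside the recovery tolerance
        rng = np.random.default_rng(11)
        J, N = 3, 1000
        a = rng.uniform(0.8, 1.3, J)
        d = rng.uniform(-1.0, 1.0, J)
        theta = rng.normal(0, 1, N)
        y = (rng.random((N, J)) < expit(a * theta[:, None] + d)).astype(float)
        fit = fit_regularized(ResponseMatrix(y, None), 0, 0.0,
                              EMControls(n_starts=1, max_iter=400, tol=1e-8))
        assert fit.converged
        assert np.sqrt(np.mean((fit.params.a - a) ** 2)) <= 0.25
        assert np.sqrt(np.mean((fit.params.d - d) ** 2)) <= 0.25

    def test_large_lambda_matches_no_dif_fit(self):
        ds = ld.generate_dataset(ld.ScenarioConfig(
            name="tiny", N=300, J=8, K=1, class_proportions=(0.7, 0.3),
            class_means=(0.0, 0.5), class_variances=(1.0, 1.5),
            dif_items_per_class=((1, 2, 3),), dif_ranges=((0.5, 1.5),),
            seed=5), 1)
        controls = EMControls(n_starts=2, max_iter=300, Q=21)
        big = fit_regularized(ds.responses, 1, 1e4, controls)
        assert big.support.n_nonzero == 0
        null = fit_regularized(ds.responses, 1, 0.0, controls,
                               fixed_support=SupportPattern.empty(8, 1))
        # the large-lambda limit is a no-DIF mixture fit; multistart basins
        # may differ, so it must do at least as well as the pinned null fit
        assert big.objective_trace[-1] <= -null.loglik + 0.5

    def test_objective_trace_monotone_and_invariants(self, rng):
        for trial in range(3):
            y = (rng.random((80, 6)) < rng.uniform(0.2, 0.8, 6)).astype(float)
            fit = fit_regularized(ResponseMatrix(y, None), 1, 0.5,
                                  EMControls(n_starts=2, max_iter=60, Q=15))
            trace = np.asarray(fit.objective_trace)
            assert np.all(np.diff(trace) <= 1e-9 * np.maximum(1, np.abs(trace[:-1])))
            p = fit.params
            assert p.nu.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all(p.nu >= 0)
            assert np.all(p.sigma2 > 0)
            assert p.mu[0] == 0.0 and p.sigma2[0] == 1.0
            np.testing.assert_array_equal(fit.support.nonzero, p.delta != 0)

    def test_sparsity_is_exact(self, rng):
        y = (rng.random((100, 6)) < 0.5).astype(float)
        fit = fit_regularized(ResponseMatrix(y, None), 1, 2.0,
                              EMControls(n_starts=1, max_iter=80, Q=15))
        nz = fit.params.delta[fit.params.delta != 0]
        assert np.all(np.abs(nz) > 1e-8)

    def test_refit_attains_no_worse_unpenalised_objective(self, rng):
        y = (rng.random((120, 6)) < rng.uniform(0.3, 0.7, 6)).astype(float)
        data = ResponseMatrix(y, None)
        controls = EMControls(n_starts=2, max_iter=150, Q=15)
        pen = fit_regularized(data, 1, 1.0, controls)
        refit = fit_regularized(data, 1, 0.0, controls, init=pen.params,
                                fixed_support=SupportPattern.full(6, 1))
        assert refit.loglik >= pen.loglik - 1e-6

    def test_nonconvergence_reported_not_raised(self, rng):
        y = (rng.random((50, 5)) < 0.5).astype(float)
        fit = fit_regularized(ResponseMatrix(y, None), 1, 0.1,
                              EMControls(n_starts=1, max_iter=2, tol=1e-14, Q=15))
        assert isinstance(fit.converged, bool)
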