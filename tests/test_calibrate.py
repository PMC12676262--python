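import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dynemu.calibrate import (
    CalibConfig,
    CalibState,
    bias_ffbs,
    emulator_conditional,
    inverse_transform_phi,
    log_jacobian,
    log_target_phi,
    make_bundle,
    metropolis_step,
    tau2_gibbs,
    transform_phi,
    y_gibbs,
)
from dynemu.emulator import train_emulator


def _coords(s):
    return np.arange(float(s))[:, None]


def scalar_config(T=1, **kw):
    defaults = dict(priors=[("lognormal", 0.0, 1.0)], coords=_coords(1),
                    rho=1.5, fix_rho=True)
    defaults.update(kw)
    return CalibConfig(**defaults)


class TestTransforms:
    def test_lognormal_unit_jacobian(self):
        priors = [("lognormal", 0.0, 1.0)] * 4
        eta = np.ones(4)
        assert log_jacobian(eta, priors) == pytest.approx(0.0)  # J = 1

    def test_uniform_midpoint_factor(self):
        priors = [("uniform", 0.0, 1.0)]
        # (0.5)^-1 + (0.5)^-1 = 4
        assert log_jacobian(np.array([0.5]), priors) == pytest.approx(np.log(4.0))

    def test_round_trip(self):
        priors = [("lognormal", -3.0, 0.5), ("uniform", 0.2, 1.7)]
        eta = np.array([0.07, 0.9])
        back = inverse_transform_phi(transform_phi(eta, priors), priors)
        np.testing.assert_allclose(back, eta, atol=1e-12)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            transform_phi(np.array([0.0]), [("lognormal", 0.0, 1.0)])
        with pytest.raises(ValueError):
            transform_phi(np.array([1.0]), [("uniform", 0.0, 1.0)])

    @given(
        st.floats(min_value=-3.0, max_value=3.0),
        st.floats(min_value=0.1, max_value=2.0),
        st.floats(min_value=-2.5, max_value=2.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_lognormal_round_trip_property(self, mu, sigma, psi):
        priors = [("lognormal", mu, sigma)]
        eta = inverse_transform_phi(np.array([psi]), priors)
        back = transform_phi(eta, priors)
        np.testing.assert_allclose(back, [psi], atol=1e-9)

    def test_lognormal_transform_is_prior_standardization(self):
        # g(eta) ~ N(0,1) exactly when eta ~ lognormal(mu, sigma)
        rng = np.random.default_rng(3)
        eta = np.exp(-3.0 + 0.5 * rng.standard_normal(20_000))
        psi = np.array([transform_phi(np.array([e]), [("lognormal", -3.0, 0.5)])[0]
                        for e in eta[:2000]])
        assert stats.kstest(psi, "norm").pvalue > 0.01


class TestTau2Gibbs:
    def test_zero_residual_zero_increment_prior_form(self):
        config = scalar_config(n0z=4.0, d0z=2.0)
        rng = np.random.default_rng(0)
        z = np.zeros((3, 1))
        y = np.zeros((3, 1))
        u = np.zeros((4, 1))
        draws = np.array([
            tau2_gibbs(u, y, z, np.eye(1), config, np.random.default_rng(i))
            for i in range(30_000)
        ])
        # IG(b n0 + S~, b d0) = IG(5, 2): E[1/tau2] = 5/2
        assert (1.0 / draws).mean() == pytest.approx(2.5, rel=0.02)

    def test_scalar_conjugacy_shape_and_rate(self):
        # S~=1, U=1: shape = b n0 + 1, rate = b d0 + (du^2 + r^2)/2
        config = scalar_config(n0z=3.0, d0z=1.5, b=2.0)
        z = np.array([[1.0]])
        y = np.array([[0.4]])
        u = np.array([[0.1], [0.3]])
        du, r = 0.2, 1.0 - 0.4 - 0.3
        shape = 2.0 * 3.0 + 1
        rate = 2.0 * 1.5 + 0.5 * (du**2 + r**2)
        draws = np.array([
            tau2_gibbs(u, y, z, np.eye(1), config, np.random.default_rng(i))[0]
            for i in range(30_000)
        ])
        assert (1.0 / draws).mean() == pytest.approx(shape / rate, rel=0.02)
        assert (1.0 / draws).var() == pytest.approx(shape / rate**2, rel=0.05)

    def test_gamma_moment_selfcheck(self):
        config = scalar_config(n0z=6.0, d0z=3.0)
        z = np.full((1, 1), 2.0)
        y = np.zeros((1, 1))
        u = np.zeros((2, 1))
        rng = np.random.default_rng(10)
        draws = np.array([tau2_gibbs(u, y, z, np.eye(1), config, rng)[0]
                          for _ in range(100_000)])
        shape, rate = 6.0 + 1, 3.0 + 2.0
        assert (1.0 / draws).mean() == pytest.approx(shape / rate, rel=0.02)


class TestYGibbs:
    def test_huge_tau2_ignores_data(self, rng):
        mu = np.array([[1.0, -1.0]])
        sig = np.eye(2)
        _, means, _ = y_gibbs(mu, 0.5, sig, np.array([1e12]),
                              np.array([[50.0, 50.0]]), np.zeros((2, 2)), rng,
                              return_moments=True)
        np.testing.assert_allclose(means[0], mu[0], atol=1e-6)

    def test_flat_emulator_returns_data_minus_bias(self, rng):
        mu = np.zeros((1, 2))
        sig = 1e12 * np.eye(2)
        z = np.array([[3.0, -2.0]])
        u = np.zeros((2, 2))
        u[1] = [0.5, 0.5]
        _, means, _ = y_gibbs(mu, 1.0, sig, np.array([0.1]), z, u, rng,
                              return_moments=True)
        np.testing.assert_allclose(means[0], z[0] - u[1], atol=1e-6)

    def test_scalar_precision_weighting(self, rng):
        mu = np.array([[1.0]])
        sig = np.array([[2.0]])  # kappa * Sigma with kappa=1
        tau2 = np.array([0.5])
        z = np.array([[3.0]])
        u = np.zeros((2, 1))
        _, means, covs = y_gibbs(mu, 1.0, sig, tau2, z, u, rng,
                                 return_moments=True)
        prec = 1 / 2.0 + 1 / 0.5
        expected = (mu[0, 0] / 2.0 + z[0, 0] / 0.5) / prec
        assert means[0, 0] == pytest.approx(expected)
        assert covs[0, 0, 0] == pytest.approx(1 / prec)

    def test_degenerate_emulator_pins_y(self, rng):
        mu = np.array([[0.7, 0.1]])
        y = y_gibbs(mu, 0.0, np.eye(2), np.array([1.0]),
                    np.array([[5.0, 5.0]]), np.zeros((2, 2)), rng)
        np.testing.assert_array_equal(y, mu)


class TestBiasFFBS:
    def test_scalar_single_season_kalman_oracle(self):
        # T=1, S~=1: z1 = y1 + u1 + e, u1 = u0 + w; joint Gaussian by hand
        config = scalar_config(m0z=0.0, M0z=np.eye(1), tau0sq=2.0)
        tau2 = np.array([0.5])
        z = np.array([[1.2]])
        y = np.array([[0.2]])
        U = np.eye(1)
        # prior: u0 ~ N(0, tau0^2 M0) = N(0, 2); u1 = u0 + N(0, 0.5)
        # obs: z - y = 1.0 = u1 + N(0, 0.5)
        var_u1 = 2.0 + 0.5
        gain = var_u1 / (var_u1 + 0.5)
        post_mean_u1 = gain * 1.0
        post_var_u1 = var_u1 * (1 - gain)
        draws = np.array([
            bias_ffbs(z, y, tau2, U, config, np.random.default_rng(i))
            for i in range(40_000)
        ])
        assert draws[:, 1, 0].mean() == pytest.approx(post_mean_u1, abs=0.01)
        assert draws[:, 1, 0].var() == pytest.approx(post_var_u1, rel=0.05)
        # u0 | z: cov(u0, z) = 2.0
        gain0 = 2.0 / (var_u1 + 0.5)
        assert draws[:, 0, 0].mean() == pytest.approx(gain0 * 1.0, abs=0.01)

    def test_no_discrepancy_signal_concentrates_near_zero(self):
        config = scalar_config(M0z=1e-6 * np.eye(1), tau0sq=1.0)
        tau2 = np.full(4, 1e-6)
        z = np.zeros((4, 1))
        y = np.zeros((4, 1))
        u = bias_ffbs(z, y, tau2, np.eye(1), config, np.random.default_rng(0))
        assert np.max(np.abs(u)) < 0.05

    def test_joint_gaussian_oracle_T3_S2(self):
        # brute-force joint normal over (u_0..u_3, z_1..z_3)
        rng = np.random.default_rng(8)
        s, T = 2, 3
        U = np.array([[1.0, 0.6], [0.6, 1.0]])
        config = CalibConfig(priors=[("lognormal", 0, 1)], coords=_coords(s),
                             m0z=np.array([0.3, -0.2]),
                             M0z=np.array([[1.5, 0.2], [0.2, 0.8]]),
                             tau0sq=1.3)
        tau2 = np.array([0.7, 1.1, 0.4])
        y = rng.standard_normal((T, s))
        z = y + rng.standard_normal((T, s))

        dim = (T + 1) * s
        mu = np.tile(config.m0z, T + 1)
        K = np.zeros((dim, dim))
        cum = config.tau0sq * config.M0z
        covs = [cum.copy()]
        for t in range(1, T + 1):
            cum = cum + tau2[t - 1] * U
            covs.append(cum.copy())
        for a in range(T + 1):
            for b_ in range(T + 1):
                K[a * s:(a + 1) * s, b_ * s:(b_ + 1) * s] = covs[min(a, b_)]
        H = np.zeros((T * s, dim))
        for t in range(1, T + 1):
            H[(t - 1) * s:t * s, t * s:(t + 1) * s] = np.eye(s)
        Kzz = H @ K @ H.T + np.kron(np.diag(tau2), np.eye(s))
        Kuz = K @ H.T
        resid = (z - y).reshape(-1)
        mean_u = mu + Kuz @ np.linalg.solve(Kzz, resid - H @ mu)
        cov_u = K - Kuz @ np.linalg.solve(Kzz, Kuz.T)

        _, h, Hm = bias_ffbs(z, y, tau2, U, config, np.random.default_rng(0),
                             return_moments=True)
        for t in range(T + 1):
            np.testing.assert_allclose(h[t], mean_u[t * s:(t + 1) * s],
                                       atol=1e-8)
            np.testing.assert_allclose(
                Hm[t], cov_u[t * s:(t + 1) * s, t * s:(t + 1) * s], atol=1e-8
            )
        draws = np.array([
            bias_ffbs(z, y, tau2, U, config, np.random.default_rng(i))
            for i in range(30_000)
        ])
        np.testing.assert_allclose(draws.mean(axis=0).reshape(-1), mean_u,
                                   atol=0.03)
        emp_cov = np.cov(draws.reshape(30_000, -1).T)
        np.testing.assert_allclose(emp_cov, cov_u, atol=0.05)


def _lv_like_fit(rng, n=8, T=4, s=2, L=30):
    """Tiny smooth 2-column training set for bundle tests."""
    inputs = np.linspace(0.2, 1.8, n)[:, None]
    tensor = np.empty((T + 1, n, s))
    for t in range(T + 1):
        tensor[t, :, 0] = np.log(2 + inputs[:, 0]) + 0.1 * t
        tensor[t, :, 1] = np.cos(inputs[:, 0]) - 0.05 * t
    tensor[0] = tensor[0, 0]  # shared mechanistic initial condition
    return train_emulator(tensor, inputs, L=L, rng=rng, beta=[2.0]), inputs, tensor


class TestEmulatorConditional:
    def test_training_input_is_degenerate_and_exact(self, rng):
        fit, inputs, tensor = _lv_like_fit(rng)
        bundle = make_bundle(fit, [0, 1])
        y_state = tensor[1:, 3, :]  # truth trajectory of input 3
        mu, kappa, _ = emulator_conditional(inputs[3], 0, bundle, y_state)
        assert kappa == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(mu, tensor[1:, 3, :], atol=1e-6)

    def test_far_input_no_borrowing(self, rng):
        fit, inputs, tensor = _lv_like_fit(rng)
        bundle = make_bundle(fit, [0, 1])
        y_state = np.zeros((4, 2))
        eta_far = np.array([50.0])
        mu, kappa, sig = emulator_conditional(eta_far, 0, bundle, y_state)
        assert kappa == pytest.approx(1.0, abs=1e-10)
        # mu = F~ Theta with F~ rows from y_state (zeros for t >= 2)
        th1 = bundle.theta_site[0][1]
        np.testing.assert_allclose(mu[0], bundle.y0_row @ th1, atol=1e-10)

    def test_single_site_scalar_conditioning(self, rng):
        n, T = 5, 2
        inputs = np.linspace(0, 1, n)[:, None]
        tensor = rng.standard_normal((T + 1, n, 1))
        tensor[0] = tensor[0, 0]
        fit = train_emulator(tensor, inputs, L=5, rng=rng, beta=[1.0])
        bundle = make_bundle(fit, [0])
        eta = np.array([0.31])
        y_state = rng.standard_normal((T, 1))
        mu, kappa, _ = emulator_conditional(eta, 2, bundle, y_state)
        from dynemu.emulator import sq_exp_corr

        J = sq_exp_corr(inputs, eta[None, :], [1.0])
        V = fit.V
        th = bundle.theta_site[2]
        w = np.linalg.solve(V, J)
        f1 = bundle.y0_row[None, :]
        expect = f1 @ th[1] + w.T @ (fit.Y[1] - fit.spec.F[0] @ th[1])
        assert mu[0, 0] == pytest.approx(expect[0, 0], abs=1e-8)
        assert kappa == pytest.approx(1 - (J.T @ w).item(), abs=1e-10)

    def test_subset_sites_rejected_for_ar_designs(self, rng):
        fit, *_ = _lv_like_fit(rng)
        with pytest.raises(ValueError, match="every"):
            make_bundle(fit, [0])


class TestMetropolis:
    def test_equal_targets_always_accept(self, rng):
        psi = np.zeros(2)
        new, accepted, _ = metropolis_step(psi, lambda p: 0.0, np.eye(2), rng)
        assert accepted

    def test_zero_proposal_never_moves(self, rng):
        psi = np.array([1.0])
        new, _, _ = metropolis_step(psi, lambda p: -0.5 * p @ p,
                                    1e-300 * np.eye(1), rng)
        np.testing.assert_allclose(new, psi, atol=1e-250)

    def test_acceptance_rate_matches_independent_estimate(self):
        # RW Metropolis on N(0,1) with proposal sd 2: compare the realized
        # acceptance rate with a direct Monte-Carlo estimate of
        # E[min(1, phi(x + 2 eps)/phi(x))] under stationarity
        s = 2.0
        rng = np.random.default_rng(4)
        x = rng.standard_normal(400_000)
        eps = rng.standard_normal(400_000)
        theory = np.mean(np.minimum(1.0, np.exp(-(x + s * eps) ** 2 / 2 + x**2 / 2)))
        chain_rng = np.random.default_rng(5)
        psi = np.zeros(1)
        acc = 0
        n = 40_000
        for _ in range(n):
            psi, a, _ = metropolis_step(psi, lambda p: -0.5 * float(p @ p),
                                        s * np.eye(1), chain_rng)
            acc += a
        assert acc / n == pytest.approx(theory, abs=0.01)


class TestLogTarget:
    def _setup(self, rng):
        fit, inputs, tensor = _lv_like_fit(rng)
        bundle = make_bundle(fit, [0, 1])
        T = bundle.T
        z = tensor[1:, 2, :] + 0.05
        state = CalibState(
            eta=np.array([0.9]), rho=1.5, tau2=np.full(T, 0.3),
            u=0.01 * np.ones((T + 1, 2)), y=tensor[1:, 2, :].copy(),
        )
        config = CalibConfig(priors=[("lognormal", 0.0, 0.5)],
                             coords=_coords(2), rho=1.5, fix_rho=True)
        return bundle, state, z, config

    def test_scalar_hand_assembly(self, rng):
        # T=1, S~=1: target = log N(y|Bb,B) + log N(z|y+u1,tau2)
        #                    + log N(u1|u0, tau2 U) + log N(psi|0,1)
        n, T = 6, 1
        inputs = np.linspace(0.2, 1.2, n)[:, None]
        tensor = rng.standard_normal((T + 1, n, 1))
        tensor[0] = tensor[0, 0]
        fit = train_emulator(tensor, inputs, L=4, rng=rng, beta=[1.5])
        bundle = make_bundle(fit, [0])
        z = np.array([[0.8]])
        state = CalibState(eta=np.array([0.7]), rho=1.5,
                           tau2=np.array([0.4]),
                           u=np.array([[0.05], [0.1]]),
                           y=np.array([[0.5]]))
        config = CalibConfig(priors=[("lognormal", 0.0, 1.0)],
                             coords=_coords(1), rho=1.5, fix_rho=True)
        psi = transform_phi(state.eta, config.priors)
        got = log_target_phi(psi, 1, bundle, state, z, config)

        mu, kappa, sig = emulator_conditional(state.eta, 1, bundle, state.y)
        s2 = kappa * sig[0, 0]
        B = 1.0 / (1.0 / s2 + 1.0 / 0.4)
        b = mu[0, 0] / s2 + (z[0, 0] - state.u[1, 0]) / 0.4
        expected = (
            stats.norm.logpdf(state.y[0, 0], B * b, np.sqrt(B))
            + stats.norm.logpdf(z[0, 0], state.y[0, 0] + state.u[1, 0],
                                np.sqrt(0.4))
            + stats.norm.logpdf(state.u[1, 0], state.u[0, 0], np.sqrt(0.4))
            + stats.norm.logpdf(psi[0])
        )
        assert got == pytest.approx(expected, abs=1e-8)

    def test_rho_change_leaves_data_terms_fixed(self, rng):
        bundle, state, z, config = self._setup(rng)
        psi = transform_phi(state.eta, config.priors)
        configs = [
            CalibConfig(priors=config.priors, coords=_coords(2), rho=r,
                        fix_rho=True)
            for r in (1.5, 2.5)
        ]
        targets = [log_target_phi(psi, 0, bundle, state, z, c) for c in configs]
        # difference must equal the bias-innovation term difference alone
        from dynemu._linalg import chol_logdet, chol_lower
        from scipy.linalg import solve_triangular

        def u_terms(c):
            cu = chol_lower(c.U())
            tot = 0.0
            for t in range(1, bundle.T + 1):
                du = state.u[t] - state.u[t - 1]
                w = solve_triangular(cu, du, lower=True)
                tot += -0.5 * (2 * np.log(2 * np.pi * state.tau2[t - 1])
                               + chol_logdet(cu) + w @ w / state.tau2[t - 1])
            return tot

        assert targets[0] - targets[1] == pytest.approx(
            u_terms(configs[0]) - u_terms(configs[1]), abs=1e-5
        )

    def test_inflating_residuals_decreases_target(self, rng):
        bundle, state, z, config = self._setup(rng)
        psi = transform_phi(state.eta, config.priors)
        base = log_target_phi(psi, 0, bundle, state, z, config)
        worse = log_target_phi(psi, 0, bundle, state, z + 5.0, config)
        assert worse < base

    def test_constant_shift_invariance_in_alpha(self, rng):
        # only differences enter the acceptance ratio
        bundle, state, z, config = self._setup(rng)
        psi = transform_phi(state.eta, config.priors)
        a = log_target_phi(psi, 0, bundle, state, z, config)
        b = log_target_phi(psi + 0.3, 0, bundle, state, z, config)
        assert np.isfinite(a - b)


class TestGewekeConsistency:
    def test_tau2_and_bias_joint_consistency(self):
        """Successive-conditional simulation must preserve prior moments."""
        T, s = 2, 2
        U = np.array([[1.0, 0.5], [0.5, 1.0]])
        config = CalibConfig(priors=[("lognormal", 0, 1)], coords=_coords(s),
                             n0z=8.0, d0z=6.0, tau0sq=1.0)
        y = np.zeros((T, s))
        rng = np.random.default_rng(12)
        cu = np.linalg.cholesky(U)

        def draw_prior(rng):
            tau2 = 1.0 / rng.gamma(config.n0z, 1.0 / config.d0z, size=T)
            u = np.zeros((T + 1, s))
            u[0] = rng.standard_normal(s)  # M0z = I, tau0 = 1
            for t in range(1, T + 1):
                u[t] = u[t - 1] + np.sqrt(tau2[t - 1]) * cu @ rng.standard_normal(s)
            return tau2, u

        def draw_data(tau2, u, rng):
            return y + u[1:] + np.sqrt(tau2)[:, None] * rng.standard_normal((T, s))

        n_sweeps = 4000
        tau2, u = draw_prior(rng)
        sc_inv_tau, sc_u = [], []
        for _ in range(n_sweeps):
            z = draw_data(tau2, u, rng)
            tau2 = tau2_gibbs(u, y, z, cu, config, rng)
            u = bias_ffbs(z, y, tau2, U, config, rng)
            sc_inv_tau.append(1.0 / tau2)
            sc_u.append(u[1:].copy())
        sc_inv_tau = np.array(sc_inv_tau)
        sc_u = np.array(sc_u)

        mc = [draw_prior(np.random.default_rng(1000 + i)) for i in range(n_sweeps)]
        mc_inv_tau = np.array([1.0 / t for t, _ in mc])
        mc_u = np.array([uu[1:] for _, uu in mc])

        np.testing.assert_allclose(sc_inv_tau.mean(axis=0),
                                   mc_inv_tau.mean(axis=0), rtol=0.08)
        np.testing.assert_allclose(sc_u.mean(axis=0), mc_u.mean(axis=0),
                                   atol=0.12)
        np.testing.assert_allclose(sc_u.std(axis=0), mc_u.std(axis=0),
                                   rtol=0.12)
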