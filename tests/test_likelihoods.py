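"""Likelihood families: densities normalise, fitters maximise their objectives."""

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from jointseg.likelihoods import (
    DSWBetaParams,
    GaussianParams,
    LogGaussianParams,
    NIWHyper,
    WishartParams,
    dswbeta_logpdf,
    fit_dswbeta,
    fit_gaussian_map,
    fit_loggauss,
    fit_wishart_map,
    gaussian_logpdf,
    gaussian_map_objective,
    loggauss_logpdf,
    watson_log_normaliser,
    wishart_logpdf,
    wishart_map_objective,
)
from jointseg.synthetic import sample_watson

from conftest import random_spd


class TestGaussian:
    def test_standard_normal_at_mean(self):
        p = GaussianParams([0.0], [[1.0]])
        assert gaussian_logpdf(np.array([0.0]), p) == pytest.approx(
            -0.5 * np.log(2 * np.pi)
        )

    def test_normalises_on_grid(self):
        p = GaussianParams([1.3], [[0.7]])
        xs = np.linspace(-10, 12, 20001)
        dens = np.exp(gaussian_logpdf(xs[:, None], p))
        assert np.trapezoid(dens, xs) == pytest.approx(1.0, abs=1e-4)

    def test_matches_quadratic_form_oracle(self, rng):
        for _ in range(20):
            mu = rng.standard_normal(3)
            cov = random_spd(rng)
            x = rng.standard_normal(3)
            p = GaussianParams(mu, cov)
            expect = (
                -0.5 * 3 * np.log(2 * np.pi)
                - 0.5 * np.linalg.slogdet(cov)[1]
                - 0.5 * (x - mu) @ np.linalg.inv(cov) @ (x - mu)
            )
            assert gaussian_logpdf(x, p) == pytest.approx(expect, abs=1e-12)

    def test_singular_covariance_errors(self):
        with pytest.raises(ValueError):
            GaussianParams([0.0, 0.0], [[1.0, 1.0], [1.0, 1.0]])


class TestGaussianMAP:
    def test_noninformative_limit_is_weighted_moments(self, rng):
        s = rng.normal(3.0, 2.0, size=(500, 2))
        w = rng.random(500)
        p = fit_gaussian_map(s, w)
        mu = (w[:, None] * s).sum(0) / w.sum()
        cov = (w[:, None] * (s - mu)).T @ (s - mu) / w.sum()
        assert np.allclose(p.mean, mu, atol=1e-12)
        assert np.allclose(p.cov, cov, atol=1e-12)

    def test_point_mass_hits_floor(self, rng):
        s = rng.normal(size=(10, 1))
        w = np.zeros(10)
        w[4] = 1.0
        p = fit_gaussian_map(s, w)
        assert np.allclose(p.mean, s[4])
        assert "cov_floor" in p.flags

    def test_informative_hyper_matches_numerical_oracle(self, rng):
        """MAP fit equals black-box maximisation of the same objective."""
        s = rng.normal(5.0, 1.5, size=(200, 1))
        w = rng.random(200) + 0.1
        hyper = NIWHyper(mean=np.array([2.0]), strength=40.0)
        p = fit_gaussian_map(s, w, hyper)

        def neg(x):
            mu, logvar = x
            q = GaussianParams([mu], [[np.exp(logvar)]])
            return -gaussian_map_objective(q, s, w, hyper)

        res = optimize.minimize(
            neg, [s.mean(), 0.0], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12},
        )
        assert p.mean[0] == pytest.approx(res.x[0], abs=1e-6)
        assert p.cov[0, 0] == pytest.approx(np.exp(res.x[1]), abs=1e-6)

    def test_shrinkage_formula(self, rng):
        s = rng.normal(size=(100, 1))
        w = np.ones(100)
        hyper = NIWHyper(mean=np.array([10.0]), strength=50.0)
        p = fit_gaussian_map(s, w, hyper)
        expect = (100 * s.mean() + 50.0 * 10.0) / 150.0
        assert p.mean[0] == pytest.approx(expect, abs=1e-12)


class TestWishart:
    def test_logpdf_matches_scipy(self, rng):
        V = random_spd(rng)
        p = WishartParams(dof=8.0, scale=V)
        for _ in range(10):
            X = random_spd(rng)
            T = np.linalg.inv(X)
            assert wishart_logpdf(T, p) == pytest.approx(
                stats.wishart.logpdf(X, df=8.0, scale=V), abs=1e-10
            )

    def test_sample_mean_identity(self, rng):
        n, V = 10.0, np.diag([2.0, 1.0, 0.5])
        X = stats.wishart.rvs(df=n, scale=V, size=5000, random_state=rng)
        err = np.linalg.norm(X.mean(axis=0) - n * V) / np.linalg.norm(n * V)
        assert err < 0.05

    def test_mode_dominates(self, rng):
        V = np.diag([1.0, 2.0, 0.5])
        p = WishartParams(dof=9.0, scale=V)
        mode = (9.0 - 4.0) * V  # (n - p - 1) V with p = 3
        at = lambda X: wishart_logpdf(np.linalg.inv(X), p)
        assert at(mode) > at(2.0 * mode)
        assert at(mode) > at(0.5 * mode)

    def test_monte_carlo_normalisation(self, rng):
        """E[1] under the density itself: importance check via sampling."""
        n, V = 7.0, np.eye(3) * 1.5
        p = WishartParams(dof=n, scale=V)
        X = stats.wishart.rvs(df=n, scale=V, size=4000, random_state=rng)
        lp_mine = np.array(
            [wishart_logpdf(np.linalg.inv(x), p) for x in X[:500]]
        )
        lp_scipy = stats.wishart.logpdf(X[:500].transpose(1, 2, 0), df=n, scale=V)
        assert np.abs(np.exp(lp_mine - lp_scipy) - 1.0).max() < 0.02

    def test_dof_leq_2_rejected(self):
        with pytest.raises(ValueError):
            WishartParams(dof=2.0, scale=np.eye(3))

    def test_parameter_recovery(self, rng):
        n_true, V_true = 10.0, np.array(
            [[2.0, 0.3, 0.0], [0.3, 1.0, 0.1], [0.0, 0.1, 0.5]]
        )
        X = stats.wishart.rvs(df=n_true, scale=V_true, size=20000, random_state=rng)
        T = np.linalg.inv(X)
        p = fit_wishart_map(T, np.ones(len(T)))
        assert abs(p.dof - n_true) / n_true < 0.10
        assert np.linalg.norm(p.scale - V_true) / np.linalg.norm(V_true) < 0.05

    def test_stationarity_of_fit(self, rng):
        X = stats.wishart.rvs(df=9.0, scale=np.eye(3), size=2000, random_state=rng)
        T = np.linalg.inv(X)
        w = rng.random(2000)
        p = fit_wishart_map(T, w)
        base = wishart_map_objective(p, T, w)
        h = 1e-5
        up = wishart_map_objective(
            WishartParams(p.dof + h, p.scale, p.gamma_hyper), T, w
        )
        dn = wishart_map_objective(
            WishartParams(p.dof - h, p.scale, p.gamma_hyper), T, w
        )
        grad = (up - dn) / (2 * h)
        assert abs(grad) / max(abs(base), 1.0) < 1e-5

    def test_degenerate_single_sample_flagged(self, rng):
        T = np.stack([random_spd(rng) for _ in range(5)])
        w = np.zeros(5)
        w[2] = 1.0
        p = fit_wishart_map(T, w)
        assert "dof_boundary" in p.flags

    def test_prior_pulls_dof_down(self, rng):
        """Doubling weights moves the MAP dof toward the data value."""
        n_true = 12.0
        X = stats.wishart.rvs(df=n_true, scale=np.eye(3), size=3000,
                              random_state=rng)
        T = np.linalg.inv(X)
        p1 = fit_wishart_map(T, np.ones(len(T)))
        p2 = fit_wishart_map(T, 2.0 * np.ones(len(T)))
        # the prior favours small dof; more data weight weakens it
        assert p1.dof < p2.dof
        assert abs(p2.dof - n_true) < abs(p1.dof - n_true) + 0.05


class TestLogGaussian:
    def test_value_at_mean(self):
        p = LogGaussianParams(np.zeros(6), 1.0)
        assert loggauss_logpdf(np.zeros(6), p) == pytest.approx(
            -3.0 * np.log(2 * np.pi)
        )

    def test_symmetric_pair_equal_density(self, rng):
        m = rng.standard_normal(6)
        p = LogGaussianParams(m, 0.4)
        delta = rng.standard_normal(6)
        assert loggauss_logpdf(m + delta, p) == pytest.approx(
            loggauss_logpdf(m - delta, p), abs=1e-12
        )

    def test_formula_oracle(self, rng):
        m = rng.standard_normal(6)
        var = 0.7
        d = rng.standard_normal(6)
        p = LogGaussianParams(m, var)
        expect = stats.multivariate_normal.logpdf(d, m, var * np.eye(6))
        assert loggauss_logpdf(d, p) == pytest.approx(expect, abs=1e-12)

    def test_fit_degenerate_floors(self):
        d = np.tile(np.arange(6.0), (10, 1))
        p = fit_loggauss(d, np.ones(10))
        assert np.allclose(p.mean, np.arange(6.0))
        assert "var_floor" in p.flags

    def test_two_point_midpoint(self):
        d = np.stack([np.zeros(6), np.ones(6)])
        p = fit_loggauss(d, np.ones(2))
        assert np.allclose(p.mean, 0.5)

    def test_fit_matches_numerical_oracle(self, rng):
        d = rng.standard_normal((300, 6)) * 0.5 + 1.0
        w = rng.random(300) + 0.05
        p = fit_loggauss(d, w)

        def neg(x):
            q = LogGaussianParams(x[:6], np.exp(x[6]))
            return -float(np.sum(w * loggauss_logpdf(d, q)))

        res = optimize.minimize(neg, np.zeros(7), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 5000, "maxfev": 5000})
        assert np.allclose(p.mean, res.x[:6], atol=1e-5)
        assert p.var == pytest.approx(np.exp(res.x[6]), abs=1e-6)


class TestWatsonNormaliser:
    def test_uniform_limit(self):
        assert np.exp(watson_log_normaliser(0.0)) == pytest.approx(4 * np.pi)

    @pytest.mark.parametrize("kappa", [1.0, 10.0, 100.0])
    def test_density_integrates_to_one(self, kappa):
        logZ = watson_log_normaliser(kappa)
        val, _ = integrate.quad(
            lambda t: 2 * np.pi * np.exp(kappa * t**2 - logZ), -1, 1, limit=200
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_strictly_increasing(self):
        ks = np.linspace(0, 9000, 200)
        vals = watson_log_normaliser(ks)
        assert np.all(np.diff(vals) > 0)

    def test_branch_continuity(self):
        # the hyp1f1 / Kummer-transform switch at 300 must be seamless
        below = watson_log_normaliser(299.999)
        above = watson_log_normaliser(300.001)
        assert abs(above - below) < 1e-2


class TestDSWBeta:
    def test_antipodal_symmetry(self, rng):
        p = DSWBetaParams(3.0, 2.0, np.array([0.0, 0.6, 0.8]), 15.0)
        for _ in range(10):
            phi = rng.standard_normal(3)
            phi /= np.linalg.norm(phi)
            f = rng.random()
            assert dswbeta_logpdf(f, phi, p) == pytest.approx(
                dswbeta_logpdf(f, -phi, p), abs=1e-12
            )

    def test_zero_fa_direction_uniform(self):
        p = DSWBetaParams(2.0, 2.0, np.array([1.0, 0.0, 0.0]), 50.0)
        v1 = dswbeta_logpdf(0.0, np.array([1.0, 0.0, 0.0]), p)
        v2 = dswbeta_logpdf(0.0, np.array([0.0, 0.0, 1.0]), p)
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_joint_density_integrates_to_one(self):
        p = DSWBetaParams(4.0, 3.0, np.array([0.0, 0.0, 1.0]), 20.0)

        def inner(f):
            logZ = 0.0  # spherical part by 1-D quadrature over t = psi.phi
            val, _ = integrate.quad(
                lambda t: 2
                * np.pi
                * np.exp(
                    p.concentration * f * t**2
                    - watson_log_normaliser(p.concentration * f)
                ),
                -1,
                1,
            )
            return val * stats.beta.pdf(f, p.beta_a, p.beta_b)

        total, _ = integrate.quad(inner, 0, 1, limit=100)
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_uniform_directions_fit_zero_kappa(self, rng):
        phi = rng.standard_normal((10000, 3))
        phi /= np.linalg.norm(phi, axis=1, keepdims=True)
        f = rng.random(10000)
        p = fit_dswbeta(f, phi, np.ones(10000))
        assert abs(p.concentration) < 0.2

    def test_parameter_recovery(self, rng):
        psi0 = np.array([1.0, 1.0, 0.5])
        psi0 /= np.linalg.norm(psi0)
        k0 = 30.0
        f = rng.beta(5, 2, 20000)
        phi = sample_watson(psi0, k0 * f, rng)
        p = fit_dswbeta(f, phi, np.ones(20000))
        ang = np.degrees(np.arccos(min(1.0, abs(p.mean_dir @ psi0))))
        assert ang < 2.0
        assert abs(p.concentration - k0) / k0 < 0.10
        assert abs(p.beta_a - 5.0) / 5.0 < 0.15
        assert abs(p.beta_b - 2.0) / 2.0 < 0.15

    def test_degenerate_alignment_hits_cap(self):
        phi = np.tile([0.0, 0.0, 1.0], (100, 1))
        f = np.ones(100)
        p = fit_dswbeta(f, phi, np.ones(100))
        assert "kappa_cap" in p.flags

    def test_fa_outside_range_rejected(self):
        p = DSWBetaParams(2.0, 2.0, np.array([1.0, 0.0, 0.0]), 5.0)
        with pytest.raises(ValueError):
            dswbeta_logpdf(1.5, np.array([1.0, 0.0, 0.0]), p)

    def test_rotation_equivariance(self, rng):
        psi0 = np.array([0.0, 0.0, 1.0])
        f = rng.beta(5, 2, 5000)
        phi = sample_watson(psi0, 25.0 * f, rng)
        p0 = fit_dswbeta(f, phi, np.ones(5000))
        th = 0.7
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        p1 = fit_dswbeta(f, phi @ R.T, np.ones(5000))
        assert abs(abs(p1.mean_dir @ (R @ p0.mean_dir)) - 1.0) < 1e-6
        assert p1.concentration == pytest.approx(p0.concentration, rel=1e-3)


class TestWeightScaleInvariance:
    """Prior-free fitters must be invariant to uniform weight rescaling."""

    def test_loggauss(self, rng):
        d = rng.standard_normal((200, 6))
        w = rng.random(200)
        p1 = fit_loggauss(d, w)
        p2 = fit_loggauss(d, 5.0 * w)
        assert np.allclose(p1.mean, p2.mean, atol=1e-12)
        assert p1.var == pytest.approx(p2.var, abs=1e-12)

    def test_dswbeta(self, rng):
        f = rng.beta(4, 3, 2000)
        phi = sample_watson(np.array([0.0, 1.0, 0.0]), 20.0 * f, rng)
        w = rng.random(2000)
        p1 = fit_dswbeta(f, phi, w)
        p2 = fit_dswbeta(f, phi, 3.0 * w)
        assert abs(abs(p1.mean_dir @ p2.mean_dir) - 1.0) < 1e-10
        assert p1.concentration == pytest.approx(p2.concentration, abs=1e-3)
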