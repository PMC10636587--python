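"""Reflection operators, plane estimation and joint contralateral fitting."""

import numpy as np
import pytest
from itertools import combinations_with_replacement

from jointseg.likelihoods import (
    DSWBetaParams,
    LogGaussianParams,
    WishartParams,
    dswbeta_logpdf,
    fit_dswbeta,
    fit_loggauss,
    loggauss_logpdf,
    wishart_logpdf,
)
from jointseg.symmetry import (
    ReflectionPlane,
    ReflectionTerm,
    SymmetryPairing,
    build_reflection_terms,
    fit_pair_symmetric,
    optimise_reflection,
    reflect_logvecs,
    reflect_params,
    reflection_objective,
)
from jointseg.synthetic import sample_watson

from conftest import random_spd


class TestReflectionPlane:
    def test_householder_properties(self, rng):
        pl = ReflectionPlane(rng.standard_normal(3))
        H = pl.householder
        assert np.allclose(H, H.T)
        assert np.allclose(H @ H, np.eye(3), atol=1e-12)
        assert np.linalg.det(H) == pytest.approx(-1.0)

    def test_in_plane_direction_fixed(self):
        pl = ReflectionPlane(np.array([1.0, 0.0, 0.0]))
        p = DSWBetaParams(2.0, 2.0, np.array([0.0, 1.0, 0.0]), 5.0)
        assert np.allclose(reflect_params(p, pl).mean_dir, [0.0, 1.0, 0.0])

    def test_normal_direction_flips(self):
        pl = ReflectionPlane(np.array([1.0, 0.0, 0.0]))
        p = DSWBetaParams(2.0, 2.0, np.array([1.0, 0.0, 0.0]), 5.0)
        r = reflect_params(p, pl)
        assert np.allclose(r.mean_dir, [-1.0, 0.0, 0.0])
        # same density by antipodal symmetry
        phi = np.array([0.3, 0.5, 0.81])
        phi /= np.linalg.norm(phi)
        assert dswbeta_logpdf(0.5, phi, p) == pytest.approx(
            dswbeta_logpdf(0.5, -phi, r), abs=1e-12
        )

    @pytest.mark.parametrize("family", ["dsw-beta", "log-gaussian", "wishart"])
    def test_double_reflection_is_identity(self, rng, family):
        pl = ReflectionPlane(rng.standard_normal(3))
        if family == "dsw-beta":
            p = DSWBetaParams(3.0, 2.0, rng.standard_normal(3), 12.0)
            p2 = reflect_params(reflect_params(p, pl), pl)
            assert np.abs(p2.mean_dir - p.mean_dir).max() < 1e-12
        elif family == "log-gaussian":
            p = LogGaussianParams(rng.standard_normal(6), 0.3)
            p2 = reflect_params(reflect_params(p, pl), pl)
            assert np.abs(p2.mean - p.mean).max() < 1e-12
        else:
            p = WishartParams(8.0, random_spd(rng))
            p2 = reflect_params(reflect_params(p, pl), pl)
            assert np.abs(p2.scale - p.scale).max() < 1e-12

    def test_reflection_preserves_density(self, rng):
        """logpdf of reflected params at reflected data == original."""
        pl = ReflectionPlane(rng.standard_normal(3))
        H = pl.householder
        # DSW-beta
        p = DSWBetaParams(3.0, 2.0, rng.standard_normal(3), 9.0)
        phi = rng.standard_normal(3)
        phi /= np.linalg.norm(phi)
        assert dswbeta_logpdf(0.4, H @ phi, reflect_params(p, pl)) == pytest.approx(
            dswbeta_logpdf(0.4, phi, p), abs=1e-12
        )
        # log-Gaussian
        q = LogGaussianParams(rng.standard_normal(6), 0.5)
        d = rng.standard_normal(6)
        assert loggauss_logpdf(
            reflect_logvecs(d, H), reflect_params(q, pl)
        ) == pytest.approx(loggauss_logpdf(d, q), abs=1e-10)
        # Wishart
        wv = WishartParams(7.0, random_spd(rng))
        T = random_spd(rng)
        assert wishart_logpdf(H @ T @ H, reflect_params(wv, pl)) == pytest.approx(
            wishart_logpdf(T, wv), abs=1e-9
        )


def _dsw_pair_terms(rng, tilt_deg=5.0, kappa=40.0, n=8000):
    th = np.radians(tilt_deg)
    r_true = np.array([np.cos(th), np.sin(th), 0.0])
    H = np.eye(3) - 2 * np.outer(r_true, r_true)
    psiL = np.array([0.3, 0.8, 0.5])
    psiL /= np.linalg.norm(psiL)
    fL = rng.beta(8, 2.5, n)
    fR = rng.beta(8, 2.5, n)
    phiL = sample_watson(psiL, kappa * fL, rng)
    phiR = sample_watson(H @ psiL, kappa * fR, rng)
    fa = np.concatenate([fL, fR])
    pdir = np.vstack([phiL, phiR])
    q = np.zeros((2 * n, 2))
    q[:n, 0] = 1.0
    q[n:, 1] = 1.0
    pairing = SymmetryPairing(pairs=[(0, 1)])
    pL = DSWBetaParams(8.0, 2.5, psiL, kappa)
    terms = build_reflection_terms(pairing, {0: pL}, {"fa": fa, "pdir": pdir}, q)
    return terms, r_true


class TestPlaneEstimation:
    def test_recovers_tilted_plane_within_one_degree(self, rng):
        terms, r_true = _dsw_pair_terms(rng, tilt_deg=5.0)
        plane, degen = optimise_reflection(terms, np.array([1.0, 0.0, 0.0]))
        assert not degen
        ang = np.degrees(np.arccos(min(1.0, abs(plane.normal @ r_true))))
        assert ang < 1.0

    def test_exact_symmetry_recovers_axis(self):
        """A perfectly x-mirrored configuration yields r = (+-1, 0, 0)."""
        psiL = np.array([0.6, 0.64, 0.48])
        psiL /= np.linalg.norm(psiL)
        r0 = np.array([1.0, 0.0, 0.0])
        H = np.eye(3) - 2 * np.outer(r0, r0)
        # noiseless sufficient statistics: scatter exactly mirrored
        S_R = np.outer(H @ psiL, H @ psiL)
        terms = [ReflectionTerm(40.0, np.outer(psiL, psiL), S_R)]
        plane, degen = optimise_reflection(terms, np.array([0.97, 0.2, 0.1]))
        assert not degen
        ang = abs(abs(plane.normal @ r0) - 1.0)
        assert ang < 1e-6

    def test_isotropic_pair_is_degenerate(self, rng):
        terms = [ReflectionTerm(0.0, np.eye(3) / 3, np.eye(3) / 3)]
        plane, degen = optimise_reflection(terms, np.array([1.0, 0.0, 0.0]))
        assert degen
        assert np.allclose(plane.normal, [1.0, 0.0, 0.0])

    def test_objective_never_decreases_from_init(self, rng):
        terms, _ = _dsw_pair_terms(rng, tilt_deg=8.0)
        r0 = np.array([1.0, 0.0, 0.0])
        before = reflection_objective(terms, r0)
        plane, _ = optimise_reflection(terms, r0)
        assert reflection_objective(terms, plane.normal) >= before - 1e-9

    def test_objective_is_quartic_on_sphere(self, rng):
        """15 generic evaluations determine the objective exactly."""
        terms, _ = _dsw_pair_terms(rng)
        monos = list(combinations_with_replacement(range(3), 4))

        def basis(r):
            return np.array([r[a] * r[b] * r[c] * r[d] for a, b, c, d in monos])

        pts = rng.standard_normal((15, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        A = np.array([basis(p) for p in pts])
        y = np.array([reflection_objective(terms, p) for p in pts])
        coef = np.linalg.solve(A, y)
        test = rng.standard_normal((40, 3))
        test /= np.linalg.norm(test, axis=1, keepdims=True)
        rel = max(
            abs(basis(p) @ coef - reflection_objective(terms, p)) for p in test
        ) / max(abs(y))
        assert rel < 1e-10


class TestPairFitting:
    def test_mirrored_data_equals_left_only_fit(self, rng):
        psi = np.array([0.2, 0.9, 0.4])
        psi /= np.linalg.norm(psi)
        f = rng.beta(6, 3, 4000)
        phi = sample_watson(psi, 30.0 * f, rng)
        plane = ReflectionPlane(np.array([1.0, 0.2, 0.0]))
        H = plane.householder
        pl, pr = fit_pair_symmetric(
            (f, phi), np.ones(4000), (f, phi @ H.T), np.ones(4000), plane,
            "dsw-beta",
        )
        solo = fit_dswbeta(f, phi, np.ones(4000))
        assert abs(abs(pl.mean_dir @ solo.mean_dir) - 1.0) < 1e-10
        assert pl.concentration == pytest.approx(solo.concentration, abs=1e-6)
        assert np.allclose(np.abs(pr.mean_dir), np.abs(H @ solo.mean_dir), atol=1e-8)

    def test_zero_left_weight_gives_reflected_right_fit(self, rng):
        d = rng.standard_normal((500, 6)) * 0.4 + 2.0
        plane = ReflectionPlane(np.array([0.9, 0.1, 0.3]))
        H = plane.householder
        pl, pr = fit_pair_symmetric(
            d, np.zeros(500), d, np.ones(500), plane, "log-gaussian"
        )
        right_only = fit_loggauss(d, np.ones(500))
        assert np.allclose(pr.mean, right_only.mean, atol=1e-10)
        assert np.allclose(pl.mean, reflect_logvecs(right_only.mean, H),
                           atol=1e-10)

    def test_asymmetric_pair_matches_brute_force(self, rng):
        """Joint fit maximises the summed paired likelihood (log-Gaussian)."""
        from scipy import optimize

        plane = ReflectionPlane(np.array([1.0, 0.0, 0.0]))
        H = plane.householder
        dl = rng.standard_normal((300, 6)) * 0.5 + 1.0
        dr = rng.standard_normal((300, 6)) * 0.5 - 0.5  # not mirrored
        wl = rng.random(300) + 0.1
        wr = rng.random(300) + 0.1
        pl, pr = fit_pair_symmetric(dl, wl, dr, wr, plane, "log-gaussian")

        def neg(x):
            m, logv = x[:6], x[6]
            left = LogGaussianParams(m, np.exp(logv))
            right = reflect_params(left, plane)
            return -(
                float(np.sum(wl * loggauss_logpdf(dl, left)))
                + float(np.sum(wr * loggauss_logpdf(dr, right)))
            )

        res = optimize.minimize(neg, np.append(dl.mean(0), 0.0),
                                method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-11,
                                         "maxiter": 20000, "maxfev": 20000})
        assert np.allclose(pl.mean, res.x[:6], atol=1e-4)
        assert pl.var == pytest.approx(np.exp(res.x[6]), abs=1e-5)
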