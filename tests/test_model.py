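"""GEM engine: E step, weight updates, objective, epsilon, full fits."""

import numpy as np
import pytest

import jointseg as js
from jointseg.grids import VoxelGrid
from jointseg.likelihoods import GaussianParams, LogGaussianParams, fit_loggauss
from jointseg.mixture import MixtureSpec
from jointseg.model import (
    FitConfig,
    JointSegmentationModel,
    choose_epsilon,
    e_step,
    m_step,
    objective,
    posterior_volumes,
    _weight_update,
)
from jointseg.presets import default_phantom_spec
from jointseg.synthetic import make_box_atlas, sample_phantom


class TestChooseEpsilon:
    def test_matched_grids(self):
        g = VoxelGrid.isotropic((5, 5, 5), 1.0)
        assert choose_epsilon(g, g) == 1.0

    def test_volume_ratio_one_eighth(self):
        s = VoxelGrid.isotropic((8, 8, 8), 1.0)
        d = VoxelGrid.isotropic((4, 4, 4), 2.0)
        assert choose_epsilon(s, d) == pytest.approx(1.0 / 8.0)

    def test_capped_at_unity(self):
        s = VoxelGrid.isotropic((8, 8, 8), 1.0)
        d = VoxelGrid.isotropic((8, 8, 8), 0.7)
        assert choose_epsilon(s, d) == 1.0

    def test_bad_override_rejected(self):
        g = VoxelGrid.isotropic((5, 5, 5), 1.0)
        with pytest.raises(ValueError):
            choose_epsilon(g, g, override=1.5)
        with pytest.raises(ValueError):
            choose_epsilon(g, g, override=0.0)


def small_spec():
    return MixtureSpec(
        class_names=["a", "b", "c"],
        structural_support=[[0], [0, 1], [1]],
        diffusion_support=[[0, 1], [1], [0]],
        n_structural=2,
        n_diffusion=2,
    )


class TestEStep:
    def test_matches_brute_force_enumeration(self, rng):
        """q == normalised product of prior, weights and likelihood factors."""
        spec = small_spec()
        V = 8
        log_prior = np.log(rng.dirichlet(np.ones(3), size=V))
        slogp = rng.normal(size=(V, 2))
        dlogp = rng.normal(size=(V, 2))
        eps = 0.6
        q, bad = e_step(log_prior, slogp, dlogp, spec, spec.g, spec.w, eps)
        assert not bad.any()

        cc, ii, jj = spec.triples
        for v in range(V):
            num = np.array(
                [
                    spec.g[c, i]
                    * spec.w[c, j]
                    * np.exp(log_prior[v, c])
                    * np.exp(slogp[v, i])
                    * np.exp(dlogp[v, j]) ** eps
                    for c, i, j in zip(cc, ii, jj)
                ]
            )
            assert np.abs(q[v] - num / num.sum()).max() < 1e-12

    def test_uniform_components_give_uniform_q(self):
        spec = MixtureSpec(["a", "b"], [[0], [0]], [[0], [0]], 1, 1)
        V = 4
        log_prior = np.full((V, 2), np.log(0.5))
        q, _ = e_step(log_prior, np.zeros((V, 1)), np.zeros((V, 1)), spec,
                      spec.g, spec.w, 1.0)
        assert np.allclose(q, 0.5)

    def test_delta_prior_concentrates(self):
        spec = small_spec()
        log_prior = np.log(
            np.array([[1.0 - 2e-300, 1e-300, 1e-300]])
        )
        q, _ = e_step(log_prior, np.zeros((1, 2)), np.zeros((1, 2)), spec,
                      spec.g, spec.w, 1.0)
        cc, _, _ = spec.triples
        assert q[0][cc == 0].sum() == pytest.approx(1.0, abs=1e-12)


class TestWeightUpdate:
    def test_closed_form_ratio(self):
        """Mass split 3:1 between the two components of one class."""
        spec = MixtureSpec(["x"], [[0, 1]], [[0]], 2, 1)
        cc, ii, jj = spec.triples
        q = np.zeros((4, len(cc)))
        q[:, ii == 0] = 0.75
        q[:, ii == 1] = 0.25
        g, w = _weight_update(q, spec)
        assert np.allclose(g[0], [0.75, 0.25])
        assert np.allclose(w[0], [1.0])


class TestObjective:
    def test_degenerate_mixture_is_sum_of_logpdfs(self, rng):
        spec = MixtureSpec(["only"], [[0]], [[0]], 1, 1)
        V = 6
        slogp = rng.normal(size=(V, 1))
        dlogp = rng.normal(size=(V, 1))
        log_prior = np.zeros((V, 1))
        val = objective(log_prior, slogp, dlogp, spec, spec.g, spec.w, 1.0)
        assert val == pytest.approx(float((slogp + dlogp).sum()), abs=1e-12)

    def test_epsilon_power_rule(self, rng):
        spec = MixtureSpec(["only"], [[0]], [[0]], 1, 1)
        V = 5
        slogp = np.zeros((V, 1))
        dlogp = rng.normal(size=(V, 1))
        log_prior = np.zeros((V, 1))
        full = objective(log_prior, slogp, dlogp, spec, spec.g, spec.w, 1.0)
        half = objective(log_prior, slogp, dlogp, spec, spec.g, spec.w, 0.5)
        assert half == pytest.approx(0.5 * full, abs=1e-12)

    def test_matches_brute_force_toy(self, rng):
        """4-voxel 2-class toy against hand-coded sums."""
        spec = MixtureSpec(["a", "b"], [[0], [1]], [[0], [1]], 2, 2)
        V = 4
        prior = rng.dirichlet(np.ones(2), size=V)
        slogp = rng.normal(size=(V, 2))
        dlogp = rng.normal(size=(V, 2))
        eps = 0.8
        val = objective(np.log(prior), slogp, dlogp, spec, spec.g, spec.w, eps)
        expect = sum(
            np.log(
                prior[v, 0] * np.exp(slogp[v, 0]) * np.exp(dlogp[v, 0]) ** eps
                + prior[v, 1] * np.exp(slogp[v, 1]) * np.exp(dlogp[v, 1]) ** eps
            )
            for v in range(V)
        )
        assert val == pytest.approx(expect, abs=1e-12)


class TestEpsilonConsistency:
    def test_duplication_equivalence(self, rng):
        """k-fold duplicated voxels with eps = 1/k give the identical
        diffusion fit as the un-duplicated eps = 1 data."""
        k = 4
        n = 500
        d = rng.standard_normal((n, 6)) * 0.4 + 1.0
        w = rng.random(n) + 0.1
        base = fit_loggauss(d, 1.0 * w)  # eps = 1
        dup = np.repeat(d, k, axis=0)
        wdup = np.repeat(w, k) * (1.0 / k)  # eps = 1/k scaling in the M step
        dup_fit = fit_loggauss(dup, wdup)
        assert np.abs(dup_fit.mean - base.mean).max() < 1e-6
        assert dup_fit.var == pytest.approx(base.var, abs=1e-6)

    def test_duplication_equivalence_through_m_step(self, rng):
        spec = MixtureSpec(["only"], [[0]], [[0]], 1, 1)
        n, k = 200, 3
        data = {
            "intensities": rng.normal(size=(n, 1)),
            "logvecs": rng.standard_normal((n, 6)),
        }
        q = np.ones((n, 1))
        sp1, dp1, _, _ = m_step(q, data, spec, [None], "log-gaussian", 1.0)
        data_dup = {key: np.repeat(val, k, axis=0) for key, val in data.items()}
        sp2, dp2, _, _ = m_step(
            np.ones((n * k, 1)), data_dup, spec, [None], "log-gaussian", 1.0 / k
        )
        assert np.abs(dp1[0].mean - dp2[0].mean).max() < 1e-6
        assert dp1[0].var == pytest.approx(dp2[0].var, abs=1e-6)


class TestPosteriorVolumes:
    def test_hard_posteriors_count_voxels(self):
        grid = VoxelGrid.isotropic((2, 2, 2), 2.0)
        post = np.zeros((8, 2))
        post[:3, 0] = 1.0
        post[3:, 1] = 1.0
        vols = posterior_volumes(post, grid)
        assert np.allclose(vols, [3 * 8.0, 5 * 8.0])

    def test_uniform_posteriors_split_equally(self):
        grid = VoxelGrid.isotropic((3, 3, 3), 1.0)
        post = np.full((27, 2), 0.5)
        vols = posterior_volumes(post, grid)
        assert vols[0] == vols[1] == pytest.approx(13.5)

    def test_total_volume_conserved(self, rng):
        grid = VoxelGrid.isotropic((4, 4, 4), 1.3)
        post = rng.random((64, 5))
        post /= post.sum(axis=1, keepdims=True)
        vols = posterior_volumes(post, grid)
        assert vols.sum() == pytest.approx(64 * grid.voxel_volume_mm3, rel=1e-6)


@pytest.fixture(scope="module")
def phantom_fit():
    pspec, mspec = default_phantom_spec(size=14, seed=3)
    mesh = make_box_atlas(pspec)
    labels, svol, tf = sample_phantom(mesh, pspec)
    cfg = FitConfig(seed=0, max_cycles=4, max_inner_iter=10, deform_iters=8)
    model = JointSegmentationModel(
        svol, tf.grid, tf, mesh, mspec, family="dsw-beta", config=cfg
    )
    return labels, tf.grid, model.fit(), (pspec, mspec, svol, tf)


class TestFullFit:
    def test_objective_trace_monotone(self, phantom_fit):
        _, _, res, _ = phantom_fit
        tr = res.objective_trace
        rel = np.diff(tr) / np.maximum(np.abs(tr[:-1]), 1.0)
        assert rel.min() > -1e-8

    def test_labels_are_argmax_of_posteriors(self, phantom_fit):
        _, grid, res, _ = phantom_fit
        assert np.array_equal(
            res.labels.reshape(-1), np.argmax(res.posteriors, axis=-1)
        )

    def test_volumes_sum_to_fov(self, phantom_fit):
        _, grid, res, _ = phantom_fit
        assert res.volumes_mm3.sum() == pytest.approx(
            grid.n_voxels * grid.voxel_volume_mm3, rel=1e-6
        )

    def test_recovers_sampled_labels(self, phantom_fit):
        labels, grid, res, _ = phantom_fit
        from jointseg.metrics import ROIMask, dice

        for c in range(4):
            d = dice(ROIMask(grid, labels == c), ROIMask(grid, res.labels == c))
            assert d > 0.9

    def test_deterministic_given_seed(self, phantom_fit):
        _, _, res, (pspec, mspec, svol, tf) = phantom_fit
        mesh2 = make_box_atlas(pspec)
        cfg = FitConfig(seed=0, max_cycles=4, max_inner_iter=10, deform_iters=8)
        model2 = JointSegmentationModel(
            svol, tf.grid, tf, mesh2, mspec, family="dsw-beta", config=cfg
        )
        res2 = model2.fit()
        assert np.array_equal(res.labels, res2.labels)
        assert np.array_equal(res.objective_trace, res2.objective_trace)

    def test_summary_mentions_key_quantities(self, phantom_fit):
        _, _, res, _ = phantom_fit
        text = res.summary()
        assert "epsilon" in text
        assert "volume_mm3" in text
        assert "dsw-beta" in text

    def test_model_dump_roundtrips_json(self, phantom_fit, tmp_path):
        import json

        _, _, res, _ = phantom_fit
        path = tmp_path / "dump.json"
        res.save_model_dump(path)
        dump = json.loads(path.read_text())
        assert dump["family"] == "dsw-beta"
        assert len(dump["objective_trace"]) == len(res.objective_trace)
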