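"""Joint Bayesian segmentation model and its Generalised-EM driver.

The model: a deformable probabilistic atlas supplies a per-voxel prior over
C classes; each class emits structural intensity through a Gaussian mixture
and a diffusion observation through a mixture in one of three tensor
families.  Writing ``p(l_v = c)`` for the rasterised prior, the parameter
objective is

    O(theta) = log p(theta_a) + sum_i log p(theta_i^s) + sum_j log p(theta_j^d)
             + sum_v log sum_c p(l_v=c) [sum_i g_ci p(s_v|theta_i^s)]
                                        [sum_j w_cj p(d_v|theta_j^d)^eps]

where the diffusion factor is tempered by ``eps`` in (0, 1] to compensate
for the resolution mismatch between modalities (interpolating the diffusion
volume onto the finer structural grid inflates its effective sample size by
the voxel-volume ratio; eps undoes exactly that inflation).

Optimisation alternates mesh deformation (conjugate gradient on the prior
term plus topology penalty), reflection-plane re-estimation, and GEM over
the likelihood parameters: the E step computes soft assignments q over
(class, structural component, diffusion component) triples; the M step runs
each family's weighted MAP fitter on the marginal responsibilities and
updates the mixture weights in closed form.  Every step increases the EM
lower bound, so the objective trace is non-decreasing.

Interface: build a :class:`JointSegmentationModel` from data, call
``fit()``, and read the :class:`SegmentationResults` (MAP label map,
posterior-weighted volumes, fitted parameters, objective trace,
``summary()``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .atlas import (
    AtlasMesh,
    ClassPriorField,
    DeformationParams,
    optimise_deformation,
    rasterise_priors,
)
from .grids import VoxelGrid
from .likelihoods import (
    GaussianParams,
    NIWHyper,
    dswbeta_logpdf,
    fit_dswbeta,
    fit_gaussian_map,
    fit_loggauss,
    fit_wishart_map,
    gaussian_logpdf,
    loggauss_logpdf,
    params_to_dict,
    wishart_logpdf,
    wishart_map_objective,
)
from .mixture import MixtureSpec, kmeans_init, merge_outputs, validate_spec
from .symmetry import (
    ReflectionPlane,
    SymmetryPairing,
    build_reflection_terms,
    fit_pair_symmetric,
    optimise_reflection,
    reflect_params,
)
from .tensors import (
    TensorField,
    clean_tensor_field,
    log_field_from_tensors,
    logvec_to_matrix,
    resample_log_tensors,
    summarise_field,
    tensor_field_from_log,
)

__all__ = [
    "FitConfig",
    "FitState",
    "SegmentationResults",
    "JointSegmentationModel",
    "choose_epsilon",
    "e_step",
    "m_step",
    "objective",
    "posterior_volumes",
]

LOG_FLOOR = -745.0  # configurable floor for zero-likelihood voxels


def choose_epsilon(
    s_grid: VoxelGrid, d_grid: VoxelGrid, override: float | None = None
) -> float:
    """Diffusion-likelihood tempering exponent from the voxel-volume ratio.

    eps = min(1, structural voxel volume / diffusion voxel volume): after
    resampling the diffusion data to the structural grid, the sum over the V
    structural voxels tempered by eps matches the sum over the V_d source
    voxels.  Diffusion finer than structural caps at 1.
    """
    if override is not None:
        if not (0.0 < override <= 1.0):
            raise ValueError(f"epsilon override must be in (0, 1], got {override}")
        return float(override)
    return float(min(1.0, s_grid.voxel_volume_mm3 / d_grid.voxel_volume_mm3))


@dataclass
class FitConfig:
    """Tunables of the fitting procedure (defaults suit small volumes)."""

    epsilon: float | None = None  # None = auto from voxel-volume ratio
    use_diffusion: bool = True
    symmetry: SymmetryPairing | None = None
    seed: int = 0
    max_cycles: int = 30
    outer_tol: float = 1e-5
    max_inner_iter: int = 100
    inner_tol: float = 1e-6
    deform_iters: int = 20  # 0 disables mesh deformation
    hyper_strength_frac: float = 0.1
    kmeans_prior_threshold: float = 0.5
    clean_kernel_sigma_mm: float = 2.0


@dataclass
class FitState:
    """All estimated quantities at one point of the optimisation."""

    deformation: DeformationParams
    structural_params: list
    diffusion_params: list
    g: np.ndarray
    w: np.ndarray
    plane: ReflectionPlane | None
    epsilon: float
    objective_trace: list = dataclass_field(default_factory=list)
    flags: list = dataclass_field(default_factory=list)


# --------------------------------------------------------------------------
# Core GEM operations (module-level, individually testable)
# --------------------------------------------------------------------------


def _component_log_matrices(
    data: dict,
    structural_params: list,
    diffusion_params: list,
    family: str,
    use_diffusion: bool,
    diffusion_valid: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """(V, G) structural and (V, W) diffusion log-densities.

    Voxels with invalid diffusion data contribute only through the
    structural likelihood: their diffusion log-density row is zero (the
    factor is treated as 1 rather than imputed).
    """
    s = data["intensities"]
    V = len(s)
    slogp = np.column_stack([gaussian_logpdf(s, p) for p in structural_params])
    W = len(diffusion_params)
    dlogp = np.zeros((V, W))
    if use_diffusion and W:
        if diffusion_valid is None:
            diffusion_valid = np.ones(V, dtype=bool)
        dv = diffusion_valid
        for j, p in enumerate(diffusion_params):
            if family == "dsw-beta":
                dlogp[dv, j] = dswbeta_logpdf(data["fa"][dv], data["pdir"][dv], p)
            elif family == "log-gaussian":
                dlogp[dv, j] = loggauss_logpdf(data["logvecs"][dv], p)
            elif family == "wishart":
                dlogp[dv, j] = wishart_logpdf(data["tensors"][dv], p)
            else:
                raise ValueError(f"unknown family {family!r}")
    return slogp, dlogp


def e_step(
    log_prior: np.ndarray,
    slogp: np.ndarray,
    dlogp: np.ndarray,
    spec: MixtureSpec,
    g: np.ndarray,
    w: np.ndarray,
    epsilon: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Soft assignment over supported (class, i, j) triples, in log space.

    q[v, k] is proportional to ``g_ci w_cj prior_vc p(s_v|i) p(d_v|j)^eps``
    normalised per voxel.  Voxels whose numerator underflows entirely are
    assigned uniform responsibility over the support and flagged.

    Returns (q, flagged_voxel_mask).
    """
    cc, ii, jj = spec.triples
    with np.errstate(divide="ignore"):
        log_gw = np.log(g[cc, ii]) + np.log(w[cc, jj])
        logq = (
            log_gw[None, :]
            + log_prior[:, cc]
            + slogp[:, ii]
            + epsilon * dlogp[:, jj]
        )
    norm = logsumexp(logq, axis=1)
    bad = ~np.isfinite(norm)
    q = np.exp(logq - norm[:, None])
    if bad.any():
        finite_support = np.isfinite(log_gw)
        q[bad] = finite_support / max(finite_support.sum(), 1)
    return q, bad


def _param_log_prior(
    structural_params: list,
    structural_hyper: list,
    diffusion_params: list,
    family: str,
) -> float:
    """Sum of log p(theta | gamma) terms that the fitters also maximise."""
    total = 0.0
    for p, h in zip(structural_params, structural_hyper):
        if h is not None and h.strength > 0:
            diff = p.mean - h.mean
            total += -0.5 * h.strength * float(diff @ np.linalg.solve(p.cov, diff))
    if family == "wishart":
        for p in diffusion_params:
            a, b = p.gamma_hyper
            t = 0.5 * (p.dof - 2.0)
            total += float((a - 1.0) * np.log(t) - b * t)
    return total


def objective(
    log_prior: np.ndarray,
    slogp: np.ndarray,
    dlogp: np.ndarray,
    spec: MixtureSpec,
    g: np.ndarray,
    w: np.ndarray,
    epsilon: float,
    param_log_prior: float = 0.0,
    deformation_penalty_value: float = 0.0,
) -> float:
    """The marginal log-posterior objective driving the whole fit."""
    cc, ii, jj = spec.triples
    with np.errstate(divide="ignore"):
        log_gw = np.log(g[cc, ii]) + np.log(w[cc, jj])
    logq = (
        log_gw[None, :] + log_prior[:, cc] + slogp[:, ii] + epsilon * dlogp[:, jj]
    )
    per_voxel = logsumexp(logq, axis=1)
    per_voxel = np.maximum(per_voxel, LOG_FLOOR)
    return float(per_voxel.sum()) + param_log_prior - deformation_penalty_value


def _marginal_weights(
    q: np.ndarray, spec: MixtureSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel marginal responsibilities by class, structural and
    diffusion component."""
    cc, ii, jj = spec.triples
    V = q.shape[0]
    qc = np.zeros((V, spec.n_classes))
    qs = np.zeros((V, spec.n_structural))
    qd = np.zeros((V, spec.n_diffusion))
    np.add.at(qc.T, cc, q.T)
    np.add.at(qs.T, ii, q.T)
    np.add.at(qd.T, jj, q.T)
    return qc, qs, qd


def _weight_update(q: np.ndarray, spec: MixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form mixture-weight update: class-normalised triple masses."""
    cc, ii, jj = spec.triples
    mass_ci = np.zeros((spec.n_classes, spec.n_structural))
    mass_cj = np.zeros((spec.n_classes, spec.n_diffusion))
    tot = q.sum(axis=0)
    np.add.at(mass_ci, (cc, ii), tot)
    np.add.at(mass_cj, (cc, jj), tot)
    g = spec.g.copy()
    w = spec.w.copy()
    for c in range(spec.n_classes):
        ms = mass_ci[c].sum()
        if ms > 0:
            g[c] = mass_ci[c] / ms
        md = mass_cj[c].sum()
        if md > 0:
            w[c] = mass_cj[c] / md
    return g, w


def m_step(
    q: np.ndarray,
    data: dict,
    spec: MixtureSpec,
    structural_hyper: list,
    family: str,
    epsilon: float,
    use_diffusion: bool = True,
    diffusion_valid: np.ndarray | None = None,
    pairing: SymmetryPairing | None = None,
    plane: ReflectionPlane | None = None,
) -> tuple[list, list, np.ndarray, np.ndarray]:
    """Generalised M step: family fitters on marginal responsibilities.

    Structural components are fitted with marginal weights ``sum_{c,j} q``;
    diffusion components with the tempered weights ``eps * sum_{c,i} q``
    restricted to valid-diffusion voxels.  Contralateral pairs listed in
    ``pairing`` are fitted jointly through the reflection plane.  Mixture
    weights follow the closed-form class-normalised update.
    """
    _, qs, qd = _marginal_weights(q, spec)

    structural_params = []
    for i in range(spec.n_structural):
        wv = qs[:, i]
        if wv.sum() <= 0:
            raise ValueError(f"structural component {i} received zero weight")
        try:
            structural_params.append(
                fit_gaussian_map(data["intensities"], wv, structural_hyper[i])
            )
        except ValueError as e:
            raise ValueError(f"structural component {i}: {e}") from e

    diffusion_params = [None] * spec.n_diffusion
    if use_diffusion and spec.n_diffusion:
        if diffusion_valid is None:
            diffusion_valid = np.ones(q.shape[0], dtype=bool)
        qd = qd * diffusion_valid[:, None] * epsilon
        paired_right = pairing.paired_right if pairing else set()
        handled: set[int] = set()
        if pairing and plane is not None:
            for left, right in pairing.pairs:
                if family == "dsw-beta":
                    ld = (data["fa"], data["pdir"])
                    rd = ld
                elif family == "log-gaussian":
                    ld = rd = data["logvecs"]
                else:
                    ld = rd = data["tensors"]
                try:
                    pl, pr = fit_pair_symmetric(
                        ld, qd[:, left], rd, qd[:, right], plane, family
                    )
                except ValueError as e:
                    raise ValueError(
                        f"diffusion pair ({left}, {right}): {e}"
                    ) from e
                diffusion_params[left] = pl
                diffusion_params[right] = pr
                handled.update((left, right))
        for j in range(spec.n_diffusion):
            if j in handled:
                continue
            wv = qd[:, j]
            if wv.sum() <= 0:
                raise ValueError(f"diffusion component {j} received zero weight")
            try:
                if family == "dsw-beta":
                    diffusion_params[j] = fit_dswbeta(data["fa"], data["pdir"], wv)
                elif family == "log-gaussian":
                    diffusion_params[j] = fit_loggauss(data["logvecs"], wv)
                elif family == "wishart":
                    diffusion_params[j] = fit_wishart_map(data["tensors"], wv)
                else:
                    raise ValueError(f"unknown family {family!r}")
            except ValueError as e:
                raise ValueError(f"diffusion component {j}: {e}") from e

    g, w = _weight_update(q, spec)
    return structural_params, diffusion_params, g, w


def posterior_volumes(posteriors: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Posterior-weighted label volumes in mm^3.

    volume_l = sum_v posterior_vl * voxel volume; soft voxels contribute
    fractionally, so the label volumes always sum to the volume of the
    whole field of view.
    """
    post = np.asarray(posteriors, dtype=float)
    flat = post.reshape(-1, post.shape[-1])
    return flat.sum(axis=0) * grid.voxel_volume_mm3


# --------------------------------------------------------------------------
# Model / Results
# --------------------------------------------------------------------------


class SegmentationResults:
    """Fitted segmentation: MAP labels, posteriors, volumes, diagnostics."""

    def __init__(
        self,
        model: "JointSegmentationModel",
        state: FitState,
        posteriors_class: np.ndarray,
        converged: bool,
        n_cycles: int,
    ) -> None:
        self.model = model
        self.state = state
        self.converged = converged
        self.n_cycles = n_cycles
        spec = model.spec
        grid = model.grid
        merged = merge_outputs(posteriors_class, spec.merge_map)
        self.class_posteriors = posteriors_class
        self.posteriors = merged
        self.labels = np.argmax(merged, axis=-1).reshape(grid.shape)
        self.volumes_mm3 = posterior_volumes(merged, grid)

    @property
    def objective_trace(self) -> np.ndarray:
        return np.asarray(self.state.objective_trace, dtype=float)

    @property
    def label_names(self) -> list[str]:
        spec = self.model.spec
        names = [""] * spec.n_output_labels
        for c, l in spec.merge_map.items():
            if not names[l]:
                names[l] = spec.class_names[c]
            elif spec.class_names[c] not in names[l]:
                names[l] += "+" + spec.class_names[c]
        return names

    def volumes_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label_id": np.arange(len(self.volumes_mm3)),
                "label_name": self.label_names,
                "volume_mm3": self.volumes_mm3,
            }
        )

    def summary(self) -> str:
        """Human-readable fit report."""
        lines = []
        lines.append("Joint structural+diffusion Bayesian segmentation")
        lines.append("=" * 52)
        lines.append(f"diffusion family : {self.model.family}")
        lines.append(f"epsilon          : {self.state.epsilon:.6g}")
        lines.append(
            f"cycles           : {self.n_cycles}"
            f" ({'converged' if self.converged else 'max cycles reached'})"
        )
        tr = self.objective_trace
        if len(tr):
            lines.append(f"objective        : {tr[-1]:.6f} (delta last step "
                         f"{(tr[-1] - tr[-2]) if len(tr) > 1 else 0.0:.3g})")
        if self.state.plane is not None:
            r = self.state.plane.normal
            lines.append(f"reflection normal: [{r[0]:+.4f} {r[1]:+.4f} {r[2]:+.4f}]")
        if self.state.flags:
            lines.append(f"flags            : {sorted(set(self.state.flags))}")
        lines.append("")
        lines.append("Posterior-weighted volumes (mm^3)")
        lines.append(self.volumes_table().to_string(index=False))
        return "\n".join(lines)

    def model_dump(self) -> dict:
        """JSON-serialisable record of the fitted model (reproducibility)."""
        st = self.state
        return {
            "family": self.model.family,
            "epsilon": st.epsilon,
            "converged": self.converged,
            "n_cycles": self.n_cycles,
            "objective_trace": [float(x) for x in st.objective_trace],
            "reflection_normal": (
                st.plane.normal.tolist() if st.plane is not None else None
            ),
            "structural_params": [params_to_dict(p) for p in st.structural_params],
            "diffusion_params": [
                params_to_dict(p) for p in st.diffusion_params if p is not None
            ],
            "g": st.g.tolist(),
            "w": st.w.tolist(),
            "flags": list(st.flags),
            "seed": self.model.config.seed,
        }

    def save_model_dump(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.model_dump(), fh, indent=2)


class JointSegmentationModel:
    """Joint structural+diffusion mixture segmentation of one subject.

    Parameters
    ----------
    structural
        Structural volume, shape (X, Y, Z) or (X, Y, Z, S) for S channels.
    grid
        The structural voxel grid (the segmentation grid).
    tensor_field
        Diffusion tensors, on their own grid; cleaned, log-resampled to the
        structural grid and summarised as needed by the chosen family.
    atlas_mesh
        Deformable probabilistic atlas.
    spec
        Mixture specification (class/component assignments, merge map).
    family
        Diffusion likelihood family: 'dsw-beta', 'wishart' or 'log-gaussian'.
    coarse_seg
        Optional coarse whole-structure label map used for the affine atlas
        initialisation and the structural hyperpriors.
    config
        Fitting configuration.
    """

    FAMILIES = ("dsw-beta", "wishart", "log-gaussian")

    def __init__(
        self,
        structural: np.ndarray,
        grid: VoxelGrid,
        tensor_field: TensorField | None,
        atlas_mesh: AtlasMesh,
        spec: MixtureSpec,
        family: str = "dsw-beta",
        coarse_seg: np.ndarray | None = None,
        config: FitConfig | None = None,
    ) -> None:
        if family not in self.FAMILIES:
            raise ValueError(f"family must be one of {self.FAMILIES}, got {family!r}")
        self.family = family
        self.grid = grid
        self.mesh = atlas_mesh
        self.spec = spec
        self.config = config or FitConfig()
        self.coarse_seg = coarse_seg
        validate_spec(spec)

        structural = np.asarray(structural, dtype=float)
        if structural.ndim == 3:
            structural = structural[..., None]
        if structural.shape[:3] != grid.shape:
            raise ValueError("structural volume does not match grid shape")
        self.structural = structural

        self._prepare_diffusion(tensor_field)

    # -- data preparation ---------------------------------------------------

    def _prepare_diffusion(self, tf: TensorField | None) -> None:
        cfg = self.config
        V = self.grid.n_voxels
        data: dict = {
            "intensities": self.structural.reshape(V, -1),
        }
        if tf is None or not cfg.use_diffusion:
            self.config.use_diffusion = False
            self.epsilon = 1.0
            self.diffusion_valid = np.zeros(V, dtype=bool)
            self.data = data
            return

        self.epsilon = choose_epsilon(self.grid, tf.grid, cfg.epsilon)
        cleaned = clean_tensor_field(tf, cfg.clean_kernel_sigma_mm)
        logf = log_field_from_tensors(cleaned)
        if not tf.grid.same_world_space(self.grid):
            logf = resample_log_tensors(logf, self.grid)
        self.diffusion_valid = logf.valid_mask.reshape(V)
        data["logvecs"] = logf.logvecs.reshape(V, 6)
        resampled = tensor_field_from_log(logf)
        data["tensors"] = resampled.tensors.reshape(V, 3, 3)
        with np.errstate(all="ignore"):
            data["precisions"] = np.linalg.inv(
                np.where(
                    self.diffusion_valid.reshape(self.grid.shape + (1, 1)),
                    resampled.tensors,
                    np.eye(3),
                )
            ).reshape(V, 3, 3)
        summ = summarise_field(resampled)
        data["fa"] = summ.fa.reshape(V)
        data["pdir"] = summ.pdir.reshape(V, 3)
        self.data = data

    # -- initialisation -----------------------------------------------------

    def _initial_hyper(self, priors_flat: np.ndarray) -> list:
        """Structural hyperpriors from the coarse initial segmentation.

        The hypermean of component i is the median intensity over voxels
        initially assigned (argmax prior) to classes using i; its strength
        is a fraction of that voxel count (the hypermean's effective sample
        size).
        """
        s = self.data["intensities"]
        init_class = np.argmax(priors_flat, axis=1)
        hyper: list = []
        for i in range(self.spec.n_structural):
            classes = [
                c
                for c in range(self.spec.n_classes)
                if i in self.spec.structural_support[c]
            ]
            sel = np.isin(init_class, classes)
            count = int(sel.sum())
            if count == 0:
                hyper.append(None)
                continue
            M = np.median(s[sel], axis=0)
            hyper.append(
                NIWHyper(mean=M, strength=self.config.hyper_strength_frac * count)
            )
        return hyper

    def _initial_params(self, priors_flat: np.ndarray) -> tuple[list, list]:
        seed = self.config.seed
        thr = self.config.kmeans_prior_threshold
        structural = kmeans_init(
            self.data, priors_flat, self.spec, "gaussian", "structural", seed, thr
        )
        sp = [structural[i] for i in range(self.spec.n_structural)]
        dp: list = [None] * self.spec.n_diffusion
        if self.config.use_diffusion:
            diffusion = kmeans_init(
                self.data, priors_flat, self.spec, self.family, "diffusion", seed, thr
            )
            dp = [diffusion[j] for j in range(self.spec.n_diffusion)]
        return sp, dp

    # -- fitting ------------------------------------------------------------

    def fit(self) -> SegmentationResults:
        """Run the full coordinate-ascent / GEM optimisation.

        Cycle structure: E step, mesh-deformation conjugate-gradient update
        on the class responsibilities, reflection-plane re-estimation, then
        inner GEM (E/M) iterations to convergence.  Deterministic for a
        fixed config seed.
        """
        cfg = self.config
        spec = self.spec
        mesh = self.mesh

        if self.coarse_seg is not None:
            from .atlas import initial_affine_from_mask

            mask = np.asarray(self.coarse_seg) > 0
            mesh.affine_to_subject = initial_affine_from_mask(mesh, mask, self.grid)

        deform = DeformationParams.zeros(mesh)
        prior_field = rasterise_priors(mesh, deform, self.grid)
        priors_flat = prior_field.flat
        log_prior = np.log(np.maximum(priors_flat, 1e-300))

        hyper = self._initial_hyper(priors_flat)
        sp, dp = self._initial_params(priors_flat)
        g = spec.g.copy()
        w = spec.w.copy()
        plane = None
        pairing = cfg.symmetry
        if pairing is not None and pairing.pairs and cfg.use_diffusion:
            # left-right voxel axis mapped to world coordinates
            axis = self.grid.affine[:3, 0]
            plane = ReflectionPlane(axis / np.linalg.norm(axis))

        state = FitState(
            deformation=deform, structural_params=sp, diffusion_params=dp,
            g=g, w=w, plane=plane, epsilon=self.epsilon,
        )
        from .atlas import deformation_penalty

        trace: list[float] = []
        flags: list[str] = []
        q = None
        converged = False
        cycle = 0
        prev_obj = -np.inf
        for cycle in range(1, cfg.max_cycles + 1):
            slogp, dlogp = self._log_matrices(state)
            q, bad = e_step(log_prior, slogp, dlogp, spec, state.g, state.w,
                            state.epsilon)
            if bad.any():
                flags.append("underflow_voxels")

            if cfg.deform_iters > 0:
                qc, _, _ = _marginal_weights(q, spec)
                state.deformation = optimise_deformation(
                    mesh, state.deformation, qc, self.grid,
                    max_iter=cfg.deform_iters,
                )
                if state.deformation.warn_flag:
                    flags.append("deformation_no_step")
                prior_field = rasterise_priors(mesh, state.deformation, self.grid)
                priors_flat = prior_field.flat
                log_prior = np.log(np.maximum(priors_flat, 1e-300))

            # inner GEM iterations
            inner_prev = -np.inf
            for _ in range(cfg.max_inner_iter):
                slogp, dlogp = self._log_matrices(state)
                q, bad = e_step(log_prior, slogp, dlogp, spec, state.g,
                                state.w, state.epsilon)
                if pairing is not None and plane is not None:
                    _, _, qd = _marginal_weights(q, spec)
                    terms = build_reflection_terms(
                        pairing,
                        {j: p for j, p in enumerate(state.diffusion_params)
                         if p is not None},
                        self.data, qd,
                    )
                    if terms:
                        new_plane, degen = optimise_reflection(
                            terms, state.plane.normal
                        )
                        if degen:
                            flags.append("reflection_degenerate")
                        else:
                            state.plane = new_plane
                        # re-reflect right components through the new plane
                        for left, right in pairing.pairs:
                            state.diffusion_params[right] = reflect_params(
                                state.diffusion_params[left], state.plane
                            )
                sp_new, dp_new, g_new, w_new = m_step(
                    q, self.data, spec, hyper, self.family, state.epsilon,
                    use_diffusion=cfg.use_diffusion,
                    diffusion_valid=self.diffusion_valid,
                    pairing=pairing, plane=state.plane,
                )
                state.structural_params = sp_new
                state.diffusion_params = dp_new
                state.g, state.w = g_new, w_new

                slogp, dlogp = self._log_matrices(state)
                obj = objective(
                    log_prior, slogp, dlogp, spec, state.g, state.w,
                    state.epsilon,
                    param_log_prior=_param_log_prior(
                        state.structural_params, hyper, state.diffusion_params,
                        self.family if cfg.use_diffusion else "none",
                    ),
                    deformation_penalty_value=deformation_penalty(
                        mesh, state.deformation
                    ),
                )
                if not np.isfinite(obj):
                    raise FloatingPointError(
                        "non-finite objective; model dump: "
                        + json.dumps({"cycle": cycle})
                    )
                trace.append(obj)
                rel = abs(obj - inner_prev) / max(abs(obj), 1.0)
                inner_prev = obj
                if rel < cfg.inner_tol:
                    break

            rel_outer = abs(inner_prev - prev_obj) / max(abs(inner_prev), 1.0)
            prev_obj = inner_prev
            if rel_outer < cfg.outer_tol:
                converged = True
                break

        state.objective_trace = trace
        state.flags = flags

        # final E step for output posteriors
        slogp, dlogp = self._log_matrices(state)
        q, _ = e_step(log_prior, slogp, dlogp, spec, state.g, state.w,
                      state.epsilon)
        qc, _, _ = _marginal_weights(q, spec)
        return SegmentationResults(self, state, qc, converged, cycle)

    def _log_matrices(self, state: FitState) -> tuple[np.ndarray, np.ndarray]:
        return _component_log_matrices(
            self.data, state.structural_params, state.diffusion_params,
            self.family, self.config.use_diffusion, self.diffusion_valid,
        )
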