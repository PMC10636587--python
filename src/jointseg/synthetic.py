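"""Synthetic atlases and phantoms drawn from the model's own generative
process.

The segmentation framework is a generative forward model: sample a label
per voxel from the (deformed) atlas prior, then sample structural intensity
and a diffusion observation from that class's component distributions.
This module builds small box-shaped tetrahedral atlases with smoothly
varying class probabilities and samples phantoms from them, so that every
other module — and the full segmentation pipeline — can be exercised and
validated end-to-end without any external data.

Diffusion observations are rendered back into SPD tensors so phantoms flow
through the same public interfaces as real data:

* Wishart draws are inverted (``T = X^-1``),
* log-Gaussian draws are exponentiated from the log-vector,
* DSW-beta draws (FA from the Beta, axis from the Watson by rejection
  sampling) are reconstructed as axially symmetric tensors whose analytic
  FA equals the sampled value, at a fixed mean diffusivity of 0.7e-3 mm^2/s
  (a typical parenchyma scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .atlas import AtlasMesh, ClassPriorField, DeformationParams, rasterise_priors
from .grids import VoxelGrid
from .likelihoods import (
    DSWBetaParams,
    GaussianParams,
    LogGaussianParams,
    WishartParams,
)
from .tensors import TensorField, logvec_to_matrix, tensor_from_logvec

__all__ = [
    "PhantomSpec",
    "make_box_atlas",
    "sample_phantom",
    "sample_watson",
    "tensor_from_fa_direction",
    "degrade_resolution",
]

MEAN_DIFFUSIVITY = 0.7e-3  # mm^2/s


@dataclass
class PhantomSpec:
    """Recipe for a synthetic phantom.

    ``structural_params[c]`` / ``diffusion_params[c]`` give the generating
    component of class c; ``family`` names the diffusion family used for
    every class.  ``blob_centers``/``blob_sigma`` shape the atlas prior for
    the non-background classes (fractions of the grid extent).
    """

    shape: tuple[int, int, int]
    voxel_mm: float
    class_names: list[str]
    structural_params: list[GaussianParams]
    diffusion_params: list
    family: str
    blob_centers: list[tuple[float, float, float]] = None
    blob_sigma: float = 0.22
    mesh_spacing: int = 6
    stiffness: float = 1.0
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


def _box_mesh(grid: VoxelGrid, spacing: int) -> tuple[np.ndarray, np.ndarray]:
    """Regular lattice of vertices over the grid, each cell split into 5 tets.

    The lattice extends half a spacing beyond the grid so every voxel centre
    lies strictly inside the mesh after identity placement.
    """
    shape = np.array(grid.shape, dtype=float)
    # vertex coordinates in voxel-index units, padded beyond the volume
    axes = []
    for n in shape:
        k = max(2, int(np.ceil(n / spacing)) + 1)
        axes.append(np.linspace(-1.0, n, k))
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    verts_idx = np.stack([gx, gy, gz], axis=-1)
    dims = verts_idx.shape[:3]
    verts = grid.index_to_world(verts_idx.reshape(-1, 3))

    def vid(i: int, j: int, k: int) -> int:
        return (i * dims[1] + j) * dims[2] + k

    tets = []
    # 5-tet decomposition of each cell, parity-flipped for face compatibility
    for i in range(dims[0] - 1):
        for j in range(dims[1] - 1):
            for k in range(dims[2] - 1):
                c = [
                    vid(i, j, k), vid(i + 1, j, k), vid(i, j + 1, k),
                    vid(i + 1, j + 1, k), vid(i, j, k + 1), vid(i + 1, j, k + 1),
                    vid(i, j + 1, k + 1), vid(i + 1, j + 1, k + 1),
                ]
                if (i + j + k) % 2 == 0:
                    cells = [
                        (c[0], c[1], c[2], c[4]), (c[1], c[3], c[2], c[7]),
                        (c[1], c[4], c[5], c[7]), (c[2], c[4], c[7], c[6]),
                        (c[1], c[2], c[4], c[7]),
                    ]
                else:
                    cells = [
                        (c[1], c[0], c[3], c[5]), (c[0], c[2], c[3], c[6]),
                        (c[0], c[4], c[6], c[5]), (c[3], c[5], c[6], c[7]),
                        (c[0], c[3], c[6], c[5]),
                    ]
                tets.extend(cells)
    tets = np.array(tets, dtype=int)
    # orient all tets positively
    a, b, cc, d = (verts[tets[:, m]] for m in range(4))
    vol = np.einsum("ij,ij->i", b - a, np.cross(cc - a, d - a))
    flip = vol < 0
    tets[flip, 0], tets[flip, 1] = tets[flip, 1], tets[flip, 0].copy()
    return verts, tets


def make_box_atlas(spec: PhantomSpec) -> AtlasMesh:
    """Build a box atlas whose per-vertex class probabilities are Gaussian
    blobs (one per foreground class) over a background floor.

    Class 0 is background.  Probability rows are normalised exactly, so all
    atlas invariants hold by construction.
    """
    if min(spec.shape) < 4:
        raise ValueError("phantom grid must be at least 4 voxels per axis")
    grid = VoxelGrid.isotropic(spec.shape, spec.voxel_mm)
    verts, tets = _box_mesh(grid, spec.mesh_spacing)
    C = spec.n_classes
    if C < 2:
        raise ValueError("need a background plus at least one foreground class")

    centers = spec.blob_centers
    if centers is None:
        rng = np.random.default_rng(spec.seed)
        centers = [tuple(0.25 + 0.5 * rng.random(3)) for _ in range(C - 1)]
    if len(centers) != C - 1:
        raise ValueError(
            f"{C - 1} foreground classes need {C - 1} blob centers, "
            f"got {len(centers)}"
        )

    extent = np.array(spec.shape) * spec.voxel_mm
    sigma = spec.blob_sigma * float(np.mean(extent))
    scores = np.full((len(verts), C), 0.08)  # background floor
    for c, ctr in enumerate(centers, start=1):
        mu = np.array(ctr) * extent
        d2 = np.sum((verts - mu) ** 2, axis=1)
        scores[:, c] = 3.0 * np.exp(-0.5 * d2 / sigma**2) + 1e-4
    probs = scores / scores.sum(axis=1, keepdims=True)

    return AtlasMesh(
        reference_vertices=verts,
        tetrahedra=tets,
        vertex_probs=probs,
        class_names=list(spec.class_names),
        stiffness=spec.stiffness,
        background_class=0,
    )


def sample_watson(
    psi: np.ndarray, kappa: np.ndarray | float, rng: np.random.Generator,
    max_rounds: int = 10000,
) -> np.ndarray:
    """Sample axial directions from Watson(psi, kappa) by rejection.

    Proposals are uniform on the sphere with envelope ``exp(kappa)``:
    accept u < exp(kappa (t^2 - 1)).  ``kappa`` may be a vector (one value
    per requested sample), which supports the effective-concentration model
    where each voxel has its own kappa * FA.  The acceptance rate decays
    like 1/kappa, so a round counter guards against pathological inputs.
    """
    psi = np.asarray(psi, dtype=float)
    psi = psi / np.linalg.norm(psi)
    kappa = np.atleast_1d(np.asarray(kappa, dtype=float))
    n = len(kappa)
    out = np.zeros((n, 3))
    todo = np.ones(n, dtype=bool)
    for _ in range(max_rounds):
        m = int(todo.sum())
        if m == 0:
            break
        z = rng.standard_normal((m, 3))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        t = z @ psi
        accept = rng.random(m) < np.exp(kappa[todo] * (t**2 - 1.0))
        idx = np.flatnonzero(todo)[accept]
        out[idx] = z[accept]
        todo[idx] = False
    if todo.any():
        raise RuntimeError(
            f"Watson rejection sampler failed to accept {int(todo.sum())} "
            f"samples within {max_rounds} rounds"
        )
    return out


def tensor_from_fa_direction(
    fa: np.ndarray, phi: np.ndarray, mean_diffusivity: float = MEAN_DIFFUSIVITY
) -> np.ndarray:
    """Axially symmetric SPD tensor with given FA, axis and mean diffusivity.

    Eigenvalues are (m(1+2 delta), m(1-delta), m(1-delta)) with
    ``delta = FA / sqrt(3 - 2 FA^2)``, which makes the analytic FA equal the
    requested value exactly.
    """
    fa = np.atleast_1d(np.asarray(fa, dtype=float))
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    fa = np.clip(fa, 0.0, 0.999)
    delta = fa / np.sqrt(3.0 - 2.0 * fa**2)
    m = mean_diffusivity
    lam_perp = m * (1.0 - delta)
    lam_par = m * (1.0 + 2.0 * delta)
    eye = np.eye(3)
    outer = phi[:, :, None] * phi[:, None, :]
    return lam_perp[:, None, None] * eye + (lam_par - lam_perp)[:, None, None] * outer


def _sample_diffusion(
    family: str, params, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample n diffusion tensors from one component of the given family."""
    if family == "wishart":
        p: WishartParams = params
        X = stats.wishart.rvs(df=p.dof, scale=p.scale, size=n, random_state=rng)
        X = X.reshape(n, 3, 3)
        return np.linalg.inv(X)
    if family == "log-gaussian":
        p: LogGaussianParams = params
        d = p.mean + np.sqrt(p.var) * rng.standard_normal((n, 6))
        return tensor_from_logvec(d)
    if family == "dsw-beta":
        p: DSWBetaParams = params
        f = rng.beta(p.beta_a, p.beta_b, size=n)
        phi = sample_watson(p.mean_dir, p.concentration * f, rng)
        return tensor_from_fa_direction(f, phi)
    raise ValueError(f"unknown diffusion family {family!r}")


def sample_phantom(
    mesh: AtlasMesh,
    spec: PhantomSpec,
    deform: DeformationParams | None = None,
) -> tuple[np.ndarray, np.ndarray, TensorField]:
    """Sample (labels, structural image, tensor field) from the generative
    model: label from the rasterised prior, intensity from the class
    Gaussian, tensor from the class diffusion component.

    Deterministic for a fixed ``spec.seed``.  Returns the label volume
    (int), the structural volume with a trailing channel axis, and the
    tensor field.
    """
    rng = np.random.default_rng(spec.seed)
    grid = VoxelGrid.isotropic(spec.shape, spec.voxel_mm)
    if deform is None:
        deform = DeformationParams.zeros(mesh)
    prior = rasterise_priors(mesh, deform, grid)
    flat = prior.flat
    V, C = flat.shape

    u = rng.random(V)
    cum = np.cumsum(flat, axis=1)
    labels = (u[:, None] >= cum).sum(axis=1)

    S = len(spec.structural_params[0].mean)
    intensities = np.zeros((V, S))
    tensors = np.zeros((V, 3, 3))
    for c in range(C):
        idx = np.flatnonzero(labels == c)
        if idx.size == 0:
            continue
        gp = spec.structural_params[c]
        L = np.linalg.cholesky(gp.cov)
        intensities[idx] = gp.mean + rng.standard_normal((idx.size, S)) @ L.T
        tensors[idx] = _sample_diffusion(spec.family, spec.diffusion_params[c],
                                         idx.size, rng)

    label_vol = labels.reshape(grid.shape)
    struct_vol = intensities.reshape(grid.shape + (S,))
    tf = TensorField(grid, tensors.reshape(grid.shape + (3, 3)))
    return label_vol, struct_vol, tf


def degrade_resolution(tf: TensorField, factor: int) -> TensorField:
    """Block-average a tensor field in the log domain to a coarser grid.

    Each ``factor^3`` block of log-tensors is averaged (log-Euclidean mean)
    and exponentiated back; the output grid has ``factor``-times larger
    voxels.  Non-divisible dimensions are cropped with a warning.  Used to
    manufacture resolution mismatches with a known voxel-volume ratio for
    the likelihood-weighting (epsilon) experiments.
    """
    import warnings as _warnings

    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return TensorField(tf.grid, tf.tensors.copy(), tf.valid_mask.copy())
    from .tensors import log_field_from_tensors

    shape = np.array(tf.grid.shape)
    new_shape = shape // factor
    if np.any(shape % factor):
        _warnings.warn(
            f"grid {tuple(shape)} not divisible by {factor}; cropping",
            stacklevel=2,
        )
    crop = tuple(slice(0, int(n * factor)) for n in new_shape)
    lf = log_field_from_tensors(tf)
    lv = lf.logvecs[crop]
    X, Y, Z = (int(n) for n in new_shape)
    blocks = lv.reshape(X, factor, Y, factor, Z, factor, 6)
    mean_log = blocks.mean(axis=(1, 3, 5))

    aff = tf.grid.affine.copy()
    aff[:3, :3] *= factor
    # voxel centre (0,0,0) of the coarse grid sits at the mean of the fine block
    centre_shift = (factor - 1) / 2.0
    aff[:3, 3] = tf.grid.index_to_world([[centre_shift] * 3])[0]
    coarse = VoxelGrid((X, Y, Z), aff)
    return TensorField(coarse, tensor_from_logvec(mean_log))
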