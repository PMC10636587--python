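"""Deformable tetrahedral probabilistic atlas.

The anatomical prior is a tetrahedral mesh in a reference space; each vertex
carries a probability vector over the C label classes.  An affine places the
mesh over the subject grid, per-vertex displacements deform it, and
barycentric interpolation inside each tetrahedron yields a per-voxel prior
probability field.  Deformations are regularised by a per-tetrahedron
penalty on the Jacobian (volume-ratio) of the deformation that diverges as
any tetrahedron collapses, so the mesh can never fold and the atlas topology
is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import VoxelGrid

__all__ = [
    "AtlasMesh",
    "DeformationParams",
    "ClassPriorField",
    "FoldedMeshError",
    "rasterise_priors",
    "deformation_penalty",
    "optimise_deformation",
    "locate_points",
    "tet_volumes",
    "initial_affine_from_mask",
]


class FoldedMeshError(RuntimeError):
    """A deformation inverted at least one tetrahedron."""


def tet_volumes(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of each tetrahedron, shape (M,)."""
    a, b, c, d = (vertices[tets[:, k]] for k in range(4))
    return np.einsum("ij,ij->i", b - a, np.cross(c - a, d - a)) / 6.0


@dataclass
class AtlasMesh:
    """Tetrahedral mesh with per-vertex class probabilities.

    ``reference_vertices`` live in atlas space (mm); ``affine_to_subject``
    carries them into subject world space for rasterisation.  ``stiffness``
    is the deformation-regulariser scale gamma_a (a required modelling
    parameter; larger values admit less deformation).
    """

    reference_vertices: np.ndarray  # (N, 3)
    tetrahedra: np.ndarray  # (M, 4) int
    vertex_probs: np.ndarray  # (N, C)
    class_names: list[str]
    stiffness: float = 1.0
    affine_to_subject: np.ndarray = field(default=None)
    background_class: int = 0

    def __post_init__(self) -> None:
        self.reference_vertices = np.asarray(self.reference_vertices, dtype=float)
        self.tetrahedra = np.asarray(self.tetrahedra, dtype=int)
        self.vertex_probs = np.asarray(self.vertex_probs, dtype=float)
        if self.affine_to_subject is None:
            self.affine_to_subject = np.eye(4)
        self.affine_to_subject = np.asarray(self.affine_to_subject, dtype=float)
        if self.vertex_probs.ndim != 2 or len(self.vertex_probs) != len(
            self.reference_vertices
        ):
            raise ValueError("vertex_probs must be (N, C)")
        rs = self.vertex_probs.sum(axis=1)
        if np.any(self.vertex_probs < -1e-12) or np.any(np.abs(rs - 1.0) > 1e-9):
            raise ValueError("vertex probability rows must be non-negative and sum to 1")
        if self.stiffness <= 0:
            raise ValueError("stiffness must be positive")
        vols = tet_volumes(self.reference_vertices, self.tetrahedra)
        if np.any(vols <= 0):
            raise ValueError(
                f"{int((vols <= 0).sum())} tetrahedra have non-positive reference volume"
            )

    @property
    def n_classes(self) -> int:
        return self.vertex_probs.shape[1]

    @property
    def n_vertices(self) -> int:
        return len(self.reference_vertices)

    def placed_vertices(self) -> np.ndarray:
        """Reference vertices after affine placement in subject world mm."""
        A = self.affine_to_subject
        return self.reference_vertices @ A[:3, :3].T + A[:3, 3]

    def deformed_vertices(self, deform: "DeformationParams") -> np.ndarray:
        return self.placed_vertices() + deform.displacements


@dataclass
class DeformationParams:
    """Per-vertex displacements (mm) applied after affine placement."""

    displacements: np.ndarray  # (N, 3)
    warn_flag: bool = False

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)

    @classmethod
    def zeros(cls, mesh: AtlasMesh) -> "DeformationParams":
        return cls(np.zeros((mesh.n_vertices, 3)))


@dataclass
class ClassPriorField:
    """Per-voxel prior probability over classes, shape (X, Y, Z, C)."""

    grid: VoxelGrid
    priors: np.ndarray

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=float)
        if self.priors.shape[:3] != self.grid.shape:
            raise ValueError("priors shape does not match grid")
        s = self.priors.sum(axis=-1)
        if np.any(self.priors < -1e-12) or np.any(np.abs(s - 1.0) > 1e-8):
            raise ValueError("per-voxel priors must be non-negative and sum to 1")

    @property
    def flat(self) -> np.ndarray:
        return self.priors.reshape(-1, self.priors.shape[-1])


def locate_points(
    vertices: np.ndarray,
    tets: np.ndarray,
    points: np.ndarray,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Find the containing tetrahedron and barycentric weights of each point.

    Returns ``(tet_idx, bary)`` with ``tet_idx[p] == -1`` for points outside
    every tetrahedron.  Points on shared faces resolve to the lowest tet
    index (tets are scanned in order; the first containing tet wins).
    """
    P = len(points)
    tet_idx = np.full(P, -1, dtype=int)
    bary = np.zeros((P, 4), dtype=float)
    unassigned = np.ones(P, dtype=bool)

    mins = vertices[tets].min(axis=1) - tol
    maxs = vertices[tets].max(axis=1) + tol

    for t in range(len(tets)):
        if not unassigned.any():
            break
        cand = np.flatnonzero(unassigned)
        inbox = np.all(points[cand] >= mins[t], axis=1) & np.all(
            points[cand] <= maxs[t], axis=1
        )
        cand = cand[inbox]
        if cand.size == 0:
            continue
        x = vertices[tets[t]]  # (4, 3)
        A = (x[:3] - x[3]).T  # columns are edge vectors
        try:
            b123 = np.linalg.solve(A, (points[cand] - x[3]).T).T
        except np.linalg.LinAlgError:
            continue
        b4 = 1.0 - b123.sum(axis=1)
        ok = np.all(b123 >= -tol, axis=1) & (b4 >= -tol)
        hit = cand[ok]
        if hit.size:
            tet_idx[hit] = t
            bary[hit, :3] = b123[ok]
            bary[hit, 3] = b4[ok]
            unassigned[hit] = False
    return tet_idx, bary


def rasterise_priors(
    mesh: AtlasMesh, deform: DeformationParams, grid: VoxelGrid
) -> ClassPriorField:
    """Rasterise the deformed atlas onto a voxel grid.

    Each voxel centre is located in its containing tetrahedron and the prior
    is the barycentric combination of the four vertex probability rows.
    Voxels outside all tetrahedra get the designated background class with
    probability 1.

    Raises
    ------
    FoldedMeshError
        If the deformation inverts any tetrahedron (never rasterise a folded
        configuration).
    """
    verts = mesh.deformed_vertices(deform)
    vols = tet_volumes(verts, mesh.tetrahedra)
    if np.any(vols <= 0):
        raise FoldedMeshError(
            f"{int((vols <= 0).sum())} tetrahedra folded under the deformation"
        )
    points = grid.voxel_centers()
    tet_idx, bary = locate_points(verts, mesh.tetrahedra, points)

    C = mesh.n_classes
    priors = np.zeros((len(points), C), dtype=float)
    inside = tet_idx >= 0
    if inside.any():
        vp = mesh.vertex_probs[mesh.tetrahedra[tet_idx[inside]]]  # (P_in, 4, C)
        priors[inside] = np.einsum("pk,pkc->pc", bary[inside], vp)
    priors[~inside, mesh.background_class] = 1.0
    # renormalise away rounding
    priors /= priors.sum(axis=1, keepdims=True)
    return ClassPriorField(grid, priors.reshape(grid.shape + (C,)))


def _penalty_terms(
    mesh: AtlasMesh, verts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    ref = mesh.placed_vertices()
    v_ref = tet_volumes(ref, mesh.tetrahedra)
    v_def = tet_volumes(verts, mesh.tetrahedra)
    return v_ref, v_def


def deformation_penalty(mesh: AtlasMesh, deform: DeformationParams) -> float:
    """Topology-preserving deformation penalty (-log prior, up to a constant).

    Per tetrahedron the volume ratio J = V_deformed / V_reference contributes
    ``(J + 1/J - 2)`` weighted by the tetrahedron's share of reference volume
    and scaled by the mesh stiffness gamma_a.  The penalty is zero at the
    identity, symmetric in expansion/contraction of the volume ratio, and
    diverges (+inf) as any tetrahedron collapses; inverted tetrahedra return
    +inf (hard folding barrier).  Rigid motions applied jointly to reference
    and deformed configurations leave it unchanged.
    """
    verts = mesh.deformed_vertices(deform)
    v_ref, v_def = _penalty_terms(mesh, verts)
    J = v_def / v_ref
    if np.any(J <= 0):
        return float("inf")
    w = v_ref / v_ref.sum()
    return float(mesh.stiffness * np.sum(w * (J + 1.0 / J - 2.0)))


def _penalty_and_grad(
    mesh: AtlasMesh, verts: np.ndarray
) -> tuple[float, np.ndarray]:
    """Penalty value and gradient w.r.t. deformed vertex positions."""
    v_ref, v_def = _penalty_terms(mesh, verts)
    J = v_def / v_ref
    if np.any(J <= 0):
        return float("inf"), np.zeros_like(verts)
    w = v_ref / v_ref.sum()
    val = float(mesh.stiffness * np.sum(w * (J + 1.0 / J - 2.0)))

    # d penalty / d v_def = gamma * w * (1 - 1/J^2) / v_ref
    coef = mesh.stiffness * w * (1.0 - 1.0 / J**2) / v_ref
    tets = mesh.tetrahedra
    a, b, c, d = (verts[tets[:, k]] for k in range(4))
    # gradients of signed volume wrt each vertex
    gb = np.cross(c - a, d - a) / 6.0
    gc = np.cross(d - a, b - a) / 6.0
    gd = np.cross(b - a, c - a) / 6.0
    ga = -(gb + gc + gd)
    grad = np.zeros_like(verts)
    for k, g in enumerate((ga, gb, gc, gd)):
        np.add.at(grad, tets[:, k], coef[:, None] * g)
    return val, grad


PRIOR_FLOOR = 1e-300  # matches the rasterised-prior flooring in the objective


def _data_term_and_grad(
    mesh: AtlasMesh,
    verts: np.ndarray,
    points: np.ndarray,
    weights: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Sum_v sum_c w_vc log prior_vc and its gradient w.r.t. vertices.

    Uses exactly the prior convention of :func:`rasterise_priors` — voxels
    outside every tetrahedron see a floored one-hot background prior — so a
    deformation step that improves this term cannot decrease the model's
    marginal objective (the EM surrogate-bound argument requires the two
    prior definitions to coincide).

    Barycentric weights b solve  Atil b = [p; 1]  with Atil the 4x4 matrix of
    homogeneous vertex coordinates; perturbing vertex k by delta changes b by
    ``db_i = -b_k * (Atil^-1)[i, :3] . delta``, which gives the analytic
    gradient of the prior term.
    """
    tet_idx, bary = locate_points(verts, mesh.tetrahedra, points)
    inside = tet_idx >= 0
    grad = np.zeros_like(verts)

    # outside voxels: background one-hot prior; any foreground posterior
    # weight there pays the floored log, acting as a barrier against the
    # mesh retreating from supported voxels
    val = 0.0
    if (~inside).any():
        w_out = weights[~inside]
        fg = np.delete(w_out, mesh.background_class, axis=1).sum()
        val += float(fg * np.log(PRIOR_FLOOR))
    if not inside.any():
        return val, grad

    ti = tet_idx[inside]
    b = bary[inside]  # (P, 4)
    tv = mesh.tetrahedra[ti]  # (P, 4)
    vp = mesh.vertex_probs[tv]  # (P, 4, C)
    w = weights[inside]  # (P, C)
    prior = np.einsum("pk,pkc->pc", b, vp)
    val += float(np.sum(w * np.log(np.maximum(prior, PRIOR_FLOOR))))

    # dF/db_i = sum_c w_c * vp[i, c] / prior_c  (gradient clip keeps the
    # near-barrier gradient finite; the monotone line search on values
    # guarantees correctness regardless)
    dFdb = np.einsum("pc,pic->pi", w / np.maximum(prior, 1e-12), vp)  # (P, 4)

    # Atil^-1 per point's tet: build (P, 4, 4)
    X = verts[tv]  # (P, 4, 3)
    Atil = np.concatenate([X.transpose(0, 2, 1), np.ones((len(X), 1, 4))], axis=1)
    Ainv = np.linalg.inv(Atil)  # (P, 4, 4)
    # grad contribution to vertex k of the tet:
    #   -b_k * sum_i dFdb_i * Ainv[i, :3]
    u = np.einsum("pi,pix->px", dFdb, Ainv[:, :, :3])  # (P, 3)
    contrib = -b[:, :, None] * u[:, None, :]  # (P, 4, 3)
    np.add.at(grad, tv.reshape(-1), contrib.reshape(-1, 3))
    return val, grad


def deformation_objective(
    mesh: AtlasMesh,
    deform: DeformationParams,
    weights_flat: np.ndarray,
    grid: VoxelGrid,
) -> float:
    """Prior-term + penalty objective used by :func:`optimise_deformation`."""
    verts = mesh.deformed_vertices(deform)
    if not np.all(tet_volumes(verts, mesh.tetrahedra) > 0):
        return -float("inf")
    points = grid.voxel_centers()
    val, _ = _data_term_and_grad(mesh, verts, points, weights_flat)
    pen, _ = _penalty_and_grad(mesh, verts)
    return val - pen


def optimise_deformation(
    mesh: AtlasMesh,
    deform: DeformationParams,
    class_posteriors: np.ndarray,
    grid: VoxelGrid,
    max_iter: int = 20,
    rel_tol: float = 1e-5,
) -> DeformationParams:
    """Increase sum_v sum_c w_vc log prior_vc - penalty over displacements.

    Nonlinear conjugate gradient (Polak-Ribiere) with a backtracking line
    search that rejects folded configurations, so every accepted step is
    monotone and the mesh stays unfolded.  If no admissible improving step
    exists the input is returned with ``warn_flag`` set.

    ``class_posteriors`` is the per-voxel class weight array, shape
    (X, Y, Z, C) or (n_voxels, C), rows summing to 1 over classes.
    """
    C = mesh.n_classes
    weights = np.asarray(class_posteriors, dtype=float).reshape(-1, C)
    points = grid.voxel_centers()
    x = deform.displacements.copy()

    def value_grad(disp: np.ndarray) -> tuple[float, np.ndarray]:
        verts = mesh.placed_vertices() + disp
        if not np.all(tet_volumes(verts, mesh.tetrahedra) > 0):
            return -float("inf"), np.zeros_like(disp)
        dval, dgrad = _data_term_and_grad(mesh, verts, points, weights)
        pval, pgrad = _penalty_and_grad(mesh, verts)
        return dval - pval, dgrad - pgrad

    f0, g = value_grad(x)
    if not np.isfinite(f0):
        raise FoldedMeshError("initial deformation is folded")
    f_init = f0
    d = g.copy()
    g_prev = g
    improved = False
    for _ in range(max_iter):
        gnorm = np.linalg.norm(g)
        if gnorm < 1e-12:
            break
        # backtracking line search along ascent direction d
        slope = float(np.sum(g * d))
        if slope <= 0:
            d = g.copy()
            slope = float(np.sum(g * g))
            if slope <= 0:
                break
        step = 1.0 / max(1.0, np.linalg.norm(d) / (0.5 * min(grid.voxel_size_mm)))
        accepted = False
        for _bt in range(25):
            xn = x + step * d
            fn, gn = value_grad(xn)
            if np.isfinite(fn) and fn > f0 + 1e-4 * step * slope:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        improved = True
        rel = abs(fn - f0) / max(abs(f0), 1.0)
        x, f0 = xn, fn
        g_new = gn
        beta = max(
            0.0,
            float(np.sum(g_new * (g_new - g_prev)) / max(np.sum(g_prev * g_prev), 1e-300)),
        )
        d = g_new + beta * d
        g_prev = g_new
        g = g_new
        if rel < rel_tol:
            break

    out = DeformationParams(x, warn_flag=not improved and f0 <= f_init)
    return out


def initial_affine_from_mask(
    mesh: AtlasMesh, mask: np.ndarray, grid: VoxelGrid
) -> np.ndarray:
    """Affine placement matching atlas foreground mass to a coarse mask.

    Translation and per-axis scaling are estimated from first and second
    moments of (a) the coarse whole-structure segmentation mask on the
    subject grid and (b) the atlas's non-background prior mass at the
    reference vertices.  This is the standard moment-matching initialisation
    when no registration is supplied.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("coarse mask is empty")
    pts = grid.index_to_world(np.argwhere(mask))
    mu_t = pts.mean(axis=0)
    sd_t = pts.std(axis=0)

    fg = 1.0 - mesh.vertex_probs[:, mesh.background_class]
    if fg.sum() <= 0:
        raise ValueError("atlas has no foreground probability mass")
    ref = mesh.reference_vertices
    mu_a = (ref * fg[:, None]).sum(axis=0) / fg.sum()
    var_a = ((ref - mu_a) ** 2 * fg[:, None]).sum(axis=0) / fg.sum()
    sd_a = np.sqrt(np.maximum(var_a, 1e-12))

    scale = np.where(sd_a > 1e-9, sd_t / sd_a, 1.0)
    A = np.eye(4)
    A[:3, :3] = np.diag(scale)
    A[:3, 3] = mu_t - scale * mu_a
    return A
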