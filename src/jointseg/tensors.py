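"""Diffusion-tensor fields: validation, log-Euclidean vectors, resampling.

Diffusion tensor imaging (DTI) summarises water diffusion in each voxel by a
3x3 symmetric positive-definite (SPD) tensor ``T_v`` (units mm^2/s).  Working
directly with tensors is awkward for interpolation and Gaussian modelling, so
we map each tensor to a 6-vector of its matrix logarithm,

    d = (t11, t22, t33, sqrt(2) t12, sqrt(2) t13, sqrt(2) t23),  t = log T,

the unique (up to permutation/sign) linear encoding for which the Euclidean
distance between vectors equals the Frobenius distance between matrix logs::

    ||log T1 - log T2||_F = ||d1 - d2||_2

Interpolating the 6-vectors is therefore interpolation of the tensors in the
log domain, which avoids the swelling artefacts of direct tensor averaging.

The module also provides tensor-field cleaning (replacing voxels whose fitted
tensor has non-positive eigenvalues by a Gaussian-weighted log-domain local
average), fractional anisotropy (FA) and principal-direction extraction, and
trilinear resampling of log-tensor fields onto a target grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .grids import VoxelGrid

__all__ = [
    "TensorField",
    "LogTensorField",
    "DTISummaryField",
    "NonSPDTensorError",
    "log_tensor_vectorize",
    "tensor_from_logvec",
    "logvec_to_matrix",
    "matrix_to_logvec",
    "clean_tensor_field",
    "resample_log_tensors",
    "fa_and_principal_direction",
    "fa_from_eigenvalues",
    "log_field_from_tensors",
    "tensor_field_from_log",
    "summarise_field",
]

_SQRT2 = np.sqrt(2.0)

# (row, col) order of the off-diagonal entries in the 6-vector convention
_OFFDIAG = [(0, 1), (0, 2), (1, 2)]


class NonSPDTensorError(ValueError):
    """Raised when an operation requiring an SPD tensor receives one with a
    non-positive eigenvalue."""


def _symmetrize(T: np.ndarray) -> np.ndarray:
    # absorb storage asymmetry before validation
    return 0.5 * (T + np.swapaxes(T, -1, -2))


def _logm_spd(T: np.ndarray, what: str = "tensor") -> np.ndarray:
    """Matrix logarithm of (a batch of) SPD matrices via eigendecomposition."""
    T = _symmetrize(np.asarray(T, dtype=float))
    lam, Q = np.linalg.eigh(T)
    if np.any(lam <= 0) or not np.all(np.isfinite(lam)):
        bad = float(np.min(lam))
        raise NonSPDTensorError(
            f"{what} is not SPD: smallest eigenvalue {bad:.6g} <= 0"
        )
    return (Q * np.log(lam)[..., None, :]) @ np.swapaxes(Q, -1, -2)


def _expm_sym(M: np.ndarray) -> np.ndarray:
    """Matrix exponential of (a batch of) symmetric matrices."""
    lam, Q = np.linalg.eigh(_symmetrize(np.asarray(M, dtype=float)))
    return (Q * np.exp(lam)[..., None, :]) @ np.swapaxes(Q, -1, -2)


def matrix_to_logvec(M: np.ndarray) -> np.ndarray:
    """Encode (a batch of) symmetric matrices as isometric 6-vectors."""
    M = np.asarray(M, dtype=float)
    out = np.empty(M.shape[:-2] + (6,), dtype=float)
    out[..., 0] = M[..., 0, 0]
    out[..., 1] = M[..., 1, 1]
    out[..., 2] = M[..., 2, 2]
    for k, (i, j) in enumerate(_OFFDIAG):
        out[..., 3 + k] = _SQRT2 * M[..., i, j]
    return out


def logvec_to_matrix(d: np.ndarray) -> np.ndarray:
    """Inverse of :func:`matrix_to_logvec`."""
    d = np.asarray(d, dtype=float)
    M = np.zeros(d.shape[:-1] + (3, 3), dtype=float)
    M[..., 0, 0] = d[..., 0]
    M[..., 1, 1] = d[..., 1]
    M[..., 2, 2] = d[..., 2]
    for k, (i, j) in enumerate(_OFFDIAG):
        M[..., i, j] = M[..., j, i] = d[..., 3 + k] / _SQRT2
    return M


def log_tensor_vectorize(T: np.ndarray) -> np.ndarray:
    """Map an SPD tensor (or batch) to its log-Euclidean 6-vector.

    The encoding is an isometry between the Frobenius metric on matrix
    logarithms and the Euclidean metric on 6-vectors.

    Raises
    ------
    NonSPDTensorError
        If any input has a non-positive eigenvalue.
    """
    return matrix_to_logvec(_logm_spd(T))


def tensor_from_logvec(d: np.ndarray) -> np.ndarray:
    """Reconstruct the SPD tensor from its log-Euclidean 6-vector."""
    return _expm_sym(logvec_to_matrix(d))


def fa_from_eigenvalues(lam: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from (batched) eigenvalue triples.

    FA = sqrt(3/2) * ||lam - mean(lam)|| / ||lam||, in [0, 1] for positive
    eigenvalues.
    """
    lam = np.asarray(lam, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(lam - mean, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.clip(np.nan_to_num(fa), 0.0, 1.0)


class FAPrincipal(NamedTuple):
    fa: float
    pdir: np.ndarray
    degenerate: bool


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Make the first component of magnitude > 1e-12 positive (axes are
    antipodally symmetric, so the sign is a pure convention)."""
    v = np.asarray(v, dtype=float)
    flat = v.reshape(-1, v.shape[-1])
    for row in flat:
        for x in row:
            if abs(x) > 1e-12:
                if x < 0:
                    row *= -1.0
                break
    return flat.reshape(v.shape)


def fa_and_principal_direction(
    T: np.ndarray, degeneracy_rtol: float = 1e-6
) -> FAPrincipal:
    """FA and unit principal eigenvector of a single SPD tensor.

    If the two largest eigenvalues coincide within ``degeneracy_rtol``
    (relative), the principal axis is ill-defined; a valid unit vector in the
    eigenspace is returned with ``degenerate=True``.
    """
    T = _symmetrize(np.asarray(T, dtype=float))
    lam, Q = np.linalg.eigh(T)
    if np.any(lam <= 0):
        raise NonSPDTensorError(
            f"tensor is not SPD: smallest eigenvalue {lam.min():.6g} <= 0"
        )
    fa = float(fa_from_eigenvalues(lam))
    gap = (lam[2] - lam[1]) / max(lam[2], 1e-300)
    pdir = _fix_sign(Q[:, 2].copy())
    pdir /= np.linalg.norm(pdir)
    return FAPrincipal(fa=fa, pdir=pdir, degenerate=bool(gap < degeneracy_rtol))


@dataclass
class TensorField:
    """Per-voxel 3x3 symmetric diffusion tensors on a voxel grid.

    ``valid_mask`` marks voxels whose tensor satisfies the SPD invariant;
    invalid voxels hold whatever the fitting produced and must be cleaned
    (see :func:`clean_tensor_field`) before log-domain processing.
    """

    grid: VoxelGrid
    tensors: np.ndarray  # (X, Y, Z, 3, 3)
    valid_mask: np.ndarray = field(default=None)  # (X, Y, Z) bool

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.shape != self.grid.shape + (3, 3):
            raise ValueError(
                f"tensors shape {self.tensors.shape} does not match grid "
                f"{self.grid.shape} + (3, 3)"
            )
        if self.valid_mask is None:
            self.valid_mask = validate_tensors(self.tensors)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.grid.shape:
                raise ValueError("valid_mask shape does not match grid")

    @property
    def all_valid(self) -> bool:
        return bool(self.valid_mask.all())


@dataclass
class LogTensorField:
    """Per-voxel log-Euclidean 6-vectors on a voxel grid."""

    grid: VoxelGrid
    logvecs: np.ndarray  # (X, Y, Z, 6)
    valid_mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.logvecs = np.asarray(self.logvecs, dtype=float)
        if self.logvecs.shape != self.grid.shape + (6,):
            raise ValueError("logvecs shape does not match grid + (6,)")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.grid.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)


@dataclass
class DTISummaryField:
    """Per-voxel FA and principal direction (the DSW-beta data model)."""

    grid: VoxelGrid
    fa: np.ndarray  # (X, Y, Z)
    pdir: np.ndarray  # (X, Y, Z, 3), unit vectors
    valid_mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.fa = np.asarray(self.fa, dtype=float)
        self.pdir = np.asarray(self.pdir, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.grid.shape, dtype=bool)


def validate_tensors(tensors: np.ndarray) -> np.ndarray:
    """Boolean mask of voxels whose tensor is finite and SPD with FA in [0,1]."""
    tensors = _symmetrize(np.asarray(tensors, dtype=float))
    finite = np.isfinite(tensors).all(axis=(-1, -2))
    lam = np.full(tensors.shape[:-2] + (3,), -1.0)
    if finite.any():
        lam_f = np.linalg.eigvalsh(tensors[finite])
        lam[finite] = lam_f
    pos = lam.min(axis=-1) > 0
    fa = fa_from_eigenvalues(np.where(lam > 0, lam, 1.0))
    return finite & pos & (fa <= 1.0) & (fa >= 0.0)


def log_field_from_tensors(tf: TensorField) -> LogTensorField:
    """Convert a fully valid tensor field to log-vector form."""
    if not tf.all_valid:
        raise NonSPDTensorError(
            "tensor field contains invalid voxels; run clean_tensor_field first"
        )
    logvecs = matrix_to_logvec(_logm_spd(tf.tensors))
    return LogTensorField(tf.grid, logvecs, tf.valid_mask.copy())


def tensor_field_from_log(lf: LogTensorField) -> TensorField:
    tensors = tensor_from_logvec(lf.logvecs)
    return TensorField(lf.grid, tensors, lf.valid_mask.copy())


def clean_tensor_field(raw: TensorField, kernel_sigma_mm: float = 2.0) -> TensorField:
    """Replace invalid tensors by a local log-domain Gaussian average.

    Voxels failing the SPD/FA validity check are replaced by the exponential
    of the Gaussian-kernel-weighted mean of the matrix logs of neighbouring
    *valid* tensors.  The kernel has standard deviation ``kernel_sigma_mm``
    (in world mm, per axis via the voxel size) and is truncated at 3 sigma.
    Valid voxels pass through bit-for-bit.

    Raises
    ------
    ValueError
        If an invalid voxel has no valid neighbour within the truncated
        kernel support (zero total weight).
    """
    valid = validate_tensors(raw.tensors)
    if valid.all():
        return TensorField(raw.grid, raw.tensors.copy(), valid)
    if not valid.any():
        raise ValueError("tensor field has no valid voxels to average from")

    out = raw.tensors.copy()
    vox = raw.grid.voxel_size_mm
    # per-axis truncation radius in voxels
    rad = np.maximum(1, np.ceil(3.0 * kernel_sigma_mm / vox).astype(int))
    log_valid = np.zeros(raw.grid.shape + (6,), dtype=float)
    log_valid[valid] = matrix_to_logvec(_logm_spd(raw.tensors[valid]))

    shape = np.array(raw.grid.shape)
    bad_idx = np.argwhere(~valid)
    for ijk in bad_idx:
        lo = np.maximum(ijk - rad, 0)
        hi = np.minimum(ijk + rad + 1, shape)
        sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        nb_valid = valid[sl]
        if not nb_valid.any():
            raise ValueError(
                f"invalid tensor at voxel {tuple(int(x) for x in ijk)} has no "
                f"valid neighbour within the 3-sigma kernel support"
            )
        offsets = (
            np.indices(nb_valid.shape).reshape(3, -1).T + lo - ijk
        ) * vox  # mm offsets
        w = np.exp(-0.5 * np.sum((offsets / kernel_sigma_mm) ** 2, axis=1))
        w = w.reshape(nb_valid.shape) * nb_valid
        wsum = w.sum()
        if wsum <= 0:
            raise ValueError(
                f"zero kernel weight for invalid voxel {tuple(int(x) for x in ijk)}"
            )
        mean_log = np.tensordot(w, log_valid[sl], axes=([0, 1, 2], [0, 1, 2])) / wsum
        out[tuple(ijk)] = tensor_from_logvec(mean_log)

    cleaned = TensorField(raw.grid, out)
    # keep original valid voxels bit-identical
    cleaned.tensors[valid] = raw.tensors[valid]
    cleaned.valid_mask = validate_tensors(cleaned.tensors)
    return cleaned


def resample_log_tensors(src: LogTensorField, target: VoxelGrid) -> LogTensorField:
    """Trilinearly resample a log-tensor field onto a target grid.

    Interpolation is componentwise on the 6-vectors (log-Euclidean
    interpolation of the tensors).  Target voxels needing extrapolation, or
    drawing on any invalid source voxel, are marked invalid rather than
    clamped.
    """
    if min(target.shape) < 1:
        raise ValueError("degenerate target grid")
    if target.same_world_space(src.grid):
        return LogTensorField(target, src.logvecs.copy(), src.valid_mask.copy())

    world = target.voxel_centers()
    coords = src.grid.world_to_index(world).T  # (3, P)

    inb = np.ones(coords.shape[1], dtype=bool)
    for ax in range(3):
        inb &= (coords[ax] >= -1e-9) & (coords[ax] <= src.grid.shape[ax] - 1 + 1e-9)

    out = np.empty(target.shape + (6,), dtype=float)
    for c in range(6):
        out[..., c] = ndimage.map_coordinates(
            src.logvecs[..., c], coords, order=1, mode="nearest"
        ).reshape(target.shape)

    vmask = ndimage.map_coordinates(
        src.valid_mask.astype(float), coords, order=1, mode="constant", cval=0.0
    )
    valid = (vmask > 1.0 - 1e-9) & inb
    return LogTensorField(target, out, valid.reshape(target.shape))


def summarise_field(tf: TensorField, degeneracy_rtol: float = 1e-6) -> DTISummaryField:
    """FA and principal direction for every voxel of a valid tensor field."""
    T = _symmetrize(tf.tensors)
    lam, Q = np.linalg.eigh(T)
    fa = fa_from_eigenvalues(np.where(lam > 0, lam, 1.0))
    pdir = Q[..., :, 2].copy()
    # sign convention, vectorised: flip where the first sufficiently nonzero
    # component is negative
    absd = np.abs(pdir)
    lead = np.argmax(absd > 1e-12, axis=-1)
    leadval = np.take_along_axis(pdir, lead[..., None], axis=-1)[..., 0]
    pdir = np.where((leadval < 0)[..., None], -pdir, pdir)
    norms = np.linalg.norm(pdir, axis=-1, keepdims=True)
    pdir = pdir / np.where(norms > 0, norms, 1.0)
    valid = tf.valid_mask & (lam.min(axis=-1) > 0)
    return DTISummaryField(tf.grid, fa, pdir, valid)
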