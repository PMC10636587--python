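"""Segmentation evaluation statistics.

Overlap (Dice similarity coefficient), boundary distance (95th-percentile
symmetric Hausdorff distance in mm), test-retest volume agreement (ICC(2,1),
two-way random effects, absolute agreement, single measure) and TOPSIS
multi-criteria ranking of candidate models across Dice/distance channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grids import VoxelGrid

__all__ = ["ROIMask", "DecisionMatrix", "dice", "hd95", "icc", "topsis"]


@dataclass
class ROIMask:
    """A region of interest as a boolean voxel mask on a grid."""

    grid: VoxelGrid
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")

    @classmethod
    def from_indices(cls, grid: VoxelGrid, indices: np.ndarray) -> "ROIMask":
        idx = np.asarray(indices, dtype=int)
        if idx.size and (idx.min() < 0 or np.any(idx.max(axis=0) >= grid.shape)):
            raise ValueError("indices out of grid bounds")
        mask = np.zeros(grid.shape, dtype=bool)
        if idx.size:
            mask[tuple(idx.T)] = True
        return cls(grid, mask)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def dice(X: ROIMask, Y: ROIMask) -> float:
    """Dice similarity coefficient 2|X n Y| / (|X| + |Y|).

    1 for identical non-empty masks, 0 for disjoint masks.  Two empty masks
    are defined as perfectly overlapping (returns 1 with a warning).
    """
    if X.grid.shape != Y.grid.shape:
        raise ValueError("masks must share a grid")
    nx, ny = X.n_voxels, Y.n_voxels
    if nx == 0 and ny == 0:
        warnings.warn("Dice of two empty masks defined as 1", stacklevel=2)
        return 1.0
    inter = int(np.count_nonzero(X.mask & Y.mask))
    return 2.0 * inter / (nx + ny)


def _boundary_points(roi: ROIMask) -> np.ndarray:
    """World-mm centres of 6-connectivity boundary voxels of the mask."""
    m = roi.mask
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    eroded = ndimage.binary_erosion(m, structure=struct, border_value=0)
    boundary = m & ~eroded
    idx = np.argwhere(boundary)
    return roi.grid.index_to_world(idx)


def hd95(X: ROIMask, Y: ROIMask) -> float:
    """95th-percentile symmetric Hausdorff distance between ROI boundaries.

    Boundary voxels are extracted with 6-connectivity; each boundary point's
    nearest distance (world mm) to the other boundary is computed, the 95th
    percentile (linear interpolation between order statistics) is taken in
    each direction, and the maximum of the two is returned.
    """
    if X.n_voxels == 0 or Y.n_voxels == 0:
        raise ValueError("hd95 requires two non-empty masks")
    px = _boundary_points(X)
    py = _boundary_points(Y)
    dx = cKDTree(py).query(px)[0]
    dy = cKDTree(px).query(py)[0]
    return float(max(np.percentile(dx, 95), np.percentile(dy, 95)))


def icc(volumes_a: np.ndarray, volumes_b: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    The two inputs are treated as two random "raters" measuring the same
    subjects (e.g. volumes from two acquisitions).  Computed from the
    standard mean-squares decomposition:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with n subjects and k = 2 measurements.

    Raises
    ------
    ValueError
        On unequal lengths, fewer than 3 subjects, or zero between-subject
        variance (agreement undefined).
    """
    a = np.asarray(volumes_a, dtype=float)
    b = np.asarray(volumes_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    n = len(a)
    if n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    data = np.column_stack([a, b])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / 1  # k - 1 = 1
    mse = ss_err / ((n - 1) * (k - 1))
    if msr <= 1e-300:
        raise ValueError("zero between-subject variance: ICC undefined")
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


@dataclass
class DecisionMatrix:
    """Candidates x channels matrix with per-channel optimisation direction.

    ``directions[j]`` is ``'benefit'`` (higher is better, e.g. Dice) or
    ``'cost'`` (lower is better, e.g. a boundary distance).
    """

    values: np.ndarray  # (n_candidates, n_channels)
    directions: list[str]
    channel_names: list[str] = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if len(self.directions) != self.values.shape[1]:
            raise ValueError("one direction per channel required")
        for d in self.directions:
            if d not in ("benefit", "cost"):
                raise ValueError(f"direction must be 'benefit' or 'cost', got {d!r}")
        if self.channel_names is None:
            self.channel_names = [f"ch{j}" for j in range(self.values.shape[1])]


def topsis(m: DecisionMatrix) -> np.ndarray:
    """TOPSIS similarity-to-ideal scores in [0, 1] per candidate.

    Each channel is vector-normalised; the positive (negative) ideal takes
    the per-channel best (worst) value respecting its direction; candidates
    are scored by D- / (D+ + D-), the relative L2 closeness to the positive
    ideal.  A candidate that is best in every channel scores 1; worst in
    every channel scores 0.  Zero-range channels are dropped with a warning.
    """
    X = m.values
    if X.shape[0] < 2:
        raise ValueError("TOPSIS needs at least 2 candidates")
    keep = []
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) <= 0:
            warnings.warn(
                f"dropping constant channel {m.channel_names[j]!r}", stacklevel=2
            )
        else:
            keep.append(j)
    if not keep:
        raise ValueError("all channels are constant")
    X = X[:, keep]
    dirs = [m.directions[j] for j in keep]

    norms = np.linalg.norm(X, axis=0)
    norms = np.where(norms > 0, norms, 1.0)
    R = X / norms
    best = np.array(
        [R[:, j].max() if dirs[j] == "benefit" else R[:, j].min() for j in range(R.shape[1])]
    )
    worst = np.array(
        [R[:, j].min() if dirs[j] == "benefit" else R[:, j].max() for j in range(R.shape[1])]
    )
    d_plus = np.linalg.norm(R - best, axis=1)
    d_minus = np.linalg.norm(R - worst, axis=1)
    with np.errstate(invalid="ignore"):
        score = d_minus / (d_plus + d_minus)
    return np.nan_to_num(score, nan=0.5)
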