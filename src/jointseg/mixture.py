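"""Mixture-model specification and initialisation.

Each atlas class c is modelled in each modality by a mixture over a shared
pool of component distributions: G structural Gaussians with class weights
``g[c, i]`` and W diffusion components with weights ``w[c, j]``.  Support
masks declare which (class, component) assignments are allowed — most
weights are pinned to 0 or 1 in practice, but many-to-many sharing is
supported (e.g. one component for "clean" and one for "messy" CSF).  Every
class must draw on at least one component in *each* modality so all tissue
boundaries are informed by both contrasts.

A ``merge_map`` folds model classes into output labels (classes split for
modelling purposes are merged again for output, and nuisance classes map to
background).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .likelihoods import (
    NIWHyper,
    fit_dswbeta,
    fit_gaussian_map,
    fit_loggauss,
    fit_wishart_map,
)

__all__ = ["MixtureSpec", "validate_spec", "kmeans_init", "merge_outputs"]


@dataclass
class MixtureSpec:
    """Class-to-component assignment scheme for both modalities.

    ``structural_support[c]`` / ``diffusion_support[c]`` list the component
    indices allowed for class c.  ``g`` and ``w`` are dense (C, G) / (C, W)
    weight matrices, zero off support, rows summing to one.
    """

    class_names: list[str]
    structural_support: list[list[int]]
    diffusion_support: list[list[int]]
    n_structural: int
    n_diffusion: int
    g: np.ndarray = None
    w: np.ndarray = None
    merge_map: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        C = len(self.class_names)
        if self.g is None:
            self.g = self._equal_weights(self.structural_support, self.n_structural)
        if self.w is None:
            self.w = self._equal_weights(self.diffusion_support, self.n_diffusion)
        self.g = np.asarray(self.g, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if not self.merge_map:
            self.merge_map = {c: c for c in range(C)}

    def _equal_weights(self, support: list[list[int]], K: int) -> np.ndarray:
        # non-zero weights equal for the first E step
        C = len(self.class_names)
        m = np.zeros((C, K))
        for c, comps in enumerate(support):
            for i in comps:
                m[c, i] = 1.0 / max(len(comps), 1)
        return m

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def triples(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Arrays (c, i, j) of all supported class/component combinations."""
        cc, ii, jj = [], [], []
        for c in range(self.n_classes):
            for i in self.structural_support[c]:
                for j in self.diffusion_support[c]:
                    cc.append(c)
                    ii.append(i)
                    jj.append(j)
        return np.array(cc), np.array(ii), np.array(jj)

    @property
    def n_output_labels(self) -> int:
        return max(self.merge_map.values()) + 1


def validate_spec(spec: MixtureSpec) -> dict:
    """Check every invariant; returns diagnostics, raises on violation."""
    C = spec.n_classes
    diagnostics: dict = {"n_classes": C, "n_structural": spec.n_structural,
                         "n_diffusion": spec.n_diffusion}
    for c in range(C):
        if not spec.structural_support[c] or not spec.diffusion_support[c]:
            raise ValueError(
                f"class {spec.class_names[c]!r} has empty component support"
            )
    for name, mat, support, K in (
        ("g", spec.g, spec.structural_support, spec.n_structural),
        ("w", spec.w, spec.diffusion_support, spec.n_diffusion),
    ):
        if mat.shape != (C, K):
            raise ValueError(f"{name} must be ({C}, {K}), got {mat.shape}")
        if np.any(mat < 0):
            raise ValueError(f"{name} has negative weights")
        for c in range(C):
            off = [k for k in range(K) if k not in support[c]]
            if off and np.any(mat[c, off] != 0):
                raise ValueError(f"{name}[{c}] has weight outside its support")
            s = mat[c].sum()
            if abs(s - 1.0) > 1e-9:
                raise ValueError(
                    f"{name} row {c} sums to {s:.6g}, must sum to 1"
                )
    missing = [c for c in range(C) if c not in spec.merge_map]
    if missing:
        raise ValueError(f"merge_map is missing classes {missing}")
    used = {k for sup in spec.structural_support for k in sup}
    diagnostics["unused_structural"] = sorted(set(range(spec.n_structural)) - used)
    usedd = {k for sup in spec.diffusion_support for k in sup}
    diagnostics["unused_diffusion"] = sorted(set(range(spec.n_diffusion)) - usedd)
    return diagnostics


def _family_features(family: str, data: dict) -> np.ndarray:
    """Feature matrix for k-means, per likelihood family."""
    if family == "gaussian":
        return np.atleast_2d(data["intensities"])
    if family in ("log-gaussian", "wishart"):
        return np.atleast_2d(data["logvecs"])
    if family == "dsw-beta":
        phi = np.atleast_2d(data["pdir"]).copy()
        # sign-fix so antipodal directions cluster together, then append FA
        lead = np.argmax(np.abs(phi) > 1e-12, axis=1)
        sign = np.take_along_axis(phi, lead[:, None], axis=1)[:, 0]
        phi[sign < 0] *= -1.0
        return np.hstack([phi, np.atleast_1d(data["fa"])[:, None]])
    raise ValueError(f"unknown family {family!r}")


def _fit_family(family: str, data: dict, idx: np.ndarray, weights: np.ndarray):
    w = weights[idx]
    if family == "gaussian":
        return fit_gaussian_map(np.atleast_2d(data["intensities"])[idx], w)
    if family == "log-gaussian":
        return fit_loggauss(np.atleast_2d(data["logvecs"])[idx], w)
    if family == "wishart":
        return fit_wishart_map(data["tensors"][idx], w)
    if family == "dsw-beta":
        return fit_dswbeta(
            np.atleast_1d(data["fa"])[idx], np.atleast_2d(data["pdir"])[idx], w
        )
    raise ValueError(f"unknown family {family!r}")


def kmeans_init(
    data: dict,
    priors_flat: np.ndarray,
    spec: MixtureSpec,
    family: str,
    modality: str,
    seed: int,
    prior_threshold: float = 0.5,
) -> dict[int, object]:
    """Initial component parameters by seeded k-means clustering.

    For each class, voxels where the class prior exceeds ``prior_threshold``
    are clustered into as many groups as the class has components (in the
    given ``modality``); each cluster's members are fitted with the family's
    weighted fitter to produce initial parameters.  Components shared across
    classes are initialised by the first class that reaches them (class
    order is deterministic), and clusters are ordered by their mean feature
    norm so the output is reproducible for a fixed seed.

    Raises
    ------
    ValueError
        If a class asks for more clusters than it has distinct data points.
    """
    support = (
        spec.structural_support if modality == "structural" else spec.diffusion_support
    )
    feats = _family_features(family, data)
    weights = np.ones(len(feats))
    out: dict[int, object] = {}
    for c in range(spec.n_classes):
        comps = [k for k in support[c] if k not in out]
        if not comps:
            continue
        K = len(support[c])
        sel = np.flatnonzero(priors_flat[:, c] > prior_threshold)
        if sel.size == 0:
            # fall back to the K most probable voxels for this class
            sel = np.argsort(priors_flat[:, c])[-max(K * 20, 50):]
        distinct = np.unique(feats[sel], axis=0)
        if len(distinct) < K:
            raise ValueError(
                f"class {spec.class_names[c]!r} requests {K} components but has "
                f"only {len(distinct)} distinct data points"
            )
        if K == 1:
            labels = np.zeros(sel.size, dtype=int)
        else:
            km = KMeans(n_clusters=K, random_state=seed, n_init=4)
            labels = km.fit_predict(feats[sel])
        order = np.argsort(
            [np.linalg.norm(feats[sel][labels == k].mean(axis=0)) for k in range(K)]
        )
        for slot, k in zip(support[c], order):
            if slot in out:
                continue
            idx = sel[labels == k]
            if idx.size == 0:
                idx = sel
            out[slot] = _fit_family(family, data, idx, weights)
    return out


def merge_outputs(posteriors: np.ndarray, merge_map: dict[int, int]) -> np.ndarray:
    """Sum per-class posteriors into per-output-label posteriors.

    Conserves per-voxel total mass exactly (pure re-binning).
    """
    post = np.asarray(posteriors, dtype=float)
    C = post.shape[-1]
    missing = [c for c in range(C) if c not in merge_map]
    if missing:
        raise ValueError(f"merge_map does not cover classes {missing}")
    L = max(merge_map.values()) + 1
    out = np.zeros(post.shape[:-1] + (L,), dtype=float)
    for c in range(C):
        out[..., merge_map[c]] += post[..., c]
    return out
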