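"""Reference phantom configurations.

These fix the synthetic study conditions used by the test-suite, the
acceptance script and the ``phantom`` CLI subcommand: realistic tissue-scale
intensities (arbitrary units around typical T1 grey/white values), diffusion
at parenchymal mean diffusivity, Watson concentrations in the range of
coherent white matter, and mixture specs with one component per class
(plus a shared-structural variant for the diffusion-contrast experiment).
"""

from __future__ import annotations

import numpy as np

from .likelihoods import (
    DSWBetaParams,
    GaussianParams,
    LogGaussianParams,
    WishartParams,
)
from .mixture import MixtureSpec
from .synthetic import MEAN_DIFFUSIVITY, PhantomSpec, tensor_from_fa_direction

__all__ = ["default_phantom_spec", "diffusion_contrast_phantom_spec"]

_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])


def _class_tensor(fa: float, direction: np.ndarray) -> np.ndarray:
    return tensor_from_fa_direction([fa], direction[None])[0]


def _diffusion_params(family: str, fa: float, direction: np.ndarray,
                      kappa: float, beta_ab: tuple[float, float]):
    if family == "dsw-beta":
        a, b = beta_ab
        return DSWBetaParams(beta_a=a, beta_b=b, mean_dir=direction,
                             concentration=kappa)
    T = _class_tensor(fa, direction)
    if family == "wishart":
        n = 25.0
        return WishartParams(dof=n, scale=np.linalg.inv(T) / n)
    if family == "log-gaussian":
        from .tensors import log_tensor_vectorize

        return LogGaussianParams(mean=log_tensor_vectorize(T), var=0.02)
    raise ValueError(f"unknown family {family!r}")


def default_phantom_spec(
    family: str = "dsw-beta", size: int = 20, seed: int = 0
) -> tuple[PhantomSpec, MixtureSpec]:
    """Four-class phantom with contrast in both modalities.

    Background plus three blob classes; structural means are separated by
    about three standard deviations and diffusion components differ in
    orientation and anisotropy, so the full pipeline should recover the
    sampled labels nearly perfectly.
    """
    names = ["background", "medial", "lateral", "tract"]
    structural = [
        GaussianParams([25.0], [[49.0]]),
        GaussianParams([90.0], [[36.0]]),
        GaussianParams([112.0], [[36.0]]),
        GaussianParams([140.0], [[36.0]]),
    ]
    diffusion = [
        _diffusion_params(family, 0.15, _X, 4.0, (2.0, 9.0)),
        _diffusion_params(family, 0.40, _Z, 25.0, (4.0, 6.0)),
        _diffusion_params(family, 0.50, _Y, 25.0, (5.0, 5.0)),
        _diffusion_params(family, 0.80, _X, 50.0, (8.0, 2.5)),
    ]
    pspec = PhantomSpec(
        shape=(size, size, size),
        voxel_mm=1.0,
        class_names=names,
        structural_params=structural,
        diffusion_params=diffusion,
        family=family,
        blob_centers=[(0.32, 0.35, 0.5), (0.68, 0.4, 0.45), (0.5, 0.72, 0.55)],
        blob_sigma=0.16,
        mesh_spacing=6,
        stiffness=1.0,
        seed=seed,
    )
    mspec = MixtureSpec(
        class_names=names,
        structural_support=[[0], [1], [2], [3]],
        diffusion_support=[[0], [1], [2], [3]],
        n_structural=4,
        n_diffusion=4,
    )
    return pspec, mspec


def diffusion_contrast_phantom_spec(
    family: str = "dsw-beta", size: int = 20, seed: int = 0
) -> tuple[PhantomSpec, MixtureSpec]:
    """Two foreground classes distinguishable only in diffusion.

    Both foreground classes share one structural component and have heavily
    overlapping atlas priors; their diffusion components are strongly
    anisotropic with orthogonal mean axes.  A structural-only fit can do
    little better than the prior, while the joint model separates the two
    regions voxel by voxel.
    """
    names = ["background", "bundle_a", "bundle_b"]
    structural = [
        GaussianParams([25.0], [[49.0]]),
        GaussianParams([110.0], [[36.0]]),
        GaussianParams([110.0], [[36.0]]),  # same appearance as bundle_a
    ]
    diffusion = [
        _diffusion_params(family, 0.15, _X, 4.0, (2.0, 9.0)),
        _diffusion_params(family, 0.80, _Y, 50.0, (8.0, 2.5)),
        _diffusion_params(family, 0.80, _Z, 50.0, (8.0, 2.5)),
    ]
    pspec = PhantomSpec(
        shape=(size, size, size),
        voxel_mm=1.0,
        class_names=names,
        structural_params=structural,
        diffusion_params=diffusion,
        family=family,
        # nearly concentric blobs: the prior barely separates the two bundles
        blob_centers=[(0.47, 0.5, 0.5), (0.53, 0.5, 0.5)],
        blob_sigma=0.2,
        mesh_spacing=6,
        stiffness=1.0,
        seed=seed,
    )
    mspec = MixtureSpec(
        class_names=names,
        structural_support=[[0], [1], [1]],  # shared structural component
        diffusion_support=[[0], [1], [2]],
        n_structural=2,
        n_diffusion=3,
    )
    return pspec, mspec
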