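"""Likelihood families and their weighted MAP fitters.

Four per-component likelihood models are available:

* **Gaussian** over structural intensities, with a Normal-Inverse-Wishart
  (NIW) conjugate prior on (mean, covariance).  In practice the covariance
  prior is left non-informative (scale and dof zero) and the MAP estimate
  shrinks only the mean towards the hypermean.
* **Wishart** over inverse diffusion tensors ``X = T^-1`` with a Gamma prior
  on the transformed degrees of freedom ``(n - 2) / 2 ~ Gamma(0.5, 1.5)``
  (shape-rate), which favours small dof and hence broad distributions.
* **log-Gaussian** over the log-Euclidean 6-vectors, an isotropic 6-D normal
  with scalar variance (uniform priors on both parameters).
* **DSW-beta** over (FA, principal direction): a Beta distribution on FA and
  a Dimroth-Scheidegger-Watson axial distribution on the direction, coupled
  through the *effective concentration* kappa * FA so low-anisotropy voxels
  carry less directional information.

Each family exposes a vectorised log-density and a weighted fitter that
maximises the corresponding M-step objective (weighted log-likelihood plus
log prior).  Fitters flag numerical degeneracies (variance floors, boundary
hits, concentration caps) on the returned parameter object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special

__all__ = [
    "GaussianParams",
    "NIWHyper",
    "WishartParams",
    "LogGaussianParams",
    "DSWBetaParams",
    "gaussian_logpdf",
    "gaussian_map_objective",
    "fit_gaussian_map",
    "wishart_logpdf",
    "wishart_map_objective",
    "fit_wishart_map",
    "loggauss_logpdf",
    "fit_loggauss",
    "watson_log_normaliser",
    "dswbeta_logpdf",
    "fit_dswbeta",
    "KAPPA_CAP",
    "BETA_PARAM_CAP",
]

KAPPA_CAP = 1.0e4
BETA_PARAM_CAP = 1.0e3
GAMMA_ALPHA = 0.5  # shape of the Gamma prior on (n - 2) / 2
GAMMA_BETA = 1.5  # rate of the Gamma prior on (n - 2) / 2


# --------------------------------------------------------------------------
# Structural Gaussian with NIW prior
# --------------------------------------------------------------------------


@dataclass
class GaussianParams:
    """Multivariate normal parameters for one structural component."""

    mean: np.ndarray  # (S,)
    cov: np.ndarray  # (S, S) SPD
    flags: tuple = ()

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        lam = np.linalg.eigvalsh(0.5 * (self.cov + self.cov.T))
        if lam.min() <= 0:
            raise ValueError(f"covariance not SPD (min eigenvalue {lam.min():.3g})")


@dataclass
class NIWHyper:
    """Normal-Inverse-Wishart hyperparameters {M, n, Psi, nu}.

    With ``psi`` and ``nu`` zero (the default used throughout), the
    covariance prior is flat and only the mean is shrunk, with strength
    ``n`` acting as a pseudo-count of observations at the hypermean.
    """

    mean: np.ndarray  # hypermean M (S,)
    strength: float = 0.0  # n >= 0
    psi: np.ndarray = None  # (S, S) PSD
    nu: float = 0.0

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        if self.strength < 0:
            raise ValueError("NIW strength must be non-negative")
        if self.psi is None:
            self.psi = np.zeros((len(self.mean), len(self.mean)))
        self.psi = np.atleast_2d(np.asarray(self.psi, dtype=float))

    @classmethod
    def noninformative(cls, dim: int) -> "NIWHyper":
        return cls(mean=np.zeros(dim), strength=0.0)


def gaussian_logpdf(s: np.ndarray, p: GaussianParams) -> np.ndarray:
    """Multivariate normal log-density, vectorised over rows of ``s``."""
    s_arr = np.asarray(s, dtype=float)
    single = s_arr.ndim <= 1
    s_arr = np.atleast_2d(s_arr)
    S = len(p.mean)
    if s_arr.shape[-1] != S:
        raise ValueError(f"data dimension {s_arr.shape[-1]} != mean dimension {S}")
    try:
        L = np.linalg.cholesky(p.cov)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular covariance") from e
    diff = s_arr - p.mean
    sol = np.linalg.solve(L, diff.T)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    out = -0.5 * (S * np.log(2.0 * np.pi) + logdet + maha)
    return float(out[0]) if single else out


def gaussian_map_objective(
    p: GaussianParams, samples: np.ndarray, weights: np.ndarray, hyper: NIWHyper
) -> float:
    """The M-step objective maximised by :func:`fit_gaussian_map`.

    Weighted log-likelihood plus the (improper, covariance-flat) mean
    shrinkage prior ``-(n/2) (mu - M)' Sigma^-1 (mu - M)``.
    """
    w = np.asarray(weights, dtype=float)
    ll = float(np.sum(w * gaussian_logpdf(samples, p)))
    if hyper.strength > 0:
        diff = p.mean - hyper.mean
        ll += -0.5 * hyper.strength * float(
            diff @ np.linalg.solve(p.cov, diff)
        )
    return ll


def fit_gaussian_map(
    samples: np.ndarray,
    weights: np.ndarray,
    hyper: NIWHyper | None = None,
    cov_floor_rel: float = 1e-8,
) -> GaussianParams:
    """Weighted MAP update of a Gaussian component under the NIW prior.

    With non-informative hyperparameters this is exactly the weighted sample
    mean and covariance; with mean-shrinkage strength ``n > 0`` the mean is
    ``(wbar * muhat + n * M) / (wbar + n)`` and the covariance collects the
    corresponding shrinkage scatter.  Degenerate scatter is floored at
    ``cov_floor_rel`` times the data scale and flagged.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    w = np.asarray(weights, dtype=float)
    wbar = w.sum()
    if wbar <= 0:
        raise ValueError("total weight must be positive")
    S = samples.shape[1]
    if hyper is None:
        hyper = NIWHyper.noninformative(S)

    muhat = (w[:, None] * samples).sum(axis=0) / wbar
    n = hyper.strength
    mu = (wbar * muhat + n * hyper.mean) / (wbar + n)

    diff = samples - mu
    scatter = (w[:, None] * diff).T @ diff
    if n > 0:
        dm = (mu - hyper.mean)[:, None]
        scatter = scatter + n * (dm @ dm.T)
    cov = scatter / wbar

    flags: tuple = ()
    scale = max(float(np.trace(cov)) / S, float(np.var(samples)), 1e-30)
    floor = cov_floor_rel * scale
    lam, Q = np.linalg.eigh(0.5 * (cov + cov.T))
    if lam.min() < floor:
        lam = np.maximum(lam, floor)
        cov = (Q * lam) @ Q.T
        flags = ("cov_floor",)
    return GaussianParams(mean=mu, cov=cov, flags=flags)


# --------------------------------------------------------------------------
# Wishart over inverse tensors
# --------------------------------------------------------------------------


@dataclass
class WishartParams:
    """Wishart distribution over the inverse diffusion tensor.

    The data variable is ``X = T^-1`` with ``X ~ W(n, V)``; ``n > 2`` keeps
    the density proper on 3x3 SPD matrices.
    """

    dof: float  # n > 2
    scale: np.ndarray  # V, (3, 3) SPD
    gamma_hyper: tuple[float, float] = (GAMMA_ALPHA, GAMMA_BETA)
    flags: tuple = ()

    def __post_init__(self) -> None:
        self.scale = np.asarray(self.scale, dtype=float)
        if self.dof <= 2:
            raise ValueError(f"Wishart dof must exceed 2, got {self.dof}")
        if np.linalg.eigvalsh(self.scale).min() <= 0:
            raise ValueError("Wishart scale must be SPD")


def _multigammaln3(a: float | np.ndarray) -> np.ndarray:
    return special.multigammaln(a, 3)


def _wishart_logpdf_X(X: np.ndarray, n: float, V: np.ndarray) -> np.ndarray:
    """Wishart log-density evaluated at precision matrices X (batched)."""
    p = 3
    sign, logdetX = np.linalg.slogdet(X)
    if np.any(sign <= 0):
        raise ValueError("X must be SPD")
    signV, logdetV = np.linalg.slogdet(V)
    Vinv = np.linalg.inv(V)
    tr = np.einsum("ij,...ji->...", Vinv, X)
    return (
        0.5 * (n - p - 1) * logdetX
        - 0.5 * tr
        - 0.5 * n * p * np.log(2.0)
        - 0.5 * n * logdetV
        - _multigammaln3(0.5 * n)
    )


def wishart_logpdf(T: np.ndarray, p: WishartParams) -> np.ndarray:
    """Log Wishart density of the *inverse* tensor ``X = T^-1``.

    ``T`` may be a single SPD 3x3 matrix or a batch (..., 3, 3).  The density
    is over the precision variable X (no tensor-space Jacobian is applied;
    the convention is shared by every component, so posteriors are
    unaffected).
    """
    T = np.asarray(T, dtype=float)
    X = np.linalg.inv(T)
    lam = np.linalg.eigvalsh(T)
    if np.any(lam <= 0):
        raise ValueError("tensor input to wishart_logpdf must be SPD")
    out = _wishart_logpdf_X(X, p.dof, p.scale)
    return float(out) if out.ndim == 0 else out


def wishart_map_objective(
    p: WishartParams, tensors: np.ndarray, weights: np.ndarray
) -> float:
    """Weighted Wishart log-likelihood plus the Gamma log-prior on dof."""
    w = np.asarray(weights, dtype=float)
    ll = float(np.sum(w * wishart_logpdf(tensors, p)))
    a, b = p.gamma_hyper
    t = 0.5 * (p.dof - 2.0)
    ll += float((a - 1.0) * np.log(t) - b * t)
    return ll


def fit_wishart_map(
    tensors: np.ndarray,
    weights: np.ndarray,
    gamma_hyper: tuple[float, float] = (GAMMA_ALPHA, GAMMA_BETA),
    dof_max: float = 1e4,
) -> WishartParams:
    """Weighted MAP fit of the Wishart family.

    Given ``n``, the scale has the closed form ``V = sum_w X / (wbar * n)``;
    the profiled objective over ``n`` (weighted log-likelihood plus the
    Gamma prior on ``(n-2)/2``) is maximised numerically in 1-D.  A fit
    pushed to the ``n -> 2+`` boundary is clamped and flagged.
    """
    tensors = np.asarray(tensors, dtype=float)
    if tensors.ndim == 2:
        tensors = tensors[None]
    w = np.asarray(weights, dtype=float)
    wbar = w.sum()
    if wbar <= 0:
        raise ValueError("total weight must be positive")
    lam = np.linalg.eigvalsh(tensors)
    if np.any(lam <= 0):
        raise ValueError("all tensors must be SPD")
    if np.count_nonzero(w > 0) < 2:
        return WishartParams(
            dof=2.0 + 1e-6,
            scale=np.linalg.inv(tensors[np.argmax(w)]) / (2.0 + 1e-6),
            gamma_hyper=gamma_hyper,
            flags=("dof_boundary", "degenerate_support"),
        )

    X = np.linalg.inv(tensors)
    _, logdetX = np.linalg.slogdet(X)
    mean_logdet = float(np.sum(w * logdetX) / wbar)
    Xbar = np.einsum("v,vij->ij", w, X) / wbar
    _, logdet_Xbar = np.linalg.slogdet(Xbar)
    a, b = gamma_hyper
    p = 3

    def neg_profile(n: float) -> float:
        # V*(n) = Xbar / n; substitute into the weighted log-likelihood
        val = wbar * (
            0.5 * (n - p - 1) * mean_logdet
            - 0.5 * n * p  # tr(V^-1 Xbar) = n * p
            - 0.5 * n * p * np.log(2.0)
            - 0.5 * n * (logdet_Xbar - p * np.log(n))
            - _multigammaln3(0.5 * n)
        )
        t = 0.5 * (n - 2.0)
        val += (a - 1.0) * np.log(t) - b * t
        return -val

    res = optimize.minimize_scalar(
        neg_profile, bounds=(2.0 + 1e-8, dof_max), method="bounded",
        options={"xatol": 1e-8},
    )
    n_opt = float(res.x)
    flags: tuple = ()
    if n_opt < 2.0 + 1e-5:
        n_opt = 2.0 + 1e-6
        flags = ("dof_boundary",)
    V = Xbar / n_opt
    return WishartParams(dof=n_opt, scale=V, gamma_hyper=gamma_hyper, flags=flags)


# --------------------------------------------------------------------------
# Isotropic log-Gaussian over log-tensor 6-vectors
# --------------------------------------------------------------------------


@dataclass
class LogGaussianParams:
    """Isotropic 6-D normal over log-Euclidean tensor vectors."""

    mean: np.ndarray  # (6,)
    var: float  # scalar variance sigma > 0
    flags: tuple = ()

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        if self.var <= 0:
            raise ValueError("variance must be positive")


def loggauss_logpdf(d: np.ndarray, p: LogGaussianParams) -> np.ndarray:
    """Isotropic 6-D normal log-density with scalar variance."""
    d = np.atleast_2d(np.asarray(d, dtype=float))
    sq = np.sum((d - p.mean) ** 2, axis=-1)
    out = -3.0 * np.log(2.0 * np.pi * p.var) - 0.5 * sq / p.var
    return float(out[0]) if len(out) == 1 else out


def fit_loggauss(
    logvecs: np.ndarray,
    weights: np.ndarray,
    var_floor: float = 1e-10,
) -> LogGaussianParams:
    """Weighted maximum-likelihood fit of the isotropic log-Gaussian.

    m is the weighted mean and sigma the weighted mean squared deviation
    divided by the dimension (6).  Zero-variance data hits the floor and is
    flagged.
    """
    d = np.atleast_2d(np.asarray(logvecs, dtype=float))
    w = np.asarray(weights, dtype=float)
    wbar = w.sum()
    if wbar <= 0:
        raise ValueError("total weight must be positive")
    m = (w[:, None] * d).sum(axis=0) / wbar
    sq = np.sum((d - m) ** 2, axis=-1)
    var = float(np.sum(w * sq) / (6.0 * wbar))
    flags: tuple = ()
    if var < var_floor:
        var = var_floor
        flags = ("var_floor",)
    return LogGaussianParams(mean=m, var=var, flags=flags)


# --------------------------------------------------------------------------
# DSW-beta over (FA, principal direction)
# --------------------------------------------------------------------------


@dataclass
class DSWBetaParams:
    """Joint Beta (on FA) and Watson axial (on direction) parameters.

    The Watson concentration acting on a voxel is the *effective*
    concentration ``kappa * FA``: directions in nearly isotropic voxels are
    nearly uninformative.
    """

    beta_a: float
    beta_b: float
    mean_dir: np.ndarray  # unit 3-vector psi
    concentration: float  # kappa >= 0
    flags: tuple = ()

    def __post_init__(self) -> None:
        self.mean_dir = np.asarray(self.mean_dir, dtype=float)
        nrm = np.linalg.norm(self.mean_dir)
        if not np.isclose(nrm, 1.0, atol=1e-8):
            if nrm <= 0:
                raise ValueError("mean direction must be a nonzero vector")
            self.mean_dir = self.mean_dir / nrm
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("Beta parameters must be positive")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")


def watson_log_normaliser(kappa: np.ndarray | float) -> np.ndarray | float:
    """log Z(kappa) = log(4 pi) + log M(1/2, 3/2, kappa).

    M is Kummer's confluent hypergeometric function; a uniform axial density
    has Z(0) = 4 pi.  For large kappa the Kummer transformation
    ``M(1/2, 3/2, k) = e^k M(1, 3/2, -k)`` avoids overflow, keeping the
    evaluation stable beyond kappa = 1e4.
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be non-negative")
    if np.any(kappa > KAPPA_CAP * 1.01):
        raise ValueError(f"kappa exceeds the configured cap {KAPPA_CAP:g}")
    small = kappa < 300.0
    out = np.empty_like(kappa, dtype=float)
    out[small] = np.log(special.hyp1f1(0.5, 1.5, kappa[small]))
    big = ~small
    if np.any(big):
        out[big] = kappa[big] + np.log(special.hyp1f1(1.0, 1.5, -kappa[big]))
    out = out + np.log(4.0 * np.pi)
    return float(out) if out.ndim == 0 else out


def _watson_mean_t2(kappa: np.ndarray) -> np.ndarray:
    """E[(psi'phi)^2] under Watson(kappa): d/dkappa log Z(kappa)."""
    kappa = np.asarray(kappa, dtype=float)
    h = 1e-6 + 1e-6 * kappa
    lo = np.maximum(kappa - h, 0.0)
    return (watson_log_normaliser(kappa + h) - watson_log_normaliser(lo)) / (
        kappa + h - lo
    )


def dswbeta_logpdf(
    f: np.ndarray, phi: np.ndarray, p: DSWBetaParams
) -> np.ndarray:
    """Joint log-density: Beta on FA plus Watson with effective concentration.

    log p = log Beta(f; a, b) + kappa f (psi'phi)^2 - log Z(kappa f).
    Antipodally symmetric in phi.
    """
    f = np.atleast_1d(np.asarray(f, dtype=float))
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("FA values must lie in [0, 1]")
    eps = 1e-12
    fc = np.clip(f, eps, 1.0 - eps)
    beta_term = (
        (p.beta_a - 1.0) * np.log(fc)
        + (p.beta_b - 1.0) * np.log1p(-fc)
        - special.betaln(p.beta_a, p.beta_b)
    )
    t = phi @ p.mean_dir
    keff = p.concentration * f
    watson_term = keff * t**2 - watson_log_normaliser(keff)
    out = beta_term + watson_term
    return float(out[0]) if len(out) == 1 else out


def _fit_beta_weighted(
    f: np.ndarray, w: np.ndarray, cap: float = BETA_PARAM_CAP
) -> tuple[float, float, tuple]:
    """Weighted Beta MLE: method-of-moments start, then quasi-Newton."""
    eps = 1e-6
    fc = np.clip(f, eps, 1.0 - eps)
    wbar = w.sum()
    mean = float(np.sum(w * fc) / wbar)
    var = float(np.sum(w * (fc - mean) ** 2) / wbar)
    var = max(var, 1e-8)
    common = mean * (1.0 - mean) / var - 1.0
    a0 = np.clip(mean * common, 1e-2, cap)
    b0 = np.clip((1.0 - mean) * common, 1e-2, cap)

    mlogf = float(np.sum(w * np.log(fc)) / wbar)
    mlog1mf = float(np.sum(w * np.log1p(-fc)) / wbar)

    def neg(params: np.ndarray) -> float:
        a, b = np.exp(params)
        return -((a - 1.0) * mlogf + (b - 1.0) * mlog1mf - special.betaln(a, b))

    res = optimize.minimize(neg, np.log([a0, b0]), method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 500})
    a, b = np.exp(res.x)
    flags: tuple = ()
    if a > cap or b > cap:
        a, b = min(a, cap), min(b, cap)
        flags = ("beta_cap",)
    return float(a), float(b), flags


def fit_dswbeta(
    fas: np.ndarray,
    pdirs: np.ndarray,
    weights: np.ndarray,
    kappa_cap: float = KAPPA_CAP,
    iso_tol: float = 1e-6,
) -> DSWBetaParams:
    """Weighted fit of the joint DSW-beta component.

    The mean axis psi is the dominant eigenvector of the FA-weighted scatter
    ``sum_v w_v f_v phi_v phi_v'`` (FA weighting follows from the effective
    concentration model).  kappa maximises the profiled directional
    likelihood ``sum_v w_v [kappa f_v (psi'phi_v)^2 - log Z(kappa f_v)]``
    in 1-D; the Beta parameters maximise the weighted Beta likelihood.
    Isotropic scatter yields kappa = 0 with a flag; perfectly aligned data
    hits the concentration cap and is flagged.
    """
    f = np.asarray(fas, dtype=float)
    phi = np.atleast_2d(np.asarray(pdirs, dtype=float))
    w = np.asarray(weights, dtype=float)
    wbar = w.sum()
    if wbar <= 0:
        raise ValueError("total weight must be positive")

    scatter = np.einsum("v,vi,vj->ij", w * f, phi, phi)
    lam, Q = np.linalg.eigh(scatter)
    flags: tuple = ()
    if lam[2] - lam[1] <= iso_tol * max(lam[2], 1e-300):
        psi = np.array([1.0, 0.0, 0.0])
        a, b, bflags = _fit_beta_weighted(f, w)
        return DSWBetaParams(
            beta_a=a, beta_b=b, mean_dir=psi, concentration=0.0,
            flags=("isotropic_scatter",) + bflags,
        )
    psi = Q[:, 2]
    # deterministic sign convention
    k = int(np.argmax(np.abs(psi) > 1e-12))
    if psi[k] < 0:
        psi = -psi

    t2 = (phi @ psi) ** 2

    def neg_dir(kappa: float) -> float:
        keff = kappa * f
        return -float(np.sum(w * (keff * t2 - watson_log_normaliser(keff))))

    res = optimize.minimize_scalar(
        neg_dir, bounds=(0.0, kappa_cap), method="bounded",
        options={"xatol": 1e-6},
    )
    kappa = float(res.x)
    if kappa > kappa_cap * (1.0 - 1e-4):
        kappa = kappa_cap
        flags = flags + ("kappa_cap",)
    if neg_dir(kappa) > neg_dir(0.0):
        kappa = 0.0

    a, b, bflags = _fit_beta_weighted(f, w)
    return DSWBetaParams(
        beta_a=a, beta_b=b, mean_dir=psi, concentration=kappa,
        flags=flags + bflags,
    )


# --------------------------------------------------------------------------
# Serialisation helpers (plain-JSON model dumps)
# --------------------------------------------------------------------------

_FAMILY_NAMES = {
    GaussianParams: "gaussian",
    WishartParams: "wishart",
    LogGaussianParams: "log-gaussian",
    DSWBetaParams: "dsw-beta",
}


def params_to_dict(p) -> dict:
    """Plain-type dictionary representation of any parameter object."""
    if isinstance(p, GaussianParams):
        return {"family": "gaussian", "mean": p.mean.tolist(),
                "cov": p.cov.tolist(), "flags": list(p.flags)}
    if isinstance(p, WishartParams):
        return {"family": "wishart", "dof": p.dof, "scale": p.scale.tolist(),
                "gamma_hyper": list(p.gamma_hyper), "flags": list(p.flags)}
    if isinstance(p, LogGaussianParams):
        return {"family": "log-gaussian", "mean": p.mean.tolist(),
                "var": p.var, "flags": list(p.flags)}
    if isinstance(p, DSWBetaParams):
        return {"family": "dsw-beta", "beta_a": p.beta_a, "beta_b": p.beta_b,
                "mean_dir": p.mean_dir.tolist(),
                "concentration": p.concentration, "flags": list(p.flags)}
    raise TypeError(f"unknown parameter type {type(p)!r}")


def params_from_dict(d: dict):
    fam = d["family"]
    if fam == "gaussian":
        return GaussianParams(np.array(d["mean"]), np.array(d["cov"]),
                              flags=tuple(d.get("flags", ())))
    if fam == "wishart":
        return WishartParams(d["dof"], np.array(d["scale"]),
                             gamma_hyper=tuple(d.get("gamma_hyper",
                                                     (GAMMA_ALPHA, GAMMA_BETA))),
                             flags=tuple(d.get("flags", ())))
    if fam == "log-gaussian":
        return LogGaussianParams(np.array(d["mean"]), d["var"],
                                 flags=tuple(d.get("flags", ())))
    if fam == "dsw-beta":
        return DSWBetaParams(d["beta_a"], d["beta_b"], np.array(d["mean_dir"]),
                             d["concentration"], flags=tuple(d.get("flags", ())))
    raise ValueError(f"unknown family {fam!r}")
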