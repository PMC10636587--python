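# Methods

This note documents the model, the numerical choices, and the design
decisions behind `jointseg`, in the spirit of a statistical package's
methods appendix.  Nothing here asserts an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Generative model and inference

Segmentation is posed as inversion of a voxel-wise generative model.  A
probabilistic atlas — a tetrahedral mesh whose vertices carry class
probability vectors — is placed over the subject by an affine (from moments
of a coarse initial segmentation when one is supplied, identity otherwise)
and deformed by per-vertex displacements θ_a.  Conditional on the label
field sampled from the rasterised (barycentrically interpolated) prior,
structural intensities and diffusion observations are conditionally
independent, each generated by the mixture attached to the voxel's class.

Point estimates of all parameters maximise the marginal log-posterior

    O(θ) = log p(θ_a | γ_a) + Σ_i log p(θ_i^s | γ_i^s) + Σ_j log p(θ_j^d | γ_j^d)
         + Σ_v log Σ_c p(l_v=c | A, θ_a) [Σ_i g_ci p(s_v|θ_i^s)] [Σ_j w_cj p(d_v|θ_j^d)^ε]

by coordinate ascent: mesh deformation (nonlinear conjugate gradient with a
backtracking line search), reflection-plane re-estimation, then Generalised
EM over likelihood parameters and mixture weights.  The E step computes
soft assignments over supported (class, structural component, diffusion
component) triples in log space with per-voxel normalisation; the M step
runs each family's weighted MAP fitter on the marginal responsibilities and
applies the closed-form weight update.  Because every sub-step increases
the EM lower bound — and the deformation data term uses *exactly* the same
prior convention as the rasteriser, including the floored one-hot
background prior for voxels outside the mesh — the objective trace is
non-decreasing; the test suite treats any decrease beyond 1e-8 relative as
a bug, not noise.

The MAP label map is the per-voxel argmax of the class posteriors after
applying the merge map (classes split for modelling are re-merged for
output).  Posterior-weighted volumes are Σ_v posterior_{v,label} × voxel
volume, so the label volumes always partition the field of view exactly.

## Likelihood families

* **Structural Gaussian + NIW.**  The covariance hyperparameters Ψ, ν are
  kept at zero: robustly informing a covariance prior from a coarse
  segmentation is impractical, so the prior is flat in Σ and MAP shrinkage
  acts on the mean only, with the hypermean M taken as the median intensity
  of the initialising label and strength n set to 10% of that label's voxel
  count (the hypermean's effective sample size; the fraction is a modelling
  default, configurable via `FitConfig.hyper_strength_frac`).
* **Wishart.**  The data variable is the inverse tensor X = T⁻¹ (units
  s/mm²); the density is over X with no tensor-space Jacobian — the
  convention is common to all components, so posteriors and weight updates
  are unaffected.  The Gamma prior on (n−2)/2 uses shape 0.5 and rate 1.5
  (shape–rate parameterisation, which places mass on small dof and hence
  broad component distributions).  Given n, the scale has the closed form
  V = Σ w X / (w̄ n); n is then found by bounded 1-D maximisation of the
  profiled objective.
* **log-Gaussian.**  The 6-vector encoding d = (t11, t22, t33, √2 t12,
  √2 t13, √2 t23) of t = log T makes Euclidean distance equal Frobenius
  log-distance exactly (pinned down by a randomized isometry test at
  1e-10); the component model is an isotropic 6-D normal with scalar
  variance and uniform priors, fitted by weighted moments with the variance
  divided by the dimension.
* **DSW-beta.**  FA follows a two-parameter Beta; the principal axis
  follows a Watson distribution with voxel-wise effective concentration
  κ·FA.  The normaliser Z(κ) = 4π·M(1/2, 3/2, κ) uses scipy's Kummer
  function below κ = 300 and the transformation M(1/2,3/2,κ) =
  e^κ M(1,3/2,−κ) above it, which stays finite beyond κ = 1e4 (branch
  continuity and sphere quadrature are tested).  Fitting takes ψ as the
  dominant eigenvector of the FA-weighted direction scatter
  Σ w f φφᵀ — FA weighting follows from the effective-concentration
  model — κ by bounded 1-D maximisation, and (α, β) by method-of-moments
  initialisation plus Nelder–Mead refinement.  Caps: κ ≤ 1e4, Beta
  parameters ≤ 1e3; hits are flagged on the returned parameters.

## Reflective symmetry

Contralateral structures share parameters: structural components are
simply assigned to both hemispheres' classes, while diffusion components
come in (left, right) pairs with the right member defined as the
reflection of the left through a plane of unit normal r (Householder map
H = I − 2rrᵀ; directions map as φ → Hφ, tensors and log-means by the
congruence M → HMH, dispersion parameters are invariant).  Since the
anatomical midline need not align with the voxel axes, r is re-estimated
before each M step from the r-dependent bound terms.  For every family
these reduce to sums of the generic form c·tr(A H B H) over 3×3 sufficient
statistics — quartic in r on the unit sphere (verified by exact agreement
of 15 generic evaluations with a degree-4 interpolant) — with the
dispersion statistic (κ, 1/σ, or n/2) weighting each component's
contribution and the component posteriors weighting each voxel's.  The
maximiser is found by BFGS on the scale-invariant composition r ↦ O(r/‖r‖)
from the current normal plus a few generic restarts, keeping the best; the
initial normal is retained whenever no improvement is found, so the step
is monotone.  All pairs contribute, dispersion-weighted; a flat objective
(all paired components isotropic) returns the initial plane with a
degeneracy flag.

## Resolution weighting ε

Diffusion data resampled from V_d coarse voxels onto V fine structural
voxels would otherwise enter the likelihood V/V_d times too often.  The
tempering exponent ε = min(1, structural voxel volume / diffusion voxel
volume) restores the effective sample size; it enters the E step, the
M-step diffusion weights, and the objective consistently (a single
tempered likelihood — applying it in only one place would break the
bound's monotonicity).  Duplicating every diffusion voxel k times with
ε = 1/k reproduces the un-duplicated ε = 1 parameter estimates to 1e-6,
which the tests assert at the fitter and M-step levels.

## Atlas machinery

Point-in-tetrahedron lookup scans tetrahedra in index order over their
bounding boxes; points on shared faces resolve to the lowest tetrahedron
index (deterministic, so rasterisation is bit-reproducible).  The
deformation penalty per tetrahedron is (J + 1/J − 2) with J the deformed /
reference volume ratio, weighted by the tetrahedron's share of reference
volume and scaled by the stiffness γ_a; it is zero at the identity,
symmetric in log-volume change, invariant to joint rigid motion, and +∞ at
J ≤ 0 (hard fold barrier).  γ_a has no universal default — it is a
required modelling parameter; the synthetic presets use 1.0.  The
deformation optimiser is Polak–Ribière conjugate gradient with Armijo
backtracking (max 20 iterations per cycle, relative tolerance 1e-5);
steps that would fold the mesh evaluate to −∞ and are rejected by the line
search.  Gradients of the prior term are analytic through the barycentric
system (db_i = −b_k (Ã⁻¹)_{i,:3}·δ for a perturbation δ of vertex k).

## Tensor preprocessing

Fitted DTI voxels with non-positive eigenvalues or FA outside [0, 1] are
replaced by the exponential of a Gaussian-weighted mean of neighbouring
valid log-tensors (σ = 2 mm, truncated at 3σ; an invalid voxel with no
valid neighbour inside the support is an error naming the voxel).  Cleaned
tensors are converted to log 6-vectors and trilinearly interpolated onto
the structural grid componentwise; voxels needing extrapolation, or drawing
on any invalid source voxel, are marked invalid and contribute only their
structural likelihood (no imputation).  Eigenvalue ties for the principal
direction (relative gap < 1e-6) are flagged degenerate.

## Mixture specification and initialisation

Class-to-component assignments for each modality come from a YAML config
(classes, component counts, per-class support lists, merge map); classes
may share components and a class may own several ("clean"/"messy" CSF
style).  Non-zero weights start equal over each class's support.  Initial
component parameters come from seeded k-means (scikit-learn, n_init = 4)
over voxels whose class prior exceeds 0.5, with family-appropriate
features: raw intensities, log-tensor 6-vectors, or sign-aligned principal
directions with FA appended.  Clusters are ordered by mean feature norm so
initialisation is reproducible for a fixed seed.

## Synthetic phantoms

The generator draws from the model's own generative process: labels from a
rasterised box atlas whose vertex probabilities are Gaussian blobs over a
background floor, intensities from the class Gaussians, and tensors from
the class diffusion components (Wishart draws inverted; log-Gaussian draws
exponentiated; DSW-beta draws rendered as axially symmetric tensors whose
analytic FA equals the sampled value at mean diffusivity 0.7e-3 mm²/s, a
typical parenchyma scale).  Watson sampling is rejection from the uniform
sphere with envelope e^κ; the acceptance rate decays like 1/κ, so a round
guard aborts on pathological concentrations.  The preset conditions use
structural class means separated by roughly three standard deviations and
Watson concentrations of 25–50, i.e. clearly separable tissue classes at
coherent-white-matter anisotropy; the diffusion-contrast preset makes two
foreground classes structurally identical with nearly concentric priors so
that only orientation separates them.

What the phantoms deliberately do **not** emulate: realistic anatomy and
curved fibre geometry, bias fields, Rician noise floors, susceptibility
distortion, imperfect coregistration, or partial-volume mixing beyond the
resolution-weighting mechanism.  Passing the closure tests therefore shows
the inference machinery is correct and self-consistent — not that accuracy
on clinical data matches the phantom numbers.

## Problem sizes and tolerances in the shipped checks

Test and acceptance runs use phantoms of 12³–18³ voxels with mesh spacing
6, 2–5 outer cycles and 6–15 inner GEM iterations — sizes chosen so the
whole validation battery completes in a few minutes of one CPU while still
exercising every code path; fitter-level recovery checks use 10k–20k
samples per component.  Convergence defaults: outer relative tolerance
1e-5 (max 30 cycles), inner 1e-6 (max 100 iterations).  All likelihood
products are computed in log space; variance and covariance floors default
to 1e-8–1e-10 of the data scale and are flagged when hit.

## Known limitations

* Mixture support changes (adding/removing components) require a new fit;
  there is no online model selection — TOPSIS ranks externally supplied
  candidate runs instead.
* The reflection machinery assumes exactly two hemispheres and one plane;
  focal pathological asymmetry is not modelled and will broaden the
  affected components rather than move the plane.
* Deformation optimisation treats tetrahedron membership as fixed within a
  line-search evaluation; the objective is only piecewise smooth across
  membership changes (the monotone line search keeps every accepted step
  an improvement regardless).
* ε corrects effective sample size, not the spatial mixing of signals:
  strong partial voluming at very coarse diffusion resolutions is outside
  the model.
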