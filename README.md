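# jointseg

Joint Bayesian segmentation of brain structures from co-registered
**structural** and **diffusion** MRI, built around a deformable
probabilistic atlas and per-class mixture likelihoods over both image
contrasts.

Structural MRI alone often cannot place boundaries between grey-matter
structures and adjacent white matter — the contrast simply is not there.
Diffusion tensor imaging (DTI) sees exactly those boundaries through fibre
orientation and anisotropy, but is blind to others and is acquired at lower
resolution.  `jointseg` fuses both: a tetrahedral-mesh atlas supplies a
deformable spatial prior over C anatomical classes, each class emits
structural intensity and a diffusion observation through separate mixture
models, and Generalised EM recovers the maximum-a-posteriori label map and
posterior-weighted volumes.  It is aimed at researchers building or
evaluating multi-contrast subcortical segmentation pipelines.

## Model

For voxels v = 1..V with labels l_v, intensities s_v and diffusion data
d_v, the joint model factorises as

    p(S, D, L, θ) = Π_v p(s_v | θ_{l_v}^s) p(d_v | θ_{l_v}^d) p(l_v | A, θ_a) · p(θ | γ)

where the atlas **A** is a tetrahedral mesh with per-vertex class
probabilities, deformed by vertex displacements θ_a under a
topology-preserving penalty (volume-ratio barrier, so the mesh can never
fold).  Class likelihoods are mixtures over shared component pools,

    p(s_v | class c) = Σ_i g_ci N(s_v; μ_i, Σ_i),
    p(d_v | class c) = Σ_j w_cj p(d_v | θ_j^d),

with a Normal-Inverse-Wishart prior on the Gaussian parameters.  Three
interchangeable diffusion families are provided:

* **Wishart** — the inverse tensor T_v⁻¹ ~ W(n_j, V_j), with a Gamma prior
  on (n_j − 2)/2 (shape 0.5, rate 1.5) favouring broad distributions;
* **log-Gaussian** — the log-Euclidean 6-vector d_v ~ N(m_j, σ_j I₆), where
  ‖d₁ − d₂‖₂ = ‖log T₁ − log T₂‖_F exactly;
* **DSW-beta** — only FA f_v and principal direction φ_v are modelled:
  f_v ~ Beta(α_j, β_j) and φ_v follows a Dimroth–Scheidegger–Watson axial
  distribution with *effective* concentration κ_j·f_v, so nearly isotropic
  voxels carry almost no directional information.

Fitting alternates (i) conjugate-gradient mesh deformation, (ii)
re-estimation of a reflection plane that ties contralateral diffusion
components together (the mirror normal **r** is itself estimated from the
data by maximising a quartic objective on the unit sphere), and (iii)
E/M steps over soft assignments q_v^{c,i,j}.  When the diffusion volume is
coarser than the structural grid, its likelihood is tempered by
ε = (structural voxel volume) / (diffusion voxel volume), which undoes the
sample-size inflation introduced by interpolating to the finer grid.
The objective is non-decreasing at every step by construction.

Evaluation utilities implement Dice overlap, 95th-percentile Hausdorff
boundary distance (mm), ICC(2,1) volume agreement, and TOPSIS multi-criteria
model ranking.

## Worked example

Everything runs on synthetic phantoms sampled from the model's own
generative process — no data download needed:

```python
import numpy as np
from jointseg import JointSegmentationModel, FitConfig, make_box_atlas, sample_phantom
from jointseg.presets import default_phantom_spec
from jointseg.metrics import ROIMask, dice

pspec, mspec = default_phantom_spec(size=16, seed=7)
mesh = make_box_atlas(pspec)                      # deformable box atlas
labels, smri, tensors = sample_phantom(mesh, pspec)  # ground truth + images

model = JointSegmentationModel(
    smri, tensors.grid, tensors, mesh, mspec, family="dsw-beta",
    config=FitConfig(seed=0, max_cycles=5),
)
results = model.fit()
print(results.summary())
for c, name in enumerate(mspec.class_names):
    d = dice(ROIMask(tensors.grid, labels == c),
             ROIMask(tensors.grid, results.labels == c))
    print(f"Dice[{name}] = {d:.3f}")
```

Output:

```
Joint structural+diffusion Bayesian segmentation
====================================================
diffusion family : dsw-beta
epsilon          : 1
cycles           : 3 (converged)
objective        : -19595.444943 (delta last step 5.46e-11)

Posterior-weighted volumes (mm^3)
 label_id label_name  volume_mm3
        0 background 2008.000074
        1     medial  748.755336
        2    lateral  678.244648
        3      tract  660.999943

Dice[background] = 1.000
Dice[medial] = 0.999
Dice[lateral] = 0.999
Dice[tract] = 1.000
```

The objective is the marginal log-posterior being maximised (its trace is
monotone across iterations); ε = 1 because phantom grids match; the volume
table sums posterior probability per label times voxel volume, so soft
boundary voxels contribute fractionally; the Dice scores compare the MAP
label map with the sampled ground truth.

The same pipeline is available from the shell:

```bash
jointseg phantom  --out-dir ph --seed 3 --size 14
jointseg segment  --smri ph/smri.nii.gz --tensors ph/tensors.nii.gz \
                  --atlas ph/atlas.npz --spec ph/mixture.yaml \
                  --out-dir seg --seed 0
jointseg evaluate --reference ph/truth_labels.nii.gz \
                  --candidate seg/labels.nii.gz --out eval.tsv
```

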