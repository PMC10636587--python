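"""File formats: NIfTI volumes, tensor dialects, atlas container, configs.

Tensor volumes are exchanged as 4-D NIfTI with six components per voxel.
Two component orders are found in the wild; both are supported:

* ``lower-triangular`` (default): Dxx, Dxy, Dyy, Dxz, Dyz, Dzz
* ``row-first``: Dxx, Dxy, Dxz, Dyy, Dyz, Dzz

The atlas travels as a single ``.npz`` container of named arrays
("vertices", "tetrahedra", "probs", "class_names", "stiffness") with an
optional FreeSurfer-LUT-style text sidecar mapping class indices to output
label integers and RGB colours.  Mixture specifications are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .atlas import AtlasMesh
from .grids import VoxelGrid
from .mixture import MixtureSpec
from .tensors import DTISummaryField, TensorField

__all__ = [
    "TENSOR_ORDERS",
    "read_volume",
    "write_volume",
    "read_tensor_nifti",
    "write_tensor_nifti",
    "write_fa_nifti",
    "write_decfa_nifti",
    "save_atlas",
    "load_atlas",
    "write_lut",
    "load_mixture_spec",
    "save_mixture_spec",
]

# index pairs of the six components in each supported dialect
TENSOR_ORDERS = {
    "lower-triangular": [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)],
    "row-first": [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)],
}


def read_volume(path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    grid = VoxelGrid(data.shape[:3], img.affine)
    return data, grid


def write_volume(path, data: np.ndarray, grid: VoxelGrid, dtype=None) -> None:
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    nib.save(nib.Nifti1Image(arr, grid.affine), str(path))


def read_tensor_nifti(path, order: str = "lower-triangular") -> TensorField:
    """Read a 6-component tensor NIfTI in the given component order."""
    if order not in TENSOR_ORDERS:
        raise ValueError(f"unknown tensor component order {order!r}")
    data, grid = read_volume(path)
    if data.ndim != 4 or data.shape[3] != 6:
        raise ValueError(
            f"expected a 4-D volume with 6 components, got shape {data.shape}"
        )
    tensors = np.zeros(grid.shape + (3, 3))
    for comp, (i, j) in enumerate(TENSOR_ORDERS[order]):
        tensors[..., i, j] = data[..., comp]
        tensors[..., j, i] = data[..., comp]
    return TensorField(grid, tensors)


def write_tensor_nifti(
    path, tf: TensorField, order: str = "lower-triangular"
) -> None:
    comps = np.stack(
        [tf.tensors[..., i, j] for (i, j) in TENSOR_ORDERS[order]], axis=-1
    )
    write_volume(path, comps, tf.grid)


def write_fa_nifti(path, summary: DTISummaryField) -> None:
    write_volume(path, summary.fa, summary.grid)


def write_decfa_nifti(path, summary: DTISummaryField) -> None:
    """Directionally encoded colour FA: RGB = |principal direction| * FA."""
    rgb = np.abs(summary.pdir) * summary.fa[..., None]
    write_volume(path, rgb, summary.grid)


def save_atlas(path, mesh: AtlasMesh) -> None:
    np.savez(
        str(path),
        vertices=mesh.reference_vertices,
        tetrahedra=mesh.tetrahedra,
        probs=mesh.vertex_probs,
        class_names=np.array(mesh.class_names),
        stiffness=np.array(mesh.stiffness),
        affine_to_subject=mesh.affine_to_subject,
        background_class=np.array(mesh.background_class),
    )


def load_atlas(path) -> AtlasMesh:
    with np.load(str(path), allow_pickle=False) as z:
        return AtlasMesh(
            reference_vertices=z["vertices"],
            tetrahedra=z["tetrahedra"],
            vertex_probs=z["probs"],
            class_names=[str(s) for s in z["class_names"]],
            stiffness=float(z["stiffness"]),
            affine_to_subject=z["affine_to_subject"],
            background_class=int(z["background_class"]),
        )


def write_lut(path, label_names: list[str], colors: list | None = None) -> None:
    """FreeSurfer-style colour lookup table for the output labels."""
    rng = np.random.default_rng(0)
    lines = ["# label_id  name  R  G  B  A"]
    for i, name in enumerate(label_names):
        if colors is not None:
            r, g, b = colors[i]
        else:
            r, g, b = (int(x) for x in rng.integers(0, 256, 3))
        lines.append(f"{i:4d}  {name:<24s} {r:3d} {g:3d} {b:3d}   0")
    Path(path).write_text("\n".join(lines) + "\n")


def save_mixture_spec(path, spec: MixtureSpec) -> None:
    doc = {
        "classes": list(spec.class_names),
        "structural_components": int(spec.n_structural),
        "diffusion_components": int(spec.n_diffusion),
        "assignments": {
            "structural": {
                spec.class_names[c]: list(map(int, spec.structural_support[c]))
                for c in range(spec.n_classes)
            },
            "diffusion": {
                spec.class_names[c]: list(map(int, spec.diffusion_support[c]))
                for c in range(spec.n_classes)
            },
        },
        "merge_map": {int(k): int(v) for k, v in spec.merge_map.items()},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_mixture_spec(path) -> MixtureSpec:
    doc = yaml.safe_load(Path(path).read_text())
    names = list(doc["classes"])
    ss = [list(doc["assignments"]["structural"][n]) for n in names]
    ds = [list(doc["assignments"]["diffusion"][n]) for n in names]
    merge = {int(k): int(v) for k, v in doc.get("merge_map", {}).items()}
    return MixtureSpec(
        class_names=names,
        structural_support=ss,
        diffusion_support=ds,
        n_structural=int(doc["structural_components"]),
        n_diffusion=int(doc["diffusion_components"]),
        merge_map=merge,
    )
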