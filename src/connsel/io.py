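"""NIfTI and JSON/CSV serialization for datasets, maps and voxel sets."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .design import Block, DesignSpec
from .layout import RegionSpec, make_layout
from .selection import VoxelSet
from .simulate import SubjectDataset


def _affine() -> np.ndarray:
    return np.eye(4)


def write_subject_nifti(dataset: SubjectDataset, out_dir: str | Path) -> Path:
    """Export a subject as one 4-D NIfTI per run plus a label mask.

    The label volume encodes gray matter as 1 and region r as r + 2 (in
    the order listed in a JSON sidecar, which also carries the design,
    motion series and region metadata needed to invert the export).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dims = dataset.layout.grid_dims
    for r, ts in enumerate(dataset.runs):
        vol = np.moveaxis(ts.reshape((ts.shape[0],) + dims), 0, -1)
        img = nib.Nifti1Image(vol.astype(np.float32), _affine())
        img.header.set_zooms((1.0, 1.0, 1.0, dataset.tr_seconds))
        nib.save(img, out / f"{dataset.subject_id}_run-{r + 1:02d}_bold.nii")

    labels = np.zeros(dims, dtype=np.int16)
    labels[dataset.layout.gray_mask] = 1
    region_order = list(dataset.layout.regions)
    for i, name in enumerate(region_order):
        labels.ravel()[dataset.layout.regions[name]] = i + 2
    nib.save(nib.Nifti1Image(labels, _affine()), out / f"{dataset.subject_id}_mask.nii")

    sidecar = {
        "subject_id": dataset.subject_id,
        "tr_seconds": dataset.tr_seconds,
        "grid_dims": list(dims),
        "region_order": region_order,
        "roles": dataset.layout.roles,
        "categories": dataset.layout.categories,
        "region_specs": [
            {"name": s.name, "center": list(s.center), "radius": s.radius,
             "role": s.role, "category": s.category}
            for s in dataset.layout.specs
        ],
        "design": [
            {
                "run_index": spec.run_index,
                "tr_seconds": spec.tr_seconds,
                "conditions": list(spec.conditions),
                "blocks": [
                    {"condition": b.condition, "onset": b.onset_seconds,
                     "duration": b.duration_seconds}
                    for b in spec.blocks
                ],
            }
            for spec in dataset.design
        ],
        "motion": [m.tolist() for m in dataset.motion],
    }
    (out / f"{dataset.subject_id}_sidecar.json").write_text(json.dumps(sidecar))
    return out


def read_subject_nifti(out_dir: str | Path, subject_id: str) -> SubjectDataset:
    """Invert :func:`write_subject_nifti` (truth records are not exported)."""
    out = Path(out_dir)
    sidecar = json.loads((out / f"{subject_id}_sidecar.json").read_text())
    dims = tuple(sidecar["grid_dims"])
    specs = [
        RegionSpec(s["name"], tuple(s["center"]), s["radius"], s["role"], s["category"])
        for s in sidecar["region_specs"]
    ]
    layout = make_layout(dims, specs)
    designs = []
    for d in sidecar["design"]:
        blocks = [Block(b["condition"], b["onset"], b["duration"]) for b in d["blocks"]]
        designs.append(
            DesignSpec(blocks=blocks, tr_seconds=d["tr_seconds"],
                       conditions=tuple(d["conditions"]), run_index=d["run_index"])
        )
    runs = []
    for r in range(len(designs)):
        img = nib.load(out / f"{subject_id}_run-{r + 1:02d}_bold.nii")
        vol = np.asarray(img.dataobj, dtype=np.float64)
        runs.append(np.moveaxis(vol, -1, 0).reshape(vol.shape[-1], -1))
    motion = [np.asarray(m, dtype=float) for m in sidecar["motion"]]
    return SubjectDataset(
        runs=runs, tr_seconds=sidecar["tr_seconds"], layout=layout,
        design=designs, motion=motion, truth=None, subject_id=subject_id,
    )


def export_map_nifti(values: np.ndarray, grid_dims, path: str | Path) -> None:
    """Write a per-voxel map (flat or 3-D) as a 3-D NIfTI volume."""
    vol = np.asarray(values, dtype=np.float32).reshape(grid_dims)
    nib.save(nib.Nifti1Image(vol, _affine()), str(path))


def voxelset_to_json(vset: VoxelSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(vset.to_dict()))


def voxelset_from_json(path: str | Path) -> VoxelSet:
    d = json.loads(Path(path).read_text())
    return VoxelSet(np.array(d["indices"]), d["k"], d["mode"],
                    fold_id=d["fold_id"], contrast_used=d["contrast_used"],
                    region=d["region"])


def voxelset_mask_nifti(vset: VoxelSet, grid_dims, path: str | Path) -> None:
    m = np.zeros(int(np.prod(grid_dims)), dtype=np.int16)
    m[vset.indices] = 1
    export_map_nifti(m, grid_dims, path)
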