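"""NIfTI-1, gradient-table and manifest I/O for the pipeline.

All volumes go through nibabel as NIfTI-1 with an isotropic-voxel affine;
gradient tables use the FSL bval/bvec layout (one whitespace-separated row
of b-values; three rows of x/y/z components); cohort manifests are YAML.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import yaml

from .synthetic import DiffusionScheme

__all__ = ["save_volume", "load_volume", "write_bvals_bvecs",
           "read_bvals_bvecs", "write_manifest", "read_manifest",
           "write_cohort", "load_cohort"]


def save_volume(data: np.ndarray, path, voxel_mm: float = 1.0) -> None:
    """Write an array (3-D or 4-D) as NIfTI-1 with an isotropic affine."""
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms((voxel_mm,) * 3 + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, os.fspath(path))


def load_volume(path):
    """Read a NIfTI volume; returns (data, voxel_mm)."""
    img = nib.load(os.fspath(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.get_fdata(), dtype=float), float(zooms[0])


def write_bvals_bvecs(scheme: DiffusionScheme, bval_path, bvec_path) -> None:
    """FSL layout: bvals on one row; bvecs as three rows (x, y, z)."""
    with open(bval_path, "w") as f:
        f.write(" ".join(f"{b:g}" for b in scheme.bvals) + "\n")
    with open(bvec_path, "w") as f:
        for axis in range(3):
            f.write(" ".join(f"{v:.8f}" for v in scheme.bvecs[:, axis]) + "\n")


def read_bvals_bvecs(bval_path, bvec_path) -> DiffusionScheme:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    scheme = DiffusionScheme(bvals=bvals, bvecs=bvecs)
    scheme.validate()
    return scheme


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(manifest, f, sort_keys=False)


def read_manifest(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def write_cohort(cohort, out_dir, voxel_mm: float, scheme=None,
                 config_meta: dict | None = None) -> dict:
    """Write a cohort to disk: one NIfTI per image plus a YAML manifest.

    The manifest lists subject id, age, sex, relative file paths, and any
    injected ground-truth parameters recorded during simulation.
    """
    os.makedirs(out_dir, exist_ok=True)
    subjects = []
    for s in cohort:
        entry = {"subject_id": s.subject_id, "age": round(float(s.age), 2),
                 "sex": s.sex, "files": {}}
        for attr in ("t1_8ch", "t1_32ch", "dwi_8ch", "dwi_32ch",
                     "bold_8ch", "bold_32ch"):
            img = getattr(s, attr)
            if img is None:
                continue
            fname = f"{s.subject_id}_{attr}.nii.gz"
            save_volume(img, os.path.join(out_dir, fname), voxel_mm)
            entry["files"][attr] = fname
        truth = {k: float(v) for k, v in s.truth.items()
                 if np.isscalar(v) and not isinstance(v, str)}
        if truth:
            entry["injected_truth"] = truth
        subjects.append(entry)
    if scheme is not None:
        write_bvals_bvecs(scheme, os.path.join(out_dir, "dwi.bval"),
                          os.path.join(out_dir, "dwi.bvec"))
    manifest = {"voxel_mm": voxel_mm, "n_subjects": len(cohort),
                "subjects": subjects}
    if config_meta:
        manifest["config"] = config_meta
    write_manifest(manifest, os.path.join(out_dir, "manifest.yaml"))
    return manifest


def load_cohort(manifest_dir):
    """Rebuild a cohort (images + demographics) from a written manifest.

    Phantom ground truth is not serialized; the returned SubjectPair
    objects carry a minimal phantom surrogate exposing the brain mask
    derived from the stored T1 (first available modality) so downstream
    stages that only need grid/mask information keep working.
    """
    from .synthetic import SubjectPair, TissuePhantom

    manifest = read_manifest(os.path.join(manifest_dir, "manifest.yaml"))
    voxel_mm = manifest["voxel_mm"]
    cohort = []
    for entry in manifest["subjects"]:
        images = {attr: load_volume(os.path.join(manifest_dir, fname))[0]
                  for attr, fname in entry["files"].items()}
        ref = next(iter(images.values()))
        grid = ref.shape[:3]
        zeros = np.zeros(grid)
        phantom = TissuePhantom(pv_gm=zeros, pv_wm=zeros, pv_csf=zeros,
                                tissue_means={}, shape_params={},
                                voxel_mm=voxel_mm, deform_seed=-1)
        pair = SubjectPair(subject_id=entry["subject_id"], phantom=phantom,
                           age=entry["age"], sex=entry["sex"],
                           truth=entry.get("injected_truth", {}), **images)
        cohort.append(pair)
    return cohort
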