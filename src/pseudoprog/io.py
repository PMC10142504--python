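"""NIfTI and encoding-table I/O (thin nibabel wrappers)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .dti import DWIStack, ScalarMap
from .dsc import DSCSeries

__all__ = [
    "load_scalar_map",
    "save_scalar_map",
    "save_mask",
    "load_bvals_bvecs",
    "load_dwi",
    "load_dsc",
]


def load_scalar_map(path: str | Path, name: str | None = None) -> ScalarMap:
    img = nib.load(str(path))
    return ScalarMap(
        name=name or Path(path).name.split(".")[0],
        values=np.asarray(img.dataobj, dtype=float),
        affine=img.affine,
    )


def save_scalar_map(m: ScalarMap, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(m.values.astype(np.float32), m.affine), str(path))


def save_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def load_bvals_bvecs(bval_path: str | Path, bvec_path: str | Path):
    """FSL-style encoding: one row of b-values; three rows of components."""
    bvals = np.loadtxt(str(bval_path)).ravel()
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return bvals, bvecs


def load_dwi(dwi_path, bval_path, bvec_path) -> DWIStack:
    img = nib.load(str(dwi_path))
    bvals, bvecs = load_bvals_bvecs(bval_path, bvec_path)
    zooms = img.header.get_zooms()[:3]
    return DWIStack(
        data=np.asarray(img.dataobj, dtype=float),
        bvals=bvals,
        bvecs=bvecs,
        voxel_size=tuple(float(z) for z in zooms),
        affine=img.affine,
    )


def load_dsc(path, tr: float, te: float) -> DSCSeries:
    img = nib.load(str(path))
    return DSCSeries(
        data=np.asarray(img.dataobj, dtype=float), tr=tr, te=te, affine=img.affine
    )
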