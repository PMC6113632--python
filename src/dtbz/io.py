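"""NIfTI and gradient-table I/O.

Volumes are written as NIfTI-1 with a diagonal affine built from the
voxel dimensions.  Gradient tables use the FSL bvec/bval dialect:
``*.bvec`` holds three rows (x, y, z components, one column per
measurement) and ``*.bval`` one row of b-values.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np


def save_nifti(path, data: np.ndarray, voxel_dims) -> None:
    affine = np.diag([*voxel_dims, 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(tuple(voxel_dims) + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), zooms


def write_bvec_bval(prefix, directions: np.ndarray, b_value: float) -> tuple[Path, Path]:
    """Write an FSL-style gradient table including the leading b=0 entry."""
    prefix = Path(prefix)
    n = len(directions)
    bvecs = np.zeros((3, n + 1))
    bvecs[:, 1:] = np.asarray(directions).T
    bvals = np.concatenate([[0.0], np.full(n, float(b_value))])
    bvec_path = prefix.with_suffix(".bvec")
    bval_path = prefix.with_suffix(".bval")
    np.savetxt(bvec_path, bvecs, fmt="% .10f")
    np.savetxt(bval_path, bvals[None, :], fmt="%.1f")
    return bvec_path, bval_path


def read_bvec_bval(bvec_path, bval_path) -> tuple[np.ndarray, np.ndarray]:
    bvecs = np.loadtxt(bvec_path)
    bvals = np.atleast_1d(np.loadtxt(bval_path)).ravel()
    if bvecs.shape[0] != 3:
        raise ValueError(f"bvec file must have 3 rows, got shape {bvecs.shape}")
    if bvecs.shape[1] != bvals.size:
        raise ValueError("bvec/bval column counts differ")
    return bvecs.T, bvals


def packaged_directions() -> np.ndarray:
    """The 30 electrostatically spread unit gradient directions shipped
    with the package."""
    with resources.files("dtbz.data").joinpath("directions30.txt").open() as fh:
        v = np.loadtxt(fh)
    return v / np.linalg.norm(v, axis=1, keepdims=True)
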