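"""File-format plumbing: NIfTI volumes, FSL bval/bvec, YAML configs."""

from __future__ import annotations

import numpy as np
import yaml

import nibabel as nib

__all__ = ["save_nifti", "load_nifti", "write_bval_bvec", "read_bval_bvec",
           "load_config", "dump_config"]


def default_affine(pixel_mm: float = 2.3, slice_mm: float = 8.0) -> np.ndarray:
    return np.diag([pixel_mm, pixel_mm, slice_mm, 1.0])


def save_nifti(path, data: np.ndarray, affine: np.ndarray | None = None,
               pixel_mm: float = 2.3, slice_mm: float = 8.0) -> None:
    if affine is None:
        affine = default_affine(pixel_mm, slice_mm)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    nib.save(img, str(path))


def load_nifti(path):
    """Returns ``(data, affine)``."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_bval_bvec(bval_path, bvec_path, bvals: np.ndarray,
                    bvecs: np.ndarray) -> None:
    """FSL dialect: bvals one space-separated row; bvecs three rows (x, y, z)."""
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    if bvecs.shape != (len(bvals), 3):
        raise ValueError("bvecs must be (n_volumes, 3)")
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for axis in range(3):
            fh.write(" ".join(repr(float(x)) for x in bvecs[:, axis]) + "\n")


def read_bval_bvec(bval_path, bvec_path, renormalize: bool = True):
    """Read FSL bval/bvec; non-unit b>0 columns are renormalized with a log.

    Returns ``(bvals, bvecs, log_messages)``.
    """
    log: list[str] = []
    with open(bval_path) as fh:
        tokens = fh.read().split()
    try:
        bvals = np.array([float(t) for t in tokens])
    except ValueError as exc:
        raise ValueError(f"{bval_path}: non-numeric b-value: {exc}") from exc
    rows = []
    with open(bvec_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rows.append([float(t) for t in line.split()])
            except ValueError as exc:
                raise ValueError(
                    f"{bvec_path}: non-numeric entry on line {lineno}") from exc
    if len(rows) != 3:
        raise ValueError(f"{bvec_path}: expected 3 rows (x, y, z), got "
                         f"{len(rows)}")
    bvecs = np.array(rows).T
    if bvecs.shape[0] != len(bvals):
        raise ValueError(
            f"bval/bvec length mismatch: {len(bvals)} vs {bvecs.shape[0]}")
    nonzero = bvals > 0
    norms = np.linalg.norm(bvecs[nonzero], axis=1)
    bad = np.abs(norms - 1.0) > 1e-6
    if renormalize and bad.any():
        idx = np.nonzero(nonzero)[0][bad]
        bvecs[idx] /= np.linalg.norm(bvecs[idx], axis=1, keepdims=True)
        log.append(f"renormalized {len(idx)} non-unit direction(s): "
                   f"volumes {idx.tolist()}")
    return bvals, bvecs, log


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
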