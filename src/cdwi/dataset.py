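"""In-memory container for a diffusion-weighted acquisition."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DwiDataset:
    """4-D diffusion-weighted image stack with per-volume encoding metadata.

    ``volumes`` has shape (nx, ny, n_slices, n_volumes); complex-valued as
    acquired, real-valued after phase correction.  ``bvecs`` rows are unit
    encoding directions (b=0-like volumes may carry zero vectors).
    ``exclusion_mask`` marks voxels (e.g. susceptibility-distorted regions)
    that are kept out of ROI averages but not out of the fit.
    """

    volumes: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    mask: np.ndarray
    shell_idx: np.ndarray | None = None
    dir_idx: np.ndarray | None = None
    rep_idx: np.ndarray | None = None
    scheme_label: str = "M2"
    exclusion_mask: np.ndarray | None = None
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes)
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be 4-D (x, y, slice, volume)")
        v = self.volumes.shape[-1]
        if len(self.bvals) != v or self.bvecs.shape != (v, 3):
            raise ValueError(
                f"metadata length mismatch: {v} volumes, {len(self.bvals)} "
                f"b-values, bvecs shape {self.bvecs.shape}")
        nonzero = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[nonzero], axis=1)
        if len(norms) and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("directions of b>0 volumes must be unit-norm")

    @property
    def n_volumes(self) -> int:
        return self.volumes.shape[-1]

    @property
    def n_slices(self) -> int:
        return self.volumes.shape[2]

    @property
    def shells(self) -> np.ndarray:
        return np.unique(self.bvals)

    def subset(self, keep: np.ndarray) -> "DwiDataset":
        """New dataset restricted to the volumes selected by ``keep``."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.nonzero(keep)[0]
        return DwiDataset(
            volumes=self.volumes[..., keep],
            bvals=self.bvals[keep],
            bvecs=self.bvecs[keep],
            mask=self.mask,
            shell_idx=None if self.shell_idx is None else self.shell_idx[keep],
            dir_idx=None if self.dir_idx is None else self.dir_idx[keep],
            rep_idx=None if self.rep_idx is None else self.rep_idx[keep],
            scheme_label=self.scheme_label,
            exclusion_mask=self.exclusion_mask,
            log=list(self.log),
        )
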