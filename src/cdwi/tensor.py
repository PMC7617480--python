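"""Weighted linear least-squares diffusion tensor estimation and SNR.

The estimator follows the standard two-pass WLLS scheme on log-signals:
ordinary least squares on ln S gives predicted signals, whose squares are
the weights of the second (weighted) pass — the weighting that makes the
log-linearised problem statistically efficient for Gaussian signal noise.

Because the input images are real-valued with zero-mean Gaussian noise of
known SD σ (measured from RF-free noise scans), the small-signal bias of the
log transform, E[ln(S+n)] = ln S − σ²/2S² − 3σ⁴/4S⁴ + O(σ⁶), is removed by
default with the matching series correction; samples below a noise floor of
3σ (and non-positive samples) are excluded from a voxel's fit rather than
clamped, and counted.

The module is organised as a model/results pair: build a
:class:`DiffusionTensorModel` from a :class:`~cdwi.dataset.DwiDataset`, call
``fit()``, and read estimates and diagnostics off the returned
:class:`TensorFitResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import DwiDataset

__all__ = ["DiffusionTensorModel", "TensorFitResults", "NoiseModel",
           "estimate_sigma", "snr_map", "t2_attenuation_ratio",
           "design_matrix"]


@dataclass
class NoiseModel:
    """Noise level σ (per voxel and scalar summary) in signal units."""

    sigma_map: np.ndarray | None
    sigma: float
    source: str = "noise-scans"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def estimate_sigma(noise_stack: np.ndarray) -> NoiseModel:
    """σ as the SD of the real part of RF-free noise data across repetitions.

    ``noise_stack`` is (..., n_reps) complex; the per-voxel sample SD (ddof 1)
    of the real channel forms the σ map, with the image-domain median as the
    scalar summary.
    """
    noise_stack = np.asarray(noise_stack)
    if noise_stack.shape[-1] < 2:
        raise ValueError("need at least 2 noise repetitions to estimate sigma")
    sd = np.std(noise_stack.real, axis=-1, ddof=1)
    scalar = float(np.median(sd))
    if scalar == 0:
        warnings.warn("all-zero noise stack: sigma = 0 (degenerate input)",
                      stacklevel=2)
    return NoiseModel(sigma_map=sd, sigma=scalar)


def snr_map(ds: DwiDataset, noise: NoiseModel, per_voxel_sigma: bool = True):
    """SNR(x; b, ĝ) = S̄(x; b, ĝ)/σ(x), S̄ the mean over repeats.

    Returns ``(maps, groups)``: an (nx, ny, nslice, n_groups) array and a
    DataFrame with the (b, direction) of each group.  Voxels with σ = 0 are
    masked to NaN.
    """
    sigma = (noise.sigma_map if per_voxel_sigma and noise.sigma_map is not None
             else noise.sigma)
    if np.ndim(sigma) == 0 and sigma == 0:
        raise ValueError("sigma = 0: SNR undefined")
    vols = ds.volumes.real.astype(float)
    dir_idx = (ds.dir_idx if ds.dir_idx is not None
               else np.arange(ds.n_volumes))
    keys = sorted({(b, d) for b, d in zip(ds.bvals, dir_idx)})
    maps = np.empty(vols.shape[:3] + (len(keys),))
    rows = []
    for k, (b, d) in enumerate(keys):
        sel = (ds.bvals == b) & (dir_idx == d)
        mean_sig = vols[..., sel].mean(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            snr = np.where(np.asarray(sigma) > 0, mean_sig / sigma, np.nan)
        maps[..., k] = snr
        rows.append({"b": b, "direction": d, "n_repeats": int(sel.sum())})
    return maps, pd.DataFrame(rows)


def t2_attenuation_ratio(te_a_ms: float, te_b_ms: float, t2_ms: float) -> float:
    """Signal (hence SNR) ratio exp(−(TE_a − TE_b)/T2) between two echo times."""
    if t2_ms <= 0:
        raise ValueError("t2_ms must be > 0")
    return float(np.exp(-(te_a_ms - te_b_ms) / t2_ms))


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Log-linear DTI design: ln S = X @ [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]."""
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    return np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ])


def _tensor_from_params(beta: np.ndarray) -> np.ndarray:
    """(..., 7) parameters → (..., 3, 3) symmetric tensors."""
    D = np.empty(beta.shape[:-1] + (3, 3))
    D[..., 0, 0] = beta[..., 1]
    D[..., 1, 1] = beta[..., 2]
    D[..., 2, 2] = beta[..., 3]
    D[..., 0, 1] = D[..., 1, 0] = beta[..., 4]
    D[..., 0, 2] = D[..., 2, 0] = beta[..., 5]
    D[..., 1, 2] = D[..., 2, 1] = beta[..., 6]
    return D


def _fix_eigenvector_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic sign: largest-|component| axis of each vector positive."""
    comp = np.argmax(np.abs(vecs), axis=-2)
    picked = np.take_along_axis(vecs, comp[..., None, :], axis=-2)[..., 0, :]
    sign = np.where(picked < 0, -1.0, 1.0)
    return vecs * sign[..., None, :]


class DiffusionTensorModel:
    """Voxelwise diffusion tensor model for a (preprocessed) DWI dataset.

    Parameters
    ----------
    dataset : DwiDataset
        Real-valued, registered, outlier-free volumes with b/bvec metadata.
    noise : NoiseModel, optional
        Measured noise level; enables the log-domain noise-floor correction
        and the noise-floor sample exclusion.
    min_volumes : int
        Minimum usable samples per voxel (the log-linear model has 7 free
        parameters); voxels below it are flagged unfit.
    snr_floor : float
        Samples below ``snr_floor · σ`` (σ of the possibly averaged sample)
        are excluded from that voxel's fit.
    log_bias_correction : bool
        Apply the E[ln(S+n)] series correction (needs ``noise``).
    average_repeats : bool
        Average the surviving repeats of each (b, direction) before the fit;
        the √m noise reduction keeps even the strongest-attenuation samples
        well above the noise floor, and group sizes enter the weights.
    """

    def __init__(self, dataset: DwiDataset, noise: NoiseModel | None = None,
                 min_volumes: int = 7, snr_floor: float = 3.0,
                 log_bias_correction: bool = True,
                 average_repeats: bool = True):
        if np.iscomplexobj(dataset.volumes):
            raise ValueError(
                "fit expects real-valued volumes; run phase correction first")
        self.dataset = dataset
        self.noise = noise
        self.min_volumes = int(min_volumes)
        self.snr_floor = float(snr_floor)
        self.log_bias_correction = bool(log_bias_correction)
        self.average_repeats = bool(average_repeats)
        self.X = design_matrix(dataset.bvals, dataset.bvecs)

    @classmethod
    def from_arrays(cls, volumes, bvals, bvecs, mask, **kwargs):
        ds = DwiDataset(volumes=volumes, bvals=bvals, bvecs=bvecs, mask=mask)
        return cls(ds, **kwargs)

    def _grouped_data(self):
        """Per-sample data for the fit: averaged repeat groups or raw volumes.

        Returns ``(Y, X, group_sizes)`` with Y (n_vox, n_samples) the
        (averaged) signals of masked voxels and group_sizes the number of
        volumes averaged into each sample (all ones without averaging).
        """
        ds = self.dataset
        vols = ds.volumes.astype(float)
        mask = ds.mask.astype(bool)
        if not self.average_repeats:
            return vols[mask], self.X, np.ones(ds.n_volumes)
        dir_idx = (ds.dir_idx if ds.dir_idx is not None
                   else np.arange(ds.n_volumes))
        keys = sorted({(b, d) for b, d in zip(ds.bvals, dir_idx)})
        Y = np.empty((int(mask.sum()), len(keys)))
        bvals = np.empty(len(keys))
        bvecs = np.empty((len(keys), 3))
        sizes = np.empty(len(keys))
        for k, (b, d) in enumerate(keys):
            sel = (ds.bvals == b) & (dir_idx == d)
            Y[:, k] = vols[..., sel].mean(axis=-1)[mask]
            bvals[k] = b
            bvecs[k] = ds.bvecs[np.nonzero(sel)[0][0]]
            sizes[k] = sel.sum()
        return Y, design_matrix(bvals, bvecs), sizes

    def fit(self) -> "TensorFitResults":
        ds = self.dataset
        vols = ds.volumes.astype(float)
        mask = ds.mask.astype(bool)
        vox = np.argwhere(mask)
        y_all, X, sizes = self._grouped_data()   # (n_vox, n_samples)
        sigma = self.noise.sigma if self.noise is not None else 0.0
        sigma_k = sigma / np.sqrt(sizes)          # per-sample noise SD

        floor = sigma_k * self.snr_floor if sigma > 0 else np.zeros_like(
            sigma_k)
        usable = np.isfinite(y_all) & (y_all > floor[None, :])
        n_used = usable.sum(axis=1)
        unfit = n_used < self.min_volumes
        n_excluded = int((~usable).sum())

        logy = np.full(y_all.shape, np.nan)
        pos = usable
        with np.errstate(invalid="ignore", divide="ignore"):
            logy[pos] = np.log(y_all[pos])
        if self.log_bias_correction and sigma > 0:
            r2 = (np.broadcast_to(sigma_k, y_all.shape)[pos]
                  / y_all[pos]) ** 2
            logy[pos] += 0.5 * r2 - 0.75 * r2**2

        beta = np.full((len(vox), 7), np.nan)
        resid_var = np.full(len(vox), np.nan)

        full = pos.all(axis=1) & ~unfit
        if full.any():
            beta[full], resid_var[full] = self._wlls_batch(
                X, logy[full], sizes)
        partial = ~full & ~unfit
        for i in np.nonzero(partial)[0]:
            sel = pos[i]
            b, rv = self._wlls_batch(X[sel], logy[i, sel][None, :],
                                     sizes[sel])
            beta[i], resid_var[i] = b[0], rv[0]

        shape = vols.shape[:3]
        tensors = np.zeros(shape + (3, 3))
        s0 = np.full(shape, np.nan)
        evals = np.full(shape + (3,), np.nan)
        evecs = np.full(shape + (3, 3), np.nan)
        fitted = ~unfit & np.isfinite(beta).all(axis=1)
        D = _tensor_from_params(beta[fitted])
        w_, v_ = np.linalg.eigh(D)
        order = np.argsort(w_, axis=-1)[..., ::-1]
        w_ = np.take_along_axis(w_, order, axis=-1)
        v_ = np.take_along_axis(v_, order[..., None, :], axis=-1)
        v_ = _fix_eigenvector_signs(v_)

        ix, iy, iz = vox[fitted].T
        tensors[ix, iy, iz] = D
        s0[ix, iy, iz] = np.exp(beta[fitted, 0])
        evals[ix, iy, iz] = w_
        evecs[ix, iy, iz] = v_

        unfit_map = np.zeros(shape, dtype=bool)
        unfit_map[tuple(vox[~fitted].T)] = True
        rv_map = np.full(shape, np.nan)
        rv_map[tuple(vox.T)] = resid_var
        nuse_map = np.zeros(shape, dtype=int)
        nuse_map[tuple(vox.T)] = n_used

        eps = 1e-6
        degenerate = np.zeros(shape, dtype=bool)
        degenerate[ix, iy, iz] = ((w_[:, 0] - w_[:, 1] < eps)
                                  | (w_[:, 1] - w_[:, 2] < eps))
        return TensorFitResults(
            model=self, tensors=tensors, s0=s0, evals=evals, evecs=evecs,
            mask=mask, unfit=unfit_map, degenerate=degenerate,
            residual_variance=rv_map, n_used=nuse_map,
            n_excluded_samples=n_excluded)

    @staticmethod
    def _wlls_batch(X: np.ndarray, y: np.ndarray,
                    base_w: np.ndarray | None = None):
        """Two-pass WLLS for voxels sharing a design matrix.

        Pass 1 is (base-weighted) least squares on ln S; pass 2 weights each
        sample by the squared predicted signal from pass 1 times its base
        weight (the number of repeats averaged into it, i.e. the inverse
        relative noise variance).
        """
        if base_w is None:
            base_w = np.ones(X.shape[0])
        Xw = X * base_w[:, None]
        pinv = np.linalg.pinv(Xw.T @ X) @ Xw.T
        beta1 = y @ pinv.T
        w = base_w[None, :] * np.exp(
            2.0 * np.clip(beta1 @ X.T, -700, 700))
        M = np.einsum("vn,ni,nj->vij", w, X, X)
        rhs = np.einsum("vn,ni->vi", w * y, X)
        try:
            beta = np.linalg.solve(M, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta = np.einsum("vij,vj->vi", np.linalg.pinv(M), rhs)
        resid = y - beta @ X.T
        dof = max(X.shape[0] - X.shape[1], 1)
        resid_var = np.einsum("vn,vn->v", w, resid**2) / (w.sum(axis=1)
                                                          + 1e-300) \
            * X.shape[0] / dof
        return beta, resid_var


@dataclass
class TensorFitResults:
    """Per-voxel tensor estimates, eigensystem and fit diagnostics.

    Eigenvalues are sorted descending; eigenvectors are the matching columns
    of ``evecs`` with a deterministic sign convention.  ``degenerate`` flags
    voxels where λ1−λ2 or λ2−λ3 < 1e-6 mm²/s (HA/E2A unreliable there).
    """

    model: DiffusionTensorModel
    tensors: np.ndarray
    s0: np.ndarray
    evals: np.ndarray
    evecs: np.ndarray
    mask: np.ndarray
    unfit: np.ndarray
    degenerate: np.ndarray
    residual_variance: np.ndarray
    n_used: np.ndarray
    n_excluded_samples: int

    @property
    def fitted_mask(self) -> np.ndarray:
        return self.mask & ~self.unfit

    def md_map(self) -> np.ndarray:
        md = self.evals.mean(axis=-1)
        md[~self.fitted_mask] = np.nan
        return md

    def fa_map(self) -> np.ndarray:
        lam = self.evals
        md = lam.mean(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            fa = np.sqrt(1.5 * np.sum((lam - md) ** 2, axis=-1)
                         / np.sum(lam**2, axis=-1))
        fa[~self.fitted_mask] = np.nan
        return fa

    def summary(self) -> str:
        md = self.md_map()
        fa = self.fa_map()
        ok = self.fitted_mask
        lines = [
            "Diffusion tensor WLLS fit",
            "=" * 42,
            f"voxels in mask:        {int(self.mask.sum())}",
            f"voxels fitted:         {int(ok.sum())}",
            f"voxels unfit:          {int(self.unfit.sum())}",
            f"degenerate eigenpairs: {int(self.degenerate.sum())}",
            f"samples excluded:      {self.n_excluded_samples}",
            f"MD  mean ± SD: {np.nanmean(md[ok]):.3e} ± "
            f"{np.nanstd(md[ok]):.3e} mm^2/s",
            f"FA  mean ± SD: {np.nanmean(fa[ok]):.3f} ± "
            f"{np.nanstd(fa[ok]):.3f}",
        ]
        return "\n".join(lines)
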