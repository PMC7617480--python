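"""Scalar and angular cardiac DTI metrics in the local LV frame.

Helix angle (HA): the primary eigenvector is projected onto the wall-tangent
(circumferential–longitudinal) plane; HA is the signed angle of that
projection from the circumferential axis toward the longitudinal axis, in
[−90°, 90°].  The eigenvector sign is first made canonical (non-negative
circumferential component), which also makes the map invariant to the
arbitrary sign returned by the eigendecomposition.

Secondary eigenvector angle (E2A): with the canonical e1, the cross-myocyte
in-wall direction is ĉ⊥ = normalize(r̂ × e1); E2A is the signed angle of the
projection of e2 onto the (ĉ⊥, r̂) plane from ĉ⊥ toward r̂, again sign-fixed
by antipodal symmetry of e2.  Near |HA| = 90° the canonical e1 sign (hence
the E2A sign) is ill-conditioned; such voxels keep their validity flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import LVGeometry
from .tensor import TensorFitResults

__all__ = ["MetricMaps", "helix_angle", "e2a_angle", "scalar_metrics",
           "summarize_roi", "compute_metric_maps"]

HA_HIST_BINS = np.arange(-90.0, 91.0, 10.0)


@dataclass
class MetricMaps:
    """MD, FA, HA, E2A maps for one dataset plus validity flags."""

    md: np.ndarray             # mm^2/s
    fa: np.ndarray
    ha: np.ndarray             # degrees in [-90, 90]
    e2a: np.ndarray            # degrees in [-90, 90]
    valid: np.ndarray          # voxels with a usable eigensystem
    mask: np.ndarray


def scalar_metrics(fit: TensorFitResults):
    """MD = (λ1+λ2+λ3)/3 and FA maps from the fitted eigenvalues.

    FA is √(3/2)·√(Σ(λi−MD)²/Σλi²) ∈ [0, 1] for positive-semidefinite
    tensors; all-zero tensors get FA = NaN (undefined) and MD = 0.
    """
    md = fit.evals.mean(axis=-1)
    lam = fit.evals
    ssq = np.sum(lam**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(ssq > 0,
                      np.sqrt(1.5 * np.sum((lam - md[..., None])**2, axis=-1)
                              / ssq),
                      np.nan)
    bad = ~fit.fitted_mask
    md = md.copy()
    md[bad] = np.nan
    fa[bad] = np.nan
    return md, fa


def _canonical_e1(e1: np.ndarray, geom: LVGeometry) -> np.ndarray:
    comp_c = np.sum(e1 * geom.circumferential, axis=-1)
    sign = np.where(comp_c < 0, -1.0, 1.0)
    return e1 * sign[..., None]


def helix_angle(fit: TensorFitResults, geom: LVGeometry,
                slice_index: int) -> np.ndarray:
    """HA map (degrees) for one slice; NaN where invalid."""
    e1 = _canonical_e1(fit.evecs[..., slice_index, :, 0], geom)
    comp_c = np.sum(e1 * geom.circumferential, axis=-1)
    comp_z = np.sum(e1 * geom.longitudinal, axis=-1)
    ha = np.degrees(np.arctan2(comp_z, comp_c))
    invalid = (~fit.fitted_mask[..., slice_index] | ~geom.mask
               | fit.degenerate[..., slice_index])
    ha[invalid] = np.nan
    return ha


def e2a_angle(fit: TensorFitResults, geom: LVGeometry,
              slice_index: int) -> np.ndarray:
    """E2A map (degrees) for one slice; NaN where invalid or degenerate."""
    e1 = _canonical_e1(fit.evecs[..., slice_index, :, 0], geom)
    e2 = fit.evecs[..., slice_index, :, 1]
    cperp = np.cross(geom.radial, e1)
    nrm = np.linalg.norm(cperp, axis=-1, keepdims=True)
    cperp = np.divide(cperp, nrm, out=np.zeros_like(cperp), where=nrm > 0)
    comp_cp = np.sum(e2 * cperp, axis=-1)
    comp_r = np.sum(e2 * geom.radial, axis=-1)
    sign = np.where(comp_cp < 0, -1.0, 1.0)
    e2a = np.degrees(np.arctan2(sign * comp_r, sign * comp_cp))
    invalid = (~fit.fitted_mask[..., slice_index] | ~geom.mask
               | fit.degenerate[..., slice_index]
               | (nrm[..., 0] == 0))
    e2a[invalid] = np.nan
    return e2a


def compute_metric_maps(fit: TensorFitResults,
                        geometries: list[LVGeometry]) -> MetricMaps:
    """All four metric maps over the slice stack."""
    md, fa = scalar_metrics(fit)
    shape = fit.mask.shape
    ha = np.full(shape, np.nan)
    e2a = np.full(shape, np.nan)
    for s, geom in enumerate(geometries):
        ha[..., s] = helix_angle(fit, geom, s)
        e2a[..., s] = e2a_angle(fit, geom, s)
    valid = fit.fitted_mask & ~fit.degenerate
    return MetricMaps(md=md, fa=fa, ha=ha, e2a=e2a, valid=valid,
                      mask=fit.mask)


def summarize_roi(maps: MetricMaps, exclusion_mask: np.ndarray | None = None,
                  slice_names: tuple[str, ...] | None = None):
    """Per-slice metric summaries inside the myocardium minus exclusions.

    MD and FA are reported as mean ± SD; E2A as median and interquartile
    range (25–75%, midpoint interpolation); HA as a histogram with 10° bins
    over [−90°, 90°].  Returns ``(summary DataFrame, HA histograms)``.
    """
    mask = maps.mask.astype(bool)
    if exclusion_mask is not None:
        mask = mask & ~exclusion_mask.astype(bool)
    n_slices = mask.shape[2]
    if slice_names is None:
        slice_names = tuple(str(s) for s in range(n_slices))
    rows = []
    histograms = {}
    for s in range(n_slices):
        roi = mask[..., s]
        if not roi.any():
            raise ValueError(f"empty ROI for slice {slice_names[s]!r}")
        md = maps.md[..., s][roi]
        fa = maps.fa[..., s][roi]
        e2a = maps.e2a[..., s][roi]
        ha = maps.ha[..., s][roi]
        e2a_ok = e2a[np.isfinite(e2a)]
        q25, q75 = (np.percentile(e2a_ok, [25, 75]) if len(e2a_ok)
                    else (np.nan, np.nan))
        rows.append({
            "slice": slice_names[s],
            "n_voxels": int(roi.sum()),
            "md_mean": np.nanmean(md),
            "md_sd": np.nanstd(md),
            "fa_mean": np.nanmean(fa),
            "fa_sd": np.nanstd(fa),
            "e2a_median": np.median(e2a_ok) if len(e2a_ok) else np.nan,
            "e2a_iqr_low": q25,
            "e2a_iqr_high": q75,
            "abs_e2a_mean": np.nanmean(np.abs(e2a)),
        })
        histograms[slice_names[s]] = np.histogram(
            ha[np.isfinite(ha)], bins=HA_HIST_BINS)[0]
    return pd.DataFrame(rows), histograms
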