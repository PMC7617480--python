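"""Shared fixtures: expensive designs and pipeline runs built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from cdwi import (
    DesignConstraints,
    DiffusionTensorModel,
    PhantomSpec,
    compute_metric_maps,
    estimate_sigma,
    generate_dataset,
    optimize_waveform,
    simulate_noise_scans,
)
from cdwi.design import default_timing
from cdwi.preprocess import preprocess
from cdwi.pipeline import _fit_subset

DESIGN_SETTINGS = dict(g_max=0.300, slew_max=80.0, n_timesteps=77,
                       n_restarts=3, maxwell_compensated=True)


@pytest.fixture(scope="session")
def m2_design():
    c = DesignConstraints(motion_order=2, **DESIGN_SETTINGS)
    w, report = optimize_waveform(default_timing(2), c, seed=1)
    return w, report, c


@pytest.fixture(scope="session")
def m3_design():
    c = DesignConstraints(motion_order=3, **DESIGN_SETTINGS)
    w, report = optimize_waveform(default_timing(3), c, seed=1)
    return w, report, c


@pytest.fixture(scope="session")
def noiseless_run():
    """Phantom → noise-free simulation → full pipeline → metric maps."""
    spec = PhantomSpec(seed=1)
    ds, gt, labels, sigma = generate_dataset(
        spec, seed=1, with_noise=False, with_phase=False)
    pre = preprocess(ds)
    fit = DiffusionTensorModel(pre.dataset).fit()
    maps = compute_metric_maps(fit, gt.geometry)
    return dict(spec=spec, ds=ds, gt=gt, pre=pre, fit=fit, maps=maps)


def _one_noisy_replicate(seed: int):
    spec = PhantomSpec(seed=seed)
    ds, gt, labels, sigma = generate_dataset(
        spec, seed=seed, with_noise=True, with_phase=True,
        outlier_fraction=0.02)
    noise = estimate_sigma(simulate_noise_scans(
        sigma, ds.volumes.shape[:3], n_reps=256, seed=seed + 7))
    pre = preprocess(ds, sigma=noise.sigma)
    fitcfg = {"min_volumes": 7, "log_bias_correction": True}
    fit_full = DiffusionTensorModel(pre.dataset, noise=noise).fit()
    fit_450 = _fit_subset(pre.dataset, 100.0, 450.0, noise, fitcfg)
    fit_1000 = _fit_subset(pre.dataset, 100.0, 1000.0, noise, fitcfg)
    maps = compute_metric_maps(fit_full, gt.geometry)
    return dict(spec=spec, ds=ds, gt=gt, labels=labels, sigma=sigma,
                noise=noise, pre=pre, fit=fit_full, fit_450=fit_450,
                fit_1000=fit_1000, maps=maps)


@pytest.fixture(scope="session")
def noisy_replicates():
    """Three independent noisy acquisitions at the study's SNR and scheme."""
    return [_one_noisy_replicate(seed) for seed in (101, 102, 103)]


@pytest.fixture(scope="session")
def noisy_run(noisy_replicates):
    return noisy_replicates[0]
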