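"""WLLS tensor estimation, noise-level estimation and SNR maps."""

import numpy as np
import pytest

from cdwi import (
    DiffusionTensorModel,
    DwiDataset,
    NoiseModel,
    estimate_sigma,
    simulate_noise_scans,
    snr_map,
    t2_attenuation_ratio,
)
from cdwi.design import repulsion_directions
from cdwi.tensor import design_matrix


def _synthetic_voxels(D_list, bvals, bvecs, s0=100.0):
    """Noise-free signals for a list of tensors, as a (n,1,1,V) dataset."""
    vols = np.empty((len(D_list), 1, 1, len(bvals)))
    for i, D in enumerate(D_list):
        adc = np.einsum("vi,ij,vj->v", bvecs, D, bvecs)
        vols[i, 0, 0] = s0 * np.exp(-bvals * adc)
    mask = np.ones((len(D_list), 1, 1), dtype=bool)
    return DwiDataset(volumes=vols, bvals=bvals, bvecs=bvecs, mask=mask)


@pytest.fixture(scope="module")
def scheme_vectors():
    dirs = repulsion_directions(30, seed=1)
    bvals = np.concatenate([np.full(3, 100.0), np.full(30, 1000.0)])
    bvecs = np.vstack([repulsion_directions(3, seed=2), dirs])
    return bvals, bvecs


class TestWlls:
    def test_noiseless_recovery_exact(self, scheme_vectors):
        bvals, bvecs = scheme_vectors
        rng = np.random.default_rng(0)
        Ds = []
        for _ in range(5):
            A = rng.normal(size=(3, 3))
            Ds.append(1e-3 * (A @ A.T / 10 + np.eye(3)))
        ds = _synthetic_voxels(Ds, bvals, bvecs)
        fit = DiffusionTensorModel(ds).fit()
        for i, D in enumerate(Ds):
            assert np.allclose(fit.tensors[i, 0, 0], D, rtol=1e-9,
                               atol=1e-16)
        assert np.allclose(fit.s0[:, 0, 0], 100.0, rtol=1e-9)

    def test_isotropic_md_equals_adc(self, scheme_vectors):
        bvals, bvecs = scheme_vectors
        d = 1.2e-3
        ds = _synthetic_voxels([d * np.eye(3)], bvals, bvecs)
        fit = DiffusionTensorModel(ds).fit()
        assert fit.md_map()[0, 0, 0] == pytest.approx(d, rel=1e-10)
        assert fit.fa_map()[0, 0, 0] == pytest.approx(0.0, abs=1e-8)

    def test_wlls_matches_two_pass_oracle(self, scheme_vectors):
        """Batched solver equals an explicit OLS→weighted-LS computation."""
        bvals, bvecs = scheme_vectors
        ds = _synthetic_voxels([1.1e-3 * np.eye(3)], bvals, bvecs)
        rng = np.random.default_rng(4)
        noisy = ds.volumes * np.exp(rng.normal(0, 0.05, ds.volumes.shape))
        X = design_matrix(bvals, bvecs)
        y = np.log(noisy[0, 0, 0])
        beta1 = np.linalg.lstsq(X, y, rcond=None)[0]
        w = np.exp(2.0 * X @ beta1)
        beta2 = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        beta_impl, _ = DiffusionTensorModel._wlls_batch(X, y[None, :])
        assert np.allclose(beta_impl[0], beta2, rtol=1e-9, atol=1e-12)

    def test_wlls_equals_ols_on_exact_data(self, scheme_vectors):
        """Zero residuals: the weighting cannot move the estimate off OLS."""
        bvals, bvecs = scheme_vectors
        ds = _synthetic_voxels([1.1e-3 * np.eye(3)], bvals, bvecs)
        X = design_matrix(bvals, bvecs)
        y = np.log(ds.volumes[0, 0, 0])
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        beta_w, _ = DiffusionTensorModel._wlls_batch(X, y[None, :])
        assert np.allclose(beta_w[0], beta_ols, rtol=1e-8, atol=1e-12)

    def test_rotation_equivariance(self, scheme_vectors):
        bvals, bvecs = scheme_vectors
        rng = np.random.default_rng(7)
        from scipy.stats import special_ortho_group
        R = special_ortho_group.rvs(3, random_state=rng)
        lam = np.diag([2.2e-3, 1.3e-3, 0.9e-3])
        D = lam
        ds1 = _synthetic_voxels([D], bvals, bvecs)
        ds2 = _synthetic_voxels([R @ D @ R.T], bvals, bvecs)
        f1 = DiffusionTensorModel(ds1).fit()
        f2 = DiffusionTensorModel(ds2).fit()
        assert np.allclose(R @ f1.tensors[0, 0, 0] @ R.T,
                           f2.tensors[0, 0, 0], rtol=1e-8, atol=1e-15)

    def test_md_invariant_to_s0_scaling(self, scheme_vectors):
        bvals, bvecs = scheme_vectors
        D = 1.4e-3 * np.eye(3)
        f1 = DiffusionTensorModel(
            _synthetic_voxels([D], bvals, bvecs, s0=50.0)).fit()
        f2 = DiffusionTensorModel(
            _synthetic_voxels([D], bvals, bvecs, s0=5000.0)).fit()
        assert f1.md_map()[0, 0, 0] == pytest.approx(
            f2.md_map()[0, 0, 0], rel=1e-10)

    def test_too_few_volumes_flagged_unfit(self):
        bvals = np.full(5, 450.0)
        bvecs = repulsion_directions(5, seed=3)
        ds = _synthetic_voxels([1e-3 * np.eye(3)], bvals, bvecs)
        fit = DiffusionTensorModel(ds, average_repeats=False).fit()
        assert fit.unfit[0, 0, 0]
        assert np.isnan(fit.md_map()[0, 0, 0])

    def test_voxelwise_md_bias_small_at_study_snr(self, noisy_replicates):
        """MD bias < 2% of truth pooled over >1e3 myocardial voxels."""
        errs = []
        for rep in noisy_replicates:
            md = rep["fit"].md_map()
            gt = rep["gt"]
            ok = rep["maps"].valid & gt.mask
            errs.append(md[ok] / rep["spec"].md_true - 1.0)
        pooled = np.concatenate(errs)
        assert len(pooled) > 1000
        assert abs(np.nanmean(pooled)) < 0.02

    def test_summary_mentions_fit_counts(self, noisy_run):
        text = rep_summary = noisy_run["fit"].summary()
        assert "voxels fitted" in text
        assert "MD" in text and "FA" in text


class TestNoiseEstimation:
    def test_sigma_recovered_within_10pct(self):
        stack = simulate_noise_scans(1.7, (24, 24, 3), n_reps=256, seed=2)
        nm = estimate_sigma(stack)
        assert nm.sigma == pytest.approx(1.7, rel=0.10)

    def test_linearity_in_amplitude(self):
        s1 = simulate_noise_scans(1.0, (16, 16, 1), 128, seed=3)
        nm1 = estimate_sigma(s1)
        nm2 = estimate_sigma(2.0 * s1)
        assert nm2.sigma == pytest.approx(2.0 * nm1.sigma, rel=1e-12)

    def test_all_zero_stack_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            nm = estimate_sigma(np.zeros((8, 8, 1, 4), dtype=complex))
        assert nm.sigma == 0.0

    def test_single_repetition_rejected(self):
        with pytest.raises(ValueError):
            estimate_sigma(np.zeros((8, 8, 1, 1)))


class TestSnrMap:
    def test_uniform_signal_gives_constant_snr(self):
        vols = np.full((8, 8, 1, 4), 33.0 * 1.5)
        ds = DwiDataset(volumes=vols, bvals=np.full(4, 100.0),
                        bvecs=np.tile([1.0, 0, 0], (4, 1)),
                        mask=np.ones((8, 8, 1), dtype=bool),
                        dir_idx=np.zeros(4, dtype=int))
        nm = NoiseModel(sigma_map=None, sigma=1.5)
        maps, groups = snr_map(ds, nm, per_voxel_sigma=False)
        assert np.allclose(maps, 33.0)

    def test_snr_decreases_with_b(self, noisy_run):
        maps, groups = snr_map(noisy_run["pre"].dataset, noisy_run["noise"])
        gt = noisy_run["gt"]
        med = {b: np.nanmedian(maps[..., (groups.b == b).to_numpy()][gt.mask])
               for b in (100.0, 450.0, 1000.0)}
        assert med[100.0] > med[450.0] > med[1000.0]

    def test_study_snr_level_reproduced(self, noisy_run):
        maps, groups = snr_map(noisy_run["pre"].dataset, noisy_run["noise"])
        gt = noisy_run["gt"]
        med = np.nanmedian(maps[..., (groups.b == 100.0).to_numpy()][gt.mask])
        assert med == pytest.approx(33.0, rel=0.10)

    def test_zero_sigma_rejected(self):
        vols = np.ones((4, 4, 1, 2))
        ds = DwiDataset(volumes=vols, bvals=np.full(2, 100.0),
                        bvecs=np.tile([1.0, 0, 0], (2, 1)),
                        mask=np.ones((4, 4, 1), dtype=bool))
        with pytest.raises(ValueError):
            snr_map(ds, NoiseModel(sigma_map=None, sigma=0.0),
                    per_voxel_sigma=False)


class TestT2Arithmetic:
    def test_attenuation_ratios(self):
        assert t2_attenuation_ratio(80.0, 74.0, 46.0) == pytest.approx(
            np.exp(-6.0 / 46.0))
        assert t2_attenuation_ratio(74.0, 100.0, 46.0) == pytest.approx(
            np.exp(26.0 / 46.0))
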