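# cdwi — cardiac diffusion MRI on strong-gradient systems

`cdwi` is a toolkit for in-vivo cardiac diffusion tensor imaging (DTI) with
high-performance gradient hardware (up to 300 mT/m). It covers the whole
computational chain of a spin-echo cardiac DWI study:

1. **Waveform design** — numerically optimized asymmetric diffusion-encoding
   gradient waveforms with motion compensation up to third order
   (M₂ = velocity + acceleration nulling, M₃ = + jerk nulling) and
   concomitant-field (Maxwell) compensation, maximizing the b-value under
   amplitude and slew-rate constraints.
2. **Synthetic left-ventricle data** — short-axis annular phantoms with the
   transmural helix-angle rotation of healthy myocardium, known diffusion
   tensors, complex-valued images with motion-induced phase, calibrated SNR,
   signal-dropout outliers and RF-free noise scans — so every downstream
   stage can be scored against exact ground truth.
3. **Analysis pipeline** — background-phase removal to real-valued images
   with Gaussian noise, two-pass rigid in-plane registration, shell-wise
   robust outlier rejection, weighted-linear-least-squares (WLLS) tensor
   fitting, and the cardiac metrics MD, FA, helix angle (HA) and secondary
   eigenvector angle (E2A), plus SNR maps from measured noise.
4. **Scheme comparison** — Bland–Altman limits of agreement and exact
   Wilcoxon signed-rank tests between acquisition schemes (e.g. M₂ vs M₃,
   b_max 450 vs 1000 s/mm²).

It is aimed at sequence developers and image-analysis researchers who want a
tested, reproducible reference implementation of this chain without needing
access to scanner data.

## The core quantities

A gradient waveform g(t) with the spin-echo sign convention
(g_eff = s(t)·g(t), s = +1 before the 180° pulse center, −1 after) has

- b-value  b = ∫|q(t)|² dt with q(t) = γ∫₀ᵗ g_eff(τ)dτ,
- moments  m_k = γ∫ g_eff(t)·t^k dt (nulled for all k ≤ n at order n),
- Maxwell index  ‖∫ s(t)·g(t)g(t)ᵀ dt‖_F (≈ 0 ⇒ concomitant-field phase
  cancels at the echo).

The design problem — maximize b subject to |g| ≤ g_max, |dg/dt| ≤ SR_max,
|m_k| ≤ 10⁻⁴ s^k/m and Maxwell compensation, with the encoding window
discretized into 77 timesteps — is solved with SLSQP from random restarts,
with the (effectively equality) moment constraints eliminated exactly in the
null space of the moment matrix.

The tensor is fitted per voxel from ln S = ln S₀ − b·ĝᵀDĝ by two-pass WLLS
(OLS, then weights = squared predicted signals), with a noise-floor
log-bias correction using the σ measured from RF-free noise scans. HA is
the angle of the primary eigenvector's wall-tangent projection from the
circumferential axis; E2A is the angle of the secondary eigenvector's
projection from the cross-myocyte in-wall direction toward the radial axis.

## Worked example

```python
import numpy as np
from cdwi import (DesignConstraints, optimize_waveform, scale_to_b,
                  PhantomSpec, generate_dataset, simulate_noise_scans,
                  estimate_sigma, DiffusionTensorModel, compute_metric_maps,
                  summarize_roi)
from cdwi.design import default_timing
from cdwi.preprocess import preprocess

# 1. design an acceleration-compensated waveform at TE-74-consistent timing
c = DesignConstraints(motion_order=2, n_restarts=3)
w, report = optimize_waveform(default_timing(2), c, seed=1)
print(f"M2 design: b_max = {report.b_value:.0f} s/mm^2, "
      f"max |G| = {report.max_gradient*1e3:.1f} mT/m, "
      f"max slew = {report.max_slew:.1f} T/m/s")
w1000 = scale_to_b(w, 1000.0)

# 2. simulate one subject at myocardial SNR 33 and analyse it
spec = PhantomSpec(seed=42)
ds, gt, labels, sigma = generate_dataset(spec, seed=42, outlier_fraction=0.02)
noise = estimate_sigma(simulate_noise_scans(sigma, ds.volumes.shape[:3],
                                            256, seed=49))
pre = preprocess(ds, sigma=noise.sigma)
fit = DiffusionTensorModel(pre.dataset, noise=noise).fit()
print(fit.summary())
```

prints (exact numbers for these seeds):

```
M2 design: b_max = 1579 s/mm^2, max |G| = 300.0 mT/m, max slew = 80.0 T/m/s
Diffusion tensor WLLS fit
==========================================
voxels in mask:        636
voxels fitted:         636
voxels unfit:          0
degenerate eigenpairs: 0
samples excluded:      0
MD  mean ± SD: 1.503e-03 ± 1.141e-05 mm^2/s
FA  mean ± SD: 0.340 ± 0.007
```

The designed waveform reaches b = 1579 s/mm² inside a 74 ms-echo-time
encoding window at the 300 mT/m / 80 T/m/s hardware limits; scaling it to
the study b-value of 1000 s/mm² needs only 239 mT/m. The fit on the noisy
phantom (ground truth MD 1.50×10⁻³ mm²/s, FA 0.34) recovers both metrics to
well under a percent. Per-slice metric summaries and the angular maps
follow from `compute_metric_maps(fit, gt.geometry)` and
`summarize_roi(...)`.

The same stages are exposed on the command line:

```bash
cdwi design --order 2 --b-target 1000 --seed 1 --out waveform_m2.txt
cdwi simulate --seed 42 --out sim/
cdwi run --seed 7 --out study/          # full simulate→…→compare pipeline
```

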