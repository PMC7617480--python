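# Methods

This note records the models, conventions and numerical choices behind
`cdwi`, in the order the pipeline uses them.

## Waveform design

**Problem.** A spin-echo diffusion encoding occupies two slots around the
180° pulse (pre180 / rf180 / post180). On a uniform grid of 77 timesteps
over the whole window, the gradient amplitude at every free node is chosen
to maximize b = ∫|q|²dt (q = γ∫g_eff, effective sign flipped after the
pulse center) subject to: single-axis encoding; |g| ≤ g_max (default
0.300 T/m); forward-difference slew ≤ 80 T/m/s per interval (a
stimulation-safety limit well below the amplifier capability); gradient
moments m₀…m_n below 10⁻⁴ s^k/m for the requested motion-compensation
order n; and, when enabled, a vanishing concomitant-field (Maxwell) index
‖∫s·ggᵀdt‖_F (tolerance 10⁻¹⁰ (T/m)²·s, small enough that the residual
concomitant phase across an 8 mm slice is negligible at 3 T).

**Solver.** b is a positive-semidefinite quadratic form of the amplitudes,
so maximizing it is nonconvex. The moment constraints are linear and, at
gradient scales (γ ≈ 2.675×10⁸ rad/s/T), the 10⁻⁴ threshold is an equality
for practical purposes; they are eliminated exactly by parametrizing the
free amplitudes in the null space of the (row-scaled) moment matrix, which
leaves SLSQP with the box/slew inequalities and the single quadratic
Maxwell equality. Each solve starts from a smoothed uniform-random
waveform projected into the null space; the best of `n_restarts` (default
10; the headline checks use 3) feasible restarts wins. After SLSQP a few
Newton projection steps inside the null space drive the Maxwell index to
tolerance, and one global shrink maps the solution exactly onto the
box/slew boundary (shrinking preserves moment nulling and the zeroed
Maxwell index). Equal seeds give bit-identical waveforms.

**Quadrature.** The scanner plays the sampled waveform as a
piecewise-linear function of time, so moment and Maxwell integrals are
evaluated with per-interval 3-point Gauss rules that are *exact* for
piecewise-linear g — the reported moments are then invariant under
resampling to a finer raster. Nodes whose adjacent interval overlaps the
rf180 slot are pinned to zero so the played waveform is exactly zero for
the whole pulse. b itself follows the conventional trapezoidal q-space
integration on the waveform grid (the closed-form pulsed-gradient spin-echo
value γ²G²δ²(Δ−δ/3) is reproduced to 0.1 % at 1 µs sampling, which the
test suite checks over a grid of G, δ, Δ).

**Timing.** The slot durations are free inputs. The defaults come from
spin-echo symmetry, TE = 2·pre180 + rf180 with rf180 = 7 ms, and an EPI
lead-in of 18 ms eating into the post-180 slot (post = pre − lead-in):
TE 74 ms for M₂ and 80 ms for M₃, the echo times such a system reaches at
b = 1000 s/mm². TE is reported as an estimate only — excitation, spoiler
and readout details of a real sequence are not modeled. Waveforms for
lower b-values are produced by amplitude scaling (b ∝ G²), and
`rasterize_and_balance` interpolates to the 10 µs playback raster,
appending a short trapezoidal balancing pulse if interpolation leaves a
zeroth moment above threshold.

**Direction sets.** The 3/30/30 encoding directions are generated by
electrostatic repulsion on the sphere with antipodal symmetry
(unit-arc-length annealed descent, seeded, deterministic).

## Synthetic left ventricle

Each of three independent short-axis slices (basal/mid/apical, radius
scales 1.0/0.9/0.78) is an annulus on a 48×48 grid of 2.3 mm pixels
(endo/epi radii 11/24 mm at the base — peak-systolic wall thickness).
Within the wall, transmural depth d ∈ [0,1] comes from ray-traced
endo/epi crossings; the helix angle rotates linearly, HA(d) = +60° −120°·d,
and the sheetlet angle follows a smooth deterministic azimuthal pattern
E2A(θ) = 1° + 34°·sin 2θ, whose median ≈ 1° and interquartile range ≈ ±24°
sit in the physiological systolic range. Tensor eigenvalues solve
(MD = 1.5×10⁻³ mm²/s, FA = 0.34) exactly with a fixed λ₂/λ₃ ratio of 1.4;
the ratio keeps the second eigenvector well defined so E2A is testable
(an axisymmetric λ₂ = λ₃ option exists but makes E2A degenerate). The
primary eigenvector is tilted by HA from the circumferential axis in the
wall-tangent plane, the secondary by E2A from the cross-myocyte in-wall
direction toward the radial axis.

Signals are mono-exponential, S = S₀·e^(−TE/T2)·exp(−b ĝᵀDĝ) with
T2 = 46 ms, sampled with the study scheme b = 100/450/1000 s/mm² in
3/30/30 directions with 12/6/6 repetitions (396 volumes). Motion-induced
phase is an independent second-order 2-D polynomial per image (coefficients
~ N(0, (π/2)²) on [−1,1]² coordinates, ≲3π range across the field of view);
complex Gaussian noise is calibrated so the myocardial SNR of the b = 100
images is 33 (the M₂ level; 29 for M₃ via its longer TE). Outliers
emulate the ~2 % of images discarded in quality control: randomly chosen
volumes lose 50–90 % of their signal over a random half-plane of the
myocardium. Noise-only "RF-off" stacks (default 256 repetitions) provide
the σ measurement. Everything is bit-reproducible per seed.

**What the generator does not emulate:** EPI/susceptibility distortion
(the 18 %-of-voxels exclusion masks of in-vivo work are accepted as input
masks but not synthesized), partial-volume blood or fat signal, cardiac
strain, non-Gaussian (kurtosis) diffusion, spatially varying coil
sensitivity or noise. Passing tests therefore demonstrate correctness of
the computational chain under Gaussian diffusion and stationary Gaussian
noise — not robustness to those physical confounds.

## Preprocessing

**Phase removal.** The background phase is estimated as the angle of the
Gaussian-low-passed complex image (σ_f = 2 voxels — larger than the noise
scale, smaller than the motion-phase scale) and demodulated; the real part
is kept, giving zero-mean Gaussian noise instead of Rician magnitude noise.
Three refinements matter at low SNR: (i) the pixel's own kernel
contribution is removed before taking the angle, otherwise signal-free
regions acquire a positive bias; (ii) the demodulation is iterated four
times — each pass shrinks the edge residual caused by the kernel-centroid
shift, so even steep (≈3π-range) polynomial phases are captured to better
than 1 % of the signal — with iterations beyond the first applying an
increment only where it exceeds three times its own phase-noise SD (noise
rotations must not accumulate); and (iii) since demodulating by a noisy
phase estimate attenuates the signal by E[cos δφ] ≈ exp(−σ_φ²/2) — an
SNR-dependent, hence b-dependent, loss — the applied rotations are
compensated by that factor wherever the phase estimate is informative
(σ_φ < 0.5 rad). The compensation uses the σ measured from the noise
scans and leaves background voxels untouched.

**Registration.** Two-pass in-plane rigid registration per slice exactly
in the study order: low-b volumes to one user-specified low-b volume, then
all volumes to the mean co-registered low-b image. Similarity is
normalized cross-correlation, optimized by Powell from a phase-correlation
translation initializer, with bilinear resampling in a single affine pass.
A transform is accepted only if it improves NCC by 0.05 over the
untransformed pair: aligned images of different diffusion contrast have
their NCC optimum a fraction of a voxel off center, and noise overfitting
of the three pose parameters adds spurious gains of similar size, while
genuine misalignments of ≥1 voxel gain an order of magnitude more.
Sub-quarter-voxel "corrections" are snapped to exact identity (no
resampling). Divergent solutions (>¼ field of view) are flagged and left
untransformed.

**Outlier rejection.** Per b-shell, each volume's myocardial mean
log-signal is centered on the leave-one-out median of its repeat group
(same b and direction — anisotropy makes directions genuinely differ, and
excluding the scored volume keeps the reference uncontaminated when the
group contains a corrupted image), then scored by a robust z using the
scaled MAD of the centered values pooled over the shell. Volumes with
|z| > 3 are removed; shells with fewer than 4 volumes are skipped with a
warning. The published rejection algorithm is not specified in detail;
this rule is a documented, configurable stand-in that targets the same
failure modes (dropout, misregistration).

## Tensor fit, noise and SNR

σ is the per-voxel SD of the real channel of the noise scans across
repetitions (scalar summary: image-domain median). The tensor model
ln S = ln S₀ − b ĝᵀDĝ is fitted by two-pass WLLS: ordinary least squares,
then weights equal to the squared pass-1 predicted signals. Two documented
estimator choices sit on top of the textbook scheme:

- **Repeat averaging.** Surviving repeats of each (b, direction) are
  averaged before the fit and enter the weights with their group size.
  The √m noise gain keeps even the strongest-attenuated samples well above
  the noise floor, where the log-domain series below converges fast.
- **Noise-floor log-bias correction.** For real-valued Gaussian data,
  E[ln(S+n)] = ln S − σ²/2S² − 3σ⁴/4S⁴ + O(σ⁶); observations enter the fit
  as ln X + σ²/2X² − ¾σ⁴/X⁴ with the measured σ (per averaged sample).
  Without this, the b-dependent noise floor masquerades as a b-dependence
  of MD — exactly the signature the scheme comparison must not fabricate.
  Samples below 3σ (or non-positive) are excluded from that voxel's fit
  rather than clamped, and counted; voxels with fewer than 7 usable
  samples are flagged unfit.

Eigenvalues are sorted descending; eigenvector signs are fixed
deterministically (largest-magnitude component positive); voxels with
λ₁−λ₂ or λ₂−λ₃ < 10⁻⁶ mm²/s are flagged degenerate and excluded from the
angular maps. SNR maps are S̄/σ per (b, direction) with S̄ the mean over
repeats; per-voxel or scalar σ are both supported (maps use per-voxel).

## Cardiac metrics

The local frame at each myocardial voxel is radial r̂ (from the slice's LV
center), circumferential ĉ = ẑ×r̂ and longitudinal ẑ. HA is the signed
angle of the wall-tangent projection of e₁ from ĉ toward ẑ in [−90°, 90°],
with e₁'s sign first made canonical (non-negative ĉ component) — this also
makes the map invariant to the eigensolver's arbitrary signs. E2A uses the
cross-myocyte in-wall direction ĉ⊥ = normalize(r̂×e₁) (with the canonical
e₁) and is the signed angle of e₂'s projection from ĉ⊥ toward r̂, with
e₂'s sign fixed the same way. Near |HA| = 90° the canonical e₁ sign is
ill-conditioned and the E2A sign with it; the phantom stays below ±60°.
MD and FA come from the eigenvalues in the standard way; FA of an all-zero
tensor is undefined (flagged), never clamped. ROI summaries report
mean ± SD for MD/FA, median and 25–75 % interquartile range (midpoint
interpolation) for E2A, |E2A| means for difference tables, and HA
histograms with 10° bins over [−90°, 90°] — all within the myocardial mask
minus any exclusion mask.

## Scheme comparison

Paired per-(subject, slice) metric means are compared by Bland–Altman
statistics (mean difference, SD with n−1, limits ±1.96 SD) and the
two-sided Wilcoxon signed-rank test: zero differences dropped, midranks
for ties, exact null distribution for n ≤ 25 (tie-free), normal
approximation with continuity correction above. Difference tables report
Δ, its SD, Δ % of the reference scheme and p; percentages are rounded only
in the formatted report, never in stored values. Note the signed-rank p is
invariant under increasing *affine* transforms of both arms, not under
arbitrary monotone maps (those reorder the |difference| ranks).

## Problem sizes and determinism

The bundled study conditions — 48×48×3 phantom (~640 myocardial voxels),
396 volumes, 256 noise repetitions, three replicate "subjects", and
3-restart/77-timestep designs — are the package's default experiment
scale; they make a full simulate→fit→compare cycle run in tens of seconds
while leaving Monte-Carlo error well below every tolerance the test suite
asserts. Every random stage takes an explicit seed, derived seeds stay
below 2³¹, and identical configurations produce byte-identical CSV
summaries.

## Known limitations

- TE values are estimates; pulse-sequence dead times are not modeled.
- The optimizer finds local optima; restarts mitigate but do not certify
  global optimality (the b-monotonicity property over compensation order
  is checked empirically across timing budgets).
- Registration is 2-D rigid only, as in the underlying acquisition
  protocol; through-plane motion is out of scope.
- The rejection rule operates on whole volumes; voxel-wise outlier models
  (e.g. dropout confined to a few slices of a 3-D stack) are not scored.
- The E2A sign convention is one self-consistent published-style choice;
  comparisons with other toolboxes may need a sign map.
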