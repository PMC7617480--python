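"""Numerical design of moment-nulled, Maxwell-compensated diffusion waveforms.

The design problem: on a uniform grid over the encoding window (fixed number
of timesteps), choose the gradient amplitude at every free node so that the
b-value is maximal subject to

  (i)   linear encoding (single axis; the optimizer works on the scalar
        amplitude, the direction is applied afterwards),
  (ii)  |dG/dt| <= slew_max on every interval,
  (iii) |G| <= g_max,
  (iv)  concomitant-field (Maxwell) compensation: the signed integral
        ∫ s(t) G(t)² dt vanishes, and
  (v)   effective gradient moments m_0..m_n below threshold.

b is a positive-semidefinite quadratic form of the amplitudes, so maximizing
it is a nonconvex program; it is solved with SLSQP from multiple random
smooth starts and the best restart is kept.  The moment constraints, which
are linear and (at gradient-amplitude scales) effectively equalities, are
eliminated exactly by parametrizing the amplitudes in the null space of the
moment matrix; the Maxwell equality is handled by SLSQP and polished to
tolerance with a few Newton projection steps inside that null space.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import null_space
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize

from .waveform import (
    DesignConstraints,
    GradientWaveform,
    InfeasibleDesignError,
    SequenceTiming,
    WaveformReport,
    compute_b_value,
    compute_maxwell_index,
    compute_moments,
    scale_to_b,
)

__all__ = [
    "optimize_waveform",
    "design_waveform",
    "default_timing",
    "repulsion_directions",
    "build_scheme",
    "estimate_echo_time",
]


def default_timing(motion_order: int = 2, rf180_ms: float = 7.0,
                   epi_lead_ms: float = 18.0,
                   te_ms: float | None = None) -> SequenceTiming:
    """Encoding-slot timing consistent with a spin-echo EPI echo time.

    For a spin echo the time from excitation to the 180° center equals the
    time from the 180° center to the echo, so TE = 2·pre180 + rf180 when the
    encoding starts right after excitation.  The EPI lead-in (readout time
    from the start of the readout to the k-space center) eats into the
    post-180 encoding slot: post180 = pre180 − epi_lead.

    Defaults give TE 74 ms for second-order and 80 ms for third-order motion
    compensation, matching what a 300 mT/m system achieves at b = 1000 s/mm².
    """
    if te_ms is None:
        te_ms = {0: 60.0, 1: 66.0, 2: 74.0, 3: 80.0}[motion_order]
    pre = (te_ms - rf180_ms) / 2.0
    post = pre - epi_lead_ms
    if post <= 0:
        raise InfeasibleDesignError("EPI lead-in leaves no post-180 encoding time")
    return SequenceTiming(pre180_duration=pre * 1e-3,
                          rf180_duration=rf180_ms * 1e-3,
                          post180_duration=post * 1e-3)


def estimate_echo_time(timing: SequenceTiming,
                       epi_lead_ms: float = 18.0) -> float:
    """Echo-time estimate (ms) implied by the slot durations.

    TE = 2·pre180 + rf180 provided the EPI lead-in fits in the post-180 gap
    (pre − post); otherwise the readout pushes the echo later.  This is an
    estimate: excitation and spoiler timing of a real sequence are not
    modeled.
    """
    pre = timing.pre180_duration * 1e3
    rf = timing.rf180_duration * 1e3
    post = timing.post180_duration * 1e3
    return 2.0 * max(pre, post + epi_lead_ms) + rf


class _DesignProblem:
    """Precomputed matrices for one (timing, constraints) design instance."""

    def __init__(self, timing: SequenceTiming, c: DesignConstraints):
        self.timing = timing
        self.c = c
        n = c.n_timesteps
        self.dt = timing.total_duration / n
        self.t = np.arange(n + 1) * self.dt
        lo = timing.pre180_duration
        hi = lo + timing.rf180_duration
        eps = 1e-12
        # a node is pinned to zero if either adjacent interval overlaps the
        # rf180 slot, so the piecewise-linear playback is exactly zero for
        # the whole duration of the pulse (the slot boundary need not be a
        # grid node)
        overlaps = (self.t[1:] > lo + eps) & (self.t[:-1] < hi - eps)
        fixed = np.zeros(n + 1, dtype=bool)
        fixed[:-1] |= overlaps
        fixed[1:] |= overlaps
        in_rf = (self.t >= lo - eps) & (self.t <= hi + eps)
        fixed[0] = fixed[-1] = True
        self.free = ~fixed
        self.n_free = int(self.free.sum())
        if self.n_free <= c.motion_order + 2:
            raise InfeasibleDesignError(
                "timing leaves too few free samples for the requested "
                "moment constraints")
        self.sign = np.where(self.t < timing.rf_center, 1.0, -1.0)
        self.sign[in_rf] = 0.0
        # trapezoid weights on the full grid
        w = np.full(n + 1, self.dt)
        w[0] = w[-1] = self.dt / 2.0
        self.w = w
        # cumulative-trapezoid matrix: q = gamma * C @ g_eff
        C = np.zeros((n + 1, n + 1))
        for j in range(1, n + 1):
            C[j, 0] = 0.5 * self.dt
            C[j, 1:j] = self.dt
            C[j, j] = 0.5 * self.dt
        from .waveform import _GAUSS_WT, _GAUSS_XI, GAMMA
        self.gamma = GAMMA
        Cs = C * self.sign[None, :]          # effective-sign folded in
        # b(g) = 1e-6 * gamma^2 * (Cs g)' diag(w) (Cs g)
        B_full = 1e-6 * self.gamma**2 * (Cs.T @ (w[:, None] * Cs))
        # Moment and Maxwell integrals use per-interval 3-point Gauss rules,
        # exact for the piecewise-linear waveform the scanner plays, matching
        # compute_moments / compute_maxwell_index (and invariant to later
        # raster interpolation).
        t0 = self.t[:-1]
        half = 0.5 * self.dt
        lam = 0.5 + 0.5 * _GAUSS_XI                        # (3,)
        tau = t0[:, None] + lam[None, :] * self.dt          # (n_int, 3)
        sgn = np.where(tau < timing.rf_center, 1.0, -1.0)
        wt = _GAUSS_WT[None, :] * half
        orders = np.arange(c.motion_order + 1)
        A_full = np.zeros((len(orders), n + 1))
        for k in orders:
            pk = wt * sgn * tau**k
            A_full[k, :-1] += np.sum(pk * (1.0 - lam)[None, :], axis=1)
            A_full[k, 1:] += np.sum(pk * lam[None, :], axis=1)
        A_full *= self.gamma
        # scale rows for conditioning; null space is unchanged
        T = timing.total_duration
        row_scale = self.gamma * c.g_max * T ** (orders + 1)
        A_scaled = A_full / row_scale[:, None]
        A_free = A_scaled[:, self.free]
        N = null_space(A_free)
        if N.shape[1] == 0:
            raise InfeasibleDesignError(
                "moment constraints admit only the zero waveform")
        # embed: g_full = P @ z
        P = np.zeros((n + 1, N.shape[1]))
        P[self.free, :] = N
        self.P = P
        self.nz = N.shape[1]
        self.Q = P.T @ B_full @ P            # b(z) = z' Q z  (s/mm^2)
        # slew rows: (g_{i+1} - g_i)/dt
        D = (np.diff(np.eye(n + 1), axis=0)) / self.dt
        self.S = D @ P
        # Maxwell quadratic form: ∫ s g² dt for piecewise-linear g is a
        # symmetric tridiagonal form in the samples
        ws = wt * sgn
        kll = np.sum(ws * (1.0 - lam)[None, :]**2, axis=1)
        klr = np.sum(ws * ((1.0 - lam) * lam)[None, :], axis=1)
        krr = np.sum(ws * lam[None, :]**2, axis=1)
        K = np.zeros((n + 1, n + 1))
        idx = np.arange(n)
        K[idx, idx] += kll
        K[idx + 1, idx + 1] += krr
        K[idx, idx + 1] += klr
        K[idx + 1, idx] += klr
        self.Mz = P.T @ K @ P
        self.maxwell_scale = c.g_max**2 * T

    # --- pieces used by the solver -------------------------------------
    def b_value(self, z: np.ndarray) -> float:
        return float(z @ self.Q @ z)

    def maxwell(self, z: np.ndarray) -> float:
        return float(z @ self.Mz @ z)

    def g_full(self, z: np.ndarray) -> np.ndarray:
        return self.P @ z

    def random_start(self, rng: np.random.Generator) -> np.ndarray:
        g = rng.uniform(-self.c.g_max, self.c.g_max, self.free.sum())
        g = gaussian_filter1d(g, sigma=2.0, mode="constant")
        z = self.P[self.free, :].T @ g       # orthogonal projection
        g_proj = self.g_full(z)
        peak = np.max(np.abs(g_proj))
        if peak > 0:
            z *= 0.5 * self.c.g_max / peak
        return z

    def solve_one(self, z0: np.ndarray) -> np.ndarray:
        c = self.c
        b_scale = 1000.0

        def obj(z):
            return -self.b_value(z) / b_scale

        def obj_grad(z):
            return -2.0 * (self.Q @ z) / b_scale

        cons = [
            {"type": "ineq",
             "fun": lambda z: np.concatenate([
                 c.g_max - self.P @ z, c.g_max + self.P @ z,
                 c.slew_max - self.S @ z, c.slew_max + self.S @ z]),
             "jac": lambda z: np.vstack([-self.P, self.P, -self.S, self.S])},
        ]
        if c.maxwell_compensated:
            cons.append({
                "type": "eq",
                "fun": lambda z: np.array([self.maxwell(z) / self.maxwell_scale]),
                "jac": lambda z: (2.0 * (self.Mz @ z) / self.maxwell_scale)[None, :],
            })
        res = minimize(obj, z0, jac=obj_grad, method="SLSQP",
                       constraints=cons,
                       options={"maxiter": 400, "ftol": 1e-12})
        z = res.x
        if c.maxwell_compensated:
            z = self._polish_maxwell(z)
        # SLSQP satisfies inequalities only to ~1e-8 relative; shrink the
        # amplitudes onto the box/slew boundary (moments stay nulled, the
        # Maxwell index stays at its ~0 value — both scale with z or z²)
        peak_g = np.max(np.abs(self.g_full(z)))
        peak_s = np.max(np.abs(self.S @ z))
        scale = min(1.0, c.g_max / peak_g if peak_g > 0 else 1.0,
                    c.slew_max / peak_s if peak_s > 0 else 1.0)
        return z * scale

    def _polish_maxwell(self, z: np.ndarray, n_iter: int = 12) -> np.ndarray:
        """Newton projection onto {maxwell = 0} inside the moment null space."""
        for _ in range(n_iter):
            f = self.maxwell(z)
            if abs(f) <= 0.01 * self.c.maxwell_tolerance:
                break
            grad = 2.0 * (self.Mz @ z)
            nrm2 = float(grad @ grad)
            if nrm2 == 0:
                break
            z = z - f * grad / nrm2
        return z

    def feasible(self, z: np.ndarray, tol: float = 1e-9) -> bool:
        g = self.g_full(z)
        if np.max(np.abs(g)) > self.c.g_max + tol:
            return False
        if np.max(np.abs(self.S @ z)) > self.c.slew_max + tol:
            return False
        if self.c.maxwell_compensated and \
                abs(self.maxwell(z)) > self.c.maxwell_tolerance:
            return False
        return True

    def to_waveform(self, z: np.ndarray,
                    direction: np.ndarray | None = None) -> GradientWaveform:
        if direction is None:
            direction = np.array([1.0, 0.0, 0.0])
        return GradientWaveform(samples=self.g_full(z), dt=self.dt,
                                timing=self.timing, direction=direction)


def optimize_waveform(timing: SequenceTiming, c: DesignConstraints,
                      seed: int = 0) -> tuple[GradientWaveform, WaveformReport]:
    """Maximize the b-value under the design constraints.

    Runs ``c.n_restarts`` SLSQP solves from random smooth starts and returns
    the feasible restart with the highest b-value.  Deterministic for a given
    seed.
    """
    prob = _DesignProblem(timing, c)
    best_z, best_b = None, -np.inf
    for i in range(c.n_restarts):
        rng = np.random.default_rng(np.uint32(seed) + np.uint32(i))
        z = prob.solve_one(prob.random_start(rng))
        if not prob.feasible(z):
            continue
        b = prob.b_value(z)
        if b > best_b:
            best_z, best_b = z, b
    if best_z is None or best_b <= 0:
        raise InfeasibleDesignError(
            "no restart produced a feasible nonzero waveform "
            "(moment/Maxwell constraints too tight for this timing)")
    w = prob.to_waveform(best_z)
    report = verify_waveform(w, c)
    return w, report


def verify_waveform(w: GradientWaveform, c: DesignConstraints,
                    epi_lead_ms: float = 18.0) -> WaveformReport:
    """Recompute every reported quantity from the waveform samples."""
    return WaveformReport(
        b_value=compute_b_value(w),
        moments=compute_moments(w, c.motion_order),
        maxwell_index=compute_maxwell_index(w),
        max_gradient=w.max_gradient(),
        max_slew=w.max_slew(),
        echo_time_estimate=estimate_echo_time(w.timing, epi_lead_ms),
    )


def design_waveform(c: DesignConstraints,
                    timing: SequenceTiming | None = None,
                    seed: int = 0) -> tuple[GradientWaveform, WaveformReport]:
    """Optimize, then scale down to ``c.b_target`` if one is requested."""
    if timing is None:
        timing = default_timing(c.motion_order)
    w, report = optimize_waveform(timing, c, seed=seed)
    if c.b_target is not None:
        if report.b_value < c.b_target:
            raise InfeasibleDesignError(
                f"achieved b {report.b_value:.1f} s/mm^2 below target "
                f"{c.b_target:.1f}")
        w = scale_to_b(w, c.b_target)
        report = verify_waveform(w, c)
    return w, report


# ---------------------------------------------------------------------------
# diffusion direction sets
# ---------------------------------------------------------------------------

def repulsion_directions(n: int, seed: int = 0, n_iter: int = 600,
                         step0: float = 0.1) -> np.ndarray:
    """Electrostatic-repulsion direction set (antipodally symmetric), (n, 3).

    Unit vectors are relaxed under pairwise Coulomb forces between each point
    and both the other points and their antipodes, which spreads directions
    uniformly over the half sphere.  Each iteration moves every point a
    fixed (annealed) arc length along its tangential force direction, which
    keeps the dynamics stable even when two points start close together.
    Deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    if n == 1:
        return x
    for k in range(n_iter):
        force = np.zeros_like(x)
        for sgn in (1.0, -1.0):
            d = x[:, None, :] - sgn * x[None, :, :]
            dist = np.linalg.norm(d, axis=-1)
            np.fill_diagonal(dist, np.inf)
            force += np.sum(d / np.maximum(dist, 1e-6)[..., None] ** 3,
                            axis=1)
        # tangential direction of steepest descent, unit-capped step
        force -= np.sum(force * x, axis=1, keepdims=True) * x
        nrm = np.linalg.norm(force, axis=1, keepdims=True)
        x = x + (step0 / (1 + 0.05 * k)) * force / np.maximum(nrm, 1e-12)
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    # canonical hemisphere (z >= 0, ties broken by y then x) for stable output
    flip = (x[:, 2] < 0) | ((x[:, 2] == 0) & (x[:, 1] < 0))
    x[flip] *= -1.0
    return x


def build_scheme(b_values=(100.0, 450.0, 1000.0), n_directions=(3, 30, 30),
                 n_repeats=(12, 6, 6), seed: int = 0):
    """Assemble the per-volume (b, direction, repeat) table of an acquisition.

    Returns ``(bvals, bvecs, shell_idx, dir_idx, rep_idx)`` with bvals shape
    (V,), bvecs shape (V, 3); volumes ordered shell-major, then direction,
    then repeat.
    """
    if not (len(b_values) == len(n_directions) == len(n_repeats)):
        raise ValueError("b_values, n_directions, n_repeats must align")
    bvals, bvecs, shells, dirs, reps = [], [], [], [], []
    for s, (b, nd, nr) in enumerate(zip(b_values, n_directions, n_repeats)):
        dset = repulsion_directions(nd, seed=seed + s)
        for d in range(nd):
            for r in range(nr):
                bvals.append(b)
                bvecs.append(dset[d])
                shells.append(s)
                dirs.append(d)
                reps.append(r)
    return (np.array(bvals), np.array(bvecs), np.array(shells),
            np.array(dirs), np.array(reps))
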