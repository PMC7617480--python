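"""Spin-echo diffusion gradient waveforms and their scalar measures.

A diffusion encoding waveform for a spin-echo experiment lives on a uniform
time grid spanning two encoding slots separated by the 180° refocusing pulse.
Spin phase is accrued with the *effective* gradient, i.e. the played-out
gradient with its sign flipped after the refocusing pulse.  All quantities a
scanner or a safety reviewer would ask about — b-value, gradient moments,
concomitant-field (Maxwell) index, maximum amplitude and slew rate — are
recomputable from the sampled waveform with the functions in this module.

Units are SI throughout (T/m, seconds) except b-values, which follow the
field's convention of s/mm².
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

#: proton gyromagnetic ratio, rad/s/T
GAMMA = 2.6751525e8

#: conversion factor from s/m^2 to s/mm^2
_B_TO_MM2 = 1e-6


class InvalidTimingError(ValueError):
    """Waveform grid and sequence timing are inconsistent."""


class InfeasibleDesignError(RuntimeError):
    """No waveform satisfies the requested constraints."""


class WaveformParseError(ValueError):
    """A waveform text file could not be parsed."""


@dataclass(frozen=True)
class SequenceTiming:
    """Timing of the diffusion encoding window of a spin-echo sequence.

    The encoding window is split into three contiguous slots: the interval
    before the 180° pulse, the 180° pulse itself (no encoding gradients), and
    the interval after it, ``[0, pre180) ∪ [pre180, pre180+rf180) ∪ rest``.

    Parameters
    ----------
    pre180_duration, rf180_duration, post180_duration : float
        Slot durations in seconds.
    raster_time : float
        Scanner playback raster in seconds (default 10 µs).
    """

    pre180_duration: float
    rf180_duration: float
    post180_duration: float
    raster_time: float = 10e-6

    def __post_init__(self) -> None:
        for name in ("pre180_duration", "rf180_duration", "post180_duration",
                     "raster_time"):
            if getattr(self, name) <= 0:
                raise InvalidTimingError(f"{name} must be > 0")

    @property
    def total_duration(self) -> float:
        return self.pre180_duration + self.rf180_duration + self.post180_duration

    @property
    def rf_center(self) -> float:
        return self.pre180_duration + 0.5 * self.rf180_duration


@dataclass(frozen=True)
class DesignConstraints:
    """Hardware and encoding constraints for waveform optimization.

    ``motion_order`` n requests nulling of all effective gradient moments
    m_0 … m_n (n = 1 removes velocity sensitivity, 2 acceleration, 3 jerk).
    ``maxwell_compensated`` additionally forces the concomitant-field index
    of the asymmetric waveform to (numerically) zero.
    """

    g_max: float = 0.300                 # T/m
    slew_max: float = 80.0               # T/m/s
    motion_order: int = 2
    moment_threshold: float = 1e-4       # s^k/m, applies to every order k <= n
    maxwell_compensated: bool = True
    maxwell_tolerance: float = 1e-10     # (T/m)^2 s
    n_timesteps: int = 77
    n_restarts: int = 10
    b_target: float | None = None        # s/mm^2, None = maximize

    def __post_init__(self) -> None:
        if self.g_max <= 0 or self.slew_max <= 0:
            raise ValueError("g_max and slew_max must be > 0")
        if self.motion_order not in (0, 1, 2, 3):
            raise ValueError("motion_order must be in {0, 1, 2, 3}")
        if self.moment_threshold <= 0:
            raise ValueError("moment_threshold must be > 0")
        if self.n_timesteps < 10:
            raise ValueError("n_timesteps must be >= 10")


@dataclass
class GradientWaveform:
    """Time-sampled diffusion gradient along a single encoding axis.

    ``samples[i]`` is the gradient amplitude (T/m) at time ``i * dt`` on a
    uniform grid covering the whole encoding window.  Samples are zero inside
    the rf180 slot and at both ends of the grid.
    """

    samples: np.ndarray
    dt: float
    timing: SequenceTiming
    direction: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    gamma: float = GAMMA

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        nrm = np.linalg.norm(self.direction)
        if not np.isclose(nrm, 1.0, atol=1e-8):
            raise ValueError("direction must be a unit vector")
        t_end = (len(self.samples) - 1) * self.dt
        if t_end < self.timing.pre180_duration + self.timing.rf180_duration - 1e-12:
            raise InvalidTimingError(
                "waveform grid does not cover the rf180 slot")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt

    def rf_slot_mask(self, eps: float = 1e-12) -> np.ndarray:
        t = self.times
        lo = self.timing.pre180_duration
        hi = lo + self.timing.rf180_duration
        return (t >= lo - eps) & (t <= hi + eps)

    def effective_sign(self) -> np.ndarray:
        """+1 before the center of the 180° pulse, −1 after."""
        return np.where(self.times < self.timing.rf_center, 1.0, -1.0)

    def max_gradient(self) -> float:
        return float(np.max(np.abs(self.samples)))

    def max_slew(self) -> float:
        """Maximum |dG/dt| by forward differences over grid intervals."""
        return float(np.max(np.abs(np.diff(self.samples))) / self.dt)


@dataclass(frozen=True)
class WaveformReport:
    """Verification summary for a designed waveform (all recomputable)."""

    b_value: float                 # s/mm^2
    moments: np.ndarray            # m_0..m_n, s^k/m
    maxwell_index: float           # (T/m)^2 s
    max_gradient: float            # T/m
    max_slew: float                # T/m/s
    echo_time_estimate: float      # ms


def effective_gradient(w: GradientWaveform) -> np.ndarray:
    """Gradient with the spin-echo sign convention applied.

    Returns s(t)·g(t) with s(t) = +1 before the midpoint of the rf180 slot
    and −1 after; exactly zero inside the rf180 slot.
    """
    g = w.samples * w.effective_sign()
    g[w.rf_slot_mask()] = 0.0
    return g


def compute_b_value(w: GradientWaveform) -> float:
    """Diffusion weighting b = ∫|q(t)|² dt in s/mm².

    q(t) = γ ∫₀ᵗ g_eff(τ) dτ; integrals are trapezoidal on the waveform grid.
    """
    geff = effective_gradient(w)
    q = w.gamma * cumulative_trapezoid(geff, dx=w.dt, initial=0.0)
    return float(np.trapezoid(q * q, dx=w.dt) * _B_TO_MM2)


#: 3-point Gauss-Legendre nodes/weights on [-1, 1]; exact through degree 5,
#: i.e. exact for (linear waveform) x t^k up to k = 4 and for squared
#: waveforms, so sampled-waveform integrals below are exact for the
#: piecewise-linear gradient the scanner actually plays.
_GAUSS_XI = np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)])
_GAUSS_WT = np.array([5.0, 8.0, 5.0]) / 9.0


def _gauss_eval(w: GradientWaveform):
    """Gauss nodes over each grid interval: times, interpolated g, sign, weights."""
    t = w.times
    g = w.samples.copy()
    g[w.rf_slot_mask()] = 0.0
    t0, t1 = t[:-1], t[1:]
    mid = 0.5 * (t0 + t1)
    half = 0.5 * w.dt
    tau = mid[:, None] + _GAUSS_XI[None, :] * half          # (n_int, 3)
    lam = (tau - t0[:, None]) / w.dt
    gtau = g[:-1, None] * (1.0 - lam) + g[1:, None] * lam
    sign = np.where(tau < w.timing.rf_center, 1.0, -1.0)
    wt = _GAUSS_WT[None, :] * half
    return tau, gtau, sign, wt


def compute_moments(w: GradientWaveform, max_order: int) -> np.ndarray:
    """Effective gradient moments m_k = γ ∫ g_eff(t) t^k dt, k = 0..max_order.

    Time origin at waveform start; units s^k/m.  The integral is evaluated
    exactly for the piecewise-linear waveform defined by the samples, so the
    moments are invariant under resampling to a finer raster.
    """
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    tau, gtau, sign, wt = _gauss_eval(w)
    return np.array([
        w.gamma * float(np.sum(wt * sign * gtau * tau**k))
        for k in range(max_order + 1)
    ])


def compute_maxwell_index(w: GradientWaveform) -> float:
    """Concomitant-field (Maxwell) index √Tr(M Mᵀ), (T/m)²·s.

    M = ∫ s(t) g(t) g(t)ᵀ dt with g the 3-vector waveform.  For a linear
    (single-axis) encoding g(t) = G(t)·d̂ this reduces to |∫ s(t) G(t)² dt|,
    evaluated exactly for the piecewise-linear waveform.  A small index means
    the concomitant phase of the two encoding slots cancels at the echo.
    """
    _, gtau, sign, wt = _gauss_eval(w)
    m_scalar = float(np.sum(wt * sign * gtau**2))
    M = m_scalar * np.outer(w.direction, w.direction)
    return float(np.sqrt(np.trace(M @ M.T)))


def scale_to_b(w: GradientWaveform, b_target: float) -> GradientWaveform:
    """Scale amplitudes (shape and timing fixed) so the b-value is b_target.

    Because b ∝ G², the scale factor is √(b_target/b).  Moment nulling is
    preserved (moments are linear in amplitude).
    """
    b = compute_b_value(w)
    if b_target > b * (1 + 1e-9):
        raise ValueError(
            f"b_target {b_target:.6g} exceeds waveform b-value {b:.6g} s/mm^2")
    if b == 0:
        raise ValueError("cannot rescale an all-zero waveform")
    scale = np.sqrt(b_target / b)
    return replace(w, samples=w.samples * scale)


def _balancing_pulse(area: float, g_max: float, slew_max: float,
                     raster: float) -> np.ndarray:
    """Trapezoidal pulse of given signed area on the raster grid."""
    a_abs = abs(area)
    sign = 1.0 if area >= 0 else -1.0
    # triangle if the area is reachable before hitting g_max
    amp_tri = np.sqrt(a_abs * slew_max)
    if amp_tri <= g_max:
        ramp_n = max(int(np.ceil(amp_tri / (slew_max * raster))), 1)
        amp = a_abs / (ramp_n * raster)  # exact area with this ramp count
        up = np.linspace(0.0, amp, ramp_n + 1)
        shape = np.concatenate([up, up[-2::-1]])
    else:
        ramp_n = max(int(np.ceil(g_max / (slew_max * raster))), 1)
        flat_time = a_abs / g_max - ramp_n * raster
        flat_n = max(int(np.ceil(flat_time / raster)), 0)
        up = np.linspace(0.0, g_max, ramp_n + 1)
        shape = np.concatenate([up, np.full(flat_n, g_max), up[-2::-1]])
        # trim amplitude so the trapezoid area is exact
        shape *= a_abs / (np.trapezoid(shape, dx=raster))
    return sign * shape


def rasterize_and_balance(w: GradientWaveform, raster: float | None = None,
                          moment_threshold: float = 1e-4,
                          g_max: float = 0.300, slew_max: float = 80.0,
                          max_extension: float = 2e-3) -> GradientWaveform:
    """Linear interpolation to the scanner raster plus zeroth-moment balancing.

    The optimized waveform is resampled linearly to the playback raster; this
    resampled waveform is the one whose b-value counts.  If interpolation
    leaves a residual zeroth moment above ``moment_threshold``, a short
    trapezoidal balancing pulse is appended after the post-180 slot (within
    ``max_extension`` seconds, respecting g_max and slew_max) to null it.
    """
    if raster is None:
        raster = w.timing.raster_time
    if raster <= 0:
        raise ValueError("raster must be > 0")
    total = (len(w.samples) - 1) * w.dt
    n = int(round(total / raster))
    t_new = np.arange(n + 1) * raster
    samples = np.interp(t_new, w.times, w.samples)
    samples[0] = 0.0
    samples[-1] = 0.0
    out = GradientWaveform(samples=samples, dt=raster, timing=w.timing,
                           direction=w.direction, gamma=w.gamma)
    m0 = compute_moments(out, 0)[0]
    if abs(m0) <= moment_threshold:
        return out
    # the pulse sits after the 180°, where the effective sign is −1:
    # m0_new = m0 − γ·area  =>  area = m0/γ
    pulse = _balancing_pulse(m0 / w.gamma, g_max, slew_max, raster)
    if (len(pulse) - 1) * raster > max_extension:
        raise InfeasibleDesignError(
            "balancing pulse does not fit in the remaining slot "
            f"(needs {(len(pulse) - 1) * raster * 1e3:.3f} ms)")
    samples = np.concatenate([samples, pulse[1:]])
    timing = replace(w.timing,
                     post180_duration=w.timing.post180_duration
                     + (len(pulse) - 1) * raster)
    out = GradientWaveform(samples=samples, dt=raster, timing=timing,
                           direction=w.direction, gamma=w.gamma)
    m0 = compute_moments(out, 0)[0]
    if abs(m0) > moment_threshold:
        raise InfeasibleDesignError(
            f"balancing failed: residual m0 = {m0:.3e} s^0/m")
    return out


def export_waveform(w: GradientWaveform, path, g_max: float = 0.300,
                    b_nominal: float | None = None) -> None:
    """Write a waveform text file: '#' header lines, then g/g_max per line."""
    if b_nominal is None:
        b_nominal = compute_b_value(w)
    header = [
        "# cdwi gradient waveform",
        f"# dt_s: {w.dt!r}",
        f"# pre180_s: {w.timing.pre180_duration!r}",
        f"# rf180_s: {w.timing.rf180_duration!r}",
        f"# post180_s: {w.timing.post180_duration!r}",
        f"# raster_s: {w.timing.raster_time!r}",
        f"# g_max_T_m: {g_max!r}",
        f"# b_nominal_s_mm2: {b_nominal!r}",
        "# direction: " + " ".join(repr(float(x)) for x in w.direction),
    ]
    body = [repr(float(x)) for x in w.samples / g_max]
    with open(path, "w") as fh:
        fh.write("\n".join(header + body) + "\n")


def read_waveform(path) -> GradientWaveform:
    """Read a waveform text file written by :func:`export_waveform`."""
    meta: dict[str, str] = {}
    samples: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line[1:].partition(":")
                    meta[key.strip()] = val.strip()
                continue
            try:
                samples.append(float(line))
            except ValueError as exc:
                raise WaveformParseError(
                    f"{path}: non-numeric waveform sample on line {lineno}: "
                    f"{line!r}") from exc
    try:
        g_max = float(meta["g_max_T_m"])
        timing = SequenceTiming(
            pre180_duration=float(meta["pre180_s"]),
            rf180_duration=float(meta["rf180_s"]),
            post180_duration=float(meta["post180_s"]),
            raster_time=float(meta["raster_s"]),
        )
        dt = float(meta["dt_s"])
        direction = np.array([float(x) for x in meta["direction"].split()])
    except KeyError as exc:
        raise WaveformParseError(f"{path}: missing header field {exc}") from exc
    return GradientWaveform(samples=np.asarray(samples) * g_max, dt=dt,
                            timing=timing, direction=direction)
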