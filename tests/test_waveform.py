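"""Waveform measures: effective gradient, b-value, moments, Maxwell index."""

import numpy as np
import pytest

from cdwi import (
    GAMMA,
    GradientWaveform,
    SequenceTiming,
    compute_b_value,
    compute_maxwell_index,
    compute_moments,
    effective_gradient,
    export_waveform,
    rasterize_and_balance,
    read_waveform,
    scale_to_b,
)
from cdwi.waveform import InvalidTimingError, WaveformParseError


def _pgse(G, delta, Delta, dt=1e-6):
    """Rectangular pulsed-gradient spin echo on a fine grid."""
    total = Delta + delta + 3e-3
    gap_mid = (Delta + delta) / 2.0
    timing = SequenceTiming(pre180_duration=gap_mid - 1e-3,
                            rf180_duration=2e-3,
                            post180_duration=total - gap_mid - 1e-3)
    t = np.arange(0, total + dt / 2, dt)
    g = np.where((t < delta) | ((t >= Delta) & (t < Delta + delta)), G, 0.0)
    g[0] = g[-1] = 0.0
    return GradientWaveform(samples=g, dt=dt, timing=timing)


def _symmetric_lobes(G=0.1, dt=1e-4):
    """Identical rectangular lobes mirror-symmetric about the 180 center.

    Built by sample index so the post-180 lobe is the exact mirror of the
    pre-180 lobe (total duration 24 ms, rf slot 10–14 ms).
    """
    timing = SequenceTiming(pre180_duration=10e-3, rf180_duration=4e-3,
                            post180_duration=10e-3)
    n = round(timing.total_duration / dt)
    g = np.zeros(n + 1)
    i0, i1 = round(1e-3 / dt), round(9e-3 / dt)
    g[i0:i1 + 1] = G
    g[n - i1:n - i0 + 1] = G
    g[0] = g[-1] = 0.0
    return GradientWaveform(samples=g, dt=dt, timing=timing)


class TestEffectiveGradient:
    def test_sign_flips_after_refocusing(self):
        w = _symmetric_lobes()
        geff = effective_gradient(w)
        t = w.times
        assert np.all(geff[(t > 1e-3) & (t < 9e-3)] >= 0)
        assert np.all(geff[(t > 15e-3) & (t < 23e-3)] <= 0)
        assert np.any(geff > 0) and np.any(geff < 0)

    def test_zero_waveform_zero_effective(self):
        w = _symmetric_lobes(G=0.0)
        assert np.all(effective_gradient(w) == 0)

    def test_pre_only_lobe_passes_through(self):
        w = _symmetric_lobes()
        g = w.samples.copy()
        g[w.times > 12e-3] = 0.0
        w2 = GradientWaveform(samples=g, dt=w.dt, timing=w.timing)
        geff = effective_gradient(w2)
        pre = w2.times < 10e-3
        assert np.allclose(geff[pre], g[pre])
        assert np.all(geff[~pre] == 0)

    def test_grid_not_covering_rf_slot_is_invalid(self):
        timing = SequenceTiming(pre180_duration=10e-3, rf180_duration=5e-3,
                                post180_duration=10e-3)
        with pytest.raises(InvalidTimingError):
            GradientWaveform(samples=np.zeros(50), dt=1e-4, timing=timing)


class TestBValue:
    @pytest.mark.parametrize("G,delta,Delta", [
        (0.080, 10e-3, 20e-3),
        (0.300, 8e-3, 16e-3),
        (0.300, 5e-3, 30e-3),
        (0.150, 15e-3, 25e-3),
    ])
    def test_pgse_closed_form(self, G, delta, Delta):
        """b of rectangular PGSE matches γ²G²δ²(Δ−δ/3) within 0.1%."""
        w = _pgse(G, delta, Delta)
        b = compute_b_value(w)
        b_cf = GAMMA**2 * G**2 * delta**2 * (Delta - delta / 3) * 1e-6
        assert b == pytest.approx(b_cf, rel=1e-3)

    def test_zero_waveform(self):
        assert compute_b_value(_symmetric_lobes(G=0.0)) == 0.0

    def test_quadratic_amplitude_scaling(self):
        w = _pgse(0.1, 8e-3, 16e-3)
        b1 = compute_b_value(w)
        w2 = GradientWaveform(samples=3.0 * w.samples, dt=w.dt,
                              timing=w.timing)
        assert compute_b_value(w2) == pytest.approx(9.0 * b1, rel=1e-12)

    def test_time_reversal_invariance(self):
        w = _symmetric_lobes()
        b1 = compute_b_value(w)
        w2 = GradientWaveform(samples=w.samples[::-1].copy(), dt=w.dt,
                              timing=w.timing)
        assert compute_b_value(w2) == pytest.approx(b1, rel=1e-9)


class TestMoments:
    def test_zero_waveform_zero_moments(self):
        m = compute_moments(_symmetric_lobes(G=0.0), 3)
        assert np.all(m == 0)

    def test_monopolar_lobe_not_nulled(self):
        w = _symmetric_lobes()
        g = w.samples.copy()
        g[w.times > 12e-3] = 0.0
        w2 = GradientWaveform(samples=g, dt=w.dt, timing=w.timing)
        assert abs(compute_moments(w2, 0)[0]) > 1.0

    def test_symmetric_lobes_null_m0(self):
        # equal lobes + sign flip => zeroth moment cancels
        m0 = compute_moments(_symmetric_lobes(), 0)[0]
        assert abs(m0) < 1e-6

    def test_moments_scale_linearly(self):
        w = _symmetric_lobes()
        m1 = compute_moments(w, 2)
        w2 = GradientWaveform(samples=0.5 * w.samples, dt=w.dt,
                              timing=w.timing)
        assert np.allclose(compute_moments(w2, 2), 0.5 * m1)


class TestMaxwellIndex:
    def test_symmetric_lobes_cancel(self):
        assert compute_maxwell_index(_symmetric_lobes()) < 1e-12

    def test_monopolar_lobe_positive(self):
        w = _symmetric_lobes(G=0.2)
        g = w.samples.copy()
        g[w.times > 12e-3] = 0.0
        w2 = GradientWaveform(samples=g, dt=w.dt, timing=w.timing)
        idx = compute_maxwell_index(w2)
        # oracle: the same integral on a 100x-refined grid of the
        # piecewise-linear waveform
        tf = np.arange(0, w2.times[-1] + 1e-6 / 2, 1e-6)
        gf = np.interp(tf, w2.times, g * (w2.times < 12e-3))
        expected = np.trapezoid(gf**2, dx=1e-6)
        assert idx == pytest.approx(expected, rel=1e-4)


class TestScaleToB:
    def test_scale_down_to_target(self):
        w = _pgse(0.3, 8e-3, 16e-3)
        ws = scale_to_b(w, 100.0)
        assert compute_b_value(ws) == pytest.approx(100.0, rel=1e-3)
        assert np.max(np.abs(ws.samples)) < np.max(np.abs(w.samples))

    def test_identity_at_current_b(self):
        w = _pgse(0.1, 8e-3, 16e-3)
        b = compute_b_value(w)
        ws = scale_to_b(w, b)
        assert np.allclose(ws.samples, w.samples)

    def test_target_above_current_raises(self):
        w = _pgse(0.1, 8e-3, 16e-3)
        with pytest.raises(ValueError):
            scale_to_b(w, 10 * compute_b_value(w))

    def test_moments_scale_with_amplitude(self):
        w = _symmetric_lobes()
        b = compute_b_value(w)
        ws = scale_to_b(w, b / 4.0)
        assert np.allclose(compute_moments(ws, 2),
                           0.5 * compute_moments(w, 2), atol=1e-10)


class TestRasterizeAndBalance:
    def test_already_on_raster_identity(self):
        w = _symmetric_lobes(dt=1e-5)
        out = rasterize_and_balance(w, raster=1e-5)
        assert np.allclose(out.samples, w.samples)
        assert len(out.samples) == len(w.samples)

    def test_balancing_pulse_restores_m0(self):
        # craft a waveform with deliberately unbalanced zeroth moment
        w = _symmetric_lobes()
        g = w.samples.copy()
        g[(w.times > 15e-3) & (w.times < 23e-3)] *= 0.95   # weaken post lobe
        w2 = GradientWaveform(samples=g, dt=w.dt, timing=w.timing)
        assert abs(compute_moments(w2, 0)[0]) > 1e-4
        out = rasterize_and_balance(w2, raster=1e-5)
        assert abs(compute_moments(out, 0)[0]) <= 1e-4
        assert len(out.samples) > round(w.timing.total_duration / 1e-5) + 1

    def test_interpolation_without_residual_keeps_length(self):
        w = _symmetric_lobes(dt=2e-5)
        out = rasterize_and_balance(w, raster=1e-5)
        assert abs(compute_moments(out, 0)[0]) <= 1e-4
        assert len(out.samples) == round(w.timing.total_duration / 1e-5) + 1


class TestWaveformFileRoundTrip:
    def test_round_trip_exact(self, tmp_path):
        w = _symmetric_lobes()
        path = tmp_path / "wave.txt"
        export_waveform(w, path, g_max=0.3)
        w2 = read_waveform(path)
        assert np.allclose(w2.samples, w.samples, atol=1e-12)
        assert w2.dt == w.dt
        assert w2.timing == w.timing

    def test_zero_waveform_file(self, tmp_path):
        w = _symmetric_lobes(G=0.0)
        path = tmp_path / "zero.txt"
        export_waveform(w, path)
        w2 = read_waveform(path)
        assert np.all(w2.samples == 0)

    def test_non_numeric_line_reports_lineno(self, tmp_path):
        w = _symmetric_lobes()
        path = tmp_path / "bad.txt"
        export_waveform(w, path)
        lines = path.read_text().splitlines()
        lines[15] = "not-a-number"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(WaveformParseError, match="line 16"):
            read_waveform(path)
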