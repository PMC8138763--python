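"""Hilbert phase analysis: closed-form oracles and circular statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gqsignal.phase_sync import (
    GridMismatchError,
    ZeroAmplitudeError,
    circular_mean_deg,
    instantaneous_phase,
    phase_coherence,
    phase_difference,
    population_phase_summary,
)

from conftest import make_trace


def sine_trace(f=0.01, duration=600.0, rate=2.0, amplitude=1.0, phase=0.0):
    t = np.arange(0.0, duration, 1.0 / rate)
    offset = amplitude + 1.0   # keep intensities nonnegative
    return make_trace(t, amplitude * np.sin(2 * np.pi * f * t + phase) + offset)


class TestInstantaneousPhase:
    def test_sinusoid_phase_slope_matches_frequency(self):
        """The unwrapped phase of sin(2 pi f t) advances at 2 pi f rad/s
        (checked on the interior 80% of samples, within 1%)."""
        f = 0.01
        ps = instantaneous_phase(sine_trace(f=f))
        core = ps.interior
        slope = np.polyfit(ps.time[core], ps.phase_unwrapped[core], 1)[0]
        assert abs(slope - 2 * np.pi * f) / (2 * np.pi * f) < 0.01

    def test_quadrature_pair_differs_by_90_degrees(self):
        f, t = 0.01, np.arange(0.0, 600.0, 0.5)
        cos_tr = make_trace(t, 2.0 + np.cos(2 * np.pi * f * t))
        sin_tr = make_trace(t, 2.0 + np.sin(2 * np.pi * f * t))
        pc = instantaneous_phase(cos_tr, detrend="mean")
        psn = instantaneous_phase(sin_tr, detrend="mean")
        res = phase_difference(pc, psn)
        assert abs(res.mean_pd - 90.0) < 2.0

    def test_envelope_recovers_amplitude(self):
        amp = 3.7
        ps = instantaneous_phase(sine_trace(amplitude=amp), detrend="mean")
        core = ps.amplitude[ps.interior]
        assert np.all(np.abs(core - amp) / amp < 0.02)

    def test_constant_trace_rejected(self):
        t = np.arange(0.0, 30.0, 0.5)
        with pytest.raises(ZeroAmplitudeError):
            instantaneous_phase(make_trace(t, np.full_like(t, 5.0)))

    def test_nonuniform_grid_rejected(self):
        t = np.concatenate([np.arange(0.0, 10.0, 0.5),
                            np.arange(10.0, 30.0, 1.0)])
        with pytest.raises(ValueError):
            instantaneous_phase(make_trace(t, np.sin(t) + 2))

    def test_matches_direct_dft_analytic_signal(self):
        """Cross-check against an explicitly constructed DFT analytic
        signal (zero negative frequencies) on a random band-limited
        signal, with padding and detrending disabled."""
        rng = np.random.default_rng(0)
        n = 512
        spec = np.zeros(n, dtype=complex)
        idx = np.arange(3, 20)
        spec[idx] = rng.normal(size=idx.size) + 1j * rng.normal(size=idx.size)
        x = np.real(np.fft.ifft(spec))
        x -= x.mean()
        tr = make_trace(np.arange(n) * 0.5, x + 10.0)  # offset for positivity

        ps = instantaneous_phase(tr, detrend="mean", pad_frac=0.0)

        h = np.fft.fft(x)
        h[1:(n + 1) // 2] *= 2.0
        h[(n // 2) + 1:] = 0.0
        oracle_phase = np.angle(np.fft.ifft(h))
        core = ps.interior
        dev = np.angle(np.exp(1j * (ps.phase_wrapped[core]
                                    - oracle_phase[core])))
        assert np.max(np.abs(dev)) < 1e-6


class TestPhaseDifference:
    def test_self_pair_is_zero_with_unit_coherence(self):
        ps = instantaneous_phase(sine_trace())
        res = phase_difference(ps, ps)
        assert res.mean_pd == pytest.approx(0.0, abs=1e-9)
        assert res.pd_dispersion == pytest.approx(0.0, abs=1e-6)
        assert res.coherence_r == pytest.approx(1.0, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        a = instantaneous_phase(sine_trace(duration=600.0))
        b = instantaneous_phase(sine_trace(duration=500.0))
        with pytest.raises(GridMismatchError):
            phase_difference(a, b)

    def test_absolute_convention_folds_to_180(self):
        f, t = 0.01, np.arange(0.0, 600.0, 0.5)
        x = instantaneous_phase(make_trace(t, 2 + np.sin(2 * np.pi * f * t)),
                                detrend="mean")
        y = instantaneous_phase(
            make_trace(t, 2 + np.sin(2 * np.pi * f * t + np.radians(80))),
            detrend="mean")
        res = phase_difference(x, y, convention="absolute")
        assert 0.0 <= res.mean_pd <= 180.0
        assert abs(res.mean_pd - 80.0) < 3.0

    def test_time_reversal_leaves_summary_invariant(self):
        f, t = 0.008, np.arange(0.0, 600.0, 0.5)
        xa = 2 + np.sin(2 * np.pi * f * t)
        ya = 2 + np.sin(2 * np.pi * f * t + 0.7)
        fwd = phase_difference(
            instantaneous_phase(make_trace(t, xa), detrend="mean"),
            instantaneous_phase(make_trace(t, ya), detrend="mean"))
        rev = phase_difference(
            instantaneous_phase(make_trace(t, xa[::-1]), detrend="mean"),
            instantaneous_phase(make_trace(t, ya[::-1]), detrend="mean"))
        d_fwd = min(fwd.mean_pd, 360 - fwd.mean_pd)
        d_rev = min(rev.mean_pd, 360 - rev.mean_pd)
        assert abs(d_fwd - d_rev) < 2.0
        assert abs(fwd.coherence_r - rev.coherence_r) < 0.02


class TestCoherence:
    def test_constant_pd_gives_unity(self):
        assert phase_coherence(np.full(100, 123.4)) == pytest.approx(1.0)

    def test_antipodal_clusters_cancel(self):
        pd = np.concatenate([np.full(50, 10.0), np.full(50, 190.0)])
        assert phase_coherence(pd) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_null_is_small(self):
        rng = np.random.default_rng(5)
        hits = sum(
            phase_coherence(rng.uniform(0, 360, 10_000)) < 0.05
            for _ in range(50)
        )
        assert hits >= 49

    @given(shift=st.floats(min_value=-720.0, max_value=720.0))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_rotation_invariance(self, shift):
        rng = np.random.default_rng(9)
        pd = rng.uniform(0, 360, 500)
        assert phase_coherence(pd + shift) == pytest.approx(
            phase_coherence(pd), abs=1e-9)


class TestPopulationSummary:
    def test_close_angles_average_arithmetically(self):
        res = [_fake_result(a) for a in (10.0, 20.0, 30.0)]
        summary = population_phase_summary(res)
        assert summary.mean_pd == pytest.approx(20.0, abs=1e-9)
        assert summary.n_cells == 3

    def test_wraparound_average(self):
        summary = population_phase_summary(
            [_fake_result(359.0), _fake_result(1.0)])
        assert min(summary.mean_pd, 360 - summary.mean_pd) < 1e-9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            population_phase_summary([])

    def test_circular_mean_helper(self):
        assert circular_mean_deg(np.array([359.0, 1.0])) == pytest.approx(
            0.0, abs=1e-9)


def _fake_result(mean_pd):
    from gqsignal.phase_sync import PhaseSyncResult
    return PhaseSyncResult(
        time=np.arange(3.0), pd_series=np.full(3, mean_pd),
        mean_pd=mean_pd, pd_dispersion=0.0, coherence_r=1.0,
        unit_circle=np.exp(1j * np.radians(np.full(3, mean_pd))),
        n_timepoints=3)
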