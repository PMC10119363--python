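"""Circular statistics, Hilbert phases, coupling aggregation and delays."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from lidosc.phasecon import (
    PhasePair,
    bandpass_about_median,
    circular_mean_deg,
    instantaneous_phase,
    mean_angle_test,
    pair_phase_stats,
    phase_to_delay,
    resultant_length,
    structure_coupling,
)

FS = 2000.0


class TestCircularStats:
    def test_identical_phases(self):
        p = pair_phase_stats(np.full(100, 40.0), np.full(100, 40.0))
        assert p.delta_phi_deg == pytest.approx(0.0)
        assert p.r == pytest.approx(1.0)

    def test_wraparound_mean(self):
        # circular mean of {179, -179} is 180, not 0
        assert abs(circular_mean_deg(np.array([179.0, -179.0]))) == pytest.approx(180.0)

    def test_uniform_null_resultant(self):
        rng = np.random.default_rng(0)
        phases = rng.uniform(-180, 180, 10_000)
        assert resultant_length(phases) < 0.03  # E[r] ~ sqrt(pi/4N)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pair_phase_stats(np.zeros(10), np.zeros(11))

    @settings(max_examples=30, deadline=None)
    @given(
        hnp.arrays(
            float, st.integers(10, 200),
            elements=st.floats(-180, 179.99, allow_nan=False),
        )
    )
    def test_antisymmetry(self, phases):
        rng = np.random.default_rng(1)
        other = rng.uniform(-180, 180, len(phases))
        ab = pair_phase_stats(phases, other)
        ba = pair_phase_stats(other, phases)
        assert ab.r == pytest.approx(ba.r, abs=1e-9)
        diff = (ab.delta_phi_deg + ba.delta_phi_deg + 180.0) % 360.0 - 180.0
        assert abs(diff) < 1e-6


class TestInstantaneousPhase:
    def test_phase_slope_of_pure_tone(self):
        t = np.arange(0, 4, 1 / FS)
        phi = instantaneous_phase(np.cos(2 * np.pi * 90 * t), FS)
        slope = np.polyfit(np.arange(len(phi)) / FS, np.unwrap(phi, period=360.0), 1)[0]
        assert slope == pytest.approx(360.0 * 90, rel=1e-3)

    def test_quarter_period_shift_is_90_degrees(self):
        t = np.arange(0, 4, 1 / FS)
        f0 = 90.0
        a = np.cos(2 * np.pi * f0 * t)
        b = np.cos(2 * np.pi * f0 * (t - 1 / (4 * f0)))
        p = pair_phase_stats(instantaneous_phase(a, FS), instantaneous_phase(b, FS))
        assert p.delta_phi_deg == pytest.approx(90.0, abs=0.5)
        assert p.r > 0.99

    def test_amplitude_modulation_leaves_phase_slope(self):
        t = np.arange(0, 4, 1 / FS)
        am = (1 + 0.8 * np.sin(2 * np.pi * 1.0 * t)) * np.cos(2 * np.pi * 90 * t)
        phi = instantaneous_phase(am, FS)
        slope = np.polyfit(np.arange(len(phi)) / FS, np.unwrap(phi, period=360.0), 1)[0]
        assert abs(slope / 90 - 360.0) < 1.0  # within 1 degree per cycle

    def test_edges_trimmed(self):
        x = np.zeros(int(4 * FS))
        phi = instantaneous_phase(x, FS, trim_s=0.5)
        assert len(phi) == len(x) - int(FS)


class TestBandpass:
    def test_median_frequency_from_detections(self):
        class Det:
            params = [
                type("P", (), {"b": b})() for b in (85.0, 90.0, 95.0)
            ]
            detected = np.array([True, True, True])

        _, m = bandpass_about_median(np.zeros(int(4 * FS)), FS, detections=Det())
        assert m == 90.0

    def test_out_of_band_tone_suppressed(self):
        t = np.arange(0, 10, 1 / FS)
        x = np.sin(2 * np.pi * 70 * t)
        y, _ = bandpass_about_median(x, FS, median_freq_hz=90.0)
        y = y[0][int(FS) : -int(FS)]
        assert np.sqrt((y**2).mean()) < 0.05 * np.sqrt((x**2).mean())

    def test_no_detections_is_an_error(self):
        class Det:
            params = []
            detected = np.array([], dtype=bool)

        with pytest.raises(ValueError):
            bandpass_about_median(np.zeros(100), FS, detections=Det())

    def test_imposed_lag_recovered(self):
        # 1 ms delay at 90 Hz -> 32.4 degrees
        t = np.arange(0, 6, 1 / FS)
        rng = np.random.default_rng(2)
        x = np.sin(2 * np.pi * 90 * t) + 0.1 * rng.standard_normal(len(t))
        y = np.sin(2 * np.pi * 90 * (t - 1e-3)) + 0.1 * rng.standard_normal(len(t))
        xf, _ = bandpass_about_median(x, FS, median_freq_hz=90.0)
        yf, _ = bandpass_about_median(y, FS, median_freq_hz=90.0)
        p = pair_phase_stats(
            instantaneous_phase(xf[0], FS), instantaneous_phase(yf[0], FS)
        )
        assert p.delta_phi_deg == pytest.approx(32.4, abs=1.0)
        assert p.r > 0.9

    def test_passband_center_invariance(self):
        # recovered phase difference moves < 1 degree when the passband
        # center shifts +/- 2 Hz around the true frequency
        t = np.arange(0, 6, 1 / FS)
        x = np.sin(2 * np.pi * 90 * t)
        y = np.sin(2 * np.pi * 90 * (t - 1e-3))
        ref = None
        for m in (88.0, 90.0, 92.0):
            xf, _ = bandpass_about_median(x, FS, median_freq_hz=m)
            yf, _ = bandpass_about_median(y, FS, median_freq_hz=m)
            p = pair_phase_stats(
                instantaneous_phase(xf[0], FS), instantaneous_phase(yf[0], FS)
            )
            ref = p.delta_phi_deg if ref is None else ref
            assert p.delta_phi_deg == pytest.approx(ref, abs=1.0)


def _pair(r, dphi, si="A", sj="B"):
    return PhasePair(0, 1, si, sj, delta_phi_deg=dphi, r=r)


class TestStructureCoupling:
    def test_all_pairs_perfect(self):
        out = structure_coupling([_pair(1.0, 30.0), _pair(1.0, 30.0)])
        c = out[("A", "B")]
        assert c.mean_r == pytest.approx(1.0)
        assert c.mean_dphi_deg == pytest.approx(30.0)

    def test_quality_filter_semantics(self):
        out = structure_coupling([_pair(0.9, 30.0), _pair(0.2, -120.0)])
        c = out[("A", "B")]
        assert c.mean_r == pytest.approx(0.55)
        assert c.mean_dphi_deg == pytest.approx(30.0)  # only the r=0.9 pair
        assert c.n_pass_filter == 1 and c.n_pairs == 2

    def test_no_passing_pair_reports_missing(self):
        out = structure_coupling([_pair(0.3, 10.0)])
        assert out[("A", "B")].mean_dphi_deg is None


class TestMeanAngleTest:
    def test_offset_cluster_rejected(self):
        rng = np.random.default_rng(3)
        angles = 30.0 + 5.0 * rng.standard_normal(50)
        res = mean_angle_test(angles, mu0_deg=0.0)
        assert res.conclusive and res.reject

    def test_centered_cluster_retained(self):
        rng = np.random.default_rng(4)
        angles = 5.0 * rng.standard_normal(50)
        res = mean_angle_test(angles, mu0_deg=0.0)
        assert res.conclusive and not res.reject

    def test_uniform_inconclusive(self):
        rng = np.random.default_rng(5)
        res = mean_angle_test(rng.uniform(-180, 180, 50))
        assert not res.conclusive

    def test_bonferroni_widens_interval(self):
        rng = np.random.default_rng(6)
        angles = 10.0 + 20.0 * rng.standard_normal(30)
        plain = mean_angle_test(angles)
        adj = mean_angle_test(angles, n_comparisons=20)
        assert adj.ci_halfwidth_deg > plain.ci_halfwidth_deg

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            mean_angle_test(np.zeros(5))


class TestPhaseToDelay:
    def test_reported_nbg_delay(self):
        # 30 degrees at the 94.9 Hz narrowband-gamma mean -> 0.878 ms
        assert phase_to_delay(30.0, 94.9) == pytest.approx(0.878, abs=0.001)

    def test_zero_phase_zero_delay(self):
        assert phase_to_delay(0.0, 123.0) == 0.0

    def test_full_cycle(self):
        assert phase_to_delay(360.0, 100.0) == pytest.approx(10.0)

    def test_invalid_frequency(self):
        with pytest.raises(ValueError):
            phase_to_delay(30.0, 0.0)
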