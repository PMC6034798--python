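import numpy as np
import pytest

from acg.extraction import (
    SpectralEstimate,
    estimate_coarse_delay,
    lsm_decompose,
    transmit_estimate,
    window_signal,
)
from acg.features import (
    AmbiguityError,
    WindowFeatures,
    aggregate_exam,
    attenuation,
    combine_tof,
    density_change_rel,
    derived_acoustics,
    fft_features,
    time_of_flight,
)
from acg.signal_model import MediumModel, make_pulse_spec, propagate, synthesize_pulse

from conftest import SHORT_SETTLE, SHORT_WINDOW


def _estimate(freqs, amplitudes, phases):
    return SpectralEstimate(
        frequencies_hz=tuple(freqs),
        amplitudes=np.asarray(amplitudes, dtype=float),
        phases_rad=np.asarray(phases, dtype=float),
        window_index=0,
        window_duration_s=1.0,
        residual_rms=0.0,
    )


def _pipeline_tof(spec, medium):
    tx = synthesize_pulse(spec)
    rx = propagate(tx, spec, medium)
    coarse = estimate_coarse_delay(rx, tx)
    win = window_signal(rx, SHORT_WINDOW, start_s=SHORT_SETTLE)[0]
    est = lsm_decompose(win, spec.frequencies_hz)
    return time_of_flight(transmit_estimate(spec), est, coarse)


class TestTimeOfFlight:
    def test_pure_delay_recovered_everywhere(self, short_spec):
        # 97.7 us is the scale of a head-path transit time
        c = 0.15 / 97.7e-6
        medium = MediumModel(path_length_m=0.15, c0_mps=c)
        toa_us = _pipeline_tof(short_spec, medium)
        np.testing.assert_allclose(toa_us, 97.7, atol=1e-6)  # 1e-3 ns

    def test_dispersive_profile_matches_forward_model(self, short_spec):
        medium = MediumModel(path_length_m=0.15, c0_mps=1535.0,
                             dispersion_slope_mps_per_mhz=2.7,
                             ref_frequency_hz=1.35e6)
        toa_us = _pipeline_tof(short_spec, medium)
        truth_us = medium.delay_s(np.asarray(short_spec.frequencies_hz)) * 1e6
        assert np.all(np.diff(toa_us) < 0)  # faster at higher frequency
        np.testing.assert_allclose(toa_us, truth_us, atol=1e-6)

    def test_zero_delay_identical_estimates(self, short_spec):
        tx = transmit_estimate(short_spec)
        toa = time_of_flight(tx, tx, 0.0)
        np.testing.assert_array_equal(toa, 0.0)

    def test_inconsistent_phase_raises_ambiguity_error(self, short_spec):
        tx = transmit_estimate(short_spec)
        delay = 1e-4
        freqs = np.asarray(short_spec.frequencies_hz)
        phases = -2 * np.pi * freqs * delay
        phases[5] += np.pi  # half a cycle off at one component
        phases = np.angle(np.exp(1j * phases))
        rx = _estimate(freqs, short_spec.amplitudes, phases)
        with pytest.raises(AmbiguityError):
            time_of_flight(tx, rx, delay)

    def test_combined_estimate_is_frequency_weighted(self, short_spec):
        freqs = np.asarray(short_spec.frequencies_hz)
        toa = np.full(10, 97.4)
        assert combine_tof(toa, freqs) == pytest.approx(97.4)
        toa[-1] += 1.0  # high-frequency components carry more weight
        assert combine_tof(toa, freqs) > 97.4 + 0.1


class TestAttenuation:
    def test_lossless_is_zero(self, short_spec):
        tx = transmit_estimate(short_spec)
        assert np.all(attenuation(tx, tx) == 0.0)

    def test_power_law_monotone_nondecreasing(self, short_spec):
        medium = MediumModel(path_length_m=0.15, c0_mps=1540.0,
                             alpha0_np_per_m=1.5, attenuation_exponent=1.8)
        tx = synthesize_pulse(short_spec)
        rx = propagate(tx, short_spec, medium)
        win = window_signal(rx, SHORT_WINDOW, start_s=SHORT_SETTLE)[0]
        est = lsm_decompose(win, short_spec.frequencies_hz)
        att = attenuation(transmit_estimate(short_spec), est)
        assert np.all(np.diff(att) >= -1e-12)
        truth = 1 - medium.amplitude_ratio(np.asarray(short_spec.frequencies_hz))
        np.testing.assert_allclose(att, truth, atol=1e-9)

    def test_zero_transmit_amplitude_rejected(self, short_spec):
        tx = _estimate(short_spec.frequencies_hz, np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError):
            attenuation(tx, tx)


class TestDerivedAcoustics:
    def test_speed_and_bulk_modulus_arithmetic(self):
        out = derived_acoustics(np.full(10, 97.4026), 0.15, rho_ref_kg_m3=1040.0)
        assert out.c_band_mps == pytest.approx(1540.0, abs=0.05)
        assert out.k_pa == pytest.approx(2.466e9, rel=1e-3)

    def test_density_linearization_reproduces_printed_value(self):
        # dc = 1.25 m/s at c = 1540 m/s -> |d rho / rho| = 1.6e-3
        assert abs(density_change_rel(1.25, 1540.0)) == pytest.approx(1.62e-3, abs=5e-5)
        assert density_change_rel(0.0, 1540.0) == 0.0

    def test_nonpositive_tof_rejected(self):
        with pytest.raises(ValueError):
            derived_acoustics(np.array([-1.0]), 0.15)


class TestFftFeatures:
    def test_single_tone_energy_localizes(self, short_spec):
        fs = short_spec.sampling_rate_hz
        f5 = short_spec.frequencies_hz[4]
        t = np.arange(int(1e-3 * fs)) / fs
        y = np.sin(2 * np.pi * f5 * t)
        energies, centroid = fft_features(y, fs, short_spec.frequencies_hz)
        assert centroid == pytest.approx(f5, rel=1e-3)
        # rectangular-window leakage outside the half-spacing band costs ~0.1%
        assert energies[4] == pytest.approx(0.5, rel=3e-3)
        others = np.delete(energies, 4)
        assert np.all(others < 1e-3 * energies[4])

    def test_equal_tone_centroid_is_midband(self, short_spec):
        rec = synthesize_pulse(short_spec)
        energies, centroid = fft_features(
            rec.samples, rec.sampling_rate_hz, short_spec.frequencies_hz
        )
        assert centroid == pytest.approx(np.mean(short_spec.frequencies_hz), rel=1e-3)

    def test_parseval_partition(self, short_spec):
        rec = synthesize_pulse(short_spec)
        energies, _ = fft_features(
            rec.samples, rec.sampling_rate_hz, short_spec.frequencies_hz
        )
        total = np.mean(rec.samples**2)
        assert energies.sum() <= total * (1 + 1e-9)
        assert energies.sum() == pytest.approx(total, rel=1e-3)


class TestAggregation:
    def _wf(self, value):
        return WindowFeatures(
            toa_us=np.full(10, value),
            att=np.full(10, value / 1000),
            fft_band_energy=np.full(10, value),
            fft_centroid_hz=value,
        )

    def test_median_of_identical_windows(self, short_spec):
        records = [[self._wf(5.0)] * 3 for _ in range(3)]
        fv = aggregate_exam(records, short_spec.frequencies_hz)
        np.testing.assert_allclose(fv.toa_us, 5.0)

    def test_median_robust_to_outlier(self, short_spec):
        records = [[self._wf(1.0)], [self._wf(2.0)], [self._wf(100.0)]]
        fv = aggregate_exam(records, short_spec.frequencies_hz)
        np.testing.assert_allclose(fv.toa_us, 2.0)

    def test_equals_brute_force_median_of_nine(self, short_spec, rng):
        values = rng.normal(97, 3, size=9)
        records = [[self._wf(v) for v in values[i * 3 : (i + 1) * 3]] for i in range(3)]
        fv = aggregate_exam(records, short_spec.frequencies_hz)
        np.testing.assert_allclose(fv.toa_us, np.median(values))

    def test_permutation_invariance(self, short_spec, rng):
        values = rng.normal(97, 3, size=9)
        perm = rng.permutation(9)
        make = lambda vals: [[self._wf(v) for v in vals[i * 3 : (i + 1) * 3]] for i in range(3)]
        fv1 = aggregate_exam(make(values), short_spec.frequencies_hz)
        fv2 = aggregate_exam(make(values[perm]), short_spec.frequencies_hz)
        np.testing.assert_allclose(fv1.toa_us, fv2.toa_us)

    def test_requires_three_records(self, short_spec):
        with pytest.raises(ValueError, match="3 records"):
            aggregate_exam([[self._wf(1.0)]], short_spec.frequencies_hz)

    def test_mean_aggregation_option(self, short_spec):
        records = [[self._wf(1.0)], [self._wf(2.0)], [self._wf(6.0)]]
        fv = aggregate_exam(records, short_spec.frequencies_hz, method="mean")
        np.testing.assert_allclose(fv.toa_us, 3.0)
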