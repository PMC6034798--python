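import numpy as np
import pytest

from acg.extraction import Window, lsm_decompose
from acg.signal_model import (
    ConfigurationError,
    MediumModel,
    RecordedSignal,
    band_power,
    make_pulse_spec,
    propagate,
    quality_score,
    select_transmit_amplitudes,
    synthesize_pulse,
)

FREQS_10 = np.linspace(0.7e6, 2.0e6, 10)


class TestPulseSpec:
    def test_uniform_grid_spacing(self):
        spec = make_pulse_spec(0.7e6, 2.0e6, 10, 25e6)
        assert spec.n_components == 10
        np.testing.assert_allclose(np.diff(spec.frequencies_hz), 1.3e6 / 9)
        assert spec.spacing_hz == pytest.approx(0.144444e6, rel=1e-4)

    def test_two_components_are_the_endpoints(self):
        spec = make_pulse_spec(0.7e6, 2.0e6, 2, 25e6)
        assert spec.frequencies_hz == (0.7e6, 2.0e6)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(sampling_rate_hz=3e6),            # undersampled
            dict(n_components=1),                  # single tone
            dict(f_low_hz=2.0e6, f_high_hz=0.7e6), # inverted band
            dict(amplitudes=[0] * 10),             # silent transmit
            dict(amplitudes=[300] * 10),           # above the 8-bit scale
        ],
    )
    def test_invalid_configurations_raise(self, kwargs):
        base = dict(f_low_hz=0.7e6, f_high_hz=2.0e6, n_components=10, sampling_rate_hz=25e6)
        base.update(kwargs)
        with pytest.raises((ConfigurationError, ValueError)):
            make_pulse_spec(**base)


class TestSynthesize:
    def test_component_powers_additive_on_integer_period_window(self):
        # 90 us is an integer number of periods of every grid component
        spec = make_pulse_spec(sampling_rate_hz=25e6, record_duration_s=90e-6,
                               amplitudes=np.arange(1, 11) * 10)
        sig = synthesize_pulse(spec)
        expected = sum(a**2 / 2 for a in spec.amplitudes)
        assert np.mean(sig.samples**2) == pytest.approx(expected, rel=1e-12)
        for f, a in zip(spec.frequencies_hz, spec.amplitudes):
            p = band_power(sig.samples, spec.sampling_rate_hz, f, spec.spacing_hz)
            assert p == pytest.approx(a**2 / 2, rel=1e-9)

    def test_single_sine_reextraction_is_exact(self):
        fs, f, dur = 25e6, 1.3e6, 1e-4  # 130 periods exactly
        t = np.arange(int(fs * dur)) / fs
        y = 3.2 * np.sin(2 * np.pi * f * t + 0.7)
        est = lsm_decompose(Window(y, fs, 0.0, 0), [f])
        assert est.amplitudes[0] == pytest.approx(3.2, rel=1e-9)
        assert est.phases_rad[0] == pytest.approx(0.7, abs=1e-9)


class TestPropagate:
    def test_pure_delay_shifts_every_phase(self, short_spec):
        medium = MediumModel(path_length_m=0.154, c0_mps=1540.0)  # 100 us
        tx = synthesize_pulse(short_spec)
        rx = propagate(tx, short_spec, medium)
        n0 = int(3e-4 * short_spec.sampling_rate_hz)
        win = Window(rx.samples[n0:], short_spec.sampling_rate_hz,
                     n0 / short_spec.sampling_rate_hz, 0)
        est = lsm_decompose(win, short_spec.frequencies_hz)
        for f, a, phi in zip(short_spec.frequencies_hz, est.amplitudes, est.phases_rad):
            expected = np.angle(np.exp(1j * (-2 * np.pi * f * 1e-4)))
            assert phi == pytest.approx(expected, abs=1e-9)
            assert a == pytest.approx(128.0, rel=1e-9)

    def test_attenuation_monotone_in_frequency(self, short_spec):
        medium = MediumModel(path_length_m=0.15, c0_mps=1540.0,
                             alpha0_np_per_m=2.0, attenuation_exponent=1.0)
        ratios = medium.amplitude_ratio(FREQS_10)
        assert np.all(np.diff(ratios) < 0)

    def test_received_power_never_exceeds_transmitted(self, short_spec):
        medium = MediumModel(path_length_m=0.15, c0_mps=1540.0,
                             alpha0_np_per_m=1.0, attenuation_exponent=1.3)
        tx = synthesize_pulse(short_spec)
        rx = propagate(tx, short_spec, medium)
        for f in short_spec.frequencies_hz:
            p_rx = band_power(rx.samples, rx.sampling_rate_hz, f, short_spec.spacing_hz)
            p_tx = band_power(tx.samples, tx.sampling_rate_hz, f, short_spec.spacing_hz)
            assert p_rx <= p_tx * (1 + 1e-9)

    def test_noise_requires_explicit_rng(self, short_spec):
        medium = MediumModel(path_length_m=0.15, c0_mps=1540.0, snr_db=20.0)
        tx = synthesize_pulse(short_spec)
        with pytest.raises(ValueError, match="rng"):
            propagate(tx, short_spec, medium)

    def test_negative_path_length_rejected(self):
        with pytest.raises(ValueError):
            MediumModel(path_length_m=-0.1, c0_mps=1540.0)

    def test_phase_error_scales_with_inverse_root_window_length(self, rng):
        # tripling the window length shrinks the phase SE by sqrt(3)
        fs, f, a, sigma = 10e6, 1.3e6, 100.0, 50.0
        ses = []
        for n in (20000, 60000):
            t = np.arange(n) / fs
            base = a * np.sin(2 * np.pi * f * t + 0.3)
            phases = []
            for _ in range(120):
                y = base + rng.normal(0, sigma, n)
                est = lsm_decompose(Window(y, fs, 0.0, 0), [f])
                phases.append(est.phases_rad[0])
            ses.append(np.std(phases))
        assert ses[0] / ses[1] == pytest.approx(np.sqrt(3), rel=0.25)


class TestQualityScore:
    def test_lossless_propagation_scores_one(self, short_spec):
        medium = MediumModel(path_length_m=0.154, c0_mps=1540.0)
        tx = synthesize_pulse(short_spec)
        rx = propagate(tx, short_spec, medium, onset=False)
        # band integration with a rectangular window leaks ~0.2% of energy
        assert quality_score(rx, short_spec, tx) == pytest.approx(1.0, abs=5e-3)

    def test_pure_noise_fails_the_acceptance_threshold(self, short_spec, rng):
        tx = synthesize_pulse(short_spec)
        noise = RecordedSignal(
            rng.normal(0, 128.0, short_spec.n_samples),
            short_spec.sampling_rate_hz,
            short_spec.record_duration_s,
        )
        assert quality_score(noise, short_spec, tx) < 0.70

    def test_half_energy_attenuation_scores_half(self, short_spec):
        # frequency-flat attenuation with exp(-2 alpha L) = 0.5
        length = 0.15
        alpha0 = np.log(2) / (2 * length)
        medium = MediumModel(path_length_m=length, c0_mps=1540.0,
                             alpha0_np_per_m=alpha0, attenuation_exponent=0.0)
        tx = synthesize_pulse(short_spec)
        rx = propagate(tx, short_spec, medium, onset=False)
        assert quality_score(rx, short_spec, tx) == pytest.approx(0.5, abs=5e-3)


class TestTransmitAmplitudeSelection:
    def test_equalizes_expected_received_energy(self, short_spec):
        medium = MediumModel(path_length_m=0.15, c0_mps=1540.0,
                             alpha0_np_per_m=2.0, attenuation_exponent=2.0)
        boosted = select_transmit_amplitudes(short_spec, medium)
        amps = np.asarray(boosted.amplitudes)
        assert np.all((amps >= 1) & (amps <= 255))
        assert np.all(amps == np.round(amps))
        assert amps[-1] == 255  # most attenuated component at full scale
        received = amps * medium.amplitude_ratio(FREQS_10)
        # flat to within integer-quantization error of the 8-bit scale
        assert received.max() / received.min() < 1.02
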