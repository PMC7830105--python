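import numpy as np
import pytest
from scipy import stats as sps
from scipy.signal import correlate

from phasecoupling import (DegenerateInputError, ValidationError,
                           bandpass_extract, extract_phase,
                           instantaneous_rate, moving_average_detrend,
                           protophase, protophase_to_phase, zscore_normalize)
from phasecoupling.preprocess import BandComponent, PhaseSeries


FS = 50.0
T = np.arange(0, 120, 1 / FS)


class TestDetrend:
    def test_constant_maps_to_zero(self):
        out = moving_average_detrend(np.full(1000, 3.7), 50.0, 5.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_passband_sinusoid_preserved(self):
        x = np.sin(2 * np.pi * 1.0 * T)
        out = moving_average_detrend(x, FS, 30.0)
        rms_err = np.sqrt(np.mean((out - x) ** 2))
        assert rms_err < 0.01 * np.sqrt(np.mean(x ** 2))

    def test_linear_ramp_removed(self):
        ramp = np.linspace(0, 10, T.size)
        out = moving_average_detrend(ramp, FS, 10.0)
        interior = out[int(10 * FS):-int(10 * FS)]
        assert np.sqrt(np.mean(interior ** 2)) < 0.02 * np.sqrt(np.mean(ramp ** 2))

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValidationError):
            moving_average_detrend(np.zeros(100), 10.0, 0.0)


class TestZScore:
    def test_basic_normalisation(self):
        out = zscore_normalize(np.array([1.0, 2.0, 3.0]))
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std() == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        x = np.random.default_rng(0).normal(size=1000)
        once = zscore_normalize(x)
        np.testing.assert_allclose(zscore_normalize(once), once, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(DegenerateInputError):
            zscore_normalize(np.ones(10))


class TestBandpass:
    def test_cardiac_band_passes_1hz(self):
        x = np.sin(2 * np.pi * 1.0 * T)
        comp = bandpass_extract(x, FS, (0.6, 2.0))
        interior = slice(int(10 * FS), -int(10 * FS))
        ratio = np.sqrt(np.mean(comp.samples[interior] ** 2)
                        / np.mean(x[interior] ** 2))
        assert ratio >= 0.95

    def test_respiratory_band_rejects_1hz(self):
        x = np.sin(2 * np.pi * 1.0 * T)
        comp = bandpass_extract(x, FS, (0.1, 0.6))
        interior = slice(int(10 * FS), -int(10 * FS))
        atten = np.sqrt(np.mean(comp.samples[interior] ** 2)
                        / np.mean(x[interior] ** 2))
        assert 20 * np.log10(1 / atten) >= 20.0

    def test_zero_in_zero_out(self):
        comp = bandpass_extract(np.zeros(1000), FS, (0.6, 2.0))
        assert not comp.samples.any()

    def test_zero_phase_no_lag(self):
        x = np.sin(2 * np.pi * 1.0 * T)
        comp = bandpass_extract(x, FS, (0.6, 2.0))
        interior = slice(int(10 * FS), -int(10 * FS))
        xc = correlate(comp.samples[interior], x[interior], mode="full")
        lag = np.argmax(xc) - (len(x[interior]) - 1)
        assert lag == 0

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValidationError):
            bandpass_extract(np.zeros(100), 10.0, (0.6, 6.0))


class TestProtophase:
    def test_pure_cosine_protophase_linear(self):
        comp = BandComponent("cardiac", (0.6, 2.0),
                             np.cos(2 * np.pi * 1.0 * T), FS)
        proto = protophase(comp)
        interior = slice(int(5 * FS), -int(5 * FS))
        resid = proto.phase[interior] - 2 * np.pi * 1.0 * T[interior]
        assert np.max(np.abs(resid - resid.mean())) < 0.05

    def test_phase_gain_matches_frequency(self):
        comp = BandComponent("cardiac", (0.6, 2.0),
                             np.cos(2 * np.pi * 1.0 * T), FS)
        proto = protophase(comp)
        expected = 2 * np.pi * 1.0 * (T[-1] - T[0])
        assert proto.phase[-1] - proto.phase[0] == pytest.approx(
            expected, rel=0.02)

    def test_zero_signal_rejected(self):
        with pytest.raises(DegenerateInputError):
            protophase(BandComponent("cardiac", (0.6, 2.0),
                                     np.zeros(100), FS))


class TestProtophaseToPhase:
    def test_uniform_rotation_is_identity(self):
        theta = PhaseSeries(2 * np.pi * 1.0 * T, FS, "protophase")
        phi = protophase_to_phase(theta)
        np.testing.assert_allclose(phi.phase, theta.phase, atol=2e-3)

    def test_distorted_protophase_uniformised(self):
        # theta = phi + 0.5 sin(phi) distortion of a uniform rotation
        n = 10_000
        phi_true = np.linspace(0, 2 * np.pi * 100, n, endpoint=False)
        theta = PhaseSeries(phi_true + 0.5 * np.sin(phi_true), 10.0,
                            "protophase")
        out = protophase_to_phase(theta)
        wrapped = np.mod(out.phase, 2 * np.pi) / (2 * np.pi)
        ks = sps.kstest(wrapped, "uniform").statistic
        assert ks < 0.02
        # and the distorted input itself fails this bound
        ks_in = sps.kstest(np.mod(theta.phase, 2 * np.pi) / (2 * np.pi),
                           "uniform").statistic
        assert ks_in > 0.05

    def test_total_gain_preserved(self):
        rng = np.random.default_rng(3)
        theta_lin = np.cumsum(np.abs(rng.normal(0.08, 0.02, 5000)))
        theta = PhaseSeries(theta_lin + 0.3 * np.sin(theta_lin), 25.0,
                            "protophase")
        out = protophase_to_phase(theta)
        gain_in = theta.phase[-1] - theta.phase[0]
        gain_out = out.phase[-1] - out.phase[0]
        assert abs(gain_in - gain_out) < 2 * np.pi

    def test_too_few_cycles_rejected(self):
        theta = PhaseSeries(np.linspace(0, 4 * np.pi, 100), 10.0, "protophase")
        with pytest.raises(ValidationError):
            protophase_to_phase(theta)


class TestInstantaneousRate:
    def test_linear_phase_gives_60_bpm(self):
        phase = PhaseSeries(2 * np.pi * 1.0 * T, FS)
        rate = instantaneous_rate(phase, smooth_s=0.0)
        np.testing.assert_allclose(rate, 60.0, atol=1e-6)

    def test_rsa_modulation_visible_at_respiratory_frequency(self):
        # cardiac phase frequency-modulated at 0.25 Hz
        f_r = 0.25
        phi = 2 * np.pi * 1.0 * T + (0.4 / (2 * np.pi * f_r)) * np.sin(
            2 * np.pi * f_r * T)
        rate = instantaneous_rate(PhaseSeries(phi, FS), smooth_s=0.5)
        spec = np.abs(np.fft.rfft(rate - rate.mean()))
        freqs = np.fft.rfftfreq(rate.size, 1 / FS)
        peak = freqs[np.argmax(spec)]
        assert peak == pytest.approx(f_r, abs=0.02)

    def test_constant_phase_rejected(self):
        # a non-advancing phase violates the phase contract at construction
        with pytest.raises(ValidationError):
            PhaseSeries(np.zeros(100), 10.0)
        # and a protophase (monotonicity not guaranteed) is refused here
        proto = PhaseSeries(np.linspace(0, 20 * np.pi, 100), 10.0,
                            "protophase")
        with pytest.raises(ValidationError):
            instantaneous_rate(proto, 0.0)


class TestFullPhasePipeline:
    def test_composed_observable_phases_recovered(self, coupled_pair):
        # single-stage composite signal with known phases: both extracted
        # phases track the truth within 0.15 rad RMS away from the edges
        from phasecoupling import compose_observable
        p1, p2, _ = coupled_pair
        rec = compose_observable(p1, p2, (1.0, 2.0), noise_sd=0.1, seed=0)
        fs = rec.fs
        edge = int(10 * fs)
        for band, truth in (((0.6, 2.0), p1), ((0.1, 0.6), p2)):
            est = extract_phase(rec.samples[0], fs, band)
            d = est.phase[edge:-edge] - truth.phase[edge:-edge]
            d -= d.mean()
            assert np.sqrt(np.mean(d ** 2)) < 0.15, band

    def test_extracted_phase_tracks_truth(self, short_run):
        rec, proto, truth = short_run
        fs = rec.fs
        edge = int(10 * fs)
        ph_c = extract_phase(rec.channel("BP"), fs, (0.6, 2.0),
                             detrend_window_s=20.0)
        d = ph_c.phase[edge:-edge] - truth.phases["BP_cardiac"][edge:-edge]
        d -= d.mean()
        assert np.sqrt(np.mean(d ** 2)) < 0.15
        ph_r = extract_phase(rec.channel("BP"), fs, (0.1, 0.6),
                             detrend_window_s=20.0)
        d = ph_r.phase[edge:-edge] - truth.phases["resp"][edge:-edge]
        d -= d.mean()
        assert np.sqrt(np.mean(d ** 2)) < 0.2
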