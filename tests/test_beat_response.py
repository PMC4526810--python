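"""Beat-response extraction: spectra, channel criterion, summaries, phase."""

import math

import numpy as np
import pytest
from scipy import stats as sps

import tempotag as tt
from tempotag.beat_response import ChannelSpectrum, segment_coefficients
from tempotag.errors import DegenerateInputError, InvalidInputError
from conftest import cosine, make_recording


class TestArtifactScreening:
    def test_clean_recording_passes(self):
        rng = np.random.default_rng(0)
        rec = make_recording({"Fz": rng.standard_normal(5000),
                              "Cz": rng.standard_normal(5000)})
        report = tt.screen_artifacts(rec)
        assert report.verdict == "pass"
        assert all(f < 1e-3 for f in report.flagged_fraction.values())

    def test_injected_spikes_are_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(5000)
        idx = rng.choice(5000, size=10, replace=False)
        x[idx] = 20 * x.std() * np.sign(x[idx] + 0.5)
        rec = make_recording({"Fz": x})
        report = tt.screen_artifacts(rec)
        assert set(idx) <= set(report.flagged_indices["Fz"])

    def test_many_spikes_trigger_repeat_verdict(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(5000)
        x[::20] = 50.0  # 5% of samples
        report = tt.screen_artifacts(make_recording({"Fz": x}))
        assert report.verdict == "repeat"

    def test_constant_channel_passes_with_warning_note(self):
        rec = make_recording({"Fz": np.zeros(2000)})
        report = tt.screen_artifacts(rec)
        assert report.verdict == "pass"
        assert report.flagged_fraction["Fz"] == 0.0
        assert any("degenerate" in n for n in report.warnings)


class TestChannelSpectrum:
    def test_exact_bin_cosine_amplitude_and_phase(self):
        rec = make_recording({"Fz": cosine(6, 2e-6, 120, 1000, phase=0.8)},
                             sample_rate_hz=1000)
        spec = tt.channel_spectrum(rec)
        i6 = spec.bin_index(6.0)
        assert spec.amplitude[0, i6] == pytest.approx(2e-6, rel=1e-9)
        assert np.angle(spec.coefficients[0, i6]) == pytest.approx(0.8, abs=1e-9)
        off = np.delete(spec.amplitude[0], i6)
        assert off.max() < 1e-15

    def test_two_sinusoids_recovered_by_linearity(self):
        x = cosine(6, 1.0, 10, 500) + cosine(11, 0.3, 10, 500)
        spec = tt.channel_spectrum(make_recording({"Fz": x}, 500))
        assert spec.amplitude[0, spec.bin_index(6.0)] == pytest.approx(1.0, abs=1e-9)
        assert spec.amplitude[0, spec.bin_index(11.0)] == pytest.approx(0.3, abs=1e-9)

    def test_nan_rejected(self):
        x = np.zeros(2000)
        x[5] = np.nan
        with pytest.raises(InvalidInputError):
            tt.channel_spectrum(make_recording({"Fz": x}))


def _constructed_spectrum(beat_excess_sd: float, seed: int = 0) -> ChannelSpectrum:
    """Spectrum with known neighbor statistics and a controlled beat excess."""
    rng = np.random.default_rng(seed)
    freqs = np.arange(0, 20.01, 1 / 30)  # 30-s resolution
    amps = np.abs(rng.normal(1.0, 0.1, freqs.size))
    in_band = (freqs >= 5) & (freqs <= 7) & (np.abs(freqs - 6.0) > 0.1)
    i6 = int(np.argmin(np.abs(freqs - 6.0)))
    neigh = amps[in_band]
    amps[i6] = neigh.mean() + beat_excess_sd * neigh.std(ddof=1)
    return ChannelSpectrum(freqs_hz=freqs, coefficients=amps[None, :].astype(complex),
                           channel_labels=("Fz",))


class TestBeatResponsiveChannels:
    def test_three_sd_excess_included(self):
        assert tt.beat_responsive_channels(_constructed_spectrum(3.0)) == ["Fz"]

    def test_one_sd_excess_excluded(self):
        assert tt.beat_responsive_channels(_constructed_spectrum(1.0)) == []

    def test_zero_variance_neighbors_excluded_with_warning(self):
        freqs = np.arange(0, 20.01, 1 / 30)
        amps = np.ones(freqs.size)
        spec = ChannelSpectrum(freqs, amps[None, :].astype(complex), ("Fz",))
        with pytest.warns(UserWarning, match="zero-variance"):
            assert tt.beat_responsive_channels(spec) == []

    def test_too_few_neighbor_bins_rejected(self):
        freqs = np.arange(0, 20.1, 0.5)  # only 4 neighbor bins in 5-7 Hz
        spec = ChannelSpectrum(freqs, np.ones((1, freqs.size), dtype=complex), ("Fz",))
        with pytest.raises(InvalidInputError):
            tt.beat_responsive_channels(spec)


class TestAverageBeatResponse:
    def test_noiseless_cosine_summary(self):
        rec = make_recording({"Fz": cosine(6, 1.0, 30, 500)}, 500)
        s = tt.average_beat_response(rec, ["Fz"])
        assert s.mean_amplitude == pytest.approx(1.0, abs=1e-9)
        assert s.sem_amplitude == pytest.approx(0.0, abs=1e-9)
        assert s.mean_phase == pytest.approx(0.0, abs=1e-9)
        assert s.n_segments == 30

    def test_averaging_identical_channels_is_idempotent(self):
        x = cosine(6, 2.0, 10, 500, phase=1.0)
        one = tt.average_beat_response(make_recording({"Fz": x}, 500), ["Fz"])
        two = tt.average_beat_response(
            make_recording({"Fz": x, "Cz": x.copy()}, 500), ["Fz", "Cz"])
        assert two.mean_amplitude == pytest.approx(one.mean_amplitude)
        assert two.mean_phase == pytest.approx(one.mean_phase)

    def test_segment_mean_amplitude_matches_rice_expectation(self):
        # signal A at the beat bin plus white time noise: per-segment moduli
        # are Rice(A, sigma_q); compare against the closed-form Rice mean
        rng = np.random.default_rng(42)
        fs, dur, amp, sigma_t = 250.0, 120.0, 1.0, 3.0
        n_seg_len = int(fs)
        sigma_q = sigma_t * math.sqrt(2.0 / n_seg_len)
        means = []
        for _ in range(20):
            x = cosine(6, amp, dur, fs) + rng.normal(0, sigma_t, int(dur * fs))
            s = tt.average_beat_response(make_recording({"Fz": x}, fs), ["Fz"])
            means.append(s.mean_amplitude)
        expected = sps.rice.mean(b=amp / sigma_q, scale=sigma_q)
        mc_sem = np.std(means, ddof=1) / math.sqrt(len(means))
        assert np.mean(means) == pytest.approx(expected, abs=4 * mc_sem + 1e-4)

    def test_amplitude_unaffected_by_distant_bins(self):
        base = cosine(6, 1.0, 20, 500, phase=0.3)
        clutter = cosine(8, 5.0, 20, 500) + cosine(40, 3.0, 20, 500)
        s0 = tt.average_beat_response(make_recording({"Fz": base}, 500), ["Fz"])
        s1 = tt.average_beat_response(make_recording({"Fz": base + clutter}, 500), ["Fz"])
        assert s1.mean_amplitude == pytest.approx(s0.mean_amplitude, abs=1e-9)
        assert s1.mean_phase == pytest.approx(s0.mean_phase, abs=1e-9)

    def test_circular_delay_shifts_phase_by_2pi_f_dt(self):
        fs, f = 500.0, 6.0
        x = cosine(f, 1.0, 10, fs, phase=0.7)
        delay_samples = 13
        delayed = np.roll(x, delay_samples)
        s0 = tt.average_beat_response(make_recording({"Fz": x}, fs), ["Fz"])
        s1 = tt.average_beat_response(make_recording({"Fz": delayed}, fs), ["Fz"])
        expected = (s0.mean_phase - 2 * np.pi * f * delay_samples / fs + np.pi) % (
            2 * np.pi) - np.pi
        assert s1.mean_phase == pytest.approx(expected, abs=1e-9)

    def test_noiseless_segment_mean_equals_full_length_amplitude(self):
        rec = make_recording({"Fz": cosine(6, 2.5, 40, 500, phase=1.1)}, 500)
        s = tt.average_beat_response(rec, ["Fz"])
        spec = tt.channel_spectrum(rec)
        full = spec.amplitude[0, spec.bin_index(6.0)]
        assert s.mean_amplitude == pytest.approx(full, abs=1e-9)

    def test_empty_channel_set_rejected(self):
        rec = make_recording({"Fz": cosine(6, 1, 5, 500)}, 500)
        with pytest.raises(InvalidInputError):
            tt.average_beat_response(rec, [])


class TestKSNormality:
    def test_gaussian_coefficients_usually_pass(self):
        rng = np.random.default_rng(3)
        passed = 0
        for _ in range(40):
            c = rng.normal(size=120) + 1j * rng.normal(size=120)
            p_re, p_im = tt.ks_normality(c)
            passed += (p_re > 0.05) and (p_im > 0.05)
        assert passed >= 36  # ~90% joint coverage

    def test_heavy_tails_usually_rejected(self):
        rng = np.random.default_rng(4)
        rejected = 0
        for _ in range(30):
            c = rng.standard_cauchy(120) + 1j * rng.standard_cauchy(120)
            p_re, p_im = tt.ks_normality(c)
            rejected += (p_re < 0.05) or (p_im < 0.05)
        assert rejected >= 27

    def test_constant_coefficients_rejected(self):
        with pytest.raises(DegenerateInputError):
            tt.ks_normality(np.full(30, 1 + 1j))

    def test_too_few_coefficients_rejected(self):
        with pytest.raises(InvalidInputError):
            tt.ks_normality(np.arange(10) * (1 + 1j))


class TestPhaseLatency:
    def test_zero_phase_is_zero_latency(self):
        assert tt.phase_to_latency(0.0, 6.0) == 0.0

    def test_half_cycle_closed_form(self):
        assert tt.phase_to_latency(np.pi, 0.5) == pytest.approx(1.0)

    def test_round_trip_inverse(self):
        assert tt.phase_to_latency(tt.latency_to_phase(0.094, 6.0), 6.0) == pytest.approx(0.094)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(InvalidInputError):
            tt.phase_to_latency(1.0, 0.0)


def test_segment_coefficients_shape_and_value():
    x = cosine(6, 1.5, 7, 200, phase=0.4)
    c = segment_coefficients(x, 200.0, 6.0, 1.0)
    assert c.shape == (7,)
    assert np.allclose(np.abs(c), 1.5, atol=1e-9)
    assert np.allclose(np.angle(c), 0.4, atol=1e-9)
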