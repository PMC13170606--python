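"""Preprocessing chain: crop, FIR, wavelet, optical density, MBLL, normalize."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.signal import periodogram

from mpa_nfdk.preprocess import (DegenerateChannelError, FilterSpec,
                                 MbllParams, WaveletSpec, apply_zero_phase,
                                 crop_to_protocol, demean_rms_normalize,
                                 design_fir, mbll_invert, preprocess_pipeline,
                                 to_optical_density, wavelet_denoise)
from mpa_nfdk.simulate import NoiseParams, forward_mbll, simulate_session

FS = 10.2


class TestCrop:
    def test_padded_recording_trimmed_to_protocol(self, config, small_montage):
        rec = simulate_session(config, 1, small_montage, seed=0,
                               pad_pre=10.0, pad_post=10.0)
        cropped = crop_to_protocol(rec)
        assert cropped.n_samples == int(round(1140 * FS))
        assert cropped.pad_pre == 0.0
        # cropped content equals the middle slice of the padded recording
        i0 = int(round(10.0 * FS))
        np.testing.assert_array_equal(
            cropped.intensity, rec.intensity[..., i0:i0 + cropped.n_samples])

    def test_exact_span_recording_unchanged(self, noisy_recording):
        assert crop_to_protocol(noisy_recording) is noisy_recording

    def test_events_referenced_to_zero(self, config, small_montage):
        rec = simulate_session(config, 1, small_montage, seed=0, pad_pre=5.0)
        cropped = crop_to_protocol(rec)
        assert cropped.times[0] == pytest.approx(0.0, abs=1 / FS)
        assert cropped.timeline.events[0].onset == 0.0


class TestFirDesign:
    def test_default_spec_1001_symmetric_taps(self):
        taps = design_fir(FilterSpec(), FS)
        assert taps.size == 1001
        np.testing.assert_allclose(taps, taps[::-1], atol=1e-16)

    def test_stopband_40db_below_passband(self):
        taps = design_fir(FilterSpec(), FS)
        h = np.fft.rfft(taps, 2 ** 16)
        f = np.fft.rfftfreq(2 ** 16, 1 / FS)
        g_pass = np.abs(h[np.argmin(np.abs(f - 0.05))])
        g_stop = np.abs(h[np.argmin(np.abs(f - 1.0))])
        assert 20 * np.log10(g_pass / g_stop) >= 40

    def test_degenerate_band_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(band=(0.05, 0.05))

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            design_fir(FilterSpec(band=(0.01, 6.0)), FS)


class TestZeroPhase:
    def test_passband_sinusoid_no_phase_shift(self):
        taps = design_fir(FilterSpec(), FS)
        t = np.arange(12000) / FS
        x = np.sin(2 * np.pi * 0.05 * t)
        y = apply_zero_phase(x, taps)
        core = slice(2000, 10000)
        xc = np.correlate(y[core], x[core], "full")
        assert abs(int(np.argmax(xc)) - (len(x[core]) - 1)) <= 1

    def test_zero_in_zero_out(self):
        taps = design_fir(FilterSpec(), FS)
        assert not np.any(apply_zero_phase(np.zeros(5000), taps))

    def test_time_reversal_symmetry(self, rng):
        taps = design_fir(FilterSpec(order=100), FS)
        x = rng.normal(size=3000)
        y = apply_zero_phase(x, taps)
        y_rev = apply_zero_phase(x[::-1], taps)
        np.testing.assert_allclose(y_rev, y[::-1], atol=1e-10)

    def test_too_short_series_rejected(self):
        taps = design_fir(FilterSpec(), FS)
        with pytest.raises(ValueError, match="too short"):
            apply_zero_phase(np.zeros(100), taps)


class TestWaveletDenoise:
    def test_lowpass_content_unchanged(self):
        """A signal equal to its own approximation-only reconstruction is a
        fixed point of the denoiser, away from the symmetric-padding
        boundary zone at either end."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=11628)
        low = wavelet_denoise(x)       # approximation + D6..D10 only
        again = wavelet_denoise(low)
        np.testing.assert_allclose(again[256:-256], low[256:-256], atol=1e-10)

    def test_central_spike_suppressed(self):
        x = np.zeros(11628)
        x[5814] = 1.0
        out = wavelet_denoise(x)
        assert np.abs(out).max() <= 0.1

    def test_cardiac_sinusoid_power_removed(self):
        t = np.arange(11628) / FS
        x = np.sin(2 * np.pi * 1.1 * t)
        out = wavelet_denoise(x)
        assert np.sum(out ** 2) / np.sum(x ** 2) <= 0.05

    def test_output_length_preserved_odd_input(self, rng):
        x = rng.normal(size=10001)
        assert wavelet_denoise(x).size == 10001

    def test_short_series_level_reduction_warns(self, rng):
        with pytest.warns(UserWarning, match="levels"):
            wavelet_denoise(rng.normal(size=512))

    def test_hopelessly_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            wavelet_denoise(np.ones(4))


class TestOpticalDensity:
    def test_zero_fluctuation_zero_od(self):
        od, n_clip = to_optical_density(np.zeros(100), 5.0)
        assert not np.any(od) and n_clip == 0

    def test_invariant_to_intensity_rescaling(self, rng):
        x = rng.normal(scale=0.1, size=200)
        od1, _ = to_optical_density(x, 1.0)
        od10, _ = to_optical_density(10 * x, 10.0)
        np.testing.assert_allclose(od1, od10, atol=1e-14)

    def test_nine_times_mean_gives_minus_one(self):
        od, _ = to_optical_density(np.array([9.0]), 1.0)
        assert od[0] == pytest.approx(-1.0)

    def test_nonpositive_argument_clipped_and_counted(self):
        od, n_clip = to_optical_density(np.array([-2.0, -1.0]), 1.0)
        assert n_clip == 2
        assert np.all(np.isfinite(od))


class TestMbllInvert:
    def test_zero_od_zero_concentration(self):
        hbo, hbr = mbll_invert(np.zeros(10), np.zeros(10))
        assert not np.any(hbo) and not np.any(hbr)

    def test_round_trip_with_forward_model(self, rng):
        conc = rng.normal(size=(1, 2, 300)) * 1e-6
        p = MbllParams(separation_cm=3.2)
        od = forward_mbll(conc, dpf=p.dpf, extinction=p.extinction,
                          separations_cm=np.array([3.2]))
        hbo, hbr = mbll_invert(od[0, 0], od[0, 1], p)
        np.testing.assert_allclose(np.stack([hbo, hbr]), conc[0],
                                   rtol=1e-10, atol=1e-18)

    def test_doubling_separation_halves_concentration(self, rng):
        od = rng.normal(size=(2, 50)) * 0.01
        c1 = mbll_invert(od[0], od[1], MbllParams(separation_cm=3.0))
        c2 = mbll_invert(od[0], od[1], MbllParams(separation_cm=6.0))
        np.testing.assert_allclose(np.stack(c2), np.stack(c1) / 2, rtol=1e-12)

    def test_singular_extinction_rejected(self):
        from mpa_nfdk.simulate import ExtinctionSpec
        with pytest.raises(np.linalg.LinAlgError):
            MbllParams(extinction=ExtinctionSpec(matrix=((1.0, 2.0), (2.0, 4.0))))


class TestNormalize:
    def test_three_point_example(self):
        out = demean_rms_normalize(np.array([1.0, 2.0, 3.0]))
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert np.sqrt(np.mean(out ** 2)) == pytest.approx(1.0, abs=1e-12)

    @given(hnp.arrays(np.float64, st.integers(3, 200),
                      elements=st.floats(-100, 100)),
           st.floats(0.1, 50), st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, x, a, b):
        """a*x + b normalizes to the same series for any a > 0."""
        if np.std(x) < 1e-6:
            return
        np.testing.assert_allclose(demean_rms_normalize(a * x + b),
                                   demean_rms_normalize(x), atol=1e-7)

    def test_sign_flip(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(demean_rms_normalize(-x),
                                   -demean_rms_normalize(x), atol=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateChannelError):
            demean_rms_normalize(np.full(10, 3.0))


class TestPipeline:
    def test_output_contract_mean_zero_rms_one(self, noisy_hemo):
        assert np.abs(noisy_hemo.hbo.mean(axis=1)).max() <= 1e-9
        assert np.abs(np.sqrt((noisy_hemo.hbo ** 2).mean(axis=1)) - 1).max() <= 1e-9
        assert np.abs(np.sqrt((noisy_hemo.hbr ** 2).mean(axis=1)) - 1).max() <= 1e-9

    def test_noise_free_recovery_tracks_ground_truth(self, silent_recording):
        """Noise-free recovery reproduces band-limited ground truth almost
        perfectly; raw ground truth keeps its sub-passband (sustained) part,
        so its correlation is lower but still strong."""
        hemo = preprocess_pipeline(silent_recording)
        taps = design_fir(FilterSpec(), FS)
        for i in range(len(hemo.channels)):
            gt = silent_recording.ground_truth[i, 0]
            gt_band = demean_rms_normalize(apply_zero_phase(gt - gt.mean(), taps))
            assert np.corrcoef(hemo.hbo[i], gt_band)[0, 1] >= 0.99
            assert np.corrcoef(hemo.hbo[i],
                               demean_rms_normalize(gt))[0, 1] >= 0.7

    def test_duplicated_channel_gives_identical_output(self, config):
        from mpa_nfdk.simulate import Montage
        m2 = Montage.default().subset(["S3-D2", "S5-D5"])
        rec = simulate_session(config, 1, m2, seed=1)
        dup = dataclasses.replace(
            rec, intensity=np.concatenate([rec.intensity,
                                           rec.intensity[:1]], axis=0),
            ground_truth=None,
            montage=Montage(channels=m2.channels + ((3, 3, 33.0, "PFC"),)))
        hemo = preprocess_pipeline(dup)
        np.testing.assert_allclose(hemo.hbo[0], hemo.hbo[2], atol=1e-10)

    @pytest.mark.parametrize("c", [0.1, 3.0, 10.0])
    def test_scale_invariance(self, noisy_recording, noisy_hemo, c):
        scaled = dataclasses.replace(noisy_recording,
                                     intensity=noisy_recording.intensity * c)
        hemo_c = preprocess_pipeline(scaled)
        assert np.abs(hemo_c.hbo - noisy_hemo.hbo).max() <= 1e-8
        assert np.abs(hemo_c.hbr - noisy_hemo.hbr).max() <= 1e-8

    def test_white_noise_output_power_below_02hz(self, config):
        """Filter + wavelet leave >= 95% of white-noise power below 0.2 Hz."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=11628)
        taps = design_fir(FilterSpec(), FS)
        y = wavelet_denoise(apply_zero_phase(x, taps))
        f, p = periodogram(y, fs=FS)
        assert p[f < 0.2].sum() / p.sum() >= 0.95

    def test_provenance_records_stage_order(self, noisy_hemo):
        stages = [p["stage"] for p in noisy_hemo.provenance]
        assert stages == ["crop", "fir_bandpass", "wavelet_denoise",
                          "optical_density", "mbll_invert",
                          "demean_rms_normalize"]
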