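"""Spectral core: framing, cepstral detection, directivity, magnitude, pipeline."""

import dataclasses
import warnings

import numpy as np
import pytest

from cibeam import (
    ArrayGeometry,
    AudioSignal,
    CepstralTracker,
    FrameConfig,
    apply_azimuth_delay,
    classify_frames,
    directivity_to_azimuth,
    enhance,
    estimate_directivity,
    estimate_speech_magnitude,
    istft_overlap_add,
    stft,
    synth_noise,
    synth_speech_like,
    update_cepstrum,
)
from cibeam.beamform import MicPair, form_channels
from cibeam.enhancer import DirectivityProfile, DirectivityUnavailableError, SpectralFrames

from conftest import make_scene

FS = 44100.0
HOP = 512


class TestStft:
    def test_frame_count_for_one_second(self):
        f = stft(AudioSignal(np.random.default_rng(0).standard_normal(44100), FS))
        assert f.n_frames == 85  # floor((44100 - 1024)/512) + 1

    def test_zero_signal_zero_power(self):
        f = stft(AudioSignal(np.zeros(8192), FS))
        assert not np.any(f.power_spectra)

    def test_tone_peaks_at_nearest_bin(self):
        t = np.arange(44100) / FS
        f = stft(AudioSignal(np.sin(2 * np.pi * 1000.0 * t), FS))
        peak_bins = np.argmax(f.power_spectra, axis=1)
        assert np.all(peak_bins == 23)  # 1000 / (44100/1024) = 23.2

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            stft(AudioSignal(np.zeros(512), FS))

    def test_round_trip_identity(self):
        x = np.random.default_rng(1).standard_normal(20480)
        y = istft_overlap_add(stft(AudioSignal(x, FS))).data
        core = slice(1024, len(y) - 1024)
        err = np.sqrt(np.mean((y[core] - x[core]) ** 2)) / np.sqrt(np.mean(x[core] ** 2))
        assert err < 1e-6

    def test_all_zero_frames_reconstruct_silence(self):
        f = stft(AudioSignal(np.zeros(8192), FS))
        assert not np.any(istft_overlap_add(f).data)

    def test_single_nonzero_frame_is_windowed_normalized_copy(self):
        cfg = FrameConfig()
        x = np.random.default_rng(2).standard_normal(4096)
        f = stft(AudioSignal(x, FS), cfg)
        spectra = np.zeros_like(f.complex_spectra)
        spectra[2] = f.complex_spectra[2]
        y = istft_overlap_add(SpectralFrames(spectra, f.frame_times, FS, cfg, f.signal_len)).data
        win = cfg.get_window()
        start = 2 * cfg.hop
        # interior of the frame where neighbouring (zero) frames also overlap
        seg = slice(start, start + cfg.frame_len)
        # reconstruction divides by the summed window, so the lone frame comes
        # back as x * w / wsum on its support
        wsum = np.zeros(f.signal_len)
        for i in range(f.n_frames):
            wsum[i * cfg.hop : i * cfg.hop + cfg.frame_len] += win
        expected = x[seg] * win / wsum[seg]
        np.testing.assert_allclose(y[seg], expected, atol=1e-12)
        out = np.ones(f.signal_len, bool)
        out[seg] = False
        assert np.allclose(y[out], 0.0, atol=1e-12)


class TestCepstralTracker:
    def test_identical_frames_have_zero_distance(self):
        p = np.abs(np.random.default_rng(3).standard_normal(513)) + 0.1
        tr, _ = update_cepstrum(CepstralTracker(), p)
        tr, d = update_cepstrum(tr, p)
        assert d == pytest.approx(0.0, abs=1e-20)

    def test_default_update_weight(self):
        assert CepstralTracker().beta == 0.85

    def test_tone_frame_far_from_noise_template(self):
        """White-noise template vs a pure-tone frame: distance ratio >= 5.

        The oracle recomputes both distances directly from log spectra."""
        rng = np.random.default_rng(4)
        noise_frames = [np.abs(rng.standard_normal(513)) ** 2 + 1e-3 for _ in range(8)]
        tone = np.full(513, 1e-8)
        tone[100] = 100.0

        def cep(p):
            logp = np.log(np.maximum(p, max(p) * 1e-10))
            return np.fft.irfft(logp)[:13]

        def dist(c1, c0):
            return (c1[0] - c0[0]) ** 2 + 2 * np.sum((c1[1:] - c0[1:]) ** 2)

        # independent oracle distances
        d_noise = dist(cep(noise_frames[-1]), cep(noise_frames[-2]))
        d_tone = dist(cep(tone), cep(noise_frames[-1]))
        assert d_tone / d_noise >= 5

        # tracked version agrees in ordering
        tr = CepstralTracker()
        last = 0.0
        for p in noise_frames:
            tr, last = update_cepstrum(tr, p)
        _, d_t = update_cepstrum(tr, tone)
        assert d_t / max(last, 1e-12) >= 5

    def test_silent_frame_leaves_tracker_unchanged(self):
        p = np.abs(np.random.default_rng(5).standard_normal(513)) + 0.1
        tr, _ = update_cepstrum(CepstralTracker(), p)
        before = tr.cepstrum.copy()
        tr2, d = update_cepstrum(tr, np.zeros(513))
        assert d == 0.0
        np.testing.assert_array_equal(tr2.cepstrum, before)

    def test_negative_power_rejected(self):
        with pytest.raises(ValueError):
            update_cepstrum(CepstralTracker(), np.array([-1.0, 1.0]))


class TestClassifyFrames:
    def test_white_noise_scene_detection_rates(self, geom):
        """>= 80 % of the noise lead-in and (on average over seeds) >= 60 %
        of the speech interval are labelled correctly at 0 dB SNR, against
        the simulator's ground-truth marks."""
        speech_rates = []
        for seed in (1, 2, 3, 4, 5):
            scene = make_scene(geom, kind="white", lead_in_s=0.5, tail_s=0.5, seed=seed)
            duals = form_channels(MicPair(scene.mic1, scene.mic2), geom)
            labels = classify_frames(stft(duals.ch1))
            lead_frames = (scene.segment_marks["lead_in_end"] - 1024) // HOP
            s0 = scene.segment_marks["speech_start"] // HOP + 2
            s1 = (scene.segment_marks["speech_end"] - 1024) // HOP
            assert labels.noise_only[:lead_frames].mean() >= 0.8, f"seed {seed}"
            speech_rates.append(1.0 - labels.noise_only[s0:s1].mean())
        assert np.mean(speech_rates) >= 0.6

    def test_stationary_noise_alone_stays_noise(self, geom):
        noise = synth_noise(3.0, "white", seed=5)
        duals = form_channels(MicPair(*apply_azimuth_delay(noise, 90.0, geom)), geom)
        labels = classify_frames(stft(duals.ch1))
        assert labels.noise_only.mean() >= 0.95

    def test_too_few_frames_rejected(self, geom):
        noise = synth_noise(0.1, "white", seed=5)
        duals = form_channels(MicPair(*apply_azimuth_delay(noise, 90.0, geom)), geom)
        with pytest.raises(ValueError):
            classify_frames(stft(duals.ch1), n_init=10)

    def test_explicit_threshold_respected(self, geom):
        noise = synth_noise(1.0, "white", seed=6)
        duals = form_channels(MicPair(*apply_azimuth_delay(noise, 90.0, geom)), geom)
        labels = classify_frames(stft(duals.ch1), CepstralTracker(threshold=1e9))
        assert labels.threshold == 1e9
        assert labels.noise_only.all()


class TestDirectivity:
    @pytest.mark.parametrize("phi, tol", [(90.0, 0.25), (120.0, 0.30)])
    def test_scalar_ratio_matches_cot4(self, geom, phi, tol):
        noise = synth_noise(3.0, "tonal_music", seed=7)
        duals = form_channels(MicPair(*apply_azimuth_delay(noise, phi, geom)), geom)
        f1, f2 = stft(duals.ch1), stft(duals.ch2)
        prof = estimate_directivity(f1, f2, classify_frames(f1))
        expected = 1.0 / np.tan(np.radians(phi / 2)) ** 4
        assert abs(prof.scalar_ratio - expected) / expected <= tol

    def test_no_noise_frames_raises_unavailable(self, geom):
        noise = synth_noise(1.0, "white", seed=8)
        duals = form_channels(MicPair(*apply_azimuth_delay(noise, 90.0, geom)), geom)
        f1, f2 = stft(duals.ch1), stft(duals.ch2)
        labels = classify_frames(f1)
        labels.noise_only[:] = False
        with pytest.raises(DirectivityUnavailableError):
            estimate_directivity(f1, f2, labels)

    def test_moving_noise_ratio_crosses_unity_near_broadside(self, geom):
        """75->105 deg sweep: the tracked ratio passes 1 around the 90 deg crossing."""
        scene = make_scene(
            geom, kind="white", lead_in_s=2.0, tail_s=0.1, speech_s=0.1, seed=4,
            noise_azimuth=75.0,
            trajectory=[(0.0, 75.0), (2.2, 105.0)],
        )
        out, diag = enhance(MicPair(scene.mic1, scene.mic2), geom=geom)
        trace = diag.scalar_ratio_trace
        # 90 deg is crossed mid-sweep (t = 1.1 s -> frame ~95)
        cross = np.flatnonzero(np.diff(np.sign(trace[10:] - 1.0)))
        assert len(cross) > 0
        t_cross = (cross[0] + 10) * HOP / FS
        assert 0.7 < t_cross < 1.5

    @pytest.mark.parametrize(
        "ratio, phi", [(1.0, 90.0), (1.0 / 9.0, 120.0), (81.0, 2 * np.degrees(np.arctan(1 / 3)))]
    )
    def test_azimuth_inversion_closed_form(self, ratio, phi):
        assert directivity_to_azimuth(ratio) == pytest.approx(phi, abs=1e-6)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            directivity_to_azimuth(0.0)


class TestMagnitudeEstimate:
    def _freqs(self, geom):
        return FrameConfig().bin_freqs(geom.sample_rate_hz)

    def test_noise_free_front_tone_recovered(self, geom):
        """With no noise the closed form returns the clean tone magnitude."""
        freqs = self._freqs(geom)
        k = 46  # ~1981 Hz
        amp = 0.7
        wdc = 2 * np.pi * freqs * geom.delay_s
        ch1_power = 4 * np.sin(wdc) ** 2 * 0.0
        ch1_power = ch1_power.copy()
        ch1_power[k] = 4 * np.sin(wdc[k]) ** 2 * amp**2
        ch2_power = np.zeros_like(freqs)
        prof = DirectivityProfile(np.zeros_like(freqs), 0.0, None, 0)
        mag = estimate_speech_magnitude(ch1_power, ch2_power, prof, geom, freqs)
        assert mag[k] == pytest.approx(amp, rel=0.02)

    def test_two_tone_mixture_suppresses_noise_bin(self, geom):
        """Speech tone at 1 kHz (front) + noise tone at 2 kHz (90 deg), equal power:
        the noise bin drops >= 20 dB below its unsubtracted value while the
        speech bin stays within 3 dB of clean. Per-bin powers follow the
        closed-form channel gains."""
        freqs = self._freqs(geom)
        ks, kn = 23, 46
        wdc = 2 * np.pi * freqs * geom.delay_s
        a2 = 1.0  # squared amplitudes, equal power
        ch1 = np.zeros_like(freqs)
        ch2 = np.zeros_like(freqs)
        # front speech: ch1 gain 2(1-cos 2wdc), ch2 gain 0
        ch1[ks] = 2 * (1 - np.cos(2 * wdc[ks])) * a2
        # 90-deg noise: both channels gain 2(1-cos wdc)
        ch1[kn] = 2 * (1 - np.cos(wdc[kn])) * a2
        ch2[kn] = 2 * (1 - np.cos(wdc[kn])) * a2
        ratio = np.ones_like(freqs)  # cot^4(45 deg) = 1
        prof = DirectivityProfile(ratio, 1.0, 90.0, 100)
        mag = estimate_speech_magnitude(ch1, ch2, prof, geom, freqs)
        unsub = estimate_speech_magnitude(ch1, np.zeros_like(ch2), prof, geom, freqs)
        assert 20 * np.log10(max(mag[kn], 1e-12) / unsub[kn]) <= -20
        assert abs(20 * np.log10(mag[ks] / 1.0)) <= 3.0

    def test_negative_difference_floors_to_zero(self, geom):
        freqs = self._freqs(geom)
        prof = DirectivityProfile(np.full_like(freqs, 2.0), 2.0, None, 100)
        mag = estimate_speech_magnitude(
            np.ones_like(freqs), np.ones_like(freqs), prof, geom, freqs
        )
        assert np.all(mag == 0.0)


class TestEnhancePipeline:
    def test_clean_front_speech_identity_within_3db(self, geom, clean_speech_session):
        """Noise-free front speech passes through within 3 dB of band-limited
        spectral RMS (156-5498 Hz) after compensation."""
        at1, at2, onset, n_speech = clean_speech_session
        out, diag = enhance(MicPair(at1, at2), geom=geom)
        reg = slice(onset + 1024, onset + n_speech - 1024)
        fo = stft(AudioSignal(out.data[reg], FS))
        fc = stft(AudioSignal(at1.data[reg], FS))
        freqs = fo.bin_freqs
        sel = (freqs >= 156) & (freqs <= 5498)
        dev = 10 * np.log10(fo.power_spectra[:, sel].sum() / fc.power_spectra[:, sel].sum())
        assert abs(dev) <= 3.0

    @pytest.mark.parametrize(
        "builder",
        [
            lambda n: np.zeros(n),
            lambda n: np.full(n, 0.25),
            lambda n: 0.5 * np.cos(np.pi * np.arange(n)),  # Nyquist tone
        ],
        ids=["silence", "dc", "nyquist"],
    )
    def test_degenerate_inputs_produce_finite_output(self, geom, builder):
        x = AudioSignal(builder(16384), FS)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out, diag = enhance(MicPair(x, AudioSignal(x.data.copy(), FS)), geom=geom)
        assert np.all(np.isfinite(out.data))

    def test_short_input_passthrough_with_warning(self, geom):
        x = AudioSignal(np.random.default_rng(9).standard_normal(3000), FS)
        with pytest.warns(RuntimeWarning):
            out, diag = enhance(MicPair(x, AudioSignal(x.data.copy(), FS)), geom=geom)
        assert diag.passthrough
        assert np.all(np.isfinite(out.data))

    def test_azimuth_recovered_within_15_degrees(self, geom, babble_scene, babble_enhanced):
        _, diag = babble_enhanced
        az = diag.azimuth_trace[~np.isnan(diag.azimuth_trace)]
        assert abs(az[-1] - 90.0) <= 15.0

    def test_bad_phase_source_rejected(self, geom):
        x = AudioSignal(np.zeros(8192), FS)
        with pytest.raises(ValueError):
            enhance(MicPair(x, x), geom=geom, phase_source="mic2")
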