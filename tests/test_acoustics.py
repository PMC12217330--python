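"""Feature extraction: planted-parameter recovery and analytic invariants."""

import numpy as np
import pytest

from levospeech.acoustics import (
    FEATURE_NAMES,
    InvalidParameterError,
    Waveform,
    analyze_frames,
    ddk_features,
    extract_all,
    ltas_moments,
    phonation_features,
    segment_speech_pauses,
    spectral_moments,
    text_features,
    track_f0,
)
from levospeech.synthgen import (
    AudioGroundTruth,
    synth_ddk,
    synth_phonation,
    synth_reading,
)

RATE = 48_000


def _tone(freq=150.0, dur=2.0, rate=RATE):
    t = np.arange(int(dur * rate)) / rate
    return Waveform(samples=np.sin(2 * np.pi * freq * t), rate=rate, task="phon")


class TestF0Tracking:
    def test_pure_tone_f0(self):
        track = track_f0(_tone(150.0))
        assert np.nanmedian(track.f0) == pytest.approx(150.0, abs=1.0)

    def test_white_noise_mostly_unvoiced(self, rng):
        voiced_fracs = []
        for _ in range(20):
            w = Waveform(rng.normal(0, 0.3, 2 * RATE), RATE, "phon")
            tr = analyze_frames(w)
            voiced_fracs.append(np.mean(np.isfinite(tr.f0)))
        assert np.mean(voiced_fracs) < 0.05

    def test_silence_gives_zero_voiced_frames(self):
        tr = analyze_frames(Waveform(np.zeros(RATE), RATE, "phon"))
        assert np.isfinite(tr.f0).sum() == 0

    def test_invalid_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            track_f0(_tone(), f_min=500.0, f_max=100.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_vibrato_semitone_sd(self, seed):
        """±2 st sinusoidal vibrato -> F0-track SD near 2/sqrt(2) st."""
        w = synth_phonation(
            AudioGroundTruth(task="phon", f0_sd=2.0, vibrato_rate=5.0, seed=seed)
        )
        feats = analyze_frames(w)
        f0 = feats.f0[np.isfinite(feats.f0)]
        st = 12 * np.log2(f0 / np.exp(np.mean(np.log(f0))))
        assert np.std(st, ddof=1) == pytest.approx(2 / np.sqrt(2), abs=0.15)


class TestIntensity:
    def test_constant_tone_low_sd(self):
        tr = analyze_frames(_tone())
        voiced = np.isfinite(tr.f0)
        assert np.std(tr.intensity[voiced], ddof=1) < 0.2

    def test_amplitude_doubling_shifts_by_6dB(self):
        w = _tone()
        tr1 = analyze_frames(w)
        # intensity is dB re waveform peak, so absolute doubling cancels;
        # check the raw log law on the frame RMS instead
        w2 = Waveform(w.samples * 2, w.rate, w.task)
        tr2 = analyze_frames(w2)
        voiced = np.isfinite(tr1.f0) & np.isfinite(tr2.f0)
        np.testing.assert_allclose(
            tr2.intensity[voiced], tr1.intensity[voiced], atol=0.01
        )
        assert np.std(tr2.intensity[voiced]) == pytest.approx(
            np.std(tr1.intensity[voiced]), abs=0.01
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_planted_slope_recovered(self, seed):
        w = synth_phonation(
            AudioGroundTruth(task="phon", intensity_slope=-2.0, seed=seed)
        )
        feats = phonation_features(w)
        assert feats["Int_slope_phon"] == pytest.approx(-2.0, abs=0.2)


class TestSegmentation:
    def test_planted_pauses_recovered(self):
        w = synth_reading(
            AudioGroundTruth(
                task="text", syllable_count=10, pause_durations=(0.2, 0.4), seed=0
            )
        )
        seg = segment_speech_pauses(analyze_frames(w))
        assert len(seg.pause_intervals) == 2
        durations = sorted(e - s for s, e in seg.pause_intervals)
        assert durations[0] == pytest.approx(0.2, abs=0.010)
        assert durations[1] == pytest.approx(0.4, abs=0.010)

    def test_continuous_phonation_no_pauses(self):
        w = synth_phonation(AudioGroundTruth(task="phon", seed=0))
        seg = segment_speech_pauses(analyze_frames(w))
        assert seg.pause_intervals == []

    @pytest.mark.parametrize("seed", range(5))
    def test_syllable_nuclei_count(self, seed):
        w = synth_reading(
            AudioGroundTruth(
                task="text", syllable_count=10, pause_durations=(0.3,), seed=seed
            )
        )
        seg = segment_speech_pauses(analyze_frames(w))
        assert abs(len(seg.syllable_times) - 10) <= 1

    def test_all_silence_empty_segmentation(self):
        seg = segment_speech_pauses(analyze_frames(Waveform(np.zeros(RATE), RATE, "text")))
        assert seg.speech_intervals == []


class TestTextFeatures:
    def test_planted_rates_and_pauses(self):
        w = synth_reading(
            AudioGroundTruth(
                task="text", syllable_count=10, pause_durations=(0.2, 0.4),
                f0_sd=0.0, seed=1,
            )
        )
        f = text_features(w)
        net_true = 10 * 0.150 + 7 * 0.030
        assert f["NSR_text"] == pytest.approx(10 / net_true, rel=0.10)
        assert f["DPI_text"] == pytest.approx(300.0, abs=15.0)
        assert f["sdF0_text"] < 0.2
        assert f["RST_text"] > 0

    def test_wrong_task_rejected(self):
        with pytest.raises(InvalidParameterError):
            text_features(_tone())

    def test_unvoiced_input_missing_markers(self, rng):
        w = Waveform(rng.normal(0, 0.2, 2 * RATE), RATE, "text")
        f = text_features(w)
        assert np.isnan(f["sdF0_text"]) and np.isnan(f["NSR_text"])


class TestPhonationFeatures:
    @pytest.mark.parametrize("dur", [1.5, 3.0])
    def test_mpt_matches_planted_duration(self, dur):
        w = synth_phonation(AudioGroundTruth(task="phon", phonation_dur=dur, seed=0))
        assert phonation_features(w)["MPT_phon"] == pytest.approx(dur, abs=0.05)

    @pytest.mark.parametrize("snr", [10.0, 20.0])
    def test_hnr_recovers_snr(self, snr):
        w = synth_phonation(AudioGroundTruth(task="phon", snr=snr, seed=3))
        assert phonation_features(w)["HNR_phon"] == pytest.approx(snr, abs=3.0)

    def test_hnr_monotone_in_snr(self):
        vals = [
            phonation_features(
                synth_phonation(AudioGroundTruth(task="phon", snr=s, seed=7))
            )["HNR_phon"]
            for s in (10.0, 40.0)
        ]
        assert vals[1] > vals[0]

    def test_short_voicing_missing_markers(self, rng):
        w = Waveform(rng.normal(0, 0.2, RATE), RATE, "phon")
        f = phonation_features(w)
        assert all(np.isnan(v) for v in f.values())


class TestDdkFeatures:
    @pytest.mark.parametrize("gap", [10.0, 25.0, 50.0])
    def test_vot_recovers_planted_gap(self, gap):
        w = synth_ddk(
            AudioGroundTruth(task="ddk", syllable_count=36, vot_gap=gap, seed=0)
        )
        f = ddk_features(w)
        assert f["n_syllables"] == 36
        assert f["VOT_ddk"] == pytest.approx(gap, abs=5.0)

    def test_zero_gap_small_vot(self):
        w = synth_ddk(AudioGroundTruth(task="ddk", syllable_count=12, vot_gap=0.0, seed=0))
        assert ddk_features(w)["VOT_ddk"] <= 10.0

    def test_noise_input_missing_marker(self, rng):
        w = Waveform(rng.normal(0, 0.2, 2 * RATE), RATE, "ddk")
        assert np.isnan(ddk_features(w)["VOT_ddk"])


class TestLtasMoments:
    def test_flat_spectrum_uniform_moments(self, rng):
        # white noise at 16 kHz is flat across the 0-8 kHz band
        w = Waveform(rng.normal(0, 0.3, 4 * 16000), 16000, "text")
        mean, sd, skew, kurt = ltas_moments(w)
        assert mean == pytest.approx(4000.0, rel=0.01)
        assert sd == pytest.approx(8000 / np.sqrt(12), rel=0.01)
        assert abs(skew) < 0.05

    def test_single_line_degenerate(self):
        w = Waveform(_tone(200.0, dur=3.0).samples, RATE, "phon")
        mean, sd, _, _ = ltas_moments(w)
        assert mean == pytest.approx(200.0, abs=25.0)
        assert sd < 120.0

    def test_gaussian_bump_matches_numerical_oracle(self, rng):
        freqs = np.linspace(0, 8000, 2000)
        power = np.exp(-0.5 * ((freqs - 1000) / 200) ** 2)
        mean, sd, skew, kurt = spectral_moments(freqs, power)
        # brute-force numerical moments on the same normalized spectrum
        p = power / power.sum()
        mu = (freqs * p).sum()
        s = np.sqrt(((freqs - mu) ** 2 * p).sum())
        assert mean == pytest.approx(mu, rel=1e-6)
        assert sd == pytest.approx(s, rel=1e-6)
        assert skew == pytest.approx((((freqs - mu) / s) ** 3 * p).sum(), abs=1e-6)
        assert kurt == pytest.approx((((freqs - mu) / s) ** 4 * p).sum(), rel=1e-6)
        assert mean == pytest.approx(1000.0, abs=20.0)
        assert sd == pytest.approx(200.0, abs=20.0)
        assert kurt == pytest.approx(3.0, abs=0.1)

    def test_silent_input_errors(self):
        with pytest.raises(InvalidParameterError):
            ltas_moments(Waveform(np.zeros(2 * RATE), RATE, "text"))


@pytest.fixture(scope="module")
def subject_recordings():
    return {
        "phon": synth_phonation(
            AudioGroundTruth(task="phon", intensity_slope=-1.0, snr=20, seed=5)
        ),
        "ddk": synth_ddk(
            AudioGroundTruth(task="ddk", syllable_count=24, vot_gap=25, seed=5)
        ),
        "text": synth_reading(
            AudioGroundTruth(
                task="text", syllable_count=20, pause_durations=(0.3, 0.3, 0.4),
                f0_sd=1.0, intensity_sd=1.5, seed=5,
            )
        ),
    }


class TestInvariances:
    def test_amplitude_scaling_leaves_all_features(self, subject_recordings):
        vec = extract_all(subject_recordings)
        scaled = {
            k: Waveform(w.samples * 0.5, w.rate, w.task)
            for k, w in subject_recordings.items()
        }
        vec2 = extract_all(scaled)
        for name in FEATURE_NAMES:
            assert vec2[name] == pytest.approx(vec[name], rel=0.02, abs=0.05), name

    def test_time_reversal_invariants(self, subject_recordings):
        w = subject_recordings["text"]
        f = text_features(w)
        f_rev = text_features(Waveform(w.samples[::-1].copy(), w.rate, w.task))
        for name in ("sdF0_text", "Int_sd_text", "Int_kurt_text",
                     "LTAS_mean", "LTAS_sd", "LTAS_skew", "LTAS_kurt"):
            assert f_rev[name] == pytest.approx(f[name], rel=0.05, abs=0.05), name
        p = subject_recordings["phon"]
        slope = phonation_features(p)["Int_slope_phon"]
        slope_rev = phonation_features(
            Waveform(p.samples[::-1].copy(), p.rate, p.task)
        )["Int_slope_phon"]
        assert slope_rev == pytest.approx(-slope, abs=0.2)


class TestExtractAll:
    def test_repeats_averaged(self):
        w1 = synth_phonation(AudioGroundTruth(task="phon", phonation_dur=2.8, seed=0))
        w2 = synth_phonation(AudioGroundTruth(task="phon", phonation_dur=3.2, seed=1))
        vec = extract_all({"phon": [w1, w2]})
        assert vec["MPT_phon"] == pytest.approx(3.0, abs=0.07)

    def test_absent_tasks_missing(self):
        w = synth_reading(
            AudioGroundTruth(task="text", syllable_count=10,
                             pause_durations=(0.3,), seed=0)
        )
        vec = extract_all({"text": w})
        assert np.isfinite(vec["sdF0_text"])
        assert np.isnan(vec["MPT_phon"]) and np.isnan(vec["VOT_ddk"])

    def test_full_subject_all_finite(self):
        recs = {
            "phon": synth_phonation(AudioGroundTruth(task="phon", snr=25, seed=2)),
            "ddk": synth_ddk(AudioGroundTruth(task="ddk", syllable_count=36, seed=2)),
            "text": synth_reading(
                AudioGroundTruth(task="text", syllable_count=24,
                                 pause_durations=(0.3, 0.4), f0_sd=1.0, seed=2)
            ),
        }
        vec = extract_all(recs)
        assert np.isfinite(vec[list(FEATURE_NAMES)]).all()

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            extract_all({})
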