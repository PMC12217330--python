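"""The 16 digital speech biomarkers of hypokinetic/hyperkinetic dysarthria.

Twelve basic biomarkers plus the first four standardized moments of the
long-term average spectrum (LTAS), computed from task-labeled waveforms:

==================  =========  =====================================================
feature             task       meaning
==================  =========  =====================================================
``sdF0_text``       reading    monopitch — st. dev. of F0 in semitones
``Int_sd_text``     reading    monoloudness — st. dev. of the intensity contour (dB)
``Int_kurt_text``   reading    kurtosis of the intensity contour
``Int_skew_text``   reading    skewness of the intensity contour
``NSR_text``        reading    net speech rate, syllables per second of net speech
``DPI_text``        reading    mean duration of pause intervals, ms
``RST_text``        reading    rate of speech timing — speech+pause segments per min
``VOT_ddk``         DDK        mean voice onset time in /pa-ta-ka/ repetitions, ms
``HNR_phon``        phonation  harmonics-to-noise ratio, dB
``MPT_phon``        phonation  maximal phonation time, s
``Int_slope_phon``  phonation  linear slope of intensity during phonation, dB/s
``Int_sd_phon``     phonation  st. dev. of intensity during phonation, dB
``LTAS_mean``       reading    first spectral moment, Hz
``LTAS_sd``         reading    second spectral moment, Hz
``LTAS_skew``       reading    third standardized spectral moment
``LTAS_kurt``       reading    fourth standardized spectral moment
==================  =========  =====================================================

All intensity statistics are computed on the dB contour and are therefore
invariant to overall amplitude scaling; missing features propagate as NaN
markers, never silent zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

logger = logging.getLogger(__name__)

#: Canonical biomarker names; the interchange contract of the feature CSVs.
FEATURE_NAMES: tuple[str, ...] = (
    "sdF0_text",
    "Int_sd_text",
    "Int_kurt_text",
    "Int_skew_text",
    "NSR_text",
    "DPI_text",
    "RST_text",
    "VOT_ddk",
    "HNR_phon",
    "MPT_phon",
    "Int_slope_phon",
    "Int_sd_phon",
    "LTAS_mean",
    "LTAS_sd",
    "LTAS_skew",
    "LTAS_kurt",
)

TASKS = ("phon", "ddk", "text")


class InvalidParameterError(ValueError):
    """Raised for non-finite or out-of-range analysis/synthesis parameters."""


@dataclass(frozen=True)
class Waveform:
    """Mono audio with sample rate and task label."""

    samples: np.ndarray
    rate: float
    task: str

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise InvalidParameterError(f"rate must be positive, got {self.rate}")
        if self.task not in TASKS:
            raise InvalidParameterError(f"task must be one of {TASKS}, got {self.task!r}")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class FrameTrack:
    """Frame-wise F0 (NaN where unvoiced) and intensity (dB re waveform peak)."""

    times: np.ndarray
    f0: np.ndarray
    intensity: np.ndarray

    @property
    def voiced(self) -> np.ndarray:
        return np.isfinite(self.f0)


@dataclass
class Segmentation:
    """Speech/pause intervals in seconds plus detected syllable-nucleus times."""

    speech_intervals: list[tuple[float, float]]
    pause_intervals: list[tuple[float, float]]
    syllable_times: list[float]

    @property
    def net_speech_time(self) -> float:
        return float(sum(e - s for s, e in self.speech_intervals))


@dataclass(frozen=True)
class AcousticConfig:
    """Analysis defaults.

    The defaults follow common dysarthria-analysis practice: 40 ms frames with
    a 10 ms hop, F0 search range 60–400 Hz with an autocorrelation voicing
    threshold of 0.45, 60 ms segmentation floors for both pauses and speech
    stretches, and an LTAS band of 0–8 kHz on linear power weights.
    """

    frame_length: float = 0.040
    hop: float = 0.010
    f0_min: float = 60.0
    f0_max: float = 400.0
    voicing_threshold: float = 0.45
    silence_threshold_db: float = -35.0  # re the waveform's peak frame intensity
    min_pause: float = 0.060
    min_speech: float = 0.060
    db_floor: float = -80.0
    ltas_band: tuple[float, float] = (0.0, 8000.0)
    ltas_db_weights: bool = False
    syllable_min_prominence_db: float = 2.0
    syllable_min_separation: float = 0.08


DEFAULT_CONFIG = AcousticConfig()


# ---------------------------------------------------------------------------
# frame analysis


def _frame_signal(x: np.ndarray, rate: float, cfg: AcousticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Return (frames, frame-center times); frames are windows of frame_length."""
    n = int(round(cfg.frame_length * rate))
    hop = int(round(cfg.hop * rate))
    if len(x) < n:
        return np.empty((0, n)), np.empty(0)
    starts = np.arange(0, len(x) - n + 1, hop)
    frames = np.lib.stride_tricks.sliding_window_view(x, n)[starts]
    times = (starts + n / 2) / rate
    return frames, times


def _autocorr_f0(
    frames: np.ndarray, rate: float, cfg: AcousticConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-wise F0 and periodicity via window-corrected autocorrelation.

    The normalized autocorrelation of each Hann-windowed, mean-subtracted
    frame is divided by the autocorrelation of the window itself so that a
    perfectly periodic frame scores ~1 at its period lag regardless of lag.
    """
    n = frames.shape[1]
    win = np.hanning(n)
    lag_min = max(2, int(np.floor(rate / cfg.f0_max)))
    lag_max = int(np.ceil(rate / cfg.f0_min))
    lag_max = min(lag_max, n - 2)

    fx = frames - frames.mean(axis=1, keepdims=True)
    fw = fx * win
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(fw, nfft, axis=1)
    ac = np.fft.irfft(np.abs(spec) ** 2, nfft, axis=1)[:, : lag_max + 2]
    r0 = ac[:, 0].copy()
    r0[r0 <= 0] = np.inf
    ac /= r0[:, None]

    wspec = np.fft.rfft(win, nfft)
    wac = np.fft.irfft(np.abs(wspec) ** 2, nfft)[: lag_max + 2]
    wac /= wac[0]
    wac[wac < 1e-6] = 1e-6
    ac = ac / wac[None, :]

    # small octave cost breaks the tie between the true period and its
    # multiples (a periodic frame scores ~1 at every multiple of the period)
    lags = np.arange(lag_min, lag_max + 1)
    octave_cost = 0.02 * np.log2(lags / lag_min)
    search = ac[:, lag_min : lag_max + 1] - octave_cost[None, :]
    best = np.argmax(search, axis=1) + lag_min
    # parabolic interpolation around the peak
    f0 = np.full(len(frames), np.nan)
    strength = np.zeros(len(frames))
    for i, b in enumerate(best):
        y0, y1, y2 = ac[i, b - 1], ac[i, b], ac[i, b + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
        delta = float(np.clip(delta, -1, 1))
        lag = b + delta
        strength[i] = y1 - 0.25 * (y0 - y2) * delta
        if lag > 0:
            f0[i] = rate / lag
    return f0, strength


def analyze_frames(w: Waveform, config: AcousticConfig | None = None) -> FrameTrack:
    """Joint F0/intensity frame analysis shared by all feature extractors."""
    cfg = config or DEFAULT_CONFIG
    frames, times = _frame_signal(w.samples, w.rate, cfg)
    if len(frames) == 0:
        return FrameTrack(np.empty(0), np.empty(0), np.empty(0))

    rms = np.sqrt(np.mean(frames**2, axis=1))
    peak = np.max(np.abs(w.samples))
    if peak <= 0:
        intensity = np.full(len(frames), cfg.db_floor)
    else:
        with np.errstate(divide="ignore"):
            intensity = 20.0 * np.log10(rms / peak)
        intensity = np.maximum(intensity, cfg.db_floor)

    f0, strength = _autocorr_f0(frames, w.rate, cfg)
    energetic = intensity > intensity.max() + cfg.silence_threshold_db
    voiced = (
        (strength > cfg.voicing_threshold)
        & energetic
        & (f0 >= cfg.f0_min)
        & (f0 <= cfg.f0_max)
    )
    f0 = np.where(voiced, f0, np.nan)
    f0 = _reject_f0_outliers(f0)
    return FrameTrack(times=times, f0=f0, intensity=intensity)


def _reject_f0_outliers(f0: np.ndarray, max_dev_st: float = 5.0) -> np.ndarray:
    """Unvoice frames whose F0 jumps > max_dev_st semitones off the local track.

    Catches octave errors and boundary frames that straddle two segments;
    genuine vibrato and per-syllable pitch scatter stay well below the cut.
    """
    voiced = np.isfinite(f0)
    if voiced.sum() < 5:
        return f0
    vals = f0[voiced]
    smooth = sps.medfilt(vals, kernel_size=5)
    dev = np.abs(12.0 * np.log2(vals / np.maximum(smooth, 1e-6)))
    keep = dev <= max_dev_st
    out = f0.copy()
    idx = np.where(voiced)[0]
    out[idx[~keep]] = np.nan
    return out


def track_f0(
    w: Waveform,
    f_min: float | None = None,
    f_max: float | None = None,
    config: AcousticConfig | None = None,
) -> FrameTrack:
    """Frame-wise F0 via autocorrelation with a voicing decision.

    Unvoiced frames are NaN. An all-silent input yields a track with zero
    voiced frames, not an error.
    """
    cfg = config or DEFAULT_CONFIG
    if f_min is not None or f_max is not None:
        cfg = replace(
            cfg,
            f0_min=f_min if f_min is not None else cfg.f0_min,
            f0_max=f_max if f_max is not None else cfg.f0_max,
        )
    if not (0 < cfg.f0_min < cfg.f0_max <= w.rate / 2):
        raise InvalidParameterError(
            f"require 0 < f_min < f_max <= rate/2, got ({cfg.f0_min}, {cfg.f0_max})"
        )
    return analyze_frames(w, cfg)


def intensity_contour(w: Waveform, config: AcousticConfig | None = None) -> FrameTrack:
    """Frame RMS in dB re the waveform peak, on the same grid as the F0 track."""
    if len(w.samples) == 0:
        raise InvalidParameterError("empty audio")
    return analyze_frames(w, config)


# ---------------------------------------------------------------------------
# segmentation


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as [start, end) index pairs."""
    if len(mask) == 0:
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def segment_speech_pauses(
    track: FrameTrack, config: AcousticConfig | None = None
) -> Segmentation:
    """Energy-threshold speech/pause labeling with duration floors.

    Pauses shorter than ``min_pause`` are merged into speech, then speech
    stretches shorter than ``min_speech`` are relabeled as pause.  Syllable
    nuclei are intensity peaks within voiced stretches.  Pauses are gaps
    *between* speech intervals; leading/trailing silence is not a pause.
    """
    cfg = config or DEFAULT_CONFIG
    if len(track.times) == 0:
        raise InvalidParameterError("empty frame track")
    hop = float(np.median(np.diff(track.times))) if len(track.times) > 1 else cfg.hop

    if track.intensity.max() <= cfg.db_floor + 1e-9:
        return Segmentation([], [], [])  # all-silent input
    speech = track.intensity > track.intensity.max() + cfg.silence_threshold_db
    if not speech.any():
        return Segmentation([], [], [])

    # merge short pauses into speech
    lab = speech.copy()
    for s, e in _runs(~lab):
        if s == 0 or e == len(lab):
            continue  # leading/trailing silence stays silence
        if (e - s) * hop < cfg.min_pause:
            lab[s:e] = True
    # drop short speech stretches
    for s, e in _runs(lab):
        if (e - s) * hop < cfg.min_speech:
            lab[s:e] = False

    runs = _runs(lab)
    # An analysis window overlapping a speech edge by only a few milliseconds
    # already clears the energy threshold, so the outermost speech-labeled
    # frame centers overshoot the true edges by about half a window; pull the
    # interval edges back by (frame_length/2 - hop) to compensate.
    frame_len = cfg.frame_length
    shrink = max(frame_len / 2 - hop / 2, 0.0)
    speech_intervals = []
    for s, e in runs:
        lo = track.times[s] - hop / 2 + shrink
        hi = track.times[e - 1] + hop / 2 - shrink
        if hi <= lo:  # very short stretch; keep a token interval at its center
            mid = (track.times[s] + track.times[e - 1]) / 2
            lo, hi = mid - hop / 2, mid + hop / 2
        speech_intervals.append((lo, hi))
    pause_intervals = [
        (speech_intervals[i][1], speech_intervals[i + 1][0])
        for i in range(len(speech_intervals) - 1)
    ]

    # syllable nuclei: intensity peaks inside speech, at voiced frames
    syllable_times: list[float] = []
    min_dist = max(1, int(round(cfg.syllable_min_separation / hop)))
    contour = np.where(lab, track.intensity, cfg.db_floor)
    peaks, _ = sps.find_peaks(
        contour, distance=min_dist, prominence=cfg.syllable_min_prominence_db
    )
    for p in peaks:
        if lab[p] and track.voiced[p]:
            syllable_times.append(float(track.times[p]))
    # a single uninterrupted stretch with a flat top still carries one nucleus
    if not syllable_times and runs:
        for s, e in runs:
            seg = track.intensity[s:e]
            if np.isfinite(seg).any():
                syllable_times.append(float(track.times[s + int(np.argmax(seg))]))

    return Segmentation(speech_intervals, pause_intervals, sorted(syllable_times))


# ---------------------------------------------------------------------------
# spectral moments


def spectral_moments(freqs: np.ndarray, power: np.ndarray) -> tuple[float, float, float, float]:
    """First four standardized moments of a spectrum treated as a distribution.

    Returns (mean [Hz], sd [Hz], skewness, kurtosis); kurtosis is the plain
    (non-excess) fourth standardized moment, 3 for a Gaussian shape.
    """
    power = np.asarray(power, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if power.size == 0 or np.any(power < 0) or power.sum() <= 0:
        raise InvalidParameterError("spectrum must be non-empty and non-negative")
    p = power / power.sum()
    mean = float(np.sum(freqs * p))
    var = float(np.sum((freqs - mean) ** 2 * p))
    sd = np.sqrt(var)
    if sd == 0:
        return mean, 0.0, 0.0, 0.0
    skew = float(np.sum(((freqs - mean) / sd) ** 3 * p))
    kurt = float(np.sum(((freqs - mean) / sd) ** 4 * p))
    return mean, sd, skew, kurt


def ltas(
    w: Waveform,
    config: AcousticConfig | None = None,
    segmentation: Segmentation | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch long-term average spectrum over speech samples within the band."""
    cfg = config or DEFAULT_CONFIG
    track = analyze_frames(w, cfg)
    seg = segmentation or segment_speech_pauses(track, cfg)
    pieces = []
    for s, e in seg.speech_intervals:
        pieces.append(w.samples[int(s * w.rate) : int(e * w.rate)])
    if not pieces:
        raise InvalidParameterError("no speech found; cannot form a spectrum")
    x = np.concatenate(pieces)
    if len(x) < w.rate:
        raise InvalidParameterError("need at least 1 s of speech for the LTAS")
    nperseg = min(2048, len(x))
    freqs, power = sps.welch(x, fs=w.rate, window="hann", nperseg=nperseg)
    lo, hi = cfg.ltas_band
    band = (freqs >= lo) & (freqs <= hi)
    freqs, power = freqs[band], power[band]
    if cfg.ltas_db_weights:
        ref = power.max()
        power = 10.0 * np.log10(np.maximum(power / ref, 1e-12)) - cfg.db_floor
        power = np.maximum(power, 0.0)
    return freqs, power


def ltas_moments(
    w: Waveform,
    config: AcousticConfig | None = None,
    segmentation: Segmentation | None = None,
) -> tuple[float, float, float, float]:
    """LTAS mean/sd/skewness/kurtosis over the configured band."""
    freqs, power = ltas(w, config, segmentation)
    return spectral_moments(freqs, power)


# ---------------------------------------------------------------------------
# per-task features


def _semitone_sd(f0: np.ndarray) -> float:
    voiced = f0[np.isfinite(f0)]
    if len(voiced) < 2:
        return np.nan
    st = 12.0 * np.log2(voiced / np.exp(np.mean(np.log(voiced))))
    return float(np.std(st, ddof=1))


def _frames_in_intervals(times: np.ndarray, intervals: list[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(len(times), dtype=bool)
    for s, e in intervals:
        mask |= (times >= s) & (times <= e)
    return mask


def text_features(w: Waveform, config: AcousticConfig | None = None) -> dict[str, float]:
    """Reading-passage biomarkers: sdF0, intensity stats, NSR, DPI, RST, LTAS."""
    if w.task != "text":
        raise InvalidParameterError(f"expected a 'text' waveform, got {w.task!r}")
    cfg = config or DEFAULT_CONFIG
    track = analyze_frames(w, cfg)
    out = {k: np.nan for k in FEATURE_NAMES if k.endswith("_text") or k.startswith("LTAS")}
    if not track.voiced.any():
        logger.warning("text_features: no voiced frames; returning missing markers")
        return out

    seg = segment_speech_pauses(track, cfg)
    speech_mask = _frames_in_intervals(track.times, seg.speech_intervals)

    out["sdF0_text"] = _semitone_sd(track.f0)
    ints = track.intensity[speech_mask]
    if len(ints) >= 4:
        out["Int_sd_text"] = float(np.std(ints, ddof=1))
        out["Int_kurt_text"] = float(spstats.kurtosis(ints, fisher=False))
        out["Int_skew_text"] = float(spstats.skew(ints))

    net = seg.net_speech_time
    if net > 0 and seg.syllable_times:
        out["NSR_text"] = len(seg.syllable_times) / net
    if seg.pause_intervals:
        out["DPI_text"] = 1000.0 * float(
            np.mean([e - s for s, e in seg.pause_intervals])
        )
    total_min = w.duration / 60.0
    if total_min > 0:
        out["RST_text"] = (len(seg.speech_intervals) + len(seg.pause_intervals)) / total_min

    try:
        m, sd, sk, ku = ltas_moments(w, cfg, seg)
        out.update(LTAS_mean=m, LTAS_sd=sd, LTAS_skew=sk, LTAS_kurt=ku)
    except InvalidParameterError as err:
        logger.warning("text_features: LTAS unavailable (%s)", err)
    return out


def phonation_features(w: Waveform, config: AcousticConfig | None = None) -> dict[str, float]:
    """Sustained-/a/ biomarkers: MPT, HNR, intensity slope and sd."""
    if w.task != "phon":
        raise InvalidParameterError(f"expected a 'phon' waveform, got {w.task!r}")
    cfg = config or DEFAULT_CONFIG
    track = analyze_frames(w, cfg)
    out = {"MPT_phon": np.nan, "HNR_phon": np.nan, "Int_slope_phon": np.nan, "Int_sd_phon": np.nan}

    # bridge voicing dropouts of up to 100 ms before measuring the stretch
    hop = float(np.median(np.diff(track.times))) if len(track.times) > 1 else cfg.hop
    voiced = track.voiced.copy()
    max_gap = max(1, int(round(0.100 / hop)))
    for s, e in _runs(~voiced):
        if s > 0 and e < len(voiced) and (e - s) <= max_gap:
            voiced[s:e] = True
    runs = _runs(voiced)
    if not runs:
        logger.warning("phonation_features: no voiced frames")
        return out
    s, e = max(runs, key=lambda r: r[1] - r[0])
    # a voiced frame certifies voicing across its analysis window
    mpt = (e - 1 - s) * hop + cfg.frame_length
    if mpt < 0.5:
        logger.warning("phonation_features: voiced stretch < 0.5 s; missing markers")
        return out
    out["MPT_phon"] = float(mpt)

    t = track.times[s:e]
    ints = track.intensity[s:e]
    slope, _ = np.polyfit(t, ints, 1)
    out["Int_slope_phon"] = float(slope)
    out["Int_sd_phon"] = float(np.std(ints, ddof=1))

    # HNR from the window-corrected periodicity r: 10 log10(r / (1 - r))
    frames, _ = _frame_signal(w.samples, w.rate, cfg)
    _, strength = _autocorr_f0(frames, w.rate, cfg)
    r = np.clip(strength[s:e], 1e-6, 1.0 - 1e-6)
    out["HNR_phon"] = float(np.mean(10.0 * np.log10(r / (1.0 - r))))
    return out


def _band_envelope(
    x: np.ndarray, rate: float, lo: float, hi: float, win_s: float = 0.004
) -> np.ndarray:
    """Moving-RMS envelope of a bandpassed signal."""
    nyq = rate / 2
    hi = min(hi, 0.95 * nyq)
    sos = sps.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    y = sps.sosfiltfilt(sos, x)
    n = max(4, int(win_s * rate))
    kernel = np.ones(n) / n
    env = np.sqrt(np.convolve(y**2, kernel, mode="same"))
    return env


def ddk_features(w: Waveform, config: AcousticConfig | None = None) -> dict[str, float]:
    """DDK voice-onset-time: burst onset to voicing onset, averaged over syllables.

    Burst onsets are rises of the high-band (>2.5 kHz) envelope; voicing
    onsets are rises of the low-band (<1.5 kHz) envelope following a burst,
    giving millisecond resolution independent of the frame grid.
    """
    if w.task != "ddk":
        raise InvalidParameterError(f"expected a 'ddk' waveform, got {w.task!r}")
    cfg = config or DEFAULT_CONFIG
    out = {"VOT_ddk": np.nan}

    x = w.samples
    if np.max(np.abs(x)) <= 0:
        logger.warning("ddk_features: silent input")
        return out
    high = _band_envelope(x, w.rate, 2500.0, 9000.0)
    low = _band_envelope(x, w.rate, 60.0, 1500.0, win_s=0.006)

    hmax = high.max()
    min_dist = int(0.08 * w.rate)
    peaks, _ = sps.find_peaks(high, height=0.45 * hmax, distance=min_dist)
    if len(peaks) < 3:
        logger.warning("ddk_features: fewer than 3 syllable bursts detected")
        return out

    def _onset_extrapolated(env: np.ndarray, start: int, limit: int, ref: float) -> int | None:
        """Envelope onset by linear back-extrapolation of the 15%/40% crossings.

        Cancels the smoothing latency of the moving-RMS window, which would
        otherwise bias the crossing time by a few milliseconds.
        """
        t15 = t40 = None
        for k in range(start, limit):
            if t15 is None and env[k] >= 0.15 * ref:
                t15 = k
            if env[k] >= 0.40 * ref:
                t40 = k
                break
        if t15 is None or t40 is None or t40 <= t15:
            return t15
        return max(start, int(round(t15 - 0.15 / 0.25 * (t40 - t15))))

    vots = []
    for i, p in enumerate(peaks):
        # burst onset: back-extrapolate the high-band rise before the peak
        j = p
        while j > 0 and high[j] > 0.10 * high[p]:
            j -= 1
        burst_on = _onset_extrapolated(high, j, p + 1, high[p])
        # voicing onset: back-extrapolate the low-band rise after the burst
        limit = peaks[i + 1] if i + 1 < len(peaks) else len(x)
        voice_on = _onset_extrapolated(low, p, limit, low.max())
        if burst_on is None or voice_on is None:
            continue
        vot = (voice_on - burst_on) / w.rate * 1000.0
        if 0 <= vot <= 150:
            vots.append(vot)
    if len(vots) < 3:
        logger.warning("ddk_features: fewer than 3 measurable VOTs")
        return out
    out["VOT_ddk"] = float(np.mean(vots))
    out["n_syllables"] = len(peaks)
    return out


def extract_all(
    recordings: dict[str, list[Waveform] | Waveform],
    config: AcousticConfig | None = None,
) -> pd.Series:
    """Full 16-feature vector from per-task recordings.

    ``recordings`` maps task name -> waveform or list of repeat waveforms;
    phonation and DDK features are averaged over available repeats (matching
    a protocol that records those tasks twice).  Absent tasks leave their
    features as NaN markers.
    """
    if not recordings:
        raise InvalidParameterError("at least one task recording is required")
    vec = pd.Series(np.nan, index=list(FEATURE_NAMES), dtype=float)
    extractors = {"phon": phonation_features, "ddk": ddk_features, "text": text_features}
    for task, waves in recordings.items():
        if task not in extractors:
            raise InvalidParameterError(f"unknown task {task!r}")
        if isinstance(waves, Waveform):
            waves = [waves]
        rows = [extractors[task](wv, config) for wv in waves]
        frame = pd.DataFrame(rows)
        means = frame.mean(axis=0, skipna=True)
        for name, val in means.items():
            if name in vec.index:
                vec[name] = val
    return vec
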