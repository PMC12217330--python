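"""Ground-truthed synthetic audio and OFF/ON cohorts.

Patient voice recordings from levodopa-challenge studies cannot be shared, so
every downstream stage of this package is exercised on synthetic material
with known ground truth:

* three speech-task synthesizers (sustained /a/ phonation, /pa-ta-ka/ DDK,
  reading passage) whose planted parameters — F0 contour, vibrato, intensity
  slope, SNR, pauses, syllable counts, voice onset time — are recoverable by
  :mod:`levospeech.acoustics` within documented tolerances;
* a feature-level cohort generator with a latent dopaminergic-response
  structure linking biomarker changes to clinical-score changes, emulating a
  cohort of PD patients assessed OFF and ON medication plus healthy controls.

The glottal source is a sum of 10 harmonics with a -12 dB/octave power
rolloff — simple enough that LTAS moments stay analytically predictable; no
formant filtering by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from levospeech.acoustics import FEATURE_NAMES, InvalidParameterError, Waveform

logger = logging.getLogger(__name__)

RATE = 48_000.0  # Hz; matches a 48 kHz / 16-bit clinical recording protocol
N_HARMONICS = 10
EDGE_SILENCE = 0.15  # s of leading/trailing silence


@dataclass(frozen=True)
class AudioGroundTruth:
    """Planted parameters for one synthetic recording.

    ``f0_sd`` doubles as the vibrato half-extent (semitones) for phonation
    and as the per-syllable F0 scatter for the reading task.  ``snr`` is the
    harmonic-to-noise power ratio in dB and is what the HNR biomarker should
    recover.
    """

    task: str
    f0_mean: float = 120.0
    f0_sd: float = 0.0
    vibrato_rate: float = 5.0
    intensity_slope: float = 0.0
    intensity_sd: float = 0.0
    snr: float = 40.0
    phonation_dur: float = 3.0
    pause_durations: tuple[float, ...] = ()
    syllable_count: int = 0
    vot_gap: float = 25.0
    jitter_pct: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("f0_mean", "f0_sd", "vibrato_rate", "intensity_slope",
                     "intensity_sd", "snr", "phonation_dur", "vot_gap", "jitter_pct"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise InvalidParameterError(f"{name} must be finite, got {v}")
        if self.phonation_dur <= 0:
            raise InvalidParameterError("phonation_dur must be positive")
        if any(p <= 0 for p in self.pause_durations):
            raise InvalidParameterError("pause durations must be positive")
        if self.syllable_count < 0:
            raise InvalidParameterError("syllable_count must be >= 0")
        object.__setattr__(self, "pause_durations", tuple(self.pause_durations))


def _harmonic_tone(phase: np.ndarray) -> np.ndarray:
    """Sum of N_HARMONICS harmonics with -12 dB/octave power rolloff."""
    out = np.zeros_like(phase)
    for h in range(1, N_HARMONICS + 1):
        out += h**-2 * np.sin(h * phase)
    return out


def _phase_from_f0(f0: np.ndarray, rate: float = RATE) -> np.ndarray:
    return 2 * np.pi * np.cumsum(f0) / rate


def _edge_ramp(n: int, ramp: int) -> np.ndarray:
    env = np.ones(n)
    r = min(ramp, n // 2)
    if r > 0:
        win = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
        env[:r] = win
        env[-r:] = win[::-1]
    return env


def _add_noise_at_snr(
    x: np.ndarray, voiced_mask: np.ndarray, snr_db: float, rng: np.random.Generator
) -> np.ndarray:
    sig_power = np.mean(x[voiced_mask] ** 2) if voiced_mask.any() else np.mean(x**2)
    noise_power = sig_power / 10 ** (snr_db / 10)
    return x + rng.normal(0.0, np.sqrt(noise_power), len(x))


def _finalize(x: np.ndarray, task: str) -> Waveform:
    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.9 * x / peak
    # quantize to the 16-bit grid the recording protocol would produce
    x = np.round(x * 32767.0) / 32767.0
    return Waveform(samples=x, rate=RATE, task=task)


def synth_phonation(truth: AudioGroundTruth) -> Waveform:
    """Sustained /a/ with planted F0 contour, intensity slope and SNR.

    F0 follows ``f0_mean`` modulated by sinusoidal vibrato of half-extent
    ``f0_sd`` semitones at ``vibrato_rate`` Hz (plus optional cycle jitter);
    the amplitude envelope has the planted dB/s slope; white noise is added
    at the planted SNR.
    """
    if truth.task != "phon":
        raise InvalidParameterError("task must be 'phon'")
    if truth.phonation_dur < 0.5:
        raise InvalidParameterError("phonation_dur must be >= 0.5 s")
    rng = np.random.default_rng(truth.seed)
    n = int(truth.phonation_dur * RATE)
    t = np.arange(n) / RATE

    st_dev = truth.f0_sd * np.sin(2 * np.pi * truth.vibrato_rate * t)
    if truth.jitter_pct > 0:
        # slow random F0 perturbation, band-limited below ~30 Hz
        pert = rng.normal(0, 1, n)
        kernel = np.hanning(int(RATE / 30))
        pert = np.convolve(pert, kernel / kernel.sum(), mode="same")
        st_dev = st_dev + truth.jitter_pct / 100.0 * 12.0 * pert / max(pert.std(), 1e-12)
    f0 = truth.f0_mean * 2 ** (st_dev / 12)
    voice = _harmonic_tone(_phase_from_f0(f0))

    env = 10 ** (truth.intensity_slope * t / 20.0)
    voice = voice * env * _edge_ramp(n, int(0.005 * RATE))

    lead = np.zeros(int(EDGE_SILENCE * RATE))
    x = np.concatenate([lead, voice, lead])
    mask = np.zeros(len(x), dtype=bool)
    mask[len(lead) : len(lead) + n] = True
    x = _add_noise_at_snr(x, mask, truth.snr, rng)
    return _finalize(x, "phon")


#: fixed DDK syllable rate (syll/s); typical of a fast /pa-ta-ka/ repetition
DDK_RATE = 6.0
_DDK_BURST = 0.004
_DDK_VOWEL = 0.090


def synth_ddk(truth: AudioGroundTruth) -> Waveform:
    """/pa-ta-ka/ train: per syllable a broadband burst, ``vot_gap`` ms of
    aspiration noise, then a voiced vowel segment.

    The burst and aspiration occupy the >2.5 kHz band while vowel harmonics
    stay below 1.5 kHz, so burst and voicing onsets are separable downstream.
    """
    if truth.task != "ddk":
        raise InvalidParameterError("task must be 'ddk'")
    if truth.syllable_count < 3:
        raise InvalidParameterError("syllable_count must be >= 3")
    if truth.vot_gap < 0:
        raise InvalidParameterError("vot_gap must be >= 0")
    period = 1.0 / DDK_RATE
    gap_s = truth.vot_gap / 1000.0
    if _DDK_BURST + gap_s + _DDK_VOWEL > period:
        raise InvalidParameterError(
            f"vot_gap {truth.vot_gap} ms does not fit the {period * 1000:.0f} ms syllable period"
        )
    rng = np.random.default_rng(truth.seed)
    from scipy import signal as sps

    nyq = RATE / 2
    sos_high = sps.butter(4, [2500 / nyq, 8000 / nyq], btype="band", output="sos")

    n_total = int((truth.syllable_count * period + 2 * EDGE_SILENCE) * RATE)
    x = np.zeros(n_total)
    f0 = truth.f0_mean
    for k in range(truth.syllable_count):
        start = int((EDGE_SILENCE + k * period) * RATE)
        nb = int(_DDK_BURST * RATE)
        burst = sps.sosfilt(sos_high, rng.normal(0, 1, nb + 200))[200:]
        burst /= max(np.max(np.abs(burst)), 1e-12)
        x[start : start + nb] += burst
        ng = int(gap_s * RATE)
        if ng > 0:
            asp = sps.sosfilt(sos_high, rng.normal(0, 1, ng + 200))[200:]
            asp /= max(np.max(np.abs(asp)), 1e-12)
            x[start + nb : start + nb + ng] += 0.18 * asp
        nv = int(_DDK_VOWEL * RATE)
        tv = np.arange(nv) / RATE
        vowel = _harmonic_tone(2 * np.pi * f0 * tv) * _edge_ramp(nv, int(0.005 * RATE))
        v0 = start + nb + ng
        x[v0 : v0 + nv] += 0.6 * vowel / np.max(np.abs(vowel))

    mask = np.abs(x) > 0
    x = _add_noise_at_snr(x, mask, max(truth.snr, 30.0), rng)
    return _finalize(x, "ddk")


_SYL_DUR = 0.150
_SYL_GAP = 0.030  # below the 60 ms pause floor -> merged into speech


def synth_reading(truth: AudioGroundTruth) -> Waveform:
    """Reading passage: voiced pseudo-syllabic stretches alternating with
    silent pauses of exactly the listed durations.

    ``syllable_count`` syllables are distributed over ``len(pause_durations)+1``
    stretches; each syllable is a 150 ms harmonic pulse with per-syllable F0
    offset ~ N(0, f0_sd st) and intensity offset ~ N(0, intensity_sd dB),
    separated within a stretch by 30 ms micro-gaps (below the segmentation
    pause floor).
    """
    if truth.task != "text":
        raise InvalidParameterError("task must be 'text'")
    if not truth.pause_durations:
        raise InvalidParameterError("pause_durations must be non-empty")
    if truth.syllable_count < 1:
        raise InvalidParameterError("syllable_count must be >= 1")
    for p in truth.pause_durations:
        if p < 0.060:
            logger.warning(
                "pause of %.0f ms is below the 60 ms segmentation floor; "
                "synthesized anyway", p * 1000
            )
    rng = np.random.default_rng(truth.seed)

    n_stretch = len(truth.pause_durations) + 1
    counts = np.full(n_stretch, truth.syllable_count // n_stretch)
    counts[: truth.syllable_count % n_stretch] += 1
    counts = np.maximum(counts, 1)

    nsyl = int(_SYL_DUR * RATE)
    tgap = np.zeros(int(_SYL_GAP * RATE))
    tv = np.arange(nsyl) / RATE
    pieces = [np.zeros(int(EDGE_SILENCE * RATE))]
    for i, c in enumerate(counts):
        for j in range(int(c)):
            f0 = truth.f0_mean * 2 ** (rng.normal(0, truth.f0_sd) / 12)
            gain_db = rng.normal(0, truth.intensity_sd)
            syl = _harmonic_tone(2 * np.pi * f0 * tv)
            # arched envelope: a clear intensity peak per syllable with
            # several-dB dips at the micro-gaps, so nuclei are detectable
            env = _edge_ramp(nsyl, int(0.020 * RATE)) * (0.45 + 0.55 * np.sin(np.pi * tv / _SYL_DUR))
            syl = syl * env * 10 ** (gain_db / 20)
            pieces.append(syl)
            if j < c - 1:
                pieces.append(tgap)
        if i < len(truth.pause_durations):
            pieces.append(np.zeros(int(truth.pause_durations[i] * RATE)))
    pieces.append(np.zeros(int(EDGE_SILENCE * RATE)))
    x = np.concatenate(pieces)
    mask = np.abs(x) > 1e-6
    x = _add_noise_at_snr(x, mask, max(truth.snr, 30.0), rng)
    return _finalize(x, "text")


def synth_subject(
    truths: dict[str, AudioGroundTruth]
) -> dict[str, list[Waveform]]:
    """All recordings for one subject/state; phon and ddk performed twice."""
    out: dict[str, list[Waveform]] = {}
    synths = {"phon": synth_phonation, "ddk": synth_ddk, "text": synth_reading}
    for task, truth in truths.items():
        repeats = 2 if task in ("phon", "ddk") else 1
        out[task] = [
            synths[task](replace(truth, seed=truth.seed + 7919 * r)) for r in range(repeats)
        ]
    return out


# ---------------------------------------------------------------------------
# feature-level cohorts


#: Hypokinetic planted loadings (feature change per unit latent response D),
#: expressed in units of the feature's healthy-control SD; signs mirror the
#: direction in which each biomarker improves when hypokinetic symptoms do.
DEFAULT_HYPO_LOADINGS: dict[str, float] = {
    "sdF0_text": +1.0,
    "Int_kurt_text": -1.0,
    "RST_text": +1.0,
    "LTAS_skew": -1.0,
    "Int_sd_text": +1.0,
    "NSR_text": +1.0,
    "LTAS_mean": +1.0,
    "VOT_ddk": -1.0,
}

#: Hyperkinetic planted loadings (feature change per unit dyskinesia K).
DEFAULT_HYPER_LOADINGS: dict[str, float] = {
    "MPT_phon": +1.0,
    "Int_sd_text": +0.8,
    "Int_sd_phon": -1.0,
    "LTAS_sd": +1.0,
    "LTAS_skew": +0.8,
    "LTAS_kurt": -1.0,
}

#: Healthy-control reference mean and SD per biomarker (plausible magnitudes
#: in each feature's natural units; the analysis chain is scale-free).
HC_REFERENCE: dict[str, tuple[float, float]] = {
    "sdF0_text": (2.5, 0.5),
    "Int_sd_text": (6.0, 1.0),
    "Int_kurt_text": (3.0, 0.8),
    "Int_skew_text": (-0.5, 0.4),
    "NSR_text": (4.5, 0.6),
    "DPI_text": (350.0, 80.0),
    "RST_text": (50.0, 8.0),
    "VOT_ddk": (25.0, 5.0),
    "HNR_phon": (20.0, 3.0),
    "MPT_phon": (15.0, 4.0),
    "Int_slope_phon": (-1.0, 0.5),
    "Int_sd_phon": (1.5, 0.5),
    "LTAS_mean": (500.0, 80.0),
    "LTAS_sd": (800.0, 120.0),
    "LTAS_skew": (2.0, 0.5),
    "LTAS_kurt": (8.0, 2.0),
}

#: OFF-state PD shift from the HC mean, in HC-SD units (hypokinetic
#: dysarthria: reduced pitch/loudness variability, slower timing, longer
#: pauses, steeper intensity decay).
DEFAULT_OFF_SHIFTS: dict[str, float] = {
    "sdF0_text": -1.2,
    "Int_sd_text": -1.0,
    "NSR_text": -0.9,
    "DPI_text": +0.9,
    "RST_text": -0.8,
    "Int_slope_phon": -0.8,
    "LTAS_mean": -0.7,
    "LTAS_skew": +0.6,
    "LTAS_kurt": +0.5,
    "HNR_phon": -0.5,
    "MPT_phon": -0.5,
    "VOT_ddk": +0.5,
    "Int_kurt_text": +0.4,
}

LATENT_SD = 0.1  # SD of the latent responses around their mean of 1
LATENT_CORR = 0.3  # correlation between dopaminergic response D and dyskinesia K
UPDRS_GAIN = 17.0  # mean no-tremor MDS-UPDRS-III improvement at effect_scale 1
MARCONI_GAIN = 4.0  # mean axial Marconi increase at effect_scale 1

# Idiosyncratic change noise per feature, in HC-SD units.  The clinical
# changes respond to the *realized* standardized feature changes (latent
# response plus this noise), so every planted feature carries a genuine
# partial coefficient; together with the outcome noise below this calibrates
# the 8-predictor hypokinetic model to an in-sample R^2 near 0.6 at n = 51.
FEATURE_NOISE_SD = 1.0
OUTCOME_NOISE_SD = 5.1  # residual SD of the UPDRS change, points
MARCONI_NOISE_SD = 3.2  # residual SD of the Marconi axial change, points

#: collapsed MDS-UPDRS-III item maxima (laterality summed)
UPDRS3_ITEM_MAX: dict[str, int] = {
    "updrs3_01": 4, "updrs3_02": 4, "updrs3_03": 20, "updrs3_04": 8,
    "updrs3_05": 8, "updrs3_06": 8, "updrs3_07": 8, "updrs3_08": 8,
    "updrs3_09": 4, "updrs3_10": 4, "updrs3_11": 4, "updrs3_12": 4,
    "updrs3_13": 4, "updrs3_14": 4, "updrs3_15": 8, "updrs3_16": 8,
    "updrs3_17": 20, "updrs3_18": 4,
}
BRADY_ITEMS = ("updrs3_04", "updrs3_05", "updrs3_06", "updrs3_07", "updrs3_08")
RIGIDITY_ITEMS = ("updrs3_03",)
AXIAL_ITEMS = ("updrs3_01", "updrs3_02", "updrs3_09", "updrs3_10",
               "updrs3_11", "updrs3_12", "updrs3_13", "updrs3_14")
TREMOR_ITEMS = ("updrs3_15", "updrs3_16", "updrs3_17", "updrs3_18")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Conditions for one synthetic OFF/ON cohort.

    Defaults emulate the study design this package targets: 51 PD patients
    with moderate-to-severe motor fluctuations assessed OFF and ON, 43
    language/gender-matched healthy controls, 8 planted hypokinetic and 6
    planted hyperkinetic biomarker responses.
    """

    n_pd: int = 51
    n_hc: int = 43
    planted_hypo_features: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HYPO_LOADINGS)
    )
    planted_hyper_features: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HYPER_LOADINGS)
    )
    noise_sd: dict[str, float] | None = None
    outcome_noise_sd: float = OUTCOME_NOISE_SD
    effect_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pd < 3:
            raise InvalidParameterError("n_pd must be >= 3")
        for name, mapping in (
            ("planted_hypo_features", self.planted_hypo_features),
            ("planted_hyper_features", self.planted_hyper_features),
        ):
            for feat, loading in mapping.items():
                if feat not in FEATURE_NAMES:
                    raise InvalidParameterError(
                        f"{name}: {feat!r} is not one of the 16 canonical biomarkers"
                    )
                if not np.isfinite(loading):
                    raise InvalidParameterError(f"{name}: loading for {feat} not finite")


@dataclass
class PairedCohortTable:
    """Per-subject OFF/ON biomarker vectors, clinical records and HC rows."""

    features_off: pd.DataFrame
    features_on: pd.DataFrame
    clinical_off: pd.DataFrame
    clinical_on: pd.DataFrame
    demographics: pd.DataFrame
    hc_features: pd.DataFrame | None = None
    hc_covariates: pd.DataFrame | None = None
    truth: dict | None = None

    def change(self) -> pd.DataFrame:
        """Biomarker change scores, ON − OFF."""
        return self.features_on - self.features_off

    def clinical_change(self, column: str) -> pd.Series:
        return self.clinical_on[column] - self.clinical_off[column]

    @property
    def subjects(self) -> pd.Index:
        return self.features_off.index


def _updrs_totals(items: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=items.index)
    out["updrs3_total"] = items.sum(axis=1)
    out["updrs3_no_tremor"] = items.drop(columns=list(TREMOR_ITEMS)).sum(axis=1)
    out["updrs3_brady"] = items[list(BRADY_ITEMS)].sum(axis=1)
    out["updrs3_rigidity"] = items[list(RIGIDITY_ITEMS)].sum(axis=1)
    out["updrs3_axial"] = items[list(AXIAL_ITEMS)].sum(axis=1)
    out["updrs3_tremor"] = items[list(TREMOR_ITEMS)].sum(axis=1)
    return out


def _sample_updrs_off(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """OFF-state item scores targeting a moderate-to-severe no-tremor total."""
    target = np.clip(rng.normal(33.0, 8.0, n), 8.0, 75.0)
    weights = {"brady": 0.45, "axial": 0.30, "rigidity": 0.25}
    items = pd.DataFrame(
        0.0, index=range(n), columns=list(UPDRS3_ITEM_MAX), dtype=float
    )
    groups = {
        "brady": BRADY_ITEMS,
        "axial": AXIAL_ITEMS,
        "rigidity": RIGIDITY_ITEMS,
    }
    for g, names in groups.items():
        share = target * weights[g]
        w = rng.dirichlet(np.ones(len(names)) * 4.0, size=n)
        for j, it in enumerate(names):
            items[it] = np.minimum(share * w[:, j], UPDRS3_ITEM_MAX[it])
    for it in TREMOR_ITEMS:
        items[it] = np.minimum(
            rng.poisson(1.0, n).astype(float), UPDRS3_ITEM_MAX[it]
        )
    return items.round()


def _apply_updrs_change(
    items_off: pd.DataFrame, delta_nt: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """ON items: subtract the no-tremor improvement, weighted 50/30/20 across
    bradykinesia/axial/rigidity; tremor items change only by noise."""
    items_on = items_off.copy().astype(float)
    weights = {"brady": 0.5, "axial": 0.3, "rigidity": 0.2}
    groups = {"brady": BRADY_ITEMS, "axial": AXIAL_ITEMS, "rigidity": RIGIDITY_ITEMS}
    for i in items_off.index:
        drop = -float(delta_nt[i])  # positive improvement magnitude
        totals = {g: float(items_off.loc[i, list(n_)].sum()) for g, n_ in groups.items()}
        drops = {g: drop * w for g, w in weights.items()}
        # redistribute overflow so capped groups do not shrink the total change
        for _ in range(3):
            overflow = 0.0
            headroom = {g: totals[g] - min(drops[g], totals[g]) for g in groups}
            for g in groups:
                if drops[g] > totals[g]:
                    overflow += drops[g] - totals[g]
                    drops[g] = totals[g]
            open_room = sum(headroom[g] for g in groups if headroom[g] > 0)
            if overflow <= 1e-9 or open_room <= 0:
                break
            for g in groups:
                if headroom[g] > 0:
                    drops[g] += overflow * headroom[g] / open_room
        for g, names in groups.items():
            if totals[g] > 0:
                frac = min(drops[g], totals[g]) / totals[g]
                items_on.loc[i, list(names)] = items_off.loc[i, list(names)] * (1 - frac)
    for it in TREMOR_ITEMS:
        items_on[it] = np.clip(
            items_off[it] + rng.integers(-1, 2, len(items_off)),
            0, UPDRS3_ITEM_MAX[it],
        )
    return items_on.round().clip(lower=0)


def gen_cohort(spec: SyntheticCohortSpec) -> PairedCohortTable:
    """Generate a paired OFF/ON cohort with planted latent response structure.

    Two correlated latent components drive the changes: the dopaminergic
    response ``D_i`` (mean 1, SD 0.3, truncated at 0) drives the hypokinetic
    feature changes and the no-tremor MDS-UPDRS-III improvement; the
    dyskinesia component ``K_i`` (same marginal, correlation 0.3 with D)
    drives the hyperkinetic feature changes and the axial Marconi increase.
    ``effect_scale = 0`` yields a null cohort with no feature-outcome link.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pd
    feats = list(FEATURE_NAMES)

    # latent responses
    cov = LATENT_SD**2 * np.array([[1.0, LATENT_CORR], [LATENT_CORR, 1.0]])
    latent = rng.multivariate_normal([1.0, 1.0], cov, size=n)
    latent = np.clip(latent, 0.0, None)
    D, K = latent[:, 0], latent[:, 1]

    hc_mean = np.array([HC_REFERENCE[f][0] for f in feats])
    hc_sd = np.array([HC_REFERENCE[f][1] for f in feats])

    # OFF baselines, HC-referenced
    shift = np.array([DEFAULT_OFF_SHIFTS.get(f, 0.0) for f in feats])
    off = hc_mean + shift * hc_sd + rng.normal(0, 1.2, (n, len(feats))) * hc_sd
    features_off = pd.DataFrame(off, columns=feats)

    # change scores: latent component plus idiosyncratic noise per feature
    noise_sd = np.zeros(len(feats))
    lam_d = np.zeros(len(feats))
    lam_k = np.zeros(len(feats))
    for j, f in enumerate(feats):
        lam_d[j] = spec.planted_hypo_features.get(f, 0.0)
        lam_k[j] = spec.planted_hyper_features.get(f, 0.0)
        if spec.noise_sd is not None and f in spec.noise_sd:
            noise_sd[j] = spec.noise_sd[f]
        else:
            noise_sd[j] = FEATURE_NOISE_SD * hc_sd[j]
    eps = rng.normal(0, 1, (n, len(feats))) * noise_sd
    delta = (
        spec.effect_scale * (np.outer(D, lam_d) + np.outer(K, lam_k)) * hc_sd
        + eps
    )
    features_on = features_off + delta

    # clinical outcomes respond to the realized standardized feature changes,
    # oriented by the planted loading signs; effect_scale = 0 severs the link
    z = delta / hc_sd
    hypo_names = list(spec.planted_hypo_features)
    hyper_names = list(spec.planted_hyper_features)
    hypo_sum = np.zeros(n)
    for f in hypo_names:
        j = feats.index(f)
        hypo_sum += np.sign(spec.planted_hypo_features[f]) * z[:, j]
    hyper_sum = np.zeros(n)
    for f in hyper_names:
        j = feats.index(f)
        hyper_sum += np.sign(spec.planted_hyper_features[f]) * z[:, j]
    abs_hypo = sum(abs(v) for v in spec.planted_hypo_features.values()) or 1.0
    abs_hyper = sum(abs(v) for v in spec.planted_hyper_features.values()) or 1.0
    c_updrs = UPDRS_GAIN / abs_hypo
    c_marconi = MARCONI_GAIN / abs_hyper

    delta_nt = -c_updrs * spec.effect_scale * hypo_sum + rng.normal(
        0, spec.outcome_noise_sd, n
    )
    delta_nt = np.minimum(delta_nt, 0.0)
    items_off = _sample_updrs_off(n, rng)
    nt_off = items_off.drop(columns=list(TREMOR_ITEMS)).sum(axis=1).to_numpy()
    delta_nt = np.clip(delta_nt, -nt_off, 0.0)  # ON no-tremor total stays in [0, 92]
    items_on = _apply_updrs_change(items_off, delta_nt, rng)

    marconi_off = np.round(np.abs(rng.normal(0.0, 0.4, n)))
    delta_marconi = c_marconi * spec.effect_scale * hyper_sum + rng.normal(
        0, MARCONI_NOISE_SD, n
    )
    marconi_on = np.clip(np.round(marconi_off + delta_marconi), 0, 12)

    demo = pd.DataFrame(
        {
            "age": np.clip(rng.normal(63.0, 8.0, n), 35, 90),
            "gender": rng.choice(["m", "f"], size=n, p=[0.8, 0.2]),
            "language": rng.choice(
                ["german", "french", "italian", "english"],
                size=n, p=[0.66, 0.22, 0.10, 0.02],
            ),
            "moca": np.clip(np.round(rng.normal(26.0, 3.0, n)), 10, 30),
            "disease_duration": np.clip(rng.normal(11.0, 4.0, n), 1, 30),
        }
    )

    def clinical_frame(items: pd.DataFrame, marconi: np.ndarray) -> pd.DataFrame:
        cf = pd.concat([items, _updrs_totals(items)], axis=1)
        cf["marconi_axial"] = marconi
        cf["updrs1"] = np.clip(np.round(rng.normal(12.6, 5.2, n)), 0, 52)
        cf["updrs2"] = np.clip(np.round(rng.normal(15.6, 6.4, n)), 0, 52)
        cf["updrs4"] = np.clip(np.round(rng.normal(9.7, 4.2, n)), 0, 24)
        return cf

    clinical_off = clinical_frame(items_off, marconi_off)
    clinical_on = clinical_frame(items_on, marconi_on)

    hc_features = pd.DataFrame(
        hc_mean + rng.normal(0, 1, (spec.n_hc, len(feats))) * hc_sd, columns=feats
    )
    hc_covariates = pd.DataFrame(
        {
            "age": np.clip(rng.normal(67.0, 8.5, spec.n_hc), 35, 95),
            "gender": rng.choice(["m", "f"], size=spec.n_hc, p=[0.79, 0.21]),
            "moca": np.clip(np.round(rng.normal(26.7, 2.3, spec.n_hc)), 10, 30),
        }
    )

    truth = {
        "spec": spec,
        "D": D,
        "K": K,
        "planted_hypo": dict(spec.planted_hypo_features),
        "planted_hyper": dict(spec.planted_hyper_features),
    }
    return PairedCohortTable(
        features_off=features_off,
        features_on=features_on,
        clinical_off=clinical_off,
        clinical_on=clinical_on,
        demographics=demo,
        hc_features=hc_features,
        hc_covariates=hc_covariates,
        truth=truth,
    )
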