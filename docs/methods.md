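# Methods

This note documents the models, algorithmic defaults and design choices
behind `levospeech`, in the spirit of a methods appendix: what is computed,
why the defaults are what they are, and what the synthetic ground truth does
and does not establish.

## 1. Acoustic analysis

All analysis operates on mono waveforms at 48 kHz (other rates are resampled
on load), framed at **40 ms with a 10 ms hop**.

**F0 tracking.** Frame-wise autocorrelation of the Hann-windowed,
mean-subtracted frame, normalized by the autocorrelation of the window
itself so a perfectly periodic frame scores ~1 at its period lag. The search
range is **60–400 Hz**; a frame is voiced when the corrected peak exceeds
**0.45** and the frame is within 35 dB of the loudest frame. A small octave
cost (0.02 per octave of lag) resolves the tie between the true period and
its multiples; frames whose F0 jumps more than 5 semitones off a 5-point
median track are unvoiced retroactively (octave errors and segment-boundary
frames). sdF0 is the SD of the voiced F0 contour in **semitones relative to
the speaker's (geometric) mean F0**, making it invariant to the speaker's
register.

**Intensity.** Frame RMS in dB re the waveform peak, floored at −80 dB.
Because every intensity statistic used downstream (SD, skewness, kurtosis,
slope) is shift-invariant on the dB scale, all 16 biomarkers are invariant
to overall amplitude scaling — the package asserts this property in tests.

**Segmentation.** Energy threshold at −35 dB re the loudest frame; pauses
shorter than **60 ms** merge into speech, speech stretches shorter than
**60 ms** are relabeled as pause; pauses are gaps *between* speech intervals
(leading/trailing silence is neither). Because an analysis window
overlapping a speech edge by a few milliseconds already clears the
threshold, interval edges are pulled in by (frame − hop)/2; with the default
frame/hop this recovers planted pause durations to within ±10 ms. Syllable
nuclei are intensity peaks (prominence ≥ 2 dB, separation ≥ 80 ms) at voiced
frames within speech.

**Timing features.** NSR = detected syllable nuclei per second of net
speech time. DPI = mean pause duration (ms). RST = (number of speech +
pause segments) per minute of total passage duration. The literature that
introduced these labels does not pin down single formulas; these definitions
are documented stand-ins chosen for monotonicity with their names and are
configurable at the segmentation level.

**VOT.** Bursts are rises of the >2.5 kHz envelope, voicing onsets rises of
the <1.5 kHz envelope after each burst; both onsets are back-extrapolated
from the 15%/40% crossings to cancel the smoothing latency of the 4 ms
moving-RMS envelope, giving millisecond resolution independent of the frame
grid. VOT is the mean burst-to-voicing interval; fewer than three measurable
syllables yields a missing marker.

**HNR.** The window-corrected periodicity r of each voiced frame is mapped
to 10·log10(r/(1−r)) dB and averaged. For a harmonic source in white noise
this estimates the SNR; the estimate is accurate to ±3 dB in the 5–25 dB
range and saturates above ~35 dB, where the window correction dominates the
residual.

**LTAS.** Welch spectrum (2048-point segments, Hann) of the concatenated
speech-interval samples, restricted to **0–8 kHz**, normalized to a
distribution over frequency; the four features are its mean, SD, skewness
and (non-excess) kurtosis. Linear power weights are the default; a dB-weight
dialect is available (`ltas_db_weights`) since conventions differ across
labs. Moments agree with a brute-force numerical-moment oracle to 1e−6
relative in tests.

**Missing data.** Features that cannot be computed (no voiced frames, too
few syllables, silent input) propagate as NaN markers with logged warnings,
never as silent zeros. Phonation/DDK features are averaged over repeat
recordings, matching a protocol that performs those tasks twice.

## 2. Synthetic audio

The synthesizer plants exactly the parameters the extractor measures. The
glottal source is a sum of 10 harmonics with a −12 dB/octave power rolloff —
deliberately simple so the LTAS moments stay analytically predictable; no
formant filtering (a config option deliberately left off by default).
Phonation carries a sinusoidal vibrato (the F0-track SD of a ±A st vibrato
is A/√2 st — a closed-form oracle used in tests), a dB/s amplitude envelope,
and white noise at a planted SNR. DDK syllables are a 4 ms high-band click,
a planted aspiration gap, then a low-band vowel, so burst and voicing onsets
are separable by band. The reading task alternates pseudo-syllable stretches
(150 ms arched syllables with 30 ms micro-gaps, below the pause floor) with
silent pauses of exactly the listed durations. Waveforms are peak-normalized
and quantized to the 16-bit grid; identical seeds give byte-identical audio.

These signals establish that the extraction chain recovers planted
parameters; they do not establish robustness to formants, reverberation,
channel noise or conversational speech, which real recordings would add.

## 3. Synthetic cohorts

The feature-level generator emulates a cohort of 51 PD patients with motor
fluctuations assessed OFF and ON, plus 43 language/gender-matched healthy
controls (HC). Per subject two latent components are drawn, truncated at 0:
a dopaminergic response D ~ N(1, 0.1²) and a dyskinesia component
K ~ N(1, 0.1²), correlated at 0.3. Biomarker changes are

    Δx_k = s_k · ( λ_k·D + γ_k·K ) · effect_scale + ε_k,   ε_k ~ N(0, s_k²),

where s_k is the feature's HC SD, λ (8 features) and γ (6 features) are the
planted hypokinetic and hyperkinetic loadings (defaults ±1, signs following
the direction in which each biomarker improves), and ε is idiosyncratic.
The clinical changes respond to the **realized standardized feature
changes**:

    ΔUPDRS_nt = −(17/Σ|λ|) · effect_scale · Σ_k sign(λ_k)·(Δx_k/s_k) + η,
    ΔMarconi  = +(4/Σ|γ|) · effect_scale · Σ_k sign(γ_k)·(Δx_k/s_k) + η_m,

with η ~ N(0, 5.1²) and η_m ~ N(0, 3.2²), bounded to the scales' ranges
([0, 92] without tremor items; [0, 12] axial). OFF baselines are drawn
HC-referenced with shifts in the directions characteristic of hypokinetic
dysarthria, so PD-vs-HC contrasts exist; ON = OFF + Δ holds exactly.
MDS-UPDRS-III item scores (laterality collapsed) are generated so that the
improvement is absorbed 50/30/20 by the bradykinesia/axial/rigidity item
groups with overflow redistribution, while tremor items change only by
noise — this is what makes bradykinesia and axial subscores predictable
from speech changes and tremor not.

Two design choices deserve emphasis:

- *Measurement-mediated outcome.* If the clinical change depended on the
  latent D alone, the 8 planted features would be statistically
  exchangeable proxies and no selection procedure could be expected to
  retain all of them at n = 51. Coupling the outcome to the realized
  feature changes gives every planted feature a genuine partial
  coefficient. Likewise the latent heterogeneity is kept small (SD 0.1)
  because a strong shared component reintroduces proxy redundancy.
- *Calibration.* The outcome noises are set so the stepwise hypokinetic
  model explains a true fraction ≈ 0.6 of the outcome variance (in-sample
  medians run ≈ 0.65 through selection optimism at n = 51) and the
  hyperkinetic model ≈ 0.37 in-sample. Under these conditions backward
  stepwise recovers ≥ 6 of the 8 planted hypokinetic features in ~90% of
  seeds.

The generator is an emulation for validating machinery, not a claim about
patient data. In particular its univariate OFF/ON effect sizes (~1 SD of
the change distribution) are larger than the modest effects clinical
studies report (~0.3–0.5): with a single response factor at n = 51 one
cannot simultaneously plant small univariate effects and a multivariable
model explaining ~60% of outcome variance with eight recoverable
predictors. The generator is calibrated for the latter, structural
properties; conclusions about univariate sensitivity on real data do not
follow from it.

With `effect_scale = 0` both couplings vanish: feature changes are pure
noise and clinical changes are pure noise, giving exact null cohorts.

## 4. Statistics

Paired OFF/ON comparisons route on the Shapiro–Wilk normality of the paired
*differences* (they are what the paired test sees) at α = 0.05: normal →
paired t with Cohen's d (mean difference / SD of differences); otherwise
Wilcoxon signed-rank with the matched-pairs rank-biserial correlation
(W⁺ − W⁻)/(W⁺ + W⁻). Change direction is ON − OFF throughout. Holm–
Bonferroni is implemented step-down with monotonicity enforcement and is
cross-checked against statsmodels in tests. Effect-magnitude labels use the
conventional ≤0.2 / ≤0.5 / ≥0.8 thresholds with the (0.5, 0.8) gap labeled
"medium-to-large". PD-vs-HC contrasts fit `feature ~ group + age + gender +
MoCA` by OLS with the standardized group β as effect size; gender is a
binary indicator and language is not a covariate. Paired-t power is exact
noncentral-t (df = n−1, noncentrality d√n), verified against a
100,000-replicate Monte Carlo within ±0.01.

## 5. Stepwise selection and relative importance

Backward elimination starts from the full candidate pool (default: all 16
change scores — the selected panel is the natural candidate set, and the
retained subsets emerge from selection, not curation) and removes whichever
predictor's removal lowers AIC most, stopping at a local AIC optimum; ties
break lexicographically on feature names so runs are reproducible.
Collinear pools (condition number > 1e8) raise an error naming the
offending pair. The logistic variant uses binomial-deviance AIC and falls
back to a small-L2 (α = 0.01, intercept unpenalized) Newton fit under
perfect separation, with a logged warning.

LMG importance is the Shapley decomposition of R²: the average over all p!
predictor orderings of each predictor's sequential R² increment. pmvd
(Feldman 2005) averages the same increments with data-dependent ordering
weights ∝ Π over proper non-empty prefixes S of 1/(R²_full − R²(S)); a
prefix that already attains the full R² is regularized at 1e−12. Both are
computed exactly by dynamic programming over the memoized 2^p subset-R²
lattice (orderings are never enumerated), guarded at p ≤ 12 with a seeded
ordering-sampling mode beyond. Tests verify LMG and pmvd against explicit
p! enumeration (1e−10), shares summing to R², non-negativity, permutation
invariance, and pmvd's defining exclusion property (a correlated predictor
with zero population coefficient receives <1% of R² at n = 5000, where LMG
gives it >5%). For logistic models the same machinery runs on sequential
McFadden pseudo-R² increments — a documented stand-in, since no standard
logistic convention exists.

Compound scores z-score each selected change against the PD cohort's change
distribution (the reference is captured in the score definition, so a score
can be transferred to new data), weight by normalized importance shares and
sign by the final coefficients. The build∘apply composition is invariant to
affine rescaling of any raw feature.

## 6. Evaluation

LOOCV refits coefficients per fold with the feature set fixed — selection
runs once on the full data, mirroring common practice in clinical modeling
papers. This choice retains **selection optimism**: on null cohorts the
non-nested LOOCV transition AUC sits near 0.67, not 0.5, purely from
selection leakage. The package therefore exposes `nested_selection=True`
(per-fold re-selection), and the null-cohort validation uses that
leakage-free route (AUC ≈ 0.5) together with compound-definition transfer
to independent null cohorts (|r| ≈ 0.1). The contrast between the two
routes is itself informative about how much optimism the
selection-once protocol leaves in reported metrics. OLS LOOCV residuals are
verified against the hat-matrix identity e_i/(1 − h_ii) to 1e−8.

The transition experiment assigns each subject a fair-coin label from a
seeded generator; label 0 keeps the ON−OFF change vector (OFF→ON), label 1
negates it (ON→OFF) — signed orientation on both branches, the only
construction under which a classifier can recover the transition direction.
The candidate pool is the union of the features selected by the hypokinetic
and hyperkinetic models. AUC is computed from pooled LOO probabilities by
the Mann–Whitney rank statistic (exact pair-counting equivalence is tested
up to n = 200); confusion metrics use threshold 0.5; the accuracy interval
is Clopper–Pearson. With balanced labels at n = 51 the null deviance equals
2n·ln 2 ≈ 70.7 — a structural identity the tests check.

## 7. Problem sizes and determinism

Default analyses run at the study scale (51 PD / 43 HC). Simulation-based
checks use 20–50 seeds per property, and the acceptance script uses 30
cohort seeds (12 for transition AUC, 5 for the nested null AUC, 10 audio
seeds) — sizes chosen so the medians and rates they estimate are stable at
the tolerances asserted. Every stochastic step takes an explicit seed;
identical seeds give identical audio, cohorts and model outputs.

## 8. Known limitations

- The audio model has no formants, consonant variety or prosodic phrasing;
  acoustic recovery results bound algorithmic error, not robustness on real
  speech (noise, microphone and channel effects are known to hit intensity
  measures hardest).
- RST and NSR follow documented in-package definitions; other labs'
  conventions may differ by constant factors.
- The cohort generator's effect sizes are calibration-driven (see §3); its
  transition AUC (~0.99) is accordingly higher than a real cohort would
  give.
- HNR saturates above ~35 dB; VOT assumes aspirated stop bursts separable
  from voicing in frequency.
- pmvd beyond 12 predictors requires the sampling mode; sampled shares are
  unbiased but noisy.
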