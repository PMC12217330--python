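# levospeech

Digital speech biomarkers of acute levodopa response in Parkinson's disease
(PD).

Speech in PD is affected by hypokinetic dysarthria — monopitch, monoloudness,
imprecise consonants, dysphonia, respiratory insufficiency — and, under
dopaminergic medication, by peak-dose dyskinesia. This package implements the
full analysis chain of an OFF/ON levodopa-challenge speech study for
researchers in clinical speech signal processing and movement disorders:

- **16 digital speech biomarkers** from three tasks — sustained /a/ phonation,
  fast /pa-ta-ka/ repetition (DDK), and a reading passage: sdF0 (monopitch),
  intensity SD/kurtosis/skewness, net speech rate (NSR), duration of pause
  intervals (DPI), rate of speech timing (RST), voice onset time (VOT),
  harmonics-to-noise ratio (HNR), maximal phonation time (MPT), intensity
  slope and SD during phonation, and the first four standardized moments of
  the long-term average spectrum (LTAS).
- **Paired OFF/ON statistics**: Shapiro–Wilk-routed paired t / Wilcoxon
  tests, Holm–Bonferroni correction, Cohen's d / rank-biserial effect sizes,
  covariate-adjusted PD-vs-HC regression contrasts, test–retest reliability,
  and the exact noncentral-t power of the paired design.
- **Modeling**: backward stepwise selection by AIC (linear and logistic),
  relative importance by proportional marginal variance decomposition
  (pmvd, Feldman 2005) or LMG, and weighted z-scored **compound scores** for
  the hypokinetic and hyperkinetic speech domains.
- **Evaluation**: leave-one-out cross-validation (MAE, RMSE, R²_pred),
  per-subscore prediction, and a randomized **medication-state-transition
  classifier** with LOOCV ROC analysis.
- **Synthetic ground truth**: because patient voice recordings from such
  studies cannot be shared, the package generates task audio with planted
  acoustic parameters and feature-level OFF/ON cohorts with a planted latent
  dopaminergic-response structure, so every stage is testable end to end.

## The model at the core

For each subject the change score of every biomarker is Δx = x(ON) − x(OFF).
The hypokinetic model regresses the no-tremor MDS-UPDRS-III change
(range /92) on the 16 Δx by backward stepwise AIC; the hyperkinetic model
does the same for the axial Marconi dyskinesia change (/12). The model R² is
decomposed over predictor orderings into pmvd importance shares
w<sub>k</sub>, and the compound score is

    S = Σ_k  sign(β_k) · w_k · z_k(Δx_k),

with z-scoring against the cohort's change distribution. The transition
experiment assigns each subject a fair-coin label, keeps Δx for label 0
(OFF→ON) and negates it for label 1 (ON→OFF), and asks a stepwise logistic
model to recover the orientation under LOOCV.

## Worked example

```bash
python examples/03_stepwise_and_compound.py
```

prints, for the default synthetic cohort (51 PD subjects):

```
selected (10): Int_kurt_text, Int_sd_text, Int_slope_phon, LTAS_mean,
LTAS_skew, MPT_phon, NSR_text, RST_text, VOT_ddk, sdF0_text
in-sample R2 0.72, adjusted 0.66

pmvd importance shares (sum to R2):
VOT_ddk           0.150
Int_kurt_text     0.147
sdF0_text         0.129
...

compound score vs clinical change: r = 0.82
LOOCV of the selected model: MAE 4.56/92, RMSE 5.81/92, R2_pred 0.54
```

The selected set recovers the planted hypokinetic biomarkers (8 of 8 here,
plus two spurious extras, as expected for AIC at n = 51); the compound
score correlates strongly with the clinical change, and LOOCV shows how much
of that survives out-of-sample. `examples/01_synthesize_and_extract.py`
shows planted acoustic parameters (phonation time, intensity slope, SNR,
VOT, pauses) being recovered from synthesized audio;
`examples/02_paired_statistics.py` the univariate OFF/ON layer (including
the 0.94 / 0.998 power of the paired design at d = 0.5 / 0.7);
`examples/04_transition_classifier.py` the medication-state-transition ROC.

A thin CLI covers the same pipeline on files:

```bash
levospeech simulate --out-dir sim --features-only --seed 1
levospeech evaluate --features-csv sim/features.csv \
    --clinical-csv sim/clinical.csv --out-dir reports
```

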