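# Methods

## Acoustic measure

Each annotated sibilant token is reduced to one number, its spectral
centroid, in four steps.

1. **Mid-segment window.** A 40 ms span centred on the token midpoint
   (sample indices by `round(t·fs)`, half-open intervals). Tokens shorter
   than 40 ms are analysed whole and flagged rather than dropped: a short
   token still carries frication, and dropping it would bias per-child
   means for fast speakers.
2. **DPSS tapers.** K orthonormal discrete prolate spheroidal sequences
   (symmetric tridiagonal formulation, via `scipy.signal.windows.dpss`),
   time-bandwidth NW = 4, K = 7 = 2·NW − 1. This is the standard Thomson
   choice: K = 2NW − 1 uses every well-concentrated taper (concentrations
   at the default window length: the first six exceed 0.99, the seventh
   ≈ 0.94) for maximal variance reduction at acceptable bias. Both NW and
   K are configurable.
3. **Multitaper PSD.** Unweighted mean of the K eigenspectra (adaptive
   weighting would change results by well under the between-token spread
   and costs determinism-by-inspection; it is noted as an extension, not
   implemented). The window is demeaned; the one-sided density is scaled
   so its trapezoidal integral over [0, Nyquist] equals the window's
   sample variance. No zero padding: the DFT grid is the window length,
   so the estimate is a pure function of the input.
4. **Centroid.** Power-weighted mean frequency over [550 Hz, Nyquist].
   The 550 Hz floor excludes voicing remnants and room rumble from the
   fricative moment, a common convention in sibilant spectral-moment
   work; full-band and amplitude-weighted modes are exposed for
   sensitivity analyses, since "weighted mean frequency" is ambiguous
   between power and amplitude weights. Power weighting is the default
   because the centroid is defined on the spectral *distribution*, i.e.
   the power spectrum.

No pre-emphasis is applied. Non-44.1 kHz rates are carried through all
the arithmetic; multichannel audio is rejected rather than downmixed
because mixing microphones changes the spectrum being measured.

## Per-child aggregation

A child's score per phoneme is the arithmetic mean of the nine token
centroids (no trimming — no outlier rule is part of the design; a median
mode exists for robustness checks). The differentiation score is
D = mean[s] − mean[ʃ]. Children lacking tokens for either phoneme are
excluded with a logged reason. Group tables use whole-year age bins
(floor of age in days / 365.25); statistics use raw age in days.

Transcription error rates use one denominator — all scored target tokens
of the included children — so the by-phoneme and by-age shares sum to the
total rate before rounding. Rates are printed to one decimal.

## Statistical battery

* Pearson r with two-tailed p from t = r√(n−2)/√(1−r²); pairwise deletion
  of missing ratings (a listwise run is just a pre-filtered call).
* Benjamini–Hochberg at Q = 0.05 across the m = 6 scale family. The table
  reports both the rank-i critical value (i/m)·Q — the quantity each raw
  p is compared against — and the genuine step-up adjusted p-value
  min_{j≥i}(m·p₍ⱼ₎/j); conflating the two is a common reporting error, so
  they are kept in separate columns.
* OLS with intercept; classical covariance SEs; β_j = B_j·sd(x_j)/sd(y);
  model F on (k, n−k−1) df; both R² and adjusted R² are always reported,
  since with F(1, 29) = 12.9 at n = 31 the two differ visibly (0.308 vs
  0.284) and published tables do not always say which they print.
* Moderation: y ~ x + z + x·z with x and z mean-centred before forming
  the product. Centring does not change the interaction test (invariance
  is asserted in the tests) but keeps the main-effect rows interpretable.
* Report rounding: r to 2 decimals, p and BH values to 3, coefficients to
  2, round-half-even throughout.

## Synthetic cohorts

The generator exists so the pipeline's statistical behaviour can be
verified against closed-form truth; it does not attempt acoustically
realistic fricatives (no source-filter or formant-cavity modelling).

* **Tokens.** White Gaussian noise shaped in the frequency domain by an
  envelope E(f) (Gaussian bump, σ = 800 Hz, or flat band), inverse
  transformed, peak-normalised to 0.9 to keep 16-bit headroom. The
  realised power spectrum tracks E(f)² in expectation, so the analytic
  centroid ∫f·E²df / ∫E²df is a valid oracle; the pipeline estimator is
  unbiased within 2% of the centre frequency across 4.5–8.5 kHz.
* **Cohort.** Defaults mirror the target study conditions: 31 children,
  ages uniform on [4, 7) years, nine tokens per sibilant, population
  centroid means 7,400 Hz ([s]) and 5,100 Hz ([ʃ]), between-child SD
  900 Hz. The within-child token SD (400 Hz) is not reported anywhere for
  this design; it was chosen once so simulated group SDs resemble the
  ~0.8–1.6 kHz spread typical of 4-6-year-olds, and is config-exposed.
  Token durations are uniform on [100, 180] ms.
* **EF ratings.** GEC = 50 + 10·(ρ·z + √(1−ρ²)·ε), with z the latent
  differentiation standardised by its population SD (√2·900 Hz) and
  ε ~ N(0,1), so corr(Δ, GEC) = ρ exactly (default ρ = −0.56; negative
  means better EF with a bigger contrast). Subscales are the GEC plus
  independent N(0, 5²) noise — a modelling convenience that makes
  subscale correlations weaker than the GEC's, not a claim about BRIEF
  factor structure. Scores are clipped to the valid t-score range
  [20, 120] (a 3σ event; the effect on ρ is negligible).
* **Transcription labels.** Per-token mistranscription probabilities
  (17% for [ʃ], 2% for [s], modulated ±50% by the child's standardised
  differentiation) give cohort error rates near 9-10% with mostly-[ʃ]
  errors, matching the pattern such tasks produce.
* **Determinism.** All randomness descends from the single cohort seed
  through `numpy.random.SeedSequence` spawning: one stream per child, one
  spawned sequence per token (its first state word, mod 2³¹, is the token
  seed). Identical specs therefore reproduce identical fixture bytes;
  token audio is regenerated on demand from the stored token seed.

### What passing on synthetic data does and does not show

The generator reproduces the *moment structure* the pipeline measures
(centroid location, between/within-child variance, a controlled
articulation-EF correlation). It does not contain coarticulation,
amplitude ramps, voicing leakage, background noise, or channel effects —
so green tests certify the estimator and the statistics, not robustness
of segmentation or of the 550 Hz band edge on noisy field recordings.

### Attenuation of the recovered correlation

The measured score adds token noise to the latent Δ: with per-token
variance σ_w² + σ_est² (within-child jitter plus centroid-estimator
noise, the latter ≈ 40 Hz SD) averaged over 9 tokens per phoneme, the
expected sample correlation shrinks by
λ = √(2σ_b² / (2σ_b² + 2(σ_w² + σ_est²)/9)) ≈ 0.989 at the defaults. The
recovery test checks the 200-cohort mean estimate against λ·ρ within
2 Monte-Carlo SEs; attenuation shrinks as tokens-per-phoneme grows.

## Problem sizes

The test suite simulates 200 replicate 31-child cohorts plus one
500-child cohort through the full audio pipeline (~2.5 minutes on one
CPU); the acceptance script uses 100 replicates (~1 minute). These sizes
put the Monte-Carlo SE of the mean correlation near 0.009, small enough
to detect a mis-specified generator while staying cheap to rerun.

## Known limitations

* The centroid is the only spectral moment used; variance/skew/kurtosis
  of the spectrum are not computed.
* No forced alignment or automatic segmentation: boundaries are taken as
  given, including any co-articulated transitions the annotator included.
* BRIEF raw-item scoring and norm lookup are out of scope; t-scores are
  consumed as input. The BRIEF-vs-BRIEF-P version comparison is served by
  a generic two-sample t-test on shared scales only if both versions
  appear in the input.
* The TextGrid reader handles interval tiers in the long and short text
  formats (UTF-8/UTF-16); point tiers are skipped.
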