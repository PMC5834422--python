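# sibilant-ef

Quantifies how distinctly a child produces the two voiceless sibilant
fricatives — [s] as in *sun* and [ʃ] as in *ship* — and relates that
acoustic skill to parent-rated executive function (EF).

The package is aimed at speech scientists and developmental
psycholinguists who have (a) mono WAV recordings of a word-repetition task
with hand-placed token annotations (TSV or Praat TextGrid) and (b) a CSV
of BRIEF/BRIEF-P t-scores per child. Because such recordings are rarely
shareable, a synthetic-cohort generator with analytically known structure
is a first-class part of the package: every stage of the pipeline can be
exercised, and its statistical behaviour checked, without any real audio.

## The measure and the statistics

For each annotated token, a 40 ms slice centred on the segment midpoint is
analysed with Thomson's multitaper estimator (K = 7 DPSS tapers, NW = 4):

&nbsp;&nbsp;Ŝ(f) = (1/K) Σₖ |DFT(vₖ ⊙ x)|²,&nbsp;&nbsp; scaled so ∫Ŝ(f) df = var(x).

The token's **spectral centroid** is the power-weighted mean frequency
over the analysis band (550 Hz – Nyquist by default):

&nbsp;&nbsp;C = Σ fᵢ Ŝ(fᵢ) / Σ Ŝ(fᵢ).

A child's **differentiation score** is D = C̄ₛ − C̄_ʃ, the difference of the
mean centroids over that child's nine [s] and nine [ʃ] tokens. A larger D
means a crisper sibilant contrast (typical values: 2–2.5 kHz at ages 4–6).

D is then correlated (Pearson) with the BRIEF Global Executive Composite
(GEC) and the five subscales shared by the BRIEF and BRIEF-P forms, with
Benjamini–Hochberg control at a 5% false discovery rate across the
six-test family (rank-i critical value (i/m)·Q, step-up decisions, plus
genuine step-up adjusted p-values). OLS regressions in both directions
(D ~ GEC, GEC ~ D, each with age in days as a covariate, plus a
mean-centred moderation model) report B, SE, standardised β, t, F, R² and
adjusted R². Lower t-scores mean better EF, so a *negative* correlation
says better EF goes with a larger sibilant contrast.

## Worked example

```bash
sibilant-ef demo --seed 7 --n-children 31 --out results/demo
```

prints

```
GEC vs differentiation: r = -0.67, p = 0.000, FDR pass = True
Reports in results/demo
```

and writes one CSV per report table. `table4_correlations.csv`:

```
variable,r,p,n,rank,bh_critical,passes_fdr,adjusted_p
gec,-0.67,0.0,31,1,0.008,True,0.0
inhibit,-0.54,0.002,31,6,0.05,True,0.002
shift,-0.55,0.001,31,5,0.042,True,0.002
emotional_control,-0.62,0.0,31,3,0.025,True,0.0
working_memory,-0.57,0.001,31,4,0.033,True,0.001
plan_organize,-0.63,0.0,31,2,0.017,True,0.0
```

Each row is one EF scale correlated with the differentiation score of the
31 simulated children: the sample r, its two-tailed p, the BH rank and
critical value (i/6)·0.05, the step-up decision, and the adjusted p. Here
the simulated cohort was generated with a population correlation of −0.56
between latent differentiation and GEC, and the whole family is recovered
as significant. `table3_centroids.csv` shows the familiar fricative
geometry — [s] centroids near 7.4 kHz, [ʃ] near 5.1 kHz, differentiation
around 2.5 kHz — by age group.

Real data use `analyze`:

```bash
sibilant-ef analyze --audio-dir wavs/ --segments segments.tsv \
    --ef-csv ef_ratings.csv --out results/study
```

`simulate` writes a complete on-disk fixture (per-child WAVs,
`segments.tsv`, `ef_ratings.csv`, a latent `truth.csv`) that `analyze`
consumes unchanged.

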