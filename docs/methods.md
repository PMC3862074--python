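# Methods note

This note records the exact definitions, numerical conventions and
generator design choices implemented in `hrvrisk`.  Where a published
convention admits variants, the choice made here is stated explicitly.

## Preprocessing

- **Adaptive NN filter** (`io_preprocess.adaptive_nn_filter`): a beat is
  flagged when its annotation is non-normal or when it deviates from an
  exponentially updated reference by more than
  `max(0.20 · ref, 50 ms)`.  The reference is initialized at the median
  interval (robust to ectopy at record start) and updated only on
  accepted beats with smoothing weight 0.1.  Flagged beats are replaced
  by linear interpolation between the nearest accepted neighbours, so
  the beat count is preserved; the flagged fraction is reported as the
  record's ectopy fraction and records strictly above 10 % are excluded.
- **Segments**: `h24` (everything), `first30` (beats within the first
  1800 s), `day30`/`night30` (most stationary 30 min of the clock
  windows 16:00–20:00 and 24:00–04:00).  Stationarity is scored on the
  linearly interpolated interval function resampled at 4 Hz, in 30-min
  windows shifted by 1 min, by `cvNN30min = sdNN30min / meanNN30min³`
  (units 1/ms²) — note the cubed mean, kept deliberately as the
  historical form of this screening statistic rather than the
  conventional coefficient of variation; for windows of comparable mean
  the two orderings agree.  Ties go to the earliest window, and the
  winning window is mapped back to the *original* beats.

## Linear indices

- Time domain: meanNN, sdNN (sample SD, ddof 1), rmssd.
- Spectrum: one periodogram of the whole segment after linear
  interpolation and resampling at 2 Hz, mean removed, 4-term
  Blackman-Harris window, zero-padded to the next power of two,
  density scaling (the window power is compensated, so the integral of
  the density over frequency equals the variance of the resampled
  signal — Parseval).  Band powers are integrated over half-open bands
  VLF (0, 0.04], LF (0.04, 0.15], HF (0.15, 0.4] Hz;
  `P = VLF + LF + HF`; ratios LF/HF and VLF/P; normalized LFn/HFn.
- A caveat worth knowing: linear interpolation of beat-sampled signals
  attenuates power near the upper HF band edge (a 0.25 Hz oscillation
  sampled at ~1.25 beats/s retains roughly 75 % of its variance after
  resampling).  Band powers are therefore exact for the resampled
  signal, slightly conservative for fast oscillations of the underlying
  beat series.  Below ~0.1 Hz the attenuation is under 5 %.

## Symbolic dynamics

- **Classical SD**: symbols relative to the segment mean µ with
  α = 0.1 — `0: µ < NN ≤ 1.1µ`, `1: NN > 1.1µ`, `2: 0.9µ < NN ≤ µ`,
  `3: NN ≤ 0.9µ`; overlapping 3-symbol words (64 types).  `wpsum02` /
  `wpsum13` sum the probabilities of words using only {0,2} / {1,3};
  `pTHk` counts word types with probability strictly above k %.
- **Binary patterns**: successive differences coded 1 when
  `|ΔNN| ≥ 5 ms`; `plvar5`/`phvar5` are the probabilities of the
  all-zero / all-one overlapping 6-word.
- **Segmented short-term SD** (24-h segment only): classical SD per
  30-min window shifted by 1 min (window-local mean), summarized by the
  mean and SD of each index across the S windows and by the Shannon
  entropy of each word type's probability over windows, binned into
  `nob = round(1 + 3.32·log10 S)` bins spanning that word's [min, max]
  (a constant word type has entropy 0).  A gap-free 24-h record gives
  S = 1411 windows.
- **Short-term SD**: non-overlapping 300-beat windows, 6 equal-width
  levels over the window's own [min, max]
  (`level = min(5, floor((x − lo)/(hi − lo)·6))`), families of the
  overlapping 3-symbol patterns: 0V (all equal), 1V (= PLATEAU, exactly
  one equal successive pair), 2V (no equal pair) split into strictly
  monotone ascents/descents, peaks and valleys; reported as per-window
  fractions plus mean/SD aggregates.
- **SD-coded SD**: sliding windows of M = 5 intervals (shift 1); the
  symbol is the count of the 4 successive differences with
  `ΔNN < −1·SD_window` (sample SD); `tau1_p001` counts symbol values
  with probability above 1 %.

## Fractal and Poincaré

- **DFA**: integrate the mean-centred NN series, split into
  non-overlapping boxes of every integer size n = 4…64, remove the
  per-box least-squares line, and average the squared residuals with an
  **(n − 1) per-box denominator** before the square root.  First-order
  DFA overestimates fluctuations in very small boxes; with the naive
  `n` denominator the 4–16-beat slope of white noise comes out ≈ 0.58.
  The (n − 1) convention was calibrated against analytically known
  exponents *before* the acceptance tests were written: it recovers
  α1 ≈ 0.507 / 0.948 / 1.470 for 1/f^β noise with β = 0/1/2 and ≈ 1.43
  for a Brownian walk (20 seeds, N = 10 000).  α1 is the slope of
  log10 F(n) vs log10 n over 4–16, α2 over 16–64; α2 is omitted for
  records shorter than 128 beats.
- **SPPA**: the lag-1 return map is rotated 45° about its centroid;
  a 12×12 grid with cell height SD1 and width SD2 (sample SDs of the
  rotated coordinates) covers ±6 SD, and points beyond are clipped into
  the border cells so no probability mass is lost.  Row/column
  occupation is reported in percent, plus the Shannon entropy of the
  144-cell distribution.  A cloud with SD1 = 0 or SD2 = 0 is an error.

## Statistics

- Screening: two-tailed Mann-Whitney U per index (exact permutation
  null for tie-free samples with min(n) ≤ 25, tie- and
  continuity-corrected normal approximation otherwise), flags at 0.05
  and at a stricter 0.01 level for multiplicity; medians and quartiles
  per group.  Normality is checked with the Lilliefors-corrected KS
  test.
- Candidate pools for the set search: significant indices pruned of
  Pearson redundancy (|r| > 0.7 against an already retained, more
  significant index).  When a composition would be infeasible the pools
  are topped up with the best-ranked remaining indices; the
  non-clinical pool is capped at the 10 smallest-p candidates to keep
  the exhaustive search tractable.
- Five-index sets: exhaustive enumeration under the compositions
  clinical 5+0, non-clinical 0+5, mixed 3+2 and 2+3 (clinical pool:
  BMI, LVEF, LVDD, LVSD, NT-proBNP, NYHA).  Each set is scored by a
  pooled-covariance linear discriminant on standardized features
  (ridge 1e-6 fallback on singular covariance); SENS/SPEC/PPA are read
  at the maximal-Youden-J ROC point and AUC is the trapezoid area.
  Ties resolve to higher SENS, then to the lexicographically smallest
  index set, so results do not depend on candidate order.

## Synthetic cohort generator

Each record is built on the beat axis as

```
NN_n = meanNN + A_c·cos(2π(clock_n − 03:00)/24 h)
       + Σ_b A_b·sin(2π f_b t_n + φ_b) + σ·ε_n,    ε ~ 1/f^β
```

with oscillators at 0.01 / 0.10 / 0.25 Hz, fractal noise from spectral
synthesis (unit variance, exact exponent), clamping to [300, 2000] ms
and truncation at the requested duration.  Ectopy is inserted as
annotated short-long couplets (0.6× / 1.4× the local interval) so the
adaptive filter faces realistic artefacts.  Recording start times are
drawn uniformly from the clinic day (08:00–15:28), so the day/night
clock windows fall at different record offsets per patient.

Group profiles: low-risk — meanNN 860 ms, circadian amplitude 80 ms,
LF amplitude 15 ms, β = 1.6, noise 35 ms, ectopy 2 %; high-risk —
meanNN 816 ms, weaker circadian and LF modulation, β = 1.3, noise
28 ms, ectopy 5 %, plus covariate distributions with higher NT-proBNP
(median 184 vs 70 ng/l) and more NYHA III (45.7 % vs 14.5 %).  The
`contrast` parameter interpolates every generating difference linearly;
contrast 0 makes the groups exchangeable (null calibration).
Between-subject heterogeneity is drawn per record (normal meanNN with
SD 120 ms, log-normal amplitudes and noise, normal β with SD 0.4,
Gamma-distributed ectopy rate), chosen so the cohort's index spread
resembles published inter-quartile ranges rather than collapsing each
group to a point.

**Limitations**: the generator is additive and Gaussian — it has no
respiratory-cardiac phase coupling, no sleep staging, no transient
arrhythmic episodes, and its ectopy is memoryless; absolute index
values (especially rmssd-type short-term variability and the AUCs of
the discriminant sets) should be read as internally consistent for the
simulated model, not as clinical reference values.

## Problem sizes and runtime

Defaults reproduce the study design: 221 low-risk + 35 high-risk
patients, 24-h records (~10⁵ beats each).  On one CPU a full-size run
costs roughly 0.6 s per record for generation + filtering + all-segment
feature extraction (~2.5 min for the cohort) and ~20 s for screening
plus the exhaustive set search; the reduced example cohort (30 + 15)
finishes in under a minute.  All randomness flows from
`numpy.random.SeedSequence` spawns of a single seed, so every table is
bit-reproducible.
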