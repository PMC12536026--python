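# Methods

## Scope and data contract

The pipeline begins where image processing ends. Upstream stages —
realignment, slice timing, smoothing, spatial normalization, tensor
fitting, FA-map ROI placement, FreeSurfer choroid-plexus segmentation —
are assumed done, and their outputs enter through three table contracts:
per-subject gBOLD/CSF time series (TSV, uniform sampling, TR in the
header), per-hemisphere directional diffusivities (CSV), and volumetry
plus clinical fields (CSV). A toy 4-D phantom and mask-mean extraction
exist so the signal-extraction step can be exercised on images, but no
spatial processing is implemented.

## Signal model and preprocessing

A subject's resting-state pair is modelled as

- gBOLD: band-limited Gaussian noise, white noise shaped in the frequency
  domain by a Gaussian envelope (SD 0.015 Hz) centred on a dominant
  frequency f0 and truncated to the analysis band;
- CSF: `sqrt(s) · z(−d/dt gBOLD) + sqrt(1−s) · z(noise)`, where
  `s ∈ [0,1]` is the fraction of CSF variance explained by the negated
  gBOLD derivative and `z(·)` standardizes. Optional half-wave
  rectification mimics the one-sided inflow effect; it is off by default
  so closed-form sinusoid checks hold exactly.

Defaults: 240 volumes at TR = 2 s, f0 = 1/16 Hz, band 0.01–0.1 Hz,
`s = 0.9`. With f0 = 1/16 Hz the derivative relation places the
cross-correlation extrema at a quarter period, ±4 s, exactly on the 2-s
lag grid — the geometry under which the +4 s coupling index is defined.

Temporal preprocessing is: discard the first 10 volumes (magnetization
equilibrium), remove the least-squares linear trend, band-pass
0.01–0.1 Hz, z-score. The band-pass is realized as a hard mask on the
real FFT: exactly zero-phase, passband amplitudes untouched, stopband
(and DC) exactly removed, and idempotent — applying it twice is a no-op,
which the pipeline's invariants rely on. A 4th-order Butterworth
forward–backward filter is available (`method="butterworth"`) for users
who prefer a recursive realization; it meets the same amplitude contract
(≥90% passband retention, ≤10% at twice the upper edge) but attenuates
at the band edges (|H|² = 1/2 per pass), so it is not the default.
Z-scoring is cosmetic for Pearson-based statistics and fixed only for
reproducibility of written artifacts.

The derivative operator is `numpy.gradient`: central differences in the
interior (truncation error ≤ (2πf·TR)²/6 relative, for a sinusoid at
frequency f), one-sided at the ends.

## Coupling statistic and permutation null

`r(L)` pairs the gBOLD sample at `t + L` with the CSF sample at `t`,
computed on the overlapping segment with that segment's own means and
SDs (per-lag renormalization, the standard choice; the alternative of
fixed full-series moments changes nothing at these lengths). The sign
convention is fixed so that CSF = −d/dt gBOLD yields the negative
extremum at *positive* lag, i.e. CSF fluctuations lead gBOLD.

The coupling index is the *signed* negation −r(+4 s), not an absolute
value: group-level summaries (ALS mean 0.01, SD 0.13) imply that
individually negative indices exist, which |·| could not produce.

The permutation null reassigns CSF series across subjects uniformly at
random (identity permitted — with n = 84 its probability is negligible
and the null stays valid), recomputing the group-mean correlogram per
draw. All subject-pair lag correlations are precomputed as an
(n_lags × n × n) array, so 10,000 draws cost one gather per lag rather
than 10,000 re-correlations. The two-sided p uses the add-one estimator
`(1 + #{|null| ≥ |obs|}) / (n_perm + 1)`, which cannot return 0; the 95%
band is the per-lag 2.5th/97.5th percentile of null means.

## Markers

- ALPS: ratio of x-diffusivity (perpendicular to both fiber systems,
  the perivascular orientation) to y/z diffusivity along them. The
  bilateral combining rule is unstated in most reports; the default is
  the mean of per-hemisphere ratios, with a pooled mode (average the
  four diffusivities across hemispheres, then one ratio) exposed — the
  two agree exactly for symmetric hemispheres. The index is unit-free;
  I/O fixes diffusivities at 10⁻³ mm²/s.
- CPV fraction: `100·CPV/TIV`, stored as percent (0.09 means 0.09%).
- Progression rate: `(48 − ALSFRS-R) / duration(months)`, points lost
  per month from the fully functional score of 48.

## Synthetic cohort

Marker marginals are normal except where the study cohort is visibly
skewed: the HC CPV fraction is log-normal (median 0.06%, log-SD 0.25,
matching the reported median and IQR), and ALS disease duration is
log-normal (median 17.5 months, log-SD 0.586, i.e. mean ≈ 20.8, SD
≈ 13.3 — durations must stay positive). ALSFRS-R draws are clipped to
[0, 48].

Within the ALS group, the ALPS index and the CPV *fraction* are drawn
jointly through a Gaussian copula with correlation −0.537; TIV is drawn
independently and CPV in ml is derived as `fraction · TIV / 100`, so the
fraction column is exactly consistent with its defining ratio and the
imposed correlation is not attenuated by TIV noise. For normal marginals
the copula correlation *is* the population Pearson r; the expected
sample r at n = 41 is ≈ −0.532 because of the usual O(1/n) attenuation
of the sample correlation coefficient. Within HC the markers are
independent by default (no within-HC structure is reported), and the
correlation is configurable. Demographics (age, sex, BMI, education) are
generated for table parity but drive no computation.

The retest generator emulates delineating ROIs twice: each measurement
is the subject's value plus independent noise with SD 0.217 of the
marker SD, chosen from the closed form ICC = 1/(1 + f²) to match the
reported retest reliability of ≈ 0.955.

A diffusivity table consistent with each subject's ALPS index is emitted
by giving both hemispheres `dxx = ALPS · d0`, `dyy = dzz = d0` with a
per-hemisphere baseline `d0 ~ N(0.75, 0.05)`; the ratio is scale-free,
so recomputing the index from the table recovers the marker column
exactly — an end-to-end identity the tests exploit.

What the generator does **not** emulate: scanner noise and motion,
physiological confounds, non-Gaussian marker tails beyond the two
log-normal marginals, any coupling between the signal model and a
subject's tabular coupling index, or between-marker correlations other
than the single imposed pair. Passing tests therefore demonstrate the
correctness and statistical calibration of the *methods*, not the
clinical replicability of the study's effect sizes on new data.

## Statistics

Group comparisons gate on Shapiro–Wilk at α = 0.05 in both groups
(the normality test itself is a design choice; the criterion is
standard): pass → pooled-variance Student's t (Welch by flag), fail →
Mann–Whitney U, with summaries formatted to match (mean ± SD vs median
(IQR)). FDR is Benjamini–Hochberg step-up over an explicit family — by
default the nine within-ALS marker/clinical pairs; the family is never
inferred from the data. Published q-values for that family are not an
exact BH step-up of the published p-values (e.g. p = 0.129 → BH
q = 0.232, reported 0.246), suggesting a different family or unrounded
inputs; standard BH is implemented and the discrepancy is noted, not
imitated. Partial correlation residualizes both variables on the
covariate (intercept included) and tests the residual correlation on
n − 3 degrees of freedom; a variable collinear with the covariate gets
partial r = 0 by convention, and a constant covariate falls back to the
plain correlation with a warning.

ICC: reports of a "two-way mixed-effects, absolute agreement, ICC(3,1)"
model conflate two coefficients, so both are computed from the two-way
ANOVA decomposition and returned: the consistency form
`(MS_R − MS_E)/(MS_R + (k−1)MS_E)` and the absolute-agreement form,
which additionally penalizes systematic shifts via the column mean
square.

## Diagnostics

ROC is empirical over all distinct thresholds; AUC is the Mann–Whitney
probability (ties counted half), its CI from DeLong's
structural-components variance (a bootstrap CI could be substituted; the
choice is immaterial to the point estimates). The cut-off maximizes
Youden's J, the conventional criterion when reports give a cut-off with
sensitivity/specificity but no rule. A direction flag (auto by default)
orients markers so AUC ≥ 0.5 — lower ALPS indicates disease, higher CPV
fraction does.

The combined model is an unregularized maximum-likelihood logistic
regression on exactly the three markers as linear main effects
(Newton/IRLS, log-likelihood tolerance 1e-8); complete separation is
detected and raised as an error rather than allowed to diverge. The
nomogram anchors each feature at the end of its observed range that
minimizes its contribution, scales the largest |coefficient × span| to
100 points, and maps total points back to probability through the
reconstructed linear predictor — an affine identity, so nomogram-read
probabilities equal model predictions to < 1e-6.

Calibration bins predictions into deciles (sparse bins merged with a
warning) and corrects the apparent curve by bootstrap optimism: refit on
each resample, difference of per-bin miscalibration on the resample vs
on the original data, averaged over 1,000 resamples by default;
resamples that lose a class or separate are skipped and counted.
Decision curves report net benefit `TP/N − FP/N · pt/(1−pt)` for the
rule `p ≥ pt`, against treat-all and treat-none references.

## Problem sizes and numerical choices

The analysis scripts and acceptance checks use the study's own sizes:
41/43 subjects, 240→230 volumes at TR = 2 s, ±10 s lag grid, 10,000
permutations, 1,000 bootstrap repetitions, 200 replicate cohorts for
Monte-Carlo means (50 for median p-values). The permutation test is
vectorized as described, so the full 84-subject, 10,000-draw null takes
well under a second. Seeds: every stage draws from a named child of the
run seed (`numpy.random.SeedSequence.spawn`); identical config + seed
gives bit-identical artifacts.

Degenerate inputs are errors, not warnings: non-positive diffusivities,
volumes or durations, out-of-range ALSFRS-R, overlapping phantom masks,
constant series offered for z-scoring or correlation, lag grids that do
not contain the index lag, single-class label vectors.

## Known limitations

- The synthetic cohort's limits are listed above; in particular the
  per-subject tabular coupling index and the signal-derived one are
  generated independently, so cross-marker analyses mixing the two are
  only meaningful on real data.
- DeLong CIs are asymptotic and can touch the [0,1] clip at extreme
  AUCs with small samples.
- The optimism-corrected calibration assumes the refit model family is
  the truth's family, as bootstrap optimism correction always does.
- No external validation machinery: the design has a single cohort.
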