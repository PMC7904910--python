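# Methods

This note documents the statistical models implemented in `digibench`,
the design choices made where the design was genuinely open, what the
synthetic-data generators emulate, and the package's known limitations.

## Score model

A trial yields a count of correct symbol–digit matches over a duration.
All scores are rescaled to the 90-second convention,
`score = n_correct / duration_s × 90`, and carried unrounded; rounding
to one decimal happens only at serialization.  Cross-sectional analyses
use each subject's first sitting and, by default, trial 1 (the
convention is a config switch, `trial1 | trial2 | mean`, because either
reading of "the raw score" is defensible when a sitting holds two
trials).

## Agreement and outlier adjustment

Simple Bland–Altman limits are `bias ± 1.96·SD` of the paired
differences (sample SD; the 1.96 multiplier is the 95% convention and
is configurable).  For repeated measures — one trial-1/trial-2 pair per
sitting, many sittings per subject — the differences are modelled with
a subject-level random intercept (REML); the bias is the fixed-effect
mean and the limits use the total variance (between-subject + residual),
i.e. they describe a new difference from a new subject
(Parker/Myles-style variance-component limits).  Difference conventions
are fixed: `written − app` (design bias appears positive, ≈ +7.8
points) and `trial1 − trial2` (practice advantage appears negative,
≈ −0.19).

The outlier rule treats a two-trial sitting whose difference falls
outside the closed interval `[loa_low, loa_high]` as containing one
aberrant trial; the lower-performing trial's score is raised by exactly
the amount that brings the difference to the nearest limit.  Scores are
never decreased, differences exactly at a limit are not outliers (with
a 1e-9 relative tolerance so float round-off cannot re-flag an adjusted
sitting), and the operation is idempotent.

Lin's CCC uses population (1/n) moments,
`2·cov(x,y) / (var x + var y + (mean x − mean y)²)`, with a Fisher-z CI
using Lin's 1989 variance; degenerate cases (perfect agreement, zero
correlation) collapse the CI to the estimate or fall back to the plain
Fisher SE.

## Reliability

`ICC = σ²_between / (σ²_between + σ²_within)` from a linear mixed model
with subject random intercept and a fixed effect absorbing the shared
practice trend — the sitting number as a linear slope by default
(categorical-factor and days-from-first variants are options; a linear
slope is the most parsimonious encoding and the alternatives gave
analogous results in development).  Variance components are estimated
by REML; on convergence failure the report falls back to
method-of-moments one-way ANOVA components on detrended scores and is
flagged (`estimator="moments"`).  Negative component estimates are
truncated at zero, keeping ICC in [0, 1].

## Contiguous piecewise-linear regression

The change-point model is a linear spline
`y = b0 + b1·x + Σ g_j·(x − t_j)+` — contiguous lines that meet at each
breakpoint.  For fixed breakpoints the least-squares solution is
linear, so breakpoints are located by exhaustive search over a
candidate grid (interval midpoints and interior observations, every
segment keeping ≥ 3 points for identifiability), followed by bounded
scalar refinement within the winning intervals.  Ties in SSE break
toward the earlier breakpoint — for learning curves the conservative,
shorter-learning-period choice.  For n ≤ 25 the search is exact with
respect to the grid (verified against an independent brute-force
enumeration in the tests), and SSE is non-increasing in the number of
breakpoints.

**Learning-end detection** fits 0- and 1-breakpoint models to the
per-sitting scores (≥ 20 sittings required) and reports the breakpoint,
rounded to the nearest sitting, when (i) the pre-break slope is
positive, (ii) the post-break slope is plateau-compatible — its 99% CI
contains 0 *and* the point estimate is below 0.5 points/sitting — and
(iii) the breakpoint improves on a plain line by an F-test at 0.05.
No numeric plateau criterion is standard, so all three thresholds are
configurable; the slope CI uses the conservative 0.01 level applied to
inferential claims throughout the package, while the F gate is model
selection and uses the conventional 0.05 (at 0.01 it rejected 18–30% of
true plateaus in calibration).  A continuously positive slope fails
(ii) and is reported "not identified".

**Minimum test time** truncates both same-sitting trials at every 5-s
cutoff (5…90 s), computes the between-trial Spearman correlation of
correct counts across subjects, fits a 2-breakpoint model to the
(cutoff, ρ) curve, and reports the first breakpoint (1-s resolution) as
the duration after which reliability improves only at a slower pace.

## Criterion-validity model

An elastic net (scikit-learn, mixing parameter 0.5 by default — the
mixing value is not pinned by any external constraint, so it is
configurable and logged) regresses the SDMT score on BPFr and T2LL plus
covariates (dominant-hand taps + age, or NeurEx subsystem scores).
Features are standardized internally; the penalty strength comes from
10-fold CV on the training set only, and coefficients are reported on
the original scale.  The train/validation split is 2/3–1/3, stratified
on the 3×3 cross of age and score tertiles (no binning rule is
canonical; tertiles give 9 strata that remain populated at n ≈ 100),
seeded and deterministic.  Validation metrics (R², Spearman ρ with CI,
CCC) are computed on held-out subjects only.

Because the fit is affine it rearranges exactly: with coefficients
`app = w_b·BPFr + w_t·T2LL + w_taps·taps + w_age·age + b`, the
covariate-adjusted score `app − w_taps·taps − w_age·age − b` equals the
MRI-side composite `w_b·BPFr + w_t·T2LL` identically.  With the
published coefficients this is
`app − 0.24·taps + 0.16·age + 5.9 = 55.5·BPFr − 306.5·T2LL`.

## Decline thresholds

Within-subject differences are `later − earlier`.  Two threshold rules:
`iqr1.5 = |mean − 1.5·IQR|` (the rule behind the 13-point six-month
written threshold) and `sd2 = |mean| + 2·SD`.  IQR uses the
linear-interpolation (type-7) quantile convention; the convention
materially moves the threshold and is configurable.  For k-averaged
thresholds each subject's post-learning sittings are cut into
consecutive *non-overlapping* blocks of k, block means are differenced
between adjacent blocks, and differences are pooled across subjects
(an overlapping-blocks mode exists behind a flag; non-overlapping is
the default because overlapping differences are serially correlated,
which biases the IQR).  For i.i.d. noise the threshold scales as
1/√k.  Decliner classification flags `earlier − later ≥ threshold` and
compares disability changes (ΔCombiWISE, ΔNeurEx) between flagged and
unflagged subjects by rank-sum test.

Group comparisons use the Wilcoxon rank-sum test (exact for small
tie-free samples) with a Hodges–Lehmann shift estimate and rank-based
CI.  The significance threshold for inferential claims is 0.01
throughout.

## Synthetic-data generators: what they emulate

All generators are bit-reproducible for a fixed seed; the pipeline fans
one global seed into per-stage seeds via `numpy.random.SeedSequence`.

**Cross-sectional cohort** (default 39 HV / 154 MS split into
PPMS/SPMS/RRMS): a latent disease-severity variable drives BPFr (down),
T2LL (up), tap counts (down), NeurEx, EDSS, CombiWISE and PASAT-3, so
the correlation matrix has the clinically expected sign pattern.  The
app score is generated from the linear biomarker structure
`55.5·BPFr − 306.5·T2LL + 0.24·taps − 0.16·age − 5.9 + ε`
(ε Gaussian, SD 5 by default), the written score adds the +7.8-point
design bias plus noise whose SD (1.33 × residual SD) places the
written-vs-app limits of agreement near [−5.3, 20.8].  Per-group tap
means are solved so group app-score medians land on 54 (HV) and
34.8 (MS).  BPFr is simulated in [0.75, 0.95]; T2LL in [0, 0.05] on the
same volume-normalized scale (the units consistent with a −306.5
coefficient producing plausible score ranges; both ranges are config
constants).  Scores are clipped to [0, 110].  Gender is a label only
and enters no computation.

**Longitudinal cohort** (default 16 subjects × 25 sittings, two trials
per sitting): piecewise-linear learning curves rising at 3.5
points/sitting to a subject-specific plateau (between-subject SD 17) at
sitting 8; 2/16 subjects instead follow a continuously positive slope
(slope 1 point/sitting) and never plateau.  Noise is decomposed
ANOVA-style: sitting-score noise SD 5 (shared by both trials) and a
within-sitting trial contrast with mean 0.19 (the trial-2 practice
advantage) and SD √2×4, which puts the repeated-measures limits of
agreement near ±11 points.  These defaults were calibrated once, by
Monte Carlo, so that the plateau detector recovers the break within ±2
sittings for ≈ 84% of plateauing subjects and identifies a plateau in a
mean of ≈ 13 of 16 subjects; they were then frozen.  The resulting ICC
is ≈ 0.88 over all sittings and ≈ 0.92 post-learning — excluding the
learning period never lowered the ICC in 50 calibration seeds.

**Answer streams**: gamma-renewal event times (shape 3 ≈ moderately
regular answering) at a per-subject speed uniform on 0.2–0.9
answers/second, small per-trial speed jitter, an optional onset delay,
and a 3.3% rate increase over the final 15 s that produces a 75-vs-90-s
speed difference of ≈ 0.005 points/s.  The between-trial correlation
curve rises monotonically and plateaus near ρ = 0.9.

**Six-month written retest** (n = 112): difference distribution
−0.7 + mixture(0.84·U(−8.6, 8.6), 0.10·N(0, 2.5), 0.06·N(0, 10)).  A
single Gaussian cannot simultaneously produce a 2·SD near 10.3 and a
`mean − 1.5·IQR` threshold near 13 (those constraints imply
IQR/SD ≈ 1.6, a mid-heavy, short-tailed shape); the mixture reproduces
mean −0.7, 2·SD ≈ 10.4, threshold ≈ 12.7–13 and a 4-point-decline
fraction near 29%.  Disability changes are drawn independently of the
SDMT change, mirroring the observed lack of association.

### What the generators do *not* emulate

* No symbol/digit stimuli or response-level errors — only counts and
  times.
* The reliability-vs-duration curve's inflection lands near 15–20 s
  rather than the ≈ 40–45 s seen clinically: in a renewal-count model
  the early-cutoff noise shrinks like 1/t, so short cutoffs become
  informative faster than real early-trial behaviour (re-orientation,
  warm-up) allows.  Pushing the inflection later with large onset-delay
  noise inflates the 75-vs-90-s speed-change metric five-fold, so the
  speed-change calibration was given priority.
* The heavy 13-point decliner tail: the mixture constraints above cap
  the tail at ≈ 0.7% vs the ≈ 2.7% (3 of 112 subjects) seen clinically.
* Passing tests therefore show the *computations* are correct under the
  assumed generative structure, not that real cohorts follow that
  structure.

## Numerical choices and degenerate inputs

* Breakpoint candidates exclude placements leaving a segment with
  < 3 points; refinement never worsens the SSE; `fit_piecewise` with 0
  breakpoints is plain OLS.
* ICC at zero total variance is defined as 1 (all scores identical).
* CCC with zero variance and zero shift is undefined and raises.
* Wilcoxon signed-rank on all-zero differences returns p = 1 (no
  evidence of change) rather than raising.
* Rank-sum CIs use the normal-approximation rank construction.
* Empty cohorts return empty tables with a warning; invalid parameters
  (negative SDs, break beyond the series) raise at construction.

## Problem sizes

The test suite and the acceptance script run the generators at the
study-condition sizes (193 cross-sectional subjects, 16 × 25
longitudinal sittings, 22-subject stream cohorts, 112 retest pairs) and
use 200-replicate Monte Carlo for detector-recovery checks and 2000
subjects for noise-free coefficient recovery; the whole suite completes
in well under a minute on one CPU.
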