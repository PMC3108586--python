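# Methods

## Cosinor model and conventions

All rhythm fits use the fixed-period single cosinor with τ = 24 h
(entrained LD12∶12 design; no period estimation, no harmonics, no
subject-level random effects — each animal contributes one observation at
one Zeitgeber time). The linearization
y = M + β·cos(ωt) + γ·sin(ωt), ω = 2π/24, is fitted by OLS; amplitude and
acrophase derive from the coefficients as A = √(β² + γ²),
φ = atan2(γ, β)/ω reduced to [0, 24). The acrophase is reported as
*positive ZT hours of the fitted maximum*, not in the negative-radian
convention sometimes used in chronobiology software; clock labels
("ZT13∶35") round to the nearest minute. When the data are exactly flat the
amplitude is 0 and the acrophase is undefined (NaN, label "ZT—"), never
silently 0.

Preconditions: at least 4 samples spanning at least 3 distinct sampling
times (the model has 3 parameters). Ingested times are reduced modulo the
period.

### Confidence limits

Default (`ci_method="delta"`): delta-method standard errors from the OLS
covariance of (β, γ) with t(n − 3) critical values. The amplitude CI is
truncated at 0; the acrophase CI wraps modulo 24 (an interval crossing ZT24
is reported with endpoints such as 23∶10 to 1∶40) and degrades to the whole
cycle when the half-width reaches 12 h. `ci_method="ellipse"` instead
projects the joint elliptical confidence region
(b − b̂)′Σ⁻¹(b − b̂) ≤ 2·F(level; 2, n−3) of (β, γ) onto polar coordinates,
tracing 3600 boundary points; it is conservative and, when the ellipse
contains the origin, reports an amplitude lower limit of 0 and an
unconstrained acrophase.

The relative amplitude (100·A/M, "% of mesor") divides the amplitude CI by
the mesor *point estimate*; mesor uncertainty is deliberately not
propagated. This is an approximation chosen for its simplicity and its
symmetric intervals; it slightly understates the interval width when the
mesor is poorly determined.

### Rhythm detection

The zero-amplitude test compares the cosinor against the intercept-only
model: F = [(RSS₀ − RSS)/2]/[RSS/(n − 3)] on F(2, n − 3). Flat data give
F = 0, p = 1; a numerically perfect fit with positive amplitude reports
p = 0 with an explicit `PerfectFitWarning`.

## Rhythm-parameter comparison

The joint ("Hotelling-type") test stacks both groups into one regression
with group-specific mesors and shared-vs-free (β, γ): the nested-model F
statistic [(RSS_reduced − RSS_full)/2]/[RSS_full/(n − 6)] on
F(2, n_A + n_B − 6). Under homoscedastic Gaussian errors this is an exact
F test — the Monte-Carlo type-I calibration in the acceptance suite
confirms a 4–6% rejection rate at α = 0.05 — and it equals the
pooled-covariance T² on the coefficient difference. Single-parameter
comparisons (acrophase, amplitude, mesor) use the delta-method z from the
two independent fits, reported as z² against χ²(1) so the result is
invariant to group order; acrophase differences are taken on the shortest
circular arc in (−12, 12].

## Factorial ANOVA

`factorial_anova` is a thin layer over statsmodels OLS + `anova_lm` with
all interactions up to the full requested order. Balanced designs use
sequential (Type I) sums of squares; unbalanced designs use Type III with
sum-to-zero contrasts. The choice, and the fact that the toxicity grade is
an ordinal score analysed as numeric, are recorded in the returned table's
metadata. Empty design cells raise a warning naming the cells; a constant
response short-circuits all factor F statistics to exactly 0 (p = 1) rather
than returning 0/0 floating-point noise. No multiplicity correction is
applied; all raw p-values are emitted so one can be layered on.

## Toxicity grading and incidence

The grade is the count of lesioned ileum compartments (surface epithelium,
villi, crypt glands), 0–3. Records with a missing indicator are excluded
with a warning. Lesion-free incidence is the per-stratum fraction of
grade-0 animals with binomial SEM √(p(1−p)/n); vehicle controls are
excluded from treated-stratum summaries by default. The 2×2 free-vs-
lesioned comparison uses Pearson χ² with df = 1, Yates continuity
correction **off** by default (with these small counts Yates materially
changes p; both options are exposed), and Fisher's exact test as an
alternative. Pooling over "best" vs "worst" dosing times uses the timing
*label* as the key — each strain×sex group is dosed at its own clock time
(best: ZT11 or ZT15; worst: ZT23, ZT3 or ZT7) — and pools sacrifice days
2/4/6 by default, with a per-day breakdown always emitted.

On the published pooled counts (13/28 best vs 3/26 worst) the package
computes χ² = 7.87, p ≈ 0.005 (Fisher p ≈ 0.007). No standard 2×2 test on
those counts yields the much smaller p-value printed alongside them in the
source study; the package reports its computed values and does not attempt
to match that figure.

## Image quantification

Per image: background-subtracted fluorescent area (clipped at 0 on
ingestion; subtraction itself happens upstream in the acquisition software)
divided by the nucleus count. Per section: the mean of its (nominally
three) images' percent-of-control values; sections with fewer images are
kept with a warning. Per group: mean ± SEM over *sections* (not images).
The control reference is a single scalar area-per-nucleus supplied in
config — one control ileum section — not re-estimated per batch.

## Synthetic-data generator

The generator encodes the study conditions the analyses assume:

* **Expression** — 8 ZTs every 3 h (or 6 every 4 h) × 5 animals per ZT per
  strain/sex group; group truths mirror the fitted rhythms of the source
  study (relative amplitudes 51–72% of mesor, acrophases ZT9∶30–ZT11∶50,
  the B6CBAF1 mesor doubled). Noise is additive Gaussian, `noise_sd = 0.25`
  relative units at mesor 1 — homoscedastic error consistent with
  roughly constant SEM bars across timepoints; the source study publishes
  no numeric dispersion, so this value is a package default, not a
  calibration. An optional log-normal multiplicative switch exists for
  sensitivity checks. With `noise_sd = 0` the samples lie exactly on the
  cosine, so cosinor fitting inverts the generator to numerical precision.
* **Toxicity** — three independent Bernoulli site indicators per animal
  (the joint lesion distribution is unpublished); an optional
  `shared_frailty` parameter makes a fraction of animals reuse one latent
  uniform across sites, inducing positive inter-site correlation. Default
  per-site probabilities (best 0.23, worst 0.515, controls 0) reproduce
  the published pooled lesion-free fractions (≈46% and ≈11%). Under
  independence these probabilities imply mean grades 0.69/1.55, which
  cannot simultaneously match the published mean grades 0.64/1.00 — a
  structural limit of the product-Bernoulli model, documented rather than
  tuned around. Cohorts split across sacrifice days 2/4/6.
* **Imaging** — three images per section, Poisson(120) nuclei, the
  area-per-nucleus ratio normal around multiplier × control with CV 0.1.

What passing tests on synthetic data do **not** show: robustness to
heteroscedastic or skewed biological noise, inter-animal correlation,
non-sinusoidal waveforms, or histopathologist scoring variability — none
of which the generator emulates.

## Determinism and numerics

Every pipeline run flows all randomness from one config seed through
spawned child seeds (`numpy.random.SeedSequence`); identical config + seed
reproduces every CSV byte for byte, and the run directory's manifest echoes
the fully resolved configuration. Ties in the peak/trough fold change break
to the earliest ZT. The grid-search oracle used in the test suite minimizes
the SSE over (M, A, φ) at steps of 1% of the data range and 0.01 h via an
exact sufficient-statistic expansion. Simulation sizes in the test and
acceptance suites (500 replicates for recovery/coverage, 5000 for type-I
calibration, 20–50 grid-oracle instances) were chosen to keep Monte-Carlo
error well inside the asserted bands.

## Known limitations

Single-component cosinor only (no periodograms, no period estimation, no
mixed-effects cosinor); incidence analysis assumes independent animals;
the relative-amplitude CI approximation above; the ordinal grade treated
as numeric in ANOVA (a proportional-odds model is out of scope).
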