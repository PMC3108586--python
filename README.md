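# chronostat

Cosinor rhythmometry and circadian chronotoxicity analysis for dosing-time
studies, built around the analysis chain of a mouse ileum chronotolerance
experiment: circadian expression of the drug-efflux transporter abcc2
(mRNA and protein) and the dependence of irinotecan-induced ileum damage on
the Zeitgeber time of dosing, genetic background (B6D2F1 vs B6CBAF1) and sex.

It is written for chronobiologists and chrono-pharmacologists who have
cross-sectional timed measurements (one animal, one timepoint) and need the
standard analysis battery — rhythm detection, rhythm-parameter confidence
limits, between-group rhythm comparison, factorial ANOVA, and incidence
tests for a binary toxicity endpoint — plus a synthetic-data generator that
reproduces the statistical structure of such a study for testing and power
exploration.

## The model

Expression at Zeitgeber time *t* (hours after light onset) follows the
fixed-period single cosinor

y(t) = M + A·cos(2π(t − φ)/τ) + ε,  τ = 24 h, ε ~ N(0, σ²)

with **mesor** M (rhythm-adjusted mean), **amplitude** A (half the
peak-to-trough extent) and **acrophase** φ (clock time of the fitted
maximum, referred to ZT0). The model is linearized as
y = M + β·cos(ωt) + γ·sin(ωt) and fitted by ordinary least squares;
A = √(β² + γ²) and φ = atan2(γ, β)/ω. Rhythm detection is the
**zero-amplitude F test** F = [(RSS₀ − RSS)/2]/[RSS/(n − 3)] against
F(2, n − 3). Rhythm parameters are compared between groups either jointly —
a pooled-covariance Hotelling-type T² on (β, γ), computed as the exact
nested-regression F test with (2, n_A + n_B − 6) degrees of freedom — or
singly (acrophase on the shortest circular arc) via delta-method standard
errors.

Toxicity is an integer **grade 0–3**: the count of ileum compartments
(surface epithelium, villi, crypt glands) with histologic lesions. The
lesion-free incidence (grade 0) is compared across dosing-time/strain/sex
strata by Pearson χ² on the 2×2 free-vs-lesioned table (Fisher exact as an
alternative), and the grade by factorial ANOVA. Immunofluorescence
quantification divides the background-subtracted fluorescent area by the
nucleus count per image, averages the three images of each section, and
expresses the result as percent of a single control section.

## Worked example

```python
import numpy as np
from chronostat import (ExpressionDesign, generate_expression, fit_cosinor,
                        acrophase_to_zt_string, compare_rhythms, chi2_incidence)

# 8 Zeitgeber times x 5 animals, truth: M=1, A = 72% of mesor, peak ZT10:20
design = ExpressionDesign(mesor=1.0, rel_amplitude=0.72, acrophase_h=10.33,
                          noise_sd=0.25, seed=42)
samples = generate_expression(design)
fit = fit_cosinor(samples)
print(f"amplitude {fit.amplitude:.3f}  ({fit.rel_amplitude_pct:.0f}% of mesor)")
print(f"acrophase {acrophase_to_zt_string(fit.acrophase_h)}")
print(f"zero-amplitude test p = {fit.p_zero_amplitude:.2e}")

females = generate_expression(ExpressionDesign(mesor=1.0, rel_amplitude=0.70,
                                               acrophase_h=9.5, noise_sd=0.25,
                                               sex="female", seed=43))
res = compare_rhythms(samples, females, parameter="acrophase")
print(f"male vs female acrophase difference {res.estimate:+.2f} h, p = {res.p_value:.3f}")

chi = chi2_incidence((13, 28), (3, 26))   # lesion-free counts, best vs worst timing
print(f"chi2 = {chi.chi2:.2f}, p = {chi.p_value:.4f}")
```

prints

```
amplitude 0.750  (74% of mesor)
acrophase ZT10∶27
zero-amplitude test p = 2.54e-17
male vs female acrophase difference +1.05 h, p = 0.007
chi2 = 7.87, p = 0.0050
```

The fit recovers the simulated truth (74% vs 72% relative amplitude,
ZT10∶27 vs ZT10∶20 acrophase) and flags the rhythm as highly significant;
the acrophase comparison detects the one-hour male/female phase difference;
and the incidence test shows that mice dosed at their best circadian time
are lesion-free far more often (46.4%) than at the worst time (11.5%).

A full deterministic run (simulate → fit → compare → toxicity report, with
figures and a manifest) is one command:

```bash
chronostat run --seed 7 --out runs/demo
```

Subcommands `simulate`, `fit`, `compare`, `tox` and `quantify` expose the
individual stages; `--config config.yaml` overrides the default study-like
designs.

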