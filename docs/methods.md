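# Methods

## The problem

Indirect comparisons between medication and psychotherapy trials in
youth depression assume the two trial populations and designs are
exchangeable. This package quantifies departures from that assumption
using only per-arm summary statistics: baseline characteristics by
modality, the within-arm pre–post improvement of each arm type, trial
design features, and the intensity match between psychotherapy active
and control arms.

## Effect measure

For one arm with baseline mean `m_pre`, baseline SD `s_pre`, endpoint
mean `m_post` and size `n`, the within-arm standardized mean difference
is the baseline-SD (Becker-type) estimator

    d = (m_post − m_pre) / s_pre           (negative = improvement)
    var(d) = 2(1 − r)/n + d²/(2n)

with `r` the pre–post score correlation. We standardize by the baseline
SD rather than the change-score SD because it keeps the *point
estimate* free of `r`: only the standard error depends on the unknown
correlation, which is exactly the quantity whose uncertainty the
simulation propagates. A change-score standardizer
(`d = Δ/s_change`, `var = 1/n + d²/(2n)`) is available via
`standardizer="change"` for sensitivity work. Hedges'
small-sample correction `J = 1 − 3/(4(n−1) − 1)` is applied by default
and can be toggled off.

Missing dispersion statistics are recovered in a fixed priority order
(reported change SD; SD from SE; SD from a 95% CI; SE from a t
statistic; t from a two-sided p with n−1 df; the identity
`s_change² = s_pre² + s_post² − 2 r s_pre s_post`), with every rule that
fired recorded as provenance flags on the effect. The p-to-t inversion
assumes two-sided p values; one-sided inputs must be converted upstream.

Baseline severity is made scale-free as a fraction of the instrument's
total-score range, `(score − min)/(max − min)`; two scales are built in
(CDRS-R spanning 17–113; HAM-D spanning 0–52 — the HAM-D span is a
package convention, as published variants differ).

## Meta-analytic models

**Univariate pooling** (`meta_core`) is the standard random-effects
model `y_i = μ + u_i + e_i`, `u_i ~ N(0, τ²)`, `e_i ~ N(0, v_i)` with
known `v_i`. τ² is estimated by REML (default; bounded scalar
optimization of the restricted likelihood with an explicit check of the
τ² = 0 boundary) or DerSimonian–Laird. CIs use the normal quantile by
default; a Knapp–Hartung variant exists but is off, matching the
convention the analysis's published CIs are consistent with. The
between-subgroup test is the usual Q statistic on pooled subgroup means
against chi-square with G−1 df.

Per-study inputs to the baseline meta-analyses: severity uses the
n-weighted mean arm fraction with variance `(pooled SD/range)²/n`;
percent female uses `100²·p(1−p)/n` (a common variance estimated from
the data when n is unavailable); age uses `sd_age²/n`. Trials enrolling
100% female samples are excluded from the sex analysis, since they
reflect a design restriction rather than a sampled sex mix. One row per
study is used throughout (multi-arm studies do not contribute twice).

**Three-level meta-regression** (`multilevel`) nests arms in studies:

    y_ij = x_ij'β + u_j + w_ij + e_ij,
    u_j ~ N(0, σ²_study),  w_ij ~ N(0, σ²_arm),  e_ij ~ N(0, v_ij).

This is the canonical structure for multi-arm trials: the study effect
absorbs shared protocol/population shifts, the arm effect residual
arm-level heterogeneity. Sampling covariance between arms of one study
is set to 0 (within-arm SMDs come from disjoint participant groups).
The restricted likelihood is evaluated per study block with the
rank-one Woodbury identity, σ² components are optimized on the log
scale by bounded L-BFGS-B with three starts (objective tolerance 1e-8),
candidate boundary solutions (either component = 0) are compared
explicitly, and β and its covariance come from GLS at the optimum. The
default design is the four arm-type indicators with no intercept, so
each coefficient is that arm type's pooled SMD; contrasts use
`se² = Var(β_a) + Var(β_b) − 2Cov(β_a, β_b)`. The fit is validated
against a dense-matrix likelihood, a brute-force 2-D likelihood grid,
and an independent R/metafor `rma.mv` fit in the test suite.

**Regression to the mean.** Arms that start higher on the scale have
more room to fall, so the arm-type contrast is re-tested with each
arm's baseline severity fraction, centered at its grand mean, added as
a moderator. The moderator is arm-level and on the fraction scale (an
aggregate-data adaptation of baseline-adjustment regression); a
constant moderator is dropped with a warning. With modest arm sizes the
observed fraction shares sampling noise with the SMD (both contain
`m_pre`), which biases the slope away from zero — the recovery test
therefore uses a large-n fixture; on real data the moderator should be
read as adjustment, not as an unbiased slope estimate.

## Correlation-uncertainty simulation

`r` is almost never reported. The analysis draws it uniformly on
(0.45, 0.9) — one shared value per simulated dataset by default
(`per_dataset`), or independently per study (`per_study`) — recomputes
every arm's variance, refits the three-level model, and reports the
mean of the coefficients and of their CI bounds across `n_sims`
datasets (default 1000 for full runs; 200 in tests and the acceptance
script, which already gives Monte Carlo noise well below the reported
precision). Stability is the proportion of datasets in which
`z = (β_psy_ctl − β_med_ctl)/se` exceeds 1.645, i.e. the one-sided test
that the pill-placebo improvement is larger. Refits after the first are
warm-started at the incumbent variance components (the optimum moves
smoothly in `r`); every solution is still checked against boundary
candidates, and per-simulation fit failures abort the run if they
exceed 1% of draws. Identical database + spec + seed reproduces the
summary bit for bit.

## Synthetic evidence base

The generator emulates the structure of a 92-trial evidence base
(39 medication / 53 psychotherapy studies) and is the package's
acceptance surface: its defaults *are* the study conditions.

- True within-arm change SMDs: −1.9 pill placebo, −0.6 psychotherapy
  control (the published control-arm values); −2.3 / −1.3 for active
  arms (assumptions — within-arm active values are not published —
  chosen to keep plausible active-over-control gaps). Between-study SD
  0.3, between-arm SD 0.1; per-study `r ~ U(0.45, 0.9)`.
- Severity fraction means 0.42 (medication) vs 0.37 (psychotherapy)
  with between-study SDs 0.05 / 0.09 — SDs are not published as such;
  these give heterogeneity of the printed order while keeping the
  modality gap detectable at realistic power. Percent-female and age
  means/SDs are taken from the published per-modality summaries (SDs as
  square roots of the printed τ²). Site counts: Normal(36, 25) vs
  Normal(3, 3), rounded and clipped at 1 (clipping rather than
  redrawing keeps the mean near its nominal value); site-count
  missingness ~28% / ~15%. Under this prescribed distribution nearly
  all psychotherapy trials end up multisite, unlike the real base
  (~54%) — the site *t*-test, not the proportion, is the analysis
  target.
- Arms: every study has a control and an active arm; 25% gain a second
  active arm, 17% of psychotherapy studies a second control. Control
  types are drawn 14:28:20 waitlist:TAU:other for psychotherapy;
  medication controls are always pill placebo. Arm sizes are log-normal
  with medians 90 (medication) / 40 (psychotherapy), floor 10.
- Observed statistics are exact under normality: sample means are
  bivariate normal given n and the true `r`; sample SDs come from the
  chi-square distribution with n−1 df. Post-SD is masked in 25% of
  arms, in which case the change SD is re-expressed as an SE, a 95% CI,
  a t statistic or a reported change SD — exercising every imputation
  rule against coherent inputs.
- Intensity descriptors follow the published active/control group
  moments; waitlist arms get zero sessions/hours by definition (session
  length left missing), and non-waitlist control means are scaled up so
  the control mixture reproduces the printed control means. Per-variable
  missingness mirrors the published available-case K's.
- Two psychotherapy studies are all-female; ~15% of psychotherapy
  studies carry the subclinical flag.

What the generator does *not* emulate: publication bias, non-normal
outcome distributions, correlated moderators (e.g. severity–site-count
dependence), multi-scale reporting within a study, or extraction error.
Passing recovery tests therefore show the estimators are correct under
the stated model, not that the published numbers are right.

A null configuration (`null_no_modality_difference`) shares every
generating parameter across modalities, removes waitlists and equates
control with active intensity; it drives the calibration tests (the
subgroup test rejects at ~5%, the Bonferroni-judged intensity battery
at ~1.25% per test).

## Sensitivity filters

Filters are conjunctions over {exclude waitlist, exclude subclinical,
scale whitelist, maximum SMD variance, require reported post-SD,
exclude all-female}. Waitlist exclusion removes whole studies only when
*all* their control arms are waitlist (the decision is derived once
from the full arm set and carried through subsets, which keeps filters
idempotent and order-independent); multi-control studies lose just the
waitlist arm. The variance filter is arm-level and strict (`< 0.02`)
at the reference correlation r = 0.675 — the midpoint of the simulated
range — since the variance depends on `r` and a fixed reference makes
the filter deterministic. The post-SD filter is likewise arm-level.

## Numerical and interface choices

- Missing values are empty CSV cells, never sentinel numbers.
- Report CSVs are written with a fixed float format so identical
  config + seed yields byte-identical files.
- CLI exit codes: 0 success, 2 schema/config, 3 convergence,
  4 coverage.
- The primary scale per study is an input column; the selection
  hierarchy among multiple reported instruments is left to the data
  preparer (documented limitation).
- Table-1-style p values printed from rounded inputs are treated as
  qualitative: tests assert significance patterns and hand-computed
  statistics, not third-decimal agreement.

## Problem sizes

Default test and acceptance scales: 92 synthetic studies (~210 arms),
200 correlation draws per simulation, 400 null seeds for subgroup
calibration and 1000 for the intensity battery, a 201×201 likelihood
grid for the REML oracle. A full 1000-draw simulation over all
sensitivity variants runs in a few minutes on one CPU.
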