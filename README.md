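# armcompare

Quantitative comparability analysis of medication versus psychotherapy
randomized controlled trial (RCT) evidence in child and adolescent
depression.

Treatment guidelines for youth depression rest largely on *indirect*
comparisons: meta-analyses of medication trials on one side and of
psychotherapy trials on the other. Those comparisons are only valid if
the two bodies of trials are comparable — in who they enroll, in how
they are designed, and in what their control conditions actually do.
`armcompare` implements the statistical machinery to interrogate that
assumption from per-arm summary statistics:

- **Baseline sample comparability.** Random-effects meta-analyses of
  baseline depression severity (expressed as a fraction of the rating
  scale's range so different instruments are poolable), percent female,
  and mean age, with a between-modality subgroup Q test.
- **Within-arm improvement by arm type.** For each trial arm, the
  pre–post standardized mean difference
  `d = (m_post − m_pre) / s_pre` (negative = improvement) with sampling
  variance `var(d) = 2(1−r)/n + d²/(2n)`, where `r` is the rarely
  reported pre–post correlation. The four arm types (medication
  active, pill placebo, psychotherapy active, psychotherapy control)
  are pooled with a three-level REML meta-regression (arms nested in
  studies, known sampling variances), and the uncertainty in `r` is
  propagated by simulating many datasets with `r ~ U(0.45, 0.9)` and
  averaging estimates and CI bounds across them. A stability analysis
  counts how often the pill-placebo vs psychotherapy-control contrast
  exceeds z = 1.645.
- **Trial design.** Welch t-test on per-study site counts by modality
  and multisite proportions; a regression-to-the-mean check that adds
  each arm's centered baseline severity fraction as a moderator.
- **Control-condition intensity.** Welch t and pooled-SD Cohen's d
  comparing psychotherapy active vs control arms on session counts,
  frequency, length and total hours, judged at a Bonferroni-corrected
  threshold (0.05/4 = 0.0125).

Because the underlying trial-level extraction is not bundled, the
package ships a first-class synthetic-data generator
(`armcompare.synthetic_data`) that emulates a ~92-trial evidence base
with known generating truths, so every stage is testable end to end by
parameter recovery.

## Worked example

```python
import armcompare as ac

# a full-scale synthetic evidence base (92 studies, known truths)
db = ac.make_fixture("paper_scale_default")

# propagate pre-post correlation uncertainty over 200 datasets
summ = ac.run_simulation(db, ac.SimulationSpec(n_sims=200, seed=11))
for arm, d in sorted(summ.per_arm_type.items()):
    print(f"{arm:24s} SMD {d['mean_smd']:6.2f} "
          f"[{d['mean_ci_low']:6.2f}, {d['mean_ci_high']:6.2f}]")
print("stability:", summ.stability.proportion_above)
```

prints

```
medication_active        SMD  -2.34 [ -2.46,  -2.22]
medication_control       SMD  -1.84 [ -1.96,  -1.72]
psychotherapy_active     SMD  -1.36 [ -1.46,  -1.25]
psychotherapy_control    SMD  -0.61 [ -0.71,  -0.51]
stability: 1.0
```

The generating truths were −2.3, −1.9, −1.3 and −0.6: each arm-type
SMD is recovered well inside ±0.15, and the pill-placebo vs
psychotherapy-control gap (≈1.2 SMD units) clears z = 1.645 in every
simulated dataset — placebo responses in medication trials dwarf the
improvement seen in psychotherapy control arms, so equal-looking
between-group effect sizes start from very different reference points.

Single statistics work straight from group summaries:

```python
>>> import armcompare as ac
>>> cmp = ac.welch_t(68, 12.94, 11.02, 41, 5.71, 6.10)  # sessions
>>> round(cmp.t, 1), round(cmp.df, 2), round(cmp.d, 2)
(4.4, 106.38, 0.76)
>>> round(ac.fraction_to_score(0.42, ac.CDRS_R), 2)     # severity
57.32
```

## Command line

```bash
armcompare simulate --seed 3 --out data/          # synthetic CSVs + truth.json
armcompare run --config config.yaml               # full report bundle
armcompare table1 --arms data/arms.csv --studies data/studies.csv
armcompare config --show-defaults
```

`run` writes `table1.csv`, `table2.csv`, `fig2_data.csv`,
`fig3_data.csv`, `sites.json`, `stability.csv`, `rtm.json` and
`run.log`; identical config + seed reproduces every file byte for byte.

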