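# hemorisk

Statistical machinery for nested case-control studies of circulating
hemostatic biomarkers — tissue plasminogen activator (t-PA) antigen, D-dimer
and von Willebrand factor (VWF) — and coronary heart disease (CHD) risk.
The package is aimed at epidemiologists and biostatisticians who want a
tested, reusable implementation of the analysis pipeline used in large
prospective biomarker studies, together with a synthetic-cohort generator
with known ground truth so that every stage can be validated without access
to restricted participant data.

## What it computes

**Per-SD standardized odds ratios.** Markers are analysed on the natural-log
scale; effects are odds ratios per 1 SD higher log level, estimated by
unconditional logistic regression (appropriate under frequency matching)
and adjusted progressively — matching factors (age, sex, recruitment
period), then non-lipid risk factors, then lipids:
OR = exp(β̂), 95% CI = exp(β̂ ± 1.96·SE). An SD of s log units corresponds
to an e^s-fold difference on the original scale.

**Fifths with floated variances.** Dose-response shape is assessed across
fifths of the control distribution. Floating absolute risk assigns each
fifth g (including the reference) a floated variance f_g such that
Var(β̂_j − β̂_k) ≈ f_j + f_k. The f are found by minimizing the
Kullback–Leibler divergence between N(0, V), V the estimated contrast
covariance, and the independence approximation N(0, diag(f₁..f₄) + f₀J);
the attained divergence and the range of approximated/true contrast-SE
ratios are reported as diagnostics.

**Regression dilution correction.** With repeat measurements taken years
apart in a subsample, the regression dilution ratio (RDR) — the slope of
repeat on baseline — estimates the attenuation factor under the classical
error model. Participant-level "usual levels" predicted from the
calibration regression replace the baseline values in the outcome model to
give corrected ORs, with either naive Wald or two-stage bootstrap CIs.

**Per-SD harmonized meta-analysis.** Published estimates in heterogeneous
forms (per SD, per unit, per log unit, extreme quantile contrasts) are
re-expressed per 1 SD — an extreme top-vs-bottom q-fraction contrast is
divided by d_q = 2φ(Φ⁻¹(1−q))/q (≈2.18, 2.54, 2.80 for thirds, quarters,
fifths) — then pooled by DerSimonian–Laird random effects, with Cochran's
Q, I², method-of-moments meta-regression, Egger's small-study-bias test and
subgroup comparisons.

## Worked example

```python
import hemorisk as hr

spec = hr.CohortSpec(seed=1)                    # study-like defaults
cohort = hr.generate_cohort(spec)
cc = hr.sample_nested_case_control(cohort, ratio=1.88, seed=1)
data = cc.subset(cohort)
print(f"cohort n={len(cohort)}, sample: "
      f"{len(cc.case_ids)} cases / {len(cc.control_ids)} controls")

tiers = hr.default_tiers()
for m in ("tpa", "ddimer", "vwf"):
    rs = hr.or_per_sd_progressive(data, f"{m}_log_base", tiers)
    row = "  ".join(f"{r.tier}: {r.or_per_sd:.2f} "
                    f"({r.ci_low:.2f}, {r.ci_high:.2f})" for r in rs)
    print(f"{m:7s} {row}")

pairs = hr.serial_pairs(cohort, "tpa")
rd = hr.estimate_rdr(pairs, adjust=["age", "sex"])
print(f"RDR t-PA: {rd.rdr:.2f} (95% CI {rd.ci_low:.2f}, {rd.ci_high:.2f}), "
      f"n_pairs={rd.n_pairs}")
corr = hr.corrected_or_per_sd(data, "tpa", tiers[-1],
                              ci_method="naive", calib_pairs=pairs)
print(f"corrected OR t-PA: {corr.or_per_sd:.2f} "
      f"({corr.ci_low:.2f}, {corr.ci_high:.2f})")
```

prints (seed 1):

```
cohort n=18912, sample: 2362 cases / 4422 controls
tpa     minimal: 1.12 (1.06, 1.18)  plus_nonlipid: 1.12 (1.05, 1.18)  plus_lipid: 1.07 (1.00, 1.13)
ddimer  minimal: 1.00 (0.95, 1.06)  plus_nonlipid: 1.06 (1.01, 1.13)  plus_lipid: 1.08 (1.02, 1.15)
vwf     minimal: 1.18 (1.13, 1.25)  plus_nonlipid: 1.07 (1.01, 1.13)  plus_lipid: 1.06 (1.00, 1.12)
RDR t-PA: 0.36 (95% CI 0.26, 0.46), n_pairs=371
corrected OR t-PA: 1.19 (1.01, 1.41)
```

Reading this: the minimally adjusted t-PA association (OR 1.12 per SD)
weakens to 1.07 once conventional risk factors are added — most of the
crude association runs through adiposity, blood pressure and lipids, which
t-PA antigen tracks. D-dimer shows the opposite pattern (null crude OR that
strengthens on adjustment) because it is *inversely* correlated with those
same risk factors. Correcting the fully adjusted t-PA OR for within-person
variability (RDR ≈ 0.36 over an 11.6-year gap) moves it from 1.07 to 1.19
with a correspondingly wider CI.

The same pipeline is scriptable from the shell:

```sh
hemorisk all --seed 1 --out results/run1          # simulate + analyse + meta
hemorisk casecontrol --config my_run.yaml         # user-supplied CSVs
```

Each run emits plain CSV tables (per-SD ORs, fifths with floated CIs,
percentage differences, interaction tests, RDRs, corrected ORs, forest /
funnel / subgroup / meta-regression data) and a `manifest.json` recording
the seed, config hash and every output file with row counts; outputs are
byte-identical for a fixed seed and config.

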