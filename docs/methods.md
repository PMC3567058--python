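# Methods

This note documents the statistical models implemented in `hemorisk`, the
assumptions behind them, the synthetic-data model used to exercise them, and
the numerical and design choices that were genuinely open.

## The analysis problem

In a nested case-control study of hemostatic markers and coronary heart
disease, all incident first-ever CHD cases from a prospective cohort are
compared with controls sampled from cohort members who remained free of
CHD, frequency matched on sex, 5-year age band and recruitment period.
Markers (t-PA antigen, D-dimer, VWF) are right-skewed and analysed on the
natural-log scale; effects are expressed per 1 SD higher log level so that
markers with different units and spreads are comparable. Three questions
drive the pipeline: how strong is each association after progressively
finer confounder adjustment; what is the shape of the dose-response
relation; and how much is the association attenuated because a single
baseline measurement is a noisy snapshot of the long-term ("usual") level.

## Case-control models

Odds ratios come from unconditional logistic regression fitted by
iteratively reweighted least squares (Newton–Raphson with step halving, so
the log-likelihood is monotonically non-decreasing). Convergence requires
the largest coefficient change to fall below 1e-8 within 50 iterations;
the covariance matrix is the inverse observed information. Rank-deficient
designs and separation (diverging coefficients, or a singular information
matrix from fitted probabilities collapsing to 0/1) raise explicit errors
rather than returning unstable output. Unconditional (rather than
conditional) logistic regression is correct here because matching is by
frequency, not individual pairing, and every model contains the matching
factors.

Adjustment tiers form a nested ladder — `minimal` (age, sex, recruitment
period), `plus_nonlipid` (+ smoking, BMI, diabetes history, systolic BP),
`plus_lipid` (+ total cholesterol, log triglycerides), optionally
`plus_crp` — and all tiers are fitted on the complete cases of the widest
tier requested so that n is constant down the ladder. Recruitment period
enters as stage indicator variables (the coding is not standardized in the
field; indicators are the least restrictive choice).

The SD used for standardization is computed on the pooled case+control
sample by default, with a controls-only switch. The two differ negligibly
when case and control spreads are similar (as here, where the generator
gives both groups the same marker SDs); pooled was chosen as the default
because the analysis sample as a whole defines the "per 1 SD" contrast
being reported.

Subgroup analyses use likelihood-ratio tests comparing models with and
without standardized-marker × modifier-category interaction terms;
continuous modifiers are coded into thirds at control tertile cutoffs. The
marker enters as standardized continuous within every subgroup level (an
alternative — re-estimating per-SD effects within subgroups — changes the
question being asked, not just the test).

Cross-sectional associations among controls are summarized as adjusted
percentage differences: linear regression of the log marker on a covariate
plus adjusters, with 100·(exp(b·SD_cov) − 1) per 1 SD of a continuous
covariate, or 100·(exp(b) − 1) versus the reference category of a binary
one. CIs transform the coefficient CI through the same map.

## Fifths and floated variances

Fifths are defined by the 20/40/60/80 empirical percentiles of the control
distribution, with percentiles computed by linear interpolation of the
empirical CDF and ties assigned to the lower fifth (both conventions are
stated explicitly so cutpoint behaviour is exactly testable). All subjects
are then classified by the control cutpoints; per-fifth geometric means are
computed on the original (unlogged) scale.

Group effects are estimated with four fifth-indicators (bottom fifth
reference) plus tier covariates. Floated variances f₀..f₄ approximate the
contrast covariance V of the four estimated log-ORs by
F = diag(f₁..f₄) + f₀·J, minimizing KL(N(0,V) ‖ N(0,F)). The
minimization runs in log f (enforcing positivity) with the analytic
gradient under L-BFGS-B at tolerance 1e-10, initialized from a moment
heuristic (f₀ = mean off-diagonal covariance, the value that decorrelates a
compound-symmetric V; remaining f from the residual diagonal). Fixed
initialization and tolerance make the fit deterministic. Two diagnostics
are always reported: the attained divergence, and the min/max ratio of
approximated to true contrast SEs over all group pairs — on balanced
designs this band stays within about ±10%, and a user can see directly
when the independence approximation is poor. K = 2 groups is rejected
because only f₀+f₁ is identified from a single contrast variance.

## Regression dilution correction

Under the classical error model, baseline = usual + error with
non-differential additive error on the log scale, the regression of an
error-prone repeat measurement on baseline has slope
σ²_usual/(σ²_usual+σ²_error) — the regression dilution ratio — which is
also the attenuation factor of the per-SD log-OR. The calibration
regression (repeat on baseline, adjusted for age and sex by default,
configurable) provides fitted-value predictions of usual levels for *all*
participants; these predictions shrink each baseline toward its conditional
mean with slope RDR. The corrected OR refits the outcome model with the
predicted usual level, standardized by the baseline SD so "per 1 SD" keeps
its original meaning (standardizing by the SD of usual levels is available
behind a flag). When several repeats exist their mean is used.

Corrected CIs: the default is a two-stage bootstrap (resample the analysis
table and the calibration pairs, re-run both stages, percentile interval
over ≥500 replicates), because the naive Wald interval from the refitted
outcome model ignores calibration uncertainty — material when the repeat
subsample is small. Both methods are provided since the CI construction for
dilution-corrected estimates is not standardized.

A literature-style trend analysis (inverse-variance-weighted regression of
self-correlation/RDR estimates on the time gap between measurements) is
included; under the generator's optional drift model the self-correlation
declines linearly with gap length while the RDR slope itself is unchanged,
mirroring how longer gaps erode the correlation between snapshots.

Caveat: correction multiplies the estimated log-OR by roughly 1/RDR, so for
a truly null association it amplifies sampling noise symmetrically away
from the null — "corrected" does not mean "closer to the truth" when the
truth is no association.

## Meta-analysis harmonization

Per-SD re-expression of published estimates assumes the marker is normal on
the analysis (log) scale. A top-vs-bottom q-fraction contrast then
corresponds to d_q = 2φ(Φ⁻¹(1−q))/q SDs (≈2.1813, 2.5427, 2.7997 for
thirds, quarters, fifths), so log RR and SE are divided by d_q; per-unit
and per-log-unit effects are multiplied by the relevant SD. SEs are
recovered from published CIs as (ln hi − ln lo)/(2·1.96), assuming
log-scale symmetry.

Pooling is DerSimonian–Laird (method of moments): τ² = max(0,(Q−df)/c)
with c = Σw − Σw²/Σw, chosen over REML to match the standard practice of
the literature being synthesized. Meta-regression estimates residual τ² by
the analogous moment equation on the weighted-regression residual Q and
tests slopes with z-statistics using weight-based (not residual-scaled)
variances, the meta-analytic convention. Egger's test is the classical
unweighted regression of y/se on 1/se with a t-test on the intercept
(df = k−2). Subgroup comparisons (e.g. ≥500 vs <500 cases) use a z-test on
the difference of independent pooled estimates.

The study-estimate simulator draws per-SD effects
y_i ~ N(true + bias·se_i, se_i²+τ²) — `bias` injects small-study
inflation — and converts them into native forms by inverting the
harmonization, so the transform pair round-trips exactly; this is what
makes the harmonization testable end to end.

## The synthetic cohort

The generator emulates the statistical structure of a large mid-century
European cohort: ~18,900 participants, five recruitment stages, ages drawn
uniform on 33–86, 48% male, conventional risk factors with control-group
means/SDs (smoking 48%, diabetes 2%, BMI 25.4 (3.7) kg/m², SBP 142 (20)
mmHg, cholesterol 6.4 (1.1) mmol/L, log-triglycerides 0.0 (0.4)), and
log-marker baselines with means (2.5, 4.8, 4.6) and SDs (0.5, 1.0, 0.4)
for t-PA antigen, D-dimer and VWF. Usual log-levels combine linear loadings
on standardized covariates with a correlated Gaussian residual whose
covariance is chosen so the *total* usual-level correlation matrix equals
the spec (default: −0.35 between t-PA and D-dimer, mildly positive
elsewhere — the inverse t-PA/D-dimer association is the distinctive feature
of these markers). Loadings are set to about half the marginal
cross-sectional percentage differences observed in such cohorts: marginal
pairwise associations are mutually confounded, and independent covariates
carrying the full marginal values would jointly over-explain the
usual-level variance implied by the RDR targets.

Measurement error is classical: baseline = usual + e with
σ²_e = σ²_u(1−RDR)/RDR per marker, equivalently σ²_u = RDR·σ²_baseline, so
the stated marker SDs are *observed baseline* SDs and the marginal slope of
repeat on baseline equals the target RDR (defaults 0.47, 0.30, 0.55 over an
11.6-year gap, 371 repeat participants). Age/sex-adjusted RDR estimates run
slightly below the marginal targets because adjustment removes
covariate-explained usual-level variance; the package estimates both.
An optional linear drift of the usual level
(λ = 1 − decay·gap, off by default) lowers the baseline-repeat
self-correlation with gap length without changing marker variances.

Disease follows a logistic model in the *usual* (not observed) levels,
standardized per baseline SD, plus covariate effects — this defines
unambiguous ground truth: the naive baseline analysis is attenuated by
≈RDR and the corrected analysis should recover the usual-level log-OR.
Default true per-SD ORs are (1.15, 1.11, 1.10) with moderate conventional
risk-factor effects and ~10% cumulative risk, giving roughly 2,200 cases
per cohort. Frequency matching samples round(ratio·cases) controls without
replacement within each sex × 5-year-age-band × period stratum (depleted
strata take all available controls with a warning); the default ratio 1.88
reproduces the roughly 2-per-case control yield of such studies.

All randomness flows from a single seed through named substreams
(covariates, markers, measurement error, repeats, events, sampling), so
sub-steps are independently reproducible and byte-identical across runs.

What the generator does **not** emulate: real demography (age is uniform,
periods are balanced), competing risks and loss to follow-up, short-term
(diurnal/seasonal) marker variability, non-normal marker tails, and any
dependence structure beyond the Gaussian copula on the log scale. Passing
tests therefore demonstrate that the estimators do what they claim under
the classical-error, log-normal model — not that real data satisfy that
model.

## Problem sizes and tolerances in the test suite

Simulation-based tests use cohort sizes of 2,000–50,000 and 60–500
replicates, chosen so Monte-Carlo standard errors sit several times below
the asserted tolerances: e.g. the attenuation/correction recovery check
averages 200 cohorts of n = 20,000 (relative MC error ≈1.5% against a 5%
band), and null-calibration checks use 500 replicates with a KS threshold
of p > 0.01. Closed-form identities (2×2 log-ORs, Egger intercepts,
DerSimonian–Laird hand example, quantile spacings) are asserted at 1e-3 to
1e-12 as appropriate. The floated-variance optimizer is validated against
an independent coordinate-wise dense-grid minimizer of the same divergence
to 3 decimals on covariances of realistic (log-OR²) magnitude.

## Known limitations

- The corrected-OR bootstrap treats the calibration pairs and the analysis
  table as independently resampled stages; when the pairs are a subset of
  the analysis rows this ignores their small overlap correlation.
- Floated variances assume the contrast covariance is well estimated; with
  sparse fifths (few cases in a group) the KL fit inherits that noise.
- Harmonization of extreme-quantile estimates is exact only under log-scale
  normality of the marker; heavier-tailed true distributions make d_q too
  small and the per-SD estimate conservative.
- Meta-regression with few studies relies on z-tests; no Knapp–Hartung
  small-sample adjustment is provided.
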