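# Methods

## The estimand and the two-step procedure

`seetrial` evaluates *trial-level* surrogacy inside one two-arm survival
trial. The unit of analysis (country, trial site, or geographical region)
partitions the trial into pseudo-trials; the association of interest is
between the per-group treatment effects on the surrogate endpoint (time
to first event of a composite: non-fatal myocardial infarction, non-fatal
stroke, CV death) and on the true endpoint (CV death primarily, all-cause
death secondarily), both measured as log hazard ratios, active vs
control.

Step 1 fits, per group, a Cox proportional-hazards model with treatment
as the only covariate, per endpoint. Step 2 regresses the true-endpoint
log hazard ratios on the surrogate ones by weighted least squares with
the group subject counts as weights, and summarises the association by
R²_group. Measurement error in the step-1 estimates is deliberately not
propagated into step 2: the weights are subject counts, not inverse
variances, matching the procedure this package operationalises. The
consequence — attenuation of R̂² when groups are small — is quantified
below.

## Grouping algorithm

Units are sorted by descending true-event count; ties are broken by
ascending case-insensitive label comparison. The scan accumulates units
into the current group and closes it as soon as the group's event total
reaches the minimum `min_events` (checked *after* adding the current
unit). A trailing remainder that cannot reach the minimum joins the last
closed group. Consequences: group ids are consecutive, groups are
contiguous runs of the sorted order, and every group meets the minimum
whenever the trial-wide total does (otherwise grouping raises). On the
bundled published per-country table this reproduces the printed
9 / 13 / 7 partitions at minima 30 / 20 / 40 exactly, including the
merge of the sub-threshold tail into the last group.

The printed source table's tie order is not strictly alphabetical in one
run of countries with two CV deaths; the caption's alphabetical rule is
implemented. Ties never straddle a group boundary in that table, so the
discrepancy cannot alter any group id (asserted in tests).

Region maps are fixed analysis sets. When every region holds at least
`min_events` true events, each region stays its own group; otherwise the
regions are fed through the same scan. Note that the smallest bundled
region set contains a region (Asia) with fewer than 30 CV deaths in the
published table, so reproducing a fixed four-region analysis at such a
minimum requires passing a minimum that every region meets (e.g.
`min_events=10`); the conditional rule is the package's default because
silently keeping an under-minimum group would contradict the grouping
contract everywhere else.

## Cox fit

With a single binary covariate the partial likelihood is one-dimensional.
The solver uses the Efron tie correction and Newton iterations on the
score (tolerance |score| < 1e-8, at most 50 damped steps) with a
bracketed root search as fallback; the standard error is the inverse
square root of the observed information at the optimum. The
implementation is cross-checked against an independent Cox implementation
(lifelines) to 1e-6 in tests, including tied data. Degenerate inputs are
signalled distinctly: no events at all (`NoEventsError`) and all events
in one arm (`MonotoneLikelihoodError`, the monotone-likelihood case).
Groups with a degenerate fit on either endpoint are flagged
`usable=False` with a logged warning and excluded from step 2 — no
continuity corrections are injected into a regression with only a handful
of points; users who need those groups should pre-merge sparse units
instead. CV death is analysed as a cause-specific hazard: non-CV death
censors it, as does administrative end of follow-up.

## Step-2 regression, R² interval, prediction band, STE

Effects enter on the log-HR scale (a raw-HR scale is available via
`log_scale=False` for comparison; hazard ratios are multiplicative, so
the log scale is the defensible default and all reporting converts back
to HRs). R² is computed about the weighted mean and equals the squared
weighted Pearson correlation (property-tested). The 95% CI uses the
delta-method variance Var(R²) = 4R²(1−R²)²/(n−3) with normal quantiles,
clipped to [0, 1]; this closed form reproduces the published intervals
for (R², n) = (0.85, 9), (0.23, 14), (0.23, 17) and (0.29, 11) at 2-dp
rounding, which is why it is the default; a group-level percentile
bootstrap (default 2,000 resamples, seeded) is the alternative. The
interval requires n ≥ 4; a 3-group fit succeeds with `r2_ci=None`.

The prediction interval for a new group's true-endpoint effect at
surrogate effect x₀ is ŷ(x₀) ± t₍ₙ₋₂₎ √(σ̂² (1/w₀ + [1,x₀](XᵀWX)⁻¹[1,x₀]ᵀ))
with σ̂² the weighted residual variance (df = n−2). The new group's
weight w₀ defaults to the mean of the fitted group weights — the
procedure does not define how a future trial is weighted, and the mean
keeps band widths comparable across grouping granularities; w₀ is a
parameter. The expression is invariant to rescaling all weights by a
constant.

The surrogate threshold effect is exp(x*) where the upper limit of the
95% prediction band crosses a true-endpoint log HR of 0, located by
bracketed root search over HR ∈ [0.05, 1] (solved to ≈1e-10 on the log
scale; tests assert the upper limit at the returned STE is within 1e-6 of
zero). The STE is reported absent, with a reason, in three cases:
non-positive slope; upper limit above zero throughout the range (band too
wide); upper limit below zero throughout (benefit predicted everywhere in
range, so no crossing exists in the search domain). Degenerate inputs:
identical surrogate effects raise (undefined slope); identical true
effects yield R² = 0 with a warning.

## Synthetic trial generator

The generator emulates the structure the pipeline needs, not any
particular patient population. Each subject in country *i*, arm *z*,
draws independent exponential latent times: non-fatal MI (rate λ_mi
e^(γᵢz)), non-fatal stroke (λ_stroke e^(γᵢz)), CV death (λ_cvd e^(βᵢz)),
non-CV death (λ_oth, unaffected by treatment). The composite endpoint
takes the earliest of MI/stroke/CV-death, censored by non-CV death and by
administrative follow-up F; CV death is observed if it precedes non-CV
death and F; all-cause death is the earlier of the two deaths. These
rules make the composite-dominance invariants hold by construction.

Country effects (αᵢ, βᵢ) — composite and CV-death log HRs — are bivariate
normal with means (ln 0.87, ln 0.78), SDs (sd_alpha, sd_beta) and
correlation ρ, so the true trial-level R² is ρ². The non-fatal multiplier
is back-solved per country from
e^γᵢ = (e^αᵢ(λ_nf+λ_cvd) − λ_cvd e^βᵢ)/λ_nf so the composite
cause-specific hazard ratio is exactly e^αᵢ. The solution must be
positive; draws where the CV-death effect is vastly more harmful than the
composite effect (≈0.96 on the log scale at the defaults) are infeasible
and raise a named error. Simulation studies that replicate over seeds
redraw such seeds before any estimation — conditioning on generator
feasibility only.

Default parameters (units: events per person-year; follow-up years):

| parameter | default | rationale |
|---|---|---|
| country sizes | published 32-country N column (total 9,340) | structural comparability |
| sites/country | 13 | ≈410 sites / 32 countries, assigned uniformly |
| λ_mi, λ_stroke | 0.0164, 0.0089 | split 579:315, the printed component event counts |
| λ_cvd, λ_oth | 0.0157, 0.0093 | see calibration below |
| F (follow-up) | 4.0 | within the trial's 3.5–5-year window |
| mean HRs | 0.87 (composite), 0.78 (CV death) | the trial's headline effects |
| sd_alpha, sd_beta | 0.25 | moderate between-country heterogeneity |
| ρ | 0.92 | ρ² ≈ 0.85, the published headline R² |
| allocation | 0.5 | 1:1 randomisation |

The four rates were solved jointly (before any testing) so the expected
totals at the default configuration equal ≈1,304 composite events, 498 CV
deaths and 830 deaths — the published totals are 1,302 / 497 / 828; a
±15% realized-total check over seeds is part of the suite.

What the generator does **not** emulate: staggered recruitment and
variable follow-up, dropout, covariates and case-mix differences between
countries, non-proportional hazards, and within-country site effects
(sites are uniform noise). Passing tests therefore demonstrate that the
pipeline's estimators recover the effects of this generative model — not
that any particular clinical dataset satisfies it.

## Recovery study design

The acceptance-level simulation uses sd_alpha = sd_beta = 0.7 and ρ = 0.9
(target R² = 0.81). The choice is driven by attenuation arithmetic: with
per-group standard errors se² ≈ 4/events, classical measurement-error
attenuation multiplies the expected R̂² by roughly
(σ²/(σ²+se²_x))(σ²/(σ²+se²_y)). At 50 groups of ~210 CV deaths
(4,000 subjects each) this predicts a median near 0.77; at the published
trial's scale (~10 groups of ~55 CV deaths) near 0.67 — so the estimator
is expected to sit within ±0.10 and ±0.20 of ρ² respectively, and the
observed medians (≈0.79 and ≈0.69 over 100 replicates) agree. Estimation
error shared between the endpoints (CV deaths are a subset of composite
events) partially offsets the attenuation. This is the known downward
bias of subject-count-weighted two-step SEE with small groups, and is the
quantitative reason the grouping minimum trades off against the number of
groups.

Problem sizes in the test suite (100 replicates of 200,000-subject trials
at the large scale; 100 replicates of 9,340-subject trials at trial
scale) were chosen to make the Monte-Carlo error of the reported medians
(≲0.01) negligible against those tolerances while the whole suite stays
interactive (~1 minute).

## Known limitations

- Only two arms and a single binary covariate; no stratification,
  adjustment or frailty.
- Individual-level surrogacy measures (adjusted association, likelihood
  reduction) are out of scope; the package quantifies the group/trial
  level only.
- The delta-method CI is a large-n approximation applied at n as small
  as 7–17 groups; it is used because it reproduces the reference
  intervals, with the bootstrap as a check.
- The R² of subject-count-weighted two-step SEE is attenuated when groups
  carry few true events (see above); interpret R̂² jointly with the group
  sizes, or increase the grouping minimum.
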