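# Methods

## Problem setting

An eGFR validation study compares estimating equations against a measured
reference (mGFR) on a per-subject basis. All GFR values are in
mL/min/1.73 m² (body-surface-area indexed via the Dubois formula); serum
creatinine is in mg/dL, cystatin C in mg/L. The toolkit treats each
cohort row as an independent subject-visit; repeated enrolments of the
same subject are analyzed as independent rows by default, with an opt-in
cluster bootstrap (`BootstrapSpec.cluster_by_subject`) that resamples
subject ids instead of rows for sensitivity analyses.

## Equations

The 2021 CKD-EPI equations are sex-specific piecewise power laws,

    eGFR = level · min(Scr/κ, 1)^α · max(Scr/κ, 1)^β
                 · [min(Scys/0.8, 1)^γ₁ · max(Scys/0.8, 1)^γ₂]
                 · age_base^age · (female multiplier),

with the bracketed cystatin factor present only in the two-marker
equation. Coefficients live in `data/ckd_epi_2021.json` (level 142,
κ 0.7/0.9 F/M, α −0.241/−0.302, β −1.200, age base 0.9938, female
multiplier 1.012 for the creatinine equation; level 135, α −0.219/−0.144,
β −0.544, γ₁ −0.323, γ₂ −0.778, age base 0.9961, multiplier 0.963 for
creatinine–cystatin). Storing them as data keeps the audit trail diffable
and makes further equations pluggable without code changes. The
evaluators are continuous at the marker breakpoints by construction
(both branch factors equal 1 there) and strictly decreasing in each
marker and in age.

Conventions: units are fixed; µmol/L creatinine is accepted only behind
the explicit `scr_umol_per_l=True` flag (÷88.4). Ages below 18 evaluate
with a logged warning (`W-AGE-UNDER18`) rather than an error — these are
adult equations, but a hard failure would be the wrong behavior for
boundary data entry. KDIGO stages use lower-inclusive intervals
(G2 = [60, 90)); guidelines label the intervals but do not state tie
handling, so the convention is pinned here and tested at every boundary.

## Agreement statistics

* **Bias**: median of d_i = eGFR_i − mGFR_i.
* **Precision**: IQR of d, with quartiles by linear interpolation between
  order statistics (the default of the common statistical environments;
  pinned because IQRs are reported to 0.1 precision and quartile
  definitions differ by up to that much at n ≈ 100).
* **Accuracy Px**: 100·#{|d_i| ≤ (x/100)·mGFR_i}/n with an *inclusive*
  boundary ("within x%" does not specify ties; inclusivity is the pinned
  reading and is exercised by boundary tests). P15 ≤ P20 ≤ P30 holds by
  construction; the REC curve is the same quantity on a dense tolerance
  grid.
* **Bootstrap**: percentile method, 2,000 replicates by default,
  subject-level resampling, explicit seed recorded in every bundle. BCa
  or normal-theory intervals are deliberately not offered: the percentile
  flavor is the transparent default when the interval flavor is otherwise
  unspecified, and switching flavors would silently move CI endpoints.
* **Pairwise tests** (two equations on the same subjects):
  - bias: Wilcoxon signed-rank on d_A − d_B, zeros dropped, average
    ranks for ties; *exact* by full sign-assignment enumeration when the
    post-drop n ≤ 10, otherwise the normal approximation with tie
    correction (no continuity correction, the classic large-sample
    treatment). The exact two-sided p uses the symmetric-distance rule
    P(|T − E T| ≥ |t_obs − E T|), which reduces to the usual doubled
    tail for untied data.
  - precision: paired bootstrap of IQR_A − IQR_B; two-sided p =
    2·min(share ≤ 0, share ≥ 0) floored at 1/replicates. The floor means
    a single replicate can never report p < 1 — degenerate but explicit.
  - accuracy: McNemar on the discordant within-tolerance counts (b, c);
    continuity-corrected χ² = (|b−c|−1)²/(b+c) on 1 df, with the exact
    binomial conditional test auto-selected when b + c < 25 (the χ²
    approximation is poor there); p = 1 with a logged note when b+c = 0.
  - subgroup contrasts: Wilcoxon rank-sum with the same exact-vs-
    asymptotic split (exact enumeration when both strata ≤ 10).
* **Multiplicity**: Benjamini–Hochberg step-up, applied within each
  metric family (all pairwise contrasts of one metric form one family).
  Whether the third contrast of a three-method comparison belongs to the
  family is ambiguous in practice; including all pairs is the
  conservative, symmetric choice made here.
* **Subgroup eligibility**: contrasts whose flag-positive stratum has ≤ 25
  subjects (configurable) are still computed but marked ineligible rather
  than suppressed — small-stratum results are flagged, not hidden.
* **Sample-size planning**: two normal-approximation variants are
  shipped — CI half-width n = z²p(1−p)/d², and a one-sample test of p
  against p₀ = p − d at power 1−β. For a prior accuracy of 0.715 at a
  15% absolute margin (α = 0.05, power 0.90) the test variant gives 107;
  published planning figures near this value depend on unstated software
  rounding conventions, so no exact equality is asserted anywhere.

## Prediction intervals

Seven linear conditional-quantile models of mGFR on eGFR (levels 0.025,
0.10, 0.25, 0.50, 0.75, 0.90, 0.975) are fitted independently by exact
minimization of the check (pinball) loss, cast as a linear program
(residual split u⁺/u⁻, objective τ·Σu⁺ + (1−τ)·Σu⁻) and solved with
HiGHS through `scipy.optimize.linprog` using a sparse constraint matrix
(the dense form would need ~1.6 GB at n = 10⁴). The LP optimum is exact
up to solver tolerance; tests verify it against a vertex-enumeration
oracle (an optimal check-loss line passes through two data points) on
every small random dataset, and against statsmodels' IRLS `QuantReg` on
larger ones.

The linear-in-eGFR predictor is the minimal model consistent with
single-threshold evaluation; a log-axis variant would be a configuration
change, not a new method. Evaluating the seven lines at a threshold gives
the predicted mGFR percentiles; the 95/80/50% widths are the spreads of
the (2.5, 97.5), (10, 90) and (25, 75) pairs. Independently fitted
quantile lines may cross at a given threshold: crossings are *reported*
(warning `W-QUANTILE-CROSSING` with the offending level pairs) and widths
floored at zero — never silently reordered, because a crossing is a
diagnostic about data sparsity at the tails, not a nuisance to hide.
Stage-crossing flags compare the 2.5th/97.5th predictions against the
nearest KDIGO cutoffs strictly below/above the threshold; tail-quantile
fits are flagged unstable below n = 100.

The threshold set defaults to {45, 60, 90}; 30 is excluded by default
because cohorts referred for clearance measurement rarely populate the
G4/G5 range densely enough for tail quantiles there, but it is
configurable.

## Synthetic cohorts: what they emulate, and what they do not

The generator's defaults describe a routine mGFR-referral cohort: mGFR ~
truncated normal with post-truncation mean 64.2 and SD 20.8 on [10, 140]
(the truncation bounds avoid a dense G5 region such cohorts lack), age
54.9 ± 10.6 truncated at 18, 56.5% male, height 171.7 ± 9.9 cm on
[148, 195], weight 87.9 ± 20.8 kg on [51, 161]. The truncated normals
are moment-calibrated: the underlying location/scale are solved
numerically so the *post-truncation* moments hit the targets, which is
what makes the n = 10,000 sample-moment recovery tests robust rather than
borderline. Default condition-flag prevalences (CKD 66.1%, kidney
transplant 60%, hypertension 69.6%, hyperlipidemia 60%,
immunosuppressives 87.8%, corticosteroids 47.8%, beta blockers 35.7%)
carry zero marker shifts unless configured.

Markers are constructed by exact equation inversion: creatinine solves
ckd_epi_2021_cr(scr) = mGFR·exp(ε_cr) branch-wise (demographic factor
first, then the min- or max-branch exponent depending on whether the
residual factor exceeds 1), and cystatin C solves the two-marker equation
given that creatinine. Error scales default to σ_cr = σ_cys = 0.20 and
σ_ext = 0.15 with log-bias μ_ext = 0.031 for the external column — chosen
once so the implied P30 values (≈87% and ≈95%) and the external median
bias (≈ +2 at the cohort median GFR) sit in the range reported for
creatinine-based vs multi-marker equations in validation cohorts of this
type. A single lognormal scale cannot reproduce a realistic P15/P20/P30
triple exactly (real error distributions are heavier-tailed and often
bimodal); the generator trades that realism for analytic tractability.

Because the error model is explicit, ground truths are closed-form:
expected Px = Φ((ln(1+x/100) − μ)/σ) − Φ((ln(1−x/100) − μ)/σ); the
external column's median bias is median(mGFR)·(e^μ − 1); a subgroup's
"non-GFR marker shift" is implemented as a log-shift on the
marker-implied eGFR target before inversion (equivalent to a
multiplicative marker shift propagated through the power law), so the
induced bias contrast is analytic too. The optional bimodal mode adds an
extra log-shift δ to a random fraction π of the marker errors. Note a
mixture separated by |δ| < 2σ is *unimodal*; with the default σ = 0.20
the illustrative δ = −0.3 skews rather than splits the distribution, and
on the absolute-bias scale the wide mGFR range smears proportional shifts
further. The bimodality recovery test therefore uses a tight-assay
scenario (σ = 0.10) and counts KDE modes on the relative (log-ratio)
bias scale, where the mixture components are exactly N(0, σ²) and
N(δ, σ²).

What passing these tests does **not** show about real data: the generator
has no assay-level imprecision distinct from the equation error, no
correlation between creatinine error and muscle mass or between cystatin
error and inflammation, no longitudinal structure, and lognormal tails
only. Recovery results certify the *analysis machinery*, not any claim
about how a particular equation behaves clinically.

## Pipeline conventions

Missing data are handled available-case: each statistic uses the rows
complete for its own inputs (pairwise tests use rows where both columns
are present), mirroring per-characteristic "n missing" accounting; a
strict complete-case mode is a one-line filter away. Validity filtering
excludes flagged rows and rows without usable mGFR, each with a logged
reason, and aborts if nothing remains. All bootstrap seeds derive from
the single run seed through a fixed order, so a (cohort, config, seed)
triple yields a byte-identical JSON bundle; renderers read bundle fields
verbatim. Warnings carry stable grep-able codes (`W-AGE-UNDER18`,
`W-QUANTILE-CROSSING`, `W-EQ-SKIP`, `W-SMALL-N`, ...).

## Problem sizes used by the shipped tests

Analytic Px recovery runs at n = 5,000 (tolerance ±1.5 percentage
points); prediction-interval coverage fits n = 10,000 and scores a fresh
n = 10,000 (95% band within [94, 96]%, 50% within [48, 52]%);
median-model recovery uses 100 replications of n = 500; exact-test
oracle equivalence enumerates all inputs up to n = 8 (tests run the exact
path up to n = 10); subgroup recovery uses 50 replications of 400
subjects (~200 per stratum). These sizes make the Monte-Carlo tolerances
comfortably non-flaky on a single CPU.

## Known limitations

Bootstrap CIs are percentile-only; BCa would matter for strongly skewed
statistics at small n. The cluster bootstrap loops in Python and is
noticeably slower than the vectorized subject bootstrap. Quantile models
are linear in eGFR; genuinely nonlinear conditional quantiles (e.g.
variance growing with GFR) are captured only through the slope of the
tail models. The exact rank-sum path enumerates combinations and is
O(C(n+m, n)); it is gated to strata of ≤ 10 for that reason. GFR
equations outside the shipped 2021 CKD-EPI pair (2009/2012 equations,
cystatin-only, pediatric) are pluggable via the JSON document but not
shipped.
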