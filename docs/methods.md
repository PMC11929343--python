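# Methods

This note documents the models, defaults and numerical choices behind
`bevmr`, and what the synthetic-data generators do and do not emulate.

## Two-sample MR pipeline

**Instrument selection.** SNPs with trait association p strictly below the
threshold (default 5e-8; 5e-6 is the conventional relaxation for weakly
heritable behavioural exposures such as beverage intake) are pruned by
greedy p-ordered LD clumping: the lowest-p SNP is kept and every remaining
SNP on the same chromosome within ±`clump_window_kb` (default 10,000 kb)
with r² ≥ `clump_r2` (default 0.001) is discarded, repeating until
exhaustion.  Ties in p break on snp_id, so the result is independent of
input order.  The algorithm is the de facto standard; only the thresholds
are study-specific.

**Instrument strength.** Per-SNP F = (β̂/se)² (the squared z-score, exact
for a one-degree-of-freedom Wald test); the headline figure is the
arithmetic mean across instruments, flagged when ≤ 10.

**Harmonization.** Outcome effects are aligned to the exposure's effect
allele: swapped alleles negate β and mirror the frequency; strand flips
are resolved by complementing and re-checking.  Palindromic SNPs (A/T,
C/G) are kept only when both allele frequencies fall outside the ambiguity
band (default 0.42–0.58) — a frequency conflict across datasets is treated
as a hidden strand flip — and dropped with reason codes otherwise,
including whenever a frequency is missing.  Dropping rather than guessing
is the conservative convention; the band is configurable.

**Estimators.** Wald ratios use the first-order SE se_out/|β_exp|,
ignoring exposure-side uncertainty; this is standard when instruments pass
the F > 10 rule and avoids the weak-instrument correction territory that
is out of scope here.  "Random effects" IVW means multiplicative
overdispersion — the fixed-effect SE scaled by max(1, √(Q/(k−1))) — which
is the usual choice for summary-data MR; additive random effects are not
implemented.  Weighted-median SEs come from a seeded parametric bootstrap
(θ\_j\* ~ N(θ̂\_j, se\_j), default 1000 draws).  MR-Egger uses weights
se_out⁻² with no measurement-error (NOME) correction; instrument strength
is reported via mean F instead.  Egger slope and intercept are tested
against t with k−2 df; Wald/IVW/weighted-median p-values are two-sided
normal.

**MR-PRESSO.** The global test compares the observed weighted residual sum
of squares of leave-one-out IVW fits with an empirical null obtained by
simulating β_out* ~ N(β_exp·θ̂_loo, se_out) (default 1000 draws, seeded).
Outlier detection is *iterative*: each round computes every remaining
SNP's empirical residual p against its own simulated distribution and
removes the single worst SNP whose Bonferroni-corrected p falls below
alpha, then re-simulates.  A single-pass test was rejected during
development because one dominant outlier (large ratio with small SE)
contaminates the leave-one-out fits of all valid instruments and causes
mass false flagging; iterative deletion is the standard robust-statistics
remedy and leaves null calibration unchanged.  The corrected estimate is
random-effects IVW on the surviving SNPs; the distortion test compares the
corrected-vs-full shift against removals of random same-size subsets.

**Two-step mediation.** Indirect effect = θ̂₁·θ̂₂ (product of
coefficients).  Because the exposure, mediator and outcome GWAS samples
are non-overlapping, the two steps are independent and the delta-method
variance has no covariance term.  PM = indirect/total uses the raw IVW
total effect (a config switch could substitute the outlier-corrected
total; raw is the default because correction is a sensitivity analysis).
For binary outcomes PM is a ratio of log-odds effects.  Negative PM is
reported as 0% with a `truncated` flag; the CI is deliberately left
untruncated so the uncertainty statement is not distorted.  PM > 100% is
reported as computed (only the negative tail has a defined floor).

## Synthetic GWAS generator

Three *disjoint* samples are drawn under the chain X → M → Y with a direct
X → Y path and a shared unmeasured confounder U ~ N(0,1) entering all
three phenotypes (coefficient √(0.3·(1−h²_x)) on X, 0.3 on M and Y), so
that observational X–Y association is confounded but instruments are not.
Genotypes are Binomial(2, maf) with maf ~ U(maf_range), i.e. linkage
equilibrium; LD enters only through a user-supplied r² matrix for clumping
tests.  Instrument effects γ_j split h²_x equally (random sign); an
optional second SNP block with variance share h²_m acts directly on the
mediator, giving it instruments of its own as real anthropo-metabolic
traits have — without this block, "mediator instruments" selected from the
mediator GWAS would all be exposure SNPs and step 2 would estimate
θ_total/β_xm instead of β_my.  Pleiotropy enters as per-SNP effects δ_j on
the mediator, reaching the outcome through β_my: balanced δ_j ~ N(0, sd²);
directional δ_j ~ N(sd, (sd/2)²) *on the exposure-increasing allele
orientation* (allele coding is arbitrary, so a nonzero mean is only
meaningful after orienting on sign(γ_j)).  δ is drawn independently of γ,
so InSIDE holds in both modes.

Summary statistics are produced by actually running per-SNP regressions of
the simulated phenotypes on the simulated genotypes (vectorized simple
linear regressions; two-parameter Newton logistic regressions for binary
outcomes, verified against statsmodels), so SE/p structure — including
weak-instrument behaviour — is realistic rather than "true beta plus
noise".  Binary outcomes use a logistic link; note that marginal logistic
SNP coefficients are non-collapsible, so the IVW estimate on the log-odds
scale is attenuated relative to the latent conditional effect (visible in
the worked example: latent 0.3 → estimated ≈ 0.248).  Estimates are
therefore compared against each other and against continuous-outcome
truth, never against the latent binary coefficient.

What the generator does **not** emulate: LD between instruments, sample
overlap between GWAS, allele-frequency mismatch between populations,
winner's-curse selection bias, and effect-size distributions of real
instruments (γ_j equal-magnitude with random sign is a modelling choice;
nothing here depends on its shape).  Passing tests show the estimators are
correct and calibrated under the stated assumptions, not that those
assumptions hold in any particular real dataset.

## Synthetic cohort generator

Event times follow a Weibull proportional-hazards model,
S(t|η) = exp(−(t/scale)^shape · e^η), with
η = log(hr_direct)·E + b_MH·M + 0.05·Σ confounders and mediator
M = b_EM·E + 0.1·Σ confounders + N(0,1); follow-up is administratively
censored at `censor_time`.  Defaults emulate an elderly female cohort with
a low-prevalence beverage exposure: 13,567 subjects, 11% exposed, 16
standard-normal confounders, 15 years of follow-up, baseline scale 580 and
shape 1.1 giving ~14.8 years mean follow-up, an incidence near 1.2 per
1000 person-years (~240 events), and a mediator carrying ~22% of the total
log-hazard effect (hr_direct = 1.43, b_MH = 0.26, b_EM = 0.4).  With a
rare outcome the total log HR is approximately direct + indirect
(non-collapsibility of the hazard scale is second-order at these event
rates), which is what makes the difference method and two-step MR
comparable.  At ~240 events the single-replicate difference-method PM is
intrinsically noisy; replicate means are the meaningful quantity.

## Observational arm

The Cox partial likelihood with Efron tie handling is maximized by
Newton–Raphson with step-halving (the log-likelihood never decreases
between iterations, up to a 1e-9 relative float-noise allowance that
prevents stalling at the optimum).  Convergence requires max |score| <
1e-8 within 50 iterations; covariance is the inverse observed information.
Design columns are mean-centered and the linear predictor max-shifted for
numerical stability (both leave the partial likelihood and slopes
invariant).  Monotone likelihood (perfect separation) is reported as an
error naming the offending term, triggered either by divergence during
iteration (|β| > 50) or by a "converged" coefficient larger than 15 —
a log hazard ratio beyond e¹⁵ means the likelihood flattened along a
separating direction rather than attaining an interior maximum.  The
implementation is cross-checked against lifelines and against a
brute-force grid-search oracle on small instances; lifelines also backs
the scaled-Schoenfeld proportional-hazards diagnostic (rank transform)
behind `schoenfeld_test`, and statsmodels OLS backs the mediator screen.

Categorical exposures enter as indicator contrasts against the lowest
category (use an ordered pandas Categorical to control the reference; a
plain string column falls back to lexicographic order).  The
difference-method PM is defined on the log-HR scale by default; the
(1−HR_direct)/(1−HR_total) scale is available via `scale="one_minus_hr"`.
Its CI is a seeded subject-level nonparametric bootstrap (default 500
replicates, percentile interval) of the entire two-model procedure;
non-convergent replicates are dropped and more than 5% dropped is an
error.  A closed-form variance for the difference estimator exists under
extra assumptions, but the bootstrap is assumption-light and directly
testable, which is why it is the shipped default.

## Problem sizes used by the test suite and acceptance script

Monte-Carlo checks use replicate counts and sample sizes chosen to make
their target property measurable with comfortable margin: IVW bias and
coverage at n = 50,000 per sample with 50 instruments over 100 replicates;
Egger intercept type-I error under balanced pleiotropy at n = 10,000 with
30 instruments over 500 replicates; planted-outlier MR-PRESSO detection
over 100 replicates at the summary level (where the sampling distribution
of the statistics is exactly normal); two-step PM recovery of a true 25%
mediated fraction at n = 20,000 over 40 replicates; and the cross-arm
consistency check (difference method vs two-step MR under a shared
rare-outcome model, both with true PM 25%) at n = 20,000 over 100
replicates per arm.  Delta-method CI coverage is checked at the summary
level — step estimates drawn from their exact sampling distributions —
because that isolates the property being tested from simulation noise in
the GWAS chain.

## Known limitations

* No multivariable MR, Steiger filtering, CAUSE/mode-based estimators, or
  Fine–Gray competing-risks regression.
* No LD simulation, proxy-SNP lookup, or reference-panel r² computation.
* First-order Wald SEs understate uncertainty when instruments are weak;
  the mean-F flag is the guardrail, not a correction.
* The binary-outcome MR estimand is the marginal log-odds effect
  (non-collapsible; attenuated relative to the latent conditional effect).
* Mediation truncation at 0% is a reporting convention; the untruncated
  value and CI are always retained alongside it.
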