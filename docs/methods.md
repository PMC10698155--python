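# Methods

## Setting and model

The package analyzes retrospective (case-control) samples: subjects are
selected by disease status, so exposure distributions are modeled
conditional on status and only odds ratios — not absolute risks — are
identified.  Disease is modeled per sex stratum by logistic regression

    logit P(case | x) = β0 + β' x,

with binary exposure indicators and continuous age (in years, uncentered, so
coefficients read as per-year log-odds).  The sexes are always modeled
separately: in the motivating data the male-only exposures are collinear
with sex, and no coherent pooled model exists.

### Coding rules

- Exposures reported by a case in the same calendar year as, or after,
  disease onset are censored to "no event", never to missing: prodromal
  disease can cause the apparent exposure (e.g. balance problems causing
  falls and head injury), so such reports are not risk events.  Controls
  have no onset and are never censored.  Censoring is idempotent and can
  only decrease exposure counts.
- A second head-injury indicator keeps only events more than 10 years before
  onset (events within the window count as no event), a stricter
  reverse-causality guard.
- Onset and event timing may arrive as calendar years or as ages; when only
  ages are available, years are reconstructed as
  `survey_year − floor(age) + floor(event age)`.  Year-level resolution is
  all the censoring rules need.
- Family history "unknown" (a relative reported without degree) is treated
  as missing.
- Every model uses its own complete-case subset; the retained per-status
  counts are reported as "N with data".  No imputation.

## Estimators

### Corrected Woolf OR (descriptive features)

OR = ((a+k)(d+k)) / ((b+k)(c+k)) with k = 0.5 added to **all four** cells
unconditionally, CI = exp(log OR ± z·√Σ 1/(cell+k)).  Applying the
correction only when a zero cell occurs would change estimates for tables
that need no rescue (4.85 → 4.92 for a 345/430/57/345 table); the
unconditional rule keeps the estimator a single continuous function of the
data.  Univariable risk-factor ORs use *uncorrected* logistic regression
instead — the two procedures serve different tables and are deliberately not
unified.

### Logistic regression

IRLS from β = 0, convergence when the largest coefficient step < 1e-10 or
the log-likelihood change < 1e-12, at most 100 iterations.  Model covariance
is the inverse observed information; the robust (sandwich) covariance is
bread·meat·bread with meat Σ(yᵢ−pᵢ)²xᵢxᵢ'.  Quasi-complete separation is
flagged deterministically when any |β| exceeds 15 during iteration or the
information matrix's condition number exceeds 1e12; a separated fit refuses
inference and recommends the Firth penalty.  One-sided inference uses fixed
quantiles z = 1.644854 (one-sided 95%, equivalently two-sided 90%) and
1.959964 (two-sided 95%), always in the risk-increasing direction — the
factors are studied *because* they raise risk elsewhere, so the alternative
is one-sided by design.

### Firth penalty

Maximizes ℓ(β) + ½log|I(β)| by modified-score Newton steps
(score + hᵢ(½−pᵢ) correction, hᵢ the logistic hat diagonal) with
step-halving on the penalized likelihood; same tolerances as IRLS.
Covariance is the inverse penalized information at the optimum.  The
penalty is O(1/n): on large simulated cohorts Firth and ML coefficients
agree to <0.01 (tested), so using it as an automatic fallback under
separation does not distort well-behaved fits.

### Miettinen PAF and its interval

PAF = p_c(1 − 1/RR), RR ≈ adjusted OR under the rare-disease assumption.
p_c is the exposed fraction of cases **on the multivariable complete-case
subset** — the same rows that produced the adjusted OR — not the larger
univariable subset; mixing subsets would make the two PAF inputs refer to
different populations.

The interval treats PAF = p_c(1 − e^(−β_e)) as a functional of (p_c, β_e)
and applies the delta method with a joint sandwich covariance from the
stacked estimating equations

    Σᵢ xᵢ(yᵢ − pᵢ) = 0        (logistic score)
    Σᵢ yᵢ(eᵢ − p_c) = 0       (case exposure prevalence)

Because neither equation involves the other's parameter, the M-estimation
bread is block-diagonal and

    Var(p̂_c)        = p_c(1−p_c)/n_cases
    Cov(β̂, p̂_c)    = I(β)⁻¹ · Σᵢ xᵢ(yᵢ−pᵢ)·yᵢ(eᵢ−p_c) / n_cases,

with the cross term clipped to the Cauchy–Schwarz bound so the 2×2
covariance stays positive semi-definite (this also gives the exact
binomial-only limit when Var(β̂) → 0).  The interval is Wald-symmetric on
the PAF scale (published intervals of this kind are symmetric about the
point estimate), truncated above at 1.  A protective estimate (PAF < 0) is
returned as computed, with a warning.  The interval's validity is
established by simulation (94–96% coverage at nominal 95%, n = 1200) and by
agreement with a stratified nonparametric bootstrap of the same estimator
(within 15% relative width), rather than by bit-equality with any external
package.

### Joint PAF

PAF_joint = 1 − Π(1 − PAF_i) assumes no interaction between factors; the
guard fits every pairwise product term and permits the joint estimate only
when all two-sided Wald p-values exceed a threshold (default 0.05).  The
plug-in interval applies the joint formula to the sets of component lower
and upper bounds; it inherits the components' symmetric-Wald behavior and
is a bounding device, not a coverage-calibrated interval.

## Synthetic cohorts

The generator emulates the retrospective design directly: exposures are
sampled conditional on status at control prevalence p₀ and the implied case
prevalence p₁ = OR·p₀/(1 − p₀ + OR·p₀), ages are normal per status, and
missingness is independent per variable.  Defaults mirror the motivating
study's dimensions (808 cases / 415 controls overall; 512/125 male-like and
296/290 female-like strata with the published exposure prevalences and
univariable ORs).  An interaction option samples an exposure pair from the
joint Bernoulli model whose disease log-odds include a product term;
`make_separated_cohort` constructs a zero exposed-control cell.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: confounding structure between exposures
(they are independent by default), recall bias, differential missingness by
status, age-exposure dependence, and onset-age processes (onset years are
assigned only to exercise the censoring rules).  Simulation results validate
the estimators under a correctly specified model, not the epidemiology.

## Problem sizes and numerical choices

Simulation-based tests use 200–1000 replicates at 600 cases / 600 controls
(coverage, recovery, interaction calibration), 25–60 replicates for power
checks at n = 2000, and single large cohorts (2·10⁵ subjects) for
law-of-large-numbers checks; these sizes give Monte-Carlo error comfortably
inside the asserted tolerances while keeping the suite quick.  Replicate r
of a study uses seed base + r under numpy's default generator, so every
result is reproducible from one integer.

Brute-force oracles in the tests maximize the (penalized) log-likelihood on
iteratively refined 21×21 grids, independent of the IRLS/Newton route they
check, to 1e-4.

## Known limitations

- No exact/conditional logistic regression; spousal pairs are analyzed as an
  unmatched subgroup, not as matched pairs.
- No Levin (population-prevalence) PAF, no time-to-event attributable
  fractions, no projection of PAFs to other populations — PAF depends on
  local exposure prevalence and does not transport.
- No multiple-testing correction anywhere (matching the analysis design the
  package reproduces).
- The joint-PAF plug-in interval has no coverage guarantee; it brackets the
  joint estimate by construction.
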