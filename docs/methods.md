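# Methods

## Generative model

Each simulated subject is independent. Two binary diseases are drawn from
their exact joint distribution: both have prevalence `d`, and the target
Pearson correlation `rho` between them fixes the joint cell
`P(1,1) = d² + rho·d(1−d)` (solving `cov = rho·d(1−d)`). This construction —
rather than dichotomizing a latent Gaussian — makes `rho` hold exactly in
expectation, so recovery of `rho` is testable without bias terms. For equal
margins the feasible range is `−min(d,1−d)/max(d,1−d) ≤ rho ≤ 1`; infeasible
pairs raise an error (none occur on the default grid, whose `rho` values are
nonnegative).

The symptom is Bernoulli per subject: probability `q = min(ir·rr, 1)` when
disease 1 is present, `ir` otherwise. Disease 2 never enters the symptom
law; it exists as a negative control, and its regression coefficient is zero
by construction. Capped combinations (`ir·rr ≥ 1`) are retained, not
dropped: they form the "reaching 1" stratum that the analyses contrast with
the "less than 1" stratum. Products exactly equal to 1 are classified as
reaching 1, since all diseased subjects are then symptomatic exactly as in
capped combinations.

## Statistics per run

The disease-1-by-symptom table (a, b, c, dd) yields the observed measures
`d̂ = (a+c)/n`, `îr = b/(b+dd)`, `q̂ = a/(a+c)`, `r̂r = q̂/îr`, and the sample
phi via the standard 2×2 formula `(a·dd − b·c)/sqrt` of the margin product.
The correlation p-value uses the t transform `t = phi·sqrt((n−2)/(1−phi²))`
with `n−2` degrees of freedom (two-tailed) — the conventional test for a
Pearson correlation. Chi-squared is computed both uncorrected (which
satisfies the identity `chi2 = n·phi²`) and with the Yates continuity
adjustment; both p-values use the 1-df upper tail. Degenerate tables (a zero
margin) are flagged invalid and carry NaN statistics; they are excluded from
— and counted by — every downstream analysis, never silently dropped. At the
default `n = 10,000` and the default grid they essentially never occur.

Because `q̂ = îr·r̂r` by construction, the closed-form phi evaluated at a
run's observed measures reproduces that run's sample phi to floating-point
precision. This is the mechanism behind the identity fits returning R² = 1:
it is an algebraic identity on the observed table, not a statistical fit.

## Study design and defaults

The default factorial grid defines the study conditions:
`rho ∈ {0, 0.3, 0.7}`, `d ∈ {0.05, 0.1, 0.2, 0.4, 0.8}`,
`ir ∈ {0.05, 0.1, 0.2, 0.4, 0.8}`, `rr ∈ {0.5, 1, 2, 5, 10, 25}`,
`n = 10,000` subjects per run, 10 replicates per combination (450
combinations, 4,500 runs). Of the 30 (ir, rr) cells, 13 reach an at-risk
incidence of 1. The acceptance script raises replicates to 30 to stabilise
the grid-level regression estimates; all other conditions are unchanged.

Seeding is counter-based: run `k` uses `SeedSequence(master_seed,
spawn_key=(k,))`, so any single run is re-creatable in isolation and a
sequential re-run reproduces the record table byte-identically. The scheme
identifier is recorded in the output manifest.

## Regression analyses

Three analysis families operate on the per-run records:

* **Identity fits** regress each run's sample phi (or chi-squared) on the
  closed form at that run's observed measures. R² = 1 to numerical
  tolerance at any grid size, for both responses.
* **Approximation tables** fit OLS per response and stratum: Model A on
  (rho, d, rr, ir), Model B adding (ir·rr, d·rr, d·ir). Coefficients carry
  t-based 95% CIs and p-values; collinearity is surfaced through variance
  inflation factors, with VIF > 10 flagged.
* **R² decomposition** reports the cumulative ladder adding rho, d, ir, rr
  in that order (non-decreasing by nesting) and, for each extra predictor —
  the four cell counts a, b, c, n−a−b−c and the interactions ir·rr, d·rr,
  d·ir, d·ir·rr, d²·ir — its R² alone and joint with the four measures.

**Predictor source.** The approximation fits default to the measures
*derived from each simulated table* (`predictor_source="observed"`);
`"assumed"` substitutes the design-grid values. The observed default is a
deliberate design choice: the derived risk ratio respects the upper-limit
law `r̂r ≤ 1/îr`, so in the reaching-1 stratum the derived product `îr·r̂r`
is pinned at 1. That near-constant column duplicates the intercept, and
only the *sum* of the intercept and the ir·rr coefficient is identified —
the signature behaviour of the interaction model in that stratum (a fitting
environment that solves the normal equations by QR reports two enormous
offsetting coefficients; the minimum-norm least-squares solution used here
splits the same identified sum across the pair). With assumed values the
two strata differ only negligibly in R² (< 0.01), so the choice matters for
coefficient interpretation, not for variance explained.

**Stratification** uses the design product `ir·rr` (reaching 1 iff ≥ 1).
The per-run observed criterion `q̂ = 1` gives the identical partition on the
default grid, because capped combinations force `q̂ = 1` while uncapped ones
essentially never attain it at n = 10,000; both labels are derivable from
every record.

Significance concordance cross-tabulates the correlation and chi-squared
tests at a common alpha (default 0.05). The chi-squared side defaults to the
Yates-corrected p-value: without the correction the two tests are the same
statistic up to the t-versus-normal tail and never disagree, whereas the
correction's conservatism produces the small correlation-significant-only
remainder (about 0.1% of runs on the default grid) that a concordance
analysis is designed to expose.

## Numerical choices

* Expected tables carry fractional cells; closed forms are population
  identities and are never rounded.
* `phi_from_table` returns NaN (not an exception) on a zero margin so grid
  runs always complete.
* `|phi| = 1` maps to a correlation p-value of 0 rather than an infinite t.
* OLS is solved by pseudo-inverse (statsmodels default); rank-deficient
  terms are reported with infinite VIF rather than failing.
* CSV output uses a 12-significant-digit float format, enough for the
  `chi2 = n·phi²` identity to survive a write/read round trip at the
  tolerances used anywhere downstream.

## What the generator does and does not emulate

The simulation realises the idealised cohort the closed forms describe:
homogeneous risk within disease strata, random symptom occurrence,
perfectly measured binary states, and a causally inert correlated disease.
It does not emulate population heterogeneity (e.g. age-concentrated
symptoms), misclassification, confounding structures, censoring or
time-to-event aspects of real cohorts. Passing tests therefore demonstrate
the algebraic translation and the behaviour of the association statistics
under the idealised model — not that real-world correlations can be
recovered from published measures, where these violations add variance and
bias that the equations do not capture.

## Known limitations

* Grid-level regression R² values depend strongly on the composition of the
  design grid (which parameter values, and how strata partition them):
  stratified versus unstratified fits of the same response can flip
  coefficient signs (the proportion-diseased coefficient for phi is ≈ 0.2
  unstratified but ≈ 0 within the less-than-1 stratum). Comparisons across
  studies are only meaningful for an identical grid and stratification.
* The chi-squared translation `chi2 = n·phi²` holds for the uncorrected
  statistic only; continuity-corrected values fall below it.
* At very small `n` or extreme measures, degenerate tables become common
  and the derived-measure predictors lose rows; the fits report exclusion
  counts but make no small-sample correction.
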