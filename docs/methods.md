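# Methods

## Study design being modelled

The pipeline models a single-center aftercare tracking design: male drug
patients released from compulsory isolated detoxification, assigned 1:2 to
an experimental arm (social-worker aftercare) or a control arm by the
seat-number rule at questionnaire collection (seat numbers that are
multiples of 3 → experimental), then revisited at fixed days after release
— 7, 30, 90, 180, 270, 360 — to establish whether drug use has resumed.
Monthly release batches are approximated by staggering release days
uniformly over the first 365 study days, with study end at day 395, so
censor times range from 30 to 395 days and right censoring is
heterogeneous across subjects.

Day counting: the release day is day 0 and the earliest possible relapse
day is day 1.  A relapse detected at visit `v` after a clean previous
visit `p` is recorded with the printed integer bounds `(L, R) = (p+1, v)`
("91 < <180"); the equivalent continuous event-time region used everywhere
internally is `(L−1, R] = (p, v]`.  A relapse occurring after the last
*attended* visit but before study end is treated as detected at the final
study-end assessment, giving the open window `(last visit, censor]`; the
follow-up design itself does not say how such events would be coded, so
this is a package choice, and visits are assumed fully attended.

## Synthetic cohort generator

Covariate marginals default to the cohort's published baseline
distribution (e.g. 69.1% single, 43.4% household registration in other
provinces, age 33.99 (SD 7.027)).  SOCRATES totals are drawn from
N(72.47, 7.124²) rounded and clipped to [19, 95]; HADS totals from
N(8.44, 7.284²) clipped to [0, 42].  Totals are spread to items by a
deterministic round-robin (every item starts at its minimum; remaining
points are dealt one per item per pass), which preserves totals exactly —
item-level detail only matters for internal-consistency checks, so no
item-level correlation structure is imposed, and Cronbach's α of generated
items is therefore unrealistically high.  Anxiety items are positions
1, 3, 5, ... of the 14-item HADS; the reverse-key mask is configurable and
empty by default (generated items are already in scored orientation).

Two relapse-time processes are available:

* **mixture** (default): with per-group probability `p_early` the relapse
  day is uniform in [1, 7]; otherwise it is a Weibull truncated beyond day
  7 with scale `α_g + r_s·M_i`.  Defaults (`p_early` 0.111/0.457,
  intercepts 852/737 days, `r_s` = 2.6, k = 1) were fixed analytically so
  that a default 510-subject run lands near a 48% relapse fraction with
  roughly 74% of relapses in week one — visually comparable to the
  published pattern without claiming to reproduce it.
* **weibull_aft**: a pure Weibull event time with scale
  `λ_i = α_g + r_s·M_i`, matching the estimation model exactly; used for
  parameter recovery with user-set truths.

What the generator does **not** emulate: follow-up attrition or refusal
(none is modelled), covariate–covariate dependence (marginals are drawn
independently), within-scale item structure, missed visits, or any
female-cohort extension.  Passing recovery tests therefore demonstrates
correctness of the estimation machinery under the assumed model, not
robustness to real-data violations of it.

## Survival model and sampler

Event times are `T_i ~ Weibull(k, λ_i)` (scale parameterization,
`S(t) = exp(−(t/λ_i)^k)`) with `λ_i = α_g + r_s·M_i`, one intercept per
arm (or a single one when ungrouped) and a slope shared between arms.  The
identity link keeps the motivation effect directly expressible in days per
SOCRATES point via `r = r_s·Γ(1+1/k)`; mean survival is
`(1/n)Σ λ_i Γ(1+1/k)`.  Proposals that make any subject's scale
non-positive are rejected, which enforces the parameter constraint.

Inference is Metropolis-within-Gibbs with data augmentation.  Each
iteration draws every latent event time from its Weibull truncated to the
subject's region — `(L−1, R]` for relapse windows, `(censor, ∞)` for
compliant subjects, by inverse CDF in a log-stable form — then runs
several (default 5) random-walk Metropolis sweeps over `log k`, each
`α_g`, and `r_s` against the complete-data log posterior.  Multiple sweeps
per refresh bring parameter mixing close to the ideal two-block Gibbs
rate, which is what makes the strict C.S. ≤ 1.002 convergence criterion
attainable at 5,000 iterations.  The covariate is centered internally
(`λ_i = α' + r_s(M_i − M̄)`) to decorrelate intercept and slope; draws are
reported uncentered.  Proposal scales adapt toward a 0.44 acceptance rate
during burn-in only and are frozen afterwards, so the retained chain is
Markovian.  Chains are initialized overdispersed around a crude
interval-midpoint scale estimate.

Priors are weakly informative and configurable: `k ~ Gamma(2, 1)`,
`α_g ~ N(200, 200²)`, `r_s ~ N(0, 50²)`.  On the day scale of this
problem they contribute negligibly at n ≈ 500.

Defaults: 5,000 iterations, 1,000 burn-in, no thinning, 4 chains.  Groups
are ordered by first appearance in the data (not alphabetically), which
makes relabelling arms swap the two group summaries exactly under a fixed
seed.

### Diagnostics and summaries

The convergence statistic is the classic (non-split) Gelman–Rubin PSRF
`sqrt(var⁺/W)` with `var⁺ = (n−1)/n·W + B/n`, matching the printed-table
"C.S." convention with its ≤ 1.002 convergence threshold; it is computed
per parameter and for the reported functionals.  ESS uses the multi-chain
autocorrelation estimate with Geyer's initial-monotone positive-pair
rule; the Monte-Carlo SE of a posterior mean is SD/√ESS.  Posterior
summaries report mean, MC SE, SD, C.S., percentile 95% bounds and the
posterior sample extremes ("Min"/"Max" are sample extremes of the
functional across retained draws, not subject-level extremes).

### Closed-form check

With `k` fixed at 1, no covariate and (numerically) exact event times the
model collapses to the exponential, whose posterior mean of mean survival
approaches the MLE `ΣT/n` up to an O(2/n) skew term (the posterior mean of
a scale parameter sits slightly above the MLE).  The check fixture
therefore thins the chain to a modest effective sample size so that
Monte-Carlo error, not that analytic O(1/n) term, is the dominant
difference at n = 2,000.

## Imputation

Per-subject survival times are imputed by reusing the sampler's latent
event times at m = 10 retained iterations selected at equal spacing across
the flattened retained chain (deterministic; a seed argument exists only
for interface symmetry).  This is the Gibbs-augmentation analogue of
drawing the imputation parameters from their posterior and guarantees that
every draw — hence the combined mean for relapse subjects — respects the
censoring region; compliant subjects' imputed times are uncapped tail
draws beyond their censor day, so combined times can exceed the follow-up
span.  The combined value is the plain mean of the m draws; Rubin's-rules
variance pooling is intentionally not applied because downstream analysis
consumes point values only.

## Risk model

The combined times are ranked ascending and `round(0.27·n)` subjects enter
each tail: bottom → low survival (1), top → high survival (0), middle 46%
excluded from the regression (the tails maximize discriminative power; the
excluded-middle design is configurable).  Ties break by stable input
order.  Four strictly nested logistic models enter predictor blocks in
batches — sociodemographic; + drug-abuse history; + clinical situation;
+ group — with categorical predictors dummy-coded against fixed reference
levels (single, other provinces, senior high school and above, mixed drug
type, experimental group as control-indicator reference) and age, age at
first use and the HADS total entered untransformed.  Each fit reports
exponentiated coefficients with log-odds SEs, the likelihood-ratio χ²
against the intercept-only model, Nagelkerke's R²
`(1 − exp(2(LL₀−LL₁)/n)) / (1 − exp(2LL₀/n))`, −2LogLik, classification
accuracy at the 0.5 cutoff, and the χ²/df increments between consecutive
models.  Maximum likelihood is delegated to statsmodels' Logit; perfect
separation is detected beforehand and reported with the offending
predictor's name.

## Problem sizes

Default analyses use the full 510-subject design.  The recovery
experiments in the test suite and acceptance script use 500-subject
cohorts with 5,000 iterations × 4 chains (≈ 13 s per fit), three seeds in
the test suite; unit-level fits use 150–400 subjects with shorter chains,
sizes chosen to keep each check's Monte-Carlo error well inside its
assertion margin.

## Known limitations

* The identity link `λ_i = α_g + r_s·M_i` can produce invalid (negative)
  scales for extreme covariates; a log-link AFT variant would avoid this
  but would not report the effect in days per point directly.  The
  sampler's positivity rejection handles the boundary.
* Printed posterior means from the motivating study (220.35 / 393.32 /
  175.10 days; effect 2.629) are scale references only: they derive from
  raw subject-level data and a modelling tool whose exact likelihood is
  not recoverable, so the package validates by parameter recovery on
  synthetic data instead of by reproducing those numbers.
* No cure fraction is modelled despite the first-week spike; the mixture
  generator can create data the Weibull estimation model fits only
  approximately.  No time-varying covariates, no frequentist
  Turnbull/NPMLE estimator, no multiple-testing adjustment.
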