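# Methods

## Annual status scoring

A site-year is `occupied` if breeding birds were found on any visit during
the breeding season, `unoccupied` if the site was visited at least once and
breeding birds were never found, and `unknown` if it was not surveyed.
`unknown` is a statement about monitoring, never about the birds. Multiple
rows for one site-year are treated as within-season visits and collapsed by
that any-visit rule; callers who want contradictions surfaced instead can
pass `on_conflict="error"` to `build_occupancy_series`. When a site's
recorded substrate changes between years the series is split into one
series per substrate run, because turnover and longevity are analysed as
substrate-specific; unknown years inherit the running substrate and
trailing unknowns are dropped. Dates beyond the calendar year are ignored —
the tables are annual.

## Turnover events and denominators

Cessation of use: occupied at *t*−1, surveyed and unoccupied at *t*.
Possible cessation: occupied at *t*−1 and surveyed at *t*. Colonization:
known unoccupied at *t*−1 and occupied at *t*, counted only from a
configurable start year (default 2006, the first year pair with systematic
re-checking of vacant sites). Possible colonization requires the site to be
*known* unoccupied at *t*−1 — "not known occupied" would silently admit
unmonitored years into the denominator and bias rates toward zero. A
site-year pair is never simultaneously a possible cessation and a possible
colonization, and events plus non-events always equal possible events; the
test suite asserts this conservation identity on every simulated dataset.

Per-substrate rates use exact Clopper–Pearson intervals rather than normal
approximations because several cells have fewer than ten events. Substrates
with fewer than five records for a given rate (the `min_records` filter)
have that rate omitted entirely — never reported as 0/0.

## Binomial mixed model

Occupancy, cessation and colonization differences are tested with a
logit-link Bernoulli model with a normal random intercept for year.
No frequentist binomial mixed-model routine exists in the scientific Python
stack, so the marginal likelihood

  L = ∏_g ∫ φ(u; 0, σ²) ∏_{i∈g} p_i(u)^{y_i}(1−p_i(u))^{1−y_i} du

is maximised directly with 30-node Gauss–Hermite quadrature over u and BFGS
over (β, log σ). With the small group counts typical of annual surveys
(≤ ~10 years) this matches `lme4::glmer` with adaptive quadrature to about
three decimals (asserted in the test suite with R as the independent
oracle). Standard errors come from the numerical observed information;
p-values are Wald. The occupancy model includes year both as a fixed factor
and as the random intercept — an unusual but deliberate specification that
separates systematic year shifts from residual annual correlation; the
turnover models use substrate only as fixed. Treatment coding uses cattail
marsh (and the first study year) as reference. Complete separation (a
substrate level with all-0 or all-1 outcomes) attaches a warning and flags
the affected terms rather than failing. The information criterion reported
is AICc = AIC + 2k(k+1)/(n−k−1).

ANOVA-style tables are computed as the sequential (Type I) sums-of-squares
partition of the response over the fixed-effect design by ordinary least
squares, with partial eta-squared h² = SS_effect/(SS_effect+SS_error) per
effect. For a binary response the residual mean square is then the
within-cell Bernoulli variance, which is the scale on which published
occupancy partitions of this kind are reported. Note that h² computed this
way need not match a whole-model R².

## Colony longevity

Maximal runs of consecutive occupied years form spells. A run that ends at
a known unoccupied year is an observed event; a run truncated by an unknown
year or by the edge of the record is right-censored. A run whose start was
never observed (occupied in the first observed year, or preceded by an
unknown year) is flagged left-censored; since the standard AFT likelihood
has no left-truncation term, such spells enter the likelihood as
right-censored at their observed duration — the observed run is a lower
bound on the true duration. The flag is preserved so users can drop these
spells for sensitivity analysis.

The Weibull AFT model log T = μ + σW (W standard minimum extreme value) is
fitted by explicit censored maximum likelihood: with z = (log t − xβ)/σ,
events contribute −log σ − log t + z − e^z and censored spells −e^z. The
optimizer is BFGS on (β, log σ) with the analytic gradient, started from
the closed-form exponential solution (σ = 1, rate = events/total time);
convergence requires gradient norm below 10⁻⁸ (an explicit error reports
the final gradient norm otherwise). Fixing log σ = 0 recovers the
exponential special case exactly, which the tests use as a closed-form
check; the free fit is cross-checked against lifelines' Weibull AFT and
against a brute-force grid search of the likelihood. Integer yearly
durations are modelled as continuous, matching standard parametric survival
practice on annual data. All spells censored makes the likelihood unbounded
and is rejected up front.

The likelihood-ratio statistic 2(ℓ_full − ℓ_reduced) is referred to the
chi-squared distribution with the parameter-count difference as degrees of
freedom. Its null rejection rate, measured over 500 simulated null
datasets of 200 spells, sits within Monte-Carlo error of the nominal 5%
(slight finite-sample inflation of order 1/n is visible in the mean
statistic, as expected for likelihood-ratio tests without a Bartlett
correction).

## Reproduction

RS (chicks per nest at roughly 7–9 days after first hatch, zeros included)
and RSS (the same mean over successful nests only) satisfy
RS = RSS · prop_successful as an algebraic identity, which holds exactly in
every estimator and fixture here. Bird counts convert to nests by ×2/3 and
nests to birds by ×1.5, exact mutual inverses; when both a visual bird
estimate and a direct nest count exist, the nest count wins. The substrate
model is a linear mixed model with a colony random intercept fitted by ML
(statsmodels MixedLM). Observer and year enter only if they lower AICc —
the model re-tests the observer term on every dataset rather than assuming
pooling is safe. RS is modelled on its natural scale. With a single
substrate the model degenerates gracefully to an intercept-only fit.

## Habitat value

x = RS · (2/3) · mean birds is the predicted chick production of an
average-size colony. The ×2/3 step is applied because RS is per nest while
sizes are recorded in birds; it is a switch (`convert_birds_to_nests`,
default on) since published chick-production figures do not always state
whether the conversion was applied. SD(x) = x·√(s₁²+s₂²) with s₁, s₂ the
coefficients of variation of colony size and RS — the first-order
delta-method SD of a product of independent estimates, verified against
Monte-Carlo simulation in the tests. Multiplying by occupancy gives chicks
per site per year; it can never exceed x, and the RS ingredient defaults to
raw per-substrate means rather than model-based means (a flag on the model
results exposes the latter). Decadal summaries use ln(birds) with
zero-or-negative sizes excluded and counted; recent (2000–2011) colony
sizes are reported both as arithmetic means and as back-transformed mean
logs (geometric means), labelled as such, because the two differ
substantially for right-skewed sizes.

## Synthetic surveys

Each site follows a two-state Markov chain: P(occupied_t | occupied_{t−1})
= 1 − e_s, P(occupied_t | unoccupied_{t−1}) = c_s, with stationary
occupancy c/(c+e). Occupied site-years draw a lognormal colony size and a
30-nest sample in which each nest fails with probability f_s and each
successful nest rears max(1, round(N(rss_mean, rss_sd))) chicks — a
discretized positive distribution chosen because field summaries imply only
a mean and SD for successful-nest output. Site-years are surveyed
independently with probability `monitoring_prob` (missing at random).

Defaults are the study conditions of a declining itinerant colonial
breeder: cessation rates from 0.20 (nettle) to 0.83 (grain fields) with
cattail marsh at 0.49, a common colonization rate of 0.211, initial
occupancy at each substrate's stationary value, lognormal sizes with
log-SD 1.0 whose arithmetic means equal the recent per-substrate colony
sizes (135–995 birds), and failure/RSS pairs back-derived from the observed
RS = (1−f)·RSS relationship per substrate. `monitoring_prob` defaults to
0.85, a realistic incomplete-monitoring level chosen once; real monitoring
effort was likely targeted at previously occupied sites, and the parameter
is exposed precisely so that such informative-missingness experiments can
be run, but the default generator is missing-at-random. A single root seed
drives one independent substream per (substrate, site) via spawned seed
sequences, so raising the site count never changes existing sites' draws.

What passing tests show — and what they do not: the generator reproduces
the statistical structure the estimators assume (Markov turnover, MAR
monitoring, zero-inflated nest outcomes, independence across sites). Real
surveys violate some of these (targeted monitoring, spatial dependence,
within-season movement between sites), so parameter recovery here
demonstrates correctness of the estimators under their stated assumptions,
not robustness to those violations.

## Problem sizes and numerical choices

Test and acceptance runs use 120–300 sites over 7–30 years with 5–20
replicate seeds, and 500 replicates for the likelihood-ratio calibration
and 500-spell draws for the survival-likelihood checks — sizes at which
Monte-Carlo error is small relative to the stated tolerances while the
whole suite completes in about a minute. Grid-search likelihood
verification uses an 81×81 lattice of half-width 0.2 around the optimum.
Ties and degenerate inputs are handled explicitly: 0/0 rates are omitted,
eta-squared with both sums zero is an error, zero-bird colonies are
excluded before log transforms, and empty nest samples are rejected.

## Known limitations

- No detection probability: an occupied site surveyed is assumed found
  occupied (no MacKenzie-style occupancy modelling).
- Left-censored spells are approximated as right-censored lower bounds;
  true interval/left-truncation handling would need colonization dates.
- The binomial GLMM uses non-adaptive quadrature; with very large groups
  or extreme σ more nodes may be needed (the node count is a parameter).
- The habitat-value SD propagation is first-order and treats size and RS
  as independent; occupancy uncertainty is not propagated into the
  adjusted output.
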