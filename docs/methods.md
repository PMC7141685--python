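# Methods

## Problem and observation model

A village-scale mark–resight survey of free-roaming domestic dogs (FRDD)
proceeds in two stages: a door-to-door campaign collars `Mc` owned dogs
and interviews their owners, then `T` foot-patrol transect rounds count
dogs seen in streets and open yards, split into marked (`m_t`) and
unmarked (`u_t`). The estimand is the number of owned FRDD `N_o`, the
expected number of ownerless dogs `λ_u`, and their sum.

Four processes connect the counts to the estimands:

1. **Recapture.** An unconfined dog present in the site is counted on a
   given round with probability `p`, the product of three survey
   properties: the fraction of the site effectively scanned (coverage),
   the chance a dog in the scanned area crosses the team's path
   (encountering), and the chance a crossed dog is recorded (recording).
2. **Confinement.** An owned dog is confined — invisible to the
   transect — with probability `c` during the survey hours. Ownerless
   dogs are never confined.
3. **Collar loss.** Collars are lost at a constant rate over the study,
   so the probability a marked dog no longer carries its collar at round
   `t` is `lm(t) = (Ml/Mc)·(t/T)` with `Ml` the total collars lost. The
   number of dogs still carrying a collar is `M_t = round(Mc·(1−lm(t)))`
   (ties rounded half-up); dogs that lost the collar re-enter the
   owned-unmarked pool.
4. **Ownerless dogs.** Their expected number is `λ_u = r·N_o`, with `r`
   the ownerless:owned ratio.

Counts per round, independent across rounds:

```
m_t ~ Binomial(M_t, p(1−c))
u_t = A_t + B_t,  A_t ~ Binomial(N_o − M_t, p(1−c)),  B_t ~ Poisson(λ_u·p)
```

The ownerless detections are Poisson rather than binomial. Two reasons:
the ownerless subpopulation size is itself an expectation (`λ_u` is
continuous, and surveys report fractional ownerless means with continuous
intervals, e.g. 0.12 (0–0.26)), and the Poisson is the small-expectation
limit of the binomial in exactly the regime these surveys occupy (ratios
around `e^{-7}`, i.e. a fraction of a dog per village). The reported
"number of ownerless dogs" is `λ_u`, not an integer realisation.

A single `p` and a single `c` are shared across rounds: the elicitation
produces one prior per site, and nothing in the counts identifies
per-round detection separately from `N_o` at `T = 4`.

## Priors and their elicitation

| parameter | prior | elicited from | typical values |
|---|---|---|---|
| `p` | Uniform(l, u) | products of the min/max coverage × encountering × recording bounds | 0.14–0.89 across sites |
| `c` | Uniform(l, u) | dog-count-weighted means of per-roaming-category confinement limits | 0.13–0.32 |
| `r` | LogNormal(μ, τ) | per-respondent ownerless/owned estimate ratios | μ ≈ −7, τ ≈ 5 |
| `N_o` | DiscreteUniform(Mc, cap) | dogs collared; cap well above any plausible count | cap 1000 |

Details and conventions:

- **Coverage** is computed from transect geometry: buffer the transect
  polylines by a half-width (25 m by default — the distance within which
  the team reliably spots dogs), union the buffers (round caps and
  joins), clip to the site polygon, and divide by the site area
  (`estimators.coverage_fraction`, shapely). Coordinates must be
  projected in metres; no CRS transformation is attempted. Reported
  prior bounds are rounded half-up to 2 decimals, and the rounded values
  are what the fit uses (callers wanting full precision pass
  `report_decimals=None`).
- **Confinement limits per category** during survey hours: never
  free-roaming = 1, always = 0, day-only = 0–0.25, a-few-hours-a-day =
  0.5, night-only = 0.75–1. The lower (upper) prior bound is the
  dog-count-weighted mean of the lower (upper) limits.
- **Ratio fit.** `τ` is a *precision* (1/variance of the log), the
  convention of BUGS-family samplers. Respondents with a zero owned or
  ownerless estimate are excluded (the log-ratio is undefined); the
  exclusion count is logged. The variance uses the unbiased (n−1)
  estimator. A zero-variance ratio set gets `τ` capped at 1e6 rather
  than infinity so downstream sampling stays finite. The precision
  reading is verified analytically: `exp(μ + 1/(2τ))` times the
  posterior owned mean reproduces the published posterior ownerless
  means at all three surveyed sites to two decimals
  (`tests/test_acceptance.py`).
- **Owned count.** The minimum is `Mc` (every collared dog is an owned
  FRDD); the default cap of 1000 is far above any village in scope.

## Inference

Metropolis-within-Gibbs, one update block per parameter and iteration:

- `p` and `c`: Gaussian random walks on the logit of the position within
  the uniform support, with the change-of-variables correction; a prior
  with zero width fixes the parameter and skips the block.
- `log r`: Gaussian random walk (the prior is normal on the log scale).
- `N_o`: symmetric integer random walk, jump size uniform on
  `{1..step}`; proposals outside the prior support are rejected (no
  reflection).

Step sizes adapt every 50 iterations toward a 44% acceptance rate during
burn-in only, so post-burn-in draws come from a fixed Markov kernel.
Defaults are 4 chains × 50 000 iterations with 10 000 burn-in; a seed is
mandatory and chains draw from independent spawned generators, making
every fit bit-reproducible. Zero post-burn-in acceptance in a block
raises a diagnostic error unless all chains agree on a single value (a
point-mass posterior, which arises legitimately, e.g. perfect detection
pinning `N_o` at `Mc` — then it is a warning). R̂ > 1.1 attaches a
convergence warning to the results.

The unmarked-count likelihood is an exact convolution of the binomial
and Poisson terms over the feasible split, truncating Poisson terms
whose upper-tail mass is below 1e−12 (the truncation bound is
`λ + 12√λ + 30`, conservative for all rates). The sampler's inner loop
uses a precomputed log-factorial table; the same quantity is exposed as
`unmarked_count_log_pmf`, cross-checked in the tests against a numpy
full-convolution oracle and a 10⁶-draw Monte-Carlo frequency.

Summaries are posterior means with equal-tailed 2.5/97.5 percentile
intervals (linear interpolation). Reports round half-up: whole dogs for
owned and total, two decimals for the ownerless mean. Effective sample
size and split-chain R̂ come from `arviz`; with a single chain R̂ is
undefined and reported as null.

## Simple estimators

- `human_dog_ratio_estimate(humans, ratio)` = round(humans/ratio) — the
  vaccination-planning convention (5:1 nationally in the study setting).
- `detection_percentage(estimate, census)` — whole-number percentage of
  the census an estimate detects.
- `empirical_human_dog_ratio(humans, owned_dogs)` — observed ratio to
  one decimal. All rounding is half-up; with truncation 160.8 would
  print 160, whereas the surveys report 161. One published cell (804/289
  printed as 2.7) appears truncated at source; this package prints 2.8
  and documents the difference rather than replicating truncation.
- `aggregate_transect_counts` / `land_cover_enrichment` — per
  site×method totals and observed-vs-available land-cover ratios, with
  `inf` flagged where dogs were seen in a class of zero mapped area.

## The synthetic village generator

`simulate_survey` is the exact generative dual of the likelihood:
roaming categories are multinomial with configurable weights; the ratio
`r` is drawn log-normally and the ownerless count Poisson(`r·N_o`); each
owned dog is collared independently; collars lost are binomial with a
configured expectation; transect rounds follow the binomial/Poisson
detection law above, with the confined fraction realised per round from
the category mixture (ranged categories redraw their value each round)
so elicited priors are centred on the generative truth. Owner interviews
report a truncated-normal estimate of the owned count (15% coefficient
of variation), a Poisson ownerless estimate around the respondent's own
perceived ratio (respondent ratios scatter around the village
log-normal), and a small Poisson community-dog estimate; the respondent
error model is this package's own construction, as field studies do not
publish one.

Defaults mirror the surveyed study conditions: ~100 owned dogs, mostly
always-roaming (elicited confinement ≈ 0.19–0.24), 60% collared, ~3
collars lost, 4 transect rounds, detection probability 0.55, ratio
μ = −6.6, τ = 5, 40 interviews. Everything is seeded and
bit-reproducible, with separate derived streams per pipeline stage.

What passing synthetic tests do *not* show about real surveys: the
generator has no spatial structure (no distance-dependent detection, no
heterogeneous dog behaviour), no double-counting error, no interview
bias beyond symmetric noise, and collar loss independent of roaming
behaviour. Violations of these idealisations in the field bias the real
estimates in ways the synthetic calibration cannot detect.

## Calibration evidence

Computed by the test suite at the problem sizes noted:

- **Credible-interval coverage**: with truths drawn from the fitting
  priors (owned 50–200, detection 0.4–0.8, 4 rounds), the 95% CrI for
  the owned count must cover the truth in ≥ 85% of 50 replicate
  simulate-and-refit cycles (short chains: 1 × 2500 iterations).
- **Simulation-based calibration**: over 200 replicates (3 rounds,
  owned 40–120, 1 × 1400 iterations, thinned), the rank of the true
  owned count among posterior draws is uniform (χ² on 10 bins not
  rejected at α = 0.01).
- **Closed-form cross-check**: on one round with no collar loss,
  confinement or ownerless dogs, the posterior mode agrees with
  Chapman's estimator `(Mc+1)(n+1)/(m+1) − 1` within 10%.
- **Prior sensitivity** (on the packaged synthetic fixture): widening
  the confinement prior by 0.25 moves the posterior total by < 5%; a
  Gamma ratio prior moves the owned/ownerless split more than the
  total — the behaviour expected when the data identify the total
  better than its decomposition.

## Degenerate inputs and tie-breaks

- `Mc = 0`: the model refuses to fit (no recapture information);
  `collar_loss_probability` returns 0 by convention.
- `m_t` exceeding `M_t` under the loss schedule: impossible data —
  `log_posterior` returns −∞ and the model constructor raises.
- Equal prior bounds (e.g. an elicited confinement of exactly
  0.157–0.157) fix the parameter; point priors have log-density 0.
- `N_o` proposals at the support edge are rejected, not reflected.
- Fewer than 1000 summary draws triggers a warning, not an error.

## Known limitations

- The likelihood conditions on `Mc`, `Ml` as known totals; uncertainty
  in the marking process itself is not propagated.
- Collar loss is linear in time and rounded to whole dogs; with tiny
  `Mc·Ml` the rounding granularity can matter.
- No spatial or distance-sampling structure; surveys where detection
  decays with distance from the transect need a different likelihood.
- The human:dog-ratio and census comparisons address the *owned* dog
  population including puppies and fully confined dogs, while the
  capture-recapture estimand excludes them; the package reports the
  numbers side by side but the populations differ by design.
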