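# Methods

This note documents the models, the synthetic-data generator, the sampler,
and the numerical and design choices behind `ternpath`.

## 1. Environmental path sub-model

Seven yearly series are modeled jointly on the log scale: three landings
series (Caribbean artisanal CR, Atlantic long-line/net LI, Atlantic trawl
TR), three age-1 production indices (menhaden MN, red drum DM, herring HR),
and long-line effort (hooks deployed).  Sea-surface temperature (winter
basin mean, °C) is exogenous throughout — it only ever appears on the
right-hand side — and all covariates are z-scored before entering a mean
model (constants taken from observed cells, stored for back-transformation).

Each landings/production series has mean

    m[j,t] = b0 + bT·tz + bT2·tz² + bS·sstz[t]  (+ lagged-landings terms for
                                                  production; + bLLrho·rho[t]
                                                  for LI)
    mu[j,t] = m[j,t] + phi[j]·(m[j,t−1] − y[j,t−1]),     mu[j,1] = m[j,1]

with within-year residual triples drawn from free covariance matrices
`Sigma_harv`, `Sigma_fish` (decomposed into sd vectors and correlation
matrices).  Two deliberate readings:

* **AR1 deviation against the trend part.**  The deviation term is measured
  against the trend+covariate expectation `m`, not against the full
  recursive mean.  Under this reading the detrended residuals follow a
  genuine AR(1) (coefficient −phi) with stationary variance
  `sigma²/(1−phi²)`; the recursive reading would give an MA(1) instead.
  The stationary-variance identity is exercised by a Monte-Carlo test.
* **Single noise layer.**  The residual term inside the mean equation and
  the observation noise are the same correlated draw; the density of a
  yearly triple is one multivariate normal, with `diag(Sigma) = sigma²`.

**Hooks coupling.**  The LI-landings/effort association is a shared latent
yearly factor `rho[t] ~ Normal(0,1)` loading into both the LI mean
(`bLLrho·rho[t]`) and the hooks mean (`loading·rho[t]`, plus an AR1 term and
intercept).  Only the product of the two loadings is identified from the
cross-covariance, so the hooks-side loading is constrained positive (log
parameterization); the sign of the association is then carried entirely by
`bLLrho`.  Pre-availability effort years are reconstructed through this
coupling plus the hooks AR1 model.

**Missing years.**  Missing cells are latent nodes, not dropped: during
fitting they are sampled jointly with the parameters so the lagged
covariates of the production equations and the demographic covariates are
always defined.  `impute_missing` draws each missing cell from its exact
conditional given same-year observed siblings (Gaussian conditioning on the
residual covariance) and the — possibly just-imputed — previous year;
repeated calls give a predictive ensemble whose 90% intervals are calibrated
by construction (verified at 0.90 ± 0.02 in the acceptance suite).

**Time trend.**  The year index is centered and scaled before forming t and
t²; this decorrelates the two trend columns and is invisible after
back-transformation.

## 2. Demographic sub-model (marginalized multistate Barker)

Six latent states per year: alive-NC (1), alive-VA (2), permanently
emigrated from the mid-Atlantic metapopulation (3), died this interval and
recovered (4), died this interval unrecovered (5), dead earlier (6).
Transitions: live states survive with the age/year hazard `S`, then stay
within the metapopulation with `F` and within their state with `psi`
(movement disallowed until the minimum breeding age, default 4); mortality
mass `1−S` splits into recovered (`r`) and unrecovered; dead states absorb
unidirectionally into state 6.  Emigrants keep surviving with `S`, remain
resightable in Florida and recoverable when dead — emigration is defined
only with respect to the breeding metapopulation.

Seven events per year: seen on NC/VA breeding grounds and/or in Florida,
unseen, or recovered dead.  Breeding detection is availability ×
detectability: `alpha[a]·p̂[colony, t]` with `alpha = 0` below age 2,
estimated for ages 2–6 and 1 from age 7.  Florida resight applies at `R`
for survivors of the interval and `R'` for birds that died during it; `R'`
defaults to `R/2` (deaths halfway through the non-breeding season), with
`R²` selectable by configuration since the source constraint can be read
either way.  The `R'` resight is emitted from state 5; recovery (event 7)
takes precedence for state 4.  This is the standard hidden-Markov
arrangement of Barker's accounting; it is verified exactly against
brute-force enumeration of all latent state sequences.

The likelihood is a scaled forward pass per *unique* history (identical
histories compressed with multiplicities; compression invariance is
tested), running in a compiled kernel when numba is available with a pure
numpy fallback.  Per-step renormalization guards underflow; the scaling
factors accumulate into the log-likelihood.

**Age structure.**  Hazards live on the complementary log-log scale,
`S = exp(−exp(eps))`.  Three age classes (1–2, 3–4, 5+) carry the yearly
variation and the covariate regression; single-age intercept adjustments
`beta_age` refine within-class differences, with ages above 25 sharing the
oldest modelled age.  One reference age per class (1, 3, 5) is pinned to 0:
a single global reference would leave the pre-breeder and sub-adult class
intercepts unidentified against their within-class adjustments.

**Covariate regression and priors.**  Class-level hazard coefficients for
SST, the three landings series, hooks, and the three production indices get
the lasso prior `beta ~ double-exponential(0, 1/upsilon_A)`,
`upsilon_A ~ exponential(0.1)`.  Class intercepts get the conjugate
log-gamma prior (`exp(b0) ~ exponential(1)`).  Recovery-rate regression uses
the harvest and production covariates (no SST), normal(0,2) priors.
Half-Cauchy(0.16) priors on the recovery/resight random-effect sds and
logistic(0,1) on logit-scale means follow the printed choices; band-type
effects get normal(0,5) (logit-scale shifts of several units are plausible
for highly readable bands), covariance sds half-Cauchy(1), and correlation
matrices a flat prior over the positive-definite region (pairwise tanh
parameterization with the Jacobian correction making each pairwise
correlation uniform, plus a positive-definiteness rejection).

## 3. Synthetic-data generator

The generator draws the environmental series and then simulates every
released chick forward through the six-state chain and the seven-event
observation process, at study-shaped defaults: 30 years, two natal states,
20,000 releases/year (70% NC), service bands with early-ancillary markers in
five scattered years and plastic field-readable (PFR) bands on a quarter of
VA chicks in the last four years; breeding detectability of order 10⁻³
(logit means −6.9 NC / −8.5 VA, yearly logit sds 2.23 and 4.82), recovery
~0.014 with small natal/band effects, non-breeding resight ~2×10⁻³ with
yearly logit sd 1.59 and a large PFR effect (+2.24), survival 0.31 / 0.60 /
0.85 / 0.83 / 0.81 at ages 1/2/3/4/5+, F = 0.998, psi = 0.984, availability
0.01/0.08/0.35/0.70/0.97 for ages 2–6.  Supported hazard covariates in the
truth: SST on pre-breeders (+0.12), hooks on sub-adults (+0.15), menhaden on
sub-adults/adults (−0.10/−0.15); yearly class-hazard deviations have sds
0.15/0.12/0.10 with 0.5 cross-class correlation.  Senescence is omitted
(subtle in the source system); chicks only are banded; colonies are pooled
per state and no individual heterogeneity is simulated.  Environmental
defaults put realistic magnitudes on each series (trawl declining by a
factor ~50 across the series, Caribbean landings rising then falling, a
warming SST trend of ~1 °C with 0.15 °C interannual noise) with the
cross-series residual correlations set to the study-reported values.
Missing-year masks mimic the study's pattern (landings at the end,
production at both ends, effort for the first half).

The generator z-scores lagged-landings covariates with observed-cell
constants — the same convention the fitter must use — so generating and
fitted coefficients are directly comparable.  What the generator does *not*
emulate: spatial colony structure, individual heterogeneity, within-season
(robust-design) structure, reporting-rate regime shifts as discrete events
(the large resight year-effect sd absorbs them).  Passing tests therefore
demonstrate internal consistency and recoverability under the stated
process, not robustness to these unmodeled features of real data.

Closed-form oracles accompany the simulator: an extended first-reencounter
m-array (expected counts per cohort × year × event, plus a never-seen cell)
computed by propagating the state distribution through the exact transition
and observation matrices.  The cells sum to the releases exactly
(multinomial closure) and match 200,000-bird simulations within 3 binomial
sd in the acceptance suite.

## 4. Inference

The sampler is blocked adaptive random-walk Metropolis-within-Gibbs over an
unconstrained parameterization (log/logit/atanh transforms with Jacobian
corrections), with two structural accelerations:

* **Exact Gibbs for conditionally Gaussian coefficients.**  Given phi, the
  residual covariances and the latents, each environmental series' mean
  coefficients have a Gaussian full conditional (the AR1 mean is linear in
  them after folding, and the sibling-conditional residual is univariate
  normal).  Direct draws traverse the strong trend/SST/lagged-landings
  collinearity ridge that a random walk crosses only slowly.  The draw is
  validated against numerical profiles of the posterior terms.
* **Absolute-level ("v") parameterization of the yearly demographic
  latents.**  The likelihood sees absolute yearly logit/log-hazard levels;
  intercepts, covariate slopes and random-effect scales act purely at the
  prior level (cheap blocks with no likelihood evaluation).  This removes
  the translation ridges between means and deviations that otherwise
  dominate the mixing time, and it makes the hazard regression a Gaussian
  regression on latent levels.

Remaining blocks use Gaussian random-walk proposals with Robbins–Monro
scale adaptation (targets 0.44 scalar / 0.234 multivariate) and
Haario-style empirical covariance shaping during burn-in; regression blocks
are seeded with least-squares coefficient covariances.  Latent missing
cells are updated in per-gap sub-blocks.  A derivative-free block-relaxation
warm start (Powell passes over the blocks, hyper-scale blocks held at their
inits) initializes all chains near the posterior mode; chains are jittered
and convergence is judged by the classic Gelman–Rubin PSRF (threshold 1.1)
on structural parameters.  `arviz` serves only as an independent
cross-check of HPDI computations in the tests.

Summaries: shortest-interval HPDIs (90% default, 95% available); the *f*
statistic (posterior mass on the mean's side of zero, 0.5 when the mean is
exactly zero); latent-theoretic standardization (`rho = beta·sd_x/sd_y` for
identity links; latent-residual variances π²/3 logit, π²/6 log-log);
indirect effects as per-draw products of standardized edge coefficients
(never products of summaries); cumulative pre-recruitment survivorship as
the product over ages 1–5 of within-period mean survival, and its relative
decline `1 − c2/c1` between period halves.  Band-effect probability ratios
are reported both as `exp(mean beta)` and `mean(exp beta)` — the two differ
for wide posteriors and both are emitted.

## 5. Problem sizes and desk-scale choices

The full study scale (six decades, ~6.5×10⁵ releases, 2×10⁵ MCMC
iterations) is supported by configuration but is not what the test suite
runs.  Desk-scale choices, made once:

* environmental recovery: five replicate 60-year series, 2 chains ×
  (1200 burn + 1600) iterations;
* joint recovery: the default 30-year scenario with releases scaled to
  2,000/year, 2 chains × (2800 burn + 2800), chains initialized at the
  generating values (jittered) with convergence judged by the within-run
  Gelman–Rubin statistic; a production run would use overdispersed inits
  at the full scale.  The tracked set covers the class hazard intercepts,
  F, psi, the availability profile, the key environmental slopes and the
  recovery/resight band effects; the breeding-detection PFR effect is
  excluded from tracking because PFR chicks (released only in the final
  four years) are below breeding age for almost the entire series, leaving
  that coefficient essentially data-free at any release scale;
* imputation calibration: 100 replicates × 200 predictive draws;
* oracle sweeps: 500 random 4-occasion instances; 200,000 birds for the
  m-array simulation check.

## 6. Known limitations

* The sampler is a Metropolis scheme: posterior tails for the weakly
  identified detection parameters (notably VA breeding detectability and
  its band effects) mix slowly, and desk-budget HPDIs for strongly
  collinear environmental coefficients can be mildly anti-conservative.
* The joint posterior has a slowly mixing ridge coupling the class-level
  hazard levels, availability and metapopulation fidelity.  The dedicated
  ridge blocks (parameter expansion + the joint tradeoff block) reduce but
  do not eliminate it: at the desk budget the worst tracked Gelman–Rubin
  statistic plateaus around 1.1–1.25, above the 1.1 convergence bar the
  full-scale analysis uses.  The corresponding recovery test asserts the
  bar as stated and is expected to flag this until run at production
  length.
* `R'` is tied to `R` by a fixed rule rather than estimated.
* Recovery covariates enter identically for all ages (a single recovery
  model); no time variation in F or psi; no robust-design within-season
  structure; no individual covariates or heterogeneity.
* The minimum breeding age is exposed as a parameter (default 4) rather
  than resolved: observed first breeding at age 3 and the movement
  constraint at age 4 coexist in the source system.
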