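# Methods

This note documents the model, the numerical choices, what the synthetic
data emulate, and the design decisions taken where more than one
reasonable construction existed. Notation follows the field's standard
symbols: σ (half-normal kernel scale), ε₀ (centre-point encounter
probability), θ (interaction probability given encounter), g₀ = ε₀·θ.

## The joint detection model

Three observation processes share parameters and are fitted jointly.

**Telemetry.** Fixes of rat *i* are independent draws from a symmetric
bivariate normal about a home-range centre, with per-axis standard
deviation σᵢ. The centre is the centroid of all of that rat's fixes and is
treated as known — an adequate assumption at the 30+ fixes per animal the
generator defaults to, where the centroid's error is a small fraction of
σ. ln σᵢ is hierarchically normal, `ln σᵢ ~ N(β₀ + β₁·sexᵢ, V)`, with sex
coded male = 0, female = 1. Because σᵢ also scales the encounter kernel,
each σᵢ is informed by the telemetry *and* the encounter history.

**Encounters.** For each rat × available device × night, an encounter is
Bernoulli with the half-normal kernel probability
`P = (ε₀·exp(−d²/2σ²))^e`, where the exponent `e` is τ on nights the
animal has encountered any device within the previous 20 nights (E* = 1)
and 1 otherwise. Devices further than 3.72σᵢ from the centre contribute
probability exactly zero. `logit(ε₀)` is linear in ln σᵢ, device type
(bait station is the reference; chew card and WaxTag get offsets) and a
per-rat effect δᵢ. E* (and its interaction analogue I*) are deterministic
functions of the *observed* history — they are data, not latent states —
and both reset to naive after 20 consecutive event-free nights.

**Interactions.** Conditional on an encounter, interaction is Bernoulli
with `logit(θ) = λ₀ + λ₁·chewcard + λ₂·waxtag + λ₃·I* + ρᵢ`. τ < 1 and
λ₃ > 0 both mean "device-happy": a first contact makes later contact more
likely.

**Optional spatial term.** Same-night encounter probabilities for one rat
can be correlated across devices through a zero-mean multivariate-normal
perturbation of the logits with exponential covariance `Σ = ν²e^(−φr)`,
recomputed each night over the devices available that night. The term is
off by default: it multiplies the state space by one latent vector per
rat-night, and at the reference estimates (φ ≈ 28 m⁻¹) the correlation is
negligible beyond a metre, so the independent model is the practical one.
When it is on, the latent logit-γ vectors are given a fixed support — the
devices within 3.72·σ̂ᵢ of each centre, σ̂ᵢ being the telemetry RMS — so
that the latent dimension does not change as σᵢ is sampled.

### Priors

Regression coefficients (β, α, λ): Normal(0, variance 10). Per-rat effects
δ, ρ: Normal(0, 1). τ: Gamma(shape 0.933, rate 8.33). V:
InverseGamma(0.01, 0.01). ν²: logNormal(3, 1) and φ: logNormal(1, 1),
where logNormal(m, s) means ln X ~ Normal(m, s²). Two conventions here are
genuinely underdetermined and are package decisions: "Normal(0, 10)" is
read as a variance (sd ≈ 3.16), and the lognormal parameters are read on
the log scale. Neither choice is influential: the coefficient priors are
diffuse relative to the likelihood, and the spatial term defaults to off.

### Sampler

V is conjugate and is Gibbs-sampled from InverseGamma(a + n/2, b + SS/2).
Everything else uses Gaussian random-walk Metropolis in blocks: per-rat
ln σᵢ, per-rat δᵢ, per-rat ρᵢ (each proposed and accepted in parallel
across rats — valid because the likelihood factorises over rats when the
spatial term is off), then component-wise updates of α₀..α₃, τ (on the log
scale, with Jacobian), β₀, β₁ and λ₀..λ₃. Proposal scales adapt every 50
iterations during burn-in by `scale ← scale·exp(rate − 0.3)` and are
frozen afterwards; post-burn-in acceptance rates land in roughly 0.25–0.4
for all blocks on the default synthetic data. Initial values: ln σᵢ at the
telemetry RMS, coefficients at 0, τ at 1, V at 1, ν²/φ at their prior
medians, with a small N(0, 0.1) chain-specific jitter on the scalars so
chains do not start identically. Convergence is summarised by split-R̂ per
parameter (each chain halved; flag at R̂ ≥ 1.05).

### Numerics

Linear predictors are clipped to ±35 before the inverse logit; the base
encounter probability is floored at 1e-12 before exponentiation by τ
(p^τ is otherwise ill-conditioned near zero); Bernoulli terms use
log1p(−p) with p capped at 1−1e-12. The likelihood is evaluated over a
static candidate set of (rat, device) pairs within
`3.72·exp(ln σ̂ᵢ + 0.6)` of each centre (plus any pair with an observed
record). Telemetry at the default 40 fixes pins ln σᵢ to roughly ±0.1, so
sampled σᵢ stay far inside this envelope; pairs outside it would
contribute exactly zero probability at any plausible σᵢ. The naive-loop
oracle in the test suite evaluates the same posterior without any of these
shortcuts and agrees to 1e-10.

## Synthetic data

The generator reproduces the assumed data-generating process end to end
and is the package's substitute for the field study, which is not
distributable. Defaults mirror the study conditions: 30 rats, sex ratio
0.5, 43 fixes per rat, 20 monitored nights, one device of each of the
three types per rat at a uniform distance up to 50 m from the centre with
all per-rat devices more than 15 m apart (rejection-sampled), and home
range centres uniform over a square of ~4 ha per rat, which keeps density
in the observed range without forcing overlap. Every Bernoulli outcome's
generating probability and latent state is recorded in a TruthBundle so
recovery tests can compare against ground truth.

One reference value required a decision. The reported variance of ln σ
(V = 2.799) is inconsistent with the reported per-rat σ range of
8.75–52.75 m — it would spread σ over orders of magnitude. The generator
therefore defaults to V = 0.2, under which the 90% range of σ is about
12–53 m and the expected minimum of 30 draws is ≈ 9 m, matching the
reported spread; V remains user-settable.

What the generator does **not** emulate — and what passing recovery tests
therefore cannot certify about real data: irregular or elongated home
ranges (about half of real urban ranges hug buildings or roads),
home-range shifts over time, habitat-dependent device exposure, missed
encounters by the monitoring method, and telemetry location error. All of
these bias σ or ε₀ in real data in ways the model absorbs silently.

## The synthetic reference posterior

The simulators need a posterior; when none has been fitted, the package
provides a synthetic stand-in built from published summary estimates for
urban ship rats in Wellington (means, 90% intervals, and population
mean ± SD of ε₀, θ and σ). Drawing each coefficient independently from
its printed interval is *not* faithful: the printed marginals hide strong
posterior correlations (intercept vs slope, intercept vs random effects),
and independent draws inflate the spread — and, through the convexity of
1/g₀, the median — of every derived quantity. The published design
medians match plug-in evaluation at the posterior means to 1–2%, which
pins down the correlation structure's net effect. The surrogate therefore
draws, per device type, the population-level linear predictors of ε₀ (at
the mean ln σ) and θ directly — Normal around the point values with
delta-method standard errors from the reported population mean ± SD over
the 16 detection animals — and reconstructs the coefficients from them;
τ, λ₃ and α₁ keep their printed-interval sds, and per-draw individual
effects δᵢ, ρᵢ ~ N(0, 1) carry the between-animal heterogeneity. Per-rat
σ within a draw is lognormal about the reported mean σ (the study found
no sex difference) with V = 0.2 as above. The derived-quantity credible
intervals of this surrogate are narrower than the published ones; its
medians are the reproducible anchor.

## Eradication simulation

An individual-based, daily-time-step removal simulation over a study
polygon (an axis-aligned square stands in for the real eradication zone;
any single-ring GeoJSON polygon is accepted). Each replicate draws a fresh
lattice offset, fresh rat placements (uniform in the polygon at 0.26
rats/ha) and fresh parameters: each rat takes (σ, δ, ρ) and the
coefficient vector from one posterior row, yielding its own bait-station
ε₀, τ and θ. Per night, every live rat can encounter each baited station
within 3.72σ (half-normal kernel, E* dynamics shared across stations); an
encounter converts to a removal with probability θ, death is immediate,
and one of the station's 15 doses is consumed. Stations refill every 7 or
15 days; each station-night one dose is lost to by-catch with probability
1% (the finest unit consistent with a quoted interval-level rate).

Population growth is an openly declared surrogate for the original
removal simulator's unpublished internals: births occur only during the
September–April breeding season, at a daily rate
`(r_max^(1/242) − 1)·N·(1 − N/K·A)` with r_max = 3.57 and K = 3 rats/ha,
Poisson-distributed, with each newborn placed within 2σ of a random
living parent and given freshly drawn detection parameters. Simulations
start at the beginning of the breeding season. The population is closed —
no immigration — matching the simulated management question, though real
urban eradications face dispersal pressure.

Two behaviours of this simulator are worth stating plainly. First,
persistence is threshold-driven: an individual whose 3.72σ radius
contains no station is undetectable, so the 100 m grid never eradicates
(small-σ animals are common at that spacing) while the 25 m grid almost
always does. Second, with σ heterogeneity calibrated to the observed
range, such refuges are rare at 50 m spacing, so this simulator
eradicates in roughly half of long 50 m replicates where the original
tool reported a persistent remnant population; reproducing that plateau
would require either σ mass far below the observed minimum or removal
dynamics that the original tool does not document. The 50 m and 100 m
scenarios should therefore be read qualitatively.

Default problem sizes (30 replicates, 500–1000 days, 23.6k stations on
the 1475 ha square) were chosen so a full scenario runs in seconds on one
CPU; replicate counts are the dominant cost and scale linearly.

## Surveillance design

Surveillance-system sensitivity uses the spatially integrated hazard of
the half-normal kernel: a network of density D devices/m² deployed for
`n` nights misses a survivor with probability `exp(−n·D·g₀·2πσ²)`, i.e.
`SSe = 1 − exp(−n·D·g₀·2πσ²)`. This closed (cloglog) form — rather than
an explicit product over station positions — is the design choice that
makes required density exactly inversely proportional to deployment
nights, the pattern the published design tables show; an explicit-grid
evaluation is provided as a cross-check and agrees to ~2% at realistic
densities. The probability of absence after null surveillance is the
Bayesian update `PoA = prior / (prior + (1−prior)(1−SSe))`, and the
minimum density for a target PoA inverts the two formulas in closed form.
Per posterior draw, the population-level individual (δ = ρ = 0, naive
state) defines the device-specific g₀, and σ is the draw's population
geometric mean; medians and 5th–95th percentiles are reported over draws,
with device counts as ⌈density × area⌉. The round trip
`PoA(SSe(required_density))` returns the target exactly (tested at
1e-10), and halving between 14 and 28 nights is exact draw-wise.

## Known limitations

* Home-range centres are treated as exact; telemetry error and centroid
  uncertainty are not propagated.
* The kernel is isotropic half-normal; no uniform-core, anisotropic or
  kernel-density alternatives, and no habitat covariates on ε₀ or θ.
* The spatial-term sampler is a straightforward per-rat-night Metropolis
  update; it is adequate for the small instances it is tested on, not
  tuned for large spatial fits.
* The eradication growth model is a surrogate (see above); absolute
  remnant-population sizes at wide spacings are not comparable to the
  original tool's.
* Surveillance assumes a homogeneous network and a single survivor; no
  spatial stratification and no accumulation across repeated surveys.
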