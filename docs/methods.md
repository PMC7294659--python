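# Methods

`gullmig` re-implements a complete track-to-inference workflow for
satellite-tracked gull migration: synthetic data generation with ground
truth, Argos/GPS preprocessing, Bayesian regularization of irregular
fixes to daily positions under a two-state switching movement model,
rule-based travel/stopover segmentation, ten per-track migration
characteristics, and mixed-model comparison of breeding populations.
This note records the models, the numerical choices, and what the
synthetic validation does and does not establish.

## Movement model

Daily movement is a first-difference correlated random walk (DCRW)
switching between two behavioural states, travelling (0) and foraging
(1).  With x_t the position (km on a local tangent plane) at 00:00 UTC
of day t and d_t = x_t − x_{t−1}:

    d_t = γ_{b_t} R(θ_{b_t}) d_{t−1} + η_t,   η_t ~ N(0, Σ),

where γ_s ∈ [0, 1] is move persistence, R(θ_s) rotates by the
state-specific mean turning angle, Σ is a 2×2 process covariance shared
across states, and the state sequence b_t is a first-order Markov chain
with transition matrix P.  States are identified by ordering:
γ_travel ≥ γ_forage (draws are relabelled accordingly), which matches
the biology — travel days are long, directionally persistent
displacements; foraging days are short and tortuous.

The observation model ties each irregular fix at time τ ∈ (t−1, t] to
the time-weighted interpolation w·x_t + (1−w)·x_{t−1} (w the fractional
day offset), plus independent Student-t error per planar coordinate
with a location-class-specific scale: configurable defaults of
0.5 / 1 / 2.5 / 10 km (ν = 4) for Argos classes 3/2/1/0, round-number
stand-ins for published empirical Argos error distributions, and an
effective 0 m (numerically 1 m) for GPS-quality class F.

Positions, process and priors all live on a local
azimuthal-equirectangular tangent plane; geographic coordinates are
obtained by inverse projection.  The plane is the *definition* of the
process model, not an approximation of a spherical one.  For migration
simulation the plane is anchored at the midpoint of colony and
wintering target so the metric distortion stays balanced along the
route; model fitting anchors at the colony of the fitted population.

## Posterior computation

The model is fitted by a blocked Gibbs sampler in which every update is
an exact conditional draw:

1. **Daily positions** per individual: Kalman forward filter /
   backward sampler on the state vector z_t = (x_t, x_{t−1}), which
   makes the DCRW transition linear.  Student-t errors are expanded as
   a scale mixture of normals with one latent Gamma precision per fix
   per coordinate, so the filter sees Gaussian noise.  Fixes enter as
   scalar sequential updates (no matrix inversion); the backward pass
   samples only the two new coordinates per step, since x_t is already
   determined by the draw at t+1.
2. **States** per individual: discrete forward-backward on the
   displacement sequence.
3. **Per-fix precisions**: conjugate Gamma.
4. **Transition matrix rows**: conjugate Dirichlet(1, 1) posterior on
   pooled transition counts.
5. **Persistence/turning**: parametrized as (a, b) = γ(cos θ, sin θ),
   in which the DCRW mean is linear, giving a conjugate bivariate
   normal; the flat prior is truncated to the unit disk (γ ≤ 1) by
   rejection.  This induces a prior density ∝ γ on γ — a deliberate
   choice traded for exact conjugacy; with hundreds of transitions per
   state the likelihood dominates it.
6. **Process covariance**: conjugate inverse-Wishart
   (ν₀ = 4, S₀ = diag(100, 100) km² — weakly informative, prior mean
   10 km daily noise SD).

Movement parameters are shared across all individuals of one breeding
population (one hierarchical fit per population); latent paths, states
and fix precisions are per individual.  The hot loops (both
forward-backward passes) are numba-compiled with 4×4 linear algebra
written out explicitly.

Run lengths: the desk-scale default is 2 chains × 4,000 samples with
1,000 burn-in and thinning by 5 (600 retained per chain), which the
parameter-recovery tests show is enough for calibrated γ intervals on
tracks of 100–200 days.  Production-scale runs (2 × 400,000 samples,
50,000 burn-in, thin 50 → 7,000 retained per chain) use the same
configuration object; `retained_per_chain` is the exact floor formula.

**Diagnostics.**  Gelman–Rubin PSRF in the classic two-chain form;
Geweke z comparing the first 10% against the last 50% of each chain
with autocovariance-corrected (initial-positive-sequence) standard
errors; lag-k autocorrelations.  `converged` means all PSRF < 1.1 and
all |z| < 2.  With a single chain the PSRF is reported as unavailable,
never fabricated.  Exactly copied chains give PSRF = √((n−1)/n) ≈ 1,
so "PSRF = 1 within tolerance" is the degenerate-case check.

**Gap pruning.**  Daily estimates with no observed fix within ±1 day
are withheld (the smoother's interpolation through long holes is not
biologically meaningful); observation gaps > 7 days are logged.
Whether "observed" means pre- or post-speed-filter fixes is an open
choice; this package uses post-filter fixes, since removed outliers
should not rescue the days around them.

## Preprocessing

Duplicates are identical (individual, timestamp) pairs; the first
occurrence wins, including when coordinates differ.  The speed filter
removes fixes implying > 200 km/h great-circle speed from the last
*retained* fix in a single forward pass (McConnell-style re-linking);
this is one concrete choice among several published variants — the
threshold alone does not determine an algorithm — and it is idempotent
and produces a subsequence of its input.  Filtering uses the spherical
haversine; reported distances use Vincenty's inverse on the WGS-84
ellipsoid (implemented in `gullmig.geo`, verified against R
`geosphere`); the two differ by < 0.6%, far below the 200 km/h margin.
Near-antipodal pairs, where Vincenty's iteration need not converge,
fall back to the haversine.

## Segmentation

A day is a **travel day** if (1) within any 3-transition sliding
window containing it, the day-to-day latitude change exceeds 0.3° in a
consistent direction on ≥ 2 of the 3 transitions *and the day's own
change is one of those*, or (2) its single-day displacement exceeds
75 km; otherwise it is a **stopover day**.  A "2 of 3 days" rule
leaves the window anchoring ambiguous; this package evaluates
every window containing the day and requires sign consistency, which
reproduces the intended reading (a +0.1° day between two −0.4° days
stays a stopover).  The thresholds default to the fixed values above;
percentile mode instead derives both as the 90th percentile of the
pooled day-to-day |Δlatitude| and displacement (linear-interpolation
quantile), reproducing how such thresholds are chosen from data.
Gap-flagged days carry no label, break runs and windows, and are
excluded from threshold derivation; bridging single flagged days is
config-switchable and off by default.

**Migration window.**  Start: first day of the travel run that
achieves the *final* exit from the 200 km colony radius (a run that
exits, returns, and is followed by a later re-departure is logged as a
candidate but superseded — departure excludes pre-migratory excursions).
End: last day of the latest travel run after which the latitude stays
within ±1° of the run's final latitude for every remaining tracked day,
with at least 21 such days ("remained during the winter" needs an
operational rule; half-width and dwell are exposed in the config and
flagged as a stand-in).  If no run ever exits the radius the result is
"no migration detected", not an exception; if no run is followed by
confirmed residency the last travel run is used and the window flagged
unconfirmed.

**Stopover sites** are maximal runs of consecutive stopover days inside
the window — temporal runs, not spatial clusters; two runs split by one
travel day at the same place stay distinct.  Centroid = mean daily
position, length = run length.

## Migration characteristics

Ten per-track quantities: migration distance (sum of day-over-day
Vincenty steps whose destination day is a travel day in the window —
including the departure step into the first window day), duration
(end − start + 1 days; the "+1" resolves the ambiguity of "days
between" globally, so population contrasts are unaffected), start and
end day of year, directness (distance over the geodesic from the
departure origin — the day before the first travel day, whose step is
counted — to the window end; a straight transit scores exactly 1, and
the reciprocal is also emitted because both orientations appear in the
literature), migration speed (distance/duration), travel speed
(distance/travel days), total stopover days, travel:stopover ratio
(distance per stopover day; undefined and reported as NaN when there
are no stopover days), and the per-site stopover lengths.

Invariants maintained and tested: directness ≥ 1 − ε (ε covers metric
mismatch), travel speed ≥ migration speed, Σ site lengths = total
stopover days, stopover + travel days = duration (on gap-free windows),
and speed × duration reconstructs the distance.

## Population comparison

Each characteristic is a GLMM response with breeding population fixed
(long-distance population as reference level, so coefficients are
contrasts) and individual as a random intercept (several individuals
contribute 2+ annual tracks).  Families: Gaussian identity link for
distance, start/end date, directness, both speeds and the
travel:stopover ratio; Poisson log link for duration, total stopover
days and stopover length (one row per stopover site).  Estimation is
ML, not REML, so fixed-effect likelihood-ratio tests are valid:

* Gaussian: closed-form marginal likelihood of the random-intercept
  model, fixed effects profiled by GLS, 2-D quasi-Newton optimization
  of the variance components.
* Poisson: the random intercept integrated by 30-node Gauss–Hermite
  quadrature; fixed-effect covariance from the observed information by
  central differences.

Both fitters reproduce lme4 (`lmer`/`glmer`, ML) to 4 significant
figures on the frozen test fixture, and the Gaussian path is
cross-checked against statsmodels `MixedLM` at test time.

A random-intercept variance below 10⁻⁶ × the residual variance
(Gaussian) or below 10⁻⁶ (Poisson, log scale) is a singular fit: the
model is refit without the random effect, flagged, and the null model
for the LRT keeps the matching structure.  The LRT statistic is the
raw 2Δℓ with df = number of population contrasts (3 for four
populations); the p-value scales the statistic by (n − p_full)/n
before the χ² reference — a Bartlett-style small-sample correction
chosen at design time because the uncorrected χ² reference is
anticonservative at n ≈ 48 tracks; the simulation study in the
acceptance suite verifies the resulting type-I error sits inside the
binomial 95% band around 0.05 for both families.  Wald 95% intervals
are reported on the link scale.

Marginal/conditional R² follow the fixed-vs-total variance
decomposition: marginal = var(Xβ)/total, conditional adds the
random-intercept variance; Poisson models use the lognormal
approximation ln(1 + 1/λ̄) with λ̄ = exp(mean linear predictor + τ²/2)
as the distribution-specific residual variance.  Singular fits report
conditional = marginal.  Residual diagnostics are randomized quantile
residuals with a KS uniformity test, advisory only.

## Synthetic data

Two generators:

* `simulate_dcrw` is the *pure* process model above — the right tool
  for parameter recovery, since fit and truth share one likelihood.
* `simulate_migration` is schedule-driven: pre-migratory residency at
  the colony (small anchored wander, no fueling excursions — residency
  behaviour is a free choice the data do not constrain), travel bouts
  steered along geographic via-points toward a wintering target with
  per-individual step length and route jitter, interleaved multi-day
  stopovers, then winter residency.  Coastal via-points are what make
  routes realistically indirect; each individual's via-points are
  jittered and their lateral deviation from the straight colony-target
  line is stretched by a per-individual factor (SD 0.25 by default),
  which is the main source of between-individual variation in distance
  and directness.  Intermediate via-points hand over at 0.7× the
  individual's step length so the route follows the configured arc
  rather than cutting corners.  The departure day's step is floored
  at 250 km so the scheduled departure and the radius-based detection
  rule agree by construction; the final approach lands exactly on the
  target with a step bounded below 0.5× the individual's step length,
  so arrival days remain travel days.

Observation thins the linearly interpolated true path through a duty
cycle (fix count Poisson at the configured mean rate, times uniform
over the on-intervals), assigns location classes by configured
frequencies, and adds the class-specific t errors.  Seeding is
hierarchical and documented: `default_rng([config seed, individual,
repeat, purpose])`, so every track is independently reproducible.

The four-population study configuration mirrors the tracked
deployments: colony coordinates of the real breeding sites, 8/12/17/11
tracks per population with several individuals tracked in more than
one year, device mixes (Argos-only, GPS-only, hybrid) and duty cycles
of the deployed hardware, and schedule parameters set so the
long-distance population travels roughly four times farther than the
Atlantic populations while overall migration pace stays comparable —
the contrast structure the population models are meant to detect.

**What the synthetic validation shows — and does not.**  Simulated
travel steps (≳ 100 km) and stopover wander (~2 km/day) are cleanly
separated relative to the 75 km / 0.3° thresholds, so day labels and
windows recovered from noiseless daily positions match the stored
truth exactly; that validates the bookkeeping, not the thresholds'
discriminative power on ambiguous real behaviour.  Parameter-recovery
tests draw data from the fitted model itself, so they validate sampler
correctness and interval calibration, not robustness to model
misspecification (smooth-path interpolation, shared Σ, first-order
switching are all idealizations real Argos tracks violate to some
degree).  The Argos error scales are stand-ins, not the published
empirical distributions.

## Problem sizes and determinism

Default problem sizes are chosen as the package's routine working
scale: recovery studies use 2–5 tracks of 100–200 days with the
desk-scale MCMC; the calibration study uses 500 null and 200 power
replicates; the study pipeline runs 48 tracks of 90–130 days.  All
randomness flows from explicit seeds (numpy `Generator`; one seed per
entry point), and repeated runs are byte-identical.

## Known limitations

* No continuous-time formulation; fixes are tied to bracketing daily
  positions by linear interpolation, which understates within-day
  path curvature.
* Σ is shared across states and individuals; per-state or
  per-individual covariances are not implemented.
* θ for the low-persistence state is weakly identified (γ ≈ 0 makes
  rotation nearly meaningless); its posterior mixes slowly and is
  reported but rarely informative.
* Spring migration, multi-trip annual segmentation, wind/landscape
  covariates, and sex/carry-over effects are out of scope.
* The wintering-residency rule (±1°, 21 days) is an operational
  stand-in; windows that depend on it are flagged in the outputs.
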