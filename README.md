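# gullmig

Migration-strategy analysis for satellite-tracked gulls: from raw
Argos/GPS fixes to population-level comparisons of how far, how fast,
and how interruptedly birds migrate.

Herring gulls breeding in eastern North America range from short-distance
migrants (Atlantic Canada to the Gulf of Maine) to long-distance migrants
(eastern Arctic to the Gulf of Mexico).  Telemetry from such populations
is irregular in time and heterogeneous in error — Doppler-derived Argos
fixes carry class-structured, heavy-tailed positional error, while GPS
fixes are essentially exact — so raw fixes cannot be compared across
populations directly.  This package implements the standard inference
chain for that problem:

1. **Preprocessing** (`gullmig.trackio`) — Movebank-dialect CSV input,
   duplicate removal, iterative 200 km/h speed filter.
2. **Regularization** (`gullmig.ssm`) — a Bayesian hierarchical
   switching state-space model estimates positions at 24 h intervals.
   The process model is a two-state first-difference correlated random
   walk: d_t = γ_b R(θ_b) d_{t−1} + N(0, Σ), with behavioural states
   (travel/forage) following a Markov chain; the observation model
   links each fix to interpolated daily positions with Student-t
   location-class errors.  Fitted by a blocked Gibbs sampler
   (Kalman + discrete forward-filter/backward-samplers, conjugate
   parameter updates), with Gelman–Rubin and Geweke diagnostics and
   pruning of estimates more than a day from any observed fix.
3. **Segmentation** (`gullmig.segment`) — each day is a travel day if
   latitude changes > 0.3° in a consistent direction on 2 of 3
   sliding-window transitions or the day's displacement exceeds 75 km;
   otherwise a stopover day.  The autumn migration window runs from the
   travel period that finally leaves a 200 km colony radius to the
   travel period followed by winter residency.
4. **Characteristics** (`gullmig.migmetrics`) — ten per-track metrics
   (distance, duration, start/end date, directness, migration and
   travel speed, stopover usage), with distances on the WGS-84
   ellipsoid (Vincenty).
5. **Population comparison** (`gullmig.popstats`) — GLMMs per
   characteristic (population fixed effect, individual random
   intercept; Gaussian or Poisson family by response), likelihood-ratio
   tests, Nakagawa marginal/conditional R², randomized-quantile
   residual checks.

A first-class synthetic-data module (`gullmig.syntrack`) simulates
duty-cycled, class-structured observations of schedule-driven
migrations with complete ground truth (daily positions, behavioural
states, migration windows, all ten characteristics), which is how the
pipeline's correctness is established: parameter recovery for the
state-space model, exact rule-oracle equivalence for the classifier,
and truth recovery for the metrics.

## Worked example

The `analysis/` scripts run a four-population study patterned on real
deployments (one Arctic long-distance population and three Atlantic
short-distance populations; 48 tracks from 33 individuals; mixed
Argos/GPS devices and duty cycles):

```
python analysis/01_simulate_tracks.py --seed 1
python analysis/02_preprocess.py
python analysis/03_fit_ssm.py
python analysis/04_segment.py
python analysis/05_metrics.py
python analysis/06_population_models.py
python analysis/07_calibration.py
```

Selected output (seed 1):

```
== 01_simulate_tracks
simulated 48 tracks, 31915 fixes across 33 individuals in 4 populations
== 02_preprocess
31915 raw fixes -> 31912 after deduplication -> 31361 after the
200 km/h speed filter (554 removed)
== 03_fit_ssm
bay_of_fundy: 11 tracks fitted in 29 s; gamma_travel 0.94,
  gamma_forage 0.26, max PSRF 1.009, 0 gap-flagged days
eastern_arctic: 8 tracks fitted in 26 s; gamma_travel 0.98, ...
== 05_metrics   (mean / sd per population)
                migration_distance_km   duration_days  directness  travel_speed
bay_of_fundy           958.4   33.1        6.6   2.3    1.1  0.0    206.1  27.9
eastern_arctic        7731.5  551.7       57.9   9.7    1.9  0.1    358.3  34.1
newfoundland          2469.1  189.7       28.8   8.9    1.3  0.1    246.5  32.1
sable_island          1609.5  106.3       11.9   5.8    1.2  0.1    242.6  48.7
== 06_population_models
migration_distance_km   gaussian chi2_3= 149.54 p=0.000  R2m=0.99 R2c=1.00
migration_speed_km_day  gaussian chi2_3=   9.27 p=0.037  R2m=0.21 R2c=0.40
travel_speed_km_day     gaussian chi2_3=  41.01 p=0.000  R2m=0.65 R2c=0.96
stopover_length         poisson  chi2_3=  70.21 p=0.000  R2m=0.49 R2c=0.49
                        (singular random effect: dropped)
== 07_calibration
type-I error: gaussian 0.060, poisson 0.052 (nominal 0.05 +/- 0.019)
power for a 4x distance contrast at n=8/12/17/11: 1.000
```

Reading this: the long-distance population migrates roughly four times
farther than the Atlantic populations and its routes are the least
direct; the distance contrast is overwhelming (χ²₃ ≈ 150), travel
speed differs clearly, while overall migration speed — distance over
the whole window including stopovers — barely does.  High conditional
R² with modest marginal R² means individual identity explains much of
the remaining variation: individuals are consistent between years.
The calibration study confirms the likelihood-ratio test holds its
nominal 5% size and has essentially full power for a four-fold
distance contrast at these group sizes.

Each script is a thin driver over the library; the same computations
are importable (`gullmig.pipeline.run_pipeline` runs the whole chain on
a list of tracks).  A `gullmig` console script exposes the same steps
as subcommands (`simulate`, `preprocess`, `fit-ssm`, `classify`,
`metrics`, `compare`).

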