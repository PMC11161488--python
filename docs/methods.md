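# Methods

## Scope and data model

The package reconstructs daily positions of demersal fish from archival
depth/temperature series matched against gridded ocean reference fields,
optionally fused with acoustic detections, and summarises the resulting
tracks with the standard telemetry metrics. All coordinates are WGS84
decimal degrees; distances are great-circle with Earth radius 6371 km; a
"day" is 00:00–24:00 UTC; depth is positive down, with sensor readings
down to −1 m tolerated and clamped to 0 in summaries. Seasons follow the
meteorological grouping December–February, March–May, June–August,
September–November, with December assigned to the following winter.

## Preprocessing

* **Depth-sensor drift** is removed by subtracting a centred running
  minimum over 7 days (window clipped at the record edges) and clamping
  at 0. The correction assumes the fish surfaces at least once per
  window; where it does not, genuine distance-to-surface is absorbed
  too, which is the standard trade-off of the running-minimum method.
  The step is idempotent once the corrected series touches 0 in every
  window.
* **Daily summaries** per calendar day: max/min/median depth, mean
  temperature, temperature range, and a vertical activity index
  Σ|Δdepth| within the day. Days with fewer than two samples carry an
  undefined activity index and are flagged.
* **Mortality**: a terminal run of ≥ 7 days with activity < 1 m and
  depth range < 0.5 m marks the fish dead from the run's first day.
  This rule runs on the *uncorrected* series: the centred running
  minimum smears a death discontinuity across half its window, while
  drift does not affect within-day variability. Thresholds are exposed
  because aliveness judgements on real tags are ultimately expert
  decisions.
* **Cooling-water plumes**: a day whose mean temperature exceeds the
  domain-wide surface maximum for that date by > 2 °C while the fish
  stayed shallower than 15 m cannot be explained by the reference field
  and is flagged; flagged days drop the temperature likelihood term
  (not the whole day).
* **Inshore variability**: ≥ 7 consecutive days with daily temperature
  range > 5 °C at depths < 5 m indicate shallow inshore water the
  reference field cannot represent; the series is truncated at the
  episode's first day.
* **Detection QC** removes (first) detections that are the sole
  detection of a tag on an entire receiver array, then isolated
  detections implying a > 100 km out-and-back movement within one day
  relative to both flanking detections. Singletons are removed first so
  they cannot anchor the implausibility test.

## Geolocation

The latent state is the occupied water cell. The diffusion kernel is
Gaussian in great-circle distance with per-axis variance 2DΔt, hard
truncated at 4·√(2DΔt) for sparsity and row-normalised; when the support
falls below one cell the operator degrades to the identity (so D below
roughly `diag²/128` is indistinguishable on a given grid — a resolution
floor, not a bug). Day-1 mass sits at the water cell nearest the release
position; an optional terminal anchor (recovered-tag position) is off by
default because recovery positions of drifting floatable tags need not
be fish positions.

Per-day likelihoods are combined multiplicatively and normalised to sum
to one, which makes the model log-likelihood invariant to uniform
rescaling of any day's likelihood. Days whose combined or predicted mass
vanishes are relaxed to uniform and recorded as warnings rather than
aborting long series. Smoothing uses scaled forward–backward recursions;
the most probable sequence comes from log-domain Viterbi with ties
broken toward the lower cell index. Exhaustive path enumeration on small
instances is the correctness oracle for both.

σ_z defaults to 4 m (bathymetric tolerance), σ_T to 0.5 °C, σ_d to
566 m (the 50% daily detection range). The recovery experiments fit with
σ_T = 0.2 °C: the temperature entering the likelihood is a daily mean of
~144 samples, so its error budget is set by the median-depth-fraction
interpolation approximation (~0.2 °C for a two-layer column), not by
single-reading sensor noise. σ_T and σ_z are fixed, not estimated; the
search estimates only D (golden-section on log D in [1, 100] km²/day,
5% relative tolerance). With behavioural switching, a two-state Gaussian
HMM on log(1 + activity) (EM, ≤ 500 iterations, tol 1e-6) decodes daily
low/high states; the fit counts as converged only when EM converged and
the state means are ≥ 1 pooled SD apart — an automated stand-in for
visual screening. Switching then indexes the daily kernel by the origin
day's state and refines (D_low, D_high) by Nelder–Mead under
D_high ≥ D_low, initialised from the single-D fit. Decoding states first
and conditioning the movement model on them (rather than a joint
cell×state HMM) matches how the two-stage analysis is done in practice
and keeps the state space small.

Track reliability uses the per-day maximum of the Viterbi-vs-mean and
Viterbi-vs-mode distances: reliable below 50 km median and 120 km max;
temporal-only up to a 240 km max; unreliable beyond. Only reliable
tracks are mapped; temporal-only tracks still contribute to area
timelines; unreliable tracks are excluded from area assignment.

## Area assignment and strategies

A day's area is the Viterbi position's polygon, demoted to "unknown"
whenever the posterior-mean or posterior-mode position falls in a
different polygon, and overridden to "cooling waters" on plume-flagged
days. The migration strategy of a > 90-day series is the most distal
area class occupied for ≥ 5 known-label days, ordered North Sea <
Channel E < Channel W < Celtic Sea–Bay of Biscay. The 5-day persistence
threshold and the 1° W-style east/west Channel split are package
choices (the underlying study discerned strategies by inspection); both
are arguments. When battery life is unknown, the last observation date
stands in for battery end in the residency denominator.

## The synthetic study system

`basstrack.synthetic` generates the full joint dataset from one seeded
config; identical configs give byte-identical outputs.

* **Bathymetry**: a land strip along the eastern edge with depth ramping
  west from the coast to 120 m plus smooth bumps — a caricature of a
  shelf sea with a single coastline.
* **Temperature**: latitudinal gradient (−0.8 °C/°lat), seasonal
  sinusoid (±4.5 °C, peaking mid-August), a bathymetry-linked
  thermal-inertia term (shallow water tracks the season more strongly,
  up to 1.5 °C), summer bottom-layer stratification, and a smooth
  spatial anomaly field evolving as AR(1) in time (SD 0.6 °C,
  decorrelation ~10 days) like mesoscale SST anomalies. The anomaly
  field's time evolution matters: a static texture creates permanent
  temperature aliases between distant cells that no geolocation method
  could disambiguate.
* **Trajectories**: daily Gaussian steps with per-axis variance
  2D(state)Δt, the state following a two-state Markov chain
  (defaults D_low = 5, D_high = 30 km²/day — bracketing the resident and
  migrant estimates for seabass). Steps proposing land or
  leaving the domain are redrawn (≤ 100 times, then the fish holds
  position); this preserves the no-land invariant and the diffusion law
  in open water, at the cost of slightly suppressed mobility along
  coasts. An optional death day freezes the position; a dead fish reads
  a constant seabed pressure (excursion noise below sensor resolution).
* **Sensor series**: 10-minute sampling; high-activity days draw depths
  uniformly over the water column, low-activity days make small
  excursions (5% of bathymetry) around a daily base depth, so the
  activity HMM is learnable; temperature is the two-layer interpolation
  at the sampled depth fraction plus N(0, 0.5 °C) noise; optional linear
  depth drift; cooling-water plume sources add their ΔT to a contiguous
  within-day stretch of samples (the fish moves in and out), raising
  both the daily mean and the daily range as real plume signatures do.
* **Acoustics**: daily per-station detection probability
  exp(−ln2·(d/r50)²) with r50 = 566 m, hard-truncated beyond 5·r50
  (p < 3e-8); detected days log 1–20 time-stamped detections. Fish are
  released at shallow-water sites each guarded by a receiver pair, with
  a background network of ~40 coastal stations, mirroring real tagging
  designs.
* **Recaptures**: geometric recapture day (default p = 0.0035/day, i.e.
  a ~285-day mean time at large) with ~1 km position jitter.

What the generator does *not* emulate: tides, advection, habitat
attraction (fish are pure diffusers, so inter-array acoustic transitions
are rarer than for real structure-associated seabass), 3-D temperature
profiles beyond two layers, tag clock drift, and biofouling. Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not performance on real
tags.

## Validation experiments and problem sizes

The suite and `scripts/acceptance.py` run, on one CPU in a few minutes:
1,000 random small HMM instances (≤ 10 cells × ≤ 5 days) against
exhaustive enumeration; a 20-tag recovery cohort (true D = 30 km²/day,
120 days, 40×40-cell grid at 0.15°, ~1,480 water cells) checking the
fitted D within a factor of two and the pooled median Viterbi error
under three cell diagonals (~59 km); drift-correction residuals under an
injected 0.1 m/day drift; 100 mortality replicates (death at day 40 of
80); and 5,000 simulated station-days at exactly r50. Published cohort
percentages are recomputed from their printed counts with the same
formatter used for cohort tables (ratio × 100, half-up to one decimal).

## Known limitations

* The bathymetry likelihood is one-sided (deep cells are never
  penalised); longitudinal information therefore rests on the
  temperature field's cross-shore structure.
* D below the grid's resolution floor collapses to the identity kernel.
* Strategy classification and the mortality/plume/inshore heuristics
  automate judgements made by eye in real studies; their thresholds are
  exposed and should be reviewed per tag on real data.
* The mean posterior track may cross land (it is a posterior average);
  only Viterbi and modal tracks are guaranteed to sit on water cells.
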