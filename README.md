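# basstrack

Movement analysis for European seabass (*Dicentrarchus labrax*) tagged in
the southern North Sea, built around grid-based hidden-Markov geolocation
of archival (data-storage) tags and the standard telemetry /
mark-recapture summaries used in shelf-sea movement ecology: residency
indices, area fidelity, migration-strategy classification and seasonal
movement networks. Because real tag data and ocean reference products are
not redistributable, the package ships a seeded synthetic-data module
that emulates the whole study system — shelf bathymetry, daily two-layer
temperature fields, two-state diffusive fish trajectories, 10-minute
depth/temperature sensor records, acoustic detections and recaptures —
so every stage is testable end to end against known truth.

Audience: movement ecologists and fisheries scientists working with
data-storage tags, acoustic telemetry or mark-recapture data, and anyone
who wants a transparent, fully tested reference implementation of
HMM geolocation.

## The model

The fish's daily position is a latent cell `x_t` on a regular lat/lon
grid restricted to water. Movement between days is isotropic diffusion:
the transition weight from cell `i` to cell `j` is

```
K_D(i, j) ∝ exp( − d(i,j)² / (4 D Δt) ),   Δt = 1 day,
```

with `d` the great-circle distance and `D` (km²/day) the diffusion
coefficient, truncated beyond `4·√(2DΔt)` and row-normalised. Each day's
observation likelihood over cells is the product of independent terms:

* **bathymetry**: cells shallower than the day's maximum depth decay as
  `exp(−(z_max − bathy)²/(2σ_z²))` (default σ_z = 4 m); deeper cells are
  unconstrained;
* **temperature**: `exp(−(T̄ − T_ref)²/(2σ_T²))` where `T_ref`
  interpolates the surface and bottom reference layers at the fish's
  median daily depth fraction; days flagged as cooling-water are
  uninformative;
* **acoustic detections** (ADST tags): `exp(−ln2 · (d/σ_d)²)` around the
  detecting stations, calibrated so the weight is 0.5 at the 50% daily
  detection range σ_d = 566 m; days without detections are uniform.

Scaled forward–backward recursions give the daily smoothed posteriors
and the likelihood used to estimate `D` (golden-section search; with
behavioural switching, a two-state activity HMM decoded from the depth
series selects between `D_low` and `D_high` kernels and the pair is
refined by Nelder–Mead under `D_high ≥ D_low`). The reported track is the
Viterbi (jointly most probable) sequence; its per-day distance to the
posterior-mean and posterior-mode tracks grades each track as
`reliable` (median < 50 km and max < 120 km), `temporal_only`
(max ≤ 240 km) or `unreliable`.

Downstream metrics follow the field's definitions: a detection-positive
day (DPD) is a calendar day with ≥ 1 detection; the residency index is
RI = DPD / days at large; fidelity to an area means an observation there
≥ 180 days after tagging; migration strategies order the most distal
area reached (North Sea < eastern Channel < western Channel <
Celtic Sea–Biscay) with a 5-day persistence requirement.

## Worked example

The numbered scripts under `analysis/` run a three-tag demo cohort
(40×40-cell shelf domain, 120 days) plus an eight-tag coastal acoustic
cohort, writing tables under `results/demo*/`:

```
$ python analysis/01_simulate.py
grid: 40x40 cells, 1480 water
tag000: 120 days, 62 high-activity days
...
detections: 40, recaptures: 1

$ python analysis/03_geolocate.py
tag000: D_low=9.4, D_high=25.5 km^2/day, reliability=reliable, median error vs truth 8.6 km
tag001: D_low=12.6, D_high=21.8 km^2/day, reliability=reliable, median error vs truth 11.2 km
tag002: D_low=12.9, D_high=27.9 km^2/day, reliability=reliable, median error vs truth 9.9 km
```

The fish were simulated with `D_low = 5`, `D_high = 30` km²/day; the
switching fits bracket the truth and the decoded tracks land within a
grid cell (~10 km) of the true daily positions. `04_metrics.py` prints
the Table-1/Table-2-shaped residency and strategy summaries and
`05_network.py` the seasonal station-to-station movement graph. The same
pipeline is scriptable through the `basstrack` CLI
(`simulate | preprocess | geolocate | metrics | network | run-all`,
with `--config config.yaml --seed N --outdir DIR`).

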