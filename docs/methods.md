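# Methods

`paleogradient` couples three pieces: a synthetic dynamic paleo-landscape
generator, a forward-in-time eco-evolutionary simulator, and an analysis
layer that turns simulated clades into latitudinal diversity gradients
(LDGs), diversification-rate surfaces, tanh shape fits and simplified
Köppen belts. This note records the model, its assumptions, the defaults
and why, and what the synthetic worlds do and do not emulate.

## The synthetic landscape

Worlds are cell-centered lon/lat grids (longitude periodic, latitude
clamped at the poles; cell area ∝ cos lat) carrying elevation (m),
temperature (°C), precipitation (m/yr), water discharge (m³/yr) and a
land–sea mask, at 1 Myr steps with ages decreasing to 0.

**Continents** are smoothed Gaussian blobs advected by per-continent
velocities; the land mask is the exceedance set of the configured areal
land fraction (default 0.3), so land fraction is constant by
construction. Centers are drawn area-uniformly on the sphere up to 65°,
with the hemisphere chosen with probability (1+a)/2 for the north, where
a = `hemisphere_asymmetry` ∈ [0,1]. Because the realized area also
depends on blob overlap, the generator checks the realized series and,
if the south came out heavier, regenerates the exact mirror
configuration — a positive asymmetry therefore always yields a northern
land excess, and a = 0 is symmetric in expectation. Optional
fragmentation events split the largest blob in two with diverging
velocities, emulating continental breakup. Orogeny events add Gaussian
elevation bumps that ramp up over ~5 Myr and persist.

**Climate** is zonal: temperature declines as cos(lat) between
`equator_T` (default 27 °C) and `pole_T` (−18 °C), modulated by a
mid-series thermal maximum (amplitude 3 °C, echoing a Cretaceous-style
optimum), an AR(1) step-to-step wobble (sd 1.5 °C), and the pseudo-K-Pg
factor below. Precipitation peaks at the tropics (Gaussian in latitude,
width 22°, default 1.8 → 0.3 m/yr pole-ward) with an AR(1) fractional
wobble (sd 0.10) and a static spatial texture tied to the terrain noise.
Zonal-mean temperature is non-increasing in |lat| at every step by
construction, and the generator asserts it.

**Pseudo-K-Pg.** A transient harshening: temperature and precipitation
profiles are multiplied by (1 − severity) for `kpg_duration` steps
(default 2) and recover linearly over 5 steps. The background offsets
are frozen inside the window so the step-over-step relative drop equals
the configured severity exactly. One side effect of the multiplicative
form: sub-zero polar temperatures move toward 0 °C during the event
(their relative change is still −severity); at the default settings the
event still cools every band with T > 0 and expands the polar Köppen
belt, which is the behaviour that matters downstream.

**Discharge** accumulates precipitation × contributing area down the
single-flow-direction (steepest descent) drainage network; pits retain
their flux as a lake proxy and `flow_accumulate` conserves water volume
exactly. The hierarchical flux classification (log10 bounds 7–10)
presupposes fluxes computed on a ~0.05° mesh and *interpolated* — not
aggregated — to the working grid; the generator emulates that provenance
by using the area of a 0.05° cell as the local contributing area, which
makes the synthetic discharge distribution resolution-independent and
spread across all five classes.

*What the generator does not emulate:* real plate reconstructions,
spherical geodesy beyond cos(lat) weighting, elevation–temperature lapse
(temperature is purely zonal), evaporation in lake budgets, monsoonal or
orographic precipitation. Tests passing on these worlds show the machine
behaves as specified under Earth-like gross structure; they do not
validate against any real reconstruction.

## Physiography

TPI (topographic position index) is local elevation minus the mean over
an annular neighbourhood, computed at two scale bands — at the working
resolution, a ring of radius 1 cell and rings of radii 2–3 cells — then
standardized (×100, grid mean/sd) and averaged into a single layer
before categorization, so the diversity index uses exactly three
categorical variables. Slope is the arctan of the maximum absolute
gradient to the 8-neighbourhood. Categories: slope 10 classes with the
inclusive lower bounds 0.03, 0.11, 0.3, 0.5, 0.85, 1.65, 2.4, 3.5, 4.5
degrees; water flux 5 log-spaced classes (these also define the
hydrological categories H); standardized TPI in per-slice decile bins
(no published thresholds exist for it).

Physiographic diversity Φ is Shannon *equitability* per variable —
each variable's Shannon index over the cell's square window (radius 1 by
default, clipped at coasts, sea cells never contribute) divided by the
log of that variable's class count — averaged over the three variables.
The alternative reading (pooling all observations into one index and
dividing by ln 3) can exceed 1; the per-variable form is bounded in
[0,1] with Φ = 0 iff all three layers are locally constant, and
reproduces the two-of-ten worked value (ln 2/ln 10)/3 ≈ 0.1003.

## The eco-evolutionary engine

**Normalization.** Temperature: 100 °C per trait unit, which ties the
fixed evolutionary step σ = 0.005 to exactly 0.5 °C per step.
Precipitation: divided by the series-wide maximum. Resource inputs to
carrying capacity (P̄, H̄, Φ̄) are each normalized by their per-slice
maximum over land.

**Cost graph.** Cells connect to their 8 neighbours; edge weight is the
great-circle distance (km), doubled on any edge touching a sea cell, and
multiplied by (1 + |ΔΦ|) on land–land edges under distance+Φ dispersal
(M1d). Pairwise cost-distance is the shortest path (sea transit allowed
at doubled cost).

**Dispersal.** One Weibull(shape ϕ, scale Ψ) distance draw per occupied
cell per step; every land cell within that cost-distance is a candidate
colonization, which establishes only if its post-reapportionment share
is at least 0.01. Arrivals copy trait values from their cost-nearest
source. The kernel parameters are defined on a 2° grid; on other
resolutions effective distances (kernel draws and the clustering
reachability below) rescale by lat_res/2°, preserving the connectivity
structure of the reference design in scaled-down worlds.

**Clustering and speciation.** Each species' occupied cells are
partitioned into geographic clusters: connected components under
cost-distance ≤ Ψ, the model's only length scale. Under Φ-based
speciation (M1s), edges incident to barrier cells (land Φ above the 0.75
quantile) are severed first; under M1d the *plain* distance graph is
used (Φ affects dispersal only). Lineage demes carry a divergence
ledger: +1 per step between demes in different clusters, −1 on secondary
contact (floor 0, fully healed co-clustered demes merge; split demes
inherit divergence by maximum). A cluster whose demes have all diverged
≥ τ from every outside deme buds off as a new species (the most populous
cluster always stays with the parent). With Ψ below the cell span every
occupied cell is its own cluster — fine-grained allopatry in which
speciation and adaptation operate per cell; this is the small-Ψ limit of
the distance-isolation mechanism, not an error state.

**Trait evolution.** Per cluster, one half-normal step |N(0, σ²)| moves
the thermal optimum toward the cluster-mean local temperature, never
overshooting. A literal reflect-around-the-local-mean update is not a
usable trait dynamic (it discards the lineage's state each step); the
bounded directed step realizes the intended behaviour — a ±0.5 °C
fluctuation directed toward the local average. Precipitation optima are
fixed at founding.

**Ecology.** Suitability K = Ks·exp(−((T̄i−T̄s)/ωt)²−((P̄i−P̄s)/ωp)²);
carrying capacity Ks = min(Kmax, (α·P̄ + β·H̄ + γ·Φ̄)·Kmax)·cos(lat)
with Kmax = 1 and the Φ term only evaluated when γ > 0 (so Φ cannot leak
into scenarios that exclude it). Population update N′ = N + N·(K − N);
populations below 0.01 are locally extinct. On colonization or local
extinction the site's total abundance is reset to Ks and split across
the present species proportionally to K, iterating the sub-0.01 removal
until stable. A species with no occupied cells is globally extinct.

**Step order** (1 Myr per step): landscape update (drowned cells
removed) → dispersal → clustering → divergence/speciation → trait
evolution → ecology. One numpy Generator per simulation drives all
stochastic draws; iteration orders are sorted, so runs are
bit-reproducible for a fixed seed.

**Scenarios** (resource weights α, β, γ; only M1e has γ > 0):
M0 distance/distance 0.5/0.5/0; M1s distance/Φ 0.5/0.5/0;
M1d distance+Φ/distance 0.5/0.5/0; M1e distance/distance 0.33/0.33/0.33.
Free parameters (τ ∈ [0.5,3] Myr, ωt, ωp ∈ [0.05,0.25], ϕ ∈ [2,3],
Ψ ∈ [100,600] km) are explored with a scrambled Sobol sequence; σ is
fixed.

**Initialization.** One ancestral species on the largest contiguous
landmass cell nearest the equator, trait optima set to local conditions.
The first 25 steps are treated as spin-up and excluded from analysis
profiles by default.

## Analysis layer

Richness, speciation, extinction, net diversification (speciation −
extinction) and turnover ((speciation + extinction)/richness, undefined
where richness is 0) are computed per cell per step. An origination is
attributed to every cell of the founding cluster with weight 1/n_cells
(extinctions likewise to the species' last cells), so spatial maps
conserve global event counts. Latitudinal profiles are cos(lat)-weighted
means over land cells per band of cell-center latitudes; sea cells are
excluded rather than zero-filled. Ensembles are averaged *before*
normalization (÷ maximum), since the two operations do not commute.

The LDG shape is summarized by fitting α(lat) = αmin + Δα·tanh(θ(lat −
lat0)) per hemisphere on absolute latitude (bounded least squares, four
starts crossing both θ signs with the lat0 quartiles, tolerances 1e-12),
canonicalized to θ ≥ 0 via the (Δα, θ) → (−Δα, −θ) reflection symmetry.
Near-flat profiles (range < 1e-10 of scale) return converged=False
instead of a spurious slope. Because "width" has no unique algebraic
definition, both candidates are reported: the midpoint lat0 and the
transition width 2/|θ|; slope likewise as raw θ and as the maximum
gradient |θ·Δα|.

Simplified Köppen belts from MAT (°C) and MAP (m/yr), in precedence
order A → B → C → D → E → none: A (MAT > 18, MAP > 0.6), B (MAP in
cm/yr < κ = 2·MAT — the cm convention is the classic Köppen reading of
the aridity threshold), C (5 < MAT < 18, 0.5 < MAP < 2), D (−5 < MAT <
10, 0.4 < MAP < 1), E (MAT < 10). The precedence order resolves the
overlapping printed definitions deterministically. Band profiles take
the modal class over land cells, ties to the lower-precedence letter.

## Problem sizes and reproducibility

The test suite and the worked examples run on deliberately small worlds:
the `tiny` preset (18×9 cells of 20°, 30 steps; 60 steps for ensemble
experiments) and `demo` (36×18 cells of 10°, 60 steps). Ensemble
experiments use 20 world seeds × 6 Sobol draws of scenario M1e, averaged
per seed — the same average-over-draws protocol as a full-scale study,
at sizes a laptop runs in a couple of minutes. The pipeline derives
every stream from one master seed (world: the seed itself; simulation
(scenario i, draw j): a counter-based SHA-256 child seed), so ensembles
are order-independent and reproducible bit-for-bit.

## Known limitations

- The scaled-down grids compress the isolation-by-distance continuum:
  clusters are either landmass-wide or cell-grained, with little in
  between; intermediate range fragmentation needs finer grids.
- No biotic interactions (competition, mutualism), no sympatric
  speciation, no marine realm; reapportionment is the only interspecific
  coupling.
- Divergence is tracked per deme pair with max-inheritance on splits; a
  cell-pair-resolved ledger could heal or diverge differently after
  complex split/merge histories.
- The tanh fit needs ≥ 8 bands with data; on the 20° tiny grid a
  hemisphere has only 4 bands, so LDG shape fitting is meaningful on
  10°-or-finer grids.
- Phylogenies record budding topology; the parent lineage keeps its
  identity through a speciation event, as in the underlying event
  model.
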