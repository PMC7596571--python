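# Methods

## Landscape geometry

A facility's procurement landscape is a circle around its centroid whose
radius follows sector and capacity: pellet mills receive 80 km when nominal
annual capacity is at least 100 thousand tons (the threshold is inclusive)
and 48 km otherwise; wood-using power plants 80 km; pulp mills 121 km.
Distances between centroids, and from centroids to ports, plots and
population units, are haversine great-circle distances on a sphere of mean
radius 6371.0088 km.  Circle–circle intersection ("lens") areas are
evaluated with the planar two-circle formula at the great-circle centre
separation; at the ≤ 322 km separations that can produce a nonzero lens the
planar error is far below every tolerance used here.  Polygon work (drought
footprints, exported circle polygons) runs through shapely in a local
equirectangular km plane anchored at the geometry's own centroid.

Boundary conventions: distance and containment thresholds are strict
(a port at exactly 121 km does not grant access; a plot or population unit
exactly on the circle is outside), while "at least" thresholds are
inclusive (capacity ≥ 100k; drought coverage ≥ 10%).  The overlap fraction
for a landscape sums lens areas of *other* facilities operational in the
3-year sampling window and divides by the full circle area, so it can
exceed 1 when the area is covered more than once; the target's own circle
never counts.  The drought flag for panel year *t* looks only at footprints
recorded for August of *t − 1* with severity in {severe, extreme,
exceptional}, and fires when they cover at least 10% of the circle.

## Inventory expansion

Each inventory plot represents a block of land through an area expansion
factor (≈ 2,428 ha, one plot per 24.28 km²) and carries per-hectare
densities for the six attributes.  For a landscape × period cell the
estimator selects timberland plots strictly inside the circle measured in
the window [t − 2, t], keeps the latest re-measurement per plot, and sums
density × expansion factor.  The reported sampling error treats the
expanded per-plot values as a simple random sample: SE(total) = √(n·s²),
expressed as a percentage of the total (zero when n < 2 or the total is 0).
The stratified post-sampling estimator used by operational inventories is
out of scope; on the synthetic study the SRS error averages ≈ 2.5%,
consistent with the small sampling errors such inventories report.
A landscape's timberland area is the sum of expansion factors of its
selected plots, which is also the divisor basis for per-hectare effects.

## Design matrix

Observations are stacked period-major ((year, facility) sorted, index
t·N + i).  Years of operation counts calendar years inclusively from the
start year, keeps accrued years after a closure, and is capped at 28 (the
largest value the panel can exhibit given the earliest modelled start
years).  The operational dummy is 1 when the operating span intersects the
3-year window.  The post-recession indicator is 1 for 2011, 2014 and 2017.
Ecoregion indicators span seven of eight labels against the Northern
Hardwoods-Red Pine baseline; columns that are identically zero (an
unoccupied ecoregion, a never-firing interaction) are dropped before
estimation and recorded.  Each of the eleven interaction columns is the
exact elementwise product of its two parents.  No centring or scaling is
applied before estimation; standardization happens only in reporting.

## Spatial weights

Raw weights are 1/d for centroid pairs strictly closer than 161 km, zero
otherwise and on the diagonal; each nonzero row is normalized to sum to 1.
Isolated landscapes keep a zero row, so their disturbance reduces to their
own composite error — global re-normalization was rejected because it would
alter every other unit's weights.  Co-located centroids are an error unless
a floor distance is configured.  The matrix is time-invariant.

## Estimation

With B = I − ρW and θ = σ²_μ/σ²_ν, the NT disturbance covariance is
(σ²_μ J_T + σ²_ν I_T) ⊗ (B⁻¹B⁻ᵀ).  The log-likelihood is evaluated through
the Kronecker eigenstructure (log-determinant
N[(T−1)log σ²_ν + log(σ²_ν + Tσ²_μ)] − 2T log|B|; the quadratic form uses
the spatially filtered residuals and their time sums), never by forming the
NT × NT matrix; a dense multivariate-normal oracle in the tests confirms
agreement to 1e-10 relative.

Fitting concentrates β and σ²_ν: filtering each period by B and
quasi-demeaning in time with c = 1 − (1 + Tθ)^(−1/2) turns GLS into OLS, so
only (ρ, θ) remain for the outer bounded L-BFGS-B search, with ρ ∈
(−0.999, 0.999) (valid for a row-normalized W), θ ≥ 0, objective tolerance
1e-10, and deterministic multi-starts (ρ ∈ {−0.5, 0, 0.5}, θ ∈ {0.1, 1})
to guard against local optima; the grid-search test verifies the optimum
against a 0.002-resolution brute-force grid.  Either parameter can be
fixed, which collapses the model onto its degenerate limits (ordinary least
squares; classical one-way random effects; pooled spatial error) — each is
verified against an independent implementation.

Reported variance components carry a degrees-of-freedom correction:
σ̂²_ν = RSS/(NT − K) (the raw maximum-likelihood value RSS/NT is also
stored), and the coefficient covariance is σ̂²_ν (X*ᵀX*)⁻¹ from the GLS
information matrix, with two-sided normal p-values and no multiple-testing
correction.  The covariance uses a symmetric pseudo-inverse so that
near-collinear designs degrade to flagged, wide intervals instead of
negative variances.

**ML vs REML.**  The default estimator is plain maximum likelihood, the
choice that matches how such models are usually reported.  At this study's
scale (K ≈ 29 mean parameters in 615 observations) ML's variance and
spatial parameters carry the familiar O(K/NT) finite-sample bias — about
−0.05 on ρ and −15% on σ²_μ in simulation.  `fit_spatial_re(reml=True)`
maximizes the restricted likelihood instead (the profile criterion gains
−½ log|X*ᵀX*| and concentrates σ²_ν over NT − K), which removes that bias;
the parameter-recovery and Hausman-size simulations in the test suite score
the REML variant for exactly this reason, while the degenerate-limit checks
validate the ML path against ML oracles.  β̂ is the GLS estimate under
both and is unbiased either way.

The fixed-effects counterpart within-demeans Y and the time-variant
covariates per landscape and fits the pooled spatial-error model on the
demeaned data; its σ̂²_ν divisor is N(T − 1) − K to account for the
demeaning rank loss.  The Hausman statistic is
(b_FE − b_RE)ᵀ(V_FE − V_RE)⁻¹(b_FE − b_RE) on the shared time-variant
coefficients, with a flagged symmetric pseudo-inverse when the variance
difference is not positive definite; at a nominal 5% level its simulated
size under a correct random-effects process is ≈ 0.05.

Balanced panels are required; empty inventory cells abort model fitting
with the offending (landscape, period) named.

## Reporting

Standardized coefficients are β·S_x/S_y with sample standard deviations
pooled over all N·T observations (the cross-sectional alternative was
rejected to keep one scale per model); zero-variance covariates yield a
flagged, undefined record rather than a silent zero.  Per-hectare effects
divide a coefficient by a timberland-hectare divisor whose policy is
explicit and configurable — default: the panel-mean timberland hectares per
landscape, with optional per-coefficient overrides (e.g. averaging over
large-capacity landscapes only for coefficients interacted with large
capacity) — and the divisor used is written on every output row, because no
single implied divisor is consistent with all published per-hectare
conversions of this model family.  Exports are CSVs at 12 significant
digits plus a JSON manifest carrying seed, config hash and convergence
flags; identical seed and config reproduce the CSVs byte for byte.

## Synthetic study

The generator reproduces the study *conditions*, not its geography: 123
pellet mills in an abstract 1,050 × 950 km box (expressed as lon/lat
through a fixed equirectangular anchor), with auxiliary layers extending
beyond the facility box far enough that no landscape is ever clipped by a
data edge.  Mills are placed by hard-core sequential sampling with a 54 km
minimum separation — close enough that sub-161 km neighbour structure is
dense (no isolated unit in the default draw), sparse enough to hit the
pellet-overlap target.  Calibrated once and frozen, the defaults put the
realized covariate moments on the published descriptive statistics over the
615-observation panel: operational share 0.5; years of operation mean 3.2
(max 28, from a 5.2% share of legacy mills starting 1984–1996 alongside
2007–2017 entrants); large-capacity share 0.2; export access 0.5 (23
ports); coastal share 0.3 (southern band of the box); pellet/power/pulp
overlap means 0.3/1.4/1.1 (167 power plants, 55 pulp mills at calibrated
densities); population mean 486.5 thousand (lognormal unit counts anchored
at 2011 with ~1%/yr growth, which also keeps population time-variant so the
fixed-effects fit stays identified); lagged-drought share 0.1 (Poisson
drought discs, radius 100–250 km).  A moment test re-checks all of these
across 20 seeds against 3 Monte-Carlo standard errors.  The realized
years-of-operation SD (≈ 5.3 versus the published 4.4) is the one moment
deliberately conceded: matching it exactly would break the jointly
constrained operational-share and mean-years targets.

Plots are scattered uniformly at one per 24.28 km² (≈ 39 thousand
timberland plots, close to the study's 38,626) on a three-year measurement
cycle with random phase, so every sampling window contains exactly one
measurement per plot.  Attribute densities are lognormal around
field-plausible per-hectare means (990 live trees, 220 growing-stock, 22
standing-dead, 28 t C live, 2.5 t C standing-dead, 83 t C soil — chosen to
land landscape totals at the magnitudes such studies print).

Responses for estimator testing are drawn from the model's own process with
known parameters (default ρ = 0.4, σ²_μ = σ²_ν = 25, a fixed β vector);
the stored truth object reproduces Y exactly from its components.  Six
attributes are simulated independently — cross-response error correlation
is out of scope, as the six models are fitted separately anyway.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: real hexagonal inventory tessellation and
stratified expansion factors, areal (dasymetric) population apportionment,
true drought climatology, road-network (non-circular) procurement areas,
mill closures, and any endogeneity between mill siting and timberland
conditions (covariates are exogenous by construction, so the random-effects
assumption holds in the synthetic world by design).

## Problem sizes and numerics

Test problem sizes were chosen so each oracle is sharp at desk scale: the
dense-likelihood comparison runs at N = 12, T = 3 where the NT × NT oracle
is exact and cheap; the grid oracle at N = 25 with a 0.002 step; recovery
and coverage at the full N = 123 with 200 replicates; Hausman size at
N = 40 with 500 replicates on the identified core covariate blocks (the
full interaction design is rank-deficient at that N, which would test
collinearity handling rather than size).  Monte-Carlo geometry checks use
10⁶-point rejection sampling within 3 MC standard deviations.  Degenerate
inputs are rejected loudly: non-positive capacities, unknown sectors,
out-of-range coordinates, duplicate centroids without a floor, singular
I − ρW, empty shared-coefficient sets, zero hectare divisors.
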