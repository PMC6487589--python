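# Methods

## Scope and model

The package computes, for every plant of a multi-genotype canopy, the terms
of a per-plant multiplicative biomass model

ΔBM/Δt = R_i · RIE_plant · RUE / D,  RIE_plant = LA · CI / CP,
RUE = e^ε_RUE · e^(a·R_leaf + b),

and provides the machinery around it: a parametric plant generator, a voxel
light model, variance-component genetics and a virtual-field simulator.
The identity ΔBM = R_plant · RUE (with R_plant = RIE_plant·R_i/D and
R_leaf = R_plant/LA after unit conversion) holds algebraically and is
asserted in the test suite to 10⁻⁹ relative.

## Light model

The canopy is voxelized on a regular grid, default cell 0.2 × 0.2 × 0.1 m,
coordinates in metres, z up, origin at the plot corner, cells indexed
half-open. Triangles are recursively quartered until every edge is at most
half the smallest cell edge, then each triangle's whole area is credited to
the cell containing its centroid; this avoids splitting areas across cell
faces. Each cell records leaf-area density (m² m⁻³), the per-plant share of
its area, and contributes to an area-weighted leaf-inclination histogram
(nine 10° bins).

Daily incident flux (mol m⁻² d⁻¹, one value per day) is split over a
discretized sky, default 46 downwelling directions: equal-width zenith
bands (⌊√n⌉ bands), sector counts proportional to band solid angle,
weights from the Standard Overcast Sky radiance (1 + 2·sin h)/3 integrated
as flux through a horizontal plane. The zenith-most sectors therefore carry
more weight than horizon sectors. The true sky radiance model used with
RATP-style canopy analyses varies; SOC is a documented, fully specified
choice, and `build_sky(1)` degenerates to a single vertical beam for
closed-form checks.

Extinction is first-order Beer–Lambert per traversed cell:
T ← T·exp(−G_d·Ω·LAD·ℓ), with Ω = 0.8 the clumping factor (applied as a
multiplier on LAD in the exponent) and G_d the projection coefficient of
the inclination histogram toward direction d, computed by numerical
azimuth-averaging of |n̂·d̂| per bin (config fallback: spherical, G = 0.5).
One ray is launched per top-face cell centre per direction; because every
ray enters at the same fractional cell position, the Amanatides–Woo
traversal is computed once per direction and applied to all rays
vectorized. Lateral boundaries are periodic by default (infinite-canopy
tile); an absorbing mode exists for platform-like finite canopies, where
laterally escaping flux is accounted with the ground term so the energy
budget stays closed. Scattering (default coefficient 0.16) does not enter
the extinction; it only converts intercepted into absorbed flux when
`report_absorbed` is set, because the interception-efficiency definitions
consume intercepted, not absorbed, light. Multiple scattering, penumbra,
hourly sun paths and structure shadows are out of scope.

Conservation (intercepted + transmitted = incident) holds to float
precision with scattering off; the homogeneous-slab closed form
1 − e^(−G·Ω·LAI) is met exactly under a vertical beam.

## Dissection

RIE_plant = R_plant·D/R_i may exceed 1 for dominant plants. The moving
window is the focal plant plus its k−1 nearest neighbours in x–y (k = 15
default), ties broken by plant id; LA_c and RIE_c are unweighted means with
the focal plant included, and border windows simply reach further inward
(no mirroring), which reproduces the border behaviour of CP. RIE_c is the
mean of per-plant RIEs, not the RIE of the pooled window canopy. CI uses
LA_c in the denominator ratio. R_leaf converts the daily integral with a
12 h photoperiod. RUE is the OLS slope of biomass on cumulative intercepted
light over thermal time 30–50 d20 (≥ 3 points required); biomass is fresh
weight throughout. The panel-wide fit of ln RUE on R_leaf (statsmodels OLS)
yields a < 0 — RUE declines with light — and ε_RUE as genotype-mean
residuals; fitting a and b per genotype is deliberately not offered, as the
two are nearly collinear and a single panel-wide response with one
genotypic residual is the parsimonious parameterization.

## Synthetic plants

Genotypes carry final leaf area, maximum height, leaf number, leaf-angle
mode, logistic expansion midpoint/rate and ε_RUE. Defaults: 0.55 m²,
1.6 m, 12 leaves, 35° from horizontal, midpoint 30 d20, rate 0.22 d20⁻¹ —
maize-like values for a platform-grown plant. Between-genotype variability
is log-normal with CVs 0.20 (area), 0.12 (height), 0.10 (leaf count, rate),
0.05 (midpoint), s.d. 8° (angle) and s.d. 0.045 for ε_RUE, chosen so a
255-genotype panel spans roughly [−0.13, 0.11]. Leaf area follows a
logistic in thermal time; height co-develops as the same logistic fraction
of maximum height. A plant's mesh is n planar rectangular blades in
alternate phyllotaxis: blade lengths are set by the stem geometry (the top
blade tip defines plant height exactly), widths are horizontal and carry
the area calibration, so leaf area and height are independently
controllable and mesh area matches the target to float precision.
Replicate noise is multiplicative log-normal on area and height plus
per-leaf inclination jitter (s.d. 15°·CV); per-plant random streams derive
from (seed, crc32(plant_id)) so layouts are order-independent. The
generator does not emulate leaf curvature, ears/tassels, senescence or
azimuthal light-seeking — competition signals here are purely
architectural (height, angle, area), so passing tests demonstrate the
method's internal consistency, not maize realism.

## Genetics

Variance components use the one-way ANOVA method of moments: σ²_e is the
pooled within-genotype mean square, σ²_G = max(0, (MS_b − MS_w)/r̄) with r̄
the harmonic-mean replicate count; REML would be the choice for unbalanced
real data but is unnecessary for the balanced synthetic designs here.
Genotypic means are arithmetic means of replicates. H² = σ²_G/(σ²_G +
σ²_e/r) is bounded in [0, 1] and monotone in σ²_G and r.

## Virtual fields

Canopy archetypes: A (one genotype, large periodic plot), B (four
contiguous rows per genotype), C (one row per genotype), D/Dall (balanced
random assignment). The paper-style platform and field densities are not
fixed by the framework; the default grid is 20 rows × 20 plants at
0.4 × 0.2 m spacing, all configurable. The growth loop rebuilds meshes at
each thermal-time step, traces light, evaluates RUE through the fitted
light response plus the genotype's ε_RUE, and accumulates ΔBM =
R_plant·RUE·Δt. Periodic boundaries make canopy A a true large-plot
reference.

## Canned experiments and problem sizes

`experiments.py` packages three studies at desk scale:

* **uniform_canopy_ci** — 15 × 15 identical plants at 0.4 m spacing,
  thermal time 45 d20, periodic light, interior plants ≥ 3 rows from the
  edge. By translational symmetry every interior plant intercepts the same
  flux, so CI = 1; the experiment verifies the whole pipeline preserves
  that identity (it does, to < 10⁻¹²).
* **heritability_experiment** — 60 genotypes × 3 replicates (180 plants,
  12 × 15 grid at 0.2 m), randomized positions, absorbing boundaries so
  border plants receive extra light as in a real platform. Genotypes differ
  in height and leaf angle but share a common leaf-area trajectory, making
  CP's only genetic path the focal plant's own window contribution: H²(CP)
  stays near zero on all days while H²(CI) exceeds 0.8 after canopy
  closure. With genotypic leaf-area variation included, CP picks up a small
  genetic component through the focal plant's share of its own window; the
  height-only panel isolates the architectural competition signal.
* **bias_experiment** — nine height-differentiated genotypes; canopy A
  references are 8 × 8 periodic plots, B is 36 × 8, C 18 × 8, D 12 × 12,
  all at 0.2 m spacing, three 10-d20 steps from 20 to 50 d20. The D/A
  biomass ratio regresses on genotypic CI with positive slope (r² ≈ 0.98),
  and the mean |ratio − 1| of the six extreme-CI genotypes grows from B to
  C to D: the more heterogeneous the canopy, the larger the bias in
  genotype comparison.

These sizes keep each experiment in seconds-to-tens-of-seconds while
leaving enough plants for stable variance components; all are pure
functions of a single seed.

## Numerical notes and limitations

* Grid extents snap up to whole cells; with spacings that are multiples of
  the cell edge, periodic wrap is exact and symmetric layouts stay exactly
  symmetric.
* Competition in the simulated dense stands is stronger than platform
  observations (CI spans ~0.1–3 rather than ~0.6–1.5) because planar
  blades at a common azimuthal pattern shade perfectly and nothing limits
  height-driven dominance; qualitative orderings, not absolute spreads,
  are the reproducible quantities.
* Zero-leaf-area cells are skipped implicitly (exp(0) = 1); degenerate
  blades are rejected at mesh build time.
* The RUE regression requires at least 3 days inside the interval; plants
  with fewer are dropped from the response fit rather than imputed.
* Transmission maps use nearest-cell (staircase) lookup, not bilinear
  interpolation.
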