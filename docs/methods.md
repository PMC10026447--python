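# Methods

This note documents the model assumptions, parameter choices, numerical
decisions and known limitations of the `endfeet` package.

## Surface model and point process

A vessel's endfoot sheath is represented on the unrolled cylinder: a
rectangle of width 2πr_o (circumferential) and height L (axial), periodic
in both directions. A cylinder is intrinsically flat, so the unrolled
geometry is exact — no curvature correction is needed for areas or lengths.
Periodicity in the circumferential direction is physically required
(wrapping must tile consistently); axial periodicity is a modelling choice
that removes boundary bias from the edge statistics, making every
realization an unbiased sample regardless of L.

Endfoot generators are sampled sequentially and uniformly, rejecting any
proposal closer (toroidal metric) than 0.3·√(1/ρ) to an accepted point,
where ρ is the target density. The exclusion radius suppresses
unrealistically small endfeet while keeping the process close to Poisson;
the rejection loop has an attempt budget of 10⁴ proposals per target point
and raises beyond it (the default exclusion factor 0.3 is always feasible).
Exactly round(ρ·area) points are drawn, so the realized mean cell area
equals 1/ρ exactly.

The axial length is not a physical parameter; by default it is chosen so
that 500 cells are expected per realization (L = 500·A/(2πr_o)), which
keeps the per-realization Monte-Carlo error of φ_g below about 1 %. It is
configurable everywhere (`n_cells`).

## Periodic Voronoi construction

The Voronoi diagram on the torus is computed by replicating the point set
on a 3×3 tiling of the fundamental domain and reading off the cells of the
central copy (scipy/Qhull does the planar diagram). This is exact whenever
no cell extends beyond one period from its generator — guaranteed in
practice for ≥ 3 well-spread points; an unbounded central cell raises. Cell
areas are summed and checked against the domain area at relative tolerance
1e-9 on every realization.

Edge statistics count each periodic bisector exactly once: a ridge carries
weight ½ per endpoint in the central copy, so interior edges weigh 1 and
edges crossing the seam contribute ½ from each of their two periodic
copies. Total edge length l_Σ therefore equals half the summed cell
perimeters. The axially projected length l⊥_Σ sums |Δz| per edge; a ring at
height z crosses an edge iff the edge's z-interval covers z, so
gaps/ring = l⊥_Σ/L is the exact mean cross-sectional gap count.

Two closed forms anchor the implementation: planar Poisson-Voronoi has edge
intensity 2√λ (checked within 1 % on ≥ 10⁵ pooled cells with the hard core
disabled), and a regular hexagonal tiling of cell area A has
φ_g = d·√(2√3)/√A (reproduced to 4 significant digits from triangular
lattice generators). For isotropic patterns l⊥_Σ/l_Σ → 2/π, the mean |cos|
of a uniform orientation.

Finite gap width is *not* subtracted from cell areas: at φ_g < 1 % the
effect on the area distribution is negligible, and d_g enters only through
the φ definitions. The ensemble driver derives per-realization seeds as
seed + index from one documented generator (numpy `default_rng`).

## Area relations and gap-fraction fits

The mean endfoot area grows with vessel caliber: quadratically for arterial
vessels, linearly for venous ones. The underlying regressions exist only in
graphical form in the experimental literature, so the package's defaults
are *anchored surrogates*: a zero-linear-term quadratic through
(2.9 µm, 50 µm²) and (15 µm, 490 µm²) for arteries
(A = 2.0315·r_o² + 32.915) and a line through (2.9, 50) and (15, 110) for
veins (A = 4.9587·r_o + 35.620); both kinds share the capillary anchor.
All coefficients are plain data and can be overridden from re-digitized
sources. The uncorrected capillary anchor (2.9 µm, 25 µm²) is kept for
projection tests.

Simulated gap fractions at gap width 20 nm are summarized by
φ(r_o) = c1·e^(−c2·r_o) + c3 with reference coefficients
(0.00704, 0.1668, 0.00124) arterial on [2.5, 15] µm and
(0.00468, 0.0716, 0.00226) venous on [2.5, 20] µm. `fit_gap_fraction_model`
refits this form from samples (scipy `curve_fit`, initialized from the
sample extremes; ≥ 4 distinct radii required). The closure property —
simulate at radii across the range with areas from the corrected relations,
refit, recover the reference fit within 10 % pointwise — is exercised in
the acceptance tests.

## Projection correction

The virtual 2-D measurement maps each cell to the cylinder (θ = x/r_o),
keeps cells whose generator lies on the visible half-arc, clips them to
that arc (the far side is hidden), and projects orthographically
(u = −r_o·cos θ), taking the planar polygon area as "measured". Polygon
edges are densified (default max segment 0.05·r_o, chord error ≲ 0.01 %)
before the curved mapping; wrapping parts are handled by clipping against
the ±one-period copies of the visible strip, which never double-counts.

Inclusion rule, visible arc and clipping are configuration switches
(`ProjectionConvention`), because the original measurement protocol is not
published in enough detail to pin them down. The default convention roughly
halves the capillary-scale mean area (50 → ~26 µm² at r_o = 2.9), matching
the reported factor-two discrepancy between 2-D estimates and corrected
areas; in the flat limit (cells ≪ r_o) the measured/true ratio tends to
2/π from foreshortening alone.

The measured→true correction is tabulated, not closed-form, because
wrapping makes it radius-dependent. Per (r_o, A_true) node the mean
measured area over n realizations is recorded with its standard error;
per-radius isotonic regression removes Monte-Carlo wiggles (a violation
beyond 5 standard errors raises, signalling a convention bug), plateaus are
strictified by an epsilon ramp, and inversion is piecewise-linear in
measured area with linear blending between the two bracketing radii.
Queries outside the table hull raise. The full default grid is 9 radii ×
12 area levels × 50 realizations; tests and the worked examples use smaller
grids (3 radii around the capillary caliber, 6–8 levels, 12–20
realizations, 150–200 cells per realization), which keeps the Monte-Carlo
standard error of each node near 1 % while finishing in tens of seconds.

## Transport coefficients

Gap channels are parallel plates: transmissibility t_g = d_g³/(12μl_g),
filtration coefficient L_p = φ_g·t_g/d_g = φ_g·d_g²/(12μl_g), diffusion
membrane coefficient C_M = α·φ_g/l_g. Key parameters, defaults and units:

| parameter | default | meaning |
|---|---|---|
| d_g | 20 nm | inter-endfoot gap width (EM value; L_p ∝ d_g³, C_M ∝ d_g) |
| l_g | 1.5·h_ES | tortuous gap path length (endfoot overlap), µm |
| h_ES | max(1, 1 + 0.15(r_v − 3)) µm | sheath thickness vs lumen radius |
| μ | 0.7×10⁻³ Pa·s | water at 37 °C (0.69×10⁻³ is a preset for one published figure axis) |
| α | 1 | hindrance; Renkin slit polynomial for λ = solute/gap ratio |
| D | 10⁻⁹ m²/s | free diffusion coefficient scale of small solutes |

h_ES is clamped at 1 µm below r_v = 3 µm so the linear law stays inside the
reported in-vivo 1–2.5 µm range. The outer radius follows
r_o = 1.3·r_v + 1.5 for r_v ≥ 3 µm (smooth muscle layer present) and
r_o = 1.15·r_v + 0.95 below; the 1 µm discontinuity at r_v = 3 µm reflects
the onset of the smooth muscle layer and is intentionally not smoothed.
C_M/L_p = 12μα/d_g² holds identically, so filtration and diffusion
coefficients are perfectly correlated across a network by construction.
Micro-scale inputs (nm, µm) are converted to SI exactly once at the
function boundary; all outputs are SI.

The gap Péclet number Pe_g = Δp·d_g²/(12μαD) evaluates to 4.8×10⁻³ at the
defaults with Δp = 100 Pa — the implementation exposes the formula as
stated even though a slightly smaller headline bound (3×10⁻³) circulates;
either way Pe ≪ 1 and sheath crossing is diffusion-dominated.

## Microvascular network analysis

The synthetic generator emulates a mouse-cortex block: a jittered cubic
capillary lattice (default 6×6 columns, 60 µm pitch, radii uniform in
1.6–2.8 µm) spanning 1100 µm of depth, plus 2+2 penetrating
arteriole/venule trunks tapering linearly from their pial radii (12 and
15 µm) to 3.5 µm, attached to the lattice at every depth level. The 60 µm
pitch puts the outer surface-to-volume ratio at ~2×10⁴ m²/m³ and the
capillary share of exchange surface at ≈ 7× the rest, the right orders for
real cortical networks. What it does *not* emulate: real topology
(loops/branching statistics), Strahler-ordered radius hierarchies, pial
surface vessels, or measured boundary conditions — so network tests verify
conservation laws, orderings and capillary dominance, not absolute
published capacities. Boundary pressures default to 8000 Pa at arteriole
roots and 2000 Pa at venule roots; classification depends only on the
pressure ordering, not the absolute values.

Flow: nodal Poiseuille solve, conductance g = πr_v⁴/(8μ_app·l_v), sparse
direct solve with Dirichlet pressure rows eliminated; transmural filtration
is neglected in the blood-flow balance. Apparent viscosity uses the
empirical in-vivo diameter/hematocrit law (plasma limit exactly 1 at
hematocrit 0), with diameters rescaled by (V_ref/V_RBC)^(1/3) = (92/55)^(1/3)
≈ 1.187 to transfer the human-calibrated law to mouse red blood cells;
discharge hematocrit defaults to 0.45 and a constant-viscosity mode exists
for closed-form checks. Both RBC volumes are configurable since the exact
rescaling used in prior work is not published.

Segments are arterial iff their pressure strictly exceeds the mean pressure
of all segments with r_v ≤ 4.5 µm (ties venous, as specified); capillaries
(r_v < 3 µm) are a separate reporting category that still uses its pressure
label to select the arterial/venous φ-fit. Since the sheath-geometry map
can push r_o slightly beyond a fit's valid range (up to ~21 µm for the
largest lumina), r_o is clamped into the range for coefficient assignment.

Depth aggregation uses six layers (five of 200 µm, one of 100 µm). Segment
surfaces are split across layers in proportion to the z-overlap of their
endpoint span, so layer capacities (ΣS·L_p, ΣS·C_M) sum exactly to the
network totals; horizontal segments are assigned wholly to their containing
layer. Averages are surface-area-weighted. Table-style summaries (ζ outer
and lumen volume fractions, S/V ratios) assume cylindrical segments; a
degenerate bounding box yields NaN volume normalizations rather than a
division error.

Polyline simplification is a hand-written 3-D Douglas-Peucker (established
geometry libraries only simplify in 2-D) with the local vessel radius as
tolerance; endpoints and topology are preserved and the operation is
idempotent.

## Numerical choices and tolerances

* Area conservation per realization: relative 1e-9 (shoelace sums reach
  ~1e-12).
* Interior-node mass defect relative to boundary inflow: < 1e-8 (direct
  solver reaches ~1e-13).
* Zero-length Voronoi ridges (degenerate vertices on lattices) are dropped
  from edge statistics; they carry no length.
* Gamma fits to cell areas use MLE with location fixed at 0, which
  preserves the sample mean exactly; φ_g fits are plain normal MLE.
  Zero-variance samples raise.
* Hexagonal closed form at A = 50 µm², d = 20 nm is 0.0052643 (0.0035487 at
  110 µm²); two-digit reports round the first to 0.0053 while 0.0052 is its
  truncation — comparisons are made within one unit of the last reported
  digit.
* Ensemble sizes: 200 realizations × 500 cells for reference-class means
  (Monte-Carlo SE ≈ 0.07 %, so observed 1–3 % deviations from reference
  values are systematic and within the 5 % band); 8 radii × 10
  realizations for closure refits; 10⁵ pooled cells for the Poisson oracle.

## Known limitations

* Voronoi cells are a geometric idealization; real endfeet overlap in
  plane, and overlap enters only through l_g ≥ h_ES.
* The gap width is uniform; spatial d_g variation would change L_p (∝ d³)
  disproportionately.
* The projection convention is a reconstruction; the capillary 25 → 50 µm²
  doubling is convention-dependent and checked as a soft (±25 %) property.
* The empirical radius→area coefficients are anchored surrogates, not the
  original regressions.
* The synthetic network is a structural stand-in; absolute capacities of
  real mouse networks are out of scope.
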