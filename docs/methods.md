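# Methods

## 2D vertex model

The tissue is a fixed hexagonal tiling: cells are hexagons, vertices are
shared, and neighbour relations never change (no T1 transitions, no
division or extrusion).  Lengths are dimensionless, in units of the square
root of the common target area, so every lattice cell starts with area
exactly 1 and perimeter 6·√(2/(3√3)) ≈ 3.72242.  The energy per cell is
(a − 1)² + k_p (p − p₀)² with k_p = 1 and baseline p₀ = 3.7, slightly
below the hexagon perimeter so the unconstricted lattice carries a small
uniform tension.  Apical constriction multiplies a cell's p₀ by 0.10.
Vertices follow the overdamped flow ṙ = −∇e; all vertices of the
outermost cell ring are immobile, which is how the surrounding embryonic
tissue is represented.

**Lattice and plate.**  Pointy-top hexagons in rows offset by half a cell
width.  The plate is a centered N_x × N_y block: the N_y central rows, and
within each row the N_x cells nearest the tissue midline; when a row's
cells straddle the midline symmetrically both tied boundary cells are
kept, giving the alternating extra cell that makes the plate symmetric
about the AP axis.  For the default 100×60 tissue with a 60×20 plate this
yields exactly 1200 plate cells.  The exterior uses the same uniform
lattice.

**Constriction schemes.**  `uniform`: every plate cell is flagged
independently with probability P_c, sampled in row-major order from a
single seeded generator, so a seed fully determines the pattern.
`hinge`: two bands of `hinge_width` (default 3) plate rows separated by
`hinge_separation` (default 14) rows are flagged with probability P_h
(default 0.5); rows between the bands use a lower probability (default
0.2); the block is centered on the plate's row span.

**Relaxation.**  Two routes to the same minimum:

- `euler`: explicit Euler at Δt = 10⁻⁴ until t_end (default 2000).  The
  energy trace is checked to be non-increasing (tolerance 10⁻⁹ per step);
  a violation restarts the run at Δt/2.  With a stopping force
  (`stop_force`) the step is also halved, up to ten times, whenever the
  energy plateaus before the force target is met — near collapsed cell
  clusters Δt = 10⁻⁴ sits at the oscillatory stability margin and a finer
  step is needed to settle (the inner loop is a numba kernel; a vectorized
  numpy kernel is the tested fallback).
- `minimize`: L-BFGS descent on the identical energy with frozen vertices
  eliminated, followed, for the last decade of convergence, by damped
  Newton iterations on the analytic sparse Hessian.  The hand-off exists
  because the tissue energy is O(10³) while force targets are 10⁻⁶: an
  energy-based line search cannot resolve such steps in double precision,
  but Newton steps on the gradient can.  Newton steps are accepted only if
  they reduce the force norm; rejected steps increase a Levenberg damping
  λ tenfold (from 10⁻⁸), accepted ones decay it.

**Collapsed clusters and smoothing.**  Adjacent constricting cells form
clusters that collapse to a point at the minimum — nothing in the model
(no T1s, no excluded volume) prevents it.  At an exact collapse the raw
perimeter energy has a cone singularity: vertex forces cannot vanish and
no descent converges.  Edge lengths therefore enter the energy as
√(l² + ε²) with ε = 10⁻⁴, which turns collapsed configurations into
smooth stationary points.  The cost is a perimeter error of ~5·10⁻⁸ (an
energy error ~2·10⁻⁹ per intact cell); ε = 10⁻⁵ was tried and makes the
collapse landscape too stiff to converge.  Inverted-cell validation
accordingly tolerates |area| ≤ 10⁻⁹ (a collapsed cell) but rejects
anything clearly negative.  The relaxed honeycomb with p₀ set to the
hexagon perimeter still has max force ≈ 2·10⁻⁷, comfortably stationary.

**Measurements.**  Cell elongation κ and orientation θ come from the
unweighted gyration tensor of the six cell vertices about their mean —
deliberately distinct from the area-weighted image moments used by the
morphometrics module.  Exactly isotropic cells get θ = NaN and are
excluded from angle statistics.  Plate length (along AP) and width are
distances between mean centers of groups of 5 centrally located cells on
opposite plate edges (group size configurable), identified on the lattice
topology so the same physical cells are tracked through relaxation, and
normalized by the same measurement on the relaxed P_c = 0 tissue.

## 3D vertex model

Hexagonal prisms in a flat monolayer, 20 cells along AP × 40
perpendicular by default, periodic along AP (fixed box length equal to
the initial lattice extent; gathered coordinates carry per-slot image
shifts, so periodicity is exact), outermost rows perpendicular to AP
frozen (one row per side).  Lengths are in units of the cube root of the
target cell volume.  Energy per cell: α a_a + β a_b + ½ a_l +
k_p (p_a − p₀)² + k_V (v − 1)² with α = β = 0.5, k_p = 1, k_V = 100.  The
target apical perimeter is 2·6^{1/3}(α+β)^{−1/3} ≈ 3.6342, the equilibrium
apical perimeter of a honeycomb without perimeter elasticity; constriction
multiplies it by 0.10 and is confined to the 3 center rows (the hinge),
each flagged with probability P_c.

Faces (including non-planar lateral quads) are fan-triangulated about
their vertex centroid; cell volume is the sum of signed origin tetrahedra
over the closed, outward-oriented triangulated surface.  The same
decomposition defines the analytic gradient (verified against central
finite differences at 10⁻⁵ relative).  Both the apical edge lengths and
the fan-triangle areas are smoothed at 10⁻⁴ (as in 2D — collapsing apical
loops of constricting cells otherwise create cone singularities in the
perimeter and sliver-triangle area terms where forces cannot vanish).
Relaxation uses L-BFGS to a max-force tolerance of 10⁻³ by default
(diagnostic error on failure); the energy/gradient kernel is numba-JIT
with the vectorized numpy implementation kept as the tested reference.

The initial prisms have volume exactly 1.  Because the surface tensions
slightly prefer v ≈ 0.99, the relaxed P_c = 0 tissue thins by ~1% between
the frozen edge rows and the interior; "flat" therefore means flat at the
few-percent-of-height scale, far below furrow depths (~0.5–0.9).

**Furrow depth** is a convention of this package (no standard metric
exists): mean apical z of non-frozen, non-hinge cells in the 5 rows
nearest each frozen edge, minus mean apical z of hinge cells — ~0 for a
flat tissue, positive for an apically dipping hinge.  The profile table
reports mean apical z per cell row for cross-section plots.

## Morphometrics

Image regions are described by the ellipse with the same normalized
second central moments: aspect ratio √(λ₁/λ₂) of the pixel-coordinate
covariance eigenvalues, orientation of the leading eigenvector against a
configurable reference axis (default image x = AP), folded to [0°, 90°].
Regions under 4 pixels are flagged degenerate.  AC/AE scoring uses the
relative change (final − initial)/initial of a track with threshold 0.20;
an `extrema` baseline (min/max over the track) is available but
first-vs-last is the default.  Dispersion uses the sample (n−1) standard
deviation; CV = s.d./mean.  Junctions are connected runs of boundary
pixels whose 4-connected neighbours are exactly one pair of cells; pixels
seeing ≥3 cells among their 8 neighbours are junction vertices, tabulated
separately (pair membership by 4-connectivity keeps lengths tight; vertex
detection needs 8-connectivity because a triple point's center pixel may
touch its third cell only diagonally).  Junction intensities are means
over the run mask dilated by 1 px (configurable); cytoplasm intensities
over the cell mask eroded by 1 px.

## Synthetic data

Tissues are power (Laguerre) diagrams of a jittered hexagonal site
lattice, built by convex-hull lifting, which gives exact polygons, the
site adjacency, and a rasterization (power-metric argmin per pixel) that
agree by construction.  Elongation bias is an anisotropic metric: the
diagram is computed in coordinates compressed by √(aspect) along the
preferred orientation and mapped back — stretching the lattice itself
does not work, since Voronoi cells of a stretched lattice are clamped by
their diagonal neighbours.  The constricted fraction f_c of sites gets a
negative weight −(1 − √(area_ratio))·Ā (Ā the mean cell area), producing
small cells interspersed among large ones; an optional hinge band adds
weight noise to raise the local area CV.  Junction intensity follows
base − slope·length + Gaussian noise (clipped at 0), emulating brighter
staining of shorter junctions; cell interiors get a cytoplasm level.

Ground truth is recorded from the exact polygons (area-weighted moments),
together with an "as-rendered" variant measured on the half-pixel-eroded
polygon — the continuous analogue of the rasterized region, which loses a
shared 1-px boundary.  Round-trip tests compare raster measurements with
the as-rendered truth on interior (unclipped) cells of ≥300 px; cells cut
by the frame edge are flagged `clipped` because the raster does not erode
at the image border.  Tracks drift geometrically to a target relative
change per class with per-timepoint multiplicative log-normal noise.

What the generator does not emulate: microscope point-spread functions,
illumination gradients, segmentation or tracking errors, cell
rearrangement over time.  Passing round-trip tests therefore demonstrate
the correctness of the measurement code on clean tessellations, not
robustness to real imaging artefacts.

## Problem sizes and defaults

The experiment registry runs each study in two tiers: `full` uses the
study-size lattices (100×60/60×20 in 2D; 16 aspect-ratio pairs with
N_x·N_y ≈ 1200 and a 40-cell margin; 20×40 in 3D); `smoke` uses reduced
lattices (50×30/30×10; 5 pairs at N_x·N_y ≈ 300 with a 20-cell margin;
10×20 in 3D) chosen so every direction-of-effect observation is already
clear at a fraction of the cost.  The quasi-Newton route is the default
for sweeps; Euler/quasi-Newton agreement (final per-cell areas within
10⁻³ at max force < 10⁻⁴) is verified on a 20×12 instance.  Whether the
study averaged multiple seeds per condition is not always stated; drivers
take explicit seed lists and report per-seed values alongside means.

## Known limitations

- No T1 transitions: at high P_c, collapsed constricting clusters are
  represented as geometric points rather than resolved rosettes.
- The 2D α-sweep alignment flip is a direction-of-effect statement;
  per-α angle values at the smoke tier differ from full-size runs.
- The furrow-depth metric, edge-group size (5), hinge separation
  (14 rows) and the 1-row 3D frozen boundary are package conventions
  where the underlying description is qualitative ("several", "~14",
  "outermost").
- The 3D solver targets max force 10⁻³, not the 2D's 10⁻⁶; furrow depths
  at that tolerance are converged to well under the differences the
  analyses rely on.
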