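# Methods

## The experiment

The package runs the standard in-silico test of cranial suture
function: solve the same loaded skull model twice, once with sutures as
a compliant soft tissue and once with the sutures "fused" (assigned
cortical-bone properties), and compare the strain fields.  Two load
cases are modelled — bilateral anterior (incisor) biting and unilateral
posterior (molar) biting — each driven by muscle forces derived from
muscle architecture, with the skull restrained only at the bite point(s)
and the two jaw joints.

All tissues are homogeneous, linear elastic and isotropic; the analysis
is static and small-strain.  These are the stated idealizations of the
experimental design the package reproduces, and all conclusions are
comparative (sutured vs. fused on the identical mesh), which is exactly
the regime where a linear model is informative.

## The skull phantom

Specimen imaging is replaced by a deterministic parametric generator.
The phantom is a plate, optionally bent into a cylindrical arch,
carrying the topological features the experiment needs:

* **Suture bands.** One longitudinal "sagittal" band and two transverse
  bands ("coronal" interdigitated, "lambdoid" straight).
  Interdigitation is a sinusoidal centreline; membership is true
  in-plane distance ≤ w/2 to the sampled centreline, so an
  interdigitated band claims more elements than a straight one of equal
  width (its centreline is longer), and the suture element count grows
  monotonically with both width and amplitude.  Transverse bands use a
  cosine centred on the sagittal midline so interdigitation preserves
  the phantom's left-right symmetry, which the bilateral load case
  relies on.
* **Teeth.** Four cylindrical pegs (two incisor-analogs, two
  molar-analogs): pulp core, tooth body, and a PDL sleeve at least one
  cell wide so the sleeve captures element centroids (0.2 mm, the
  anatomical minimum, is the dataclass default; the phantom spec widens
  it to the grid).
* **Trabecular core.** A mid-thickness layer inside each bone,
  inset from the plate walls and kept one cell clear of suture bands
  and pegs (how trabecular bone meets sutures is not specified by the
  source design; keeping them separated is this package's choice).
* **Node sets.** Single-node bite points at peg tips, TMJ nodes at the
  posterior ventral corners (working = left), lateral muscle-attachment
  patches spanning the zygomatic-arch range on both sides of the
  coronal band, gauge seed nodes (IFS-analog on the coronal band,
  SGS-analog on the sagittal band, PB-analog the dorsal bone node
  farthest from any suture, required ≥ 3 mm), and per-bone surface
  sets.

Meshing is a structured hexahedral lattice, each cell split into six
tetrahedra around the main diagonal; all shared-face diagonals point
the same lattice direction, so neighbouring cells triangulate their
common face identically and the mesh is conforming by construction.
Labels are decided at element centroids in the flat parametric frame,
with precedence tooth/pulp/PDL > suture > trabecular > cortical where
regions overlap.  The optional arch map treats y as mid-surface
arclength and z as radial offset, so the faceted solid's volume has the
closed form L·ny·R₀·t·sin(κ/ny) that the volume-conservation test uses.
The seed only drives optional interior-node jitter (used by the patch
test); the boundary is never jittered, so total volume is
jitter-invariant.

### Why the default phantom is slender

The default is 40 × 20 × 1 mm at 100 × 50 × 3 cells (90 000 elements),
arch 0.7 rad, bands 0.8 mm (= 2 cells) wide.  Early prototypes at
40 × 20 × 4 mm showed far-field per-bone strain shifts of up to ~38%
between variants, an artefact of scale rather than of suture mechanics:
suture-induced strain perturbations decay over roughly one plate
thickness, so with t/L = 0.1 every point of a 10 mm "bone" is
near-field, and millimetre-wide bands are a far larger width fraction
than real 0.2 mm sutures.  Real calvaria run nearer t/L ≈ 0.025 with
sutures well under 1% of bone width; the default phantom adopts that
slenderness (t = 1 mm) and the thinnest bands the two-cells-per-band
meshing rule allows.  At these proportions the far-field insensitivity
that motivates the experiment emerges naturally (worst per-bone change
≈ 16%).

## Muscles and bite statics

Default architecture (placeholders for a generic adult rat, overridable
via YAML or CSV): temporalis-analog 1.1 g, 20°, 1.1 cm, wrapped over
the vault as a single-tension polyline; masseter-analog 1.5 g, 25°,
0.9 cm, four strands per side from the lateral attachment patch to an
insertion on the virtual mandible below the plate.  PCSA uses
ρ = 1.06 g cm⁻³ and σ_m = 25 N cm⁻²; parallel-fibred muscles record
pennation 0 so the cos(0) = 1 path is exact.

The wrapped path emits the closed force system of a frictionless string
(zero net force and moment).  The distal (insertion) point lies off the
mesh on the mandible, and its share is not applied, so the cranium
receives the wrap contact forces plus the anchor pull — in sum, the
tension directed along the final segment.  The identical nodal loads
feed both the FE load cases and the rigid-statics scenarios, making the
two analyses consistent by construction.

The statics module solves the cranium's rigid equilibrium with
unknowns chosen to mirror the FE constraints: unilateral biting is the
full 6 × 6 system (bite force; balancing TMJ x, y, z; working TMJ x, z),
so its solution must coincide with the FE reactions up to solver
tolerance; bilateral biting is the 3-equation sagittal-plane reduction,
checked to 1e-9 on its in-plane equations and to 1e-2 out of plane
(bite/TMJ nodes snapped to a finite mesh sit slightly off-midline, a
genuine small couple the sagittal model cannot represent).

## FE numerics

* Element: TET4, K_e = V·BᵀDB, D from the Lamé parameters
  (ν = 0.5 rejected).  Quadratic TET10 is not implemented; requesting
  `element_order: tet10` raises a clear error.  TET4 is stiff in
  bending — the cantilever study quantifies this (50% → 21% → 7% tip
  error over three refinements against Timoshenko theory) — but the
  suture contrasts of interest are variant comparisons on one mesh,
  where discretization stiffness largely cancels.
* Constraints by elimination; the solver accepts arbitrary prescribed
  values (used by the patch tests) though the experiment only ever
  prescribes zero.
* Reduced system solved by sparse LU (SuperLU); residual on the free
  DOFs must be < 1e-8 relative, and global equilibrium
  (Σ applied + Σ reactions = 0 per axis) is asserted on every solve at
  1e-8·‖f‖₁ with a stiffness-based floor for zero-load cases.
* Strains are recovered per element from centroid-relative nodal
  displacements, so rigid translation yields exactly zero strain;
  measured null-space strain is ~1e-15 per unit displacement.
* Everything is seedless and deterministic; assembly is grouped by
  tissue but summed in fixed element order, so the fused variant is
  bit-identical to relabelling suture elements as cortical bone.

## Strain post-processing choices

* Nodal fields are volume-weighted averages of adjacent element values
  (a convex combination, so nodal values stay within the adjacent
  element range).
* Dominance ratio |ε₁/ε₃| returns a sentinel (NaN + flag) when
  |ε₃| < 1e-3 µε; VTK export encodes the sentinel as −1.
* Difference fields: positive = higher strain magnitude when fused,
  negative = higher when sutured; the relative difference divides by
  max(|ε|_sutured, 1 µε).  The experimental design leaves the exact
  denominator open; the 1 µε floor is this package's choice and is
  recorded in the outputs.
* Virtual gauges integrate over exactly 1 mm² (the rosette footprint):
  surface nodes join in distance order from the seed node, the last
  node entering with the fractional tributary-area weight that makes
  the patch area exact; readings are the area-weighted mean ± SD, and
  patches under 3 contributing nodes are rejected.  Gauge orientation
  is not modelled — principal strains are orientation-free.
* Per-bone summaries average signed ε₁ and ε₃ separately over the
  bone's surface nodes.  Whether such summaries should average
  elements or nodes is open in the source design; this package uses
  nodes.  A bone's surface set contains only nodes all of whose
  adjacent elements are non-suture: at phantom resolution,
  suture-interface nodes are a non-negligible fraction of a bone's
  surface and their averages are dominated by the band, not the bone.

## What the generator does and does not emulate

The phantom preserves the *topology* of the experiment — near-suture
vs. far-from-suture gauge sites, anterior vs. posterior bite points,
bones separated by straight and interdigitated compliant bands, teeth
with PDL sleeves, a trabecular core — and the full loading/constraint
scheme.  It does not emulate anatomical geometry (closed vault,
varying thickness, real suture networks), image-derived heterogeneity,
adaptive meshing, or in vivo strain magnitudes: the open shell is far
more compliant than a closed skull, so absolute microstrain values are
large and only relative contrasts carry meaning.  Passing tests
therefore demonstrate the mechanics of the sutured-vs-fused comparison
and the correctness of the pipeline, not specimen-level prediction.

## Problem sizes and runtimes

Default experiment: 90 000 elements / ~62 000 DOF, two load cases ×
two variants sharing one factorization per variant (~35 s on one CPU).
Verification: patch and rigid tests on 5³/4³-cell jittered blocks,
axial bar 20 × 2 × 2, cantilever study up to 80 × 8 × 8 (30 720
elements).  The coarse test phantom is 60 × 30 × 2 cells (10 800
elements).

## Known limitations

* TET4 only; near-incompressible tissues (ν = 0.49 sutures and PDL) are
  subject to volumetric locking, which inflates their stiffness
  somewhat — conservative for the suture-strain contrasts (the observed
  ~80× concentration is a lower bound in this respect).
* No contact, no dynamics, no activation model, no gape dependence;
  bite force is the maximal static value.
* The mandible is not modelled; insertions are fixed points below the
  plate.
* Report determinism is byte-exact only for identical BLAS/libraries;
  wall-clock timing is deliberately kept out of the report files.
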