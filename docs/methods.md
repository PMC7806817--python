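# Methods

`morphofold` analyzes how the folding pattern of a closed epithelial
surface encodes the 3D shape it assumes when inflated. The pipeline has
four stages — synthetic folded meshes, pressure-driven unfolding, furrow
visualization/removal by smoothing, and morphometrics — each documented
below with its assumptions, parameters and numerical choices.

## The unfolding model

The folded sheet is a triangle mesh treated as a thin, nearly
inextensible elastic membrane under internal pressure. The energy
minimized over vertex positions `x` is

```
E(x) = Σ_edges  k_s / (2 l₀) (l − l₀)²          membrane stretching
     + Σ_hinges k_b (1 − cos(θ − θ₀))           crease regularization
     − p · V(x)                                 pressure–volume work
```

with `l₀` the rest edge lengths and `θ₀` the rest dihedral angles, both
taken from the folded input mesh, and `V` the enclosed volume. A
minimizer of `E` is a quasi-static equilibrium of a pressurized balloon
whose surface metric is pinned to the folded mesh: stored surface (folds
and furrows) can deploy freely, while genuine stretching is paid for at
stiffness `k_s`. This encodes the working premise of the analysis — the
unfolded shape is produced by unfolding alone, not by growth or in-plane
expansion.

Assumptions and limitations:

* **No self-contact.** Fixtures are built so that default-pressure
  equilibria do not interpenetrate; deeply folded inputs at high pressure
  are not protected against passing through themselves.
* **No dynamics.** Only the energy minimum matters; the trajectory is a
  descent path, not a time course.
* **Uniform material.** One `k_s` everywhere; the real cuticle's spatial
  stiffness variation is out of scope.

### Parameters

* `k_stretch` (energy/length, default 1.0) — sets the overall scale; only
  ratios matter.
* `pressure` — the one physically meaningful dial is the nondimensional
  ratio `p·L/k_s` with `L` the mean rest edge length. Default 0.05:
  strong enough to deploy bellows-like folds completely, weak enough to
  keep membrane strain at the few-percent level on tube-like fixtures.
  Drumhead (disk), dome (cap) and coarse origami-tube (Yoshimura)
  fixtures use 0.0125 (`MaterialParams.with_pressure_ratio`): a flat
  membrane spanning a pinned rim balloons by stretching alone, and on
  single-cell-per-facet tessellations the edge-length scale understates
  the structural scale — at 0.05 the parasitic stretching exceeds the
  5%-area premise and washes out the shape signal carried by the folds.
* `k_bend` (energy, default `1e-4·k_s·L²`) — a tiny hinge penalty on
  dihedral deviation from the rest crease angle. It regularizes
  crumpling; it is deliberately too weak to resist unfolding. The
  `1 − cos` form is quadratic for small deviations but periodic and
  smooth: fully closed pleats sit exactly on the ±π branch of the
  dihedral angle, where a quadratic penalty has a discontinuity that
  stalls descent.
* `grad_tol` (default `1e-3·p·L²`) — convergence when the largest
  per-vertex force is three orders of magnitude below the pressure
  forcing scale.

### Minimization

The default solver is a memory-limited quasi-Newton iteration (L-BFGS
two-loop recursion, history 8) with Armijo backtracking, implemented in
the package; plain steepest descent with an adaptive step is available as
`method="steepest"`. Both guarantee a non-increasing energy series at
every accepted step, pinned vertices never move, and both converge to
the same minima (a test cross-checks the final energy against an
independent scipy L-BFGS-B run on the same functional to 0.1%); steepest
descent simply needs two to three orders of magnitude more iterations on
strongly folded meshes, which is why it is not the default.

Open meshes must have their entire boundary loop pinned; the enclosed
volume is then computed against an implicit triangle fan closing the rim
onto its centroid. Since the rim is immobile the fan contributes nothing
to the gradient of any free vertex.

### Correspondence ("rewinding")

Connectivity is frozen throughout, so the map between folded and
unfolded states is the identity on vertex indices. `map_region`
materializes this: a region outlined on the inflated mesh is read back
on any snapshot of the trajectory, including the folded input.

## Smoothing (furrow visualization and removal)

`hc_laplacian_smooth` implements the HC-modified Laplacian scheme:
uniform umbrella smoothing followed by a push-back correction
`β·b_i + (1−β)·mean_j b_j`, where `b` measures drift from a blend of the
original (`α`) and previous (`1−α`) positions. Defaults `α = 0`,
`β = 0.5`, 50 iterations: the standard shrink-resistant regime. Note
that in this formulation `β = 1` applies the *full* push-back (a no-op
at `α = 0`); the uncorrected baseline is the separate
`laplacian_smooth`, and the defining property — HC loses strictly less
enclosed volume than the plain scheme on a corrugated sphere — is
asserted in the tests.

Region-masked smoothing uses per-vertex weights: 1 inside the mask, 0
outside, with a linear ramp over `feather_width` breadth-first rings
(default 2) so furrow-removal does not imprint a sharp crease at the
region border. Weight-0 vertices are held exactly fixed, making masked
smoothing bit-exact local. Boundary vertices of open meshes are averaged
only along the boundary polyline; full umbrella averaging would curl the
rim and fake furrow signal at patch borders.

**Furrow visualization** signs the depth as
`d_i = (x_i − s_i)·n̂_i` (original minus smoothed position, projected on
the smoothed mesh's outward vertex normal): `d > 0` is a ridge, `d < 0`
a valley. Classification first subtracts the median depth: even the
shrink-resistant smoother contracts a closed surface by a small uniform
offset, which would otherwise label every vertex of a featureless
sphere a ridge. The ridge/valley threshold then defaults to 0.2× the
median nonzero |centered d| — a robust scale, since no absolute depth
cutoff is meaningful across fixtures; PLY export colors ridges red,
valleys blue, neutral gray.

**Furrow removal** smooths a masked region of the folded mesh, inflates
original and smoothed variants under identical material parameters, and
reports morphometrics of both plus deltas. Everything is deterministic;
rerunning reproduces reports bit for bit.

## Morphometrics

All measurements use the fixed anatomical frame +Z proximodistal,
+Y dorsal, +X left.

* **Extents** — max−min of vertex projections on an axis.
* **Centerline** — slab centroids marched from the proximal end along
  the local tube direction (step = maximal surface-graph distance from
  the proximal band / `n_slices`, look-ahead window 0.25–1.75 steps,
  heading smoothed 50/50 per step, stop at turns sharper than 45°).
  Marching follows the tube through arbitrary bends, which fixed-axis
  slabs cannot (past ~45° of bend one slab mixes both arms). Not meant
  for self-approaching (U-shaped) tubes.
* **Bend angle** — angle between the endpoint tangents of a global cubic
  fit (in arc length) through the centerline nodes, projected on the
  sagittal plane, signed positive-dorsal. A cubic reads a quarter-circle
  arc to within ~4°; fitting straight lines through end chunks instead
  would average the tangent over the chunk and underestimate a 90° bend
  by over 20°.
* **Branch count** — connected components of the vertex subgraph above
  `height_fraction` (default 0.6) of the axial span, ignoring components
  under 5 vertices. Robust on coarse meshes, unlike local-maximum
  counting.
* **Groove angle** — on a planar cross-section polyline, the interior
  angle between tangent arms 10% of section arc length to each side of
  the groove node; the groove is the sharpest node whose wedge opens
  along the outward surface normal (a valley, not a ridge). Machined
  V-notch plates of 90° and 120° reproduce their angles within 3°.
* **Apex offset** — lateral distance of the highest vertex from the
  pinned-rim centroid, divided by rim mean radius; 0 for an upright
  cone, large for an oblique overhang.
* **Gaussian curvature** — angle deficit over barycentric vertex area.
  The total deficit of every closed fixture equals `4π` to machine
  precision (combinatorial Gauss–Bonnet), the single sharpest check of
  the angle computation; regular cylinder walls give exactly 0
  (developable).

## Synthetic fixtures

The real primordium scans are not publicly deposited, so seeded
parametric generators emulate each folded structure the analysis needs.
All furrows are sinusoidal displacements: the true furrow cross-section
is unknown, and sinusoids make ridge/valley sign oracles analytic.
Generators are deterministic given parameters; `jitter`/`seed` adds
reproducible noise when wanted.

* **Accordion cylinder** (stalk): meridional triangle wave, 12 pleats of
  slant 0.25 over folded height 1.0 ⇒ stored meridian 6.0. Mean radius
  0.8, chosen so the unfolded stalk is slender (length ≈ 3.75 diameters)
  with pleat amplitude ≈ 0.31·radius. At the default pressure ratio the
  inflated/folded extent ratio is ≈ 5.5: full unfolding minus the
  residual crimp that hoop inextensibility leaves in a bellows.
* **Furrowed disk** (cone models): rim-pinned flat disk; furrow rings in
  the annulus 0.25–0.75 of the radius (concentric rings around a vacant
  center — slack stored mid-radius erects a cone, slack pooled at the
  center only mounds). `full_circle` erects an upright cone,
  `semicircle` (rings only at x<0, "outwardly vacant" toward +x) an
  oblique one whose apex sits at ≈ 0.27 base radii laterally, versus
  ≈ 0.05 for full circles.
* **Biased base**: distally-capped tube, proximal ring pinned, 5 ventral
  vs 1 dorsal circumferential furrows blended smoothly at the lateral
  seams. The ventral extra arc elongates that side under inflation and
  tips the tube dorsally ≈ +22°; mirroring the mesh negates the angle,
  and removing the furrows (HC smoothing of the band) drops the bend to
  ≈ +9°.
* **Yoshimura cylinder**: rings alternating in radius and offset half a
  cell, the diamond pattern of an axially compressed tube; ring spacing
  keeps the meridional slant at `height/n_axial` so the folded tube
  stores ≈ its nominal developable height.
* **Cap model**: see below.
* **Notched plate / corrugated plate / corrugated sphere**: analytic
  oracles for the groove angle, the furrow sign, and the HC shrink
  comparison.

### The cap model

The one deliberately *constructed* fixture. Its role is to show that the
decomposition of the branch-forming region — lateral tips already
present as macro-shape, medial tips erected by concentric-semicircle
furrow patches, bottom-surface furrows lifting the underside — suffices
to turn a dome into a four-branched tip under inflation; it does not
reproduce the real anatomy. Construction: a strongly flattened dome
(flattening 0.12) with a rim past the equator (112°, the overhang),
two tall smooth lobes at ±X displaced up-and-outward, two annular
semicircle furrow patches nearer the midline, parallel furrows on the
overhang underside. Under pressure the flat body balloons modestly; the
branch count at height fraction 0.6 reads 4 on the full model and 2
when the medial furrow amplitude is zeroed (the macro lobes survive,
the furrow-built tips do not) — the two-mechanism contrast the analysis
is designed to expose.

### What the fixtures do not emulate

Real primordia have nested multi-scale folds, spatially varying furrow
depth and profile, open anatomical boundaries, and measurement noise
from serial-section reconstruction. Passing tests on these fixtures
shows the *method* behaves as designed (energy descends, area is
conserved, orderings and counts match the mechanism each fixture
isolates); it does not certify accuracy on reconstructed biological
meshes.

## Problem sizes and determinism

Bundled study conditions: accordion 24×64 (≈1.8k vertices), disks 40×64
(≈2.6k), base 24×48 (≈1.2k), cap 56×84 (≈4.7k — the cap grid must
resolve its furrow patches with at least four vertices per furrow
wavelength, or their stored surface is silently absorbed into the global
balloon instead of erupting into branch cones). Each inflation
converges in 1–30k quasi-Newton steps, seconds to a few minutes on one
core. There is no randomness anywhere in the solvers or generators;
seeds only feed optional fixture jitter, so every number in the test
suite and the acceptance report is exactly reproducible.
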