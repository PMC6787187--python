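# Methods

## Continuum model of anchored self-assembly

The cell/fibrin composite is treated as a homogenized membrane: a
compressible Neo-Hookean matrix (the fibrin foam) with an active
contractile contribution of the embedded cells acting in parallel.
Poroelastic pore-pressure effects are neglected — contractility is assumed
to dominate on the time scale of mesh formation.  The stored energy per
unit reference volume is

    U(F) = μ/2 (I_C − 3 − 2 ln J) + λ/2 (ln J)² + U_a(J, η)

with deformation gradient `F_iJ = ∂x_i/∂X_J` (uppercase indices refer to
the reference configuration), `C = FᵀF`, `I_C = tr C`, `J = det F`.

Parameters, with units and defaults:

| parameter | meaning | default | unit |
|---|---|---|---|
| `E` | Young's modulus of the matrix | 1.9 | mN μm⁻² |
| `ν` | Poisson ratio | 0.3 | – |
| `β` | chemo-mechanical stiffness (active stress scale) | 2.0 | mN μm⁻² |
| `η` | activation (contraction intensity), ramped 0 → 1 | — | – |

`μ = E/2(1+ν) ≈ 0.7308` and `λ = Eν/((1+ν)(1−2ν)) ≈ 1.0962` follow.  The
model units (μm, mN) are used verbatim without physical reinterpretation:
the displacement field depends only on `ν` and `β/E`, so the absolute
stress scale does not affect any reported shape or contact result.

### The two active terms

The package ships two forms of `U_a` because the natural-looking quadratic
form has a degenerate consequence:

* **`as_printed`**: `U_a = η β (ln J)²`.  This term is minimised at
  `J = 1`, so `F = I` is a stress-free global minimiser for *every* η —
  the sheet never contracts.  The solver reproduces this null solution to
  machine precision (an analytic regression test, not a physics
  prediction).
* **`active_pressure`** (default): `U_a = η β (J − 1)`, whose first
  Piola–Kirchhoff contribution is `η β J F⁻ᵀ`, i.e. a constant isotropic
  active Cauchy tension `σ_a = η β I`.  This is the minimal one-term
  change for which activation actually drives contraction, with β acting
  directly as the contractile stress scale.  Its homogeneous equilibrium
  has a closed scalar form (below) used as an independent solver oracle.

A freely contracting homogeneous sheet with `F = λ̄ I` satisfies

    μ (λ̄² − 1)/λ̄³ + 3 λ ln λ̄ / λ̄³ + η β = 0,

solved by bracketed root finding to 1e-12; at the default parameters and
full activation λ̄ ≈ 0.797.  Because the isotropic stress-free state also
satisfies the plane-stress conditions, the finite-element solution of a
pillar-free, traction-free sheet must reproduce λ̄ — the package's primary
end-to-end solver check (measured agreement 0.02% at 40 μm elements).

### Plane stress

The sheet is thin (~25 μm) relative to its extent, so plane-stress
conditions are assumed: at every element the out-of-plane stretch λ₃
solves `σ₃₃ = 0`.  The residual `μ(λ₃² − 1) + s(J₂ λ₃)` (with
`s = λ ln J + η β J` in the default mode) is strictly increasing in λ₃, so
the root is unique; it is found by a safeguarded vectorised Newton with
bisection bracketing in [1e-3, 1e3], to an absolute tolerance of
1e-12·(μ+λ+β).  The element tangent uses the exact condensation of λ₃
(the λ₃-sensitivity term), keeping Newton quadratic.  The strain measure
`E_IJ = F_iI F_jJ − I_IJ = C − I` is reported alongside the conventional
Green–Lagrange `(C − I)/2`.

## Discretisation and solver

* **Mesh.** Linear (constant-strain) triangles, one quadrature point.  The
  mesher is a structured cross-split grid (each cell split into four
  triangles through its center) with nodes within half a cell of a pillar
  circle snapped radially onto it, coincident nodes merged, triangles with
  centroids inside a disk removed, and two safeguarded Laplacian smoothing
  passes.  This construction is invariant under the layout's reflections
  and rotations, which is what makes the solved displacement field D4
  symmetric to machine precision on symmetric layouts — a property a
  generic Delaunay mesher does not provide on grid point sets.  Hole
  boundaries are inscribed polygons of the circles; the area deficit is
  quadratic in element size (0.3% at 50 μm elements on the 4 × 4 layout).
* **Contact.** Micropillars are rigid and frictionless.  Each node carries
  a penalty on its signed gap `g = ‖x − c‖ − r`: a quadratic wall of
  stiffness `k = 10³ μ h` (h the element size) for `g < −w`, a cubic toe
  on `(−w, 0)` making the force C1 and the energy C2 at contact onset, and
  nothing for `g ≥ 0`.  The toe width `w` is half the penetration
  tolerance (0.1% of the pillar radius).  The smoothing exists because the
  initial mesh conforms to the pillar circles: with a kinked penalty,
  hundreds of nodes sit exactly at the kink at the first load step and
  the Newton line search stalls on active-set chatter.  Penalty stiffness
  is doubled (≤ 5 times) if a converged step exceeds the penetration
  tolerance; at defaults the 4 × 4 benchmark converges with max
  penetration 0.011 μm ≪ 0.2 μm without any doubling.
* **Rigid-body regularisation.** The traction-free sheet floats before
  contact engages; weak springs (stiffness 10⁻⁶ μ h per node) to the
  reference positions remove the null space while perturbing displacements
  at the 10⁻⁶ level.  They are part of the reported equilibrium, not
  subtracted, and are symmetric, so they do not bias any symmetry check.
* **Continuation.** Activation ramps through 20 uniform steps by default.
  Each step is solved by Newton with backtracking Armijo line search
  (c₁ = 10⁻⁴) on the total potential; the tangent is analytic and
  verified against finite differences in the tests.  Near detachment
  events the tangent can become indefinite; a Levenberg diagonal shift is
  then escalated until a descent direction is found and relaxed after
  acceptance.  If a step still fails it is bisected (≤ 8 times).
  Convergence: residual ∞-norm ≤ 10⁻⁸ · max(step-start residual, μ h),
  with an absolute floor of 10⁻¹² μ h.  Everything is deterministic —
  identical inputs give bitwise-identical trajectories.

## Geometry conventions

Coordinates are reference-configuration micrometres, origin at the
lower-left corner of the substrate.  `build_square_layout` places an
n×n grid at pitch = diameter + interval.  When substrate bounds are given,
the grid must fit with a margin of interval/2 per side — the rule under
which a 16 × 16 grid of 400 μm pillars at 200 μm interval exactly occupies
a 1 × 1 cm substrate (and 17 × 17 does not), reproducing the 13.57 μL
interspace volume.  When bounds are absent they default to the pillar-disk
hull expanded by one full interval per side (4 × 4 → 2600 × 2600 μm); the
tissue skirt outside the boundary pillars is visible in cross-sections of
fabricated meshes but its exact extent is not documented, so the margin is
a package choice, configurable per layout.

Postprocessing partitions the template into **junction** disks (radius
interval/2 at the interstitial points equidistant from four pillars) and
**contracted** ellipses (mid-strut regions centered between adjacent
junction centers, long semi-axis pitch/2 − r_j along the strut, short
semi-axis r_j/2).  Both are graphical annotations in the source imagery
with no printed dimensions, so only orderings of region statistics — not
their magnitudes — are treated as checkable claims.  Membership is by
reference centroid.

## Contact morphology: what detaches and what does not

Along the ramp the inner-pillar contact counts fall monotonically (32 → 4
per pillar at 50 μm elements) as the mesh openings enlarge, and at full
activation the boundary pillars carry > 99% of the total contact load —
the anchoring picture of ASA.  However, the inner pillars do not shed
their last contact nodes in this model: a grazing wrap (penetration
~3·10⁻³ μm, a few per mille of the load) persists on each inner pillar's
outward-facing flank, where the taut sheet between the inner pillar and
the neighbouring boundary pillars drapes over the circle like a rope on a
pulley.  The effect is mesh-converged (identical gaps at 50/40/33 μm
elements) and is not an artifact of the substrate margin (smaller margins
increase it).  A 2D plane-stress membrane in tension must press on any
convex obstacle its boundary wraps; complete detachment would require
either a 3D model (the sheet can also slide up the pillar) or zero wrap
angle.  Reports therefore state both the per-pillar contact counts and
the contact-force split, and "detached" is defined strictly as zero
contact nodes.

## Synthetic vessel scenes

The generator emulates a stained cross-section of the device-tissue
interface as three channels on a pixel grid: lumen disks (endothelial
marker, "green"), perfusion fill on a flagged subset ("red"), and
perimeter annuli on a flagged subset (α-SMA, "sma").  Defaults mirror the
measurement context the statistics come from: 220 vessels mm⁻² (1 mm²
scene, 2 μm pixels, 8 μm lumen radius), 50.4% perfused, 65% PVC-covered.
Placement is hard-core (no overlaps, with a margin for the annuli) so
connected-component counting is unambiguous; all randomness comes from a
single seed, and every statistic the quantification module measures is
recorded as ground truth at generation time (both count-based and
pixel-based perfusion, which differ when radii are polydisperse).

Optional degradation applies a Gaussian blur then per-pixel Gaussian
noise, independently per channel.  What passing the closed loop shows:
the quantification arithmetic is exact on its own definitions, and robust
to moderate acquisition noise (±3 percentage points at noise σ = 0.05 of
the signal).  What it does not show: performance on real histology —
merged or collapsed lumina, staining gradients, erythrocyte
identification and section artefacts are all outside the generator's
scope, and lumen identification on real images should be supplied as
manual masks.

PVC coverage needs an operational criterion (none is standard): a vessel
counts as covered when ≥ 10% of its 2-px-dilated perimeter ring is
SMA-positive.  Both parameters are configurable and recorded in outputs.

## Problem sizes and runtime

The default benchmarks are sized for a single CPU: the 4 × 4 contraction
benchmark uses 50 μm elements (~4.0k nodes, 7.2k triangles; ~40 s), the
pillar-free oracle comparison 40 μm elements (~1.3k nodes; ~25 s), and the
synthetic scenes 500² pixels.  Mesh-refinement checks compare 100 μm vs
50 μm elements (probe displacements move < 2%), and the solver has been
exercised down to 33 μm elements with identical contact morphology.

## Known limitations

* 2D plane stress: no vertical sag, gravity, or pillar-height effects;
  the grazing inner-pillar contact discussed above is the main observable
  consequence.
* The penalty contact is not an exact constraint (bounded ~0.01 μm
  penetrations at defaults).
* The active term is isotropic and spatially uniform; no cell-level
  contractility, fiber anisotropy, remodelling, or viscoelasticity.
* Quantification treats each connected lumen component as one vessel;
  merged cross-sections in dense fields would be undercounted relative to
  manual annotation.
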