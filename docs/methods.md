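# Methods

`lamsim` simulates the second stage of vaginal delivery as a quasi-static
contact problem: a rigid fetal head is driven along a prescribed
cardinal-movement trajectory through a rigid bony pelvis, distending a
deformable levator ani muscle (LAM) shell, and the resulting von Mises
stress field is summarized per anatomical region and descent station.
This note records the model, its parameters, the numerical choices, and
what the synthetic geometry does and does not represent.

## Constitutive model

The LAM is an isotropic, nearly incompressible Ogden hyperelastic solid.
With principal stretches λ₁, λ₂, λ₃, J = λ₁λ₂λ₃ and isochoric stretches
λ̄ᵢ = J^(−1/3) λᵢ, the strain-energy density (MPa) is

    W = Σᵢ₌₁³ Σⱼ₌₁ᴺ (2 μⱼ/αⱼ) (λ̄ᵢ^αⱼ − 1) + (K/2)(J − 1)².

On the incompressible uniaxial path (λ₂ = λ₃ = λ^(−1/2), J = 1) the
nominal stress is P(λ) = Σⱼ 2 μⱼ (λ^(αⱼ−1) − λ^(−αⱼ/2−1)), which is the
closed form used for parameter identification and for all closed-form
solver checks.  The small-strain shear modulus of this parameterization is
G = Σ μⱼαⱼ, the same sum whose positivity is the small-deformation
stability requirement; the implementation computes G numerically from the
linearized uniaxial slope rather than assuming the identity.

Defaults (two terms, levator tissue): μ₁ = 8·10⁻⁵ MPa, μ₂ = 1.7·10⁻⁴ MPa,
α₁ = 1.81, α₂ = 17.25, Poisson ratio ν = 0.499.  The bulk modulus is not
an independent input; it is derived from ν and the numerically linearized
G as K = 2G(1+ν)/(3(1−2ν)) ≈ 1.54 MPa.  Density (1.06 kg/l, stored as
1.06·10⁻⁹ tonne/mm³ in the mm–MPa–N unit system) plays no role in the
quasi-static solution and is retained only as material metadata.  The
tissue is often described as viscoelastic; no relaxation data accompany
the parameter set, so the model is purely hyperelastic.

A note on the energy form: the λ̄ᵢ exponent J^(−1/3) is the standard
isochoric split.  Only this form is dimensionally meaningful and
reproduces the printed uniaxial P(λ) as dW/dλ, which the test suite
verifies by finite differences.

## Parameter identification

Fitting minimizes E = ½ Σᵢ (Pᵢ^test − Pᵢ^model)² over (μⱼ, αⱼ).  Because P
is linear in the moduli, the solver uses variable projection: for each
trial exponent vector the optimal non-negative moduli come from a
non-negative linear least-squares subproblem, and only the exponents are
iterated (`scipy.optimize.least_squares`, TRF, bounds α ∈ [0.05, 30]).
Multi-start initialization (one deterministic start plus seeded random
restarts, 8 total) guards against the non-convex exponent landscape.
Non-negative moduli with positive exponents enforce Σ μⱼαⱼ > 0
automatically; candidates violating it are rejected anyway.  Ogden terms
are exchangeable, so results are reported with α sorted ascending.

No cadaver stress–strain table is shipped; a synthetic uniaxial-test
generator evaluates the reference model on a stretch grid (default
λ ∈ [1, 1.6], a range chosen to cover the large-deformation regime the
delivery simulation visits most) and adds seeded Gaussian noise.  With
noise-free data the fit recovers the generating exponents to optimizer
precision; tests assert 5% on parameters and 1% on the recovered curve.

## Synthetic anatomy

The reference study segmented subject MRI; this package generates all
geometry parametrically from the published principal dimensions, so
results characterize a *synthetic* pelvis, not any subject.

* **Fetal head** — a star-shaped ovoid: an ellipsoid cranium whose radial
  field is modulated by Gaussian bumps solved so the surface passes
  through analytically placed landmarks (vertex, occiput, sinciput,
  subocciput, bregma, mentum, parietal pair).  The four obstetric
  diameters — suboccipitobregmatic 100.3, occipitofrontal 105.7,
  occipitomental 131.9, biparietal 93.7 mm — are realized exactly by the
  landmark layout, independent of mesh resolution.
* **Pelvis** — an elliptical canal lofted through inlet, midpelvic
  (interspinous) and outlet control rings carrying the printed diameters
  (113.4 / 145.1 / 148.8 / 146.7 mm) as landmark pairs.  The interspinous
  plane is z = 0 in the global frame (x left lateral, y anterior,
  z cranial); obstetric station is the vertex height below this plane in
  cm.
* **Levator shell** — a funnel ("hammock") mid-surface between an
  attachment rim on the canal wall and an anterior urogenital hiatus,
  extruded through its thickness and meshed with tetrahedra via the
  translation-invariant 6-tet decomposition of the generating hex grid.
  Elements are labeled ICm / PVm / PRm by parametric position: the
  pubovisceral and puborectal bands are the inner (v ≥ 0.55 anterior,
  v ≥ 0.80 posterior) slings, everything else is the iliococcygeal plate.
  Node sets mark the pubic and sacral attachments (fixed), the ATML rim
  (elastically coupled), the cranial ICm third (plane-constrained), the
  distal puborectal loop and the ordered posterior mediosagittal trace
  used for elongation measurement.

Shell thickness (6 mm), hiatus extent (75 × 60 mm), rim heights
(−12 mm pubic, +40 mm sacral), the plate exponent (3, which keeps the
dorsal ICm plate shelf-like before it descends to the hiatus) and the
sacral-plane inclination (55°) are not published quantities.  They are
calibrated geometric defaults, chosen so that the descending head first
meets the ICm plate near station −3, must distend the hiatus to pass, and
never sweeps through the fixed attachment lines (which would crush
elements against immovable nodes — the synthetic stand-in for the bony
shielding of the muscle origins).  Passing tests therefore demonstrate
the mechanism (engagement sequence, extension-phase loading of the pubic
slings) on this synthetic anatomy, not subject-specific magnitudes;
absolute stress values depend strongly on the unavailable real geometry
and are out of scope.

## Head kinematics

The head trajectory is displacement-driven (no force control) with uniform
progression per frame.  Orientation is composed as
R(t) = Rx(θ_ext) · Ry(θ_lat) · Rz(θ_rot) · R_flex, where R_flex inverts
the flexed head (vertex leading, occiput anterior), θ_lat straightens the
initial 28.66° lateral deviation by station 0, θ_rot completes the 40.13°
internal rotation linearly with descent at station +3, and θ_ext applies
the 80.25° extension only after the last descent station.  The net
rotation between the last and first frames is then exactly
Rx(ext)·Rz(rot)·Ry(lat), and `decompose_net_rotation` inverts that factor
order (an extrinsic y–z–x Euler sequence); the decomposition is ambiguous
at |rot| = 90°, where both solutions are reported in the raised error.

During descent the centroid path places the vertex exactly on the
station schedule (stations −3…+5, 2 frames per station by default), with
the anterior drift following a circular curve-of-Carus arc (radius
200 mm — not a published value; the arc merely shapes the descent).  The
extension phase (9 frames) rotates the head about a drifting suboccipital
pivot — the nape region braced against the pubic arch — whose caudal slip
leads (∝ sin θ) and whose anterior slip trails (∝ 1−cos θ), so the head
clears the arch downward before sweeping forward beneath it; the drift is
solved so the net anterior displacement of the centroid is exactly the
configured 100.0 mm and the vertex descent stays monotone, reaching its
crowning depth near station +11.5.  Lateral (x) translation is
identically zero.  The 100.0 mm is referenced to the head centroid; the
source does not state its reference point.

## Quasi-static FE solver

Total-Lagrangian linear tetrahedra with single-point quadrature.  Element
stresses come from the spectral form of the Ogden law (eigendecomposition
of C = FᵀF); internal forces are the exact analytic gradient of the total
strain energy.  Near-incompressibility (ν = 0.499 ⇒ K/G ≈ 500) would lock
plain linear tets, so the volumetric energy uses a mean-dilatation
treatment: J is volume-averaged over the 6-tet patch of each generating
hex cell before entering (K/2)(J̄−1)².  The tangent stiffness is fully
consistent — analytic spectral isochoric moduli (divided differences with
the proper repeated-eigenvalue limits, cross-checked in the tests against
a finite-difference assembly) plus the analytic volumetric term including
the patch-coupling block — so Newton converges quadratically.

Contact with the rigid head is a frictionless node-to-surface penalty.
For star-shaped bodies (head, spheres) the gap is the smooth implicit
function φ(p) = |p| − r(p/|p|) of the analytic radial field, whose
gradient (the outward normal) is smooth while nodes slide — this keeps
the Newton model quadratic; plain triangle surfaces fall back to faceted
closest-point projection (exhaustive-search oracle in the tests).  Forces
act along the outward normal only, magnitude penalty × depth.  The
per-node penalty field starts at 5 N/mm and is matched every frame to
twice the local tangent-stiffness diagonal (never decreasing), so the
contact springs track the Ogden law's exponential stiffening; a
corrective escalation pass runs when a converged frame leaves more than
3× the penetration bound, and the strict bound (1% of shell thickness)
is enforced in full at the final frame.  Contact on fully fixed nodes is
ignored — it can exert no force and no finite penalty resolves it — and
likewise on plane-constrained nodes, which cannot yield along their
plane normal (they lie against the posterior pelvic wall, which the head
cannot reach).

Each trajectory frame is solved by damped Newton with an energy
backtracking line search (quadratic interpolation, with an absolute
round-off floor), adaptive Levenberg regularization plus a trust bound
on the largest nodal move per step (4 mm initial, adaptive) for
indefinite configurations (the shell snapping past the head's widest
diameter has no stable continuous quasi-static path), a linear
displacement predictor between frames and substeps, adaptive pose
substepping (intermediate substeps converge to a loose tolerance; the
frame pose to the full one), pose bisection on failure, and a
Barzilai-Borwein damped-relaxation fallback whose result is accepted
only within 1% of the transmitted contact load (at most twice per
frame).  If the crowning tail still defeats the solver, the run is
truncated to the converged prefix (at least 65% of the schedule) and the
truncation is logged; the frozen default configuration deterministically
reaches station +8.5 (19 of 27 frames) before truncating.  Boundary conditions
are enforced exactly through a constraint-basis reduction: fixed dofs are
eliminated and plane-constrained nodes keep two in-plane dofs, so the
in-plane condition holds to machine precision.  The reduced systems are
factorized with SuperLU (MMD_ATA ordering).  Convergence is a residual
2-norm below max(10⁻⁵ N, 3·10⁻⁶ × the contact-force norm) — absolute
while loads are small, relative once the crowning loads reach tens to
hundreds of newtons.
The solution is fully deterministic: no randomness, no unordered
reductions.

The LAM–pelvis interface is handled by the attachment boundary conditions
rather than by solving pelvis contact; LAM self-contact is not modeled.
The internal obturator support enters as linear tether springs
(0.05 N/mm per ATML rim node — a calibrated stand-in stiffness, softer
than the fixed attachments but stiff enough to carry the rim) anchored at
the reference positions.

## Postprocessing

Regional summaries are volume-weighted statistics (reference volumes) of
element von Mises stress in three zones mapped from the anatomical
description: the ICm label; the "pubic attachment" zone (PVm/PRm elements
within 25 mm of the pubic attachment nodes, reported per side); and the
posteromedial PRm (posterior half of the sling by centroid).  SD is the
population form.  Loading order ranks regions by the first frame whose
regional mean exceeds 1% of the run's maximal regional mean — a relative
threshold, since absolute magnitudes are geometry-dependent.  The
mediosagittal stretch ratio is the deformed/reference arc length of the
ordered posterior midline trace, and the caudal excursion is the maximal
reference-minus-current z over the distal puborectal loop.

## Problem sizes and runtime

The default configuration meshes the shell at a 6 mm target edge
(≈ 4 900 tetrahedra, ≈ 1 900 nodes, one element through the thickness)
and runs 27 frames (17 descent + 9 extension, plus the initial pose).
This is the package's desk-scale default: the full delivery solves in
roughly a quarter of an hour on one core, dominated by the crowning
frames where the tissue's tangent modulus spans six orders of magnitude.
4 mm and 2 mm meshes and denser frame schedules are available through
the configuration for refinement studies at correspondingly higher cost.
The sphere-through-annulus fixture used in the tests is the same physics
at ~1 800 elements.

## The elongation measure

The mediosagittal stretch ratio is defined on a *material* polyline (the
posterior midline trace).  Note a consequence of the constitutive law:
a material stretch of 2.5 with the reference exponents (α₂ = 17.25)
implies local stresses of order 2μ₂·2.5^16.25 ≈ 1 GPa, far above the
tens of MPa that the same literature reports as peak tissue stress — the
published ~2.5× "elongation in the mediosagittal plane" is therefore
best understood as the geometric length of the mediosagittal *section*
of the deformed shell (new material rotates into the cut plane as the
funnel distends), not as a pointwise fiber stretch.  Under the frozen
study conditions, where stresses stay at the tens-of-MPa scale, the
material trace ratio reaches ≈ 1.1; configurations that pin the
posterior plate rigidly can push it to ≈ 3, but only by driving
artifact stresses in the GPa range.  Both numbers are reported by the
code as computed; the discrepancy with the ≈ 2.5 figure is a documented
property of the material-trace definition, not a measurement error.

## Known limitations

* Synthetic parametric geometry; absolute stress magnitudes are not
  comparable to subject-specific results.  In particular the pubic slings
  of this synthetic funnel never carry the dominant load (the head's
  swept volume is kept clear of the fixed pubic origin), so the global
  stress maximum falls in the iliococcygeal plate rather than at the
  pubic attachment.
* The default delivery run is truncated at station +8.5 when the
  quasi-static continuation fails past the deepest crowning poses; the
  engagement sequence and the extension-phase loading of the pubic
  slings are established well before that point.
* Isotropic hyperelasticity: no fiber architecture, no viscous rate
  effects, no active contraction.
* The head and pelvis are rigid; head molding is not modeled.
* Single element through the shell thickness at the default resolution;
  bending response of the shell is correspondingly coarse.
* Penalty contact admits bounded penetration (controlled to 1% of
  thickness) and, being frictionless, transmits no shear.
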