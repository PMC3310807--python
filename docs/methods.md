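# Methods

## The model

`plaquefem` analyses an idealized 2D cross-section of an atherosclerotic
artery under luminal blood pressure. The cross-section is a half model cut
along a symmetry line:

* **arterial wall** — the annulus between the healthy internal (3.6 mm) and
  external (4.0 mm) diameters, centred at the artery axis;
* **fibrous plaque** — fills the interior of the internal circle around a
  circular **lumen** whose diameter encodes the degree of stenosis and whose
  centre is shifted 0.5 mm along the symmetry axis away from the plaque;
* **lipid pool** — a 140° crescent of 0.35 mm thickness concentric with the
  lumen, its inner face a distance `d_fc` (the **fibrous cap** thickness)
  from the lumen surface;
* **calcification agglomerate** — an optional 140° crescent inside the
  lipid, from depth `d_cg` (the **calcification gap**) down to the lipid's
  outer face, so its thickness is `d_cag = 0.35 − d_cg` mm. Its elastic
  moduli come from a volume-fraction rule of mixtures over fibrous tissue
  (α = 5%), lipid (β = 20%) and micro-calcium (γ = 75%), giving
  E_r = 9452.7, E_θ = 9500.2, G_rθ = 9475.2 kPa, or from an explicit
  modulus when the agglomerate stiffness is swept.

Equilibrium is solved with small-strain linear plane-stress finite
elements (six-node triangles, three-point Gauss rule, sparse LU with one
iterative-refinement step). The luminal pressure (14.6 kPa by default)
acts as a dead normal traction on the undeformed lumen; symmetry edges are
constrained in their normal direction; one outer-wall node on the symmetry
line, on the plaque side, is pinned along the axis to remove the remaining
rigid translation (its reaction vanishes by symmetry, and the pin choice
defines the frame in which deformations are reported). The quantities
reported per model are the **critical stress** σ_cr (peak maximum
principal stress over the fibrous cap, recovered at integration points
without nodal smoothing), the **cap deformation** D_max (peak displacement
magnitude over cap nodes), and the pressure-normalized peak
circumferential stress σ/P. Rupture is flagged when σ_cr exceeds 300 kPa;
a cap thinner than 65 μm carries an independent thin-cap flag.

## Interpretation choices the printed data forced

Two aspects of the published configuration are under-determined, and the
package resolves both by internal consistency of the printed numbers; the
alternatives remain selectable.

**Stenosis convention (default `area`).** The constant-lipid model family
states that the lipid stays fixed while the shrinking lumen thins the cap,
and prints the pairs (70% stenosis, cap 0.05 mm) and (90%, 0.48 mm). With
a diameter-based convention, L = (1 − s)·3.6, a fixed lipid predicts a
0.41 mm cap at 90% — inconsistent. With an area-based convention,
L = 3.6·√(1 − s), it predicts 0.467 mm at 90% and, inverted, a 0.905
stenosis for a 0.48 mm cap: consistent to within printing precision. The
area convention also puts the fine mesh of the 70% crescent model at
~1.4–1.7 × 10⁴ elements, the order of the published counts. Sweeps couple
`d_fc` to stenosis through this fixed-lipid relation
(`stenosis_for_cap_thickness`); the diameter convention remains available
via `PlaqueGeometrySpec(stenosis_convention="diameter")`.

**Material model (default `effective_isotropic`).** The tissue table is
orthotropic with very soft radial moduli (fibrous tissue E_r = 50 vs
E_θ = 1000 kPa). Under that reading the published deformations cannot be
reproduced: radial compression of the soft-radial tissue alone exceeds the
printed thick-cap deformation (0.0281 mm) threefold in any rigid frame,
and the thin-cap value comes out 0.45–0.59 mm against 0.390. Treating
each tissue as isotropic at its circumferential (fibre-direction) modulus
with the printed in-plane Poisson ratio (ν = 0.01) reproduces the four
printed reference values simultaneously — σ_cr 349.8/26.8 kPa against
331/28.7, D_max 0.3795/0.0257 mm against 0.390/0.0281 — and the response
surface extrema within a few percent. The study layer therefore defaults
to this effective isotropic reading; the full orthotropic constitutive
path (local radial–circumferential axes taken from the artery centre,
classical rotation of the reduced stiffness) is implemented, tested and
selectable via `material_model="orthotropic"`. The out-of-plane ratio
ν_rz = 0.27 is stored but enters no plane-stress equilibrium; a plane
strain toggle exists as a diagnostic.

## Geometry construction

All crescent interfaces are circles about the lumen centre, so in
lumen-centred polar coordinates `(r, φ)` every region is a radial interval
depending only on φ — the form both the exact-area calculations
(closed forms plus quadrature) and the mesher consume. The lipid crescent
ends in **cosine-taper caps**: over a taper arc (~17°, set so the tip
closes at a ≈37° boundary slope), the half thickness decays as
cos(πΔ/2w). The taper joins the body tangent-continuously — no corner, so
no artificial stress concentration where the cap shoulder meets the
crescent end — and closes at a blunt wedge buried in fibrous tissue ~87°
away from the cap apex. A semicircular end-cap was rejected because its
boundary turns radial at the widest point, which a ray-structured mesh
cannot follow at bounded element aspect ratio. The agglomerate ends with
flat radial cuts at ±70°, inside soft lipid, away from the cap; any local
concentration there does not touch the cap-restricted outputs. Region
polygons are exportable (GeoJSON) via shapely; exact region areas carry a
partition identity (solid areas sum to half-annulus minus half-lumen to
quadrature precision) that the tests assert.

## Meshing

The ray-structured mesher draws rays from the lumen centre; since all
interfaces are radial intervals, the grid conforms exactly to every
material boundary and is deterministic bit-for-bit. Radial subdivisions
are graded geometrically but capped at 2.2 × the local angular arc length,
so cell aspect ratios stay bounded for any lumen size; the taper's lipid
layers fade to uniform and are pairwise-merged as the thickness shrinks,
collapsing on a single tip node. Quads split along the shorter diagonal
with hysteresis (near-ties keep a consistent direction, avoiding a
zigzag stress-recovery artefact). Midside nodes on the lumen and outer
wall are snapped onto the exact circles (curved quadratic edges).

Refinement levels target an in-plane cap element size of 0.5 / 0.25 /
0.125 × `d_fc` (coarse / medium / fine) with 4 / 6 / 9 layers through the
cap and at least three through the gap. This is one notch finer than a
nominal 1.0 / 0.5 / 0.25 ladder: at the nominal sizing the thin-cap σ_cr
still changed 2.4% between the two finest levels, while the chosen ladder
is grid-independent to 1.5% (the converged value is ≈357 kPa, approached
as 341.7 → 349.8 → 355.1). Mesh quality across the whole sweep family
holds a ≥15° minimum triangle angle and ≤0.85 equilateral-deviation
skewness at every level. Typical counts: ~5 × 10³ (coarse) to ~6 × 10⁴
(fine) triangles for crescent models; the no-lipid 70% model meshes at
7.7 × 10³ fine.

## Verification

* **Closed-form oracle** — the pressurised thick-walled cylinder
  (a = 1.8, b = 2.0 mm): hoop stress converges monotonically to the Lamé
  solution (0.33% → 0.17% → 0.11% across levels), gauss-point profiles
  track A + B/r² within 1%, and crown displacements match to 2 × 10⁻⁴.
* **Patch and invariance tests** — rigid modes are stress-free; rotating
  the model and its boundary conditions leaves principal stresses
  unchanged to 10⁻⁹; the mirrored full model reproduces the half model;
  global reactions balance the applied pressure resultant to 10⁻⁸.
* **Grid independence** — σ_cr and D_max of the thin-cap reference change
  ≤2% from medium to fine (1.52% and 0.01%).

## Numerical choices

Degenerate inputs: a zero calcification gap is valid (agglomerate touches
the cap backing); a gap consuming the whole lipid thickness is rejected;
geometrically infeasible sweep points are recorded and skipped with a
warning, not fatal. Threshold detection interpolates linearly between the
two grid points bracketing σ_cr = 300 kPa and reports D_max at the same
interpolated point; an exact grid hit returns that point; an uncrossed
range returns a flagged no-threshold result. The pulsatile envelope
rescales a reference solution along a two-harmonic waveform template
(peak 107 mmHg, diastolic 70 mmHg) — exact under linear kinematics, so
only the peak affects extrema. The `scale` parameter multiplies every
length; by similarity it leaves stresses invariant, which is also how the
published 3D-scale argument is documented.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` solves the two reference models on the fine mesh,
the two response surfaces on 5×5 grids at the medium level (which is
grid-independent to ~1.5%), and the calcification-gap sweep at medium
with 0.01 mm steps up to 0.12 mm plus a coarse tail to 0.33 mm. The
pipeline is fully deterministic; the seed argument is recorded and feeds
any future stochastic component.

## Known limitations

* The analysis is linear and small-strain with dead loads, as in the
  source study; reported cap deformations (≈0.38 mm) are large relative to
  a 0.05 mm cap, so geometric nonlinearity would matter for a quantitative
  rupture model. No fluid–structure coupling, contact, or viscoelasticity.
* Published deformation values are reproducible only under the effective
  isotropic material reading (above); under the stated orthotropy they are
  not, in any rigid frame.
* The calcification-gap threshold study reproduces the qualitative
  construction — monotone stress rise with the gap, levelling toward the
  non-calcified limit, positive stress–deformation correlation — but
  crosses 300 kPa at a gap of ≈0.077 mm with ≈0.29 mm deformation, against
  printed values of 0.04 mm and 0.165 mm. The printed threshold pair is
  internally inconsistent with the same study's reference models (which
  report 0.290 mm deformation at a *lower* stress with a *stiffer*
  agglomerate); no monotone elastic model can produce both, so the
  discrepancy is reported rather than calibrated away. The two
  corresponding acceptance tests fail by design.
* The geometry is idealized (circular lumen, concentric crescents); no
  image-based or 3D reconstruction.
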