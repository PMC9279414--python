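# Methods

## Physical model

The package models diastolic flow through the embryonic (E16.5 mouse)
aortic root and the proximal stubs of the two main coronary arteries.
During diastole the aortic valve is closed, the root wall recoils inward,
and the coronary arteries are perfused from the aortic side. The flow is
governed by incompressible Navier–Stokes with a generalized-Newtonian
stress,

σ = −p I + 2 μ_eff(γ̇) E,  E = (∇u + ∇uᵀ)/2,

and the Carreau viscosity law

μ_eff(γ̇) = μ∞ + (μ0 − μ∞)(1 + (λγ̇)^a)^((n−1)/a).

The scalar shear rate is defined as γ̇ = √(E:E). Note this is √2 smaller
than the γ̇ = √(2 E:E) convention used in much of the rheology literature;
the definition here is the one the viscosity constants were fitted
against, and `shear_rate(..., convention="doubled")` exposes the other
reading. Defaults: μ0 = 1.38×10⁻² Pa·s and μ∞ = 3.03×10⁻³ Pa·s (fit to
adult-mouse viscometry — embryonic blood, with lower hematocrit, is
expected to be less viscous, so these are an upper envelope; they are
config-overridable and a least-squares fitting path `fit_carreau` exists
for user-supplied viscometry tables). λ = 3.313 s, n = 0.3568, a = 2 are
standard blood-Carreau constants paired with those asymptotes. A
Newtonian comparison mode uses constant μ = 4×10⁻³ Pa·s. Density is
1060 kg/m³.

Quasi-steady treatment: at radius 0.25 mm, 240 bpm, and μ0, the Womersley
number α = R√(2πf ρ/μ) ≈ 0.347, so transient inertia is subdominant and
each diastole is modeled as a steady problem. (The standard definition is
reported; claims of α ~ 10⁻³ for these parameters are not reproducible
from the definition.) An unsteady generalized-α mode exists mainly to
verify that the steady solution is the long-time limit.

## Idealized geometry

The root is a z-aligned tube: valve base (closed wall) at z = 0, aortic
outlet at z = root_length = 1.2 mm, lumen diameter 0.5 mm. Over the sinus
segment (0 ≤ z ≤ 0.5 mm) the wall bulges to sinus_bulge_ratio = 1.3 of
the nominal radius. The bulge is modulated azimuthally into three lobes,
`r(z,θ) = R₀ (1 + (b−1) sin(πz/h) · (1+cos 3θ)/2)`, because the sinuses
of Valsalva are three discrete pockets rather than an axisymmetric
swelling, and an ostium's relation to its pocket is exactly what changes
under displacement ("posteriorly toward the left coronary sinus" is an
azimuthal statement). `sinus_lobes = 0` recovers the axisymmetric bulge.

Two cylindrical coronary stubs (diameter 0.15 mm, length 0.3 mm measured
outward from the wall) pierce the sinus wall horizontally. The control
LCO sits at 0.3 of sinus height at the left-lobe center (azimuth 0°); the
RCO mirrors it at 120°. The displaced-LCO variant applies the scenario
shift (+0.4 of sinus height toward the sinotubular junction, +30°
posterior) and changes nothing else. The in vivo displacement is
quantified only relative to the valve base, so the shift magnitude is a
stated scenario parameter, not a measured reproduction. Only the aortic
diameter (0.5 mm) is a printed quantity; all other dimensions are chosen
once at E16.5 scale and are configurable.

## Boundary conditions

* WALL (root wall, valve-base disc, stub lateral walls): Dirichlet
  u = −s·n with s = (contraction · D/2)/(diastole · 60/HR) = 0.33 mm/s at
  the defaults (10% contraction, 30% diastole, 240 bpm, 0.5 mm). The
  diameter- and radius-based readings of "10% contraction" give the same
  displacement, so the ambiguity is immaterial. Node normals are
  area-weighted averages of adjacent wall-face normals.
* AORTIC_OUTLET: constant normal traction −p n with p = 9 mmHg
  (1199.9 Pa); gauge convention, distal reference 0.
* Coronary outlets: lumped resistance, traction −(R_i Q_i + p_distal) n
  with Q_i the instantaneous outlet flux. R_eq = 5.6×10³ mmHg·s/mL is
  split by Murray's law R_i = C A_i^−1.5 with C = R_eq Σ A_j^1.5, using
  the *meshed* patch areas so the split matches the discrete geometry;
  the parallel-sum identity is enforced to 1e−12. p_distal defaults to
  0 mmHg; the reference pressure behind the resistance is not otherwise
  constrained, and its influence is exactly the flow-pinning discussed
  under "Interpretation" below.

## Discretization and solver

Equal-order P1–P1 tetrahedral elements with residual-based stabilization:
PSPG + SUPG with τ_M = [(2|a|/h)² + (12ν/h²)²]^(−1/2) (h the equivalent
regular-tet edge of each element), grad-div (LSIC) with τ_C = h²/(12 τ_M).
Convection and viscosity are Picard-linearized with under-relaxation 0.7;
the nonlinear loop stops when ‖r_k‖/‖r_0‖ < 10⁻³ (tightening further does
not change the reported quantities). Backflow at traction boundaries gets
the β ρ (u·n)₋ u·v boundary term with β = 0.2. Resistance coupling is an
implicit rank-one augmentation R b bᵀ with b the patch flux vector —
unconditionally coupled, no subiteration. Linear systems are solved with
sparse LU, the factorization being reused as a GMRES preconditioner
across Picard iterations and refreshed when it goes stale; there are no
randomized components, so runs are bit-reproducible. The unsteady path is
first-order generalized-α (ρ∞ = 0.5, Δt default 10⁻⁴ s) with pressure at
the new time level.

Meshing is in-house: boundary surfaces (rims, hole edges, discs, lateral
walls) are sampled at the target edge length with irrational per-row
phase offsets (avoiding exactly degenerate point quadruples), interior
points come from a body-centred-cubic lattice, and scipy's Delaunay
triangulation restricted to the implicit solid yields the tetrahedra;
non-manifold pinches at concave junctions are peeled away until the
boundary is watertight (checked as every boundary edge sharing exactly
two faces). A structured extruded mesher provides the cylinder benchmark
fixture. Desk-scale default: target edge 48 µm ≈ 1.8×10⁴ tets per root
(the coronary stubs then carry ~1.5 elements per radius, which is the
main resolution limit of the absolute WSS values).

## WSS extraction

Per boundary face, traction t = σ·n from the adjacent element's constant
gradient and the face-mean pressure; WSS = ‖t − (t·n)n‖, reported in Pa
and cgs (1 Pa = 10 dyn/cm²). By default no gradient smoothing is applied —
adjacent-element extraction is robust at the re-entrant stub–sinus
junction. An optional superconvergent patch recovery
(`wall_shear_stress(..., recovery=True)`) fits a linear gradient per wall
node to the adjacent elements' P1 gradients sampled at their
*circumcenters* (where the P1 gradient of a quadratic field is exact);
on the smooth-walled Poiseuille benchmark this reduces the wall-WSS error
at edge R/6 from −6.5% (the systematic one-sided h/(2R) bias) to about
−1%, and the analytic benchmarks are therefore evaluated in recovery
mode. The ostial region is the set of WALL faces (sinus wall and stub
lateral wall alike) whose centroid lies within 1.0 coronary diameter of
the stub-axis/wall intersection; reported ostial WSS is the area-weighted
mean (means, not maxima — maxima are mesh-sensitive at the junction
corner), and the comparison metric is 100·(control − variant)/control.

## Verification

* Hagen–Poiseuille (structured cylinder, R = 0.25 mm, L = 2 mm,
  Δp = 10 Pa, μ = 3.03e−3): centerline velocity, flow rate and wall WSS
  within 5% of closed form at edge R/6; mass balance to machine
  precision. The refinement study tracks the wall-WSS error (−6.9%,
  −3.5%, −1.1% over R/3, R/4, R/6 in recovery mode), which is
  discretization-dominated; nodal velocities are superconvergent on the
  structured fixture and sit below 1% at every level, at the floor set by
  the stress-form traction end conditions (which admit tangential slip on
  the end discs, so the continuum limit of this benchmark differs from
  exact Poiseuille by a few tenths of a percent).
* Carreau pipe flow against an independent 1-D two-point BVP oracle
  (per-radius root-find of μ(γ̇)u′ = −Δp r/2L, quadrature for the
  profile): within 3% at edge R/5.
* Rigid-rotation equivariance of the discrete solution to machine
  precision; viscosity field bounded by the Carreau asymptotes; the
  generalized-α terminal state matches the steady solve within 2% and is
  insensitive to halving Δt.
* Murray split, wall-speed derivation, unit conversions: exact worked
  cases plus property tests.

## The comparison experiment, and its interpretation

The pipeline solves the identical problem on the control root and on the
displaced-LCO variant and reports the percent change in ostial mean WSS.
At the defaults this yields a *negative* reduction of about −11% (the
displaced ostium sees slightly **higher** WSS), stable in sign across
mesh densities (−6% to −20% over 1.8–4.3×10⁴ tets; the metric carries
roughly ±7-point mesh noise at desk scale). The mechanism is structural,
not numerical: a resistance outlet pins the coronary flow at
Q ≈ (p_root − p_distal)/R — internal viscous pressure drops are below 1%
of the 9 mmHg driving head at these scales, so Q_LCA is 0.758 mm³/s in
both scenarios to three decimals — and ostial WSS is dominated by the
through-ostium flow, hence proportional to Q times a local geometric
factor. Pure placement changes only that factor, by O(10%), and in this
geometry the displaced ostium sits on the more exposed lobe flank near
the sinotubular junction. A 30–35% WSS drop at fixed R_eq would require
roughly 0.7×10¹² Pa·s/m³ of extra serial entrance resistance — a
~3 mm-longer stub at 0.15 mm caliber, impossible inside a 1.2 mm root —
so a large reduction at a misplaced ostium must involve anatomy beyond
placement, such as a narrowed or elongated proximal coronary course
(both are documented phenotypes of the malformation this model
idealizes). The package treats the placement-only contrast as the
controlled experiment it is and reports the sign and size it actually
produces; users can probe the caliber/length mechanisms through
`GeometryConfig` overrides.

Consistent with flow pinning, the reduction metric moves by well under
10 percentage points when R_eq is perturbed by ±50% (both scenarios
scale together), and Newtonian mode reproduces a reduction of similar
size (overall WSS levels are higher there, since the high-WSS regions
are exactly the high-shear-rate regions where the Carreau viscosity
thins). Bulk median shear rates in the root are O(1–40 s⁻¹) with
excursions above 10³ s⁻¹ in the stubs, which is why the shear-thinning
law matters.

## What the synthetic data does and does not emulate

Viscometry tables are drawn from a known Carreau law with multiplicative
Gaussian noise (viscometer error scales with the reading) at log-spaced
shear rates over 0.1–10³ s⁻¹ — distributionally like a rotational-
viscometer series, without instrument-specific artifacts (torque floors,
inertial corrections). The geometry pair is a controlled idealization:
it captures ostium placement within a three-lobed sinus, not leaflet
geometry, wall compliance, the intramural course of a malpositioned
coronary, or subject-to-subject variability. Passing tests therefore
demonstrate correctness of the numerics and of the placement-only
contrast, not reproduction of traced-anatomy WSS magnitudes: absolute
ostial WSS at desk scale (tens of cgs) is order-of-magnitude
physiological but systematically under-resolved in the stubs.

## Numerical choices and degenerate inputs

Residual tolerance 10⁻³ (normalized), relaxation 0.7, linear tolerance
10⁻⁸, backflow β = 0.2, all configurable. Zero forcing converges
immediately to the rest state. Non-convergence is flagged on the
solution, never raised; WSS extraction refuses flagged solutions. Patch
labeling assigns a boundary face to an outlet only if all three nodes lie
within 10⁻³ of the outlet diameter from the outlet plane (ties to the
smallest patch id), everything else being WALL. Meshing preconditions:
target edge below one third of the coronary diameter; sliver tets are
excluded by the largest volume cut that keeps the boundary watertight.

## Known limitations

Rigid walls (no FSI) and a single quasi-steady diastolic phase — no
systole, no pulsatile WSS metrics (OSI). P1 elements resolve the stub
boundary layers only coarsely at desk scale; absolute WSS converges
from below under refinement. The idealized mutant differs from the
control only in LCO placement by design, which (per the analysis above)
excludes the caliber/length mechanisms that can produce large WSS drops
in traced anatomies. The built-in mesher targets this family of implicit
solids and modest qualities, not general CAD geometry.
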