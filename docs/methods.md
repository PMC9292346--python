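# Methods

This note records the physics, the numerical choices, and the known
limitations of `icrcell`, a package that evaluates the electrostatics of
historical FT-ICR (Penning) measuring-cell designs under one common protocol.

## Physical model

An ion of mass m and charge q in a homogeneous magnetic field B (along z)
rotates at the pure cyclotron frequency ωc = qB/m.  The trapping electrodes
add an electrostatic potential φ; if φ were the ideal harmonic field
α(z² − ρ²/2) + χ the three motional modes (reduced cyclotron ω₊, magnetron
ω₋, axial ωz) would decouple:

    ω± = ωc/2 ± √((ωc/2)² − ωz²/2),    ωz = √(2qα/m),

with the exact identities 2ω₊ω₋ = ωz² and ωc² = ω₊² + ω₋² + ωz².  Real
electrode sets are not ideal.  Because every design in scope is mirror
symmetric across z = 0, the azimuthally averaged potential is expanded in
the even axisymmetric solid harmonics of order 0, 2, 4, 6:

    φ̄(ρ,z) ≈ C + A20 (z² − ρ²/2) + A40 (8z⁴ − 24z²ρ² + 3ρ⁴)
             + A60 (16z⁶ − 120z⁴ρ² + 90z²ρ⁴ − 5ρ⁶).

A40 and A60 make the local reduced-cyclotron frequency position dependent,

    ω₊(ρ,z) = ωc/2 + √((ωc/2)² − (q/m)[A20 + A40(48z² − 12ρ²)
               + A60(240z⁴ − 360z²ρ² + 30ρ⁴)]),

so an ion cloud spanning a range of (ρ, z) dephases into a "comet" and the
detected image-current signal collapses.  The dephasing time is estimated as
the time for the phase spread to reach 2π:

    T_comet = 2π / (max ω₊ − min ω₊)

with the extrema searched on a 121×161 grid over the cloud region
ρ ∈ [r_exc − r_cloud, r_exc + r_cloud], z ∈ [−z_cloud, z_cloud].  The "+"
branch of the root is always used; the magnetron branch never enters the
comet estimate.  A frequency spread below 10⁻¹² of ω₊ is reported as an
infinite comet time.

### Reference conditions

All comparative numbers use B = 7 T, m/z = 500 Da/e, r_cloud = 2 mm,
r_exc = 6 mm, z_cloud = 8 mm (= 4 r_cloud), and singly charged ions.
Physical constants are CODATA 2018 (`constants.py`): e = 1.602176634e-19 C,
u = 1.66053906660e-27 kg.  These give ωc ≈ 1.351e6 rad/s.

## Evaluation protocol

For each cell: build the geometry (reference dimensions and voltages as
published for the 1-inch-scale comparison set) → obtain the trapping
potential (exact series where one exists, numeric Laplace solve otherwise) →
average over the polar angle → ordinary least squares of the four-term basis
on a uniform 41×81 lattice over ρ ∈ [0, 10 mm], z ∈ [−10, 10] mm → comet
time from the fitted dimensional coefficients.  Dimensionless coefficients
use the normalization length d, d² = ½(z0² + ½ρ0²): A20n = A20·d², etc.

Per-design (z0, ρ0): cubic uses half-edges; the cuboid uses the axial
half-edge and the *larger* transverse half-edge (1.27 cm, 3.81 cm) — the
only convention consistent with the published dimensionless A20 ≈ 1.9 for
that cell; cylindrical designs use (z0, R); the hyperbolic pair uses
(z0, R); the dynamically harmonized cell uses (z0 = 2R, R).  The fit is
unweighted; weighting by the cylindrical volume element ρ dρ dz moves the
cylindrical cell's A20n by well under 2% (quantified in the test suite).

Published trapping/compensation voltages are taken as already calibrated so
that the dimensional A20 is common across designs; `calibrate_voltage`
implements the calibration (rescale all applied voltages by a reference
A20 ratio — exact by linearity) but is not applied by default.  As a
consistency check, calibrating the cylindrical cell to the cubic cell's A20
reproduces the published 0.988 V within 1%.

## Field sources

**Analytic.**  The rectangular box (cuboid/cubic) uses the double-cosine /
cosh eigenfunction series; its azimuthal average is closed-form because
⟨cos(ax)cos(by)⟩_θ over a circle of radius ρ equals J0(ρ√(a²+b²)).  The
closed cylinder uses the modified-Bessel series (odd axial modes
γ_j = jπ/(2z0)); near the centre this reproduces the classical constants
γ″ = 0.2787, α″ = 2.8404 for R = z0 (checked to 5e-4 in the tests, with the
convention V ≈ V_trap[γ″ + (α″/a²)(z² − ρ²/2)], a = 2R — the unique reading
consistent with the dimensionless A20 ≈ 0.53 of that cell).  Dipolar
excitation fields are provided for the cubic cell (sinh series; near-centre
linear coefficient β₁ = 0.721) and the closed cylinder (I_m series for
90° sectors), both odd in x.

**Dynamically harmonized cell (paracell).**  The grounded leaf electrodes
narrow with z² (half-width βπ/N·(1 − z²/z0²), N = 8, β = 0.9: at z = 0 the
leaves cover the fraction β of the circumference, at z = ±z0 they vanish)
and the end caps follow 2z² − ρ² = 2z0² − R².  The full θ-dependent
potential is built per z-slice as the exact 2-D disk solution for the
biased/grounded arc pattern, via the closed-form harmonic measure of each
biased arc, plus the quadratic term βφ0(R² − r²)/(2z0²) that carries the
axial curvature; this matches the structure of the published closed form
and is exact in the 2-D limit, approximate in 3-D.  Its azimuthal mean
equals the closed-form averaged potential

    φ̄ = φ0[1 − β(1 − z²/z0²)] + βφ0 (R² − r²)/(2z0²)

identically (mean-value property), which in turn satisfies Laplace exactly
and reproduces the θ-averaged wall condition — this fixes the algebraic
grouping of the averaged form, which is ambiguous as usually typeset.

A consequence worth stating plainly: the averaged paracell field is
*exactly* the ideal harmonic field — the end-cap surface is an equipotential
of it — so in the continuum the cell's comet time diverges.  Any finite
residual A40/A60 for this cell, here or in any field solver, is
discretization error, and the computed comet time grows under grid
refinement (6.7 s at the production spacing, 13 s at half the spacing).
The number reported at the production grid is therefore a solver-resolution
statement, not a converged property of the cell; it happens to sit near the
comparable published estimate, which was obtained at a comparable
resolution.  The same caveat applies, more mildly, to the truncated
hyperbolic trap and its compensated variant, whose residual coefficients
(~10⁻⁵ dimensionless) are also at the noise floor.

**Numeric.**  Everything else is solved as a Dirichlet–Laplace problem.
Electrodes are implicit solid regions rasterized onto uniform grids with
nearest-node snapping (no sub-cell boundary interpolation); zero-width gaps
between adjacent electrodes except where gaps are part of the published
design (the ring-electrode cell).  Axisymmetric designs use the (ρ, z)
five-point stencil with the 1/ρ term and the ρ = 0 axis closed by symmetry
(limit 2φ_ρρ); the solver is a sparse LU factorization (SuperLU), giving
residuals at rounding level in a few seconds at production grids.  3-D
Cartesian grids (cubic/cuboid cross-checks, detection weight fields) use
conjugate gradients on the symmetric 7-point system.  Red-black SOR — the
classical relaxation method — is implemented as an independent reference
and cross-checked against both, with ω defaulting to 2/(1 + sin(πh))
(a fixed ω = 1.9 stalls on 513-point grids).  Open cells get a grounded
closure at the box ends; the trapping cylinders are long enough (≥ 4 z0)
that the closure choice is exponentially irrelevant in the fit region.

Production grid spacing is min(R, z0)/128 (axisymmetric; ~0.1 mm) and
min(R, z0)/64 (3-D).  `refine_study` provides Richardson-style convergence
reports; the cylindrical A20n drifts < 1% between successive refinements.

**Paracell numeric route.**  The paracell's *geometry* (cylinder wall +
axisymmetric end caps) is rotationally symmetric — only the wall voltage
pattern is not — so azimuthal Fourier modes decouple exactly and the
averaged potential solves a 2-D axisymmetric problem with the m = 0 wall
value φ0(1 − β(1 − z²/z0²)).  The pipeline uses this reduction; a direct
3-D voxelization needs roughly 10× finer grids for the same residual
accuracy because the staircased leaf edges alias into the axisymmetric
modes.

**Compensation analysis.**  For compensated designs the derivative of any
fitted coefficient with respect to V_c is computed exactly by superposition
from a single unit-V_c basis solve.  The quality factor γ =
(V∂A2/∂Vc)/(V∂A4/∂Vc) uses the Legendre-convention coefficients
(A2 = 2d²A20/V, A4 = 16d⁴A40/V); γ = 0 is the orthogonalized geometry where
tuning V_c nulls A40 without moving A20 (hence without moving ω₊).  Because
γ is defined through the expansion *about the trap centre*, the γ fit uses
a 5-mm near-centre region: the 10-mm working-volume fit aliases k ≥ 8
content into A2/A4 and shifts the hyperbolic γ-root from 1.16 to 1.18.
With the local fit the bisection gives R/z0 = 1.163, independent (tested)
of the compensation-arc thickness, angular margins, and radius — as
expected for this family.  For the closed compensated cylinder the same
sensitivities have a closed form (eigenfunction expansion with weights
(−1)^(j+1)·2sin²(λ_jΔz_c/2)/(λ_j z0 I0(λ_j R)), λ_j = (j−½)π/z0), validated
against the finite-difference solver oracle (k = 4 agrees to ~1%); its
k = 2 zero lands at R/z0 = 1.163 too, matching the published choice
R = 1.16 × 1.27 cm for that cell.

**Detection.**  The induced charge is Q = −qφ_w (reciprocity), with φ_w the
weight field of the detection electrode at 1 V.  For a long cylinder the
closed forms give odd harmonics of amplitude 2(ρ/R)^(2n+1)sin((2n+1)α)/
((2n+1)π); α = π/3 nulls the third harmonic exactly, and p alternating
electrode pairs keep only orders p(2n+1) (8 electrodes → 4ω₊).  Structural
nulls (integer multiples of π in the sine) are snapped to exactly zero.
Numeric weight fields voxelize the wall at threshold R − h/2 (centring the
staircase on the true radius; a node-on-or-outside rule biases the m-th
harmonic by ≈ (1 + h/(2R))^m) and antialias the sector edges with a
one-node linear ramp; with these, the solved weight field reproduces the
first three odd harmonic amplitudes within 2% at mid-cell.  Even harmonics
from off-centre (magnetron-shifted) orbits are accessible only through
`reciprocity_charge` with an offset orbit, not in closed form.

## Under-specified geometries

Two designs are only loosely pinned down by their published descriptions
and are implemented behind documented parameters, excluded from any
quantitative claim: the multi-ring compensated cell of the Brustkern type
(the trapping-ring length and outer grounded cylinder are assumptions:
trapping ring spans 21.87a–43.74a, a = R/31.24, grounded cylinder 1.5× that
beyond) and the trapping-ring-electrode cell (ring width 0.11/1.875 and gap
0.039/1.875 in units of `ring_unit`, default 1 inch → 1.49 mm/0.53 mm
concentric end-cap rings).  The ring-electrode cell's row is flagged
non-reference; its comet metrics have no published twin.  Angular
segmentation of the compensation rings in the two open compensated variants
is modeled as full axisymmetric rings.

## Numerical choices and degenerate inputs

* Series truncation: terms are added until the tail bound falls below
  10⁻¹² of the driving voltage or 500 per index; non-convergence raises
  with the achieved bound.  Near electrode surfaces the box series
  converges conditionally; evaluating *on* a boundary is rejected.
* Harmonic fits run in region-scaled coordinates (the raw ρ⁶ column spans
  14 decades against the constant column); rank deficiency of the scaled
  design matrix (degenerate region) is rejected, as are regions with fewer
  than 100 usable lattice nodes.
* ω₋ is computed in conjugate form (ωz²/2)/ω₊ to avoid cancellation; the
  frequency identities then hold to 1e-12 relative for any stable input.
* Unstable inputs (qA20/m > (ωc/2)², or a locally imaginary root of
  ω₊(ρ,z)) raise with the critical value or the offending location.
* The comet-time extremum search uses a fixed dense grid rather than a
  continuous optimizer; ω₊ is a smooth function (polynomial under a square
  root) and the 121×161 grid resolves it far beyond the reported precision.
  The search covers the full cloud rectangle (not only its boundary).

## What the tests do and do not show

The suite validates every closed form against an independent route
(series vs solver, closed-form harmonics vs reciprocity on a solved weight
field, sensitivity expansion vs finite differences), all the structural
invariants (Laplace, symmetries, linearity, superposition, maximum
principle, frequency identities), and the end-to-end reproduction of the
published comparative table within stated tolerances.  It does not address
space charge (ion–ion interaction), RF excitation dynamics, magnetic-field
inhomogeneity, trajectory integration, or mechanical misalignment — the
comet-time model is a frequency-spread estimate, deliberately blind to
everything that makes real clouds more (or less) robust than the
single-particle picture.
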