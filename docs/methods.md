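# Methods

This note records the model assumptions, the numerical choices, and the
known limits of `mdtsim`, in the order the pipeline runs them.

## Magnetostatics

A fully magnetized bulk superconductor is idealized by the Bean critical
state: the azimuthal current density equals the critical current density
everywhere in the cylinder, with no flux creep or demagnetization during
delivery. The external field is then a classical magnetostatics problem;
we integrate the off-axis field of circular loops (complete elliptic
integrals) over the cross-section with panel-refined Gauss–Legendre
quadrature (panels packed geometrically toward the top face and the radial
extremes, 10-point rule per panel, ~2,800 nodes). The on-axis end-face
field of this distribution has the exact closed form
B(z) = (μ₀J/2)[(z+t)·asinh(a/(z+t)) − z·asinh(a/z)], whose z = 0 limit is
the Bean formula B_T = kμ₀Ja, k = t/(2a)·asinh(a/t). The quadrature is
checked against it (< 0.5% at the surface-center singularity, ~1e-6
relative away from the surface) and against the point-dipole limit with
moment m = πJta³/3 (< 2% beyond 10a).

**Jc calibration.** The published magnets are characterized by their peak
surface field (2.11–10.80 T depending on size and operating temperature),
not by tabulated Jc(B) curves. The deposition physics depends on the magnet
only through its external field, so each preset carries a *constant* Jc
inverted from the Bean formula, which reproduces the printed B_T exactly
(round-trip check < 1%). The field-dependent Kim model
Jc(B) = Jc0·B₀/(B₀+|B|) is implemented (damped fixed point, damping 0.5,
relative tolerance 1e-3, max 100 iterations) for users who have curve
data; its far field at fixed B_T is slightly stronger than constant-Jc
because current migrates toward the low-field rim.

**Field maps.** Transport queries B and ∇H² on a Cartesian grid (default
1 mm spacing, trilinear interpolation) populated from an axisymmetric
(ρ, z) table via bicubic splines; ∇H² comes from the spline derivatives
with H = B/μ₀ (M = 0 in air and tissue). Grid-halving changes interpolated
|∇H²| by < 2%, discrete div B is at the discretization floor, and the map
agrees with the direct loop integral to < 1%.

## Airway geometry

The G0–G3 Weibel tree is planar and symmetric; branches are capped
cylinders meeting at shared points, with a bifurcation half-angle of 35°
per daughter (the angle is not tabulated in the source geometry; 35° is a
common symmetric-Weibel rendering and is exposed in the config). Junction
fillets are omitted — a documented fidelity gap; the flow-side funnel zone
(below) stands in for the smooth transition. The tumor is a sphere of
radius r = r_ratio·R_host centered *on* the host-branch wall: the
protruding part is a spherical cap that never fully occludes the lumen for
r_ratio ≤ 1. Axial stations P0/P1/P2 sit at 1/6, 1/2 and 5/6 of the host
branch (proximal/mid/distal thirds); the default study geometry uses P1
and azimuth α = 0, i.e. the cap faces the magnet. The magnet axis passes
through the tumor's axial station point (so rotating the tumor by α moves
it off the magnet axis, and relocating it to P0/P2 re-aims the magnet),
with an optional lateral offset in the config.

## Airflow surrogate

The flow solver is deliberately not a Navier–Stokes code. Branch flow
rates come from a Hagen–Poiseuille resistance network (outlets at equal
pressure); the tumor constriction enters the host resistance through
8ηπ∫ds/A_open(s)², with A_open from the closed-form disc–disc lens area.
Within a branch the profile is the fully developed parabola carrying that
branch's flow, modified by:

* **carinal skew** — daughter profiles are multiplied by
  (1 + s·ζ·cosφ) with φ measured from the inner (carinal) wall and
  s = skew·(1−ξ/L), default skew 0.3: the peak shifts toward the carina
  and relaxes to symmetric over one branch length;
* **junction funnel** — over the last parent radius before a bifurcation,
  a lateral component steers fluid toward the daughter tube (target 80% of
  the daughter radius, gain 3 e-folds), scaled by the local axial profile
  so no-slip is preserved; a tracer entering the zone exits inside a
  daughter, as it would in a filleted junction;
* **constriction continuity** — under the cap's axial shadow the axial
  speed scales with A_full/A_open(s);
* **cap deflection and separation** — the cap acts as a sphere in the
  local stream: a potential dipole cancels the flow into the cap surface
  (tracers pass around it), and within one cap radius of the surface,
  below apex height, the speed is reduced to a floor of 0.15× the local
  value. The slowdown represents the separated corner (horseshoe) and
  wake regions that a wall-mounted bluff bump develops at duct Reynolds
  numbers of order 10³, where recirculating speeds are an order of
  magnitude below the free stream; the gap jet above the apex is left at
  full speed. Both scales (extent one cap radius, floor 0.15) are standard
  bluff-body magnitudes and are fixed constants of the closure.

The surrogate is exactly linear in Q, conserves flux through every
bifurcation to round-off, and satisfies no-slip. `import_flow` accepts an
externally computed velocity field (legacy-VTK structured points) under
the same query contract, with conservation checked and reported rather
than enforced.

## Particle transport

Particles obey m_p dv/dt = F_d + F_m with Schiller–Naumann drag
(F_d = 3πηd_p(u−v)(1+0.15Re_p^0.687)) and magnetophoresis
(F_m = (π/4)d_p³μ₀K∇H², K = (μ_r,p−1)/(μ_r,p+2)); gravity, lift, Brownian
and unsteady forces are negligible for 1–7 µm particles at these field
gradients and are omitted, as is two-way momentum coupling (dilute limit).
The relaxation time τ = ρ_p d_p²/(18ηf) is 1.6e-5 s (1 µm) to 8e-4 s
(7 µm) — stiff relative to convenient step sizes — so the integrator
updates velocity and position with the exact exponential solution for
frozen coefficients. Steps are capped by displacement (0.25 mm, tightened
to 0.1 mm within 2.5 tumor radii) and a hard dt of 2e-4 s; a τ-based step
bound is unnecessary because the stiff term is integrated exactly, which
the closed-form relaxation test verifies to 0.1%. Boundary handling:
tumor hits by segment–sphere intersection, wall/outlet crossings by
bisection on the lumen indicator (1e-6 m tolerance); stick and freeze
states are absorbing. Seeding is flux-weighted over the inlet disc
(area-weighted optional) with the local air velocity; all randomness flows
from one integer seed. Runs are truncated at three convective transit
times; still-airborne particles count as suspended (in the denominator,
never the numerator).

## PDE analysis

PDE = 100·(tumor-surface deposits)/(particles released). Because
"entering the branch" is ambiguous, records carry both the released
denominator (default) and a host-branch denominator (particles whose
branch log visits the tumor's branch). Sweeps derive a fresh 31-bit
sub-seed per point from the master seed by counter, log it, and write CSV
and plot; per-point failures are recorded and the sweep continues.

## Problem sizes and sampling error

The study-scale run uses 10,000 particles. The test suite and the
acceptance script use 2,000 per point, for which the binomial sampling
error on a PDE near 10% is about ±0.7 points (1σ); trend comparisons use
common random numbers across sweep points. A full 2,000-particle case
takes ~30 s on one CPU including the cached field map.

## What the surrogate does and does not show

The pipeline reproduces the mechanisms that drive magnetically targeted
deposition — descent of particles toward the magnet at the drift velocity
F_m/(3πηd_p f), focusing toward the magnet axis, competition between
tumor capture and premature wall capture ("gathering in advance" for
strong magnets or close distances), decay of the effect to the no-magnet
baseline by d ≈ 130 mm, and the failure of targeting when the tumor faces
away (α = ±90°). Quantitatively it differs from a full CFD+FEM treatment
in known ways:

* with no magnet, deposition by inertial impaction alone is near zero
  here: parabolic profiles with idealized junction steering remove the
  secondary flows and carinal stagnation that deposit ~1–2% of 4–6 µm
  particles in resolved simulations;
* with the magnet, computed PDE values are typically several points below
  published FEM values for the same configuration: the surrogate's
  idealized cap deflection and the absence of bifurcation secondary flows
  narrow the tumor's effective capture cross-section, and its
  with-magnet PDE rises monotonically over 1–7 µm instead of peaking at
  5 µm — the upstream-gathering penalty grows more slowly here than in
  the FEM;
* the distance decay is steeper than the FEM's (the no-magnet level is
  reached by d ≈ 80 mm for the 3.42 T magnet rather than ~130 mm).

These limits live in the flow closure, not in the magnetics (verified
against closed forms) or the particle dynamics (verified against a
high-order reference integration); substituting an imported CFD field via
`import_flow` upgrades the fidelity without touching the rest of the
pipeline.
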