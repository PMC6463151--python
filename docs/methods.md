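# Methods

`trabeflow` simulates two-dimensional incompressible flow through an
idealized trabeculated embryonic ventricle and analyzes the resulting
vortex structures and wall shear stresses.  This note records the model,
the numerical choices, and what the package's synthetic test conditions do
and do not establish about real embryonic hearts.

## The physical model

At the onset of cardiac trabeculation in the zebrafish embryo (~3–4 days
post fertilization) the intracardial Reynolds number is close to one:
inertial and viscous forces balance, and small changes in morphology,
blood rheology, or flow pulsatility can reorganize the intracardial flow
topology.  The model idealizes the ventricle as a half-elliptical cavity
(semi-major axis `aV = 1.0`, semi-minor axis `bV = 0.8`, dimensionless
units) opening into a straight channel of width `wAV = wSV = 0.8` that
stands in for the atrioventricular canal and sinus venosus.  Trabeculae
are smooth bumps superimposed on the elliptical arc,

    Trab(x) = hT (1 − (x/rT)²) exp(−(x/(0.7 rT))⁸),  clamped to 0 for |x| ≥ rT,

with radius `rT = 0.10` and height `hT` the main morphological control
(`hT/bV` from 0 to 0.16; 0.08 is the biologically relevant value).  The
dimensional anchor is the 4 dpf zebrafish ventricle
(V = 0.75 cm/s, L = 208 µm, ρ = 1025 kg/m³, μ = 0.0015 kg/(m·s),
f = 3.95 beats/s), giving Re = 1.07 and dimensionless frequency
f̃ = L f / V = 0.11; the idealized pulsatile runs fix f̃ = 0.10.

Reynolds number is defined with the channel width `wAV` and the
characteristic velocity `Vin` (steady inflow) or `Vin/2` (pulsatile, the
time mean of the sin² waveform); it is varied through the kinematic
viscosity, `ν = Vchar · wAV / Re`.

The Womersley number is reported as a diagnostic only, with the
definition stated wherever it is printed: `Wo = (wAV/2)·sqrt(2πf/ν)`,
giving 0.43 for the zebrafish reference values above.  Several variants
of the definition circulate (full width vs half width, f vs 2πf) and
span roughly 0.4–0.9 on the same data; nothing in the solver or the
analyses depends on Wo.

### Trabecula placement

Six trabeculae sit at equal arc-length spacing, symmetric about the
cavity midline, with crest-to-crest pitch 2.5 rT = 0.25 — packed side by
side, the way trabeculae appear as contiguous muscular ridges in
micrographs.  This choice is load-bearing: the bump profile effectively
vanishes beyond ~0.75 rT, so at this pitch the grooves between ridges are
true notches about one bump-width wide.  Spreading the same six bumps
over the whole elliptical arc (pitch ≈ 0.47) gives a corrugation
steepness k·a ≈ 0.4, well below the ≈ 0.8 threshold at which slow
(Stokes-regime) flow over a wavy wall can separate at all — such a
geometry produces no intertrabecular recirculation at any low Reynolds
number, for any solver.  Packing tighter than ≈ 2.2 rT is also ruled
out, numerically: the groove gap falls below the support of the
regularized delta function and the notch interior degenerates into a
porous plug of overlapping wall kernels.

## The solver

The fluid-structure coupling is the classic immersed-boundary method for
nearly rigid structures:

* **Eulerian grid.** Uniform, periodic in both directions, 4.0 × 2.0
  domain units.  Resolution tiers: `tiny` 64×32 (smoke tests), `coarse`
  128×64 (unit tests), `medium` 192×96, `fine` 256×128 (production /
  reported results), `xfine` 384×192.
* **Time step.** Semi-implicit projection: skew-symmetric centered
  advection (explicit), implicit diffusion and exact discrete pressure
  projection solved together in Fourier space (5-point Laplacian symbol,
  centered-difference divergence symbol).  The centered divergence of the
  velocity is zero to round-off after every step.
* **Boundary.** Lagrangian markers at spacing ds = h/2, tethered to
  target positions by stiff linear springs, `F = −k (X − X_target)`;
  forces spread to the grid with the standard 4-point regularized delta
  kernel (exact partition-of-unity and first-moment properties, so
  interpolation — the adjoint — is exact on linear fields); markers move
  with the interpolated fluid velocity.
* **Inflow.** A relaxation band upstream of the cavity blends the
  velocity toward a parabolic profile each step (implicitly, so the
  constraint is unconditionally stable and time-step independent), while
  a Poiseuille body force `8 μ V(t) / wAV²` pumps the straight channel
  sections.  The force deliberately excludes the cavity-mouth section:
  pumping momentum through the mouth shear-drives a spurious cavity eddy
  at any Re; under the mouth the flow must be carried by pressure, as in
  a pressure-driven expansion.  A slow integral controller (time constant
  0.25) scales the pump so the measured band flux matches the target —
  this supplies exactly the pressure head the loop requires, whatever the
  mouth section's resistance, and holds the imposed flux within ~2% of
  target across Re = 0.01…100 at every tier.  A second band before the
  periodic seam damps transverse velocity so recirculated outflow
  re-enters cleanly.  Steady inflow ramps from rest over 0.5 time units
  (smooth cosine); pulsatile inflow is `Vin sin²(πt/T)` with
  `T = wAV/(f̃ Vchar)` — zero at cycle boundaries, maximal mid-cycle,
  time mean `Vin/2`.

### Tether stiffness and time step

The stiffness is auto-calibrated: an analytic traction estimate
(Poiseuille wall shear + dynamic pressure, times a geometry factor for
the mouth-corner stress concentration) seeds a short steady pilot run at
peak inflow; since spring deviation scales as 1/k, one multiplicative
correction sets the end-of-pilot deviation to 0.3% of the chamber
diameter (2 aV).  Pulsatile runs calibrate against the same steady pilot
(the sin² peak load equals the peak steady load).  Production runs abort
and restart with doubled stiffness if the deviation ever exceeds the 1%
rigid-wall contract, and with a halved step on numerical divergence;
pilots that diverge (soft walls let the flux controller wind up) restart
stiffer.

The step is the smaller of the advective CFL (0.2, with 1.8 Vin
headroom) and a tether-spring bound `2·sqrt(ρ h / k)`, extended in the
viscosity-dominated regime to `0.4·ρν/(k h)` where the implicit
diffusion overdamps the spring mode (verified empirically across the
Re range; the divergence backstop covers the remainder).

### Known numerical behaviors

* Boundary markers at the mouth corners drift slowly (~1e-4 chamber
  diameters per time unit) regardless of stiffness: the corner traction
  is mostly normal to the wall, and a normal force sheet is absorbed by
  the pressure field, so the spring reaction has almost no velocity
  response.  The drift is bounded over all run lengths used here and is
  included in the reported deviation maxima.
* Because of this drift, steady-state residuals floor near 3e-3
  (max |Δu|/Δt units).  Steady analyses therefore integrate to fixed
  physics-based horizons — 12 time units for Re ≤ 1, 50 for Re ≤ 30,
  60 above — rather than to a machine tolerance; the realized
  window-averaged residual (tolerance 5e-3) and a convergence flag are
  recorded with every run.
* The immersed wall is diffuse over the kernel support (~2h).  Fields
  within that fringe are regularization artifacts, not fluid; analyses
  that compare against closed forms (Stokes linearity, Poiseuille
  profiles) exclude it.

## Flow analysis

**Stream function.** ψ solves the discrete Poisson problem
(Dx² + Dy²)ψ = −ω in Fourier space (null modes of the centered
Laplacian dropped), plus the linear part from the mean flow, gauged to
zero on the lower channel wall.  Centered derivatives of ψ reproduce
(u, −v) to round-off for fields generated by centered differences.

**Vortex detection.** Candidates are strict interior local extrema of ψ
inside the (one-cell-eroded) cavity — in 2D incompressible flow such an
extremum is either a recirculation core or wall-kernel noise.  The two
are separated topologically, not by amplitude, because groove vortices
in near-stagnant fluid carve ψ-depths (~1e-5 Vchar·wAV) of the same
order as wall noise: (i) the innermost contour just off the extremum
must close inside the fluid with ≥ 80% of its vertices clear of the
one-cell wall fringe (real cores are interior; noise cores sit on the
wall); (ii) a log-spaced bisection finds the outermost level whose
contour still closes in the fluid around the candidate; (iii) that
contour must enclose at least 9 grid cells (a resolved core, not a
kernel-scale wiggle).  Rotation sense follows the extremum sign (maximum
= counterclockwise).  A vortex is *intertrabecular* if its center lies
in the near-wall band (within hT + rT of the smooth wall) between two
adjacent crests, *intracardial* if elsewhere in the cavity.  Extent is
the fraction of the cavity covered by the outermost closed contour
(contour area reaching into the channel does not count).  The detector
was validated against an independent RK4 particle-tracing oracle and
against direct near-wall velocity-reversal probes of the groove flow.

**Wall shear stress.** WSS = μ ∂u_t/∂n at the wall.  Because the
immersed wall is diffuse, the tangential velocity is sampled at offsets
2h, 3h, 4h along the inward normal (outside the smear), the exact
quadratic through the three samples is built, its zero crossing nearest
the wall is taken as the effective no-slip plane, and the slope is
evaluated there — exact for parabolic profiles regardless of the
kernel's wall shift (wall-averaged Poiseuille WSS within ~4% of
4μVmax/w at the fine tier).  Probes that leave the fluid (deep
concavities) flag the point invalid and it is excluded from averages.
TAWSS is |⟨WSS⟩| over one cycle and OSI = ½(1 − |⟨WSS⟩|/⟨|WSS|⟩),
clamped to [0, 0.5] and defined as 0 where the mean magnitude vanishes.
Region averages are arc-length weighted.

**Wall flow reversal** (used for the separation-onset call): tangential
velocity one cell inside the cavity arc, excluding 0.15 arc units next
to each mouth corner (their sub-resolution Stokes corner eddies are not
the chamber-scale reversal of interest); reversal requires a contiguous
negative stretch longer than twice the kernel support (8h) below
−max(2% of the forward maximum, 1e-3 Vchar).

## Sweep, tiers, and problem sizes

The bifurcation sweep runs each (Re, hT/bV, inflow-mode) cell to its
horizon, classifies per phase (pulsatile snapshots at 5, 10, 20, 40, 50,
80, 90, 95, 100% of the cycle; up to 4 cycles with early exit once the
cycle-to-cycle relative L2 difference of the whole snapshot stack falls
below 1%), and rolls up to `none | intertrabecular-only |
intracardial-only | both` ("vortex at any phase").  Cells cache on disk
keyed by the resolved cell configuration, so sweeps resume without
touching the solver.  Onset thresholds refine by bisection between
simulated values.

Reported results use the fine tier (256×128).  Onset Reynolds numbers
are mildly resolution dependent: at 128×64 the smooth-chamber separation
onset sits above Re = 30, at 256×128 it falls between 15 and 20, in
agreement with the reference value ≈ 15 for this chamber aspect ratio.
Unit tests run at `coarse`/`tiny` where the property under test is
resolution-robust.

## What the synthetic conditions do and do not show

All inputs are generated: the idealized chamber from the parameters
above, and a seeded spline-based generator of "realistic-like" ventricle
outlines (closed perturbed outline, inlet/outlet gaps, n inward
protrusions with Gaussian-distributed depths) standing in for traced
embryo geometries, which are not published.  Conclusions transfer to
real ventricles only at the level of mechanism — which flow topologies
exist in which (Re, height, pulsatility) regimes — not at the level of
individual vortex positions: real chambers beat (these walls are rigid),
are three-dimensional, and their trabeculae are irregular.  Blood is
treated as Newtonian; hematocrit effects enter only through the
effective viscosity folded into Re.

## Known limitations

* The steady intertrabecular onset is resolution-limited at the
  biologically relevant height.  At hT/bV = 0.08 the groove steepness
  sits exactly at the Stokes separation margin (k·a ≈ 0.8); the
  kernel-diffuse walls (~2h) tip the simulated grooves to attached at
  h = 1/64 and 1/96, so steady groove vortices appear here from
  hT/bV = 0.12 upward rather than from 0.08.  Resolving the marginal
  case needs grooves many kernel-widths wide, i.e. grids well beyond
  desk scale.
* Deviation creep at the mouth corners (above) makes extremely long
  integrations (hundreds of time units) eventually violate the 1%
  rigid-wall contract; all analyses here stay well inside it.
* The flux controller holds the inflow within ~2% of target; quantities
  proportional to the flux inherit that uncertainty.
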