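# Methods

`stillcan` simulates the thermal processing of a stationary (still) can of
peach halves in 20 % sugar syrup, and evaluates the microbial lethality the
process delivers at every point of the product. This note records the model,
its assumptions, the numerical choices, and what the verification suite does
and does not establish.

## Physical model

**System.** A closed tin can, 7.5 cm diameter × 10.5 cm height, completely
filled with syrup and four peach halves (no headspace), initially at 20 °C,
heated in a 100 °C medium for 20 min and then cooled in a 20 °C medium
(default 20 min; the cooling duration is configurable and the F value at the
end of heating is always reported alongside, so the sensitivity to this
choice is visible). The external heat-transfer coefficient is taken as
infinite and the metal wall resistance as negligible, so the inner can
surface follows the medium temperature exactly (Dirichlet condition). Flow
is laminar: the Rayleigh number built on the 7.5 mm annular peach–wall gap
at an 80 K driving difference and a 60 °C film temperature is ≈ 1.5×10⁶,
comfortably below the 10⁸ laminar bound (the can height as length scale
gives ≈ 10⁹, which is why the gap — the scale that actually controls the
boundary-layer flow between wall and particles — is used for the regime
check; both are exposed in `rayleigh_number`).

**Fluid.** Incompressible flow with the Boussinesq approximation: density is
constant except in the buoyancy force, which is linearised about a reference
temperature (default: the mean of the phase's starting fluid temperature and
the medium temperature, so ≈ 60 °C during heating of a 20 °C can at 100 °C).
Viscosity, conductivity and specific heat remain fully
temperature-dependent, via quadratic/cubic polynomial fits valid over
20–130 °C; evaluation outside that window is a hard error, not an
extrapolation, because the fits have no support there. The density fit's
quadratic coefficient is −2.4201×10⁻³ kg/(m³·°C²); the sign-flipped exponent
variant that sometimes appears in print (−2.4201×10³) makes density negative
above ~1 °C and is retained only behind `as_printed=True` for provenance.
Expansivity is derived analytically from the density fit, β = −ρ′(T)/ρ(T)
(≈ 3.15×10⁻⁴ 1/K at 20 °C).

**Solids.** Peach flesh is a constant-property solid (ρ = 1022 kg/m³,
Cp = 3992 J/(kg·K), k = 0.58 W/(m·K)). Each half is a half oblate spheroid
(semi-axes 30/20/30 mm, flat face horizontal) with the kernel cavity carved
into the flat face as a half ellipsoid (semi-axes 15/10/7.5 mm), leaving the
deliberately uneven flesh wall of a real peach half: 15 mm along x, 10 mm
along y, 22.5 mm along z. Only conduction acts inside the solids; the fluid
and solids share one temperature field (conjugate coupling).

**Cases.** Three orientation cases: `upward` (upright can, all cavities
opening to the can top), `downward` (cavities to the bottom), and `sideward`
(the downward arrangement with the can turned 90° about the mid-plane
normal, i.e. gravity along −x instead of −y). The axial placement of the
four halves is not uniquely determined by the geometry alone; the default
stacks them coaxially with equal 5 mm gaps above, below and between
(configurable). The halves clear the wall by 7.5 mm all round.

**Lethality.** The F value at a point is ∫10^((T−T_ref)/z) dt in equivalent
minutes at T_ref. Defaults: z = 11.5 °C (Clostridium butyricum), T_ref =
90 °C, D_ref = 1.1 min, six decimal reductions, hence a 6.6 min target F.
Accumulation is trapezoidal per voxel at every solver step (dt ≤ 0.5 s; no
subsampling). The critical point is the solid voxel of minimum accumulated
F over the whole process; the slowest-heating point is the coldest solid
voxel at the end of the heating phase (the criterion is configurable to
min-F-at-end-of-heating; both snapshots are stored). Per-particle minima are
reported both over all solid voxels and restricted to particle-interior
voxels (no fluid neighbour), since surface voxels see the hottest syrup.

## Discretisation

Uniform voxel grid over the can's bounding box, labels (fluid / solid /
exterior) assigned by voxel-centre membership; curved boundaries are
stair-stepped rather than body-fitted, and the volume-convergence tests
guard against gross error (solid volume within 3 % of the analytic
35.34 cm³ per half at 1 mm spacing). A point whose centre lies within
10⁻¹² m of the flat face counts as inside; without this, a face that lands
exactly on a voxel-centre plane flips a whole voxel layer on a 1-ulp
rounding difference.

Staggered (MAC) arrangement: velocities on faces, pressure and temperature
at centres. Momentum: explicit first-order upwind advection (a preliminary
comparison in the source study found no difference between first- and
second-order upwinding for this problem), explicit stability-limited
diffusion with face-interpolated ν(T), explicit Boussinesq buoyancy, then a
pressure projection. The projection solves the Neumann Poisson problem with
a prefactorised sparse direct solver (one factorisation per scene, one cell
pinned per connected fluid component), so the post-projection divergence is
at round-off; the configured tolerance (10⁻⁶ relative to max|u*|/h) is a
guard that raises if the solve degrades. No-slip applies on the can wall and
on every solid face.

Energy: conservative flux form. One conductive flux per face with
harmonic-mean face conductivity (the conservative choice across
fluid/solid interfaces), Dirichlet wall fluxes over the half-cell distance,
and upwinded advective fluxes of ρCpT across fluid–fluid faces. Because
each face flux is computed once and added/subtracted to the two adjacent
cells, the scheme conserves exactly: the change of Σ ρCp·V·T over a step
equals the net wall conductive heat × dt (asserted to 10⁻⁸ relative each
step in the tests). Upwinding of g(T) = ρ(T)Cp(T)·T (monotone in T over the
process range) keeps the update a convex combination under the CFL limit,
so temperatures respect the 20–100 °C maximum principle.

Time stepping: dt = min(0.5 s cap, advective Courant limit with target 0.5
on the per-cell sum of face speeds, 0.45 × the explicit viscous limit,
0.9 × h²/(12 α_max) for conduction — the factor 12 covers the half-distance
wall faces). The advective and viscous fractions sum below one, which keeps
the combined explicit update stable; `energy_step` additionally recomputes
the exact per-cell conduction limit and raises if violated. The final step
of a phase is truncated to land on the phase duration exactly.

Mid-plane symmetry (z ≥ 0 half-domain) is supported via reflected ghost
layers (zero normal flow, zero gradient at the plane) and verified against
full-domain runs; the full domain is the default, the half-domain is used
for the desk-scale study runs.

## Verification strategy and limits

* **Analytic conduction oracles.** With buoyancy off, the solver must
  reproduce textbook series solutions: an all-solid rectangular block
  (exact product of three slab series — no geometric error, isolates the
  conduction kernel) and the voxelized miniature cylinder against the
  finite-cylinder product solution, within 1 % of the 80 K driving
  difference at Fourier numbers 0.1–0.4.
* **Closed-form lethality.** Constant holds and linear ramps have exact
  antiderivatives; the trapezoidal integrator matches them to 10⁻⁴ at 1 s
  sampling, and the per-step field accumulator is algebraically identical
  to the profile integrator (10⁻¹²).
* **Structure.** Divergence-free projection, per-step energy conservation,
  the maximum principle, voxel-volume convergence, and mirror equivalence:
  the upward scene with inverted gravity must equal the mirrored downward
  scene. Lockstep steps agree to machine precision (10⁻⁹), which pins the
  scene/gravity wiring. Over 60 s at full gravity, however, the coarse-grid
  plume pattern is physically unstable and amplifies the solver's round-off
  (the direct solver's elimination order differs between the mirrored
  grids) to order-one differences — a property of the flow, not a wiring
  defect — so the 60 s mirror and mid-plane-symmetry checks run in a mildly
  buoyant steady regime (g = 0.3 m/s²) where 10⁻⁶ agreement is meaningful.
* **Study orderings.** At desk scale (2.5 mm, half-domain, full schedule)
  the three-case study must reproduce the qualitative findings: critical-F
  ordering upward < downward < sideward; critical points of the upright
  cases in the bottom peach half; the sideward per-particle minima tightest;
  the upward case heating slowest at its critical point, with its critical
  and slowest-heating points coinciding. "Coinciding" is evaluated as
  agreement within one voxel per axis: the two discrete argmins sit in the
  same flat basin and can land on adjacent voxels.

**What desk scale does not show.** The reference results for this system
were produced by a commercial finite-volume solver on a ~74k-cell
body-fitted tetrahedral mesh; a 2.5 mm stair-stepped grid (~19k half-domain
voxels) cannot and does not reproduce printed velocities, F ranges or
critical-point millimetre coordinates quantitatively. Observed desk-scale
values are nonetheless close in magnitude (e.g. 30 s heating maximum speeds
of ~2.4 cm/s against reported ~2.6, critical point within a few mm of the
reported location), and all ordering/direction claims are reproduced. The
simulator also omits: container wall conduction, finite external heat
transfer, headspace, turbulence (irrelevant at these Rayleigh numbers), and
any validation against physical thermocouple data, which is out of scope.

## Parameters that matter

| Parameter | Default | Units | Notes |
| --- | --- | --- | --- |
| spacing | 2.5 | mm | study grid; 1.5 mm for miniature scenes |
| dt cap | 0.5 | s | never exceeded |
| Courant target | 0.5 | – | on the per-cell sum of face speeds |
| pressure tolerance | 1e-6 | – | relative post-projection divergence guard |
| buoyancy reference T | phase mean | °C | β and ρ₀ evaluated here |
| heating | 100 °C, 20 min | | process schedule |
| cooling | 20 °C, 20 min | | duration is a reporting choice |
| z, T_ref, D_ref | 11.5 °C, 90 °C, 1.1 min | | C. butyricum in acid food |
| gravity | 9.81 | m/s² | reduced only in stability-sensitive tests |

## Known limitations

Stair-step geometry under-resolves the 2–3-cell flow channels between
particles at 2.5 mm, adding numerical dissipation; first-order upwinding
adds more. Both bias velocities low and smooth the F field, which is why
quantitative desk-scale values are treated as indicative. The flat-face
alignment tolerance (10⁻¹² m) means a face lying exactly on a voxel-centre
plane is included deterministically rather than by rounding luck. The
lethality integrator assumes first-order (log-linear) thermal death; no
Weibull or quality-retention kinetics are provided.
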