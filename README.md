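# stillcan

Natural-convection thermal processing of a still (non-rotating) can of
peach halves in sugar syrup: laminar buoyancy-driven flow, conjugate heat
transfer between syrup and particles, per-voxel process lethality
(F value), and critical-point location — for food-process engineers and
predictive-microbiology researchers who want a transparent, fully scripted
alternative to black-box CFD for liquid/particulate canning problems.

## The model in brief

A 7.5 × 10.5 cm can holds four peach halves (half oblate spheroids with a
kernel cavity carved into the flat face) in 20 % sugar syrup. The can is
heated 20 min in a 100 °C medium and then cooled at 20 °C, with an infinite
external heat-transfer coefficient (wall follows the medium). Syrup flow is
incompressible and laminar (gap Rayleigh number ≈ 1.5×10⁶ < 10⁸) with the
Boussinesq approximation and temperature-dependent μ, k, Cp; the peach flesh
is a constant-property conducting solid sharing the temperature field.

Microbial destruction at a point follows classical thermobacteriology:

    F = ∫ 10^((T(t) − T_ref)/z) dt        [equivalent min at T_ref]

with z = 11.5 °C, T_ref = 90 °C (Clostridium butyricum in acid food) and a
target F of 6 log reductions × D₉₀ (1.1 min) = **6.6 min**. The *critical
point* is the location accumulating the least F over the whole process.

Three particle-orientation cases are built in: cavities opening **upward**,
**downward**, and the downward can laid on its side (**sideward**). The
solver is a staggered-grid finite-volume scheme (first-order upwind
advection, exact-projection pressure solve, conservative conjugate energy
fluxes) on a voxelized geometry; see `docs/methods.md` for the details and
verification strategy.

## Worked example

Integrate the lethality of a measured (or synthetic) time–temperature log:

```bash
$ stillcan fixtures --out profile.csv --hold-min 10   # heat–hold–cool oracle
wrote profile.csv (1201 samples)
$ stillcan lethality profile.csv
F = 10.7136 min (T_ref=90.0 C, z=11.5 C)
```

The 10.71 min agrees with the closed form for that trapezoidal profile
(each 5 min ramp between 20 and 90 °C contributes 0.36 min, the 10 min hold
at 90 °C exactly 10 min) and exceeds the 6.6 min target.

Simulate one orientation case end to end (minutes of wall time):

```python
from stillcan import CaseConfig, run_case

report = run_case(CaseConfig(case_name="upward", spacing=0.0025, symmetry=True))
print(round(report.max_speed_heating_30s * 100, 2), "cm/s at 30 s of heating")
print([round(f, 1) for f in report.per_particle_min_F], "min (per-half minimum F)")
print(report.critical_point.location_mm, "mm; F_min =", round(report.F_min, 1))
```

prints (desk-scale 2.5 mm grid):

```
2.36 cm/s at 30 s of heating
[26.3, 28.9, 32.9, 33.9] min (per-half minimum F)
(-1.25, -36.25, 3.75) mm; F_min = 24.7
```

i.e. syrup rises along the hot wall at a couple of cm/s, the least-processed
peach half is the bottom one, and the critical point sits in its upper
(cavity-side) region, about 36 mm below the can centre — every interior
point still receives far more than the 6.6 min target under this schedule.
`stillcan study` runs all three orientations and reports the cross-case
comparison (the upward case accumulates the least lethality at its critical
point, the sideward case the most, with near-identical per-half minima).

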