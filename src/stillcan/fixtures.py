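"""Analytic oracles and miniature scenes for solver verification.

Everything here is generated in memory:

* transient conduction series solutions (slab, infinite cylinder, and the
  finite cylinder as their product) with a step change of wall temperature —
  the reference the conjugate solver must reproduce when buoyancy is off;
* piecewise-linear time–temperature profiles whose F value has a closed
  form, for exercising the lethality integrator;
* small cans (30 × 42 mm) with zero or one particle that voxelize and solve
  in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.special import j0, j1, jn_zeros

from .geometry import CanSpec, PeachHalfSpec, Scene, Sphere

__all__ = [
    "AnalyticConductionSpec",
    "analytic_temperature",
    "SyntheticProfileSpec",
    "make_profile",
    "mini_scene",
]

GEOMETRIES = ("slab", "infinite_cylinder", "finite_cylinder")


@dataclass(frozen=True)
class AnalyticConductionSpec:
    """Step-response conduction problem with a Dirichlet boundary.

    ``half_thickness`` is the slab half width and the cylinder half height;
    ``radius`` the cylinder radius.  ``diffusivity`` is in m²/s.
    """

    geometry: str = "finite_cylinder"
    half_thickness: float = 0.021
    radius: float = 0.015
    diffusivity: float = 1.4e-7
    initial_T: float = 20.0
    wall_T: float = 100.0
    series_terms: int = 50

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}")
        if self.series_terms < 25:
            raise ValueError("series_terms must be at least 25")
        if self.half_thickness <= 0 or self.radius <= 0 or self.diffusivity <= 0:
            raise ValueError("dimensions and diffusivity must be positive")


def _theta_slab(xi: np.ndarray, fo: float, terms: int) -> np.ndarray:
    """Dimensionless excess temperature of a slab, |xi| ≤ 1, Dirichlet walls."""
    n = np.arange(terms)
    lam = (2 * n + 1) * np.pi / 2.0
    coeff = 2.0 * (-1.0) ** n / lam
    decay = np.exp(-np.outer(np.atleast_1d(fo), lam**2))
    modes = np.cos(np.outer(np.atleast_1d(xi), lam))
    return (modes * coeff * decay).sum(axis=-1)


def _theta_cylinder(eta: np.ndarray, fo: float, terms: int) -> np.ndarray:
    """Dimensionless excess temperature of an infinite cylinder, eta = r/R."""
    lam = jn_zeros(0, terms)
    coeff = 2.0 / (lam * j1(lam))
    decay = np.exp(-np.outer(np.atleast_1d(fo), lam**2))
    modes = j0(np.outer(np.atleast_1d(eta), lam))
    return (modes * coeff * decay).sum(axis=-1)


def analytic_temperature(spec: AnalyticConductionSpec, point, t: float):
    """Series temperature (°C) at ``point`` (m) and time ``t`` (s).

    ``point``: for a slab only the first coordinate is used (distance from
    the mid-plane); for cylinders, the axial coordinate is the second entry
    and the radial distance is taken in the x–z plane, matching the can
    convention.  At t = 0 the initial temperature is returned exactly.
    """
    p = np.asarray(point, dtype=float)
    if p.shape[-1] != 3:
        raise ValueError("point must have three coordinates")
    if t < 0:
        raise ValueError("time must be non-negative")
    L = spec.half_thickness
    R = spec.radius
    x, y, z = p[..., 0], p[..., 1], p[..., 2]
    r = np.hypot(x, z)

    if spec.geometry == "slab":
        inside = np.abs(x) <= L * (1 + 1e-12)
    elif spec.geometry == "infinite_cylinder":
        inside = r <= R * (1 + 1e-12)
    else:
        inside = (r <= R * (1 + 1e-12)) & (np.abs(y) <= L * (1 + 1e-12))
    if not np.all(inside):
        raise ValueError("point outside the geometry")

    if t == 0.0:
        theta = np.ones_like(r)
    else:
        if spec.geometry == "slab":
            fo = spec.diffusivity * t / L**2
            theta = _theta_slab(x / L, fo, spec.series_terms)
        elif spec.geometry == "infinite_cylinder":
            fo = spec.diffusivity * t / R**2
            theta = _theta_cylinder(r / R, fo, spec.series_terms)
        else:
            fo_ax = spec.diffusivity * t / L**2
            fo_rad = spec.diffusivity * t / R**2
            theta = (
                _theta_slab(y / L, fo_ax, spec.series_terms)
                * _theta_cylinder(r / R, fo_rad, spec.series_terms)
            )
    out = spec.wall_T + (spec.initial_T - spec.wall_T) * np.asarray(theta)
    if p.ndim == 1:
        return float(out.reshape(-1)[0])
    return out.reshape(p.shape[:-1])


@dataclass(frozen=True)
class SyntheticProfileSpec:
    """Piecewise-linear time–temperature profile.

    ``segments`` is a sequence of (duration_min, start °C, end °C) pieces;
    consecutive pieces must be contiguous in temperature.
    """

    segments: Tuple[Tuple[float, float, float], ...]
    sampling_interval_s: float = 1.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("need at least one segment")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling interval must be positive")
        prev_end = None
        for dur, t1, t2 in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")
            if prev_end is not None and abs(t1 - prev_end) > 1e-9:
                raise ValueError("segments must be contiguous in temperature")
            prev_end = t2


def make_profile(spec: SyntheticProfileSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Sample a piecewise-linear profile; segment endpoints are hit exactly.

    Returns (times in s, temperatures in °C).
    """
    times = [0.0]
    temps = [spec.segments[0][1]]
    t0 = 0.0
    for dur_min, T1, T2 in spec.segments:
        dur_s = dur_min * 60.0
        n = max(1, int(np.ceil(dur_s / spec.sampling_interval_s - 1e-12)))
        local = np.minimum((np.arange(1, n + 1)) * spec.sampling_interval_s, dur_s)
        # force the exact endpoint even when the interval does not divide it
        if abs(local[-1] - dur_s) > 1e-12:
            local = np.append(local, dur_s)
        times.extend((t0 + local).tolist())
        temps.extend((T1 + (T2 - T1) * local / dur_s).tolist())
        t0 += dur_s
    return np.asarray(times), np.asarray(temps)


def mini_scene(kind: str = "empty_can") -> Scene:
    """Miniature can (30 × 42 mm) with at most one particle.

    Kinds: ``empty_can`` (all syrup), ``single_sphere`` (9 mm radius sphere
    at the centre), ``single_peach_half`` (a 2/3-scale peach half, cavity
    opening upward).  All voxelize at 1.5 mm spacing and solve in seconds.
    """
    can = CanSpec(diameter=0.030, height=0.042)
    if kind == "empty_can":
        particles: Tuple = ()
    elif kind == "single_sphere":
        particles = (Sphere(center=(0.0, 0.0, 0.0), radius=0.009),)
    elif kind == "single_peach_half":
        particles = (
            PeachHalfSpec(
                flesh_semi_axes=(0.010, 0.00667, 0.010),
                cavity_semi_axes=(0.005, 0.00333, 0.0025),
                flat_center=(0.0, 0.00333, 0.0),
                opening=(0.0, 1.0, 0.0),
            ),
        )
    else:
        raise ValueError(
            "kind must be 'empty_can', 'single_sphere' or 'single_peach_half'"
        )
    return Scene(can=can, particles=particles, gravity_unit=(0.0, -1.0, 0.0),
                 case_name=f"mini_{kind}")
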