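"""Can + peach-half scene construction and voxelization.

Coordinate convention: the origin sits at the geometric centre of the can,
``y`` is the axis of the upright can (positive up), and ``z`` is normal to
the mid-plane of symmetry.  All case outputs report coordinates in mm
relative to this origin.

A peach half is a half oblate spheroid (flat face horizontal in the upright
can) with the kernel cavity carved into the flat face as a half ellipsoid.
With the default dimensions (flesh semi-axes 30/20/30 mm, cavity semi-axes
15/10/7.5 mm) the remaining flesh thickness is 15 mm along x, 10 mm along y
and 22.5 mm along z — the deliberately uneven wall of a real peach half.

Three study cases exist:

``upward``   – upright can, all cavities opening toward the can top;
``downward`` – upright can, all cavities opening toward the can bottom;
``sideward`` – the downward arrangement with the can lying on its side,
               i.e. gravity rotated 90° about the mid-plane normal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "FLUID",
    "SOLID",
    "EXTERIOR",
    "CASE_NAMES",
    "GeometryError",
    "ResolutionError",
    "CanSpec",
    "PeachHalfSpec",
    "Sphere",
    "Scene",
    "VoxelScene",
    "point_material",
    "build_case",
    "voxelize",
]

FLUID, SOLID, EXTERIOR = 0, 1, 2
CASE_NAMES = ("upward", "downward", "sideward")


class GeometryError(ValueError):
    """Scene layout impossible (particles overflow the can)."""


class ResolutionError(ValueError):
    """Voxel spacing too coarse for the requested scene."""


@dataclass(frozen=True)
class CanSpec:
    """Right circular cylinder, dimensions in metres."""

    diameter: float = 0.075
    height: float = 0.105

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.height <= 0:
            raise ValueError("can dimensions must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def volume(self) -> float:
        return np.pi * self.radius**2 * self.height


@dataclass(frozen=True)
class PeachHalfSpec:
    """Posed peach half: half oblate spheroid minus kernel-cavity half ellipsoid.

    ``flat_center`` is the centre of the flat face in can coordinates and
    ``opening`` the unit vector the cavity opens toward (±y in the upright
    can).  The local frame keeps x and z aligned with the can axes, so the
    pose is a pure reflection/identity along y — sufficient for the ordered
    arrangements studied here.
    """

    flesh_semi_axes: Tuple[float, float, float] = (0.030, 0.020, 0.030)
    cavity_semi_axes: Tuple[float, float, float] = (0.015, 0.010, 0.0075)
    flat_center: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    opening: Tuple[float, float, float] = (0.0, 1.0, 0.0)

    def __post_init__(self) -> None:
        a = np.asarray(self.flesh_semi_axes)
        ac = np.asarray(self.cavity_semi_axes)
        if np.any(a <= 0) or np.any(ac <= 0):
            raise ValueError("semi-axes must be positive")
        if not np.all(ac < a):
            raise ValueError("cavity semi-axes must be smaller than flesh semi-axes")
        n = np.asarray(self.opening, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9 or abs(n[0]) > 1e-12 or abs(n[2]) > 1e-12:
            raise ValueError("opening must be a unit vector along ±y")

    @property
    def flesh_thickness(self) -> Tuple[float, float, float]:
        """Minimum flesh wall thickness along the local x, y, z axes (m)."""
        a = np.asarray(self.flesh_semi_axes)
        ac = np.asarray(self.cavity_semi_axes)
        return tuple(a - ac)

    @property
    def volume(self) -> float:
        """Analytic flesh volume (half spheroid minus half cavity ellipsoid)."""
        a, b, c = self.flesh_semi_axes
        ca, cb, cc = self.cavity_semi_axes
        return (2.0 / 3.0) * np.pi * (a * b * c - ca * cb * cc)

    def _local(self, points: np.ndarray) -> np.ndarray:
        d = np.asarray(points, dtype=float) - np.asarray(self.flat_center)
        sign = 1.0 if self.opening[1] > 0 else -1.0
        local = d.copy()
        local[..., 1] = sign * d[..., 1]
        return local

    def classify(self, points: np.ndarray) -> np.ndarray:
        """0 = outside, 1 = flesh, 2 = cavity, for an (..., 3) point array."""
        local = self._local(points)
        x, y, z = local[..., 0], local[..., 1], local[..., 2]
        a, b, c = self.flesh_semi_axes
        ca, cb, cc = self.cavity_semi_axes
        # absolute slack keeps points computed to lie exactly on the flat
        # face (a frequent grid alignment) deterministically inside
        below = y <= 1e-12
        in_flesh_env = below & ((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0)
        in_cavity = below & ((x / ca) ** 2 + (y / cb) ** 2 + (z / cc) ** 2 <= 1.0)
        out = np.zeros(x.shape, dtype=np.int8)
        out[in_flesh_env] = 1
        out[in_cavity] = 2
        return out

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.classify(points) == 1

    @property
    def bounds_y(self) -> Tuple[float, float]:
        """Axial extent (m) in can coordinates."""
        b = self.flesh_semi_axes[1]
        yc = self.flat_center[1]
        return (yc - b, yc) if self.opening[1] > 0 else (yc, yc + b)


@dataclass(frozen=True)
class Sphere:
    """Solid sphere particle (used by miniature verification scenes)."""

    center: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 0.01

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.asarray(points, dtype=float) - np.asarray(self.center)
        return np.einsum("...i,...i->...", d, d) <= self.radius**2


def point_material(spec: PeachHalfSpec, point) -> str:
    """Classify one point against a posed peach half.

    Returns ``"flesh"``, ``"cavity"`` or ``"outside"``.  The cavity wins over
    flesh (it is carved out of the flesh envelope).
    """
    code = int(spec.classify(np.asarray(point, dtype=float)))
    return {0: "outside", 1: "flesh", 2: "cavity"}[code]


@dataclass(frozen=True)
class Scene:
    """Can, posed particles and the gravity direction of one study case."""

    can: CanSpec
    particles: Tuple = ()
    gravity_unit: Tuple[float, float, float] = (0.0, -1.0, 0.0)
    case_name: str = "custom"

    def __post_init__(self) -> None:
        g = np.asarray(self.gravity_unit, dtype=float)
        if abs(np.linalg.norm(g) - 1.0) > 1e-9:
            raise ValueError("gravity_unit must be a unit vector")


def build_case(
    case: str,
    can: Optional[CanSpec] = None,
    peach: Optional[PeachHalfSpec] = None,
    n_halves: int = 4,
) -> Scene:
    """Build the ordered four-peach-half scene for one orientation case.

    The halves are stacked coaxially on the can axis, flat faces horizontal,
    with equal axial gaps above, below and between the particles.  ``peach``
    supplies the (unposed) particle dimensions.
    """
    if case not in CASE_NAMES:
        raise ValueError(f"case must be one of {CASE_NAMES}")
    can = can or CanSpec()
    base = peach or PeachHalfSpec()

    a, b, c = base.flesh_semi_axes
    if max(a, c) > can.radius:
        raise GeometryError("peach equatorial radius exceeds can radius")
    gap = (can.height - n_halves * b) / (n_halves + 1)
    if gap < 0:
        raise GeometryError("peach stack taller than the can interior")

    upward = case == "upward"
    particles: List[PeachHalfSpec] = []
    y0 = -can.height / 2.0
    for i in range(n_halves):
        slot_bottom = y0 + gap + i * (b + gap)
        if upward:
            center_y = slot_bottom + b      # flat face at slot top, dome below
            opening = (0.0, 1.0, 0.0)
        else:
            center_y = slot_bottom          # flat face at slot bottom, dome above
            opening = (0.0, -1.0, 0.0)
        particles.append(
            replace(base, flat_center=(0.0, center_y, 0.0), opening=opening)
        )

    if case == "sideward":
        gravity = (-1.0, 0.0, 0.0)  # can turned 90° clockwise about z
    else:
        gravity = (0.0, -1.0, 0.0)
    return Scene(can=can, particles=tuple(particles), gravity_unit=gravity,
                 case_name=case)


@dataclass
class VoxelScene:
    """Labelled structured grid for one scene.

    ``labels`` holds FLUID/SOLID/EXTERIOR per voxel (shape ``dims``, C order
    x, y, z); ``particle_id`` is −1 in non-solid voxels and the particle index
    otherwise.  ``origin`` is the coordinate of the grid corner (the low face
    of voxel (0,0,0)); with mid-plane symmetry only the half-space z ≥ 0 is
    gridded and the mid-plane is the low-z grid face.
    """

    spacing: float
    dims: Tuple[int, int, int]
    origin: Tuple[float, float, float]
    labels: np.ndarray
    particle_id: np.ndarray
    gravity_unit: Tuple[float, float, float]
    case_name: str
    symmetry: bool
    can: CanSpec

    def __post_init__(self) -> None:
        g = np.asarray(self.gravity_unit, dtype=float)
        if abs(np.linalg.norm(g) - 1.0) > 1e-9:
            raise ValueError("gravity_unit must be a unit vector")
        if self.labels.shape != tuple(self.dims):
            raise ValueError("labels shape does not match dims")

    @property
    def cell_volume(self) -> float:
        return self.spacing**3

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.dims[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing

    def cell_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-centre coordinates (m)."""
        xs, ys, zs = (self.axis_centers(i) for i in range(3))
        grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
        return grid

    @property
    def fluid(self) -> np.ndarray:
        return self.labels == FLUID

    @property
    def solid(self) -> np.ndarray:
        return self.labels == SOLID

    @property
    def interior(self) -> np.ndarray:
        return self.labels != EXTERIOR

    def solid_volume(self) -> float:
        """Voxel-counted solid volume (m³); doubled under symmetry."""
        v = int(self.solid.sum()) * self.cell_volume
        return 2.0 * v if self.symmetry else v

    def interior_volume(self) -> float:
        v = int(self.interior.sum()) * self.cell_volume
        return 2.0 * v if self.symmetry else v

    def index_to_mm(self, idx: Sequence[int]) -> Tuple[float, float, float]:
        """Voxel index → centre coordinates in mm from the can centre."""
        return tuple(
            1000.0 * (self.origin[a] + (idx[a] + 0.5) * self.spacing)
            for a in range(3)
        )


def voxelize(scene: Scene, spacing: float, symmetry: bool = False) -> VoxelScene:
    """Voxelize a scene by voxel-centre membership onto a uniform grid."""
    can = scene.can
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    nd = can.diameter / spacing
    nh = can.height / spacing
    if nd < 8 - 1e-9 or nh < 8 - 1e-9:
        raise ResolutionError(
            "spacing must divide the can diameter and height into >= 8 cells"
        )
    nx = int(round(nd))
    ny = int(round(nh))
    nz = int(round(can.radius / spacing)) if symmetry else nx
    origin = (-can.radius, -can.height / 2.0, 0.0 if symmetry else -can.radius)

    xs = origin[0] + (np.arange(nx) + 0.5) * spacing
    ys = origin[1] + (np.arange(ny) + 0.5) * spacing
    zs = origin[2] + (np.arange(nz) + 0.5) * spacing
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)

    inside_can = (X**2 + Z**2 <= can.radius**2) & (np.abs(Y) <= can.height / 2.0)
    labels = np.full((nx, ny, nz), EXTERIOR, dtype=np.int8)
    labels[inside_can] = FLUID
    particle_id = np.full((nx, ny, nz), -1, dtype=np.int16)
    for pid, particle in enumerate(scene.particles):
        mask = particle.contains(pts) & inside_can
        labels[mask] = SOLID
        particle_id[mask] = pid

    return VoxelScene(
        spacing=spacing,
        dims=(nx, ny, nz),
        origin=origin,
        labels=labels,
        particle_id=particle_id,
        gravity_unit=scene.gravity_unit,
        case_name=scene.case_name,
        symmetry=symmetry,
        can=can,
    )
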