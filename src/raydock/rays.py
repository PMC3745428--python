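"""Ray representation of a pocket and the rayfile text format.

Every shell point becomes a *pocket* ray and every forbidden point a
*forbidden* ray: direction in spherical coordinates about the buried origin,
plus the distance rho at which the ray meets the protein surface.  The
rayfile persists this topography so docking never touches the protein again.

Spherical convention: theta is the polar angle from +z in [0, 180] degrees,
phi the azimuth from +x in (-180, 180] degrees; phi is defined as 0 at the
poles.  Files store degrees with fixed 6-decimal fields; conversions are
exact to float round-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from .pocket import PocketDefinition

__all__ = [
    "Ray",
    "RaySet",
    "RayfileError",
    "cartesian_to_spherical",
    "spherical_to_cartesian",
    "build_rayset",
    "write_rayfile",
    "read_rayfile",
]

POCKET = "pocket"
FORBIDDEN = "forbidden"


class RayfileError(ValueError):
    """Malformed rayfile."""


@dataclass(frozen=True)
class Ray:
    kind: str  # POCKET or FORBIDDEN
    theta: float  # degrees, [0, 180]
    phi: float  # degrees, (-180, 180]
    rho: float  # Å, distance origin -> defining surface point

    def __post_init__(self):
        if self.kind not in (POCKET, FORBIDDEN):
            raise ValueError(f"bad ray kind {self.kind!r}")
        if not (0.0 <= self.theta <= 180.0):
            raise ValueError(f"theta out of range: {self.theta}")
        if not (-180.0 < self.phi <= 180.0):
            raise ValueError(f"phi out of range: {self.phi}")
        if self.rho <= 0:
            raise ValueError(f"rho must be positive: {self.rho}")

    @property
    def direction(self) -> np.ndarray:
        return spherical_to_cartesian(self.theta, self.phi)


def cartesian_to_spherical(point, origin) -> Tuple[float, float, float]:
    """(theta°, phi°, rho) of *point* about *origin*; phi := 0 at the poles."""
    v = np.asarray(point, dtype=float) - np.asarray(origin, dtype=float)
    rho = float(np.linalg.norm(v))
    if rho < 1e-12:
        raise ValueError("point coincides with origin")
    theta = math.degrees(math.acos(max(-1.0, min(1.0, v[2] / rho))))
    if theta <= 0.0 or theta >= 180.0:
        phi = 0.0
    else:
        phi = math.degrees(math.atan2(v[1], v[0]))
        if phi <= -180.0:
            phi = 180.0
    return theta, phi, rho


def spherical_to_cartesian(theta_deg: float, phi_deg: float) -> np.ndarray:
    """Unit direction vector for (theta, phi) in degrees."""
    t = math.radians(theta_deg)
    p = math.radians(phi_deg)
    st = math.sin(t)
    return np.array([st * math.cos(p), st * math.sin(p), math.cos(t)])


@dataclass
class RaySet:
    origin: np.ndarray  # (3,) Å
    rays: List[Ray]

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        if not any(r.kind == POCKET for r in self.rays):
            raise ValueError("RaySet needs at least one pocket ray")

    @property
    def n_pocket(self) -> int:
        return sum(1 for r in self.rays if r.kind == POCKET)

    @property
    def n_forbidden(self) -> int:
        return sum(1 for r in self.rays if r.kind == FORBIDDEN)

    def directions(self) -> np.ndarray:
        """(n, 3) unit direction per ray, in file order."""
        return np.array([r.direction for r in self.rays])

    def rhos(self) -> np.ndarray:
        return np.array([r.rho for r in self.rays])

    def kinds_pocket(self) -> np.ndarray:
        """Boolean mask, True where the ray is a pocket ray."""
        return np.array([r.kind == POCKET for r in self.rays])


def build_rayset(pocket: PocketDefinition) -> RaySet:
    """Cast one ray per shell point (pocket) and per forbidden point.

    Rays whose (theta, phi) agree to 1e-6 degrees are collapsed keeping the
    smaller rho (the nearer surface point shadows the farther one).
    """
    if pocket.origin is None:
        raise ValueError("pocket origin not set; run compute_ray_origin first")
    if len(pocket.shell_points) == 0:
        raise ValueError("pocket has no shell points")
    best: Dict[Tuple[str, float, float], Ray] = {}
    order: List[Tuple[str, float, float]] = []
    for kind, pts in ((POCKET, pocket.shell_points), (FORBIDDEN, pocket.forbidden_points)):
        for p in pts:
            theta, phi, rho = cartesian_to_spherical(p, pocket.origin)
            key = (kind, round(theta, 6), round(phi, 6))
            if key in best:
                if rho < best[key].rho:
                    best[key] = Ray(kind, theta, phi, rho)
            else:
                best[key] = Ray(kind, theta, phi, rho)
                order.append(key)
    return RaySet(origin=np.array(pocket.origin, dtype=float), rays=[best[k] for k in order])


_HEADER = "DARC_RAYFILE v1"


def write_rayfile(rayset: RaySet, path: str | Path) -> None:
    """Write the rayset as text: header, origin line, one `kind theta phi rho` per ray."""
    lines = [_HEADER, "origin {:.6f} {:.6f} {:.6f}".format(*rayset.origin)]
    for r in rayset.rays:
        lines.append(f"{r.kind} {r.theta:.6f} {r.phi:.6f} {r.rho:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_rayfile(path: str | Path) -> RaySet:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != _HEADER:
        raise RayfileError(f"{path}: missing or unsupported header (expected {_HEADER!r})")
    if len(lines) < 2 or not lines[1].startswith("origin"):
        raise RayfileError(f"{path}: line 2 must be the origin line")
    try:
        origin = np.array([float(x) for x in lines[1].split()[1:4]])
        if origin.shape != (3,):
            raise ValueError
    except ValueError:
        raise RayfileError(f"{path}: line 2: bad origin line {lines[1]!r}") from None
    rays: List[Ray] = []
    for ln, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split()
        try:
            if len(parts) != 4:
                raise ValueError
            rays.append(Ray(parts[0], float(parts[1]), float(parts[2]), float(parts[3])))
        except ValueError:
            raise RayfileError(f"{path}: line {ln}: malformed ray record {line!r}") from None
    if not rays:
        raise RayfileError(f"{path}: no rays found")
    return RaySet(origin=origin, rays=rays)
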