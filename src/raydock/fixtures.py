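"""Synthetic analytic fixtures: pockets with known geometry and planted ligands.

The planted fixture builds a ray map whose pocket distances are the exact
closed-form first-hit distances of a single-sphere ligand, so the planted
pose scores exactly 0 — the perfect shape complement.  A toy slab receptor
with a hemispherical pit exercises the grid pipeline end to end, and a
random multi-sphere library stands in for a screening deck.  All of it is
generated from seeds; no external data is needed anywhere.

`brute_force_score` is a deliberately naive pure-Python scorer (ray → atom
→ quadratic root) kept independent of the vectorized implementation so the
two can be checked against each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .pso import Compound
from .rays import FORBIDDEN, POCKET, Ray, RaySet, cartesian_to_spherical
from .scoring import PoseTransform, ScoreWeights
from .structures import Atom, LigandConformer, ProteinStructure

__all__ = [
    "FixtureSpec",
    "make_planted_fixture",
    "make_random_library",
    "make_toy_receptor",
    "brute_force_score",
    "planted_hit_distance",
]

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class FixtureSpec:
    """Geometry of a planted single-sphere pocket/ligand pair.

    The ligand sphere (radius r) sits at distance D from the origin along
    +z; pocket rays are confined to a cone about +z narrow enough that all
    of them hit the sphere.
    """

    n_pocket_rays: int = 500
    n_forbidden_rays: int = 50
    ligand_center_distance: float = 12.0  # D, Å
    ligand_radius: float = 2.0  # r, Å
    cone_half_angle: float = 8.0  # degrees
    seed: int = 0

    def __post_init__(self):
        if not (self.ligand_center_distance > self.ligand_radius > 0):
            raise ValueError("need D > r > 0")
        if self.n_pocket_rays < 1 or self.n_forbidden_rays < 0:
            raise ValueError("need >=1 pocket ray and >=0 forbidden rays")

    @property
    def angular_radius(self) -> float:
        """Half-angle (degrees) of the cone subtended by the ligand sphere."""
        return math.degrees(math.asin(self.ligand_radius / self.ligand_center_distance))


def planted_hit_distance(direction: np.ndarray, D: float, r: float) -> float:
    """Closed-form first-hit distance t(u) = u·c - sqrt((u·c)^2 - (D^2 - r^2))
    for a unit ray *direction* against a sphere of radius r centered at
    c = (0, 0, D).  Raises if the ray misses.

    The operation order matches the ray–sphere quadratic as the scorers
    evaluate it, so a rho stored from this function reproduces the scorer's
    hit distance bit for bit.
    """
    uc = float(direction[2]) * D
    disc = uc * uc - (D * D - r * r)
    if disc < 0:
        raise ValueError("ray direction misses the planted sphere")
    return uc - math.sqrt(disc)


def _cone_directions(n: int, half_angle_deg: float) -> np.ndarray:
    """Fibonacci-spiral unit vectors evenly covering a cone about +z."""
    cos_a = math.cos(math.radians(half_angle_deg))
    k = np.arange(n, dtype=float)
    z = 1.0 - (1.0 - cos_a) * (k + 0.5) / n
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = _GOLDEN_ANGLE * k
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def make_planted_fixture(
    spec: FixtureSpec, rng: np.random.Generator | None = None
) -> Tuple[RaySet, LigandConformer, PoseTransform]:
    """Analytic pocket + its perfectly complementary single-sphere ligand.

    Returns (rayset, conformer, planted pose).  The conformer sits at the
    coordinate origin; the planted pose translates it to (0, 0, D), where
    every pocket ray's stored rho equals its first-hit distance exactly and
    every forbidden ray (placed outside the ligand's angular radius) misses.
    """
    D, r = spec.ligand_center_distance, spec.ligand_radius
    if spec.cone_half_angle > spec.angular_radius:
        raise ValueError(
            f"cone half-angle {spec.cone_half_angle}° exceeds the ligand's angular "
            f"radius {spec.angular_radius:.3f}°; some pocket rays would miss"
        )
    rays: List[Ray] = []
    for u in _cone_directions(spec.n_pocket_rays, spec.cone_half_angle):
        theta, phi, _ = cartesian_to_spherical(u, (0.0, 0.0, 0.0))
        # rho from the direction as re-derived from (theta, phi), so the
        # stored distance matches the scorer's reconstruction exactly
        ray = Ray(POCKET, theta, phi, 1.0)
        rho = planted_hit_distance(ray.direction, D, r)
        rays.append(Ray(POCKET, theta, phi, rho))
    # forbidden rays ring the cone at a safe angular margin so they miss
    theta_f = min(175.0, spec.angular_radius + 10.0)
    for j in range(spec.n_forbidden_rays):
        phi = -180.0 + 360.0 * (j + 0.5) / spec.n_forbidden_rays
        rays.append(Ray(FORBIDDEN, theta_f, phi, D))
    conformer = LigandConformer(1, [Atom("C", np.zeros(3), r)])
    planted = PoseTransform(np.array([0.0, 0.0, D]), np.zeros(3))
    return RaySet(origin=np.zeros(3), rays=rays), conformer, planted


def make_random_library(
    n: int,
    atoms_range: Tuple[int, int] = (5, 30),
    box: float = 6.0,
    rng: np.random.Generator | None = None,
) -> List[Compound]:
    """Random multi-sphere decoy compounds, 1–3 rigid conformers each.

    Atom clouds are built as ~1.5 Å random-step chains clipped to a cubic
    box of side *box* and recentered; conformers of a compound are random
    rigid rotations of the same cloud.  Radii are uniform in [1.4, 2.0] Å.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    lo, hi = atoms_range
    if not (1 <= lo <= hi):
        raise ValueError(f"bad atoms_range {atoms_range}")
    if box <= 0:
        raise ValueError("box must be positive")
    rng = np.random.default_rng(0) if rng is None else rng
    library = []
    half = box / 2.0
    for j in range(n):
        k = int(rng.integers(lo, hi + 1))
        steps = rng.normal(size=(k, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        cloud = np.clip(np.cumsum(1.5 * steps, axis=0), -half, half)
        cloud -= cloud.mean(axis=0)
        radii = rng.uniform(1.4, 2.0, size=k)
        conformers = []
        for c in range(int(rng.integers(1, 4))):
            # random proper rotation via QR of a Gaussian matrix
            q, rdiag = np.linalg.qr(rng.normal(size=(3, 3)))
            q *= np.sign(np.diag(rdiag))
            if np.linalg.det(q) < 0:
                q[:, 0] = -q[:, 0]
            coords = cloud @ q.T
            atoms = [Atom("C", p, rad) for p, rad in zip(coords, radii)]
            conformers.append(LigandConformer(c + 1, atoms))
        library.append(Compound(compound_id=f"cmpd{j + 1:04d}", conformers=conformers))
    return library


def make_toy_receptor(
    pit_radius: float = 6.0,
    slab: Tuple[float, float, float] = (24.0, 24.0, 12.0),
    lattice: float = 0.5,
    atom_radius: float = 1.7,
) -> ProteinStructure:
    """Slab of pseudo-atoms with a hemispherical pit carved from the top face.

    Atoms sit on a simple-cubic lattice filling ``slab`` (top face at z = 0);
    every atom whose center lies within ``pit_radius + atom_radius`` of the
    pit center (the top-face midpoint) is removed, so the accessible cavity
    boundary tracks the analytic sphere of radius ``pit_radius`` about the
    origin.  Residue ('A', 1) is the single atom nearest the pit center
    (the natural grid-centering target); all atoms are also indexed under
    residue ('A', 2).
    """
    if pit_radius >= slab[2]:
        raise ValueError("pit_radius must be smaller than the slab depth")
    nx = int(round(slab[0] / lattice))
    ny = int(round(slab[1] / lattice))
    nz = int(round(slab[2] / lattice))
    xs = lattice * (np.arange(nx + 1) - nx / 2.0)
    ys = lattice * (np.arange(ny + 1) - ny / 2.0)
    zs = -lattice * np.arange(nz + 1)  # top face at z=0, slab extends downward
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    if pit_radius > 0:
        pts = pts[np.linalg.norm(pts, axis=1) >= pit_radius + atom_radius]
    atoms = [Atom("C", p, atom_radius) for p in pts]
    nearest = int(np.argmin(np.linalg.norm(pts, axis=1)))
    index = {("A", 1): [nearest], ("A", 2): list(range(len(atoms)))}
    return ProteinStructure(atoms, index)


def toy_pit_surface_distance(
    points: np.ndarray, pit_radius: float, atom_radius: float = 1.7
) -> np.ndarray:
    """Distance from each point to the toy receptor's analytic surface.

    The idealized solid is the half-space z <= h minus the open ball of
    radius ``pit_radius`` about the origin, where h = ``atom_radius`` is the
    height of the accessible surface above the top atom layer.  Its boundary
    is the spherical pit patch (|x| = R, z <= h) plus the flat face
    (z = h, |xy| >= rim), joined at the rim circle.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    R, h = pit_radius, atom_radius
    rim = math.sqrt(max(0.0, R * R - h * h))
    rho_xy = np.hypot(pts[:, 0], pts[:, 1])
    rho = np.linalg.norm(pts, axis=1)
    # flat face: nearest point has z = h and |xy| >= rim
    d_face = np.where(
        rho_xy >= rim,
        np.abs(pts[:, 2] - h),
        np.hypot(rim - rho_xy, pts[:, 2] - h),
    )
    # sphere patch: valid when the radial projection lands at z <= h
    with np.errstate(invalid="ignore", divide="ignore"):
        proj_z = np.where(rho > 0, pts[:, 2] / rho * R, R)
    on_patch = proj_z <= h
    d_rim = np.sqrt((rho_xy - rim) ** 2 + (pts[:, 2] - h) ** 2)
    d_sphere = np.where(on_patch, np.abs(rho - R), d_rim)
    return np.minimum(d_face, d_sphere)


def brute_force_score(
    rayset: RaySet,
    atoms: Sequence[Atom],
    weights: ScoreWeights = ScoreWeights(),
) -> float:
    """Naive reference scorer: explicit ray → atom → root loops, no batching,
    no elimination.  Oracle for the vectorized scorers."""
    total = 0.0
    n_contributing = 0
    first_value = None
    uniform = True
    ox, oy, oz = rayset.origin
    for ray in rayset.rays:
        ux, uy, uz = ray.direction
        best = None
        for a in atoms:
            cx, cy, cz = a.position
            dx, dy, dz = cx - ox, cy - oy, cz - oz
            b = ux * dx + uy * dy + uz * dz
            disc = b * b - (dx * dx + dy * dy + dz * dz - a.radius * a.radius)
            if disc < 0:
                continue
            s = math.sqrt(disc)
            for t in (b - s, b + s):
                if t > 0 and (best is None or t < best):
                    best = t
        value = None
        if ray.kind == POCKET:
            if best is None:
                value = weights.c3
            elif best >= ray.rho:
                value = weights.c1 * (best - ray.rho)
            else:
                value = weights.c2 * (ray.rho - best)
        elif best is not None:
            value = weights.c4
        if value is not None:
            n_contributing += 1
            total += value
            if first_value is None:
                first_value = value
            elif value != first_value:
                uniform = False
    if uniform and first_value is not None:
        # the mean of identical contributions is that value, exactly
        return first_value
    return total / n_contributing
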