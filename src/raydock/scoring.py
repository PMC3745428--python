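"""Shape-complementarity scoring of rigid ligand poses against a ray map.

Each ray cast from the buried origin knows the distance rho at which it
meets the pocket surface.  For a posed ligand, the first ray–sphere
intersection distance d is computed per ray and contributes:

* pocket ray, hit with d >= rho:  c1 * (d - rho)   (unpacking — gap between
  ligand and pocket wall)
* pocket ray, hit with d < rho:   c2 * (rho - d)   (steric clash)
* pocket ray, miss:               c3               (pocket left unfilled)
* forbidden ray, hit:             c4               (ligand spills out of the
  pocket)
* forbidden ray, miss:            0, and the ray does not count toward the
  normalization

The pose score is the sum of contributions divided by the number of
contributing rays (all pocket rays plus intersected forbidden rays); 0 is a
perfect shape complement, lower is better.  Default constants are
c1, c2, c3, c4 = 1.0, 1.4, 21.6, 9.5.

Ray elimination computes conservative angular bounds around the posed
ligand: rays outside the bounds are guaranteed misses and skip the
intersection test.  The swarm scorer evaluates many poses at once in two
stages — a per-ray contribution table over all poses, then a per-pose
reduction — mirroring how the score decomposes into independent ray terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .rays import RaySet, cartesian_to_spherical
from .structures import Atom, LigandConformer

__all__ = [
    "ScoreWeights",
    "PoseTransform",
    "ScoreBreakdown",
    "AngularBounds",
    "apply_pose",
    "first_intersection",
    "ray_contribution",
    "compute_angular_bounds",
    "score_pose",
    "score_swarm",
    "swarm_contribution_table",
    "breakdowns_to_tsv",
]

#: safety margin (degrees) added to angular bounds so grazing rays are never pruned
_ANGLE_EPS = 1e-6


@dataclass(frozen=True)
class ScoreWeights:
    c1: float = 1.0  # unpacking, per Å of gap
    c2: float = 1.4  # clash, per Å of penetration
    c3: float = 21.6  # pocket ray missing the ligand entirely
    c4: float = 9.5  # forbidden ray intersecting the ligand

    def __post_init__(self):
        if min(self.c1, self.c2, self.c3, self.c4) < 0:
            raise ValueError("score constants must be non-negative")


@dataclass(frozen=True)
class PoseTransform:
    """Rigid pose: extrinsic z-y-x rotation about the conformer centroid, then translation."""

    translation: np.ndarray  # (3,) Å
    rotation: np.ndarray  # (3,) radians, (rz, ry, rx)

    def __post_init__(self):
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        if self.translation.shape != (3,) or self.rotation.shape != (3,):
            raise ValueError("translation and rotation must be 3-vectors")

    @classmethod
    def identity(cls) -> "PoseTransform":
        return cls(np.zeros(3), np.zeros(3))

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "PoseTransform":
        v = np.asarray(v, dtype=float)
        return cls(v[:3], v[3:6])

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.translation, self.rotation])

    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("zyx", self.rotation).as_matrix()


@dataclass
class ScoreBreakdown:
    sum_unpack: float
    sum_clash: float
    sum_miss: float
    sum_forbidden: float
    n_contributing: int
    total: float


def apply_pose(conformer: LigandConformer, pose: PoseTransform) -> List[Atom]:
    """Rotate the conformer about its centroid, then translate; radii unchanged."""
    coords = _posed_coords(conformer, pose)
    return [Atom(a.element, c, a.radius) for a, c in zip(conformer.atoms, coords)]


def _posed_coords(conformer: LigandConformer, pose: PoseTransform) -> np.ndarray:
    cen = conformer.centroid
    R = pose.matrix()
    return (conformer.positions - cen) @ R.T + cen + pose.translation


def first_intersection(origin, direction, atoms: Sequence[Atom]) -> Optional[float]:
    """Distance to the first ray–sphere intersection, or None if the ray misses.

    Roots of t^2 - 2 t (u·(c-o)) + |c-o|^2 - r^2 = 0 per atom; the smallest
    strictly positive root wins.  Tangency (zero discriminant) is a hit.
    """
    o = np.asarray(origin, dtype=float)
    u = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    best = math.inf
    for a in atoms:
        delta = a.position - o
        b = float(u @ delta)
        disc = b * b - (float(delta @ delta) - a.radius * a.radius)
        if disc < 0:
            continue
        s = math.sqrt(disc)
        for t in (b - s, b + s):
            if t > 0 and t < best:
                best = t
    return None if math.isinf(best) else best


def ray_contribution(ray, d_lig: Optional[float], w: ScoreWeights) -> Tuple[float, bool]:
    """(score contribution, contributing flag) for one ray given its ligand hit distance."""
    if d_lig is not None and d_lig <= 0:
        raise ValueError(f"intersection distance must be positive, got {d_lig}")
    if ray.kind == "pocket":
        if d_lig is None:
            return w.c3, True
        if d_lig >= ray.rho:
            return w.c1 * (d_lig - ray.rho), True
        return w.c2 * (ray.rho - d_lig), True
    # forbidden ray
    if d_lig is None:
        return 0.0, False
    return w.c4, True


@dataclass
class AngularBounds:
    """Conservative (theta, phi) box outside of which no ray can hit the ligand.

    phi bounds are kept unwrapped (may extend past ±180°); membership tests
    check phi and phi±360°.  ``covers_all`` is set when any atom contains
    the origin; ``empty`` when there are no atoms at all.
    """

    theta_min: float
    theta_max: float
    phi_min: float
    phi_max: float
    covers_all: bool = False
    empty: bool = False

    def contains(self, theta: float, phi: float) -> bool:
        if self.covers_all:
            return True
        if self.empty:
            return False
        if not (self.theta_min <= theta <= self.theta_max):
            return False
        return any(self.phi_min <= p <= self.phi_max for p in (phi - 360.0, phi, phi + 360.0))

    def mask(self, thetas: np.ndarray, phis: np.ndarray) -> np.ndarray:
        """Vectorized membership for arrays of (theta, phi) in degrees."""
        if self.covers_all:
            return np.ones_like(thetas, dtype=bool)
        if self.empty:
            return np.zeros_like(thetas, dtype=bool)
        ok_t = (thetas >= self.theta_min) & (thetas <= self.theta_max)
        ok_p = np.zeros_like(ok_t)
        for shift in (-360.0, 0.0, 360.0):
            ok_p |= (phis + shift >= self.phi_min) & (phis + shift <= self.phi_max)
        return ok_t & ok_p


def compute_angular_bounds(atoms: Sequence[Atom], origin) -> AngularBounds:
    """Union angular box over the per-atom intersection cones seen from *origin*.

    Each atom at distance d with radius r subtends a cone of half-angle
    alpha = asin(r/d) about its center direction.  The theta extent of that
    cone is [theta_c - alpha, theta_c + alpha]; its azimuth extent is
    asin(sin alpha / sin theta_c) unless the cone touches a pole, in which
    case all azimuths are possible.  A small margin keeps grazing rays
    inside the box, so pruning is always conservative.
    """
    if len(atoms) == 0:
        return AngularBounds(math.inf, -math.inf, math.inf, -math.inf, empty=True)
    o = np.asarray(origin, dtype=float)
    t_lo, t_hi = math.inf, -math.inf
    p_lo, p_hi = math.inf, -math.inf
    phi_full = False
    for a in atoms:
        d = float(np.linalg.norm(a.position - o))
        if d <= a.radius:
            return AngularBounds(0.0, 180.0, -180.0, 180.0, covers_all=True)
        theta_c, phi_c, _ = cartesian_to_spherical(a.position, o)
        alpha = math.degrees(math.asin(min(1.0, a.radius / d))) + _ANGLE_EPS
        t_lo = min(t_lo, max(0.0, theta_c - alpha))
        t_hi = max(t_hi, min(180.0, theta_c + alpha))
        if theta_c - alpha <= _ANGLE_EPS or theta_c + alpha >= 180.0 - _ANGLE_EPS:
            phi_full = True
        else:
            w = math.degrees(
                math.asin(min(1.0, math.sin(math.radians(alpha)) / math.sin(math.radians(theta_c))))
            ) + _ANGLE_EPS
            p_lo = min(p_lo, phi_c - w)
            p_hi = max(p_hi, phi_c + w)
    if phi_full or (p_hi - p_lo) >= 360.0:
        p_lo, p_hi = -180.0, 180.0
    return AngularBounds(t_lo, t_hi, p_lo, p_hi)


def _first_hits_batch(
    dirs: np.ndarray, centers: np.ndarray, radii: np.ndarray, ray_chunk: int = 1024
) -> np.ndarray:
    """First-intersection distances for every (ray, pose): dirs (R,3),
    centers (P,A,3) already relative to the origin, radii (A,).  Returns
    (R,P) with inf for misses."""
    R = dirs.shape[0]
    P = centers.shape[0]
    out = np.full((R, P), np.inf)
    cc = np.einsum("pak,pak->pa", centers, centers) - radii[None, :] ** 2  # (P,A)
    for s in range(0, R, ray_chunk):
        d = dirs[s : s + ray_chunk]  # (r,3)
        b = np.einsum("rk,pak->rpa", d, centers)  # (r,P,A)
        disc = b * b - cc[None, :, :]
        hit = disc >= 0
        sq = np.sqrt(np.where(hit, disc, 0.0))
        t1 = b - sq
        t2 = b + sq
        t = np.where(hit & (t1 > 0), t1, np.where(hit & (t2 > 0), t2, np.inf))
        out[s : s + ray_chunk] = t.min(axis=2)
    return out


def _contributions_from_hits(
    d_lig: np.ndarray, rhos: np.ndarray, pocket_mask: np.ndarray, w: ScoreWeights
) -> Tuple[np.ndarray, np.ndarray]:
    """Map hit distances (R,P) to per-ray contribution values and contributing flags."""
    hit = np.isfinite(d_lig)
    rho = rhos[:, None]
    pm = pocket_mask[:, None]
    gap = d_lig - rho
    values = np.where(
        pm,
        np.where(hit, np.where(gap >= 0, w.c1 * gap, -w.c2 * gap), w.c3),
        np.where(hit, w.c4, 0.0),
    )
    contributing = pm | hit
    return values, contributing


def _reduce_mean(values: np.ndarray, contributing: np.ndarray) -> np.ndarray:
    """Mean of contributing values per column of an (n_rays, n_poses) table.

    A column whose contributing values are all identical returns that value
    exactly (the mean of a constant vector must not pick up summation
    round-off — the all-miss score is exactly c3, the planted score exactly 0).
    """
    sums = np.where(contributing, values, 0.0).sum(axis=0)
    counts = contributing.sum(axis=0)
    vmax = np.where(contributing, values, -np.inf).max(axis=0)
    vmin = np.where(contributing, values, np.inf).min(axis=0)
    return np.where(vmax == vmin, vmax, sums / np.maximum(counts, 1))


def score_pose(
    rayset: RaySet,
    conformer: Optional[LigandConformer],
    pose: PoseTransform,
    w: ScoreWeights = ScoreWeights(),
    eliminate: bool = False,
) -> ScoreBreakdown:
    """Score one posed conformer; with ``eliminate`` rays outside the angular
    bounds skip the intersection test (same result, fewer ray–atom tests).

    ``conformer=None`` scores the empty ligand: every pocket ray misses and
    the total is exactly c3.
    """
    n_rays = len(rayset.rays)
    rhos = rayset.rhos()
    pocket_mask = rayset.kinds_pocket()
    d_lig = np.full(n_rays, np.inf)
    if conformer is not None and len(conformer.atoms) > 0:
        coords = _posed_coords(conformer, pose) - rayset.origin
        radii = conformer.radii
        dirs = rayset.directions()
        if eliminate:
            posed = apply_pose(conformer, pose)
            bounds = compute_angular_bounds(posed, rayset.origin)
            thetas = np.array([r.theta for r in rayset.rays])
            phis = np.array([r.phi for r in rayset.rays])
            keep = bounds.mask(thetas, phis)
        else:
            keep = np.ones(n_rays, dtype=bool)
        if keep.any():
            d_lig[keep] = _first_hits_batch(dirs[keep], coords[None, :, :], radii)[:, 0]
    values, contributing = _contributions_from_hits(
        d_lig[:, None], rhos, pocket_mask, w
    )
    values = values[:, 0]
    contributing = contributing[:, 0]
    hit = np.isfinite(d_lig)
    unpack = pocket_mask & hit & (d_lig >= rhos)
    clash = pocket_mask & hit & (d_lig < rhos)
    miss = pocket_mask & ~hit
    forb = ~pocket_mask & hit
    n_contrib = int(contributing.sum())
    # same reduction as the swarm scorer, so the two agree bitwise
    total = float(_reduce_mean(values[:, None], contributing[:, None])[0])
    return ScoreBreakdown(
        sum_unpack=float(values[unpack].sum()),
        sum_clash=float(values[clash].sum()),
        sum_miss=float(values[miss].sum()),
        sum_forbidden=float(values[forb].sum()),
        n_contributing=n_contrib,
        total=total,
    )


def swarm_contribution_table(
    rayset: RaySet,
    conformer: LigandConformer,
    poses: Sequence[PoseTransform],
    w: ScoreWeights = ScoreWeights(),
) -> Tuple[np.ndarray, np.ndarray]:
    """Stage 1 of the batch scorer: the (n_rays, n_poses) contribution table.

    Every ray's contribution to every pose is computed independently — no
    ray elimination, so the workload per ray is identical across poses.
    Returns (values, contributing) arrays of shape (n_rays, n_poses).
    """
    centers = np.stack([_posed_coords(conformer, p) for p in poses]) - rayset.origin
    d_lig = _first_hits_batch(rayset.directions(), centers, conformer.radii)
    return _contributions_from_hits(d_lig, rayset.rhos(), rayset.kinds_pocket(), w)


def score_swarm(
    rayset: RaySet,
    conformer: LigandConformer,
    poses: Sequence[PoseTransform],
    w: ScoreWeights = ScoreWeights(),
) -> np.ndarray:
    """Score a whole swarm of poses; equals :func:`score_pose` per pose.

    Stage 2 reduces the contribution table per pose: sum of contributing
    values over the number of contributing rays.
    """
    if len(poses) == 0:
        raise ValueError("need at least one pose")
    values, contributing = swarm_contribution_table(rayset, conformer, poses, w)
    return _reduce_mean(values, contributing)


def breakdowns_to_tsv(breakdowns: Sequence[ScoreBreakdown], path: str | Path) -> None:
    """One row per pose: total, per-condition sums, contributing-ray count."""
    lines = ["total\tsum_unpack\tsum_clash\tsum_miss\tsum_forbidden\tn_contributing"]
    for b in breakdowns:
        lines.append(
            f"{b.total:.6f}\t{b.sum_unpack:.6f}\t{b.sum_clash:.6f}"
            f"\t{b.sum_miss:.6f}\t{b.sum_forbidden:.6f}\t{b.n_contributing}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
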