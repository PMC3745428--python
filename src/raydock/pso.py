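"""Rigid-body pose optimization by particle swarm, and library screening.

A pose is a 6-vector (3 translations in Å, 3 extrinsic z-y-x rotation angles
about the ligand centroid).  Each particle carries a pose, a velocity and
its personal best; particles are drawn toward their personal best and the
swarm's global best under Clerc constriction (chi = 0.7298, c_p = c_g =
2.05).  Docking a compound runs one independent swarm per rigid conformer
and keeps the best-scoring (conformer, pose); screening ranks a whole
library by that score and flags the top fraction as hits.

The search is stochastic but fully reproducible: every random draw flows
from the config seed, with per-conformer and per-compound offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .rays import RaySet
from .scoring import PoseTransform, ScoreWeights, score_swarm
from .structures import InputError, LigandConformer

__all__ = [
    "PSOConfig",
    "Particle",
    "Swarm",
    "DockResult",
    "Compound",
    "ScreenEntry",
    "default_translation_bounds",
    "initialize_swarm",
    "step_swarm",
    "dock_conformer",
    "dock_compound",
    "screen_library",
    "screen_to_tsv",
    "work_accounting",
]

_SEED_MOD = 2**31
_ROT_LO, _ROT_HI = -math.pi, math.pi


@dataclass(frozen=True)
class PSOConfig:
    n_particles: int = 200
    n_iterations: int = 200
    chi: float = 0.7298  # constriction factor
    c_p: float = 2.05  # cognitive weight
    c_g: float = 2.05  # social weight
    velocity_clamp: float = 0.5  # max |v| as a fraction of each dim's range
    seed: int = 0
    translation_bounds: Optional[np.ndarray] = None  # (2, 3): [lower, upper] Å

    def __post_init__(self):
        if self.n_particles < 1:
            raise InputError("n_particles must be >= 1")
        if self.n_iterations < 0:
            raise InputError("n_iterations must be >= 0")
        if not (0 < self.chi <= 1):
            raise InputError("chi must lie in (0, 1]")


@dataclass
class Particle:
    position: np.ndarray  # (6,) pose vector
    velocity: np.ndarray  # (6,)
    best_position: np.ndarray
    best_score: float = math.inf


@dataclass
class Swarm:
    particles: List[Particle]
    bounds_lo: np.ndarray  # (6,)
    bounds_hi: np.ndarray  # (6,)
    gbest_position: Optional[np.ndarray] = None
    gbest_score: float = math.inf

    def poses(self) -> List[PoseTransform]:
        return [PoseTransform.from_vector(p.position) for p in self.particles]


@dataclass
class DockResult:
    best_pose: PoseTransform
    best_score: float
    best_conformer_id: int
    trajectory: List[float]  # per-iteration global-best scores (non-increasing)


@dataclass
class Compound:
    compound_id: str
    conformers: List[LigandConformer]


def default_translation_bounds(rayset: RaySet, pad: float = 2.0) -> np.ndarray:
    """Bounding box of the pocket-ray surface points, padded by *pad* Å.

    The pocket rays' endpoints are the shell points, so their box is the
    natural search region for the ligand centroid.
    """
    dirs = rayset.directions()
    rhos = rayset.rhos()
    pts = rayset.origin + dirs[rayset.kinds_pocket()] * rhos[rayset.kinds_pocket(), None]
    return np.stack([pts.min(axis=0) - pad, pts.max(axis=0) + pad])


def _full_bounds(config: PSOConfig) -> Tuple[np.ndarray, np.ndarray]:
    tb = config.translation_bounds
    if tb is None:
        raise InputError("translation_bounds not set (pass explicitly or derive from a rayset)")
    tb = np.asarray(tb, dtype=float)
    lo = np.concatenate([tb[0], [_ROT_LO] * 3])
    hi = np.concatenate([tb[1], [_ROT_HI] * 3])
    return lo, hi


def initialize_swarm(config: PSOConfig, rng: np.random.Generator) -> Swarm:
    """Uniform positions inside the bounds, velocities uniform in ±clamp."""
    lo, hi = _full_bounds(config)
    vmax = config.velocity_clamp * (hi - lo)
    particles = []
    for _ in range(config.n_particles):
        x = rng.uniform(lo, hi)
        v = rng.uniform(-vmax, vmax)
        particles.append(Particle(position=x, velocity=v, best_position=x.copy()))
    return Swarm(particles=particles, bounds_lo=lo, bounds_hi=hi)


def _wrap_rotations(x: np.ndarray) -> None:
    x[3:6] = (x[3:6] - _ROT_LO) % (2 * math.pi) + _ROT_LO


def step_swarm(
    swarm: Swarm,
    scores: Sequence[float],
    config: PSOConfig,
    rng: np.random.Generator,
) -> Swarm:
    """Update personal/global bests from *scores*, then move every particle.

    Bests update only on strict improvement (ties keep the incumbent).
    Velocities follow the constriction rule, rotations wrap mod 2π, and
    translations are clipped to the bounds with the clipped velocity
    component zeroed.
    """
    if len(scores) != len(swarm.particles):
        raise InputError(
            f"got {len(scores)} scores for {len(swarm.particles)} particles"
        )
    for p, s in zip(swarm.particles, scores):
        if s < p.best_score:
            p.best_score = float(s)
            p.best_position = p.position.copy()
        if s < swarm.gbest_score:
            swarm.gbest_score = float(s)
            swarm.gbest_position = p.position.copy()
    gb = swarm.gbest_position
    vmax = config.velocity_clamp * (swarm.bounds_hi - swarm.bounds_lo)
    for p in swarm.particles:
        r1 = rng.uniform(size=6)
        r2 = rng.uniform(size=6)
        v = config.chi * (
            p.velocity
            + config.c_p * r1 * (p.best_position - p.position)
            + config.c_g * r2 * (gb - p.position)
        )
        v = np.clip(v, -vmax, vmax)
        x = p.position + v
        _wrap_rotations(x)
        low = x[:3] < swarm.bounds_lo[:3]
        high = x[:3] > swarm.bounds_hi[:3]
        x[:3] = np.clip(x[:3], swarm.bounds_lo[:3], swarm.bounds_hi[:3])
        v[:3] = np.where(low | high, 0.0, v[:3])
        p.position = x
        p.velocity = v
    return swarm


def dock_conformer(
    rayset: RaySet,
    conformer: LigandConformer,
    weights: ScoreWeights = ScoreWeights(),
    config: PSOConfig = PSOConfig(),
) -> DockResult:
    """Particle-swarm docking of one rigid conformer.

    Each iteration scores the whole swarm, updates the bests, and steps, so
    a run evaluates exactly n_particles × n_iterations poses.  With
    n_iterations = 0 the initial swarm is scored once and the best of it
    returned (degenerate mode).  Deterministic given the config seed.
    """
    if config.translation_bounds is None:
        config = replace(config, translation_bounds=default_translation_bounds(rayset))
    rng = np.random.default_rng(config.seed)
    swarm = initialize_swarm(config, rng)
    trajectory: List[float] = []
    n_rounds = max(1, config.n_iterations)
    for it in range(n_rounds):
        scores = score_swarm(rayset, conformer, swarm.poses(), weights)
        if config.n_iterations == 0:
            # degenerate mode: record the best of the initial swarm, no stepping
            for p, s in zip(swarm.particles, scores):
                if s < swarm.gbest_score:
                    swarm.gbest_score = float(s)
                    swarm.gbest_position = p.position.copy()
        else:
            step_swarm(swarm, scores, config, rng)
        trajectory.append(swarm.gbest_score)
    return DockResult(
        best_pose=PoseTransform.from_vector(swarm.gbest_position),
        best_score=swarm.gbest_score,
        best_conformer_id=conformer.conformer_id,
        trajectory=trajectory,
    )


def dock_compound(
    rayset: RaySet,
    conformers: Sequence[LigandConformer],
    weights: ScoreWeights = ScoreWeights(),
    config: PSOConfig = PSOConfig(),
) -> DockResult:
    """Dock each rigid conformer independently; keep the best-scoring one.

    Conformer k runs with seed (seed + k) mod 2^31 so runs are independent
    yet reproducible; score ties keep the earlier conformer.
    """
    if len(conformers) == 0:
        raise InputError("need at least one conformer")
    best: Optional[DockResult] = None
    for k, conf in enumerate(conformers):
        sub = replace(config, seed=(config.seed + k) % _SEED_MOD)
        res = dock_conformer(rayset, conf, weights, sub)
        if best is None or res.best_score < best.best_score:
            best = res
    return best


@dataclass
class ScreenEntry:
    rank: int  # 1-based, ascending score
    compound_id: str
    result: DockResult
    is_hit: bool


def screen_library(
    rayset: RaySet,
    library: Sequence[Compound],
    weights: ScoreWeights = ScoreWeights(),
    config: PSOConfig = PSOConfig(),
    hit_fraction: float = 0.1,
) -> List[ScreenEntry]:
    """Dock every compound, sort ascending by best score, flag the top fraction.

    Hits are the first ceil(hit_fraction · N) entries; score ties are broken
    by input order.  Compound j uses seed (seed + 10007·j) mod 2^31.
    """
    if len(library) == 0:
        raise InputError("library is empty")
    if not (0 < hit_fraction <= 1):
        raise InputError("hit_fraction must lie in (0, 1]")
    results = []
    for j, comp in enumerate(library):
        sub = replace(config, seed=(config.seed + 10007 * j) % _SEED_MOD)
        results.append((j, comp.compound_id, dock_compound(rayset, comp.conformers, weights, sub)))
    results.sort(key=lambda t: (t[2].best_score, t[0]))
    n_hits = math.ceil(hit_fraction * len(library))
    return [
        ScreenEntry(rank=i + 1, compound_id=cid, result=res, is_hit=i < n_hits)
        for i, (_, cid, res) in enumerate(results)
    ]


def screen_to_tsv(entries: Sequence[ScreenEntry], path: str | Path) -> None:
    lines = ["rank\tcompound_id\tconformer_id\tscore\ttx\tty\ttz\trz\try\trx\thit"]
    for e in entries:
        t = e.result.best_pose.translation
        r = e.result.best_pose.rotation
        lines.append(
            f"{e.rank}\t{e.compound_id}\t{e.result.best_conformer_id}"
            f"\t{e.result.best_score:.6f}"
            f"\t{t[0]:.6f}\t{t[1]:.6f}\t{t[2]:.6f}"
            f"\t{r[0]:.6f}\t{r[1]:.6f}\t{r[2]:.6f}"
            f"\t{int(e.is_hit)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def work_accounting(
    n_rays: int = 7000,
    n_atoms: int = 30,
    n_particles: int = 200,
    n_iterations: int = 200,
) -> dict:
    """Exact operation counts for a docking run without ray elimination."""
    per_pose = n_rays * n_atoms
    poses = n_particles * n_iterations
    return {
        "candidate_tests_per_pose": per_pose,
        "poses_per_run": poses,
        "candidate_tests_per_run": per_pose * poses,
        "swarm_atoms_per_ray_pass": n_particles * n_atoms,
        "ray_scores_per_iteration": n_rays * n_particles,
    }
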