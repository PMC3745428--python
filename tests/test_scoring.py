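"""Pose scoring: ray-sphere intersections, per-ray contributions, angular
bounds, and equivalence between the single-pose, batch, and brute-force
scorers."""

import math

import numpy as np
import pytest

from raydock.fixtures import FixtureSpec, brute_force_score, make_planted_fixture
from raydock.rays import POCKET, Ray, RaySet, spherical_to_cartesian
from raydock.scoring import (
    PoseTransform,
    ScoreWeights,
    apply_pose,
    compute_angular_bounds,
    first_intersection,
    ray_contribution,
    score_pose,
    score_swarm,
    swarm_contribution_table,
)
from raydock.structures import Atom, LigandConformer

W = ScoreWeights()


def _atom(pos, r):
    return Atom("C", np.array(pos, dtype=float), r)


class TestApplyPose:
    def setup_method(self):
        self.conf = LigandConformer(
            1, [_atom((1, 0, 0), 1.7), _atom((-1, 0, 0), 1.7)]
        )

    def test_identity(self):
        out = apply_pose(self.conf, PoseTransform.identity())
        np.testing.assert_allclose([a.position for a in out], self.conf.positions)

    def test_translation_only(self):
        out = apply_pose(self.conf, PoseTransform(np.array([1.0, 0, 0]), np.zeros(3)))
        np.testing.assert_allclose(
            [a.position for a in out], self.conf.positions + [1, 0, 0]
        )

    def test_180_rotation_about_z(self):
        pose = PoseTransform(np.zeros(3), np.array([math.pi, 0.0, 0.0]))
        out = apply_pose(self.conf, pose)
        # centroid is the origin; atoms swap sides, radii unchanged
        np.testing.assert_allclose(out[0].position, [-1, 0, 0], atol=1e-12)
        assert out[0].radius == 1.7


@pytest.mark.parametrize(
    "atoms,direction,expected",
    [
        ([((0, 0, 6), 2.0)], (0, 0, 1), 4.0),
        ([((0, 0, 6), 2.0)], (1, 0, 0), None),  # miss
        ([((0, 0, 6), 2.0), ((0, 0, 3), 1.0)], (0, 0, 1), 2.0),  # nearest atom wins
        ([((0, 2, 5), 2.0)], (0, 0, 1), 5.0),  # grazing tangency is a hit
    ],
)
def test_first_intersection_closed_forms(atoms, direction, expected):
    d = first_intersection(np.zeros(3), np.array(direction, dtype=float),
                           [_atom(p, r) for p, r in atoms])
    if expected is None:
        assert d is None
    else:
        assert d == pytest.approx(expected)


def test_first_intersection_requires_unit_direction():
    with pytest.raises(ValueError):
        first_intersection(np.zeros(3), np.array([0.0, 0.0, 2.0]), [_atom((0, 0, 6), 2)])


@pytest.mark.parametrize(
    "kind,rho,d_lig,expected",
    [
        (POCKET, 10.0, 10.0, (0.0, True)),  # perfect fill
        (POCKET, 10.0, 12.0, (2.0, True)),  # unpacking: c1 * 2
        (POCKET, 10.0, 7.0, (4.2, True)),  # clash: c2 * 3
        (POCKET, 10.0, None, (21.6, True)),  # pocket miss: c3
        ("forbidden", 10.0, 5.0, (9.5, True)),  # forbidden hit: c4
        ("forbidden", 10.0, None, (0.0, False)),  # forbidden miss: excluded
    ],
)
def test_ray_contribution_conditions(kind, rho, d_lig, expected):
    ray = Ray(kind, 90.0, 0.0, rho)
    value, contributing = ray_contribution(ray, d_lig, W)
    assert value == pytest.approx(expected[0])
    assert contributing is expected[1]


def test_ray_contribution_rejects_nonpositive_distance():
    with pytest.raises(ValueError):
        ray_contribution(Ray(POCKET, 90.0, 0.0, 10.0), -1.0, W)


class TestAngularBounds:
    def test_single_atom_closed_form(self):
        b = compute_angular_bounds([_atom((6, 0, 0), 2.0)], np.zeros(3))
        alpha = math.degrees(math.asin(1 / 3))
        assert b.theta_min == pytest.approx(90 - alpha, abs=1e-4)
        assert b.theta_max == pytest.approx(90 + alpha, abs=1e-4)
        assert b.phi_min == pytest.approx(-alpha, abs=1e-4)
        assert b.phi_max == pytest.approx(alpha, abs=1e-4)
        assert not b.covers_all

    def test_origin_inside_atom_covers_all(self):
        b = compute_angular_bounds([_atom((0.5, 0, 0), 2.0)], np.zeros(3))
        assert b.covers_all

    def test_empty_atom_list_excludes_everything(self):
        b = compute_angular_bounds([], np.zeros(3))
        assert not b.covers_all
        assert not b.contains(90.0, 0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_no_intersecting_ray_escapes_bounds(self, seed):
        """Exhaustive 5-degree sweep: a ray outside the bounds never hits."""
        rng = np.random.default_rng(seed)
        atoms = [
            _atom(rng.uniform(-8, 8, 3), rng.uniform(0.5, 2.0)) for _ in range(10)
        ]
        origin = np.zeros(3)
        bounds = compute_angular_bounds(atoms, origin)
        for theta in np.arange(2.5, 180.0, 5.0):
            for phi in np.arange(-177.5, 180.0, 5.0):
                if bounds.contains(theta, phi):
                    continue
                u = spherical_to_cartesian(theta, phi)
                assert first_intersection(origin, u, atoms) is None


def _single_ray_set(rho=10.0):
    return RaySet(origin=np.zeros(3), rays=[Ray(POCKET, 0.0, 0.0, rho)])


class TestScorePose:
    def test_planted_pose_scores_exactly_zero(self, planted):
        rayset, conf, pose = planted
        assert score_pose(rayset, conf, pose).total == 0.0

    def test_empty_and_far_ligand_score_c3(self, planted):
        rayset, conf, pose = planted
        assert score_pose(rayset, None, PoseTransform.identity()).total == W.c3
        far = PoseTransform(np.array([0.0, 0.0, 1000.0]), np.zeros(3))
        assert score_pose(rayset, conf, far).total == W.c3

    def test_single_ray_worked_example(self):
        rayset = _single_ray_set(rho=10.0)
        conf = LigandConformer(1, [_atom((0, 0, 13), 2.0)])
        b = score_pose(rayset, conf, PoseTransform.identity())
        assert b.total == pytest.approx(1.0)  # c1 * (11 - 10)
        assert b.n_contributing == 1

    def test_breakdown_total_consistency(self, small_planted):
        rayset, conf, pose = small_planted
        shifted = PoseTransform(pose.translation + [0.5, 0.3, -0.4], np.zeros(3))
        b = score_pose(rayset, conf, shifted)
        s = b.sum_unpack + b.sum_clash + b.sum_miss + b.sum_forbidden
        assert b.total == pytest.approx(s / b.n_contributing)
        assert b.n_contributing >= rayset.n_pocket


class TestEliminationAndBatch:
    @pytest.mark.parametrize("seed", range(5))
    def test_elimination_is_exact(self, small_planted, seed):
        rayset, conf, pose = small_planted
        rng = np.random.default_rng(seed)
        for _ in range(10):
            p = PoseTransform(
                pose.translation + rng.normal(scale=2.0, size=3),
                rng.uniform(-math.pi, math.pi, 3),
            )
            a = score_pose(rayset, conf, p, eliminate=False).total
            b = score_pose(rayset, conf, p, eliminate=True).total
            assert a == b  # exact, not approximate

    def test_swarm_equals_sequential(self, small_planted):
        rayset, conf, pose = small_planted
        rng = np.random.default_rng(7)
        poses = [
            PoseTransform(pose.translation + rng.normal(scale=1.5, size=3),
                          rng.uniform(-math.pi, math.pi, 3))
            for _ in range(20)
        ]
        batch = score_swarm(rayset, conf, poses)
        seq = [score_pose(rayset, conf, p).total for p in poses]
        # batched einsum may order the 3-term dot products differently,
        # so agreement is to float round-off, not bitwise
        np.testing.assert_allclose(batch, seq, rtol=1e-12, atol=1e-12)

    def test_swarm_against_brute_force(self, small_planted):
        rayset, conf, pose = small_planted
        rng = np.random.default_rng(11)
        poses = [
            PoseTransform(pose.translation + rng.normal(scale=1.5, size=3),
                          rng.uniform(-math.pi, math.pi, 3))
            for _ in range(20)
        ]
        batch = score_swarm(rayset, conf, poses)
        for p, s in zip(poses, batch):
            ref = brute_force_score(rayset, apply_pose(conf, p))
            assert abs(s - ref) <= 1e-9 * max(1.0, abs(ref))

    def test_contribution_table_shape(self, small_planted):
        rayset, conf, pose = small_planted
        poses = [pose] * 8
        values, contributing = swarm_contribution_table(rayset, conf, poses)
        assert values.shape == (len(rayset.rays), 8)
        assert contributing.shape == values.shape

    def test_duplicate_poses_identical_totals(self, small_planted):
        rayset, conf, pose = small_planted
        totals = score_swarm(rayset, conf, [pose, pose, pose])
        assert totals[0] == totals[1] == totals[2]


def test_translation_monotonicity_near_optimum(planted):
    """Any small displacement away from the planted pose costs score."""
    rayset, conf, pose = planted
    rng = np.random.default_rng(42)
    for _ in range(50):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        delta = rng.uniform(0.1, 1.0)
        p = PoseTransform(pose.translation + delta * u, np.zeros(3))
        assert score_pose(rayset, conf, p).total > 0.0
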