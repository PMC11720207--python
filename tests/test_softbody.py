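"""Soft-body physics: XPBD projection, shape matching, collision, skinning."""

import numpy as np
import pytest

from esgsim.softbody import (
    CapsuleSegment,
    DegenerateShapeGroupError,
    DistanceConstraint,
    ShapeMatchGroup,
    SimulationDivergedError,
    SkinBinding,
    SoftBody,
    StepConfig,
    collide_capsules,
    project_distance,
    project_shape_match,
    skin_surface,
)


def _square_body(**cfg):
    """Unit square of 4 free particles with rigid edge constraints at rest."""
    pos = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
    body = SoftBody(pos, config=StepConfig(**cfg))
    for i, j in [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2), (1, 3)]:
        body.add_distance_constraint(i, j, 0.0)
    return body


class TestStep:
    def test_equilibrium_is_fixed_point(self):
        body = _square_body()
        before = body.positions.copy()
        body.step()
        assert np.abs(body.positions - before).max() < 1e-9

    @pytest.mark.parametrize("substeps", [1, 4, 10])
    def test_ballistic_displacement_matches_closed_form(self, substeps):
        # symplectic Euler: after one frame of S substeps from rest under
        # acceleration a, displacement = a dt^2 (S+1)/(2S)
        g = 981.0
        dt = 0.01
        body = SoftBody(
            np.zeros((1, 3)),
            config=StepConfig(dt=dt, substeps=substeps, iterations=1, damping=1.0),
        )
        body.step(external_forces=np.array([[0.0, 0.0, -g]]))
        expected = -g * dt**2 * (substeps + 1) / (2 * substeps)
        assert body.positions[0, 2] == pytest.approx(expected, rel=1e-12)
        assert body.time == pytest.approx(dt)

    def test_rigid_pair_converges_and_preserves_midpoint(self):
        body = SoftBody(
            np.array([[0.0, 0, 0], [2.0, 0, 0]]),
            config=StepConfig(dt=0.01, substeps=1, iterations=50, damping=1.0),
        )
        body.add_distance_constraint(0, 1, 0.0, rest_length=1.0)
        body.step()
        sep = np.linalg.norm(body.positions[1] - body.positions[0])
        assert abs(sep - 1.0) < 1e-6
        midpoint = 0.5 * (body.positions[0] + body.positions[1])
        assert np.abs(midpoint - [1.0, 0.0, 0.0]).max() < 1e-9

    def test_residual_decreases_monotonically_with_iterations(self):
        residuals = []
        for iters in (1, 2, 5, 10, 20, 50):
            body = SoftBody(
                np.array([[0.0, 0, 0], [2.0, 0, 0]]),
                config=StepConfig(dt=0.01, substeps=1, iterations=iters, damping=1.0),
            )
            body.add_distance_constraint(0, 1, 0.0, rest_length=1.0)
            body.step()
            residuals.append(body.constraint_residuals()[0])
        assert all(b <= a + 1e-12 for a, b in zip(residuals, residuals[1:]))
        assert residuals[-1] < 1e-6

    def test_center_of_mass_preserved_by_internal_constraints(self):
        rng = np.random.default_rng(7)
        body = _square_body()
        body.add_shape_group([0, 1, 2, 3], stiffness=0.5)
        body.positions += rng.normal(0.0, 0.2, size=body.positions.shape)
        com0 = body.positions.mean(axis=0)
        body.step()
        assert np.abs(body.positions.mean(axis=0) - com0).max() < 1e-9

    def test_doubling_substeps_never_increases_rigid_residual(self):
        # with zero compliance the residual is pure solver error, which the
        # substep/stiffness decoupling drives down as substeps increase
        finals = []
        for substeps in (1, 2, 4, 8, 16):
            body = SoftBody(
                np.array([[0.0, 0, 0], [2.0, 0, 0]]),
                config=StepConfig(dt=1 / 60, substeps=substeps, iterations=8),
            )
            body.add_distance_constraint(0, 1, 0.0, rest_length=1.0)
            body.step()
            finals.append(body.constraint_residuals()[0])
        assert all(b <= a + 1e-12 for a, b in zip(finals, finals[1:]))

    def test_divergence_raises_with_step_index(self):
        body = _square_body()
        body.velocities[0] = np.inf
        with pytest.raises(SimulationDivergedError, match="step 1"):
            body.step()


class TestProjectDistance:
    def test_rigid_equal_masses_split_correction(self):
        c = DistanceConstraint(0, 1, rest_length=1.0)
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        di, dj, _ = project_distance(c, pos, np.ones(2), dt_sub=0.01)
        assert np.allclose(pos[0] + di, [0.5, 0, 0])
        assert np.allclose(pos[1] + dj, [1.5, 0, 0])

    def test_pinned_endpoint_takes_full_violation(self):
        c = DistanceConstraint(0, 1, rest_length=1.0)
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        di, dj, _ = project_distance(c, pos, np.array([0.0, 1.0]), dt_sub=0.01)
        assert np.allclose(di, 0.0)
        assert np.allclose(pos[1] + dj, [1.0, 0, 0])

    def test_compliant_correction_matches_xpbd_scalar_formula(self):
        # alpha_tilde = 1e-3 / 0.005^2 = 40; dlambda = -0.5 / (1+1+40)
        c = DistanceConstraint(0, 1, rest_length=1.0, compliance=1e-3)
        pos = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        di, dj, dlam = project_distance(c, pos, np.ones(2), dt_sub=0.005)
        expected = -0.5 / 42.0
        assert dlam == pytest.approx(expected, abs=1e-12)
        assert np.linalg.norm(di) == pytest.approx(abs(expected), abs=1e-12)
        assert np.linalg.norm(dj) == pytest.approx(abs(expected), abs=1e-12)

    def test_coincident_endpoints_skip_with_warning(self):
        c = DistanceConstraint(0, 1, rest_length=1.0)
        pos = np.zeros((2, 3))
        with pytest.warns(RuntimeWarning, match="coincident"):
            di, dj, dlam = project_distance(c, pos, np.ones(2), dt_sub=0.01)
        assert np.allclose(di, 0) and np.allclose(dj, 0) and dlam == 0.0

    def test_invalid_constraints_rejected(self):
        with pytest.raises(ValueError):
            DistanceConstraint(2, 2, rest_length=1.0)
        with pytest.raises(ValueError):
            DistanceConstraint(0, 1, rest_length=-1.0)


class TestShapeMatch:
    REST = np.array(
        [[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0], [0, 0, 1.5]]
    )

    def _group(self):
        return ShapeMatchGroup(np.arange(5), self.REST.copy())

    def test_translation_gives_identity_rotation(self):
        group = self._group()
        r, goals = project_shape_match(group, self.REST + [1.0, 2.0, 3.0])
        assert np.allclose(r, np.eye(3), atol=1e-10)
        assert np.allclose(goals, self.REST + [1.0, 2.0, 3.0], atol=1e-10)

    def test_rotation_recovered_exactly(self):
        rot90 = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        group = self._group()
        positions = self.REST @ rot90.T
        r, goals = project_shape_match(group, positions)
        assert np.allclose(r, rot90, atol=1e-10)
        assert np.allclose(goals, positions, atol=1e-10)

    def test_polar_rotation_beats_random_rotations(self):
        # optimality oracle: no sampled rotation does better in least squares
        rng = np.random.default_rng(11)
        group = self._group()
        positions = self.REST + rng.normal(0.0, 0.1, self.REST.shape)
        r, goals = project_shape_match(group, positions)
        centroid = positions.mean(0)
        best = ((goals - positions) ** 2).sum()
        for _ in range(100):
            q = rng.normal(size=(3, 3))
            qr, _ = np.linalg.qr(q)
            if np.linalg.det(qr) < 0:
                qr[:, 0] *= -1
            alt = group.rest_offsets @ qr.T + centroid
            assert best <= ((alt - positions) ** 2).sum() + 1e-12

    def test_rotations_always_orthonormal(self):
        rng = np.random.default_rng(3)
        group = self._group()
        for _ in range(25):
            positions = self.REST + rng.normal(0.0, 0.3, self.REST.shape)
            r, _ = project_shape_match(group, positions)
            assert np.abs(r.T @ r - np.eye(3)).max() < 1e-8
            assert np.linalg.det(r) > 0

    def test_degenerate_configurations_rejected(self):
        with pytest.raises(ValueError):
            ShapeMatchGroup(np.arange(2), np.zeros((2, 3)))
        collinear = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(DegenerateShapeGroupError):
            ShapeMatchGroup(np.arange(3), collinear)
        group = self._group()
        squashed = np.outer(self.REST[:, 0], [1.0, 0, 0])
        with pytest.raises(DegenerateShapeGroupError):
            project_shape_match(group, squashed)


class TestCollision:
    CAPSULE = CapsuleSegment(np.array([0.0, 0, 0]), np.array([10.0, 0, 0]), 0.5)

    def test_distant_particle_no_contact(self):
        contacts = collide_capsules(np.array([[5.0, 10.0, 0.0]]), [self.CAPSULE], 0.2)
        assert contacts == []

    def test_on_axis_contact_uses_tiebreak_normal(self):
        contacts = collide_capsules(np.array([[5.0, 0.0, 0.0]]), [self.CAPSULE], 0.2)
        assert len(contacts) == 1
        c = contacts[0]
        assert c.depth == pytest.approx(0.7)
        assert np.allclose(c.normal, [0.0, 0.0, 1.0])  # +z tie-break

    def test_random_contacts_match_brute_force(self):
        rng = np.random.default_rng(19)
        pts = rng.uniform(-2, 12, size=(100, 3))
        contacts = collide_capsules(pts, [self.CAPSULE], 0.2)
        found = {c.index for c in contacts}
        a, b = self.CAPSULE.a, self.CAPSULE.b
        expected = set()
        for k, p in enumerate(pts):
            t = np.clip(np.dot(p - a, b - a) / np.dot(b - a, b - a), 0, 1)
            if np.linalg.norm(p - (a + t * (b - a))) < 0.7:
                expected.add(k)
        assert found == expected

    def test_contact_resolution_pushes_particle_out(self):
        body = SoftBody(np.array([[5.0, 0.6, 0.0]]), config=StepConfig(substeps=1))
        body.step(colliders=[self.CAPSULE])
        dist = np.linalg.norm(body.positions[0, 1:])
        assert dist >= 0.5 + body.particle_radius - 1e-9


class TestSkinning:
    def test_rest_pose_reproduces_rest_vertices(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        binding = SkinBinding(
            particle_indices=np.array([[0, 1]]),
            weights=np.array([[0.5, 0.5]]),
            rest_offsets=np.array([[[1.0, 0, 0], [-1.0, 0, 0]]]),
        )
        quats = np.tile([0.0, 0, 0, 1.0], (2, 1))
        verts = skin_surface(binding, pos, quats)
        assert np.allclose(verts, [[1.0, 0, 0]])

    def test_rigid_translation_translates_vertices(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        binding = SkinBinding(
            particle_indices=np.array([[0, 1]]),
            weights=np.array([[0.25, 0.75]]),
            rest_offsets=np.zeros((1, 2, 3)),
        )
        quats = np.tile([0.0, 0, 0, 1.0], (2, 1))
        base = skin_surface(binding, pos, quats)
        moved = skin_surface(binding, pos + [1.0, -2.0, 3.0], quats)
        assert np.allclose(moved - base, [1.0, -2.0, 3.0])

    def test_oriented_particle_rotates_offset(self):
        # 90 deg about z: offset (1,0,0) -> (0,1,0); hand-computed
        binding = SkinBinding(
            particle_indices=np.array([[0]]),
            weights=np.array([[1.0]]),
            rest_offsets=np.array([[[1.0, 0, 0]]]),
        )
        q = np.array([[0.0, 0.0, np.sin(np.pi / 4), np.cos(np.pi / 4)]])
        verts = skin_surface(binding, np.array([[5.0, 5.0, 5.0]]), q)
        assert np.allclose(verts, [[5.0, 6.0, 5.0]], atol=1e-12)

    def test_missing_particle_index_rejected(self):
        binding = SkinBinding(
            particle_indices=np.array([[3]]),
            weights=np.array([[1.0]]),
            rest_offsets=np.zeros((1, 1, 3)),
        )
        with pytest.raises(IndexError):
            skin_surface(binding, np.zeros((2, 3)), np.tile([0.0, 0, 0, 1.0], (2, 1)))

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(ValueError):
            SkinBinding(
                particle_indices=np.array([[0, 1]]),
                weights=np.array([[0.5, 0.2]]),
                rest_offsets=np.zeros((1, 2, 3)),
            )
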