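"""Position-based soft-body core.

Implements the constraint-based dynamics used for the deformable stomach:
extended position-based dynamics (XPBD) with compliant distance constraints,
shape-matching groups with oriented particles, capsule-vs-particle collision,
and linear-blend skinning of a render/measurement mesh.

Units are centimeters, seconds, and grams throughout.  Gravity is off by
default (the endoscopic lumen is a quasi-static environment at this scale);
callers may pass any external force field.

Conventions
-----------
* Quaternions are stored ``(x, y, z, w)`` (scipy order).
* The per-frame loop is symplectic Euler per substep: velocities are kicked by
  forces, positions predicted, constraints projected over a fixed number of
  iterations, and velocities recovered from the position change.  After one
  frame of ``S`` substeps under constant acceleration ``a`` from rest, the
  displacement is ``a * dt**2 * (S + 1) / (2 * S)`` (→ ``a*dt²/2`` as S→∞).
* The batched solver applies a uniform under-relaxation factor ``relaxation``
  to all simultaneous (Jacobi-style) constraint corrections.  Because the
  scaling is uniform, pairwise corrections remain equal and opposite and the
  center of mass of equal-mass free particles is conserved exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "StepConfig",
    "DistanceConstraint",
    "ShapeMatchGroup",
    "CapsuleSegment",
    "SkinBinding",
    "SoftBody",
    "SimulationDivergedError",
    "DegenerateShapeGroupError",
    "project_distance",
    "project_shape_match",
    "collide_capsules",
    "skin_surface",
]

_IDENTITY_QUAT = np.array([0.0, 0.0, 0.0, 1.0])


class SimulationDivergedError(RuntimeError):
    """Raised when particle positions become non-finite during a step."""


class DegenerateShapeGroupError(ValueError):
    """Raised when a shape-match group's moment matrix has rank < 2."""


@dataclass
class StepConfig:
    """Integrator settings for one :meth:`SoftBody.step` frame.

    dt : float
        Frame duration in seconds.
    substeps : int
        XPBD substeps per frame; substepping (rather than more iterations)
        is what decouples stiffness from the simulation frequency.
    iterations : int
        Constraint-projection iterations per substep.
    damping : float
        Velocity retention factor applied once per substep.
    relaxation : float
        Uniform under-relaxation of simultaneous constraint corrections.
    """

    dt: float = 1.0 / 60.0
    substeps: int = 10
    iterations: int = 8
    damping: float = 0.995
    relaxation: float = 0.3

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.relaxation <= 1:
            raise ValueError("relaxation must be in (0, 1]")


@dataclass
class DistanceConstraint:
    """Compliant stretch constraint between two particles.

    ``compliance`` is the inverse stiffness (cm/N); zero means rigid.  The
    Lagrange multiplier accumulates within a substep and is reset by the
    solver at the start of each substep.
    """

    i: int
    j: int
    rest_length: float
    compliance: float = 0.0
    lagrange_multiplier: float = 0.0

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("constraint endpoints must be distinct")
        if self.rest_length <= 0:
            raise ValueError("rest_length must be positive")
        if self.compliance < 0:
            raise ValueError("compliance must be nonnegative")


def project_distance(
    constraint: DistanceConstraint,
    positions: np.ndarray,
    inverse_masses: np.ndarray,
    dt_sub: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One XPBD projection of a single distance constraint.

    Returns ``(delta_i, delta_j, delta_lambda)``: the position corrections for
    the two endpoints and the multiplier increment.  The caller is responsible
    for applying the corrections and accumulating the multiplier.

    The update rule is the standard XPBD scalar form with
    ``alpha_tilde = compliance / dt_sub**2``::

        dlambda = (-C - alpha_tilde * lambda) / (w_i + w_j + alpha_tilde)

    where ``C = |x_i - x_j| - rest_length``.
    """
    if dt_sub <= 0:
        raise ValueError("dt_sub must be positive")
    xi = positions[constraint.i]
    xj = positions[constraint.j]
    d = xi - xj
    length = float(np.linalg.norm(d))
    if length < 1e-12:
        warnings.warn(
            "coincident constraint endpoints; skipping projection "
            "(direction undefined)",
            RuntimeWarning,
            stacklevel=2,
        )
        zero = np.zeros(3)
        return zero, zero.copy(), 0.0
    n = d / length
    c = length - constraint.rest_length
    wi = float(inverse_masses[constraint.i])
    wj = float(inverse_masses[constraint.j])
    alpha_tilde = constraint.compliance / dt_sub**2
    denom = wi + wj + alpha_tilde
    if denom == 0.0:  # both endpoints pinned and rigid
        zero = np.zeros(3)
        return zero, zero.copy(), 0.0
    dlam = (-c - alpha_tilde * constraint.lagrange_multiplier) / denom
    return wi * dlam * n, -wj * dlam * n, dlam


@dataclass
class ShapeMatchGroup:
    """Particle cluster pulled toward the best-fit rigid motion of its rest shape.

    ``rest_offsets`` are the rest positions relative to the group's
    mass-weighted rest centroid, so their mass-weighted sum is zero.
    """

    members: np.ndarray
    rest_offsets: np.ndarray
    stiffness: float = 0.2
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=np.intp)
        self.rest_offsets = np.asarray(self.rest_offsets, dtype=float)
        if self.members.size < 3:
            raise ValueError("shape group needs >= 3 members")
        if not 0 <= self.stiffness <= 1:
            raise ValueError("stiffness must lie in [0, 1]")
        if self.masses is None:
            self.masses = np.ones(self.members.size)
        self.masses = np.asarray(self.masses, dtype=float)
        # non-collinearity of the rest shape
        sv = np.linalg.svd(self.rest_offsets * self.masses[:, None], compute_uv=False)
        if sv[1] <= 1e-10 * max(sv[0], 1e-30):
            raise DegenerateShapeGroupError("degenerate shape group")
        # re-center so the mass-weighted offsets sum to zero exactly
        com = (self.rest_offsets * self.masses[:, None]).sum(0) / self.masses.sum()
        self.rest_offsets = self.rest_offsets - com

    @classmethod
    def from_rest(
        cls,
        members: np.ndarray,
        rest_positions: np.ndarray,
        stiffness: float = 0.2,
        masses: np.ndarray | None = None,
    ) -> "ShapeMatchGroup":
        members = np.asarray(members, dtype=np.intp)
        m = np.ones(members.size) if masses is None else np.asarray(masses, float)
        pts = np.asarray(rest_positions, float)[members]
        com = (pts * m[:, None]).sum(0) / m.sum()
        return cls(members, pts - com, stiffness, m)


def project_shape_match(
    group: ShapeMatchGroup, positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit rotation and goal positions for one shape-match group.

    The moment matrix is ``A = sum_i m_i p_i q_i^T`` with ``p_i`` the current
    positions relative to the mass-weighted centroid and ``q_i`` the rest
    offsets; the rotation is the polar factor of ``A`` (via SVD, with a
    determinant fix so ``det R = +1``).  Goals are ``g_i = R q_i + centroid``,
    which preserves the group's mass-weighted centroid by construction.
    """
    m = group.masses
    pts = positions[group.members]
    centroid = (pts * m[:, None]).sum(0) / m.sum()
    p = pts - centroid
    a = (p * m[:, None]).T @ group.rest_offsets
    u, s, vt = np.linalg.svd(a)
    if s[1] <= 1e-12 * max(s[0], 1e-30):
        raise DegenerateShapeGroupError("degenerate shape group")
    r = u @ vt
    if np.linalg.det(r) < 0:
        u = u.copy()
        u[:, -1] *= -1.0
        r = u @ vt
    goals = group.rest_offsets @ r.T + centroid
    return r, goals


@dataclass
class CapsuleSegment:
    """Capsule collider (endoscope shaft segment)."""

    a: np.ndarray
    b: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.radius <= 0:
            raise ValueError("capsule radius must be positive")


@dataclass(frozen=True)
class Contact:
    index: int
    normal: np.ndarray
    depth: float


def collide_capsules(
    positions: np.ndarray,
    colliders: list[CapsuleSegment],
    particle_radius: float,
) -> list[Contact]:
    """Detect particle-vs-capsule contacts.

    A contact exists iff the point-to-segment distance is below the sum of the
    radii.  The normal points from the capsule axis toward the particle; for a
    particle exactly on the axis the normal is the world ``+z`` direction, or
    ``+x`` when the capsule axis itself is (near) parallel to ``+z``.
    """
    if particle_radius <= 0:
        raise ValueError("particle_radius must be positive")
    contacts: list[Contact] = []
    pos = np.asarray(positions, dtype=float)
    for cap in colliders:
        ab = cap.b - cap.a
        ab2 = float(ab @ ab)
        if ab2 < 1e-24:
            t = np.zeros(len(pos))
        else:
            t = np.clip((pos - cap.a) @ ab / ab2, 0.0, 1.0)
        closest = cap.a + t[:, None] * ab
        d = pos - closest
        dist = np.linalg.norm(d, axis=1)
        depth = particle_radius + cap.radius - dist
        for idx in np.nonzero(depth > 0.0)[0]:
            if dist[idx] < 1e-12:
                axis = ab / np.sqrt(ab2) if ab2 >= 1e-24 else np.array([0.0, 0.0, 1.0])
                fallback = np.array([0.0, 0.0, 1.0])
                if abs(axis[2]) > 0.99:
                    fallback = np.array([1.0, 0.0, 0.0])
                n = fallback
            else:
                n = d[idx] / dist[idx]
            contacts.append(Contact(int(idx), n, float(depth[idx])))
    return contacts


@dataclass
class SkinBinding:
    """Per-vertex linear-blend weights onto (oriented) particles.

    ``particle_indices``: (V, K) int, ``weights``: (V, K) summing to one per
    vertex, ``rest_offsets``: (V, K, 3) offsets in each particle's rest frame.
    """

    particle_indices: np.ndarray
    weights: np.ndarray
    rest_offsets: np.ndarray

    def __post_init__(self) -> None:
        self.particle_indices = np.asarray(self.particle_indices, dtype=np.intp)
        self.weights = np.asarray(self.weights, dtype=float)
        self.rest_offsets = np.asarray(self.rest_offsets, dtype=float)
        if np.any(self.weights < -1e-12):
            raise ValueError("skin weights must be nonnegative")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("skin weights must sum to 1 per vertex")


def skin_surface(
    binding: SkinBinding,
    positions: np.ndarray,
    orientations: np.ndarray,
) -> np.ndarray:
    """Deform mesh vertices by linear-blend skinning.

    ``x_v = sum_k w_vk (R_k r_vk + p_k)`` with ``R_k`` from the particle
    orientation quaternion.
    """
    n = len(positions)
    if binding.particle_indices.max(initial=-1) >= n or binding.particle_indices.min(
        initial=0
    ) < 0:
        raise IndexError("skin binding references a missing particle index")
    v, k = binding.particle_indices.shape
    flat = binding.particle_indices.ravel()
    rot = Rotation.from_quat(np.asarray(orientations)[flat]).as_matrix()
    rotated = np.einsum("nab,nb->na", rot, binding.rest_offsets.reshape(-1, 3))
    world = rotated + np.asarray(positions)[flat]
    return (world.reshape(v, k, 3) * binding.weights[:, :, None]).sum(axis=1)


class SoftBody:
    """Particle system state plus constraints; advanced frame by frame.

    Attributes of interest: ``positions`` (N,3), ``velocities`` (N,3),
    ``inverse_masses`` (N,) with 0 meaning pinned, ``orientations`` (N,4)
    xyzw quaternions, ``time`` (s), ``step_count``.
    """

    def __init__(
        self,
        positions: np.ndarray,
        inverse_masses: np.ndarray | None = None,
        config: StepConfig | None = None,
        particle_radius: float = 0.15,
    ) -> None:
        self.positions = np.array(positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        n = len(self.positions)
        if inverse_masses is None:
            inverse_masses = np.ones(n)
        self.inverse_masses = np.asarray(inverse_masses, dtype=float).copy()
        if np.any(self.inverse_masses < 0):
            raise ValueError("inverse masses must be nonnegative")
        self.velocities = np.zeros((n, 3))
        self.rest_positions = self.positions.copy()
        self.orientations = np.tile(_IDENTITY_QUAT, (n, 1))
        self.config = config or StepConfig()
        self.particle_radius = particle_radius
        self.constraints: list[DistanceConstraint] = []
        self.groups: list[ShapeMatchGroup] = []
        self.time = 0.0
        self.step_count = 0
        self._compiled: dict | None = None

    # ------------------------------------------------------------------ setup

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    def add_distance_constraint(
        self, i: int, j: int, compliance: float = 0.0, rest_length: float | None = None
    ) -> DistanceConstraint:
        if rest_length is None:
            rest_length = float(np.linalg.norm(self.positions[i] - self.positions[j]))
        c = DistanceConstraint(i, j, rest_length, compliance)
        self.constraints.append(c)
        self._compiled = None
        return c

    def add_shape_group(
        self, members: np.ndarray, stiffness: float = 0.2
    ) -> ShapeMatchGroup:
        g = ShapeMatchGroup.from_rest(members, self.rest_positions, stiffness)
        self.groups.append(g)
        self._compiled = None
        return g

    def _compile(self) -> dict:
        """Pack constraint lists into arrays for the vectorized solver."""
        if self._compiled is not None:
            return self._compiled
        c = self.constraints
        comp = {
            "ci": np.array([k.i for k in c], dtype=np.intp),
            "cj": np.array([k.j for k in c], dtype=np.intp),
            "rest": np.array([k.rest_length for k in c]),
            "alpha": np.array([k.compliance for k in c]),
            "lam": np.zeros(len(c)),
        }
        # groups batch only when homogeneous in size (the procedural stomach is)
        sizes = {g.members.size for g in self.groups}
        if self.groups and len(sizes) == 1:
            comp["g_idx"] = np.stack([g.members for g in self.groups])
            comp["g_rest"] = np.stack([g.rest_offsets for g in self.groups])
            comp["g_mass"] = np.stack([g.masses for g in self.groups])
            comp["g_stiff"] = np.array([g.stiffness for g in self.groups])
        self._compiled = comp
        return comp

    # ------------------------------------------------------------------ solver

    def _solve_distance(self, pred: np.ndarray, comp: dict, dt_sub: float) -> None:
        if comp["ci"].size == 0:
            return
        omega = self.config.relaxation
        w = self.inverse_masses
        d = pred[comp["ci"]] - pred[comp["cj"]]
        length = np.linalg.norm(d, axis=1)
        ok = np.isfinite(length) & (length > 1e-12)
        length_safe = np.where(ok, length, 1.0)
        with np.errstate(invalid="ignore"):
            n = d / length_safe[:, None]
            cval = length - comp["rest"]
            alpha_t = comp["alpha"] / dt_sub**2
            wi = w[comp["ci"]]
            wj = w[comp["cj"]]
            denom = wi + wj + alpha_t
            dlam = np.where(
                ok & (denom > 0),
                (-cval - alpha_t * comp["lam"]) / np.maximum(denom, 1e-30),
                0.0,
            )
        n = np.where(ok[:, None], n, 0.0)
        dlam = dlam * omega
        comp["lam"] += dlam
        corr = dlam[:, None] * n
        np.add.at(pred, comp["ci"], wi[:, None] * corr)
        np.add.at(pred, comp["cj"], -wj[:, None] * corr)

    def _solve_groups(self, pred: np.ndarray, comp: dict) -> np.ndarray | None:
        """Project all shape groups; returns batched rotations when available."""
        free = (self.inverse_masses > 0.0)[:, None]
        if "g_idx" in comp:
            idx = comp["g_idx"]
            m = comp["g_mass"][:, :, None]
            pts = pred[idx]
            cen = (pts * m).sum(1) / comp["g_mass"].sum(1)[:, None]
            p = pts - cen[:, None, :]
            a = np.einsum("gma,gmb->gab", p * m, comp["g_rest"])
            u, s, vt = np.linalg.svd(a)
            if np.any(s[:, 1] <= 1e-12 * np.maximum(s[:, 0], 1e-30)):
                raise DegenerateShapeGroupError("degenerate shape group")
            r = u @ vt
            neg = np.linalg.det(r) < 0
            if np.any(neg):
                u = u.copy()
                u[neg, :, -1] *= -1.0
                r = u @ vt
            goals = np.einsum("gab,gmb->gma", r, comp["g_rest"]) + cen[:, None, :]
            blend = comp["g_stiff"][:, None, None] * (goals - pred[idx])
            flat = idx.ravel()
            np.add.at(pred, flat, (blend.reshape(-1, 3)) * free[flat])
            return r
        for g in self.groups:
            r, goals = project_shape_match(g, pred)
            delta = g.stiffness * (goals - pred[g.members])
            pred[g.members] += delta * free[g.members]
        return None

    def _solve_collisions(
        self, pred: np.ndarray, colliders: list[CapsuleSegment]
    ) -> None:
        if not colliders:
            return
        for contact in collide_capsules(pred, colliders, self.particle_radius):
            if self.inverse_masses[contact.index] > 0:
                pred[contact.index] += contact.normal * contact.depth

    def _update_orientations(self, comp: dict, r_batch: np.ndarray | None) -> None:
        if r_batch is not None:
            quats = Rotation.from_matrix(r_batch).as_quat()
            for gi, g in enumerate(self.groups):
                self.orientations[g.members] = quats[gi]
        elif self.groups:
            for g in self.groups:
                r, _ = project_shape_match(g, self.positions)
                self.orientations[g.members] = Rotation.from_matrix(r).as_quat()
        norms = np.linalg.norm(self.orientations, axis=1, keepdims=True)
        self.orientations /= norms

    def step(
        self,
        external_forces: np.ndarray | None = None,
        colliders: list[CapsuleSegment] | None = None,
    ) -> "SoftBody":
        """Advance one frame (``config.dt`` seconds) of XPBD integration."""
        cfg = self.config
        comp = self._compile()
        colliders = list(colliders or [])
        if external_forces is None:
            forces = np.zeros_like(self.positions)
        else:
            forces = np.asarray(external_forces, dtype=float)
            if forces.shape != self.positions.shape:
                raise ValueError("external_forces must match positions shape")
            if not np.all(np.isfinite(forces)):
                raise ValueError("external forces must be finite")
        dt_sub = cfg.dt / cfg.substeps
        w = self.inverse_masses[:, None]
        r_batch = None
        for _ in range(cfg.substeps):
            self.velocities += dt_sub * forces * w
            pred = self.positions + dt_sub * self.velocities
            comp["lam"][:] = 0.0
            for _ in range(cfg.iterations):
                self._solve_distance(pred, comp, dt_sub)
                r_batch = self._solve_groups(pred, comp)
                self._solve_collisions(pred, colliders)
            self.velocities = (pred - self.positions) / dt_sub * cfg.damping
            self.positions = pred
            self._update_orientations(comp, r_batch)
            self.time += dt_sub
        # write accumulated multipliers back onto the constraint objects
        for k, con in enumerate(self.constraints):
            con.lagrange_multiplier = float(comp["lam"][k])
        self.step_count += 1
        if not np.all(np.isfinite(self.positions)):
            raise SimulationDivergedError(
                f"simulation diverged at step {self.step_count}"
            )
        return self

    # -------------------------------------------------------------- diagnostics

    def constraint_residuals(self) -> np.ndarray:
        """Current |C| for every distance constraint."""
        comp = self._compile()
        if comp["ci"].size == 0:
            return np.zeros(0)
        length = np.linalg.norm(
            self.positions[comp["ci"]] - self.positions[comp["cj"]], axis=1
        )
        return np.abs(length - comp["rest"])

    def center_of_mass(self) -> np.ndarray:
        w = self.inverse_masses
        free = w > 0
        masses = np.where(free, 1.0 / np.where(free, w, 1.0), 0.0)
        return (self.positions * masses[:, None]).sum(0) / masses.sum()
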