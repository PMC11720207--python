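"""Instrumented ESG procedure model.

Models the endoscope with its five suturing-platform elements (APC probe,
helix, needle driver, needle, cinch) acting on the soft-body stomach.  Every
action appends a typed, timestamped event to a :class:`ProcedureLog`; the log
(plus a cohort of completion times) is the sole input to the scoring engine.

Tool kinematics are scripted poses: callers position the tip and select tools
directly.  There is no torque or force-feedback model — the event stream and
the tool-tip trajectory carry everything the scoring and kinematics layers
need.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import anatomy
from .anatomy import Region, StomachModel

__all__ = [
    "Tool",
    "EndoscopeState",
    "ProcedureConfig",
    "ProcedureLog",
    "ProcedureSim",
    "Mark",
    "Grasp",
    "Bite",
    "SutureSetEnd",
    "CinchDeploy",
    "BleedOnset",
    "SessionEnd",
    "ToolMismatchError",
    "ProcedureError",
]


class Tool(enum.Enum):
    APC_PROBE = "APC_PROBE"
    HELIX = "HELIX"
    NEEDLE_DRIVER = "NEEDLE_DRIVER"
    NEEDLE = "NEEDLE"
    CINCH = "CINCH"


class ProcedureError(RuntimeError):
    pass


class ToolMismatchError(ProcedureError):
    pass


@dataclass
class EndoscopeState:
    """Scripted endoscope pose; bend angles are bounded by mechanical limits."""

    insertion_depth: float = 0.0
    bend_up_down: float = 0.0
    bend_left_right: float = 0.0
    roll: float = 0.0
    active_tool: Tool = Tool.APC_PROBE
    tip_position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    bend_limit_deg: float = 210.0

    def set_bend(self, up_down: float, left_right: float) -> None:
        if abs(up_down) > self.bend_limit_deg or abs(left_right) > self.bend_limit_deg:
            raise ProcedureError("bend angle exceeds mechanical limit")
        self.bend_up_down = up_down
        self.bend_left_right = left_right


# --------------------------------------------------------------------- events


@dataclass
class Mark:
    t: float
    tip: np.ndarray
    wall: Region
    points: np.ndarray  # (K, 3)

    type_tag = "MARK"


@dataclass
class Grasp:
    t: float
    tip: np.ndarray
    target: np.ndarray
    nearest_mark_distance: float  # cm; math.inf when no mark on this wall
    wall: Region

    type_tag = "GRASP"


@dataclass
class Bite:
    t: float
    tip: np.ndarray
    wall: Region
    axial_s: float
    full_thickness: bool
    exchange_ok: bool = True

    type_tag = "BITE"


@dataclass
class SutureSetEnd:
    t: float
    tip: np.ndarray
    declared_pattern: str  # "U" | "Z" | "NONE"

    type_tag = "SUTURE_SET_END"


@dataclass
class CinchDeploy:
    t: float
    tip: np.ndarray
    t_tag_released: bool

    type_tag = "CINCH_DEPLOY"


@dataclass
class BleedOnset:
    t: float
    tip: np.ndarray
    severity: str = "SEVERE"

    type_tag = "BLEED_ONSET"


@dataclass
class SessionEnd:
    t: float
    tip: np.ndarray
    total_time: float

    type_tag = "SESSION_END"


Event = Mark | Grasp | Bite | SutureSetEnd | CinchDeploy | BleedOnset | SessionEnd


@dataclass
class ProcedureLog:
    """Ordered event stream plus session metadata.  Serializable (JSON Lines)."""

    events: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def append(self, event: Event) -> None:
        if self.events and event.t <= self.events[-1].t:
            raise ProcedureError("event times must strictly increase")
        self.events.append(event)

    def of_type(self, cls) -> list:
        return [e for e in self.events if isinstance(e, cls)]

    @property
    def complete(self) -> bool:
        return sum(isinstance(e, SessionEnd) for e in self.events) == 1

    def validate(self) -> None:
        times = [e.t for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ProcedureError("event times must strictly increase")
        n_end = sum(isinstance(e, SessionEnd) for e in self.events)
        if n_end != 1:
            raise ProcedureError(
                f"complete log must contain exactly one SESSION_END (found {n_end})"
            )


# ------------------------------------------------------------------ simulator


@dataclass
class ProcedureConfig:
    """Tunables of the procedure layer (all centimeters/seconds)."""

    marking_range_cm: float = 0.5     # APC probe must be this close to the wall
    helix_reach_cm: float = 1.0
    mark_length_cm: float = 3.0
    mark_points: int = 8
    bleed_probability: float = 0.1    # per bite
    helix_pull_force: float = 50.0
    pull_steps: int = 4
    plication_factor: float = 0.85
    action_duration_s: float = 1.0    # clock advance per discrete action


class ProcedureSim:
    """Drives the stomach model through the ESG task and records the log."""

    def __init__(
        self,
        model: StomachModel,
        config: ProcedureConfig | None = None,
        rng: np.random.Generator | None = None,
        operator_id: str = "anonymous",
        seed: Optional[int] = None,
    ) -> None:
        self.model = model
        self.config = config or ProcedureConfig()
        if rng is None:
            rng = np.random.default_rng(seed)
        self.rng = rng
        self.scope = EndoscopeState()
        self.log = ProcedureLog(
            metadata={
                "schema": 1,
                "seed": seed,
                "operator_id": operator_id,
                "config_hash": self._config_hash(),
            }
        )
        self._start_time = model.body.time
        self._set_open = False
        self._set_bites = 0
        self._set_bite_sites: list[np.ndarray] = []
        self._helix_engaged = False
        self._helix_depth = 0.0
        self.bleeding_active = False
        self._ended = False

    def _config_hash(self) -> str:
        import hashlib

        payload = repr(sorted(vars(self.model.config).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    # ------------------------------------------------------------- time/motion

    @property
    def time(self) -> float:
        return self.model.body.time

    def advance(self, duration: float) -> None:
        """Advance the session clock without stepping physics."""
        if self._ended:
            raise ProcedureError("session already ended")
        if duration <= 0:
            raise ProcedureError("duration must be positive")
        self.model.body.time += duration

    def _tick(self) -> float:
        self.advance(self.config.action_duration_s)
        return self.time

    def select_tool(self, tool: Tool) -> None:
        self.scope.active_tool = tool

    def move_tip(self, position: np.ndarray, duration: float | None = None) -> None:
        position = np.asarray(position, float)
        if duration is None:
            dist = float(np.linalg.norm(position - self.scope.tip_position))
            duration = max(dist / 2.0, 1e-3)
        self.advance(duration)
        self.scope.tip_position = position
        self.scope.insertion_depth = float(np.linalg.norm(position))

    def _require_tool(self, tool: Tool) -> None:
        if self.scope.active_tool is not tool:
            raise ToolMismatchError(
                f"tool mismatch: {tool.value} required, "
                f"{self.scope.active_tool.value} active"
            )

    def _require_session(self) -> None:
        if self._ended:
            raise ProcedureError("session already ended")

    # ----------------------------------------------------------------- actions

    def apply_apc_mark(
        self,
        wall: Region,
        start: np.ndarray,
        direction: np.ndarray,
        length: float | None = None,
    ) -> Mark:
        """Burn a marker line onto the wall along ``direction`` from ``start``.

        The probe tip must be within ``marking_range_cm`` of the surface; the
        sampled points are projected onto the analytic rest surface so the
        stored geometry lies on the wall regardless of small tip offsets.
        """
        self._require_session()
        self._require_tool(Tool.APC_PROBE)
        if anatomy.surface_distance(self.model, self.scope.tip_position) > self.config.marking_range_cm:
            raise anatomy.OffAnatomyError(
                "APC probe tip is out of marking range of the surface"
            )
        length = self.config.mark_length_cm if length is None else length
        direction = np.asarray(direction, float)
        direction = direction / np.linalg.norm(direction)
        raw = np.asarray(start, float) + np.outer(
            np.linspace(0.0, length, self.config.mark_points), direction
        )
        points = np.array([self._project_to_surface(p) for p in raw])
        event = Mark(self._tick(), self.scope.tip_position.copy(), wall, points)
        self.log.append(event)
        return event

    def _project_to_surface(self, point: np.ndarray) -> np.ndarray:
        s, _ = anatomy._project_to_axis(self.model, point)
        center = anatomy._centerline(self.model.config, np.asarray([s]))[0]
        radial = np.asarray(point, float) - center
        nr = np.linalg.norm(radial)
        if nr < 1e-12:
            radial, nr = np.array([0.0, 1.0, 0.0]), 1.0
        r = float(anatomy._tube_radius(self.model.config, np.asarray(s)))
        return center + radial / nr * r

    def grasp_with_helix(
        self, target: np.ndarray, retraction_depth: float = 0.6
    ) -> Grasp:
        """Capture tissue at ``target`` and retract it into the platform.

        Records the distance to the nearest prior APC mark point on the same
        wall (``inf`` when that wall carries no mark) and couples into the
        physics by pulling nearby particles toward the tip for a few frames.
        """
        self._require_session()
        self._require_tool(Tool.HELIX)
        target = np.asarray(target, float)
        if anatomy.surface_distance(self.model, target) > self.config.helix_reach_cm:
            raise anatomy.OffAnatomyError("helix target is off the anatomy")
        wall = anatomy.region_of(self.model, target)
        dist = math.inf
        for mark in self.log.of_type(Mark):
            if mark.wall is wall:
                dist = min(dist, float(np.min(np.linalg.norm(mark.points - target, axis=1))))
        self._pull_tissue(target)
        self._helix_engaged = True
        self._helix_depth = retraction_depth
        event = Grasp(self._tick(), self.scope.tip_position.copy(), target, dist, wall)
        self.log.append(event)
        return event

    def _pull_tissue(self, target: np.ndarray, radius: float = 1.5) -> None:
        body = self.model.body
        d = np.linalg.norm(body.positions - target, axis=1)
        near = d < radius
        if not near.any():
            return
        forces = np.zeros_like(body.positions)
        pull_dir = self.scope.tip_position - body.positions[near]
        norms = np.maximum(np.linalg.norm(pull_dir, axis=1, keepdims=True), 1e-9)
        forces[near] = self.config.helix_pull_force * pull_dir / norms
        for _ in range(self.config.pull_steps):
            body.step(external_forces=forces)

    def begin_suture_set(self) -> None:
        self._require_session()
        if self._set_open:
            raise ProcedureError("a suture set is already open")
        self._set_open = True
        self._set_bites = 0
        self._set_bite_sites = []

    def drive_needle(self) -> Bite:
        """Pass the needle through the tissue at the current tip position.

        The bite is full thickness iff the helix is engaged with a retraction
        depth of at least the wall thickness at the site.  Each bite carries a
        seeded severe-bleeding hazard (``bleed_probability``).
        """
        self._require_session()
        if self.scope.active_tool not in (Tool.NEEDLE_DRIVER, Tool.NEEDLE):
            raise ToolMismatchError(
                "tool mismatch: NEEDLE_DRIVER required, "
                f"{self.scope.active_tool.value} active"
            )
        if not self._set_open:
            raise ProcedureError("bite without suture set open")
        site = self.scope.tip_position.copy()
        wall = anatomy.region_of(self.model, site)
        s = anatomy.axial_coordinate(self.model, site)
        full = (
            self._helix_engaged
            and self._helix_depth >= self.model.config.wall_thickness_cm
        )
        event = Bite(self._tick(), site, wall, s, full)
        self.log.append(event)
        self._set_bites += 1
        self._set_bite_sites.append(site)
        self._helix_engaged = False
        self.trigger_bleeding()
        return event

    def exchange_anchor(self, correct: bool) -> None:
        """Record the suture/anchor exchange outcome on the most recent bite."""
        bites = self.log.of_type(Bite)
        if not bites:
            raise ProcedureError("no bite to exchange on")
        bites[-1].exchange_ok = bool(correct)

    def end_suture_set(self, declared_pattern: str = "NONE") -> SutureSetEnd:
        self._require_session()
        if declared_pattern not in ("U", "Z", "NONE"):
            raise ProcedureError("declared_pattern must be U, Z, or NONE")
        event = SutureSetEnd(
            self._tick(), self.scope.tip_position.copy(), declared_pattern
        )
        self.log.append(event)
        return event

    def deploy_cinch(self, release_t_tag: bool) -> CinchDeploy:
        """Tighten and lock the open suture set, forming a plication.

        Requires at least one bite in the set.  When the T tag is released the
        plication is applied mechanically: shape-group rest offsets near the
        bite sites contract, and the body settles for a few frames.
        """
        self._require_session()
        self._require_tool(Tool.CINCH)
        if not self._set_open or self._set_bites == 0:
            raise ProcedureError("cinch with zero bites in the open suture set")
        if release_t_tag:
            self._apply_plication()
        event = CinchDeploy(
            self._tick(), self.scope.tip_position.copy(), bool(release_t_tag)
        )
        self.log.append(event)
        self._set_open = False
        self._set_bites = 0
        self.bleeding_active = False
        return event

    def _apply_plication(self, radius: float = 2.5) -> None:
        body = self.model.body
        sites = np.asarray(self._set_bite_sites)
        for group in body.groups:
            pts = body.rest_positions[group.members]
            dmin = np.min(
                np.linalg.norm(pts[:, None, :] - sites[None, :, :], axis=2), axis=1
            )
            if np.any(dmin < radius):
                group.rest_offsets *= self.config.plication_factor
        body._compiled = None
        for _ in range(self.config.pull_steps):
            body.step()

    def trigger_bleeding(self) -> Optional[BleedOnset]:
        """Seeded Bernoulli severe-bleeding hazard; fires at most per call."""
        self._require_session()
        if self.rng.random() < self.config.bleed_probability:
            event = BleedOnset(self._tick(), self.scope.tip_position.copy())
            self.log.append(event)
            self.bleeding_active = True
            return event
        return None

    def end_session(self) -> SessionEnd:
        self._require_session()
        total = self.time + self.config.action_duration_s - self._start_time
        event = SessionEnd(self._tick(), self.scope.tip_position.copy(), total)
        self.log.append(event)
        self._ended = True
        return event
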