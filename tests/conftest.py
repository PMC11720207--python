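import numpy as np
import pytest

from esgsim.anatomy import AnatomyConfig, Region, build_stomach, surface_point
from esgsim.procedure import (
    Bite,
    BleedOnset,
    CinchDeploy,
    Grasp,
    Mark,
    ProcedureLog,
    SessionEnd,
    SutureSetEnd,
)


@pytest.fixture(scope="session")
def static_model():
    """Default stomach used read-only (anatomy queries, scoring)."""
    return build_stomach()


@pytest.fixture()
def fresh_model():
    """Per-test stomach that may be deformed."""
    return build_stomach()


class LogBuilder:
    """Construct procedure logs event by event with auto-incrementing times."""

    def __init__(self, model):
        self.model = model
        self.cfg = model.config
        self.events = []
        self._t = 0.0

    def _tick(self):
        self._t += 1.0
        return self._t

    def _tip(self):
        return np.zeros(3)

    def axis_points(self, wall, s0, length_cm=3.0, n=8, circumferential=False):
        """Mark-point geometry on the analytic surface: along-axis or across."""
        from esgsim.anatomy import WALL_THETA

        theta = WALL_THETA[wall]
        if circumferential:
            dts = np.linspace(0.0, length_cm / 2.0, n)
            return np.array([surface_point(self.cfg, s0, theta + d) for d in dts])
        ds = length_cm / self.model.axis_length_cm
        svals = np.linspace(s0, s0 + ds, n)
        return np.array([surface_point(self.cfg, s, theta) for s in svals])

    def mark(self, wall, s0=0.50, circumferential=False, points=None):
        if points is None:
            points = self.axis_points(wall, s0, circumferential=circumferential)
        self.events.append(Mark(self._tick(), self._tip(), wall, points))
        return self

    def grasp(self, wall, distance=0.2):
        self.events.append(
            Grasp(self._tick(), self._tip(), self._tip(), distance, wall)
        )
        return self

    def bite(self, wall, axial_s, full=True, exchange=True):
        self.events.append(
            Bite(self._tick(), self._tip(), wall, axial_s, full, exchange)
        )
        return self

    def set_end(self, pattern="U"):
        self.events.append(SutureSetEnd(self._tick(), self._tip(), pattern))
        return self

    def cinch(self, released=True):
        self.events.append(CinchDeploy(self._tick(), self._tip(), released))
        return self

    def bleed(self):
        self.events.append(BleedOnset(self._tick(), self._tip()))
        return self

    def end(self, total_time=200.0):
        self.events.append(SessionEnd(self._tick(), self._tip(), total_time))
        return self

    def build(self, metadata=None):
        log = ProcedureLog(metadata=metadata or {"schema": 1, "operator_id": "test"})
        for e in self.events:
            log.append(e)
        return log


@pytest.fixture()
def log_builder(static_model):
    return lambda: LogBuilder(static_model)


def flawless_builder(model):
    """A rubric-perfect session log: parallel marks, near grasps, clean U set."""
    b = LogBuilder(model)
    incisura = model.config.incisura_s
    walls_u = [
        Region.ANTERIOR_WALL,
        Region.ANTERIOR_WALL,
        Region.GREATER_CURVATURE,
        Region.GREATER_CURVATURE,
        Region.POSTERIOR_WALL,
        Region.POSTERIOR_WALL,
    ]
    for wall in (
        Region.ANTERIOR_WALL,
        Region.POSTERIOR_WALL,
        Region.GREATER_CURVATURE,
    ):
        b.mark(wall, s0=incisura + 0.05)
    s = incisura + 0.03
    for wall in walls_u:
        b.grasp(wall, distance=0.2)
        b.bite(wall, s)
        s += 1.5 / model.axis_length_cm
    b.set_end("U").cinch(released=True).end(total_time=100.0)
    return b


@pytest.fixture()
def flawless_log(static_model):
    return flawless_builder(static_model).build()


FIRST_QUARTILE_COHORT = [100.0, 200.0, 300.0, 400.0]
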