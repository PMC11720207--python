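"""Synthetic operator policies.

Seeded, scripted policies that drive the simulator through a full ESG
session — mark three walls, place one or more suture sets, cinch — while
injecting rubric violations at configurable per-task probabilities.  They
stand in for human participants: the expert preset makes few errors and moves
smoothly, the novice preset errs often and moves fast and tremulously, so
cohorts generated from the presets separate on both the rubric total and the
speed/acceleration/jerk summaries.

Tool-tip trajectories are synthesized as minimum-jerk segments between the
positions the policy visits, then perturbed by band-limited tremor (a
seeded-phase sinusoid at the tremor frequency) and small smoothed white
noise.  Minimum-jerk interpolation is the standard model of smooth reaching
motion, which makes skill differences show up in the jerk summary exactly
where the smoothness literature expects them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import anatomy
from .anatomy import Region, StomachModel, build_stomach, surface_point
from .kinematics import KinematicsSummary, Trajectory, summarize
from .procedure import ProcedureConfig, ProcedureLog, ProcedureSim, Tool
from .scoring import ScoreReport, ScoringConfig, score_session

__all__ = [
    "PolicyParams",
    "SessionBundle",
    "run_policy",
    "expert_preset",
    "novice_preset",
    "flawless_preset",
    "generate_cohort",
]

_WALL_SEQUENCE_U = [
    Region.ANTERIOR_WALL,
    Region.ANTERIOR_WALL,
    Region.GREATER_CURVATURE,
    Region.GREATER_CURVATURE,
    Region.POSTERIOR_WALL,
    Region.POSTERIOR_WALL,
]
_MARK_WALLS = [Region.ANTERIOR_WALL, Region.POSTERIOR_WALL, Region.GREATER_CURVATURE]


@dataclass(frozen=True)
class PolicyParams:
    """Behavioral parameters of a synthetic operator.

    Probabilities are per opportunity (per wall for marking errors, per bite
    for bite-level errors).  ``bleed_probability`` is the per-bite severe-
    bleeding hazard passed to the procedure layer; it is grouped with the
    error probabilities so a fully deterministic flawless session exists.
    Motion: ``nominal_speed`` (cm/s) sets travel durations, ``tremor_*`` and
    ``path_noise_sd`` (cm) shape the trajectory perturbations.
    """

    nominal_speed: float = 1.5
    path_noise_sd: float = 0.005
    tremor_amplitude: float = 0.02
    tremor_frequency: float = 8.0
    miss_mark: float = 0.0
    nonparallel_mark: float = 0.0
    far_grasp: float = 0.0
    bad_exchange: float = 0.0
    shallow_bite: float = 0.0
    wrong_direction: float = 0.0
    short_bite_count: float = 0.0
    no_t_tag: float = 0.0
    fundus_bite: float = 0.0
    ignore_bleed: float = 0.0
    bleed_probability: float = 0.1
    seed: int = 0
    sample_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        for name in (
            "miss_mark", "nonparallel_mark", "far_grasp", "bad_exchange",
            "shallow_bite", "wrong_direction", "short_bite_count", "no_t_tag",
            "fundus_bite", "ignore_bleed", "bleed_probability",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.path_noise_sd < 0 or self.tremor_amplitude < 0:
            raise ValueError("noise amplitudes must be nonnegative")
        if self.nominal_speed <= 0:
            raise ValueError("nominal_speed must be positive")


def expert_preset(seed: int = 0) -> PolicyParams:
    """Low error rates, deliberate pace, minimal tremor."""
    return PolicyParams(
        nominal_speed=1.5,
        path_noise_sd=0.005,
        tremor_amplitude=0.02,
        tremor_frequency=8.0,
        miss_mark=0.05,
        nonparallel_mark=0.10,
        far_grasp=0.10,
        bad_exchange=0.08,
        shallow_bite=0.08,
        wrong_direction=0.05,
        short_bite_count=0.05,
        no_t_tag=0.02,
        fundus_bite=0.02,
        ignore_bleed=0.05,
        bleed_probability=0.1,
        seed=seed,
    )


def novice_preset(seed: int = 0) -> PolicyParams:
    """Frequent errors, hurried pace, pronounced tremor."""
    return PolicyParams(
        nominal_speed=2.5,
        path_noise_sd=0.02,
        tremor_amplitude=0.12,
        tremor_frequency=9.0,
        miss_mark=0.30,
        nonparallel_mark=0.40,
        far_grasp=0.40,
        bad_exchange=0.35,
        shallow_bite=0.40,
        wrong_direction=0.30,
        short_bite_count=0.30,
        no_t_tag=0.20,
        fundus_bite=0.15,
        ignore_bleed=0.50,
        bleed_probability=0.1,
        seed=seed,
    )


def flawless_preset(seed: int = 0) -> PolicyParams:
    """All error probabilities and noise zero: the rubric's perfect session."""
    return PolicyParams(
        nominal_speed=1.5,
        path_noise_sd=0.0,
        tremor_amplitude=0.0,
        bleed_probability=0.0,
        seed=seed,
    )


class _Policy:
    """One scripted session; collects the tip timeline for trajectory synthesis."""

    def __init__(self, model: StomachModel, params: PolicyParams) -> None:
        self.model = model
        self.params = params
        self.rng = np.random.default_rng(params.seed)
        self.sim = ProcedureSim(
            model,
            config=ProcedureConfig(bleed_probability=params.bleed_probability),
            rng=np.random.default_rng(self.rng.integers(2**31)),
            seed=params.seed,
        )
        self.timeline: list[tuple[float, np.ndarray]] = []
        self._bleeds_handled = 0

    # ------------------------------------------------------------------ motion

    def _record(self) -> None:
        self.timeline.append((self.sim.time, self.sim.scope.tip_position.copy()))

    def _move(self, pos: np.ndarray) -> None:
        dist = float(np.linalg.norm(np.asarray(pos) - self.sim.scope.tip_position))
        duration = max(dist / self.params.nominal_speed, 0.2)
        self.sim.move_tip(pos, duration)
        self._record()

    def _surface(self, wall: Region, s: float, dtheta: float = 0.0) -> np.ndarray:
        return surface_point(self.model.config, s, anatomy.WALL_THETA[wall] + dtheta)

    # ------------------------------------------------------------------ phases

    def _mark_walls(self) -> None:
        p = self.params
        cfg = self.model.config
        self.sim.select_tool(Tool.APC_PROBE)
        for wall in _MARK_WALLS:
            if self.rng.random() < p.miss_mark:
                continue
            s0 = cfg.incisura_s + 0.05
            start = self._surface(wall, s0)
            self._move(start)
            if self.rng.random() < p.nonparallel_mark:
                # circumferential burn, perpendicular to the gastric axis
                eps = 0.2
                direction = self._surface(wall, s0, eps) - self._surface(wall, s0, -eps)
            else:
                ds = 0.05
                direction = self._surface(wall, s0 + ds) - self._surface(wall, s0 - ds)
            mark = self.sim.apply_apc_mark(wall, start, direction)
            self._move(mark.points[-1])

    def _grasp(self, wall: Region, s_mark: float) -> None:
        p = self.params
        if self.rng.random() < p.far_grasp:
            offset = self.rng.uniform(1.0, 2.0)
        else:
            offset = self.rng.uniform(0.05, 0.3)
        radius = max(float(anatomy._tube_radius(self.model.config, np.asarray(s_mark))), 1e-6)
        target = self._surface(wall, s_mark, dtheta=offset / radius)
        self.sim.select_tool(Tool.HELIX)
        self._move(target)
        depth = 0.2 if self.rng.random() < p.shallow_bite else 0.6
        self.sim.grasp_with_helix(target, retraction_depth=depth)
        self._record()

    def _respond_to_bleeding(self) -> bool:
        """Premature cinch when a new bleed is not ignored.  True if cinched."""
        from .procedure import BleedOnset

        n_bleeds = len(self.sim.log.of_type(BleedOnset))
        if n_bleeds <= self._bleeds_handled:
            return False
        self._bleeds_handled = n_bleeds
        if self.rng.random() < self.params.ignore_bleed:
            return False
        self.sim.end_suture_set("NONE")
        self.sim.select_tool(Tool.CINCH)
        self.sim.deploy_cinch(release_t_tag=True)
        self._record()
        return True

    def _suture_set(self, allow_restart: bool = True) -> None:
        p = self.params
        cfg = self.model.config
        n_bites = 5 if self.rng.random() < p.short_bite_count else 6
        walls = (_WALL_SEQUENCE_U * 2)[:n_bites]
        s = cfg.incisura_s + 0.03
        mark_s = cfg.incisura_s + 0.07
        self.sim.begin_suture_set()
        for k, wall in enumerate(walls):
            if k > 0:
                if self.rng.random() < p.wrong_direction:
                    advance = -self.rng.uniform(1.0, 1.4)
                else:
                    advance = self.rng.uniform(1.05, 1.45)
                s = float(np.clip(s + advance / self.model.axis_length_cm, 0.02, 0.98))
            bite_s = 0.90 if self.rng.random() < p.fundus_bite else s
            self._grasp(wall, mark_s)
            self.sim.select_tool(Tool.NEEDLE_DRIVER)
            self._move(self._surface(wall, bite_s))
            self.sim.drive_needle()
            self.sim.exchange_anchor(self.rng.random() >= p.bad_exchange)
            self._record()
            if self.sim.bleeding_active and self._respond_to_bleeding():
                if allow_restart:
                    self._suture_set(allow_restart=False)
                return
        self.sim.end_suture_set("U")
        self.sim.select_tool(Tool.CINCH)
        self.sim.deploy_cinch(release_t_tag=self.rng.random() >= p.no_t_tag)
        self._record()

    # --------------------------------------------------------------- assembly

    def run(self) -> tuple[ProcedureLog, Trajectory]:
        entry = anatomy._centerline(self.model.config, np.asarray([0.5]))[0]
        self.sim.scope.tip_position = entry
        self._record()
        self._mark_walls()
        self._suture_set()
        self.sim.end_session()
        self._record()
        return self.sim.log, self._synthesize_trajectory()

    def _synthesize_trajectory(self) -> Trajectory:
        p = self.params
        times = np.array([t for t, _ in self.timeline])
        points = np.array([pos for _, pos in self.timeline])
        t0, t1 = times[0], times[-1]
        n = max(int((t1 - t0) * p.sample_rate_hz) + 1, 4)
        t = np.linspace(t0, t1, n)
        pos = np.empty((n, 3))
        seg = np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(times) - 2)
        ta, tb = times[seg], times[seg + 1]
        tau = np.where(tb > ta, (t - ta) / np.where(tb > ta, tb - ta, 1.0), 0.0)
        blend = 10 * tau**3 - 15 * tau**4 + 6 * tau**5  # minimum-jerk time profile
        pos = points[seg] + blend[:, None] * (points[seg + 1] - points[seg])
        if p.tremor_amplitude > 0:
            for axis in range(3):
                amp = p.tremor_amplitude * self.rng.uniform(0.6, 1.0)
                freq = p.tremor_frequency * (1.0 + 0.1 * self.rng.standard_normal())
                phase = self.rng.uniform(0.0, 2.0 * np.pi)
                pos[:, axis] += amp * np.sin(2.0 * np.pi * freq * (t - t0) + phase)
        if p.path_noise_sd > 0:
            noise = self.rng.normal(0.0, p.path_noise_sd, size=pos.shape)
            kernel = np.ones(3) / 3.0
            for axis in range(3):
                noise[:, axis] = np.convolve(noise[:, axis], kernel, mode="same")
            pos += noise
        return Trajectory(t - t0, pos)


def run_policy(model: StomachModel, params: PolicyParams) -> tuple[ProcedureLog, Trajectory]:
    """Execute one scripted ESG session; returns the event log and trajectory.

    Deterministic for a fixed ``params.seed`` and model config.  The model is
    deformed in place (grasp pulls, plication); pass a fresh model per
    session when sessions must be independent.
    """
    return _Policy(model, params).run()


@dataclass
class SessionBundle:
    participant_id: str
    label: str                      # "EXPERT" | "NOVICE"
    params: PolicyParams
    log: ProcedureLog
    trajectory: Trajectory
    kinematics: KinematicsSummary
    duration: float
    report: ScoreReport | None = None


def _jitter(params: PolicyParams, rng: np.random.Generator, seed: int) -> PolicyParams:
    """Individual variation around a preset (lognormal multiplicative jitter)."""
    def lg(sigma: float) -> float:
        return float(np.exp(rng.normal(0.0, sigma)))

    def jp(p: float) -> float:
        return float(np.clip(p * lg(0.3), 0.0, 1.0))

    return replace(
        params,
        nominal_speed=params.nominal_speed * lg(0.10),
        path_noise_sd=params.path_noise_sd * lg(0.25),
        tremor_amplitude=params.tremor_amplitude * lg(0.25),
        miss_mark=jp(params.miss_mark),
        nonparallel_mark=jp(params.nonparallel_mark),
        far_grasp=jp(params.far_grasp),
        bad_exchange=jp(params.bad_exchange),
        shallow_bite=jp(params.shallow_bite),
        wrong_direction=jp(params.wrong_direction),
        short_bite_count=jp(params.short_bite_count),
        no_t_tag=jp(params.no_t_tag),
        fundus_bite=jp(params.fundus_bite),
        ignore_bleed=jp(params.ignore_bleed),
        seed=seed,
    )


def generate_cohort(
    n_expert: int,
    n_novice: int,
    seed: int = 0,
    scoring_config: ScoringConfig | None = None,
    anatomy_config=None,
) -> tuple[list[SessionBundle], pd.DataFrame]:
    """Simulate and score a mixed cohort of synthetic sessions.

    Each participant runs one session on a fresh stomach model with
    individually jittered preset parameters.  Completion-time scoring (M18)
    uses the cohort's own durations, so the cohort needs at least 4 sessions
    in total.  Returns the session bundles and a per-session summary frame
    with columns ``participant``, ``label``, ``total_score``, ``duration``,
    ``mean_speed``, ``mean_accel``, ``mean_jerk``.
    """
    if n_expert < 1 or n_novice < 1:
        raise ValueError("need at least one participant per group")
    rng = np.random.default_rng(seed)
    bundles: list[SessionBundle] = []
    for i in range(n_expert + n_novice):
        label = "EXPERT" if i < n_expert else "NOVICE"
        preset = expert_preset() if label == "EXPERT" else novice_preset()
        params = _jitter(preset, rng, int(rng.integers(2**31)))
        model = build_stomach(anatomy_config)
        log, traj = run_policy(model, params)
        summary = summarize(traj)
        bundles.append(
            SessionBundle(
                participant_id=f"S{i + 1:02d}",
                label=label,
                params=params,
                log=log,
                trajectory=traj,
                kinematics=summary,
                duration=traj.duration,
            )
        )
    durations = np.array([b.duration for b in bundles])
    rows = []
    for b in bundles:
        model = build_stomach(anatomy_config)
        b.report = score_session(b.log, model, durations, scoring_config)
        rows.append(
            {
                "participant": b.participant_id,
                "label": b.label,
                "total_score": b.report.total,
                "duration": b.duration,
                "mean_speed": b.kinematics.mean_speed,
                "mean_accel": b.kinematics.mean_accel,
                "mean_jerk": b.kinematics.mean_jerk,
            }
        )
    return bundles, pd.DataFrame(rows)
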