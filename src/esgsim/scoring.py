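"""Automated ESG performance scoring.

Implements a 19-item inverted rubric (0 = best possible) over a procedure
event log: three APC-marking metrics, thirteen suturing metrics (including
two suture-pattern slots, M14a for U-shaped and M14b for Z-shaped sets), one
adverse-event metric, and one completion-time metric scored by cohort
quartile.  The total is the plain sum over *applicable* metrics; larger
totals mean worse performance, which lets the time penalty add in seamlessly.

Metric ids and scales
---------------------
* M1-M3 (marking, per wall): 0 parallel mark / 3 nonparallel / 5 no mark.
* M4-M13, M14a/b, M15-M17: 0 (done correctly) or 5.
* M18 (total time): cohort quartile mapped to 0 / 3 / 6 / 9.

Maximum totals: 99 when both pattern slots are always scored
(``pattern_scoring="both"``), 94 when only the detected pattern's slot is
applicable (default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .anatomy import Region, StomachModel, axis_tangent, axial_coordinate
from .procedure import (
    Bite,
    BleedOnset,
    CinchDeploy,
    Grasp,
    Mark,
    ProcedureLog,
    SessionEnd,
    SutureSetEnd,
)

__all__ = [
    "ScoringConfig",
    "MetricScore",
    "ScoreReport",
    "METRIC_IDS",
    "MAX_TOTAL_BOTH",
    "MAX_TOTAL_APPLICABLE_ONLY",
    "classify_parallel",
    "detect_pattern",
    "score_marking",
    "score_suturing",
    "score_adverse",
    "score_time",
    "score_session",
    "total_score",
    "aggregate_group_means",
    "IncompleteSessionError",
    "CohortTooSmallError",
]

METRIC_IDS = (
    "M1", "M2", "M3", "M4", "M5", "M6", "M7", "M8", "M9", "M10",
    "M11", "M12", "M13", "M14a", "M14b", "M15", "M16", "M17", "M18",
)

MAX_TOTAL_BOTH = 99
MAX_TOTAL_APPLICABLE_ONLY = 94

_MARK_WALLS = {
    "M1": Region.ANTERIOR_WALL,
    "M2": Region.POSTERIOR_WALL,
    "M3": Region.GREATER_CURVATURE,
}
_GRASP_METRICS = {
    "M5": Region.ANTERIOR_WALL,
    "M7": Region.GREATER_CURVATURE,
    "M9": Region.POSTERIOR_WALL,
}
_EXCHANGE_METRICS = {
    "M6": Region.ANTERIOR_WALL,
    "M8": Region.GREATER_CURVATURE,
    "M10": Region.POSTERIOR_WALL,
}


class IncompleteSessionError(ValueError):
    pass


class CohortTooSmallError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringConfig:
    """Rubric tunables.

    ``parallel_tolerance_deg``: max angle between a mark line and the local
    gastric-axis tangent to still count as parallel.
    ``grasp_radius_cm``: "near marked tissue" threshold.
    ``pattern_scoring``: ``"applicable_only"`` scores only the detected
    pattern's slot (an unrecognized pattern scores 5 on one slot);
    ``"both"`` always scores both slots, which is how per-metric group means
    over mixed-pattern cohorts are aggregated.
    """

    parallel_tolerance_deg: float = 15.0
    grasp_radius_cm: float = 0.5
    min_advance_cm: float = 1.0
    max_advance_cm: float = 2.0
    pattern_scoring: str = "applicable_only"

    def __post_init__(self) -> None:
        if self.pattern_scoring not in ("applicable_only", "both"):
            raise ValueError("pattern_scoring must be applicable_only or both")


@dataclass
class MetricScore:
    metric_id: str
    score: int
    applicable: bool = True
    rationale: str = ""


@dataclass
class ScoreReport:
    scores: list[MetricScore]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.scores) != len(METRIC_IDS):
            raise ValueError(f"report must contain exactly {len(METRIC_IDS)} metrics")

    @property
    def total(self) -> int:
        return sum(s.score for s in self.scores if s.applicable)

    def __getitem__(self, metric_id: str) -> MetricScore:
        for s in self.scores:
            if s.metric_id == metric_id:
                return s
        raise KeyError(metric_id)


# ----------------------------------------------------------------- primitives


def classify_parallel(
    mark_points: np.ndarray, model: StomachModel, config: ScoringConfig | None = None
) -> str:
    """Classify a mark line as ``"PARALLEL"`` or ``"NONPARALLEL"``.

    The best-fit line through the mark points (first principal direction) is
    compared with the gastric-axis tangent at the marks' mean axial
    coordinate; within tolerance counts as parallel.  Fewer than two points
    is treated as no mark upstream.
    """
    config = config or ScoringConfig()
    pts = np.asarray(mark_points, float)
    if len(pts) < 2:
        raise ValueError("need >= 2 mark points to classify a line")
    centered = pts - pts.mean(0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    s_mean = axial_coordinate(model, pts.mean(0))
    tangent = axis_tangent(model, s_mean)
    cosang = abs(float(direction @ tangent))
    angle = math.degrees(math.acos(min(1.0, cosang)))
    return "PARALLEL" if angle <= config.parallel_tolerance_deg else "NONPARALLEL"


def detect_pattern(suture_set: list[Bite]) -> str:
    """Classify a suture set's wall sequence as ``"U"``, ``"Z"``, or ``"NONE"``.

    U: the walls form contiguous blocks in monotone column order
    (anterior → greater curvature → posterior, or the reverse).
    Z: strict three-wall alternation crossing the greater curvature
    (A,G,P,A,G,P,... or the reverse).  Requires at least 6 bites.
    """
    if len(suture_set) < 6:
        return "NONE"
    order = [Region.ANTERIOR_WALL, Region.GREATER_CURVATURE, Region.POSTERIOR_WALL]
    walls = [b.wall for b in suture_set]
    if any(w not in order for w in walls):
        return "NONE"
    collapsed = [walls[0]]
    for w in walls[1:]:
        if w is not collapsed[-1]:
            collapsed.append(w)
    if collapsed == order or collapsed == order[::-1]:
        return "U"
    for cyc in (order, order[::-1]):
        start = cyc.index(walls[0])
        if all(w is cyc[(start + k) % 3] for k, w in enumerate(walls)):
            # strict alternation must actually cross the greater curvature
            if Region.GREATER_CURVATURE in walls:
                return "Z"
    return "NONE"


def _suture_sets(log: ProcedureLog) -> list[list[Bite]]:
    """Partition bites into suture sets, each terminated by a cinch."""
    sets: list[list[Bite]] = []
    current: list[Bite] = []
    for e in log.events:
        if isinstance(e, Bite):
            current.append(e)
        elif isinstance(e, CinchDeploy):
            if current:
                sets.append(current)
            current = []
    if current:
        sets.append(current)
    return sets


# ------------------------------------------------------------- metric groups


def score_marking(
    log: ProcedureLog, model: StomachModel, config: ScoringConfig | None = None
) -> list[MetricScore]:
    """M1-M3: per-wall marking quality (0 parallel, 3 nonparallel, 5 absent)."""
    config = config or ScoringConfig()
    out = []
    for mid, wall in _MARK_WALLS.items():
        marks = [m for m in log.of_type(Mark) if m.wall is wall and len(m.points) >= 2]
        if not marks:
            out.append(MetricScore(mid, 5, True, f"no mark on {wall.value}"))
            continue
        verdicts = [classify_parallel(m.points, model, config) for m in marks]
        if "PARALLEL" in verdicts:
            out.append(MetricScore(mid, 0, True, "parallel mark"))
        else:
            out.append(MetricScore(mid, 3, True, "nonparallel mark only"))
    return out


def score_suturing(
    log: ProcedureLog, model: StomachModel, config: ScoringConfig | None = None
) -> list[MetricScore]:
    """M4-M13, M14a/b, M15, M16 from the bite/grasp/cinch record."""
    config = config or ScoringConfig()
    log.validate()
    out: list[MetricScore] = []
    bites = log.of_type(Bite)
    grasps = log.of_type(Grasp)
    cinches = log.of_type(CinchDeploy)
    sets = _suture_sets(log)

    # M4: first bite proximal to the incisura on the anterior wall
    if bites and bites[0].wall is Region.ANTERIOR_WALL and bites[0].axial_s > model.incisura_s:
        out.append(MetricScore("M4", 0, True, "started proximal to incisura, anterior wall"))
    else:
        out.append(MetricScore("M4", 5, True, "started at a different location"))

    # M5/M7/M9: grasp within grasp_radius of a mark, per wall
    for mid, wall in _GRASP_METRICS.items():
        wall_grasps = [g for g in grasps if g.wall is wall]
        if wall_grasps and all(
            g.nearest_mark_distance <= config.grasp_radius_cm for g in wall_grasps
        ):
            out.append(MetricScore(mid, 0, True, "grasped near marked tissue"))
        else:
            why = "no grasp on wall" if not wall_grasps else "grasp away from marking"
            out.append(MetricScore(mid, 5, True, why))

    # M6/M8/M10: suture/anchor exchange correct for every bite on the wall
    for mid, wall in _EXCHANGE_METRICS.items():
        wall_bites = [b for b in bites if b.wall is wall]
        if wall_bites and all(b.exchange_ok for b in wall_bites):
            out.append(MetricScore(mid, 0, True, "exchanges correct"))
        else:
            why = "no bite on wall" if not wall_bites else "incorrect exchange"
            out.append(MetricScore(mid, 5, True, why))

    # M11: consecutive within-set advance of 1-2 cm distal-to-proximal
    ok_direction = bool(sets)
    for st in sets:
        ds = np.diff([b.axial_s for b in st]) * model.axis_length_cm
        if len(ds) and not np.all(
            (ds >= config.min_advance_cm - 1e-9) & (ds <= config.max_advance_cm + 1e-9)
        ):
            ok_direction = False
    out.append(
        MetricScore(
            "M11",
            0 if ok_direction else 5,
            True,
            "distal-to-proximal 1-2 cm" if ok_direction else "other direction/amount",
        )
    )

    # M12: every bite full thickness
    full = bool(bites) and all(b.full_thickness for b in bites)
    out.append(MetricScore("M12", 0 if full else 5, True,
                           "all full thickness" if full else "non-full-thickness bite"))

    # M13: >= 6 bites per suture set
    enough = bool(sets) and all(len(st) >= 6 for st in sets)
    out.append(MetricScore("M13", 0 if enough else 5, True,
                           ">=6 bites per set" if enough else "<6 bites in a set"))

    # M14a / M14b: suture-pattern slots
    patterns = {detect_pattern(st) for st in sets}
    session_pattern = patterns.pop() if len(patterns) == 1 else "NONE"
    if config.pattern_scoring == "both":
        out.append(MetricScore("M14a", 0 if session_pattern == "U" else 5, True,
                               f"detected pattern {session_pattern}"))
        out.append(MetricScore("M14b", 0 if session_pattern == "Z" else 5, True,
                               f"detected pattern {session_pattern}"))
    else:
        if session_pattern == "U":
            out.append(MetricScore("M14a", 0, True, "U-shaped pattern used"))
            out.append(MetricScore("M14b", 0, False, "not using Z-shaped pattern"))
        elif session_pattern == "Z":
            out.append(MetricScore("M14a", 0, False, "not using U-shaped pattern"))
            out.append(MetricScore("M14b", 0, True, "Z-shaped pattern used"))
        else:
            out.append(MetricScore("M14a", 5, True, "no recognized pattern"))
            out.append(MetricScore("M14b", 0, False, "no recognized pattern"))

    # M15: T tag released on every cinch
    released = bool(cinches) and all(c.t_tag_released for c in cinches)
    out.append(MetricScore("M15", 0 if released else 5, True,
                           "T tag released" if released else "T tag not released"))

    # M16: no suturing within the fundus
    in_fundus = any(
        b.wall is Region.FUNDUS or b.axial_s >= model.fundus_s for b in bites
    )
    out.append(MetricScore("M16", 5 if in_fundus else 0, True,
                           "sutured within fundus" if in_fundus else "fundus avoided"))
    return out


def score_adverse(log: ProcedureLog) -> MetricScore:
    """M17: severe bleeding handled by a premature cinch.

    Not applicable when no bleeding occurred.  Scored 0 when the first cinch
    after the bleed onset comes before any further bite (the operator stopped
    suturing and cinched to stop the bleeding), else 5.
    """
    log.validate()
    bleeds = log.of_type(BleedOnset)
    if not bleeds:
        return MetricScore("M17", 0, False, "no severe bleeding occurred")
    onset = bleeds[0].t
    for e in log.events:
        if e.t <= onset:
            continue
        if isinstance(e, CinchDeploy):
            return MetricScore("M17", 0, True, "premature cinch stopped the bleeding")
        if isinstance(e, Bite):
            break
    return MetricScore("M17", 5, True, "no premature cinch after bleeding")


def score_time(duration: float, cohort_durations: np.ndarray) -> MetricScore:
    """M18: completion-time quartile within the cohort → {0, 3, 6, 9}.

    Quartile edges are the cohort's 25/50/75 percentiles; lower edges are
    inclusive, so a duration tied with an edge takes the lower (better)
    quartile.
    """
    cohort = np.asarray(cohort_durations, float)
    if cohort.size < 4:
        raise CohortTooSmallError("cohort too small for quartile scoring (need >= 4)")
    q1, q2, q3 = np.percentile(cohort, [25, 50, 75])
    if duration <= q1:
        score, which = 0, "first"
    elif duration <= q2:
        score, which = 3, "second"
    elif duration <= q3:
        score, which = 6, "third"
    else:
        score, which = 9, "fourth"
    return MetricScore("M18", score, True, f"{which} quartile of cohort")


# ------------------------------------------------------------------ assembly


def score_session(
    log: ProcedureLog,
    model: StomachModel,
    cohort_durations: np.ndarray,
    config: ScoringConfig | None = None,
) -> ScoreReport:
    """Full 19-metric report for one complete session log."""
    config = config or ScoringConfig()
    if not log.complete:
        raise IncompleteSessionError("incomplete session: missing SESSION_END")
    log.validate()
    duration = log.of_type(SessionEnd)[0].total_time
    scores = (
        score_marking(log, model, config)
        + score_suturing(log, model, config)
        + [score_adverse(log), score_time(duration, cohort_durations)]
    )
    by_id = {s.metric_id: s for s in scores}
    ordered = [by_id[mid] for mid in METRIC_IDS]
    return ScoreReport(
        ordered,
        metadata={
            "operator_id": log.metadata.get("operator_id"),
            "seed": log.metadata.get("seed"),
            "duration_s": duration,
            "pattern_scoring": config.pattern_scoring,
        },
    )


def total_score(report: ScoreReport) -> int:
    """Plain sum of applicable metric scores (inverted scale: lower is better)."""
    return report.total


def aggregate_group_means(per_metric_means) -> float:
    """Sum a 19-entry column of per-metric group means into a group total.

    This is the aggregation used to roll published per-metric mean scores up
    into the group's mean total.
    """
    means = np.asarray(list(per_metric_means), float)
    if means.shape != (len(METRIC_IDS),):
        raise ValueError(f"expected {len(METRIC_IDS)} per-metric means")
    return float(means.sum())
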