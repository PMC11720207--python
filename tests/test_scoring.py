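"""The 19-metric inverted rubric: per-metric rules, patterns, totals."""

import numpy as np
import pytest

from conftest import FIRST_QUARTILE_COHORT, LogBuilder, flawless_builder
from esgsim.anatomy import Region
from esgsim.procedure import Bite
from esgsim.scoring import (
    MAX_TOTAL_APPLICABLE_ONLY,
    MAX_TOTAL_BOTH,
    METRIC_IDS,
    CohortTooSmallError,
    IncompleteSessionError,
    MetricScore,
    ScoreReport,
    ScoringConfig,
    aggregate_group_means,
    classify_parallel,
    detect_pattern,
    score_marking,
    score_session,
    score_time,
    total_score,
)

A, G, P = Region.ANTERIOR_WALL, Region.GREATER_CURVATURE, Region.POSTERIOR_WALL


def _bites(walls):
    return [Bite(float(k + 1), np.zeros(3), w, 0.5, True) for k, w in enumerate(walls)]


class TestClassifyParallel:
    def test_axis_aligned_mark_is_parallel(self, static_model, log_builder):
        points = log_builder().axis_points(A, 0.5)
        assert classify_parallel(points, static_model) == "PARALLEL"

    def test_circumferential_mark_is_nonparallel(self, static_model, log_builder):
        points = log_builder().axis_points(A, 0.5, circumferential=True)
        assert classify_parallel(points, static_model) == "NONPARALLEL"

    def test_oblique_mark_within_tolerance_is_parallel(self, static_model):
        # a straight line tilted 14 degrees off the local axis tangent
        from esgsim.anatomy import axis_tangent, surface_point

        base = surface_point(static_model.config, 0.5, np.pi / 2)
        tangent = axis_tangent(static_model, 0.5)
        up = np.array([0.0, 1.0, 0.0])
        # center the line on the base point so the local tangent is evaluated
        # at the line's own axial station
        tilted = np.cos(np.deg2rad(14)) * tangent + np.sin(np.deg2rad(14)) * up
        points = base + np.outer(np.linspace(-1.5, 1.5, 8), tilted)
        assert classify_parallel(points, static_model) == "PARALLEL"
        steep = np.cos(np.deg2rad(40)) * tangent + np.sin(np.deg2rad(40)) * up
        points = base + np.outer(np.linspace(-1.5, 1.5, 8), steep)
        assert classify_parallel(points, static_model) == "NONPARALLEL"

    def test_single_point_rejected(self, static_model):
        with pytest.raises(ValueError):
            classify_parallel(np.zeros((1, 3)), static_model)


class TestMarking:
    def test_parallel_marks_on_all_walls_score_zero(self, static_model, log_builder):
        b = log_builder()
        for wall in (A, P, G):
            b.mark(wall)
        scores = {s.metric_id: s.score for s in score_marking(b.build(), static_model)}
        assert scores == {"M1": 0, "M2": 0, "M3": 0}

    def test_no_marks_score_five_each(self, static_model, log_builder):
        scores = {
            s.metric_id: s.score
            for s in score_marking(log_builder().build(), static_model)
        }
        assert scores == {"M1": 5, "M2": 5, "M3": 5}

    def test_mixed_marking_scores_per_wall(self, static_model, log_builder):
        b = log_builder().mark(A).mark(P, circumferential=True)
        scores = {s.metric_id: s.score for s in score_marking(b.build(), static_model)}
        assert scores == {"M1": 0, "M2": 3, "M3": 5}


class TestPattern:
    @pytest.mark.parametrize(
        "walls,expected",
        [
            ([A, A, G, G, P, P], "U"),
            ([P, P, G, G, A, A], "U"),
            ([A, A, A, G, G, P], "U"),
            ([A, G, P, A, G, P], "Z"),
            ([P, G, A, P, G, A], "Z"),
            ([A, P, A, P, A, P], "NONE"),
            ([A, A, G, G, P, A], "NONE"),
            ([A, A, G, G, P], "NONE"),  # < 6 bites
        ],
    )
    def test_wall_sequence_grammar(self, walls, expected):
        assert detect_pattern(_bites(walls)) == expected

    def test_fundus_bite_breaks_pattern(self):
        walls = [A, A, G, G, P, Region.FUNDUS]
        assert detect_pattern(_bites(walls)) == "NONE"


class TestSessionScoring:
    def _score(self, log, model, cohort=FIRST_QUARTILE_COHORT, **cfg):
        return score_session(log, model, cohort, ScoringConfig(**cfg))

    def test_flawless_session_scores_zero(self, static_model, flawless_log):
        report = self._score(flawless_log, static_model)
        assert report.total == 0
        assert len(report.scores) == len(METRIC_IDS)
        assert report["M14a"].applicable and report["M14a"].score == 0
        assert not report["M14b"].applicable
        assert not report["M17"].applicable

    @staticmethod
    def _typed(builder):
        from esgsim.procedure import Grasp

        bites = [e for e in builder.events if isinstance(e, Bite)]
        grasps = [e for e in builder.events if isinstance(e, Grasp)]
        return bites, grasps

    @pytest.mark.parametrize(
        "mutate,metric",
        [
            # start at the wrong place: first bite distal to the incisura
            (lambda bites, grasps, m: setattr(
                bites[0], "axial_s", m.incisura_s - 0.05), "M4"),
            # far grasp on the anterior wall
            (lambda bites, grasps, m: setattr(
                grasps[0], "nearest_mark_distance", 1.2), "M5"),
            # bad anchor exchange on a greater-curvature bite
            (lambda bites, grasps, m: setattr(bites[2], "exchange_ok", False), "M8"),
            # shallow (non-full-thickness) bite
            (lambda bites, grasps, m: setattr(bites[1], "full_thickness", False), "M12"),
            # a bite inside the fundus
            (lambda bites, grasps, m: setattr(bites[5], "axial_s", 0.9), "M16"),
        ],
    )
    def test_single_violation_scores_its_metric(self, static_model, mutate, metric):
        builder = flawless_builder(static_model)
        bites, grasps = self._typed(builder)
        mutate(bites, grasps, static_model)
        report = self._score(builder.build(), static_model)
        assert report[metric].score == 5

    def test_unreleased_t_tag_fails_tightening(self, static_model):
        builder = flawless_builder(static_model)
        builder.events[-2].t_tag_released = False
        report = self._score(builder.build(), static_model)
        assert report["M15"].score == 5

    def test_five_bite_set_fails_bite_count(self, static_model):
        builder = flawless_builder(static_model)
        # drop the final grasp+bite pair (events are ... set_end, cinch, end)
        del builder.events[-5:-3]
        report = self._score(builder.build(), static_model)
        assert report["M13"].score == 5

    def test_backward_bite_fails_direction(self, static_model):
        builder = flawless_builder(static_model)
        bites = [e for e in builder.events if isinstance(e, Bite)]
        bites[3].axial_s = bites[2].axial_s - 1.5 / static_model.axis_length_cm
        report = self._score(builder.build(), static_model)
        assert report["M11"].score == 5

    def test_unrecognized_pattern_penalizes_one_slot(self, static_model):
        builder = flawless_builder(static_model)
        bites = [e for e in builder.events if isinstance(e, Bite)]
        for bite, wall in zip(bites, [A, P, A, P, A, P]):
            bite.wall = wall
        report = self._score(builder.build(), static_model)
        assert report["M14a"].score == 5 and report["M14a"].applicable
        assert not report["M14b"].applicable

    def test_both_mode_scores_both_pattern_slots(self, static_model, flawless_log):
        report = self._score(flawless_log, static_model, pattern_scoring="both")
        assert report["M14a"].score == 0 and report["M14a"].applicable
        assert report["M14b"].score == 5 and report["M14b"].applicable
        assert report.total == 5

    def test_incomplete_session_rejected(self, static_model, log_builder):
        log = log_builder().mark(A).build()
        with pytest.raises(IncompleteSessionError):
            self._score(log, static_model)

    def test_scoring_is_deterministic(self, static_model, flawless_log):
        r1 = self._score(flawless_log, static_model)
        r2 = self._score(flawless_log, static_model)
        assert [(s.metric_id, s.score, s.applicable) for s in r1.scores] == [
            (s.metric_id, s.score, s.applicable) for s in r2.scores
        ]


class TestAdverse:
    def test_no_bleeding_not_applicable(self, static_model, flawless_log):
        report = score_session(flawless_log, static_model, FIRST_QUARTILE_COHORT)
        assert report["M17"].score == 0 and not report["M17"].applicable

    def test_premature_cinch_after_bleed_scores_zero(self, static_model):
        builder = flawless_builder(static_model)
        # bleed right after the last bite, before set end + cinch
        b = LogBuilder(static_model)
        b.events = builder.events[:-3]
        b._t = b.events[-1].t
        b.bleed().set_end("U").cinch(released=True).end(total_time=100.0)
        report = score_session(b.build(), static_model, FIRST_QUARTILE_COHORT)
        assert report["M17"].score == 0 and report["M17"].applicable

    def test_ignored_bleed_scores_five(self, static_model):
        builder = flawless_builder(static_model)
        b = LogBuilder(static_model)
        b.events = builder.events[:5]  # marks + first grasp/bite
        b._t = b.events[-1].t
        b.bleed()
        b.grasp(A, 0.2).bite(A, 0.55).set_end("NONE").cinch(True).end(100.0)
        report = score_session(b.build(), static_model, FIRST_QUARTILE_COHORT)
        assert report["M17"].score == 5 and report["M17"].applicable


class TestTimeQuartiles:
    @pytest.mark.parametrize(
        "duration,expected",
        [(100.0, 0), (175.0, 0), (250.0, 3), (300.0, 6), (400.0, 9)],
    )
    def test_quartile_scores(self, duration, expected):
        assert score_time(duration, FIRST_QUARTILE_COHORT).score == expected

    def test_small_cohort_rejected(self):
        with pytest.raises(CohortTooSmallError):
            score_time(100.0, [100.0, 200.0, 300.0])


class TestTotals:
    def test_all_zero_report_totals_zero(self):
        scores = [MetricScore(mid, 0) for mid in METRIC_IDS]
        assert total_score(ScoreReport(scores)) == 0

    def test_non_applicable_metrics_do_not_count(self):
        scores = [MetricScore(mid, 0) for mid in METRIC_IDS]
        scores[-1] = MetricScore("M18", 9, applicable=False)
        assert total_score(ScoreReport(scores)) == 0

    def test_wrong_entry_count_rejected(self):
        with pytest.raises(ValueError):
            ScoreReport([MetricScore("M1", 0)])
        with pytest.raises(ValueError):
            aggregate_group_means([0.0] * 18)

    def test_range_constants(self):
        # 3 marking metrics x5 + 15 binary x5 + M18 max 9 = 99 (both slots);
        # applicable-only drops one 5-point pattern slot
        assert MAX_TOTAL_BOTH == 3 * 5 + 15 * 5 + 9
        assert MAX_TOTAL_APPLICABLE_ONLY == MAX_TOTAL_BOTH - 5

    def test_violations_never_decrease_total(self, static_model):
        # monotonicity: each injected violation can only add penalty points
        from esgsim.operators import flawless_preset, run_policy
        from dataclasses import replace

        base_total = None
        for error in (
            "miss_mark", "nonparallel_mark", "far_grasp", "bad_exchange",
            "shallow_bite", "wrong_direction", "short_bite_count",
            "no_t_tag", "fundus_bite",
        ):
            from esgsim.anatomy import build_stomach

            model = build_stomach()
            params = replace(flawless_preset(seed=3), **{error: 1.0})
            log, traj = run_policy(model, params)
            t = traj.duration
            report = score_session(
                log, model, [t, 2 * t, 3 * t, 4 * t], ScoringConfig()
            )
            if base_total is None:
                base_total = 0
            assert report.total >= base_total
            assert report.total > 0, error
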