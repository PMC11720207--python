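"""Expertise classification and group comparison.

Operators are classified EXPERT when they meet all three of: at least 5 years
(60 months) of endoscopy experience, at least 1,500 endoscopy cases, and at
least 10 endoscopic suturing cases; otherwise NOVICE.  Group comparisons of
scores and kinematic summaries use Welch's two-sample t-test (unequal
variances, Welch-Satterthwaite degrees of freedom).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Expertise",
    "ParticipantRecord",
    "WelchResult",
    "classify_expertise",
    "welch_t",
    "compare_groups",
    "DegenerateSamplesError",
    "MIN_EXPERIENCE_MONTHS",
    "MIN_ENDOSCOPY_CASES",
    "MIN_SUTURING_CASES",
]

MIN_EXPERIENCE_MONTHS = 60
MIN_ENDOSCOPY_CASES = 1500
MIN_SUTURING_CASES = 10


class Expertise(enum.Enum):
    EXPERT = "EXPERT"
    NOVICE = "NOVICE"


class DegenerateSamplesError(ValueError):
    pass


@dataclass(frozen=True)
class ParticipantRecord:
    """One roster row (demographics plus procedural volume)."""

    id: str
    age: int
    sex: str
    hand_dominance: str
    experience_months: int
    endoscopy_cases: int
    suturing_cases: int

    def __post_init__(self) -> None:
        for name in ("experience_months", "endoscopy_cases", "suturing_cases"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ValueError(f"missing field: {name}")
            if v < 0:
                raise ValueError(f"{name} must be nonnegative")


def classify_expertise(record: ParticipantRecord) -> Expertise:
    """EXPERT iff >=60 months experience, >=1500 cases, >=10 suturing cases."""
    if (
        record.experience_months >= MIN_EXPERIENCE_MONTHS
        and record.endoscopy_cases >= MIN_ENDOSCOPY_CASES
        and record.suturing_cases >= MIN_SUTURING_CASES
    ):
        return Expertise.EXPERT
    return Expertise.NOVICE


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float              # two-sided
    p_one_sided: float          # alternative: mean(a) < mean(b)
    mean_a: float
    mean_b: float
    var_a: float
    var_b: float
    n_a: int
    n_b: int

    def as_dict(self) -> dict:
        return {
            "t": self.t_statistic,
            "df": self.degrees_of_freedom,
            "p_two_sided": self.p_value,
            "p_one_sided": self.p_one_sided,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
        }


def welch_t(sample_a, sample_b) -> WelchResult:
    """Welch's unequal-variance two-sample t-test.

    ``t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b)`` with
    Welch-Satterthwaite (real-valued) degrees of freedom.  The one-sided p
    tests the alternative that group ``a`` has the smaller mean.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise DegenerateSamplesError("degenerate samples: both variances zero")
    res = stats.ttest_ind(a, b, equal_var=False)
    one_sided = stats.ttest_ind(a, b, equal_var=False, alternative="less")
    return WelchResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        p_one_sided=float(one_sided.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        var_a=float(va),
        var_b=float(vb),
        n_a=int(a.size),
        n_b=int(b.size),
    )


_MEASURES = ("total_score", "mean_speed", "mean_accel", "mean_jerk")


def compare_groups(
    session_summaries: pd.DataFrame, label_column: str = "label"
) -> dict[str, WelchResult]:
    """Welch tests (expert vs. novice) on total score and the kinematic summaries.

    ``session_summaries`` needs columns ``label`` (EXPERT/NOVICE),
    ``total_score``, ``mean_speed``, ``mean_accel``, ``mean_jerk``.  Group
    ``a`` is the expert group, so negative t-statistics mean experts score
    lower (better on the inverted scale; smoother motion).
    """
    labels = session_summaries[label_column].map(
        lambda v: v.value if isinstance(v, Expertise) else str(v)
    )
    expert = session_summaries[labels == Expertise.EXPERT.value]
    novice = session_summaries[labels == Expertise.NOVICE.value]
    if len(expert) < 2 or len(novice) < 2:
        raise ValueError("each group needs at least 2 sessions")
    return {
        m: welch_t(expert[m].to_numpy(), novice[m].to_numpy()) for m in _MEASURES
    }
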