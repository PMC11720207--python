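"""Published reference data from an ESG-simulator validation study.

Two small tables, shipped as in-memory constructors so the package stays
data-file-free:

* :func:`reference_roster` — the 12-participant roster (demographics and
  procedural volume) used to validate the expertise-classification rule,
  including the labels assigned in the study.
* :func:`reference_metric_means` — per-metric mean rubric scores for the
  expert (n=5) and novice (n=7) groups, used as the worked example for
  rolling per-metric means up into group mean totals.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_roster", "reference_metric_means"]

_ROSTER_ROWS = [
    # id, label, age, sex, hand, experience_months, endoscopy_cases, suturing_cases
    ("1", "NOVICE", 31, "F", "Right", 28, 1000, 0),
    ("2", "EXPERT", 42, "F", "Right", 125, 13000, 10),
    ("3", "EXPERT", 39, "M", "Right", 63, 7500, 120),
    ("4", "NOVICE", 36, "M", "Left", 3, 1800, 10),
    ("5", "EXPERT", 43, "M", "Right", 108, 9000, 30),
    ("6", "NOVICE", 33, "F", "Right", 17, 500, 0),
    ("7", "NOVICE", 32, "M", "Right", 28, 1000, 1),
    ("8", "EXPERT", 48, "M", "Right", 96, 18000, 1000),
    ("9", "NOVICE", 32, "F", "Right", 41, 1000, 0),
    ("10", "EXPERT", 40, "F", "Right", 87, 1500, 10),
    ("11", "NOVICE", 29, "M", "Right", 12, 70, 0),
    ("12", "NOVICE", 30, "M", "Right", 17, 400, 0),
]

_METRIC_MEANS = [
    # metric_id, expert_mean, novice_mean
    ("M1", 2.00, 1.86),
    ("M2", 1.00, 2.86),
    ("M3", 0.00, 0.71),
    ("M4", 2.00, 2.86),
    ("M5", 1.00, 2.14),
    ("M6", 2.00, 4.29),
    ("M7", 0.00, 1.43),
    ("M8", 0.00, 0.00),
    ("M9", 0.00, 1.43),
    ("M10", 0.00, 0.71),
    ("M11", 0.00, 0.71),
    ("M12", 0.00, 0.00),
    ("M13", 3.00, 3.57),
    ("M14a", 4.00, 3.58),
    ("M14b", 3.00, 4.30),
    ("M15", 0.00, 0.00),
    ("M16", 0.00, 0.00),
    ("M17", 0.00, 0.71),
    ("M18", 6.00, 3.86),
]


def reference_roster() -> pd.DataFrame:
    """The 12-participant validation roster, with the study's labels."""
    return pd.DataFrame(
        _ROSTER_ROWS,
        columns=[
            "id",
            "label",
            "age",
            "sex",
            "hand_dominance",
            "experience_months",
            "endoscopy_cases",
            "suturing_cases",
        ],
    )


def reference_metric_means() -> pd.DataFrame:
    """Per-metric mean rubric scores for the expert and novice groups."""
    return pd.DataFrame(
        _METRIC_MEANS, columns=["metric_id", "expert_mean", "novice_mean"]
    )
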