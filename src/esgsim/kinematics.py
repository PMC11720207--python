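"""Tool-tip trajectory kinematics.

Speed, acceleration, and jerk series and their summaries from a sampled
tool-tip path.  Lower magnitudes on all three indicate smoother, more
controlled motion, which is the axis along which expert and novice operators
separate.

Derivatives use second-order central differences on interior samples with
one-sided stencils at the boundaries (``numpy.gradient``); summaries are
time-weighted (trapezoidal) means of the Euclidean magnitude, with RMS
variants also reported since the choice of summary statistic is a
convention.  An optional centered moving-average smoother is available but
off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Trajectory", "KinematicsSummary", "differentiate", "summarize"]


@dataclass
class Trajectory:
    """Sampled tool-tip path: times (s, strictly increasing) and positions (cm)."""

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.positions = np.asarray(self.positions, float)
        if self.times.ndim != 1 or self.positions.shape != (self.times.size, 3):
            raise ValueError("times must be (n,), positions (n, 3)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must strictly increase")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.positions))):
            raise ValueError("trajectory samples must be finite")

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class KinematicsSummary:
    """Time-weighted mean (and RMS) magnitudes of the first three derivatives."""

    mean_speed: float          # cm/s
    mean_accel: float          # cm/s^2
    mean_jerk: float           # cm/s^3
    rms_speed: float
    rms_accel: float
    rms_jerk: float
    duration: float            # s

    def as_dict(self) -> dict:
        return {
            "mean_speed": self.mean_speed,
            "mean_accel": self.mean_accel,
            "mean_jerk": self.mean_jerk,
            "rms_speed": self.rms_speed,
            "rms_accel": self.rms_accel,
            "rms_jerk": self.rms_jerk,
            "duration": self.duration,
        }


def differentiate(traj: Trajectory, order: int) -> np.ndarray:
    """Derivative series of the given order (1 velocity, 2 acceleration, 3 jerk).

    Returns an (n, 3) array, same length as the trajectory.  Requires at
    least ``order + 1`` samples.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2, or 3")
    if len(traj) < order + 1:
        raise ValueError(
            f"need at least {order + 1} samples for order-{order} derivative"
        )
    edge = 2 if len(traj) >= 3 else 1
    series = traj.positions
    for _ in range(order):
        series = np.gradient(series, traj.times, axis=0, edge_order=edge)
    return series


def _smooth(positions: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    out = np.empty_like(positions)
    for c in range(3):
        out[:, c] = np.convolve(positions[:, c], kernel, mode="same")
    # keep endpoints unfiltered to avoid shrinking toward zero
    half = window // 2
    out[:half] = positions[:half]
    out[len(positions) - half:] = positions[len(positions) - half:]
    return out


def summarize(traj: Trajectory, smoothing_window: int | None = None) -> KinematicsSummary:
    """Kinematics summary of a trajectory (optional moving-average smoothing)."""
    if smoothing_window is not None and smoothing_window > 1:
        traj = Trajectory(traj.times, _smooth(traj.positions, smoothing_window))
    mags = [
        np.linalg.norm(differentiate(traj, order), axis=1) for order in (1, 2, 3)
    ]
    t = traj.times
    span = traj.duration
    means = [float(np.trapezoid(m, t) / span) for m in mags]
    rmses = [float(np.sqrt(np.trapezoid(m**2, t) / span)) for m in mags]
    return KinematicsSummary(*means, *rmses, span)
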