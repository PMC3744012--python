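"""Radial distractor-rejection analysis of a trained face-space map.

Discrimination ability around a group's mean face is probed by walking away
from the mean along straight trajectories in the (azimuth, elevation) chart.
Probes are placed at multiples of ``step_sd`` group standard deviations
(default 0.1 s.d. steps, capped at 1 s.d.); the threshold for a trajectory is
the first distance at which the most active classifier differs from the one
responding to the mean. Small thresholds mean a densely covered, finely
discriminating region; thresholds pinned at the cap mean the network cannot
tell the distractor from the mean within 1 s.d.

Trajectories cover all 360 degrees in 1-degree increments, giving a polar
profile per group; comparing own- and other-group profiles quantifies the
discrimination asymmetry produced by unequal exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import azel_to_unit
from .sphere import ClassifierMap

__all__ = [
    "DiscriminationProfile",
    "radial_threshold",
    "discrimination_profile",
    "compare_groups",
]


@dataclass
class DiscriminationProfile:
    """Per-angle discrimination thresholds around one group mean."""

    group: str
    thresholds: np.ndarray  # (360,) in s.d. units, multiples of step_sd
    capped: np.ndarray  # (360,) True where the probe left the octant early
    step_sd: float
    max_sd: float
    center_azel: tuple[float, float]
    group_sd: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "angle_deg": np.arange(360),
                "threshold_sd": self.thresholds,
                "capped_flag": self.capped,
            }
        )


def _probe_chart_points(
    center_azel, direction_deg: float, group_sd: float, step_sd: float, max_sd: float
) -> np.ndarray:
    n_steps = int(round(max_sd / step_sd))
    k = np.arange(1, n_steps + 1)
    theta = np.radians(direction_deg)
    step_vec = np.array([np.cos(theta), np.sin(theta)])
    return np.asarray(center_azel, dtype=float) + (
        k[:, None] * step_sd * group_sd * step_vec
    )


def radial_threshold(
    cmap: ClassifierMap,
    center_azel,
    direction_deg: float,
    group_sd: float,
    step_sd: float = 0.1,
    max_sd: float = 1.0,
) -> tuple[float, bool]:
    """Distractor-rejection threshold along one trajectory.

    Returns ``(threshold_sd, capped)``. ``threshold_sd`` is the first probe
    distance (in group s.d. units) at which the winning classifier differs
    from the winner at the center, or ``max_sd`` if the winner never changes.
    ``capped`` is True when the trajectory left the positive octant before a
    change was seen; the threshold is then the last valid probe distance.
    """
    if step_sd <= 0 or max_sd <= 0 or max_sd < step_sd:
        raise ValueError("require 0 < step_sd <= max_sd")
    weights = cmap.weights
    center_vec = azel_to_unit(np.asarray(center_azel, dtype=float))
    center_winner = int(np.argmax(weights @ center_vec))

    chart = _probe_chart_points(center_azel, direction_deg, group_sd, step_sd, max_sd)
    valid = np.all((chart >= 0.0) & (chart <= 90.0), axis=1)
    n_valid = int(valid.argmin()) if not valid.all() else chart.shape[0]
    if n_valid == 0:
        return 0.0, True
    winners = np.argmax(azel_to_unit(chart[:n_valid]) @ weights.T, axis=1)
    changed = winners != center_winner
    if changed.any():
        return float((int(changed.argmax()) + 1) * step_sd), False
    if n_valid < chart.shape[0]:
        return float(n_valid * step_sd), True
    return float(max_sd), False


def discrimination_profile(
    cmap: ClassifierMap,
    group: str,
    step_sd: float = 0.1,
    max_sd: float = 1.0,
) -> DiscriminationProfile:
    """360-degree threshold profile around a group's empirical mean.

    The center is the group's mean position in the chart; the radial unit is
    the mean of the group's two per-dimension sample standard deviations
    (an isotropic circle). All 360 trajectories are evaluated with learning
    frozen.
    """
    sub = cmap.points.subset(group)
    if len(sub) < 2:
        raise ValueError(f"group {group!r} needs at least 2 exemplars")
    center = sub.azel.mean(axis=0)
    group_sd = float(sub.azel.std(axis=0, ddof=1).mean())
    thresholds = np.empty(360)
    capped = np.empty(360, dtype=bool)
    for angle in range(360):
        thresholds[angle], capped[angle] = radial_threshold(
            cmap, center, float(angle), group_sd, step_sd, max_sd
        )
    return DiscriminationProfile(
        group=group,
        thresholds=thresholds,
        capped=capped,
        step_sd=step_sd,
        max_sd=max_sd,
        center_azel=(float(center[0]), float(center[1])),
        group_sd=group_sd,
    )


def compare_groups(
    p_own: DiscriminationProfile, p_other: DiscriminationProfile
) -> dict:
    """Descriptive comparison of two discrimination profiles (no test)."""
    if (p_own.step_sd, p_own.max_sd) != (p_other.step_sd, p_other.max_sd):
        raise ValueError("profiles must share step_sd and max_sd settings")
    diff = p_other.thresholds - p_own.thresholds
    return {
        "mean_own": float(p_own.thresholds.mean()),
        "mean_other": float(p_other.thresholds.mean()),
        "median_own": float(np.median(p_own.thresholds)),
        "median_other": float(np.median(p_other.thresholds)),
        "mean_difference": float(diff.mean()),
        "per_angle_difference": diff,
    }
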