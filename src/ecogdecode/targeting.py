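"""Simulated brain-assisted targeting task and its analytic geometry.

When an onset is detected and a direction decoded, the cursor is pre-placed
at a fraction alpha of the target radius R along the predicted direction,
and the remaining movement is simulated as straight-line travel at the
user's average speed. The geometry of the circle of radius R around the
target (the locus of points no farther than the center) gives the analytic
backbone: the lens shared with the center circle covers ~39% of its area,
random repositioning therefore lands farther from the target 61% of the
time, and a prediction within +/-60 degrees of the truth is guaranteed to
help at full repositioning (law of cosines:
d^2 = R^2 (1 + alpha^2 - 2 alpha cos(theta))).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class TargetLayout:
    """Equally spaced radial targets; index k sits at k * 360/n degrees
    (0 = rightward, counterclockwise)."""

    n_targets: int = 8
    radius: float = 1.0

    def __post_init__(self) -> None:
        if self.n_targets < 2:
            raise ValueError("need at least two targets")
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_targets) * 360.0 / self.n_targets

    def target_position(self, index: int) -> np.ndarray:
        theta = np.deg2rad(self.angles_deg[int(index)])
        return self.radius * np.array([np.cos(theta), np.sin(theta)])


def reposition_cursor(predicted: int, alpha: float,
                      layout: TargetLayout) -> np.ndarray:
    """Pre-place the cursor at distance alpha*R toward the predicted target."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * layout.target_position(predicted)


def movement_time(start: np.ndarray, target: np.ndarray,
                  speed: float) -> float:
    """Straight-line travel time between two points at constant speed."""
    if speed <= 0:
        raise ValueError("speed must be positive")
    return float(np.linalg.norm(np.asarray(target, dtype=float)
                                - np.asarray(start, dtype=float)) / speed)


def average_speed(onset_times: np.ndarray, hit_times: np.ndarray,
                  radius: float) -> float:
    """Mean over completed trials of R / (hit - onset)."""
    onset_times = np.asarray(onset_times, dtype=float)
    hit_times = np.asarray(hit_times, dtype=float)
    if onset_times.size == 0:
        raise ValueError("no completed trials")
    dt = hit_times - onset_times
    if np.any(dt <= 0):
        raise ValueError("hit times must follow onsets")
    return float(np.mean(radius / dt))


def assisted_distance(alpha: float, error_deg: float,
                      radius: float = 1.0) -> float:
    """Distance to the target after repositioning with angular error theta:
    R * sqrt(1 + alpha^2 - 2 alpha cos(theta))."""
    theta = np.deg2rad(error_deg)
    return float(radius * np.sqrt(max(
        0.0, 1.0 + alpha**2 - 2.0 * alpha * np.cos(theta))))


def optimize_alpha(prediction_pairs, layout: TargetLayout, speed: float,
                   alpha_grid=np.round(np.arange(0.0, 1.0001, 0.05), 2)
                   ) -> tuple[float, np.ndarray]:
    """Mean simulated movement time per alpha and the arg-min alpha.

    ``prediction_pairs`` is a sequence of (true_target, predicted_target).
    At alpha = 0 the cursor stays at the center, so the curve's first point
    is exactly the unassisted baseline. Ties go to the smaller alpha.
    """
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if alpha_grid.size == 0 or alpha_grid.min() < 0 or alpha_grid.max() > 1:
        raise ValueError("alpha grid must be non-empty within [0, 1]")
    pairs = list(prediction_pairs)
    mean_times = np.empty(alpha_grid.size)
    for i, a in enumerate(alpha_grid):
        times = [movement_time(reposition_cursor(pred, a, layout),
                               layout.target_position(true), speed)
                 for true, pred in pairs]
        mean_times[i] = float(np.mean(times))
    best = int(np.argmin(mean_times))  # argmin returns the first (smallest a)
    return float(alpha_grid[best]), mean_times


def lens_area_fraction(layout: TargetLayout | None = None,
                       center_distance: float | None = None) -> float:
    """Area of the lens shared by two radius-R circles, over the circle area.

    With centers R apart (the standard configuration: one circle around the
    screen center, one around a target on its rim) the fraction is
    (2 pi / 3 - sqrt(3) / 2) / pi, about 39%.
    """
    R = layout.radius if layout is not None else 1.0
    d = R if center_distance is None else float(center_distance)
    if d >= 2 * R:
        return 0.0
    lens = 2 * R**2 * np.arccos(d / (2 * R)) - (d / 2) * np.sqrt(
        4 * R**2 - d**2)
    return float(lens / (np.pi * R**2))


def error_margin(layout: TargetLayout | None = None,
                 center_distance: float | None = None) -> float:
    """Angular half-width (degrees) of the guaranteed-improvement region.

    The angle at the center between the true-target ray and the ray through
    an intersection point of the two circles; for centers R apart the
    triangle is equilateral and the margin is exactly 60 degrees.
    """
    R = layout.radius if layout is not None else 1.0
    d = R if center_distance is None else float(center_distance)
    # triangle center-target-intersection has sides d, R, R:
    # cos(angle at center) = d / (2R); for d = R this is 60 degrees
    return float(np.degrees(np.arccos(d / (2 * R))))


def chance_angular_stats(n_targets: int = 8) -> tuple[float, float]:
    """Exact mean and sd of |angular error| under uniform random prediction.

    Predictions independent of the truth on an equally spaced layout make
    the error distribution discrete over multiples of the target spacing;
    mean and sd are computed exactly over that distribution (for 8 targets:
    90.0 and sqrt(3037.5) ~ 55.11 degrees).
    """
    spacing = 360.0 / n_targets
    errors = np.array([min(spacing * k, 360.0 - spacing * k)
                       for k in range(n_targets)])
    mean = float(errors.mean())
    sd = float(np.sqrt(np.mean((errors - mean) ** 2)))
    return mean, sd


def compare_with_without(baseline_times: np.ndarray,
                         assisted_times: np.ndarray) -> dict:
    """Paired per-trial comparison of assisted vs unassisted movement times.

    Percentages partition all trials; ties (including the degenerate
    repositioning landing exactly at distance R) count as degraded, i.e. "no
    improvement". The p-value is a one-sided paired t-test of
    assisted < baseline; identical samples give p = 1.
    """
    b = np.asarray(baseline_times, dtype=float)
    a = np.asarray(assisted_times, dtype=float)
    if b.shape != a.shape or b.size == 0:
        raise ValueError("need matching non-empty per-trial time arrays")
    diffs = a - b
    improved = float(np.mean(diffs < 0) * 100.0)
    degraded = 100.0 - improved
    if np.allclose(diffs, 0.0):
        p = 1.0
    else:
        p = float(stats.ttest_rel(a, b, alternative="less").pvalue)
    return {
        "mean_baseline_time": float(b.mean()),
        "mean_assisted_time": float(a.mean()),
        "pct_improved": improved,
        "pct_degraded": degraded,
        "p_value": p,
    }
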