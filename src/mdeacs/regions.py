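"""Automatic detection of the linear scaling region of ``S(w)`` vs ``ln w``.

Real entropy curves are rarely straight end to end: finite statistics bend
the large-``w`` tail downward (heavy-tail "droop"), noise distorts the small
``w`` onset, and strongly periodic signals (ECG-like) show three distinct
linear segments.  The scaling index must be fitted on a genuinely linear
region, located here by penalized piecewise-linear least squares: an optimal
partitioning dynamic program whose penalty plays the role of a sensitivity
threshold — the larger the penalty, the fewer slope change points survive.

:func:`select_fit_region` sweeps the penalty from loose to tight in small
multiplicative increments until the policy-selected region meets the minimum
length requirement, emulating the adaptive-threshold behaviour of built-in
change detectors in numerical environments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dea import EntropyCurve

logger = logging.getLogger(__name__)

__all__ = ["FitRegionPolicy", "detect_slope_change_points", "select_fit_region"]

#: minimum points per piecewise-linear segment in the dynamic program
_MIN_SEG = 3


@dataclass(frozen=True)
class FitRegionPolicy:
    """How to turn detected change points into a fit region.

    modes
        ``auto_single``
            no change point: fit from ``start_fraction`` of the curve to its
            end; one change point: classify as heavy-tail droop (post-change
            slope < 50% of pre-change slope, region ends at the change point
            and starts at ``start_fraction``) or onset distortion (region
            starts at the change point); two change points: the intermediate
            segment.
        ``intermediate_of_two_changes``
            require two change points, fit the intermediate segment.
        ``middle_of_three_segments``
            ECG-like curves with short/intermediate/long segments: fit the
            middle one (requires two change points).
    """

    mode: str = "auto_single"
    min_length: int = 5
    start_fraction: float = 0.20

    _MODES = ("auto_single", "intermediate_of_two_changes", "middle_of_three_segments")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"mode must be one of {self._MODES}")
        if self.min_length < 3:
            raise ValueError("min_length must be >= 3")
        if not 0 <= self.start_fraction < 1:
            raise ValueError("start_fraction must lie in [0, 1)")


def _prefix_sums(x: np.ndarray, y: np.ndarray):
    z = np.zeros(1)
    return (
        np.concatenate((z, np.cumsum(x))),
        np.concatenate((z, np.cumsum(y))),
        np.concatenate((z, np.cumsum(x * x))),
        np.concatenate((z, np.cumsum(y * y))),
        np.concatenate((z, np.cumsum(x * y))),
    )


def _segment_sse(ps, i: np.ndarray, j: int) -> np.ndarray:
    """SSE of a straight-line fit to points ``i .. j-1`` (vector in ``i``)."""
    Sx, Sy, Sxx, Syy, Sxy = ps
    n = j - i
    sx = Sx[j] - Sx[i]
    sy = Sy[j] - Sy[i]
    sxx = Sxx[j] - Sxx[i] - sx * sx / n
    syy = Syy[j] - Syy[i] - sy * sy / n
    sxy = Sxy[j] - Sxy[i] - sx * sy / n
    with np.errstate(divide="ignore", invalid="ignore"):
        sse = syy - np.where(sxx > 0, sxy * sxy / np.maximum(sxx, 1e-300), 0.0)
    return np.maximum(sse, 0.0)


def detect_slope_change_points(curve: EntropyCurve, threshold: float) -> np.ndarray:
    """Indices where the best piecewise-linear description changes slope.

    Optimal partitioning of ``S`` vs ``ln w`` under a per-segment penalty of
    ``threshold``: every extra segment must reduce the residual sum of
    squares by more than the penalty to survive, so a larger threshold yields
    fewer change points.  Returned indices (sorted) are the start points of
    new segments.
    """
    n = len(curve)
    if n < 2 * _MIN_SEG:
        raise ValueError(f"curve too short for segmentation (need >= {2 * _MIN_SEG} points)")
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    x, y = curve.log_w, curve.S
    ps = _prefix_sums(x, y)
    F = np.full(n + 1, np.inf)
    F[0] = -threshold
    prev = np.zeros(n + 1, dtype=np.int64)
    for j in range(_MIN_SEG, n + 1):
        i = np.arange(0, j - _MIN_SEG + 1)
        cand = F[i] + threshold + _segment_sse(ps, i, j)
        k = int(np.argmin(cand))
        F[j] = cand[k]
        prev[j] = i[k]
    cps = []
    j = n
    while j > 0:
        i = int(prev[j])
        if i > 0:
            cps.append(i)
        j = i
    return np.array(sorted(cps), dtype=np.int64)


def _region_from_cps(
    cps: np.ndarray, n: int, policy: FitRegionPolicy, curve: EntropyCurve
):
    """Apply the policy; return (start, end) or None if not applicable yet."""
    k = cps.size
    if policy.mode in ("intermediate_of_two_changes", "middle_of_three_segments"):
        if k == 2:
            return int(cps[0]), int(cps[1])
        return None
    # auto_single
    if k == 0:
        return int(round(policy.start_fraction * n)), n - 1
    if k == 1:
        cp = int(cps[0])
        pre = np.polyfit(curve.log_w[: cp + 1], curve.S[: cp + 1], 1)[0]
        post = np.polyfit(curve.log_w[cp:], curve.S[cp:], 1)[0]
        # heavy-tail droop: the slope collapses after the change, or the
        # change sits in the latter half of the curve (finite-size droop is
        # gradual, so the slope ratio alone can miss it)
        if abs(post) < 0.5 * abs(pre) or cp >= n // 2:
            return int(round(policy.start_fraction * n)), cp
        return cp, n - 1  # onset distortion
    if k == 2:
        if cps[0] >= n // 2:  # both changes in the tail: droop structure
            return int(round(policy.start_fraction * n)), int(cps[0])
        return int(cps[0]), int(cps[1])
    return None


def select_fit_region(
    curve: EntropyCurve,
    policy: FitRegionPolicy | None = None,
    max_iter: int = 40,
    growth: float = 1.25,
) -> tuple[int, int]:
    """Locate the linear fit region by an adaptive penalty sweep.

    The penalty starts loose (many change points) and tightens by
    multiplicative increments of ``growth`` until the policy yields a valid
    region of at least ``policy.min_length`` grid points.  If the sweep is
    exhausted, the longest available segment (of at least 3 points) is
    returned with a logged warning.
    """
    policy = policy or FitRegionPolicy()
    n = len(curve)
    if n < 2 * _MIN_SEG:
        raise ValueError("curve too short to select a fit region")
    ps = _prefix_sums(curve.log_w, curve.S)
    total_sse = float(_segment_sse(ps, np.array([0]), n)[0])
    penalty = max(total_sse, 1e-9) * 1e-3
    last_cps = np.array([], dtype=np.int64)
    for _ in range(max_iter):
        cps = detect_slope_change_points(curve, penalty)
        last_cps = cps
        region = _region_from_cps(cps, n, policy, curve)
        if region is not None:
            start, end = region
            if 0 <= start < end <= n - 1 and end - start + 1 >= policy.min_length:
                return start, end
        penalty *= growth
    # fallback: longest segment delimited by the last change-point set
    bounds = np.concatenate(([0], last_cps, [n - 1]))
    lengths = np.diff(bounds)
    k = int(np.argmax(lengths))
    start, end = int(bounds[k]), int(bounds[k + 1])
    if end - start + 1 < 3:
        raise ValueError("no segment of at least 3 points available")
    logger.warning(
        "fit-region sweep exhausted; falling back to longest segment [%d, %d]",
        start,
        end,
    )
    return start, end
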