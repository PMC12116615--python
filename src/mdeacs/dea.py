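"""Core diffusion entropy analysis: stripes, events, entropy curve, scaling.

The modified DEA turns an amplitude-normalized signal into crucial events by
partitioning the amplitude range into equal "stripes" and marking each
transition between stripes as an event.  The cumulative sum of the 0/1 event
indicator is a diffusion trajectory; the Shannon-Wiener entropy ``S(w)`` of
its displacement distribution over window length ``w`` grows as
``S(w) = A + delta * ln(w)`` for a scaling process, and the slope ``delta``
is the complexity scaling index.

For renewal events with waiting-time exponent ``mu`` the asymptotic relation
is ``delta = mu - 1`` for ``1 < mu < 2`` and ``delta = 1/(mu - 1)`` for
``2 < mu < 3``; uncorrelated (Poisson) events give the ordinary-diffusion
value ``delta = 0.5``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import EventSeries

__all__ = [
    "StripeConfig",
    "EntropyCurve",
    "ScalingFit",
    "assign_stripes",
    "detect_events",
    "diffusion_displacements",
    "default_w_grid",
    "entropy_curve",
    "fit_delta",
    "delta_to_mu",
    "mu_to_delta",
]

#: minimum number of displacements required per window length
MIN_DISPLACEMENTS = 10

#: minimum number of grid points in a scaling-fit region
MIN_FIT_LENGTH = 5


@dataclass(frozen=True)
class StripeConfig:
    """Equal-width amplitude stripes over ``[range_lo, range_hi]``.

    The stripe size is ``(range_hi - range_lo) / n_stripes``.
    """

    n_stripes: int
    range_lo: float = 0.0
    range_hi: float = 1.0

    def __post_init__(self) -> None:
        if self.n_stripes < 2:
            raise ValueError("n_stripes must be >= 2")
        if not self.range_hi > self.range_lo:
            raise ValueError("range_hi must exceed range_lo")

    @property
    def stripe_size(self) -> float:
        return (self.range_hi - self.range_lo) / self.n_stripes


@dataclass(frozen=True)
class EntropyCurve:
    """Shannon-Wiener entropy ``S(w)`` (nats) on a grid of window lengths."""

    w: np.ndarray
    S: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=np.int64)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "S", np.asarray(self.S, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        if w.size and not np.all(np.diff(w) > 0):
            raise ValueError("window lengths must be strictly increasing")

    def __len__(self) -> int:
        return int(self.w.size)

    @property
    def log_w(self) -> np.ndarray:
        return np.log(self.w)


@dataclass(frozen=True)
class ScalingFit:
    """Least-squares fit of ``S(w)`` on ``ln w`` over a curve region."""

    delta: float
    intercept: float
    fit_start_idx: int
    fit_end_idx: int
    r_squared: float
    stderr: float


def assign_stripes(signal: np.ndarray, cfg: StripeConfig) -> np.ndarray:
    """Stripe index in ``[0, n_stripes-1]`` for each sample.

    Values are clamped into the configured range; the upper edge maps to the
    top stripe.
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("signal must be non-empty")
    x = np.clip(x, cfg.range_lo, cfg.range_hi)
    span = cfg.range_hi - cfg.range_lo
    idx = np.floor(cfg.n_stripes * (x - cfg.range_lo) / span).astype(np.int64)
    return np.minimum(idx, cfg.n_stripes - 1)


def detect_events(stripe_idx: np.ndarray, fs: float = 1.0) -> EventSeries:
    """Events are the samples where the stripe index changes.

    ``indicator[i] = 1`` iff ``stripe_idx[i] != stripe_idx[i-1]``; the first
    sample is never an event.
    """
    s = np.asarray(stripe_idx)
    if s.size < 2:
        raise ValueError("need at least 2 samples to detect events")
    indicator = np.concatenate(([0], (np.diff(s) != 0).astype(np.uint8)))
    return EventSeries(indicator=indicator, fs=fs)


def _indicator(events) -> np.ndarray:
    return events.indicator if isinstance(events, EventSeries) else np.asarray(events)


def diffusion_displacements(events, w: int) -> np.ndarray:
    """Displacements ``X(t+w) - X(t)`` over all overlapping unit-step starts.

    ``X`` is the cumulative sum of the event indicator, so each displacement
    is the number of events inside a window of ``w`` samples.
    """
    ind = _indicator(events)
    n = ind.size
    if not 1 <= w < n:
        raise ValueError(f"w must satisfy 1 <= w < n_samples ({n})")
    X = np.concatenate(([0], np.cumsum(ind, dtype=np.int64)))
    return X[w:] - X[:-w]


def default_w_grid(n_samples: int, num: int = 50) -> np.ndarray:
    """Geometrically spaced integer window lengths from 1 to ``n_samples/10``."""
    w_max = max(2, n_samples // 10)
    grid = np.unique(np.round(np.geomspace(1, w_max, num)).astype(np.int64))
    return grid


def entropy_curve(events, w_grid=None, min_displacements: int = MIN_DISPLACEMENTS) -> EntropyCurve:
    """Shannon-Wiener entropy of the integer displacement histogram per ``w``.

    ``S(w) = -sum_x p(x; w) ln p(x; w)`` with ``p`` estimated from the
    histogram of event counts (natural log, no smoothing: displacements are
    integers).
    """
    ind = _indicator(events)
    n = ind.size
    if w_grid is None:
        w_grid = default_w_grid(n)
    w_grid = np.asarray(w_grid, dtype=np.int64)
    if np.any((w_grid <= 0) | (w_grid >= n)):
        raise ValueError("all window lengths must lie in (0, n_samples)")
    X = np.concatenate(([0], np.cumsum(ind, dtype=np.int64)))
    S = np.empty(w_grid.size)
    counts = np.empty(w_grid.size, dtype=np.int64)
    for k, w in enumerate(w_grid):
        disp = X[w:] - X[:-w]
        counts[k] = disp.size
        if disp.size < min_displacements:
            raise ValueError(
                f"window length {w} leaves only {disp.size} displacements "
                f"(minimum {min_displacements})"
            )
        hist = np.bincount(disp)
        p = hist[hist > 0] / disp.size
        S[k] = float(-(p * np.log(p)).sum())
    return EntropyCurve(w=w_grid, S=S, counts=counts)


def fit_delta(
    curve: EntropyCurve,
    start_idx: int,
    end_idx: int,
    min_length: int = MIN_FIT_LENGTH,
) -> ScalingFit:
    """OLS of ``S`` on ``ln w`` over ``curve[start_idx : end_idx]`` (inclusive).

    Returns the slope ``delta`` with intercept, R^2 and the slope's standard
    error.
    """
    if end_idx - start_idx + 1 < min_length:
        raise ValueError(
            f"fit region [{start_idx}, {end_idx}] shorter than minimum "
            f"length {min_length}"
        )
    if not (0 <= start_idx < end_idx < len(curve)):
        raise ValueError("fit region out of curve bounds")
    x = curve.log_w[start_idx : end_idx + 1]
    y = curve.S[start_idx : end_idx + 1]
    if not np.all(np.isfinite(y)):
        raise ValueError("entropy curve non-finite inside fit region")
    res = stats.linregress(x, y)
    return ScalingFit(
        delta=float(res.slope),
        intercept=float(res.intercept),
        fit_start_idx=int(start_idx),
        fit_end_idx=int(end_idx),
        r_squared=float(res.rvalue**2),
        stderr=float(res.stderr),
    )


_BRANCHES = ("complex_1_2", "complex_2_3")


def delta_to_mu(delta: float, branch: str = "complex_2_3") -> float:
    """Map the scaling index to the IPL index ``mu``.

    ``complex_2_3`` (default, ``2 < mu < 3``): ``mu = 1 + 1/delta``;
    ``complex_1_2`` (``1 < mu < 2``): ``mu = 1 + delta``.
    """
    if branch not in _BRANCHES:
        raise ValueError(f"branch must be one of {_BRANCHES}")
    if not 0 < delta <= 1:
        raise ValueError("delta must lie in (0, 1]")
    return 1.0 + (1.0 / delta if branch == "complex_2_3" else delta)


def mu_to_delta(mu: float, branch: str = "complex_2_3") -> float:
    """Inverse of :func:`delta_to_mu` with the same branch semantics."""
    if branch not in _BRANCHES:
        raise ValueError(f"branch must be one of {_BRANCHES}")
    if branch == "complex_2_3":
        if not mu > 2:
            raise ValueError("complex_2_3 branch requires mu > 2")
        return 1.0 / (mu - 1.0)
    if not 1 < mu <= 2:
        raise ValueError("complex_1_2 branch requires mu in (1, 2]")
    return mu - 1.0
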