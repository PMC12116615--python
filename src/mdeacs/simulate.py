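"""Renewal event-train simulation with inverse-power-law waiting times.

Crucial events are renewal events whose inter-event (waiting) times follow
``psi(tau) ~ tau**-mu`` with temporal-complexity index ``1 < mu < 3``.  This
module draws such waiting times, optionally with a time-varying ``mu``,
discretizes them onto a sampling grid as a 0/1 event train, and embeds the
train in a piecewise-constant "surrogate" signal so that stripe-based event
detection can be exercised end to end.

Two generators cover the full complexity range:

* ``1 < mu < 2`` — the Mittag-Leffler map, a transformation of two uniform
  deviates with tail parameter ``beta = mu - 1``.
* ``2 <= mu < 3`` — inverse-CDF sampling of the Pareto law
  ``P(T > tau) = (tau/tau_min)**(1-mu)``; the map with ``beta > 1`` is
  undefined, and the asymptotic power-law tail is what matters downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "WaitingTimes",
    "MuSchedule",
    "EventSeries",
    "SurrogateSignal",
    "ml_waiting_time",
    "generate_waiting_times",
    "generate_time_varying",
    "waiting_times_to_event_train",
    "build_surrogate_signal",
]


@dataclass(frozen=True)
class WaitingTimes:
    """A sequence of inter-event intervals (seconds).

    Parameters
    ----------
    taus : ndarray
        Positive waiting times, in seconds.
    tau_min : float
        Smallest resolvable interval (for discretized data, the sampling
        period); scale anchor of the theoretical Pareto CCDF.
    mu_true : float or None
        Generative inverse-power-law index, if known.
    """

    taus: np.ndarray
    tau_min: float
    mu_true: float | None = None

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus, dtype=float)
        object.__setattr__(self, "taus", taus)
        if taus.ndim != 1 or taus.size < 1:
            raise ValueError("taus must be a non-empty 1-d sequence")
        if not np.all(taus > 0):
            raise ValueError("all waiting times must be positive")
        if not self.tau_min > 0:
            raise ValueError("tau_min must be positive")

    def __len__(self) -> int:
        return int(self.taus.size)


@dataclass(frozen=True)
class MuSchedule:
    """Piecewise-constant trajectory of the IPL index ``mu`` over time.

    ``breakpoints`` are the interior segment boundaries (seconds, strictly
    increasing); segment ``i`` uses ``mu_values[i]``, so there is exactly one
    more ``mu`` than breakpoints.
    """

    breakpoints: np.ndarray
    mu_values: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        mus = np.asarray(self.mu_values, dtype=float)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "mu_values", mus)
        if mus.size == 0:
            raise ValueError("schedule needs at least one mu value")
        if mus.size != bp.size + 1:
            raise ValueError("need exactly one more mu value than breakpoints")
        if bp.size and not np.all(np.diff(bp) > 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any((mus <= 1.0) | (mus >= 3.0)):
            raise ValueError("all mu values must lie in (1, 3)")

    def mu_at(self, t: float) -> float:
        """The ``mu`` in force at time ``t`` (seconds)."""
        return float(self.mu_values[np.searchsorted(self.breakpoints, t, side="right")])


@dataclass(frozen=True)
class EventSeries:
    """Binary event indicator per sample at a stated sampling rate."""

    indicator: np.ndarray
    fs: float
    n_collisions: int = 0

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicator)
        if not np.isin(ind, (0, 1)).all():
            raise ValueError("indicator values must be 0 or 1")
        object.__setattr__(self, "indicator", ind.astype(np.uint8))
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.indicator.size)

    @property
    def n_events(self) -> int:
        return int(self.indicator.sum())

    def event_indices(self) -> np.ndarray:
        return np.flatnonzero(self.indicator)


@dataclass(frozen=True)
class SurrogateSignal:
    """Piecewise-constant carrier signal with known embedded events."""

    samples: np.ndarray
    fs: float
    true_event_indices: np.ndarray
    mu_true: float | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.true_event_indices, dtype=np.int64)
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "true_event_indices", idx)
        if idx.size > 1 and not np.all(np.diff(idx) > 0):
            raise ValueError("event indices must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


def ml_waiting_time(u, v, beta: float, gamma: float = 1.0):
    """One Mittag-Leffler waiting-time deviate.

    ``tau = -gamma * ln(u) * [sin(beta*pi)/tan(beta*pi*v) - cos(beta*pi)]**(1/beta)``

    evaluated through the equivalent, numerically stable and manifestly
    positive form ``sin(beta*pi*(1-v)) / sin(beta*pi*v)`` for the bracket.
    At ``beta = 1`` the bracket is identically 1 and the draw reduces exactly
    to the exponential deviate ``-gamma * ln(u)``.

    Parameters
    ----------
    u, v : float or ndarray
        Independent uniforms, strictly inside (0, 1).
    beta : float
        Tail parameter in (0, 1]; ``beta = mu - 1``.
    gamma : float
        Positive scale constant (seconds).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any((u <= 0) | (u >= 1)) or np.any((v <= 0) | (v >= 1)):
        raise ValueError("u and v must lie strictly inside (0, 1)")
    if not 0 < beta <= 1:
        raise ValueError("beta must lie in (0, 1]")
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    if beta == 1.0:
        tau = -gamma * np.log(u)
    else:
        bracket = np.sin(beta * np.pi * (1.0 - v)) / np.sin(beta * np.pi * v)
        tau = -gamma * np.log(u) * bracket ** (1.0 / beta)
    return tau if tau.ndim else float(tau)


def _open_uniform(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniforms on the open interval (0, 1)."""
    x = rng.random(n)
    tiny = np.finfo(float).tiny
    return np.clip(x, tiny, 1.0 - np.finfo(float).epsneg)


def generate_waiting_times(
    n: int, mu: float, gamma: float = 1.0, seed: int | np.random.Generator | None = None
) -> WaitingTimes:
    """Draw ``n`` IPL waiting times with index ``mu`` in (1, 3).

    For ``mu < 2`` the Mittag-Leffler map with ``beta = mu - 1`` is used
    (``tau_min`` is reported as the smallest draw, the map having no hard
    lower cutoff); for ``mu >= 2`` the Pareto inverse CDF
    ``tau = gamma * U**(1/(1-mu))`` with ``tau_min = gamma``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 1.0 < mu < 3.0:
        raise ValueError("mu must lie in the open interval (1, 3)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if mu < 2.0:
        u = _open_uniform(rng, n)
        v = _open_uniform(rng, n)
        taus = np.asarray(ml_waiting_time(u, v, beta=mu - 1.0, gamma=gamma))
        taus = np.atleast_1d(taus)
        tau_min = float(taus.min())
    else:
        u = _open_uniform(rng, n)
        taus = gamma * u ** (1.0 / (1.0 - mu))
        tau_min = gamma
    return WaitingTimes(taus=taus, tau_min=tau_min, mu_true=mu)


def generate_time_varying(
    schedule: MuSchedule,
    duration: float,
    gamma: float | Sequence[float] = 1.0,
    seed: int | np.random.Generator | None = None,
    tau_max: float | None = None,
    _chunk: int = 4096,
) -> WaitingTimes:
    """Waiting times whose generative ``mu`` follows ``schedule`` over time.

    Each waiting time is drawn with the ``mu`` of the segment containing its
    start time; generation stops with the first waiting time whose start
    reaches ``duration`` (that final interval is kept, so a duration shorter
    than the first draw still yields one waiting time).  ``gamma`` may be a
    scalar or one scale per segment; ``tau_max`` optionally clips each draw
    (bounding the longest silent gap, which also keeps the timeline of
    heavy-tailed segments finite in memory once discretized).
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    gammas = np.broadcast_to(np.asarray(gamma, dtype=float), (schedule.mu_values.size,))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    taus_out: list[np.ndarray] = []
    t = 0.0
    while t < duration:
        seg = int(np.searchsorted(schedule.breakpoints, t, side="right"))
        mu = float(schedule.mu_values[seg])
        seg_end = duration
        if seg < schedule.breakpoints.size:
            seg_end = min(seg_end, float(schedule.breakpoints[seg]))
        chunk = generate_waiting_times(_chunk, mu, gamma=float(gammas[seg]), seed=rng).taus
        if tau_max is not None:
            chunk = np.minimum(chunk, tau_max)
        starts = t + np.concatenate(([0.0], np.cumsum(chunk[:-1])))
        keep = starts < seg_end
        kept = chunk[keep]
        taus_out.append(kept)
        t = float(starts[keep][-1] + kept[-1]) if kept.size else t
        if kept.size == chunk.size:
            continue  # segment boundary not reached in this chunk? (keep drawing)
        # first waiting time of the next segment starts at the end of the
        # last kept draw, which may overshoot seg_end; loop re-evaluates mu.
    taus = np.concatenate(taus_out)
    # truncate: drop waiting times starting at/after duration (keep the first
    # one that crosses it)
    starts = np.concatenate(([0.0], np.cumsum(taus[:-1])))
    taus = taus[starts < duration]
    mu_true = float(schedule.mu_values[0]) if schedule.mu_values.size == 1 else None
    return WaitingTimes(taus=taus, tau_min=float(taus.min()), mu_true=mu_true)


def waiting_times_to_event_train(
    wt: WaitingTimes, fs: float, duration: float
) -> EventSeries:
    """Discretize cumulative waiting times onto a sampling grid.

    An event is placed at sample ``round(cumulative_tau * fs)``; events past
    ``duration`` are dropped and coincident events collapse to one (the
    collision count is logged and recorded on the returned series).
    """
    if not fs > 0 or not duration > 0:
        raise ValueError("fs and duration must be positive")
    n_samples = int(round(duration * fs))
    if n_samples < 1:
        raise ValueError("fs * duration must be at least 1 sample")
    positions = np.round(np.cumsum(wt.taus) * fs).astype(np.int64)
    positions = positions[positions < n_samples]
    unique = np.unique(positions)
    n_collisions = int(positions.size - unique.size)
    if n_collisions:
        logger.info("event discretization collapsed %d coincident events", n_collisions)
    indicator = np.zeros(n_samples, dtype=np.uint8)
    indicator[unique] = 1
    return EventSeries(indicator=indicator, fs=fs, n_collisions=n_collisions)


def build_surrogate_signal(
    wt: WaitingTimes,
    fs: float,
    duration: float,
    n_levels: int = 10,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> SurrogateSignal:
    """Piecewise-constant signal in [0, 1] that jumps at each event.

    At every event the level moves to a uniformly chosen *different* level
    among ``n_levels`` equispaced values, so stripe detection with at least
    ``n_levels`` stripes sees every true event; optional additive Gaussian
    noise emulates measurement noise.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    events = waiting_times_to_event_train(wt, fs=fs, duration=duration)
    idx = events.event_indices()
    levels = np.linspace(0.0, 1.0, n_levels)
    # consecutive-level draws guaranteed distinct: step in {1, .., n_levels-1}
    steps = rng.integers(1, n_levels, size=idx.size + 1)
    level_idx = np.cumsum(steps) % n_levels
    bounds = np.concatenate(([0], idx, [events.n_samples]))
    seg_lengths = np.diff(bounds)
    samples = np.repeat(levels[level_idx], seg_lengths)
    if noise_sd > 0:
        samples = samples + rng.normal(0.0, noise_sd, size=samples.size)
    return SurrogateSignal(
        samples=samples, fs=fs, true_event_indices=idx, mu_true=wt.mu_true
    )
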