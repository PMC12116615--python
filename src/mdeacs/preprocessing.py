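"""Window normalization, resampling, and oscillation removal.

Heterogeneous physiological channels (EEG, ECG, respiration) span orders of
magnitude in amplitude and frequency, so each analysis window is min-max
normalized to [0, 1] before stripe detection.  Strongly oscillatory signals
such as respiration violate the renewal assumption behind the event
statistics; the dominant periodic component can be removed with a zero-phase
Kaiser-window FIR high-pass filter (default cutoff 2 Hz, order 8192), by
differentiation, or by taking the Hilbert-envelope, prior to analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationError",
    "SignalRecord",
    "normalize_minmax",
    "resample_signal",
    "highpass_zero_phase",
    "aperiodicize",
]


class NormalizationError(ValueError):
    """A window could not be normalized (flat segment)."""


@dataclass(frozen=True)
class SignalRecord:
    """Multichannel record: equal-length named series at one sampling rate.

    ``modality`` maps channel names to one of ``EEG``/``ECG``/``RESP``/
    ``other``; unnamed channels default to ``other``.
    """

    data: pd.DataFrame
    fs: float
    modality: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("record must contain at least one sample and channel")
        mod = {c: self.modality.get(c, "other") for c in self.data.columns}
        object.__setattr__(self, "modality", mod)

    @property
    def channels(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[0])

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def normalize_minmax(window: np.ndarray) -> np.ndarray:
    """Map a window affinely onto [0, 1]; both endpoints are attained.

    A window that is constant up to floating-point jitter carries no
    amplitude information and raises :class:`NormalizationError`.
    """
    x = np.asarray(window, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi - lo <= 1e-9 * max(abs(hi), abs(lo)):
        raise NormalizationError("constant window cannot be min-max normalized")
    return (x - lo) / (hi - lo)


def resample_signal(record: SignalRecord, target_fs: float) -> SignalRecord:
    """Anti-aliased downsampling of every channel to ``target_fs``.

    Polyphase resampling with the rational factor ``target_fs / fs`` (the
    built-in FIR low-pass provides the anti-alias filtering).  Upsampling is
    refused.
    """
    if target_fs > record.fs:
        raise ValueError("upsampling is not supported")
    if target_fs == record.fs:
        return record
    frac = Fraction(target_fs / record.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    cols = {
        c: sps.resample_poly(record.data[c].to_numpy(dtype=float), up, down)
        for c in record.data.columns
    }
    return SignalRecord(data=pd.DataFrame(cols), fs=target_fs, modality=dict(record.modality))


def _kaiser_highpass(ntaps: int, cutoff_hz: float, fs: float, atten_db: float = 60.0):
    beta = sps.kaiser_beta(atten_db)
    return sps.firwin(ntaps, cutoff_hz, window=("kaiser", beta), pass_zero=False, fs=fs)


def highpass_zero_phase(
    window: np.ndarray,
    fs: float,
    cutoff_hz: float = 2.0,
    order: int = 8192,
) -> np.ndarray:
    """Forward-backward Kaiser-window FIR high-pass (zero net phase).

    The FIR is applied twice (once reversed), squaring the magnitude response:
    net phase is exactly zero and stopband attenuation doubles.  When the
    window is shorter than the requested order the order is reduced to fit,
    with a logged warning (the transition consequently widens).  Edges are
    handled by reflection padding.
    """
    x = np.asarray(window, dtype=float)
    if not cutoff_hz < fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    ntaps = order + 1 if order % 2 == 0 else order  # Type-I FIR needs odd taps
    if ntaps >= x.size:
        ntaps = max(3, (x.size - 1) | 1)
        if ntaps >= x.size:
            ntaps = x.size - 1 if (x.size - 1) % 2 == 1 else x.size - 2
        logger.warning(
            "window of %d samples cannot support FIR order %d; reduced to %d taps",
            x.size,
            order,
            ntaps,
        )
    if ntaps < 3:
        raise ValueError("window too short to filter")
    b = _kaiser_highpass(ntaps, cutoff_hz, fs)
    pad = min(ntaps, x.size - 1)
    xp = np.concatenate((x[pad:0:-1], x, x[-2 : -pad - 2 : -1]))
    fwd = sps.fftconvolve(xp, b, mode="same")
    bwd = sps.fftconvolve(fwd[::-1], b, mode="same")[::-1]
    return bwd[pad : pad + x.size]


def aperiodicize(window: np.ndarray, method: str = "differentiate") -> np.ndarray:
    """Suppress dominant periodicity by differencing or envelope extraction.

    ``differentiate`` takes first differences (re-padded to the input
    length); ``hilbert_envelope`` takes the analytic-signal magnitude.  Both
    outputs are re-normalized to [0, 1], so a window whose transform is
    constant (e.g. the derivative of a linear ramp) raises
    :class:`NormalizationError`.
    """
    x = np.asarray(window, dtype=float)
    if x.size < 3:
        raise ValueError("window too short to aperiodicize")
    if method == "differentiate":
        d = np.diff(x)
        out = np.concatenate(([d[0]], d))
    elif method == "hilbert_envelope":
        out = np.abs(sps.hilbert(x))
    else:
        raise ValueError("method must be 'differentiate' or 'hilbert_envelope'")
    return normalize_minmax(out)
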