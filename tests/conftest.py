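"""Shared fixtures: seeded RNGs, small surrogates, a synthetic EDF writer."""

from __future__ import annotations

import numpy as np
import pytest

import mdeacs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def clean_surrogate():
    """Noise-free surrogate signal with a known mu=2.5 event train."""
    wt = mdeacs.generate_waiting_times(2000, 2.5, gamma=4.0, seed=7)
    return mdeacs.build_surrogate_signal(
        wt, fs=1.0, duration=float(np.sum(wt.taus)) + 2.0, n_levels=10, noise_sd=0.0, seed=7
    )


def write_minimal_edf(path, channels: dict, fs: int, record_dur: float = 1.0) -> None:
    """Write a minimal synthetic EDF file (16-bit, physical range [-1, 1]).

    Test-only helper: the environment ships an EDF reader (mne) but no
    writer, so round-trip tests construct this synthetic fixture themselves.
    """
    names = list(channels)
    ns = len(names)
    spr = int(fs * record_dur)
    n = len(next(iter(channels.values())))
    n_rec = n // spr
    header_bytes = 256 + ns * 256
    hdr = b"0".ljust(8)
    hdr += b"X X X X".ljust(80)
    hdr += b"Startdate X X X X".ljust(80)
    hdr += b"01.01.20" + b"00.00.00"
    hdr += str(header_bytes).encode().ljust(8)
    hdr += b"".ljust(44)
    hdr += str(n_rec).encode().ljust(8)
    hdr += (f"{record_dur:g}").encode().ljust(8)
    hdr += str(ns).encode().ljust(4)

    def field(vals, width):
        return b"".join(str(v).encode().ljust(width) for v in vals)

    hdr += field(names, 16)
    hdr += field(["" for _ in names], 80)  # transducer
    hdr += field(["uV" for _ in names], 8)  # physical dimension
    hdr += field([-1 for _ in names], 8)  # physical min
    hdr += field([1 for _ in names], 8)  # physical max
    hdr += field([-32768 for _ in names], 8)  # digital min
    hdr += field([32767 for _ in names], 8)  # digital max
    hdr += field(["" for _ in names], 80)  # prefiltering
    hdr += field([spr for _ in names], 8)
    hdr += field(["" for _ in names], 32)
    assert len(hdr) == header_bytes
    scaled = {
        k: np.clip(np.round(np.asarray(v) * 32767), -32768, 32767).astype("<i2")
        for k, v in channels.items()
    }
    with open(path, "wb") as f:
        f.write(hdr)
        for r in range(n_rec):
            for k in names:
                f.write(scaled[k][r * spr : (r + 1) * spr].tobytes())


@pytest.fixture
def edf_writer():
    return write_minimal_edf
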