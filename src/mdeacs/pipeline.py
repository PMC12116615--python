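"""Sliding-window complexity-synchronization (CS) pipeline.

Each channel of a multichannel record is analyzed in 30-s moving windows
with 20-s overlap (defaults): the window is normalized (oscillatory channels
optionally high-pass filtered, differenced, or enveloped first), stripes and
the linear fit region — held fixed per subject at their per-window medians —
produce one scaling index ``delta`` per window.  Complexity synchronization
between two channels is the Pearson correlation of their ``delta`` series
over jointly valid windows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import dea, ks, regions
from .preprocessing import NormalizationError, SignalRecord, aperiodicize, highpass_zero_phase, normalize_minmax

logger = logging.getLogger(__name__)

__all__ = [
    "DeltaSeries",
    "CSMatrix",
    "ModalityParams",
    "SubjectParams",
    "window_samples",
    "slide_windows",
    "prepare_window",
    "estimate_subject_params",
    "delta_series",
    "cs_correlation",
    "cs_matrix",
    "summarize_cs",
    "read_signals",
    "write_results",
]

RESP_MODES = ("raw", "highpass", "diff", "envelope")


@dataclass(frozen=True)
class DeltaSeries:
    """Per-window scaling indices for one channel."""

    channel: str
    window_start_times: np.ndarray
    deltas: np.ndarray
    mus: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        for name in ("window_start_times", "deltas", "mus"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "valid", np.asarray(self.valid, dtype=bool))
        n = {self.window_start_times.size, self.deltas.size, self.mus.size, self.valid.size}
        if len(n) != 1:
            raise ValueError("all DeltaSeries fields must have equal length")
        if not np.all(np.isfinite(self.deltas[self.valid])):
            raise ValueError("deltas must be finite where valid")

    def __len__(self) -> int:
        return int(self.valid.size)


@dataclass(frozen=True)
class CSMatrix:
    """Pairwise Pearson correlations of delta series (symmetric, unit diagonal)."""

    r: pd.DataFrame
    p: pd.DataFrame
    n_windows: pd.DataFrame


@dataclass(frozen=True)
class ModalityParams:
    n_stripes: int
    fit_start_idx: int
    fit_end_idx: int


@dataclass(frozen=True)
class SubjectParams:
    """Per-modality median stripe and fit-region settings, fixed across windows."""

    per_modality: dict = field(default_factory=dict)

    def for_modality(self, modality: str) -> ModalityParams:
        if modality in self.per_modality:
            return self.per_modality[modality]
        if "other" in self.per_modality:
            return self.per_modality["other"]
        raise KeyError(f"no parameters for modality {modality!r}")


def window_samples(win_s: float, fs: float) -> int:
    """Number of samples in a window of ``win_s`` seconds at rate ``fs``."""
    return int(round(win_s * fs))


def slide_windows(
    record: SignalRecord, win_s: float = 30.0, overlap_s: float = 20.0
) -> list[tuple[int, int]]:
    """Start/stop sample indices of overlapping moving windows.

    Windows start at 0 and advance by ``win_s - overlap_s``; a trailing
    partial window is dropped.
    """
    if not 0 <= overlap_s < win_s:
        raise ValueError("overlap must be non-negative and smaller than the window")
    win_n = window_samples(win_s, record.fs)
    step_n = window_samples(win_s - overlap_s, record.fs)
    if record.n_samples < win_n:
        raise ValueError("record shorter than one window")
    starts = range(0, record.n_samples - win_n + 1, step_n)
    return [(s, s + win_n) for s in starts]


def prepare_window(
    x: np.ndarray,
    fs: float,
    modality: str = "other",
    resp_mode: str = "highpass",
    hp_cutoff: float = 2.0,
    hp_order: int = 8192,
) -> np.ndarray:
    """Modality-specific preprocessing + min-max normalization of one window."""
    if resp_mode not in RESP_MODES:
        raise ValueError(f"resp_mode must be one of {RESP_MODES}")
    if modality == "RESP" and resp_mode != "raw":
        if resp_mode == "highpass":
            x = highpass_zero_phase(x, fs, cutoff_hz=hp_cutoff, order=hp_order)
        elif resp_mode == "diff":
            return aperiodicize(x, "differentiate")
        else:
            return aperiodicize(x, "hilbert_envelope")
    return normalize_minmax(x)


def _window_estimates(
    x: np.ndarray,
    fs: float,
    stripe_grid,
    mu_grid,
    policy: regions.FitRegionPolicy,
    w_grid=None,
):
    """(n_stripes, fit_start, fit_end) estimated on a single prepared window."""
    sol = ks.grid_search_mu_stripes(x, fs, stripe_grid=stripe_grid, mu_grid=mu_grid)
    cfg = sol.stripe_hat
    ev = dea.detect_events(dea.assign_stripes(x, cfg), fs=fs)
    curve = dea.entropy_curve(ev, w_grid)
    start, end = regions.select_fit_region(curve, policy)
    return cfg.n_stripes, start, end


def estimate_subject_params(
    record: SignalRecord,
    win_s: float = 30.0,
    overlap_s: float = 20.0,
    stripe_grid=None,
    mu_grid=None,
    policy: regions.FitRegionPolicy | None = None,
    resp_mode: str = "highpass",
    min_valid_fraction: float = 0.5,
) -> SubjectParams:
    """Median per-window stripe counts and fit regions, per modality.

    Falls back (with a warning) to 10 stripes and the policy default region
    for a modality whose windows were valid in fewer than
    ``min_valid_fraction`` of cases.
    """
    policy = policy or regions.FitRegionPolicy()
    windows = slide_windows(record, win_s, overlap_s)
    by_modality: dict[str, list[tuple[int, int, int]]] = {}
    totals: dict[str, int] = {}
    for ch in record.channels:
        modality = record.modality[ch]
        series = record.data[ch].to_numpy(dtype=float)
        for a, b in windows:
            totals[modality] = totals.get(modality, 0) + 1
            try:
                x = prepare_window(series[a:b], record.fs, modality, resp_mode)
                est = _window_estimates(x, record.fs, stripe_grid, mu_grid, policy)
            except (ValueError, NormalizationError) as exc:
                logger.debug("window [%d:%d] of %s skipped: %s", a, b, ch, exc)
                continue
            by_modality.setdefault(modality, []).append(est)
    per_modality = {}
    for modality, total in totals.items():
        ests = by_modality.get(modality, [])
        if len(ests) < min_valid_fraction * total:
            logger.warning(
                "modality %s: only %d/%d valid windows; falling back to defaults",
                modality,
                len(ests),
                total,
            )
            per_modality[modality] = ModalityParams(10, -1, -1)
            continue
        arr = np.asarray(ests)
        per_modality[modality] = ModalityParams(
            n_stripes=int(round(float(np.median(arr[:, 0])))),
            fit_start_idx=int(round(float(np.median(arr[:, 1])))),
            fit_end_idx=int(round(float(np.median(arr[:, 2])))),
        )
    return SubjectParams(per_modality=per_modality)


def delta_series(
    record: SignalRecord,
    params: SubjectParams,
    win_s: float = 30.0,
    overlap_s: float = 20.0,
    resp_mode: str = "highpass",
    mu_branch: str = "complex_2_3",
    w_grid=None,
    min_events: int = 10,
) -> dict[str, DeltaSeries]:
    """Per-channel scaling-index series over sliding windows.

    Windows that fail normalization, yield too few events, or produce a
    non-finite fit are flagged invalid (never interpolated).
    """
    windows = slide_windows(record, win_s, overlap_s)
    out: dict[str, DeltaSeries] = {}
    for ch in record.channels:
        modality = record.modality[ch]
        mp = params.for_modality(modality)
        series = record.data[ch].to_numpy(dtype=float)
        starts, deltas, mus, valid = [], [], [], []
        for a, b in windows:
            starts.append(a / record.fs)
            delta = np.nan
            mu = np.nan
            ok = False
            try:
                x = prepare_window(series[a:b], record.fs, modality, resp_mode)
                cfg = dea.StripeConfig(mp.n_stripes, float(x.min()), float(x.max()))
                ev = dea.detect_events(dea.assign_stripes(x, cfg), fs=record.fs)
                if ev.n_events < min_events:
                    raise ValueError(f"only {ev.n_events} events in window")
                curve = dea.entropy_curve(ev, w_grid)
                if mp.fit_start_idx < 0:  # fallback params: per-window auto region
                    s_idx, e_idx = regions.select_fit_region(curve)
                else:
                    s_idx = min(mp.fit_start_idx, len(curve) - 2)
                    e_idx = min(mp.fit_end_idx, len(curve) - 1)
                fit = dea.fit_delta(curve, s_idx, e_idx)
                delta = fit.delta
                if 0 < delta <= 1:
                    mu = dea.delta_to_mu(delta, mu_branch)
                ok = np.isfinite(delta)
            except (ValueError, NormalizationError) as exc:
                logger.debug("window [%d:%d] of %s invalid: %s", a, b, ch, exc)
            deltas.append(delta)
            mus.append(mu)
            valid.append(ok)
        out[ch] = DeltaSeries(
            channel=ch,
            window_start_times=np.asarray(starts),
            deltas=np.asarray(deltas),
            mus=np.asarray(mus),
            valid=np.asarray(valid),
        )
    return out


def cs_correlation(ds_a: DeltaSeries, ds_b: DeltaSeries) -> tuple[float, float, int]:
    """Pearson correlation of two delta series over jointly valid windows."""
    if len(ds_a) != len(ds_b):
        raise ValueError("delta series must cover the same windows")
    joint = ds_a.valid & ds_b.valid
    n = int(joint.sum())
    if n < 10:
        raise ValueError(f"only {n} jointly valid windows (need >= 10)")
    r, p = stats.pearsonr(ds_a.deltas[joint], ds_b.deltas[joint])
    return float(r), float(p), n


def mean_delta_series(series: list[DeltaSeries], name: str = "EEG") -> DeltaSeries:
    """Channel-mean delta series (used to summarize EEG before correlating)."""
    if not series:
        raise ValueError("need at least one series")
    deltas = np.vstack([s.deltas for s in series])
    mus = np.vstack([s.mus for s in series])
    valid = np.vstack([s.valid for s in series])
    any_valid = valid.any(axis=0)
    n_valid = np.maximum(valid.sum(axis=0), 1)
    mean_d = np.where(any_valid, np.where(valid, deltas, 0.0).sum(axis=0) / n_valid, np.nan)
    with np.errstate(invalid="ignore"):
        mus_ok = valid & np.isfinite(mus)
        n_mu = np.maximum(mus_ok.sum(axis=0), 1)
        mean_m = np.where(mus_ok.any(axis=0), np.where(mus_ok, mus, 0.0).sum(axis=0) / n_mu, np.nan)
    return DeltaSeries(
        channel=name,
        window_start_times=series[0].window_start_times,
        deltas=mean_d,
        mus=mean_m,
        valid=any_valid,
    )


def cs_matrix(series: dict[str, DeltaSeries]) -> CSMatrix:
    """Full pairwise CS correlation matrix with two-sided p-values."""
    names = list(series)
    k = len(names)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        n[i, i] = int(series[names[i]].valid.sum())
        for j in range(i + 1, k):
            rij, pij, nij = cs_correlation(series[names[i]], series[names[j]])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
            n[i, j] = n[j, i] = nij
    idx = pd.Index(names)
    return CSMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n_windows=pd.DataFrame(n, index=idx, columns=idx),
    )


def summarize_cs(matrices: dict[str, CSMatrix], alpha: float = 0.05) -> pd.DataFrame:
    """Per-dataset pairwise significance flags and the all-pairs flag.

    One row per dataset; one boolean column per channel pair plus
    ``all_pairs``.  Aggregate counts are ``table.sum()``.
    """
    if not matrices:
        raise ValueError("need at least one dataset")
    rows = {}
    for name, m in matrices.items():
        cols = list(m.p.columns)
        flags = {}
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                flags[f"{cols[i]}-{cols[j]}"] = bool(m.p.iloc[i, j] < alpha)
        flags["all_pairs"] = all(flags.values()) if flags else False
        rows[name] = flags
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# file I/O


def _infer_modality(label: str) -> str:
    u = str(label).upper()
    if u.startswith("EEG"):
        return "EEG"
    if u.startswith("ECG") or u.startswith("EKG"):
        return "ECG"
    if u.startswith("RESP"):
        return "RESP"
    return "other"


def read_signals(path, format: str | None = None, fs: float | None = None) -> SignalRecord:
    """Read a multichannel record from CSV (time + channel columns) or EDF.

    CSV needs either a leading ``time`` column (seconds; the sampling rate is
    its median increment) or an explicit ``fs``.  EDF files are read through
    ``mne`` with channel labels preserved.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = pd.DataFrame(raw.get_data().T, columns=raw.ch_names)
        modality = {c: _infer_modality(c) for c in raw.ch_names}
        return SignalRecord(data=data, fs=float(raw.info["sfreq"]), modality=modality)
    if fmt in ("csv", "tsv"):
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep)
        if df.shape[1] == 0:
            raise ValueError("malformed header: no columns found")
        first = str(df.columns[0]).lower()
        if first in ("time", "t", "time_s"):
            t = df.iloc[:, 0].to_numpy(dtype=float)
            if t.size < 2:
                raise ValueError("time column too short to infer fs")
            fs = 1.0 / float(np.median(np.diff(t)))
            df = df.iloc[:, 1:]
        elif fs is None:
            raise ValueError("CSV without a time column requires an explicit fs")
        if df.isna().any().any():
            raise ValueError("inconsistent column lengths (missing values found)")
        modality = {c: _infer_modality(c) for c in df.columns}
        return SignalRecord(data=df.astype(float), fs=float(fs), modality=modality)
    raise ValueError(f"unknown format {fmt!r}")


def write_results(
    outdir,
    fits: dict | None = None,
    deltas: dict[str, DeltaSeries] | None = None,
    matrix: CSMatrix | None = None,
) -> list[Path]:
    """Write fit reports (JSON), delta series and correlation matrices (CSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fits is not None:
        p = outdir / "fits.json"
        p.write_text(json.dumps(fits, indent=2, default=float))
        written.append(p)
    if deltas is not None:
        frames = {}
        for ch, ds in deltas.items():
            frames[f"{ch}_delta"] = ds.deltas
            frames[f"{ch}_valid"] = ds.valid.astype(int)
        df = pd.DataFrame(frames, index=pd.Index(
            next(iter(deltas.values())).window_start_times, name="window_start_s"
        ))
        p = outdir / "delta_series.csv"
        df.to_csv(p)
        written.append(p)
    if matrix is not None:
        for name, df in (("cs_r", matrix.r), ("cs_p", matrix.p), ("cs_n", matrix.n_windows)):
            p = outdir / f"{name}.csv"
            df.to_csv(p)
            written.append(p)
    return written
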