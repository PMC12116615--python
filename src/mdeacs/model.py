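"""Model/Results interface for MDEA and complexity-synchronization analysis.

Two model classes in the statsmodels idiom: construct from data, call
``fit()``, get a results object carrying estimates, uncertainties and
diagnostics with a ``summary()`` table and plotting helpers.

* :class:`MDEA` — one signal window (or whole recording) in, one scaling
  index ``delta`` (with its KS-selected stripe configuration, fit region,
  standard error and the transformed IPL index ``mu``) out.
* :class:`ComplexitySynchronization` — a multichannel record in, per-channel
  ``delta`` series over sliding windows and the pairwise CS correlation
  matrix out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dea, ks, pipeline, regions
from .preprocessing import SignalRecord, normalize_minmax

__all__ = ["MDEA", "MDEAResults", "ComplexitySynchronization", "CSResults"]


class MDEA:
    """Modified diffusion entropy analysis of a single signal.

    Parameters
    ----------
    signal : array-like
        Amplitude samples; min-max normalized internally.
    fs : float
        Sampling rate in Hz (sets ``tau_min = 1/fs`` for the KS fit).
    stripes : int or "auto"
        Fixed stripe count, or joint KS selection of stripe count and ``mu``
        over the default grids.
    fit_region : tuple(start, end) or "auto"
        Index region of the entropy curve for the ``delta`` fit; "auto" uses
        adaptive change-point detection under ``region_policy``.
    mu_branch : str
        ``delta -> mu`` branch, ``complex_2_3`` (default) or ``complex_1_2``.
    """

    def __init__(
        self,
        signal,
        fs: float,
        stripes="auto",
        fit_region="auto",
        mu_branch: str = "complex_2_3",
        region_policy: regions.FitRegionPolicy | None = None,
        stripe_grid=None,
        mu_grid=None,
        w_grid=None,
    ):
        self.signal = np.asarray(signal, dtype=float)
        if self.signal.ndim != 1 or self.signal.size < 4:
            raise ValueError("signal must be a 1-d sequence of at least 4 samples")
        self.fs = float(fs)
        self.stripes = stripes
        self.fit_region = fit_region
        self.mu_branch = mu_branch
        self.region_policy = region_policy or regions.FitRegionPolicy()
        self.stripe_grid = stripe_grid
        self.mu_grid = mu_grid
        self.w_grid = w_grid

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, column: str, fs: float | None = None, **kwargs):
        """Build from a DataFrame with an optional leading ``time`` column."""
        if fs is None:
            first = str(df.columns[0]).lower()
            if first not in ("time", "t", "time_s"):
                raise ValueError("fs required when the DataFrame has no time column")
            t = df.iloc[:, 0].to_numpy(dtype=float)
            fs = 1.0 / float(np.median(np.diff(t)))
        return cls(df[column].to_numpy(dtype=float), fs=fs, **kwargs)

    def fit(self) -> "MDEAResults":
        x = normalize_minmax(self.signal)
        ks_solution = None
        if self.stripes == "auto":
            ks_solution = ks.grid_search_mu_stripes(
                x, self.fs, stripe_grid=self.stripe_grid, mu_grid=self.mu_grid
            )
            cfg = ks_solution.stripe_hat
        else:
            cfg = dea.StripeConfig(int(self.stripes), float(x.min()), float(x.max()))
        events = dea.detect_events(dea.assign_stripes(x, cfg), fs=self.fs)
        curve = dea.entropy_curve(events, self.w_grid)
        if self.fit_region == "auto":
            start, end = regions.select_fit_region(curve, self.region_policy)
        else:
            start, end = self.fit_region
        scaling = dea.fit_delta(curve, start, end, min_length=min(5, end - start + 1))
        return MDEAResults(
            model=self,
            stripe_config=cfg,
            events=events,
            curve=curve,
            scaling=scaling,
            ks_solution=ks_solution,
        )


@dataclass
class MDEAResults:
    """Fitted MDEA scaling index with diagnostics."""

    model: MDEA
    stripe_config: dea.StripeConfig
    events: object
    curve: dea.EntropyCurve
    scaling: dea.ScalingFit
    ks_solution: ks.KSSolution | None = None

    @property
    def delta(self) -> float:
        return self.scaling.delta

    @property
    def bse(self) -> float:
        """Standard error of the fitted slope."""
        return self.scaling.stderr

    @property
    def mu(self) -> float:
        """IPL index implied by ``delta`` on the model's branch."""
        d = min(max(self.scaling.delta, 1e-12), 1.0)
        return dea.delta_to_mu(d, self.model.mu_branch)

    @property
    def mu_ks(self) -> float | None:
        """KS-selected ``mu`` (independent of the entropy fit), if available."""
        return self.ks_solution.mu_hat if self.ks_solution is not None else None

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        from scipy import stats as st

        dof = self.scaling.fit_end_idx - self.scaling.fit_start_idx - 1
        q = st.t.ppf(1 - alpha / 2, dof)
        return (self.delta - q * self.bse, self.delta + q * self.bse)

    def summary(self) -> str:
        s = self.scaling
        lo, hi = self.conf_int()
        lines = [
            "Modified Diffusion Entropy Analysis",
            "=" * 51,
            f"{'n samples':<28}{self.model.signal.size:>23d}",
            f"{'sampling rate (Hz)':<28}{self.model.fs:>23.6g}",
            f"{'stripes':<28}{self.stripe_config.n_stripes:>23d}",
            f"{'stripe size':<28}{self.stripe_config.stripe_size:>23.6g}",
            f"{'events detected':<28}{self.events.n_events:>23d}",
            f"{'fit region (grid idx)':<28}{f'[{s.fit_start_idx}, {s.fit_end_idx}]':>23}",
            f"{'delta (scaling index)':<28}{s.delta:>23.4f}",
            f"{'std err':<28}{s.stderr:>23.4f}",
            f"{'95% CI':<28}{f'[{lo:.4f}, {hi:.4f}]':>23}",
            f"{'R^2':<28}{s.r_squared:>23.4f}",
            f"{'mu from delta':<28}{self.mu:>23.4f}",
        ]
        if self.ks_solution is not None:
            lines.append(f"{'mu from KS selection':<28}{self.ks_solution.mu_hat:>23.4f}")
            lines.append(f"{'KS distance D':<28}{self.ks_solution.D:>23.4f}")
        lines.append("=" * 51)
        return "\n".join(lines)

    def plot_entropy(self, ax=None):
        """Entropy curve with the fitted scaling line over the fit region."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.scaling
        ax.semilogx(self.curve.w, self.curve.S, "o", ms=3, label="S(w)")
        w_fit = self.curve.w[s.fit_start_idx : s.fit_end_idx + 1]
        ax.semilogx(
            w_fit,
            s.intercept + s.delta * np.log(w_fit),
            "-",
            label=rf"$\delta$ = {s.delta:.3f}",
        )
        ax.set_xlabel("window length w (samples)")
        ax.set_ylabel("S(w) (nats)")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        """JSON-serializable fit report."""
        s = self.scaling
        out = {
            "delta": s.delta,
            "delta_stderr": s.stderr,
            "intercept": s.intercept,
            "r_squared": s.r_squared,
            "mu_from_delta": self.mu,
            "mu_branch": self.model.mu_branch,
            "fit_region": [s.fit_start_idx, s.fit_end_idx],
            "n_stripes": self.stripe_config.n_stripes,
            "stripe_size": self.stripe_config.stripe_size,
            "n_events": int(self.events.n_events),
            "fs": self.model.fs,
        }
        if self.ks_solution is not None:
            out["mu_ks"] = self.ks_solution.mu_hat
            out["ks_distance"] = self.ks_solution.D
        return out


class ComplexitySynchronization:
    """Sliding-window CS analysis of a multichannel record.

    Per-subject parameters (median stripe count and fit region per modality)
    are estimated once across all windows, then held fixed while the
    per-window ``delta`` series are computed; channel pairs are correlated
    over jointly valid windows.  EEG channels are averaged into one
    ``delta`` series before correlating (per-channel series remain available
    on the results object).
    """

    def __init__(
        self,
        record: SignalRecord,
        win_s: float = 30.0,
        overlap_s: float = 20.0,
        resp_mode: str = "highpass",
        mu_branch: str = "complex_2_3",
        stripe_grid=None,
        mu_grid=None,
        region_policy: regions.FitRegionPolicy | None = None,
        mean_eeg: bool = True,
    ):
        self.record = record
        self.win_s = win_s
        self.overlap_s = overlap_s
        self.resp_mode = resp_mode
        self.mu_branch = mu_branch
        self.stripe_grid = stripe_grid
        self.mu_grid = mu_grid
        self.region_policy = region_policy
        self.mean_eeg = mean_eeg

    def fit(self, params: pipeline.SubjectParams | None = None) -> "CSResults":
        if params is None:
            params = pipeline.estimate_subject_params(
                self.record,
                self.win_s,
                self.overlap_s,
                stripe_grid=self.stripe_grid,
                mu_grid=self.mu_grid,
                policy=self.region_policy,
                resp_mode=self.resp_mode,
            )
        deltas = pipeline.delta_series(
            self.record,
            params,
            self.win_s,
            self.overlap_s,
            resp_mode=self.resp_mode,
            mu_branch=self.mu_branch,
        )
        grouped = dict(deltas)
        if self.mean_eeg:
            eeg = [deltas[c] for c in self.record.channels if self.record.modality[c] == "EEG"]
            if len(eeg) > 1:
                grouped = {c: d for c, d in deltas.items() if self.record.modality[c] != "EEG"}
                grouped = {"EEG": pipeline.mean_delta_series(eeg), **grouped}
        matrix = pipeline.cs_matrix(grouped) if len(grouped) > 1 else None
        return CSResults(
            model=self, params=params, delta_series=deltas, grouped_series=grouped, matrix=matrix
        )


@dataclass
class CSResults:
    """Delta series per channel and the CS correlation matrix."""

    model: ComplexitySynchronization
    params: pipeline.SubjectParams
    delta_series: dict
    grouped_series: dict
    matrix: pipeline.CSMatrix | None

    def summary(self, alpha: float = 0.05) -> str:
        lines = [
            "Complexity Synchronization Analysis",
            "=" * 60,
            f"windows: {len(next(iter(self.delta_series.values())))}"
            f" ({self.model.win_s:g} s, overlap {self.model.overlap_s:g} s)",
        ]
        for mod, mp in self.params.per_modality.items():
            lines.append(
                f"  {mod}: {mp.n_stripes} stripes, fit region"
                f" [{mp.fit_start_idx}, {mp.fit_end_idx}]"
            )
        if self.matrix is not None:
            lines.append("-" * 60)
            lines.append("pairwise Pearson r (delta series, jointly valid windows):")
            lines.append(self.matrix.r.round(3).to_string())
            lines.append("p-values:")
            lines.append(self.matrix.p.map(lambda v: f"{v:.3g}").to_string())
            lines.append(f"note: p-values ignore delta-series autocorrelation; alpha={alpha}")
        lines.append("=" * 60)
        return "\n".join(lines)

    def plot_deltas(self, ax=None):
        """Delta series of every grouped channel over window start times."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, ds in self.grouped_series.items():
            t = ds.window_start_times[ds.valid]
            ax.plot(t, ds.deltas[ds.valid], marker="o", ms=3, label=name)
        ax.set_xlabel("window start (s)")
        ax.set_ylabel(r"scaling index $\delta$")
        ax.legend()
        return ax
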