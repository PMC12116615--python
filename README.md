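# mdeacs — modified diffusion entropy analysis & complexity synchronization

`mdeacs` measures the *temporal complexity* of physiological time series
(EEG, ECG, respiration, or any signal driven by intermittent "crucial"
events) and quantifies how that complexity co-varies across organ systems.
It is aimed at researchers in network physiology and nonlinear
neurophysiological time-series analysis.

## The method

Crucial events are renewal events whose waiting times τ follow an inverse
power law (IPL), ψ(τ) ∝ τ^(−μ) with 1 < μ < 3.  Modified diffusion entropy
analysis (MDEA) detects them by partitioning the amplitude-normalized signal
into equal-width **stripes**: every passage from one stripe to another is an
event.  The cumulative sum of the 0/1 event indicator is a diffusion
trajectory X(t); the Shannon–Wiener entropy of its displacement
distribution over window length w grows as

    S(w) = A + δ · ln w,

and the slope δ is the scaling (complexity) index, related to μ by
δ = μ − 1 for 1 < μ < 2 and δ = 1/(μ − 1) for 2 < μ < 3 (uncorrelated
events give δ = 1/2).

Two steps that are usually tuned by hand are automated here:

* **Stripe size and μ selection** — jointly chosen by minimizing the
  Kolmogorov–Smirnov distance D = sup_τ |F_emp(τ) − (τ/τ_min)^(1−μ)|
  between the empirical waiting-time CCDF and the Pareto CCDF over a grid of
  stripe counts and μ values (τ_min = one sampling period).
* **Linear fit region** — the straight part of S(w) vs ln w is located by
  penalized piecewise-linear change-point detection with an adaptive
  threshold sweep (heavy-tail droop and onset distortion are trimmed; for
  three-segment, ECG-like curves the middle segment is used).

**Complexity synchronization (CS)**: δ is computed in 30-s sliding windows
with 20-s overlap per channel (stripe count and fit region held fixed at
their per-subject medians), and channel pairs are correlated (Pearson) over
jointly valid windows.  A Mittag-Leffler-map simulator generates renewal
trains with known, optionally time-varying μ to validate every step.

## Worked example

```python
from mdeacs import MDEA
from mdeacs.studies import build_study_signal

sig = build_study_signal(2.5, fs=64.0, n_events=20_000, seed=3)  # known mu
res = MDEA(sig.samples, fs=64.0).fit()
print(res.summary())
```

```
Modified Diffusion Entropy Analysis
===================================================
n samples                                     60598
sampling rate (Hz)                               64
stripes                                          14
stripe size                               0.0714286
events detected                               20000
fit region (grid idx)                       [4, 34]
delta (scaling index)                        0.7308
std err                                      0.0014
95% CI                             [0.7279, 0.7337]
R^2                                          0.9999
mu from delta                                2.3683
mu from KS selection                         2.5000
KS distance D                                0.0040
===================================================
```

The KS grid search recovers the generative index exactly (μ̂ = 2.50, with
14 stripes and a KS distance of 0.004); the entropy slope δ = 0.731 sits
somewhat above the asymptotic value 1/(μ−1) = 0.667 because the scaling of
a finite renewal train converges slowly from above (see
`docs/methods.md`) — the δ→μ transform is therefore the noisier of the two
estimators, which is exactly why the KS-based selection exists.

For multichannel recordings:

```python
from mdeacs import ComplexitySynchronization, read_signals

record = read_signals("recording.edf")          # or CSV with a time column
res = ComplexitySynchronization(record, resp_mode="highpass").fit()
print(res.summary())                            # pairwise delta-series correlations
res.plot_deltas()
```

The same pipeline is scriptable from the shell (`mdea-cs simulate`,
`mdea-cs mdea`, `mdea-cs select-stripes`, `mdea-cs analyze`,
`mdea-cs validate bias-variance|tracking`).

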