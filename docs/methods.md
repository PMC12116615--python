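# Methods

## Model and assumptions

The package treats a physiological signal as a carrier of *crucial events*:
renewal events whose inter-event (waiting) times τ are i.i.d. with an
inverse-power-law density ψ(τ) ∝ τ^(−μ), 1 < μ < 3.  Complexity is the IPL
index μ, or equivalently the diffusion-entropy scaling index δ of the event
counting process (δ = μ − 1 for 1 < μ < 2, δ = 1/(μ − 1) for 2 < μ < 3,
δ = 1/2 for uncorrelated events).  Two assumptions matter in practice:
events are renewal (no long-range correlation between waiting times), and
the signal's amplitude excursions between events are large relative to the
noise so stripe crossings mark genuine events.  Strongly periodic signals
violate the renewal picture; that is why the respiration path offers
high-pass filtering, differencing, or Hilbert-envelope extraction before
event detection.

## Estimators

**Stripe events.**  The window is min-max normalized to [0, 1] and cut into
`n_stripes` equal bands; sample i is an event when its stripe index differs
from sample i−1's.  The stripe count is the resolution knob: too coarse
censors events (adjacent levels merge), too fine turns noise flicker into
events.

**KS selection of (μ, stripe count).**  For every candidate stripe count
the inter-event gaps (in seconds, τ_min = one sampling period) are compared
with the Pareto CCDF (τ/τ_min)^(1−μ) through the Kolmogorov–Smirnov
distance, and the pair minimizing D is selected by grid search
(μ ∈ 1.05…3.00 step 0.05; stripe counts 4…1280, roughly log-spaced; both
grids are parameters).  Ties break toward smaller μ, then fewer stripes.
Cells with fewer than 50 events are invalid; the search fails only if every
cell is invalid (e.g. a constant window).

Because sampled gaps are integer multiples of τ_min, the empirical CCDF has
an atom at one sampling period that any continuous CCDF misses by the
atom's full mass.  The discrete comparison therefore evaluates, at gap
k·τ_min, the Pareto CCDF *averaged over the cell* (k, k+1)·τ_min —
(b^(2−μ) − a^(2−μ))/((2−μ)(b−a)) with a = k, b = k+1, the μ = 2 case taken
as ln(b/a).  On rounded Pareto samples this cell average reproduces the law
essentially exactly (the midpoint rule still biases μ̂ by ≈ −0.1 near the
cutoff, where the CCDF's convexity matters).  For waiting times given
directly as continuous values the classical two-sided stair evaluation is
used instead.

**Entropy curve and δ.**  The diffusion trajectory is the cumulative event
count; displacements are taken over all overlapping unit-step window starts
(n − w + 1 of them), binned at integer resolution (they are counts), and
the Shannon–Wiener entropy uses natural logarithms throughout — δ is the
OLS slope of S(w) on ln w, so a single log convention is applied to both
axes.  The default window grid is ~50 geometrically spaced integers from 1
to n/10; each w must retain at least 10 displacements.

**Fit region.**  Change points of S vs ln w are found by optimal
partitioning (dynamic programming) of piecewise straight-line fits with a
per-segment penalty; a larger penalty yields fewer change points, so the
penalty plays the role of a detection threshold.  `select_fit_region`
sweeps the penalty from loose to tight (×1.25 per step, at most 40 steps,
starting from 10⁻³ of the single-line residual) until the policy produces a
region of at least `min_length` (default 5) grid points, falling back to
the longest available segment with a warning.  Policy `auto_single`: no
change point → fit from 20% of the curve (`start_fraction`, default 0.20)
to its end; one change point → *heavy-tail droop* when the post-change
slope falls below 50% of the pre-change slope **or** the change point lies
in the latter half of the curve (finite-sample droop is gradual, so the
slope ratio alone misses it), in which case the region runs from 20% to the
change point, otherwise the change is treated as onset distortion and the
region starts there; two change points → the intermediate segment (both in
the latter half is again read as droop structure).  ECG-like curves use
`middle_of_three_segments`.  Minimum segment length inside the dynamic
program is 3 points.

**Sliding-window CS.**  30-s windows, 20-s overlap (window and step are
parameters); per-subject stripe counts and fit regions are the medians of
the per-window estimates, per modality, and are then held fixed — windows
failing normalization or the event guard are flagged invalid and
pairwise-deleted, never interpolated.  EEG channels are averaged into one δ
series before correlating; Pearson r with the standard two-sided p-value is
reported per pair, without multiple-testing correction (a
Benjamini–Hochberg option exists but is off by default), and the p-values
ignore δ-series autocorrelation.

## Synthetic data

`ml_waiting_time` implements the Mittag-Leffler deviate
τ = −γ ln u · [sin(βπ)/tan(βπv) − cos(βπ)]^(1/β), computed through the
identical, manifestly positive form sin(βπ(1−v))/sin(βπv) and special-cased
at β = 1 so the exponential limit −γ ln u is exact to the last bit.  For
2 ≤ μ < 3 the map is undefined (β = μ − 1 > 1), and waiting times come from
the Pareto inverse CDF τ = γ·U^(1/(1−μ)); only the asymptotic power law
matters downstream, not the specific map.  Time-varying complexity is a
piecewise-constant μ(t) schedule; each waiting time takes the μ (and scale)
of the segment containing its start.

Surrogate signals are piecewise constant on 12 equispaced levels in [0, 1],
jumping to a uniformly drawn *different* level at every event, with
optional additive Gaussian noise.  Discretization places an event at sample
round(Στ·fs); coincident events collapse to one (counted and logged) —
mirroring what finite sampling does to real data.

Study conditions, chosen once: sampling at 32 Hz for estimator studies,
256 Hz for tracking, 512 Hz for the CS triad; waiting-time scale γ of one
sampling period for the Pareto branch (its hard cutoff must coincide with
the τ_min anchor of the KS fit) and two for the Mittag-Leffler branch
(whose cutoff-free body otherwise collapses into the first sample bin);
individual waiting times clipped at 10⁴ samples so heavy-tailed (μ < 2)
trains occupy bounded arrays (clipped tail mass ≲ 1%, shifting μ̂ by well
under the grid step); studies run noise-free.  The μ-tracking study uses
120-s windows with 80-s overlap because μ < 2 trains carry only ~1 event
per 200 samples, and a 1.6 → 2.4 step over two 900-s segments; the shared-
complexity record switches every 75 s between μ = 1.6 and μ = 2.4 (one
common trajectory across channels, independent event trains), a repeated
version of the same step motif — a two-level contrast keeps the per-window
complexity swing resolvable against the ~0.03–0.16 estimation noise of a
30-s window, which a continuum of nearby μ values would not be.

**What the generator does not emulate.**  Real signals move continuously
between events, carry band-limited (not white per-sample) noise, mix
crucial with non-crucial oscillatory events, and may age (non-renewal).
White per-sample noise on a piecewise-constant carrier flickers at the
sampling rate whenever a level sits near a stripe edge — a pathology no
physiological noise exhibits — so noise robustness of the stripe selection
should be read qualitatively only.  Passing tests demonstrate estimator
correctness under the renewal model, not performance on empirical
recordings.

## Numerical behaviour worth knowing

* The entropy slope of a finite μ ∈ (2, 3) renewal train converges slowly:
  the typical displacement width grows as w^(1/(μ−1)) but the variance as
  w^((4−μ)/2), and at 10⁵ samples the measured δ for μ = 2.5 sits around
  0.70–0.75 against the asymptotic 0.667.  The windowed δ̂(μ) map is
  correspondingly compressed — another reason the KS route to μ is
  preferred when waiting-time statistics suffice.
* Entropy estimates droop at large w (few effectively independent
  displacements); the fit-region policy exists precisely to trim this.
* The high-pass filter is a Kaiser-window FIR (60 dB design, cutoff 2 Hz,
  order 8192) applied forward and backward via FFT convolution with
  reflection padding: exactly zero phase, doubled attenuation.  Windows
  shorter than the order reduce it automatically with a logged warning
  (the transition widens accordingly) — a 30-s window at low rates cannot
  support 8192 taps.
* Degenerate inputs are contracts, not crashes: constant windows raise
  `NormalizationError` (and near-constant ones, within 10⁻⁹ relative, such
  as the derivative of a ramp or the envelope of a pure tone); a single
  waiting time fits with a logged low-confidence warning; a schedule must
  have one more μ than breakpoints.

## Limitations

Aging / non-renewal corrections, logistic and Manneville maps, multifractal
spectra beyond the single δ per window, bootstrap goodness-of-fit p-values
for the KS distance, and ICA-style artifact removal are out of scope.
Stripe sizes are reported both as counts and as range/count; no claim is
made that they match any particular external reporting scale.  Correlations
between δ series inherit all caveats of correlating smoothed, autocorrelated
estimates.
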