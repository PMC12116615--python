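"""Stripes, events, diffusion displacements, entropy curve, scaling fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdeacs import dea
from mdeacs.dea import (
    StripeConfig,
    assign_stripes,
    delta_to_mu,
    detect_events,
    diffusion_displacements,
    entropy_curve,
    fit_delta,
    mu_to_delta,
)


def brute_displacements(ind, w):
    """O(n*w) double-loop oracle: one displacement per overlapping start."""
    n = len(ind)
    return np.array([sum(ind[t : t + w]) for t in range(n - w + 1)])


class TestStripes:
    def test_bin_arithmetic(self):
        cfg = StripeConfig(10, 0.0, 1.0)
        assert assign_stripes([0.05], cfg)[0] == 0
        assert assign_stripes([0.55], cfg)[0] == 5

    def test_upper_edge_maps_to_top_stripe(self):
        cfg = StripeConfig(10, 0.0, 1.0)
        assert assign_stripes([1.0], cfg)[0] == 9

    def test_ramp_hits_every_stripe_monotonically(self):
        cfg = StripeConfig(10, 0.0, 1.0)
        idx = assign_stripes(np.linspace(0, 1, 1000), cfg)
        assert np.all(np.diff(idx) >= 0)
        assert set(idx.tolist()) == set(range(10))

    def test_values_clamped_into_range(self):
        cfg = StripeConfig(4, 0.0, 1.0)
        idx = assign_stripes([-5.0, 7.0], cfg)
        assert idx.tolist() == [0, 3]

    def test_errors(self):
        with pytest.raises(ValueError):
            assign_stripes([], StripeConfig(4))
        with pytest.raises(ValueError):
            StripeConfig(1)
        with pytest.raises(ValueError):
            StripeConfig(4, 1.0, 1.0)


class TestEvents:
    def test_constant_signal_no_events(self):
        ev = detect_events(np.zeros(100, dtype=int))
        assert ev.n_events == 0

    def test_ramp_crosses_nine_boundaries(self):
        idx = assign_stripes(np.linspace(0, 1, 1000), StripeConfig(10))
        assert detect_events(idx).n_events == 9

    def test_surrogate_events_match_truth(self, clean_surrogate):
        sig = clean_surrogate
        cfg = StripeConfig(10, float(sig.samples.min()), float(sig.samples.max()))
        ev = detect_events(assign_stripes(sig.samples, cfg))
        np.testing.assert_array_equal(ev.event_indices(), sig.true_event_indices)

    def test_too_short(self):
        with pytest.raises(ValueError):
            detect_events(np.array([1]))


class TestDisplacements:
    def test_all_ones(self):
        d = diffusion_displacements(np.ones(50, dtype=int), 5)
        assert np.all(d == 5) and d.size == 46

    def test_all_zeros(self):
        assert np.all(diffusion_displacements(np.zeros(50, dtype=int), 7) == 0)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        n=st.integers(min_value=2, max_value=200),
        w_frac=st.floats(min_value=0.01, max_value=0.99),
        p=st.floats(min_value=0.0, max_value=1.0),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_matches_brute_force_oracle(self, n, w_frac, p, seed):
        rng = np.random.default_rng(seed)
        ind = (rng.random(n) < p).astype(int)
        w = max(1, min(n - 1, int(round(w_frac * n))))
        np.testing.assert_array_equal(
            diffusion_displacements(ind, w), brute_displacements(ind, w)
        )

    def test_w_bounds(self):
        with pytest.raises(ValueError):
            diffusion_displacements(np.ones(10, dtype=int), 10)


class TestEntropyCurve:
    def test_degenerate_single_outcome_zero_entropy(self):
        curve = entropy_curve(np.ones(200, dtype=int), w_grid=[2, 5, 10])
        assert np.allclose(curve.S, 0.0)

    def test_non_negative(self, rng):
        ind = (rng.random(3000) < 0.3).astype(int)
        curve = entropy_curve(ind)
        assert np.all(curve.S >= 0.0)

    def test_bernoulli_half_slope(self, rng):
        ind = rng.integers(0, 2, 200_000)
        curve = entropy_curve(ind)
        sel = (curve.w >= 20) & (curve.w <= 2000)  # mid-range windows
        slope = np.polyfit(np.log(curve.w[sel]), curve.S[sel], 1)[0]
        assert slope == pytest.approx(0.50, abs=0.03)

    def test_min_displacement_guard(self):
        with pytest.raises(ValueError):
            entropy_curve(np.ones(20, dtype=int), w_grid=[15])


class TestScalingFit:
    def test_exact_line(self):
        w = np.arange(1, 51)
        curve = dea.EntropyCurve(w=w, S=0.3 + 0.7 * np.log(w), counts=np.full(50, 100))
        fit = fit_delta(curve, 0, 49)
        assert fit.delta == pytest.approx(0.7, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_region_too_short(self):
        w = np.arange(1, 51)
        curve = dea.EntropyCurve(w=w, S=np.log(w), counts=np.full(50, 100))
        with pytest.raises(ValueError):
            fit_delta(curve, 0, 1)

    def test_noisy_line_recovers_slope(self, rng):
        w = np.unique(np.round(np.geomspace(1, 1000, 30)).astype(int))
        S = 0.1 + 0.6 * np.log(w) + rng.normal(0, 0.01, w.size)
        curve = dea.EntropyCurve(w=w, S=S, counts=np.full(w.size, 100))
        fit = fit_delta(curve, 0, len(w) - 1)
        assert 0.55 <= fit.delta <= 0.65
        assert fit.stderr < 0.05


class TestDeltaMuMap:
    def test_known_values(self):
        assert delta_to_mu(2 / 3, "complex_2_3") == pytest.approx(2.5)
        assert delta_to_mu(0.8, "complex_1_2") == pytest.approx(1.8)

    @pytest.mark.parametrize("d", [0.4, 0.6, 0.9])
    @pytest.mark.parametrize("branch", ["complex_1_2", "complex_2_3"])
    def test_round_trip(self, d, branch):
        assert mu_to_delta(delta_to_mu(d, branch), branch) == pytest.approx(d)

    @pytest.mark.parametrize("d", [0.0, -0.2, 1.5])
    def test_invalid_delta(self, d):
        with pytest.raises(ValueError):
            delta_to_mu(d)


def test_delta_invariant_under_affine_rescaling(clean_surrogate):
    """Events (hence delta) are unchanged when the stripes follow an affine
    amplitude rescaling of the signal."""
    x = clean_surrogate.samples
    y = 5.0 * x - 2.0
    ev_x = detect_events(assign_stripes(x, StripeConfig(10, x.min(), x.max())))
    ev_y = detect_events(assign_stripes(y, StripeConfig(10, y.min(), y.max())))
    np.testing.assert_array_equal(ev_x.indicator, ev_y.indicator)
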