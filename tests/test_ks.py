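"""Kolmogorov-Smirnov power-law fitting and joint stripe/mu selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdeacs import generate_waiting_times
from mdeacs.ks import (
    DEFAULT_MU_GRID,
    empirical_ccdf,
    fit_mu_from_taus,
    grid_search_mu_stripes,
    ks_statistic,
    theoretical_power_ccdf,
)
from mdeacs.studies import build_study_signal
from mdeacs.preprocessing import normalize_minmax


def brute_ccdf(taus, T):
    """Direct-count oracle: fraction of the sample strictly above T."""
    taus = np.asarray(taus)
    return 1.0 - np.sum(taus <= T) / taus.size


class TestEmpiricalCCDF:
    def test_direct_count_example(self):
        c = empirical_ccdf(np.array([1.0, 2.0, 3.0]))
        at = dict(zip(c.support.tolist(), c.values.tolist()))
        assert at[2.0] == pytest.approx(1 / 3)
        assert at[1.0] == pytest.approx(2 / 3)
        assert at[3.0] == pytest.approx(0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            empirical_ccdf(np.array([]))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        n=st.integers(min_value=1, max_value=100),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_matches_brute_force_everywhere(self, n, seed):
        rng = np.random.default_rng(seed)
        taus = rng.exponential(1.0, n) + 1e-6
        c = empirical_ccdf(taus)
        for T, v in zip(c.support, c.values):
            assert v == pytest.approx(brute_ccdf(taus, T), abs=1e-12)

    def test_monotone_within_unit_interval(self, rng):
        c = empirical_ccdf(rng.pareto(1.5, 500) + 1.0)
        assert np.all(np.diff(c.values) <= 0)
        assert 0 <= c.values[-1] <= c.values[0] <= 1


class TestTheoreticalCCDF:
    def test_unit_at_tau_min(self):
        assert theoretical_power_ccdf(0.5, mu=2.3, tau_min=0.5) == 1.0

    def test_printed_values(self):
        assert theoretical_power_ccdf(2.0, mu=2.0, tau_min=1.0) == pytest.approx(0.5)
        assert theoretical_power_ccdf(10.0, mu=3.0, tau_min=1.0) == pytest.approx(0.01)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            theoretical_power_ccdf(0.1, mu=2.0, tau_min=0.5)
        with pytest.raises(ValueError):
            theoretical_power_ccdf(1.0, mu=1.0, tau_min=0.5)


class TestKSStatistic:
    def test_inverse_cdf_image_interleaves(self):
        # taus constructed as the inverse-CDF image of a uniform grid under
        # the mu=2 power CCDF: empirical and theoretical stairs interleave
        n = 500
        q = (np.arange(n) + 0.5) / n
        taus = 1.0 * q ** (1.0 / (1.0 - 2.0))
        D = ks_statistic(taus, mu=2.0, tau_min=1.0)
        assert D < 1.0 / n + 1e-3

    def test_bounded_in_unit_interval(self, rng):
        taus = rng.pareto(1.2, 300) + 1.0
        for mu in (1.1, 2.0, 2.9):
            assert 0.0 <= ks_statistic(taus, mu=mu, tau_min=1.0) <= 1.0

    def test_misspecified_mu_increases_distance(self, rng):
        wt = generate_waiting_times(5000, 2.5, seed=3)
        good = ks_statistic(wt, mu=2.5)
        bad = ks_statistic(wt, mu=1.3)
        assert good < bad


class TestFitMuFromTaus:
    def test_pareto_recovery(self):
        wt = generate_waiting_times(10_000, 2.5, seed=13)
        fit = fit_mu_from_taus(wt)
        assert 2.4 <= fit.mu_hat <= 2.6
        assert fit.D < 0.05

    def test_error_shrinks_with_sample_size(self):
        mu = 2.2
        errs = {n: [] for n in (100, 10_000)}
        for trial in range(20):
            for n in errs:
                wt = generate_waiting_times(n, mu, seed=1000 * trial + n)
                errs[n].append(abs(fit_mu_from_taus(wt).mu_hat - mu))
        assert np.mean(errs[10_000]) < np.mean(errs[100])

    def test_degenerate_single_tau_still_returns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="mdeacs.ks"):
            fit = fit_mu_from_taus(np.array([1.0]), tau_min=1.0)
        assert 0.0 <= fit.D <= 1.0
        assert "low-confidence" in caplog.text

    def test_refined_grid_never_increases_min(self):
        wt = generate_waiting_times(2000, 2.0, seed=8)
        coarse = DEFAULT_MU_GRID
        fine = np.round(np.arange(1.05, 3.0001, 0.01), 3)  # superset refinement
        assert fit_mu_from_taus(wt, mu_grid=fine).D <= fit_mu_from_taus(wt, mu_grid=coarse).D + 1e-12


class TestGridSearch:
    def test_recovery_on_surrogate(self):
        sig = build_study_signal(2.0, fs=32.0, n_events=10_000, seed=5)
        sol = grid_search_mu_stripes(normalize_minmax(sig.samples), sig.fs)
        assert 1.9 <= sol.mu_hat <= 2.1
        assert sol.stripe_hat.n_stripes >= 2
        assert np.nanmin(sol.grid_D) == sol.D

    def test_constant_signal_all_cells_invalid(self):
        with pytest.raises(ValueError):
            grid_search_mu_stripes(np.zeros(5000), fs=10.0)

    def test_deterministic(self):
        sig = build_study_signal(2.4, fs=32.0, n_events=3000, seed=6)
        x = normalize_minmax(sig.samples)
        a = grid_search_mu_stripes(x, sig.fs)
        b = grid_search_mu_stripes(x, sig.fs)
        assert a.mu_hat == b.mu_hat and a.D == b.D
        assert a.stripe_hat == b.stripe_hat

    def test_grid_D_shape_and_validity_mask(self):
        sig = build_study_signal(2.4, fs=32.0, n_events=3000, seed=6)
        sol = grid_search_mu_stripes(normalize_minmax(sig.samples), sig.fs)
        assert sol.grid_D.shape == (sol.mu_grid.size, sol.stripe_grid.size)
        valid = ~np.isnan(sol.grid_D)
        assert valid.any()
        assert np.all(sol.grid_D[valid] >= 0) and np.all(sol.grid_D[valid] <= 1)
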