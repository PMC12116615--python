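"""Waiting-time generation, event discretization, surrogate signals."""

import numpy as np
import pytest

from mdeacs import (
    EventSeries,
    MuSchedule,
    WaitingTimes,
    build_surrogate_signal,
    generate_time_varying,
    generate_waiting_times,
    ml_waiting_time,
    waiting_times_to_event_train,
)
from mdeacs.dea import StripeConfig, assign_stripes, detect_events


def hill_mu(taus: np.ndarray, frac: float = 0.02) -> float:
    """Maximum-likelihood (Hill) tail-index estimate on the upper tail,
    mapped to the waiting-time PDF exponent mu = alpha + 1.  The 2% tail
    fraction is deep enough that the pre-asymptotic body of the
    Mittag-Leffler law does not bias the estimate as beta approaches 1."""
    t = np.sort(np.asarray(taus))
    k = max(10, int(frac * t.size))
    top = t[-k:]
    return 1.0 + 1.0 / float(np.mean(np.log(top / top[0])))


class TestMLWaitingTime:
    def test_exponential_limit_exact_on_grid(self):
        u = np.linspace(0.01, 0.99, 10)
        v = np.linspace(0.05, 0.95, 10)
        uu, vv = np.meshgrid(u, v)
        tau = ml_waiting_time(uu.ravel(), vv.ravel(), beta=1.0, gamma=2.0)
        assert np.max(np.abs(tau - (-2.0 * np.log(uu.ravel())))) == 0.0

    def test_hand_evaluated_value(self):
        # bracket collapses to 1 at u=v=1/2, beta=1/2
        assert ml_waiting_time(0.5, 0.5, beta=0.5, gamma=1.0) == pytest.approx(
            np.log(2.0), rel=1e-12
        )

    def test_u_near_one_gives_vanishing_tau(self):
        assert ml_waiting_time(1 - 1e-12, 0.3, beta=0.7) == pytest.approx(0.0, abs=1e-11)

    @pytest.mark.parametrize("bad", [(0.0, 0.5), (1.0, 0.5), (0.5, 0.0), (0.5, 1.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            ml_waiting_time(bad[0], bad[1], beta=0.5)

    def test_beta_out_of_range(self):
        with pytest.raises(ValueError):
            ml_waiting_time(0.5, 0.5, beta=1.5)

    def test_always_positive_and_finite(self, rng):
        u = rng.uniform(1e-6, 1 - 1e-6, 2000)
        v = rng.uniform(1e-6, 1 - 1e-6, 2000)
        for beta in (0.1, 0.5, 0.9, 0.99):
            tau = ml_waiting_time(u, v, beta=beta)
            assert np.all(np.isfinite(tau)) and np.all(tau > 0)

    def test_unit_mean_at_beta_one(self):
        wt = generate_waiting_times(100_000, 1.999999999, gamma=1.0, seed=5)
        se = wt.taus.std() / np.sqrt(len(wt))
        assert abs(wt.taus.mean() - 1.0) < 3 * se


class TestGenerateWaitingTimes:
    @pytest.mark.parametrize("mu", [1.3, 1.5, 1.8])
    def test_tail_exponent_recovery_ml_branch(self, mu):
        wt = generate_waiting_times(100_000, mu, seed=11)
        assert hill_mu(wt.taus) == pytest.approx(mu, abs=0.1)

    @pytest.mark.parametrize("mu", [2.2, 2.5])
    def test_tail_exponent_recovery_pareto_branch(self, mu):
        wt = generate_waiting_times(100_000, mu, seed=11)
        assert hill_mu(wt.taus) == pytest.approx(mu, abs=0.15)
        assert wt.taus.min() >= wt.tau_min

    def test_deterministic_under_fixed_seed(self):
        a = generate_waiting_times(10_000, 2.0, seed=3)
        b = generate_waiting_times(10_000, 2.0, seed=3)
        np.testing.assert_array_equal(a.taus, b.taus)

    def test_single_draw(self):
        wt = generate_waiting_times(1, 1.5, seed=0)
        assert len(wt) == 1 and wt.taus[0] > 0

    @pytest.mark.parametrize("mu", [0.9, 1.0, 3.0, 3.5])
    def test_mu_out_of_range(self, mu):
        with pytest.raises(ValueError):
            generate_waiting_times(10, mu)


class TestTimeVarying:
    def test_two_segment_tail_indices_differ(self):
        sched = MuSchedule(breakpoints=np.array([2000.0]), mu_values=np.array([1.6, 2.4]))
        wt = generate_time_varying(sched, duration=4000.0, gamma=0.05, seed=21)
        starts = np.concatenate(([0.0], np.cumsum(wt.taus[:-1])))
        first = wt.taus[starts < 2000.0]
        second = wt.taus[starts >= 2000.0]
        assert abs(hill_mu(second) - hill_mu(first)) > 0.5

    def test_duration_shorter_than_first_tau(self):
        sched = MuSchedule(breakpoints=np.array([]), mu_values=np.array([2.5]))
        wt = generate_time_varying(sched, duration=1e-9, gamma=1.0, seed=0)
        assert len(wt) == 1

    def test_covers_duration(self):
        sched = MuSchedule(breakpoints=np.array([50.0]), mu_values=np.array([1.7, 2.3]))
        wt = generate_time_varying(sched, duration=100.0, gamma=0.1, seed=4)
        assert np.sum(wt.taus) >= 100.0

    def test_tau_max_clips_draws(self):
        sched = MuSchedule(breakpoints=np.array([]), mu_values=np.array([1.5]))
        wt = generate_time_varying(sched, duration=500.0, gamma=1.0, seed=9, tau_max=5.0)
        assert wt.taus.max() <= 5.0

    def test_invalid_schedule(self):
        with pytest.raises(ValueError):
            MuSchedule(breakpoints=np.array([1.0]), mu_values=np.array([2.0]))
        with pytest.raises(ValueError):
            MuSchedule(breakpoints=np.array([]), mu_values=np.array([]))
        with pytest.raises(ValueError):
            MuSchedule(breakpoints=np.array([]), mu_values=np.array([3.5]))


class TestEventTrain:
    def test_direct_placement(self):
        wt = WaitingTimes(np.array([1.0]), tau_min=0.1)
        ev = waiting_times_to_event_train(wt, fs=10.0, duration=2.0)
        assert ev.n_samples == 20
        assert ev.event_indices().tolist() == [10]

    def test_pigeonhole_with_subresolution_taus(self, rng):
        taus = rng.uniform(0.001, 0.009, 500)  # all below one sampling period
        wt = WaitingTimes(taus, tau_min=0.001)
        ev = waiting_times_to_event_train(wt, fs=100.0, duration=1.0)
        assert ev.n_events <= ev.n_samples
        assert np.isin(ev.indicator, (0, 1)).all()

    def test_event_conservation_with_collisions(self):
        wt = generate_waiting_times(5000, 2.5, gamma=1.0, seed=2)
        duration = float(np.sum(wt.taus)) + 1.0
        ev = waiting_times_to_event_train(wt, fs=1.0, duration=duration)
        retained = np.sum(np.round(np.cumsum(wt.taus)) < ev.n_samples)
        assert ev.n_events == retained - ev.n_collisions

    def test_events_past_duration_dropped(self):
        wt = WaitingTimes(np.array([1.0, 1.0, 50.0]), tau_min=0.1)
        ev = waiting_times_to_event_train(wt, fs=1.0, duration=10.0)
        assert ev.n_events == 2

    def test_error_on_empty_grid(self):
        wt = WaitingTimes(np.array([1.0]), tau_min=0.1)
        with pytest.raises(ValueError):
            waiting_times_to_event_train(wt, fs=0.1, duration=1.0)


class TestSurrogateSignal:
    def test_no_noise_stripe_detection_recovers_events(self, clean_surrogate):
        sig = clean_surrogate
        cfg = StripeConfig(10, float(sig.samples.min()), float(sig.samples.max()))
        ev = detect_events(assign_stripes(sig.samples, cfg), fs=sig.fs)
        detected = set(ev.event_indices().tolist())
        hits = sum(
            1
            for t in sig.true_event_indices
            if t in detected or t - 1 in detected or t + 1 in detected
        )
        assert hits / sig.true_event_indices.size >= 0.95

    def test_zero_events_gives_constant_signal(self):
        wt = WaitingTimes(np.array([100.0]), tau_min=1.0)
        sig = build_surrogate_signal(wt, fs=1.0, duration=50.0, n_levels=5, seed=0)
        assert np.ptp(sig.samples) == 0.0

    def test_deterministic_under_fixed_seed(self):
        wt = generate_waiting_times(100, 2.5, seed=1)
        a = build_surrogate_signal(wt, fs=2.0, duration=200.0, noise_sd=0.1, seed=5)
        b = build_surrogate_signal(wt, fs=2.0, duration=200.0, noise_sd=0.1, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_bounded_levels_without_noise(self, clean_surrogate):
        assert clean_surrogate.samples.min() >= 0.0
        assert clean_surrogate.samples.max() <= 1.0

    def test_negative_noise_rejected(self):
        wt = generate_waiting_times(10, 2.5, seed=1)
        with pytest.raises(ValueError):
            build_surrogate_signal(wt, fs=1.0, duration=10.0, noise_sd=-0.1)


def test_event_series_validates_indicator():
    with pytest.raises(ValueError):
        EventSeries(indicator=np.array([0, 2, 1]), fs=1.0)
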