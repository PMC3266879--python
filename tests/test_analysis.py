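"""Estimators: STA, dip fit, density evolution, balance and segregation."""

import numpy as np
import pytest

from eibstdp.analysis import (
    STACurve,
    asymptotic_weight,
    balance_regression,
    count_modes,
    fit_gamma,
    segregation_index,
    spike_triggered_average,
    weight_density_evolution,
)
from eibstdp.meanfield import GammaKernel


def _brute_force_sta(pre, post, duration, window=100.0, bin_width=1.0):
    """Direct double loop over all (pre, post) pairs."""
    triggers = post[(post >= window) & (post <= duration - window)]
    nb = int(round(2 * window / bin_width))
    edges = np.linspace(-window, window, nb + 1)
    counts = np.zeros(nb)
    for t in triggers:
        for s in pre:
            d = s - t
            if -window <= d < window:
                counts[int((d + window) // bin_width)] += 1
    return counts / (triggers.size * bin_width / 1000.0)


class TestSpikeTriggeredAverage:
    def test_matches_brute_force_double_loop(self, poisson_fixture_trains):
        pre, post = poisson_fixture_trains
        sta = spike_triggered_average(pre, post, duration=10e3)
        brute = _brute_force_sta(pre, post, 10e3)
        assert np.allclose(sta.conditional_rate, brute)

    def test_independent_trains_are_flat(self):
        rng = np.random.default_rng(8)
        dur = 2000e3
        pre = np.sort(rng.uniform(0, dur, rng.poisson(10 * dur / 1000)))
        post = np.sort(rng.uniform(0, dur, rng.poisson(20 * dur / 1000)))
        sta = spike_triggered_average(pre, post, duration=dur)
        # per-bin Poisson standard error of the conditional-rate estimate
        se = 1000.0 * np.sqrt(sta.pre_rate / 1000.0 * sta.n_post_spikes) / (
            sta.n_post_spikes * 1e-3 * 1000.0
        )
        assert np.all(np.abs(sta.conditional_rate - sta.pre_rate) < 4 * se)
        assert abs(sta.conditional_rate.mean() - sta.pre_rate) < 0.5

    def test_no_post_spikes_rejected(self):
        with pytest.raises(ValueError):
            spike_triggered_average(np.array([1.0]), np.array([]), 1000.0)

    def test_lags_symmetric(self, poisson_fixture_trains):
        pre, post = poisson_fixture_trains
        sta = spike_triggered_average(pre, post, duration=10e3)
        assert np.allclose(sta.lags, -sta.lags[::-1])


class TestFitGamma:
    def _synthetic_sta(self, w, amp, tau, latency, noise_sd, seed=0,
                       r_pre=10.0, nu=10.0):
        rng = np.random.default_rng(seed)
        lags = np.arange(-99.5, 100.0, 1.0)
        s = -lags
        dip = np.where(s >= latency,
                       w * amp * np.exp(-(s - latency) / tau) * r_pre / nu, 0.0)
        dip[lags > 0] = 0.0
        rate = r_pre - dip + rng.normal(0, noise_sd, lags.size)
        return STACurve(lags=lags, conditional_rate=np.maximum(rate, 0),
                        n_post_spikes=10_000, pre_rate=r_pre, post_rate=nu)

    def test_parameter_recovery_within_5_percent(self):
        sta = self._synthetic_sta(w=0.4, amp=15.0, tau=8.0, latency=0.0,
                                  noise_sd=0.05, seed=3)
        g = fit_gamma(sta, w=0.4)
        assert g.amplitude == pytest.approx(15.0, rel=0.05)
        assert g.decay_tau == pytest.approx(8.0, rel=0.05)
        assert g.latency == pytest.approx(0.0, abs=1.0)

    def test_latency_recovered_at_bin_resolution(self):
        sta = self._synthetic_sta(w=0.4, amp=15.0, tau=8.0, latency=3.0,
                                  noise_sd=0.05, seed=4)
        g = fit_gamma(sta, w=0.4)
        assert g.latency == pytest.approx(3.0, abs=1.0)
        assert g.amplitude == pytest.approx(15.0, rel=0.15)

    def test_amplitude_scales_per_unit_weight(self):
        fits = [
            fit_gamma(self._synthetic_sta(w, 15.0, 8.0, 1.0, 0.02, seed=int(w * 10)), w=w)
            for w in (0.2, 0.4)
        ]
        assert fits[0].amplitude == pytest.approx(fits[1].amplitude, rel=0.1)

    def test_flat_curve_rejected(self):
        sta = self._synthetic_sta(w=0.4, amp=0.0, tau=8.0, latency=0.0,
                                  noise_sd=0.0)
        with pytest.raises(ValueError, match="dip"):
            fit_gamma(sta, w=0.4)

    def test_nonpositive_weight_rejected(self):
        sta = self._synthetic_sta(w=0.4, amp=15.0, tau=8.0, latency=0.0,
                                  noise_sd=0.0)
        with pytest.raises(ValueError):
            fit_gamma(sta, w=0.0)


class TestDensityEvolution:
    def test_constant_runs_give_delta_density(self):
        trajs = np.full((50, 3), 0.505)
        d = weight_density_evolution(trajs, np.arange(3))
        assert d.density[:, 50] == pytest.approx(100.0)
        assert np.all(np.delete(d.density, 50, axis=1) == 0.0)

    def test_uniform_initial_conditions_flat_first_slice(self):
        trajs = np.linspace(0.005, 0.995, 200)[:, None] * np.ones((1, 2))
        d = weight_density_evolution(trajs, np.arange(2))
        assert d.density[0].min() > 0
        assert d.density[0] == pytest.approx(np.ones(100), rel=0.5)

    def test_each_slice_integrates_to_one(self):
        rng = np.random.default_rng(12)
        trajs = rng.beta(2, 5, size=(300, 4))
        d = weight_density_evolution(trajs, np.arange(4))
        widths = np.diff(d.bin_edges)
        assert np.allclose((d.density * widths).sum(axis=1), 1.0, atol=1e-6)

    def test_mode_counting(self):
        edges = np.linspace(0, 1, 101)
        rng = np.random.default_rng(2)
        uni = np.histogram(rng.normal(0.5, 0.05, 5000).clip(0, 1), bins=edges,
                           density=True)[0]
        assert count_modes(uni, edges) == 1
        bi = np.histogram(
            np.concatenate([rng.normal(0.2, 0.04, 3000),
                            rng.normal(0.8, 0.04, 3000)]).clip(0, 1),
            bins=edges, density=True,
        )[0]
        assert count_modes(bi, edges) == 2

    def test_mismatched_grid_rejected(self):
        with pytest.raises(ValueError):
            weight_density_evolution(np.zeros((5, 3)), np.arange(4))


class TestAsymptoticWeight:
    def test_constant_trajectory(self):
        m, sd = asymptotic_weight(np.full(100, 0.42))
        assert m == 0.42 and sd == 0.0

    def test_window_is_trailing_quarter(self):
        traj = np.concatenate([np.zeros(75), np.ones(25)])
        m, sd = asymptotic_weight(traj, trailing_fraction=0.25)
        assert m == 1.0 and sd == 0.0

    def test_overlong_window_rejected(self):
        with pytest.raises(ValueError):
            asymptotic_weight(np.ones(2), trailing_fraction=0.1)

    def test_replicate_consistency(self):
        """Independent noise realizations around one mean agree within 3 SD."""
        rng = np.random.default_rng(9)
        a = 0.5 + rng.normal(0, 0.02, 400)
        b = 0.5 + rng.normal(0, 0.02, 400)
        ma, sa = asymptotic_weight(a)
        mb, sb = asymptotic_weight(b)
        assert abs(ma - mb) < 3 * max(sa, sb)


class TestBalanceRegression:
    def test_collinear_points_unit_r_squared(self):
        x = np.linspace(0, 1, 8)
        pts = np.column_stack([x, 0.2 + 0.7 * x])
        s = balance_regression(pts, fit_range=(0.0, 1.0))
        assert s.r_squared == pytest.approx(1.0)
        assert s.slope == pytest.approx(0.7)
        assert s.drive_axis_intercept == pytest.approx(-0.2 / 0.7)

    def test_fit_uses_only_in_range_weights(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 10.0])
        y = np.array([0.1, 0.5, 0.6, 0.7, 0.2])  # outlier outside range
        s = balance_regression(np.column_stack([x, y]), fit_range=(0.4, 0.8))
        assert s.n_in_range == 3
        assert s.slope > 0

    def test_too_few_points_rejected(self):
        pts = np.array([[0.0, 0.6], [1.0, 0.7]])
        with pytest.raises(ValueError, match=">= 3"):
            balance_regression(pts)


class TestSegregationIndex:
    def test_identical_groups_zero(self):
        w = np.full(10, 0.3)
        labels = np.repeat([0, 1], 5)
        assert segregation_index(w, labels) == (0.0, 0.0)

    def test_split_groups(self):
        w = np.concatenate([np.full(5, 0.9), np.full(5, 0.1)])
        labels = np.repeat(["a", "b"], 5)
        idx, sd = segregation_index(w, labels)
        assert idx == pytest.approx(0.8)

    def test_window_dispersion(self):
        w = np.vstack([np.full((5, 4), 0.8), np.full((5, 4), 0.2)])
        w[:5, 2] = 0.9
        idx, sd = segregation_index(w, np.repeat([0, 1], 5))
        assert idx == pytest.approx((0.6 * 3 + 0.7) / 4)
        assert sd > 0

    def test_wrong_group_count_rejected(self):
        with pytest.raises(ValueError):
            segregation_index(np.ones(6), np.repeat([0, 1, 2], 2))


def test_inhibitory_plasticity_does_not_reduce_segregation():
    """Paired over seeds, subgroup segregation with a plastic inhibitory
    population is at least as large as without inhibition (one-sided; the
    effect is expected to be present but not dramatic)."""
    from eibstdp.runner import fig10_protocol

    wins = 0
    n_seeds = 10
    for s in range(n_seeds):
        kw = dict(seed=300 + s, within_correlations=(0.1,), mu_values=(0.05,))
        with_i = fig10_protocol(with_inhibition=True, **kw)["rows"][0]["index"]
        without = fig10_protocol(with_inhibition=False, **kw)["rows"][0]["index"]
        wins += with_i >= without
    assert wins >= n_seeds // 2 + 1
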