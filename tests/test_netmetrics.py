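"""Network statistics, discrete MLE fits, AIC selection, and series analyses."""

import numpy as np
import pytest
from scipy import optimize

from elnet.netmetrics import (
    ccdf_r2,
    clustering_coefficient,
    compare_groups,
    degree_distributions,
    edge_weight_variance,
    fit_exponential_discrete,
    fit_power_law,
    hamming_weight_profile,
    loglik_discrete_exponential,
    loglik_discrete_power_law,
    mean_degree,
    recurrence_times,
    sample_discrete_exponential,
    sample_discrete_power_law,
    summarize,
    trajectory,
    window_series,
)
from elnet.transition_network import TransitionNetwork, build_network, sliding_windows


def toy_net(edges, n=3, window=(0, 1)):
    src = np.array([e[0] for e in edges])
    dst = np.array([e[1] for e in edges])
    w = np.array([e[2] for e in edges])
    return TransitionNetwork(src, dst, w, n, window)


class TestTopologyStats:
    def test_triangle_has_full_clustering(self):
        net = toy_net([(0, 1, 1), (1, 2, 1), (2, 0, 1)])
        assert clustering_coefficient(net) == 1.0
        assert clustering_coefficient(net, "transitivity") == 1.0

    def test_star_has_zero_clustering(self):
        net = toy_net([(0, 1, 1), (0, 2, 1), (0, 3, 1)])
        assert clustering_coefficient(net) == 0.0

    def test_mean_degree_complete_graph(self):
        edges = [(i, j, 1) for i in range(4) for j in range(4) if i != j]
        assert mean_degree(toy_net(edges)) == 3.0

    def test_reciprocal_pair_collapses(self):
        net = toy_net([(0, 1, 2), (1, 0, 5)])
        assert mean_degree(net) == 1.0
        assert mean_degree(net, "directed") == 1.0

    def test_self_loops_ignored_by_topology(self):
        net = toy_net([(0, 0, 10), (0, 1, 1), (1, 1, 3)])
        assert mean_degree(net) == 1.0
        in_deg, out_deg = degree_distributions(net)
        assert in_deg.tolist() == [0, 1] and out_deg.tolist() == [1, 0]

    def test_degree_handshake(self, small_log):
        net = build_network(small_log, 0, 40)
        in_deg, out_deg = degree_distributions(net)
        assert in_deg.sum() == out_deg.sum()

    def test_single_edge_degrees(self):
        in_deg, out_deg = degree_distributions(toy_net([(0, 1, 1)]))
        assert in_deg.tolist() == [0, 1] and out_deg.tolist() == [1, 0]


class TestWeightStats:
    def test_equal_weights_zero_variance(self):
        net = toy_net([(0, 1, 5), (1, 2, 5), (2, 2, 5)])
        assert edge_weight_variance(net) == 0.0

    def test_two_edge_variance(self):
        net = toy_net([(0, 1, 1), (1, 2, 3)])
        assert edge_weight_variance(net) == pytest.approx(0.0625)

    def test_rescaling_invariance(self, small_log):
        net = build_network(small_log, 0, 30)
        scaled = TransitionNetwork(net.src, net.dst, net.weight * 7, net.n,
                                   net.window)
        assert edge_weight_variance(scaled) == pytest.approx(
            edge_weight_variance(net))

    def test_hamming_profile_concentrated_self_loop(self):
        net = toy_net([(0b101, 0b101, 9)])
        prof = hamming_weight_profile(net, 0b101)
        assert prof[0] == 1.0 and prof.sum() == pytest.approx(1.0)

    def test_hamming_profile_sums_to_one(self, small_log):
        net = build_network(small_log, 0, 40)
        prof = hamming_weight_profile(net, 0b1010)
        assert prof.sum() == pytest.approx(1.0)
        assert prof.size == small_log.n + 1

    def test_summarize_schema(self, el_log):
        net = build_network(el_log, 200, 400)
        s = summarize(net, el_log.target)
        assert 0 <= s.C_global <= 1
        assert s.hamming_profile.sum() == pytest.approx(1.0)
        assert s.local_C_hist.sum() == pytest.approx(1.0)
        assert s.max_k_in >= 1 and s.max_k_out >= 1

    def test_empty_network_rejected(self):
        empty = TransitionNetwork(np.array([], dtype=int),
                                  np.array([], dtype=int),
                                  np.array([], dtype=int), 3, (0, 0))
        for fn in (mean_degree, clustering_coefficient, edge_weight_variance):
            with pytest.raises(ValueError):
                fn(empty)


class TestDiscreteFits:
    @pytest.mark.parametrize("lam", [0.1, 0.226, 0.5])
    def test_exponential_recovery(self, rng, lam):
        samples = sample_discrete_exponential(lam, 10_000, rng)
        fit = fit_exponential_discrete(samples)
        assert abs(fit.param - lam) < 3 * fit.se

    @pytest.mark.parametrize("alpha", [1.4, 1.55, 2.5])
    def test_power_law_recovery(self, rng, alpha):
        samples = sample_discrete_power_law(alpha, 10_000, rng)
        fit = fit_power_law(samples)
        assert abs(fit.param - alpha) < 3 * fit.se

    def test_closed_form_matches_numeric_mle(self, rng):
        samples = sample_discrete_exponential(0.35, 2000, rng)
        fit = fit_exponential_discrete(samples)
        res = optimize.minimize_scalar(
            lambda l: -loglik_discrete_exponential(l, samples, 1),
            bounds=(1e-9, 20.0), method="bounded", options={"xatol": 1e-10})
        assert fit.param == pytest.approx(float(res.x), abs=1e-6)

    def test_power_law_mle_maximizes_likelihood(self, rng):
        samples = sample_discrete_power_law(1.8, 3000, rng)
        fit = fit_power_law(samples)
        ll = loglik_discrete_power_law(fit.param, samples, 1)
        for eps in (-0.01, 0.01):
            assert ll >= loglik_discrete_power_law(fit.param + eps, samples, 1)

    def test_aic_selects_power_law(self, rng):
        samples = sample_discrete_power_law(1.5, 10_000, rng)
        fit = fit_power_law(samples)
        assert fit.aic_weights["power-law"] > 0.99

    def test_aic_selects_exponential(self, rng):
        samples = sample_discrete_exponential(0.3, 10_000, rng)
        fit = fit_exponential_discrete(samples)
        assert fit.aic_weights["exponential"] > 0.99

    def test_aic_family_selection_rate(self):
        """AIC picks the generating family in >= 95% of synthetic datasets."""
        correct = total = 0
        rng = np.random.default_rng(31)
        for rep in range(15):
            s = sample_discrete_power_law(1.6, 10_000, rng)
            correct += fit_power_law(s).aic_weights["power-law"] > 0.5
            s = sample_discrete_exponential(0.25, 10_000, rng)
            correct += fit_exponential_discrete(s).aic_weights["exponential"] > 0.5
            total += 2
        assert correct / total >= 0.95

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_discrete(np.ones(50, dtype=int))
        with pytest.raises(ValueError):
            fit_power_law(np.full(50, 3))
        with pytest.raises(ValueError):
            fit_power_law(np.arange(1, 6))  # too few samples

    def test_aic_weights_sum_to_one(self, rng):
        fit = fit_power_law(sample_discrete_power_law(2.0, 500, rng))
        assert sum(fit.aic_weights.values()) == pytest.approx(1.0)

    def test_sampler_matches_zeta_pmf(self, rng):
        # chi-square of draws against the exact zeta pmf (values 1..29 + tail)
        from scipy import special, stats

        alpha = 2.0
        size = 20_000
        s = sample_discrete_power_law(alpha, size, rng)
        ks = np.arange(1, 30)
        pmf = ks ** -alpha / special.zeta(alpha, 1)
        obs = np.r_[np.bincount(s[s < 30], minlength=30)[1:30],
                    (s >= 30).sum()]
        expected = size * np.r_[pmf, 1 - pmf.sum()]
        assert stats.chisquare(obs, expected).pvalue > 0.01


class TestSeriesAnalyses:
    def test_alternating_series_recurrence(self):
        series = np.tile([1.0, 3.0], 10)
        rec = recurrence_times(series)
        assert rec.mean_level == pytest.approx(2.0)
        assert (rec.times == 1).all() and rec.times.size == 18

    def test_constant_series_at_level(self):
        rec = recurrence_times(np.full(10, 2.0), mean_level=2.0)
        assert (rec.times == 1).all()

    def test_constant_series_off_level_has_no_events(self):
        rec = recurrence_times(np.full(10, 2.0), mean_level=5.0)
        assert rec.times.size == 0

    def test_trajectory_circle_orientation(self):
        th = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        traj = trajectory(np.cos(th), np.sin(th))  # counter-clockwise
        assert traj.signed_area == pytest.approx(np.pi, rel=1e-2)
        assert traj.closure_distance < 0.1 * traj.path_length

    def test_trajectory_degenerate_diagonal(self):
        s = np.linspace(0, 1, 50)
        traj = trajectory(s, s)
        assert traj.signed_area == pytest.approx(0.0, abs=1e-12)

    def test_trajectory_length_mismatch(self):
        with pytest.raises(ValueError):
            trajectory(np.arange(3), np.arange(4))

    def test_compare_groups(self, rng):
        a = rng.normal(size=200)
        t, p = compare_groups(a, a, "t")
        assert abs(t) < 1e-9 and p > 0.99
        x = np.arange(10.0)
        r, _ = compare_groups(x, -x, "pearson")
        assert r == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0], "t")

    def test_window_series_matches_direct_builds(self, small_log):
        df = window_series(small_log, 10, stride=5, start=0)
        for _, row in df.iterrows():
            net = build_network(small_log, int(row.window_start),
                               int(row.window_start) + 10)
            assert row.MD == pytest.approx(mean_degree(net))
            assert row.var_w == pytest.approx(edge_weight_variance(net))


class TestCcdfR2:
    def test_perfect_power_law_curve(self):
        # counts chosen so the empirical CCDF is exactly k^-1.5 at each value
        N, K = 200_000, 30
        ccdf = np.arange(1, K + 1) ** -1.5
        counts = np.round(N * np.r_[ccdf[:-1] - ccdf[1:], ccdf[-1]]).astype(int)
        w = np.repeat(np.arange(1, K + 1), counts)
        assert ccdf_r2(w) >= 0.99

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            ccdf_r2(np.array([1, 1, 2]))


class TestMuSweep:
    def test_sweep_rows_and_columns(self):
        from elnet.netmetrics import mu_sweep
        from elnet.simulate import SimulationConfig

        base = SimulationConfig(n=4, steps=60, burn_in=20, seed=0)
        df = mu_sweep(base, [0.05, 0.5], trials=2, window_len=40, seed=1)
        assert list(df.mu) == [0.05, 0.5]
        assert {"MD_mean", "MD_sd", "var_w_mean", "C_mean", "R2_mean"} <= set(df)
        # heavier erosion spreads transitions over more edges
        assert df.MD_mean.iloc[1] > df.MD_mean.iloc[0]

    def test_window_series_with_clustering(self, small_log):
        from elnet.netmetrics import clustering_coefficient, window_series
        from elnet.transition_network import build_network

        df = window_series(small_log, 20, stride=20, start=0, clustering=True)
        net = build_network(small_log, 0, 20)
        assert df.C.iloc[0] == pytest.approx(clustering_coefficient(net))
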