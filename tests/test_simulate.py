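import math

import numpy as np
import pytest
from scipy.stats import kstest

import gatedscanner as g
from conftest import make_single_pause_params


def gamma2_median_oracle(scale: float) -> float:
    """Median of gamma(shape=2) by bisection on its CDF
    F(x) = 1 - (1 + x/s) exp(-x/s), independent of any library quantile."""
    lo, hi = 0.0, 50.0 * scale
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        cdf = 1.0 - (1.0 + mid / scale) * math.exp(-mid / scale)
        if cdf < 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestPauseDurations:
    def test_shape_one_is_exponential_with_mean_scale(self, wt):
        params = wt.with_(pause_shape=1, pause_scale=0.8)
        rng = np.random.default_rng(0)
        draws = np.array([g.draw_pause_duration(params, rng) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(0.8, rel=0.02)
        assert (draws > 0).all()

    def test_shape_two_median_matches_bisection_oracle(self, wt):
        scale = 0.74
        params = wt.with_(pause_shape=2, pause_scale=scale)
        rng = np.random.default_rng(1)
        draws = np.array([g.draw_pause_duration(params, rng) for _ in range(100_000)])
        oracle = gamma2_median_oracle(scale)
        assert oracle == pytest.approx(scale * 1.6783, rel=1e-3)
        assert np.median(draws) == pytest.approx(oracle, rel=0.02)


class TestSimulatePath:
    def test_no_chi_no_switching_gives_single_linear_segment(self, wt):
        params = wt.with_(p_pause=0.0, k_iso=0.0, k_detach=0.0)
        sub = g.SubstrateSpec(length_bp=5000.0)
        path = g.simulate_path(params, sub, 42)
        assert len(path.times) == 2
        assert path.events["pauses"] == []
        assert path.duration == pytest.approx(5000.0 / params.v_pre)

    def test_chi_free_substrate_never_pauses_for_any_variant(self, wt):
        sub = g.SubstrateSpec(length_bp=4000.0)
        for seed in range(30):
            path = g.simulate_path(wt.with_(k_iso=0.0, k_detach=0.0), sub, seed)
            assert path.events["pauses"] == []
            # single linear segment at v_pre
            assert len(path.times) == 2

    def test_committed_pause_arrival_time_is_deterministic_sum(self, wt):
        d = 2.5
        params = make_single_pause_params(wt, d)
        sub = g.SubstrateSpec(length_bp=7700.0, chi_positions=(4588.0,))
        path = g.simulate_path(params, sub, 3)
        expected = 4588.0 / params.v_pre + d + (7700.0 - 4588.0) / params.v_post
        assert path.duration == pytest.approx(expected, rel=1e-3)
        assert path.events["switch"]["cause"] == "chi"

    def test_spontaneous_switch_fraction_matches_closed_form(self, wt):
        # fraction switching before distance L is 1 - exp(-k_iso L / v_pre)
        k_iso, L = 0.05, 4000.0
        params = wt.with_(k_iso=k_iso, p_pause=0.0, k_detach=0.0)
        sub = g.SubstrateSpec(length_bp=L)
        rng = np.random.default_rng(9)
        n = 10_000
        switched = sum(
            g.simulate_path(params, sub, rng).events["switch"] is not None
            for _ in range(n)
        )
        expect = 1.0 - math.exp(-k_iso * L / params.v_pre)
        tol = 3 * math.sqrt(expect * (1 - expect) / n)
        assert switched / n == pytest.approx(expect, abs=tol)

    def test_locus_pause_probability_matches_closed_form(self, wt, chi10):
        # P(>=1 pause over 10 Chi) = 1 - (1 - p)^10 with no detachment
        params = wt.with_(k_detach=0.0, k_iso=0.0)
        rng = np.random.default_rng(17)
        n = 10_000
        paused = sum(
            bool(g.simulate_path(params, chi10, rng).events["pauses"])
            for _ in range(n)
        )
        expect = 1.0 - (1.0 - params.p_pause) ** 10
        tol = 3 * math.sqrt(expect * (1 - expect) / n)
        assert paused / n == pytest.approx(expect, abs=tol)

    def test_identical_seeds_identical_paths(self, wt, chi10):
        p1 = g.simulate_path(wt, chi10, 123)
        p2 = g.simulate_path(wt, chi10, 123)
        assert np.array_equal(p1.times, p2.times)
        assert np.array_equal(p1.positions, p2.positions)
        assert p1.events == p2.events


class TestRenderTrace:
    def test_noiseless_trace_equals_sampled_path(self, wt, chi10):
        path = g.simulate_path(wt, chi10, 5)
        cfg = g.TraceConfig(noise_sd_bp=0.0)
        tr = g.render_trace(path, cfg)
        assert len(tr) == math.ceil(path.duration * cfg.sample_rate_hz)
        assert np.allclose(tr.position_bp, path.position_at(tr.time_s))

    def test_noise_residual_sd_matches_configuration(self, wt):
        params = wt.with_(p_pause=0.0, k_detach=0.0)
        sub = g.SubstrateSpec(length_bp=60_000.0)  # > 10^4 samples at 60 Hz
        path = g.simulate_path(params, sub, 0)
        cfg = g.TraceConfig(noise_sd_bp=30.0, seed=2)
        tr = g.render_trace(path, cfg)
        resid = tr.position_bp - path.position_at(tr.time_s)
        assert len(tr) >= 10_000
        assert abs(resid.mean()) < 1.0
        assert resid.std() == pytest.approx(30.0, abs=1.0)

    def test_fixed_seed_is_bit_identical(self, wt, chi10):
        path = g.simulate_path(wt, chi10, 5)
        cfg = g.TraceConfig(seed=11)
        t1, t2 = g.render_trace(path, cfg), g.render_trace(path, cfg)
        assert np.array_equal(t1.position_bp, t2.position_bp)

    def test_empty_path_rejected(self):
        with pytest.raises(ValueError):
            g.render_trace(
                g.Path(np.array([0.0]), np.array([0.0]), {}), g.TraceConfig()
            )


class TestSimulateChase:
    def test_half_life_three_minutes_gives_half_survival(self, wt):
        # expectation exp(-k t): half the signal remains after one half-life
        series = g.simulate_chase(wt, [0.0, 3.0], 200_000, rng_seed=0)
        assert wt.t_half_chi_min == pytest.approx(3.0)
        assert series.fragment_fraction[0] == 1.0
        assert series.fragment_fraction[1] == pytest.approx(0.5, abs=0.005)

    def test_zero_off_rate_never_decays(self, wt):
        params = wt.with_(k_off_chi=0.0)
        series = g.simulate_chase(params, [0.0, 10.0, 100.0], 100, rng_seed=1)
        assert np.all(series.fragment_fraction == 1.0)

    def test_survival_at_half_life_within_binomial_interval(self, wt):
        n = 500
        series = g.simulate_chase(wt, [0.0, 3.0], n, rng_seed=3)
        tol = 3 * math.sqrt(0.25 / n)
        assert series.fragment_fraction[1] == pytest.approx(0.5, abs=tol)

    def test_dissociation_times_are_exponential(self, wt):
        series = g.simulate_chase(wt, [0.0, 1.0], 1000, rng_seed=4)
        res = kstest(series.dissociation_times_min, "expon",
                     args=(0, 1 / wt.k_off_chi))
        assert res.pvalue > 0.01

    def test_bad_inputs_rejected(self, wt):
        with pytest.raises(ValueError):
            g.simulate_chase(wt, [0.0, 1.0], 0)
        with pytest.raises(ValueError):
            g.simulate_chase(wt, [1.0, 0.5], 10)


class TestSimulateTriplex:
    def test_single_phase_half_time_on_chi_free_dna(self, wt):
        params = wt.with_(p_pause=0.0, k_iso=0.0, k_detach=0.0)
        sub = g.SubstrateSpec(length_bp=4000.0, triplex_pos=3000.0)
        rate = 10.0
        curve = g.simulate_triplex_curve(params, sub, 4000, rate, rng_seed=6)
        t_half = float(np.interp(0.5, curve.signal, curve.time_s))
        expected = 3000.0 / params.v_pre + math.log(2) / rate
        assert t_half == pytest.approx(expected, rel=0.05)

    def test_certain_commitment_removes_the_early_phase(self, wt):
        params = make_single_pause_params(wt, 1.0)
        sub = g.SubstrateSpec(
            length_bp=4000.0, chi_positions=(1000.0,), triplex_pos=3000.0
        )
        curve = g.simulate_triplex_curve(params, sub, 1000, 10.0, rng_seed=7)
        # everyone is delayed: no signal before the committed arrival time
        fast_arrival = 3000.0 / params.v_pre
        assert np.interp(fast_arrival + 0.1, curve.time_s, curve.signal) < 0.01

    def test_early_fraction_matches_per_chi_commitment_closed_form(self, wt):
        c = 0.25
        params = wt.with_(p_pause=1.0, p_commit=c, k_iso=0.0, k_detach=0.0,
                          pause_scale=0.05)
        sub = g.triplex_substrate(n_chi=3)
        n = 4000
        curve = g.simulate_triplex_curve(params, sub, n, 10.0, rng_seed=8)
        expect = (1 - c) ** 3
        frac_fast = 1 - curve.n_committed / curve.n_reported
        tol = 3 * math.sqrt(expect * (1 - expect) / n)
        assert frac_fast == pytest.approx(expect, abs=tol)

    def test_noiseless_curve_is_endpoint_normalized(self, wt):
        sub = g.triplex_substrate(n_chi=3)
        curve = g.simulate_triplex_curve(wt, sub, 500, 10.0, rng_seed=9)
        assert curve.signal[-1] == pytest.approx(1.0)
        assert np.all(np.diff(curve.signal) >= 0)

    def test_missing_triplex_rejected(self, wt):
        with pytest.raises(ValueError):
            g.simulate_triplex_curve(
                wt, g.SubstrateSpec(length_bp=1000.0), 10, 5.0
            )


class TestChiYield:
    def test_no_pausing_no_yield(self, wt, single_chi):
        assert g.simulate_chi_yield(wt.with_(p_pause=0.0), single_chi, 200) == 0.0

    def test_certain_recognition_full_yield(self, wt, single_chi):
        params = wt.with_(p_pause=1.0, p_commit=1.0, k_detach=0.0, k_iso=0.0)
        assert g.simulate_chi_yield(params, single_chi, 200, rng_seed=1) == 1.0

    def test_doubling_commitment_doubles_yield(self, wt, single_chi):
        base = wt.with_(p_pause=0.1, p_commit=0.5, k_detach=0.0, k_iso=0.0)
        double = base.with_(p_commit=1.0)
        n = 20_000
        y1 = g.simulate_chi_yield(base, single_chi, n, rng_seed=2)
        y2 = g.simulate_chi_yield(double, single_chi, n, rng_seed=3)
        assert y2 / y1 == pytest.approx(2.0, rel=0.15)
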