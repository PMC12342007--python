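import numpy as np
import pytest

from neurogrn.analysis import (
    DeviationSample,
    SurfaceGrid,
    crossing_times,
    daily_deviations,
    ensemble_deviations,
    io_surface,
    summarize,
)
from neurogrn.dynamics import SimConfig, Trajectory
from neurogrn.environment import eval_target
from neurogrn.exceptions import SummaryError
from neurogrn.fixtures import make_shifted_tracking_trajectory, rules_to_function
from neurogrn.objective import ObjectiveConfig
from neurogrn.regulatory_net import init_params
from neurogrn.training import Checkpoint


class TestCrossingTimes:
    def test_constructed_sine_crossing_recovered(self):
        t = np.linspace(0, 1, 2001)
        series = 1000.0 + 500.0 * np.sin(2 * np.pi * t)  # up-crosses 1000 at t = 0 and 1
        got = crossing_times(t, series, 1250.0, "up")
        # sin = 0.5 rising at t = 1/12
        assert got.size == 1
        assert got[0] == pytest.approx(1.0 / 12.0, abs=1e-3)

    def test_monotone_decreasing_has_no_up_crossings(self):
        t = np.linspace(0, 1, 100)
        assert crossing_times(t, 100.0 - t * 50, 80.0, "up").size == 0

    def test_constant_series_at_threshold_has_none(self):
        t = np.linspace(0, 1, 100)
        assert crossing_times(t, np.full(100, 50.0), 50.0, "up").size == 0

    def test_perfect_tracker_crosses_at_daily_dawn(self):
        traj = make_shifted_tracking_trajectory(0.0, 3)
        got = crossing_times(traj.times, traj.y[:, 0], 1.0e3, "up")
        assert np.allclose(got, [0.5, 1.5, 2.5], atol=2e-3)


class TestDailyDeviations:
    @pytest.mark.parametrize("shift", [-6.0, -2.4, 0.0, 2.4, 6.0])
    def test_shift_recovered_each_day(self, shift):
        traj = make_shifted_tracking_trajectory(shift, 10)
        samples = daily_deviations(traj)
        assert len(samples) == 10
        grid_step_hours = 1e-3 * 24
        for s in samples:
            assert not s.censored
            assert abs(s.deviation - shift) <= grid_step_hours

    def test_sign_convention_negative_means_early(self):
        early = daily_deviations(make_shifted_tracking_trajectory(-6.0, 2))
        assert all(s.deviation < 0 for s in early)

    def test_pinned_below_threshold_fully_censored(self):
        traj = make_shifted_tracking_trajectory(0.0, 3)
        traj.y[:, 0] = 10.0
        samples = daily_deviations(traj)
        assert len(samples) == 3 and all(s.censored for s in samples)


class TestEnsemble:
    def test_sample_count_is_reps_times_days(self, ring3_net, ring3_kin):
        ckpt = Checkpoint(net=ring3_net, kin=ring3_kin, stage=0, loss_estimate=0.0)
        samples = ensemble_deviations(
            ckpt, d=3, n_reps=7, seed=0, sim_cfg=SimConfig(dt=0.01, noise_on=True)
        )
        assert len(samples) == 21
        assert {s.realization_id for s in samples} == set(range(7))

    def test_same_seed_identical(self, ring3_net, ring3_kin):
        ckpt = Checkpoint(net=ring3_net, kin=ring3_kin, stage=0, loss_estimate=0.0)
        kw = dict(d=2, n_reps=4, seed=5, sim_cfg=SimConfig(dt=0.01, noise_on=True))
        assert ensemble_deviations(ckpt, **kw) == ensemble_deviations(ckpt, **kw)


class TestSummarize:
    def test_constant_samples_collapse_all_percentiles(self):
        samples = [DeviationSample(0, d, 1.5) for d in range(1, 11)]
        s = summarize(samples)
        assert s.p5 == s.p25 == s.p50 == s.p75 == s.p95 == 1.5

    def test_median_of_symmetric_samples(self):
        samples = [DeviationSample(0, 1, v) for v in (-1.0, 0.0, 1.0)]
        assert summarize(samples).p50 == 0.0

    def test_uniform_order_statistics(self):
        rng = np.random.default_rng(1)
        samples = [
            DeviationSample(0, 1, float(v)) for v in rng.uniform(0, 1, 100_000)
        ]
        s = summarize(samples)
        assert s.p5 == pytest.approx(0.05, abs=0.01)
        assert s.p95 == pytest.approx(0.95, abs=0.01)
        assert s.p5 <= s.p25 <= s.p50 <= s.p75 <= s.p95

    def test_censored_counted_not_summarized(self):
        samples = [DeviationSample(0, 1, 2.0), DeviationSample(0, 2, None, True)]
        s = summarize(samples)
        assert s.n_samples == 2 and s.n_censored == 1

    def test_all_censored_raises(self):
        with pytest.raises(SummaryError):
            summarize([DeviationSample(0, 1, None, True)])


class TestIoSurface:
    def test_zero_weight_network_flat_at_half(self):
        net = init_params(4, seed=0, scale=0.0)
        stack = io_surface(net, 1, SurfaceGrid(n_grid=5, n_levels=2))
        assert stack.shape == (2, 2, 5, 5)
        assert np.allclose(stack, 0.5)

    def test_shape_contract(self, ring4_net):
        grid = SurfaceGrid(n_grid=20, n_levels=3)
        stack = io_surface(ring4_net, 2, grid)
        assert stack.shape == (3, 3, 20, 20)
        assert np.all((stack > 0) & (stack < 1))

    def test_repression_monotone_along_repressor_axis(self, ring4_net):
        # ring: gene 4 is repressed by gene 3, the row-level axis
        grid = SurfaceGrid(n_grid=8, n_levels=4)
        stack = io_surface(ring4_net, 4, grid)
        panel_means = stack.mean(axis=(2, 3))  # (row_levels, col_levels)
        assert np.all(np.diff(panel_means, axis=0) < 0.05)
        assert panel_means[0].mean() > panel_means[-1].mean()
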