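import numpy as np
import pytest

from neurogrn.dynamics import (
    KineticParams,
    SimConfig,
    SystemState,
    Trajectory,
    drift,
    noise_amplitude,
    simulate,
)
from neurogrn.environment import LightSchedule
from neurogrn.exceptions import ConfigError
from neurogrn.fixtures import rules_to_function


def dark(horizon):
    return LightSchedule(np.array([]), initial_on=False, horizon=horizon)


def const_f(n, c):
    return lambda y: np.full(y.shape[:-1] + (n,), c)


def linear_closed_form(m, d, s, g, c, x0, y0, t):
    """Exact solution of x' = mc - dx, y' = sx - gy for scalar rates."""
    xs = m * c / d
    x = xs + (x0 - xs) * np.exp(-d * t)
    ys = s * xs / g
    if abs(g - d) > 1e-12:
        A = s * (x0 - xs) / (g - d)
        y = ys + A * np.exp(-d * t) + (y0 - ys - A) * np.exp(-g * t)
    else:
        y = ys + (s * (x0 - xs) * t + (y0 - ys)) * np.exp(-g * t)
    return x, y


class TestNoiseAmplitude:
    def test_branches_meet_at_threshold(self):
        assert noise_amplitude(16.0) == 4.0
        assert np.sqrt(16.0) == 16.0 / 4.0 == 4.0

    @pytest.mark.parametrize("z, expected", [(0.0, 0.0), (4.0, 1.0), (100.0, 10.0)])
    def test_known_values(self, z, expected):
        assert noise_amplitude(z) == expected

    def test_monotone_up_to_1e6(self):
        z = np.concatenate([np.linspace(0, 32, 1000), np.logspace(0, 6, 1000)])
        g = noise_amplitude(np.sort(z))
        assert np.all(np.diff(g) >= 0)

    def test_negative_abundance_rejected(self):
        with pytest.raises(ConfigError):
            noise_amplitude(-1.0)


class TestDrift:
    def test_fixed_point_of_constant_f(self):
        n, c = 3, 0.7
        kin = KineticParams.uniform(n, m=100.0, delta=2.0, s=3.0, gamma=1.5)
        x = kin.m * c / kin.delta
        y = kin.s * x / kin.gamma
        dv = drift(SystemState(x, y), kin, const_f(n, c), u=0.0)
        assert np.allclose(dv, 0.0, atol=1e-10)

    def test_zero_state_zero_f_is_stationary(self):
        n = 2
        kin = KineticParams.uniform(n)
        dv = drift(SystemState.constant(n, 0.0), kin, const_f(n, 0.0), u=0.0)
        assert np.allclose(dv, 0.0)

    def test_light_boost_hits_only_the_coupled_protein(self):
        n = 4
        kin = KineticParams.uniform(n)
        state = SystemState.constant(n, 50.0)
        f = const_f(n, 0.3)
        base = drift(state, kin, f, u=0.0)
        boosted = drift(state, kin, f, u=123.0)
        diff = boosted - base
        expected = np.zeros(2 * n)
        expected[n + 1] = 123.0  # protein of gene 2
        assert np.allclose(diff, expected)


class TestSimulate:
    def test_deterministic_matches_linear_closed_form(self):
        # gentle rates keep the Euler error under 1e-4 across the path
        n, c = 2, 0.4
        m, d, s, g = 800.0, 1.0, 1.0, 0.5
        kin = KineticParams.uniform(n, m=m, delta=d, s=s, gamma=g)
        init = SystemState(np.full(n, 200.0), np.full(n, 400.0))
        traj = simulate(init, kin, const_f(n, c), dark(4.0),
                        SimConfig(noise_on=False), 4.0)
        xe, ye = linear_closed_form(m, d, s, g, c, 200.0, 400.0, traj.times)
        assert np.max(np.abs(traj.x[:, 0] - xe) / np.abs(xe)) < 1e-4
        assert np.max(np.abs(traj.y[:, 0] - ye) / np.abs(ye)) < 1e-4

    def test_zero_noise_scale_equals_deterministic(self):
        n = 3
        kin = KineticParams.uniform(n)
        f = const_f(n, 0.5)
        init = SystemState.constant(n, 20.0)
        noisy0 = simulate(init, kin, f, dark(1.0),
                          SimConfig(noise_on=True, noise_scale=0.0, seed=4), 1.0)
        det = simulate(init, kin, f, dark(1.0), SimConfig(noise_on=False), 1.0)
        assert np.array_equal(noisy0.y, det.y)

    def test_same_seed_bitwise_identical(self, ring3_net, ring3_kin, ring3_init):
        cfg = SimConfig(noise_on=True, seed=42)
        a = simulate(ring3_init, ring3_kin, ring3_net, dark(1.0), cfg, 1.0)
        b = simulate(ring3_init, ring3_kin, ring3_net, dark(1.0), cfg, 1.0)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    def test_nonnegativity_under_noise(self):
        n = 3
        kin = KineticParams.uniform(n, m=50.0, delta=8.0, s=2.0, gamma=8.0)
        f = const_f(n, 0.1)  # low counts stress the floor
        for seed in range(20):
            traj = simulate(SystemState.constant(n, 5.0), kin, f, dark(2.0),
                            SimConfig(noise_on=True, seed=seed), 2.0)
            assert traj.x.min() >= 0.0 and traj.y.min() >= 0.0

    def test_ensemble_mean_tracks_deterministic_trajectory(self):
        # Monte-Carlo mean at t = 1 within 3 standard errors of the ODE
        from neurogrn.dynamics import _simulate_batch

        n = 2
        kin = KineticParams.uniform(n, m=2000.0, delta=4.0, s=2.0, gamma=2.0)
        f = const_f(n, 0.5)
        init = SystemState.constant(n, 100.0)
        det = simulate(init, kin, f, dark(1.0), SimConfig(noise_on=False), 1.0)
        rng = np.random.default_rng(0)
        _, states, _ = _simulate_batch(
            init.as_vector(), kin, f, dark(1.0),
            SimConfig(noise_on=True, seed=0), 1.0, batch=500, rng=rng,
        )
        end = states[-1]  # (500, 2n)
        mean = end.mean(axis=0)
        sem = end.std(axis=0, ddof=1) / np.sqrt(end.shape[0])
        det_end = np.concatenate([det.x[-1], det.y[-1]])
        assert np.all(np.abs(mean - det_end) < 3.0 * sem + 1e-9)

    def test_halving_dt_shrinks_deterministic_error(self, ring3_net, ring3_kin, ring3_init):
        errs = []
        ref = simulate(ring3_init, ring3_kin, ring3_net, dark(0.5),
                       SimConfig(dt=6.25e-5, noise_on=False), 0.5)
        for dt in (1e-3, 5e-4, 2.5e-4):
            traj = simulate(ring3_init, ring3_kin, ring3_net, dark(0.5),
                            SimConfig(dt=dt, noise_on=False), 0.5)
            errs.append(np.abs(traj.y[-1] - ref.y[-1]).max())
        # first-order scheme: error roughly halves with dt
        assert errs[1] < 0.7 * errs[0]
        assert errs[2] < 0.7 * errs[1]

    def test_dt_not_smaller_than_horizon_rejected(self):
        kin = KineticParams.uniform(2)
        with pytest.raises(ConfigError):
            simulate(SystemState.constant(2), kin, const_f(2, 0.5), dark(1.0),
                     SimConfig(dt=2.0), 1.0)

    def test_csv_round_trip(self, tmp_path, ring3_net, ring3_kin, ring3_init):
        traj = simulate(ring3_init, ring3_kin, ring3_net, dark(0.1),
                        SimConfig(noise_on=True, seed=1), 0.1)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = Trajectory.from_csv(path)
        assert np.allclose(back.y, traj.y, rtol=1e-15)
        assert np.array_equal(back.light_on, traj.light_on)
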