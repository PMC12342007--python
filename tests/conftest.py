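import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neurogrn.fixtures import (
    fit_net_to_rules,
    make_repressilator,
    repressilator_init,
    repressilator_kinetics,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ring3_rules():
    return make_repressilator(3)


@pytest.fixture(scope="session")
def ring3_net(ring3_rules):
    """3-gene cyclic-repression rules distilled into network form (slow: fit once)."""
    return fit_net_to_rules(ring3_rules, 3, seed=0, tol=0.05)


@pytest.fixture(scope="session")
def ring3_kin():
    return repressilator_kinetics(3)


@pytest.fixture(scope="session")
def ring3_init():
    return repressilator_init(3)


@pytest.fixture(scope="session")
def ring4_rules():
    return make_repressilator(4)


@pytest.fixture(scope="session")
def ring4_net(ring4_rules):
    return fit_net_to_rules(ring4_rules, 4, seed=0, tol=0.05)


def collect_waits(cfg, n_waits, horizon=200.0, seed0=0):
    """Gather i.i.d. waiting times by concatenating schedule realizations.

    Only waits that START in the first half of the window are kept: they
    complete before the horizon with overwhelming probability, so the
    sample avoids the length-biased truncation of each realization's
    censored final interval.
    """
    from neurogrn.environment import sample_light_schedule

    waits = []
    total = 0
    seed = seed0
    while total < n_waits:
        sched = sample_light_schedule(cfg, horizon, seed=seed)
        if sched.switch_times.size:
            st = sched.switch_times
            w = np.diff(np.concatenate([[0.0], st]))
            keep = w[(st - w) < horizon / 2.0]
            waits.append(keep)
            total += keep.size
        seed += 1
    return np.concatenate(waits)[:n_waits]
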