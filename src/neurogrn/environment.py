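"""Circadian target rhythm and the stochastic external light signal.

The cell's design goal is to track a deterministic 24-hour rhythm

    v(t) = (sin(2*pi*t + pi) + 1) / 2,   t in days,

which moves between 0 (deep night) and 1 (midday) and crosses 0.5 at every
integer and half-integer day — the day/night transitions.  Dawn (the upward
crossing) falls on half-integer days.

The external light signal is an on/off telegraph process: starting from a
configurable initial state it flips at random times, with waiting times
drawn i.i.d. from an exponential distribution with mean ``mean_wait`` days.
While the signal is on, light intensity follows the target rhythm raised to
a sharpness exponent and scaled to a large molecular production rate,
``u(t) = amplitude * v(t)**p``; while off it contributes nothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ConfigError, CoverageError

__all__ = [
    "CircadianTarget",
    "LightConfig",
    "LightSchedule",
    "eval_target",
    "light_input",
    "sample_light_schedule",
]


@dataclass(frozen=True)
class CircadianTarget:
    """The deterministic daily rhythm the readout TF must track.

    The period is fixed at one day; ``phase`` shifts the whole pattern
    (days, default 0 — midday at t = 0.75).
    """

    period: float = 1.0
    phase: float = 0.0

    def value(self, t):
        return eval_target(np.asarray(t, dtype=float) - self.phase)

    def dawn_times(self, d: int) -> np.ndarray:
        """Upward 0.5-crossings (entries into daytime) for days 1..d."""
        return self.phase + 0.5 + np.arange(d, dtype=float)


def eval_target(t):
    """Evaluate the circadian target v(t) = (sin(2*pi*t + pi) + 1) / 2.

    Total and periodic with period one day; v = 0.5 exactly at every
    integer and half-integer day.  Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    v = 0.5 * (np.sin(2.0 * np.pi * t + np.pi) + 1.0)
    return v if v.ndim else float(v)


@dataclass(frozen=True)
class LightConfig:
    """Parameters of the external light process.

    mean_wait
        Mean of the exponential waiting time between on/off switches (days).
    initial_on
        Signal state at t = 0.  The entrainment scenario starts dark.
    amplitude
        Peak boost to the light-coupled TF's production rate when the
        signal is on (molecules/day).
    sharpness_exponent
        Exponent applied to v(t); larger values concentrate the input
        into a sharp midday pulse.
    """

    mean_wait: float = 2.0
    initial_on: bool = False
    amplitude: float = 1.0e6
    sharpness_exponent: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if not self.mean_wait > 0:
            raise ConfigError(f"mean_wait must be positive, got {self.mean_wait}")
        if self.amplitude < 0:
            raise ConfigError(f"amplitude must be nonnegative, got {self.amplitude}")


@dataclass(frozen=True)
class LightSchedule:
    """One realization of the on/off switching process on [0, horizon].

    The state is piecewise constant and right-continuous: evaluation at an
    exact switch time returns the post-switch state.
    """

    switch_times: np.ndarray
    initial_on: bool
    horizon: float

    def __post_init__(self):
        st = np.asarray(self.switch_times, dtype=float)
        object.__setattr__(self, "switch_times", st)
        if st.size and (np.any(np.diff(st) <= 0) or st[0] < 0 or st[-1] > self.horizon):
            raise ConfigError("switch_times must be strictly increasing within [0, horizon]")

    def is_on(self, t):
        """Signal state at time(s) t; raises CoverageError outside [0, horizon]."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t > self.horizon):
            raise CoverageError(
                f"time outside schedule horizon [0, {self.horizon}] requested"
            )
        n_before = np.searchsorted(self.switch_times, t, side="right")
        on = np.logical_xor(self.initial_on, n_before % 2 == 1)
        return on if on.ndim else bool(on)

    # -- serialization ----------------------------------------------------
    def to_csv(self, path):
        """Write switch times as CSV; initial_on/horizon ride in a comment line."""
        path = Path(path)
        meta = json.dumps({"initial_on": self.initial_on, "horizon": self.horizon})
        with path.open("w") as fh:
            fh.write(f"# {meta}\n")
            fh.write("switch_time_days,new_state\n")
            state = self.initial_on
            for t in self.switch_times:
                state = not state
                fh.write(f"{float(t)!r},{int(state)}\n")

    @classmethod
    def from_csv(cls, path) -> "LightSchedule":
        path = Path(path)
        with path.open() as fh:
            first = fh.readline()
            if not first.startswith("#"):
                raise ConfigError("schedule CSV missing metadata comment line")
            meta = json.loads(first[1:].strip())
            header = fh.readline().strip()
            if header != "switch_time_days,new_state":
                raise ConfigError(f"unexpected schedule CSV header: {header!r}")
            times = [float(line.split(",")[0]) for line in fh if line.strip()]
        return cls(np.asarray(times), bool(meta["initial_on"]), float(meta["horizon"]))


def sample_light_schedule(
    cfg: LightConfig, horizon: float, seed: int | None = None
) -> LightSchedule:
    """Draw one realization of the switching process.

    All waiting times, including the one before the first switch, are
    i.i.d. exponential with mean ``cfg.mean_wait``: the process starts at
    t = 0 with a fresh clock.  Deterministic given the seed.
    """
    if horizon < 0:
        raise ConfigError(f"horizon must be nonnegative, got {horizon}")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    times = []
    t = 0.0
    while True:
        t += rng.exponential(cfg.mean_wait)
        if t > horizon:
            break
        times.append(t)
    return LightSchedule(np.asarray(times), cfg.initial_on, horizon)


def light_input(t, schedule: LightSchedule, cfg: LightConfig):
    """Light-driven production boost u(t), in molecules/day.

    Zero while the signal is off; ``amplitude * v(t)**p`` while on.
    Vectorized over t.
    """
    t = np.asarray(t, dtype=float)
    on = schedule.is_on(t)
    u = np.where(on, cfg.amplitude * eval_target(t) ** cfg.sharpness_exponent, 0.0)
    return u if u.ndim else float(u)
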