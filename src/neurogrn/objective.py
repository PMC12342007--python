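"""Hill-normalized circadian tracking loss and the curriculum schedule.

Protein counts and the target rhythm live on incompatible scales, so both
pass through order-2 Hill transforms before comparison:

    y~ = y^2 / (S^2 + y^2),      S = 10^3 molecules (state-switch threshold)
    v~ = v^2 / (c + v^2),        c = 0.25 so the half-point sits at v = 0.5

The loss is the sum of squared gaps between the transformed readout
protein and the transformed target, evaluated on a fixed grid starting at
t = 0 with increment 0.02 days (50 points per day).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import Trajectory
from .environment import CircadianTarget
from .exceptions import ConfigError, CoverageError

__all__ = [
    "ObjectiveConfig",
    "CurriculumSchedule",
    "hill_state",
    "target_transform",
    "loss_grid",
    "tracking_loss",
]


@dataclass(frozen=True)
class ObjectiveConfig:
    """Loss settings.

    S : abundance (molecules) at which the cell's internal state flips
    between night and day; the Hill transform of the readout equals 0.5
    there.  sample_dt : loss-grid increment in days.  target_half : the
    additive constant c in the target transform.  readout_gene : 1-based
    index of the tracked TF.
    """

    S: float = 1.0e3
    sample_dt: float = 0.02
    target_half: float = 0.25
    readout_gene: int = 1

    def __post_init__(self):
        if not self.S > 0:
            raise ConfigError("state-switch threshold S must be positive")
        if not 0 < self.sample_dt < 1:
            raise ConfigError("sample_dt must lie in (0, 1) days")
        if not self.target_half > 0:
            raise ConfigError("target_half must be positive")
        if self.readout_gene < 1:
            raise ConfigError("readout_gene is a 1-based gene index")


@dataclass(frozen=True)
class CurriculumSchedule:
    """Growing-horizon training schedule.

    Optimization first fits part of the first day, then lengthens the
    fitted time range stage by stage; the default ends at 4 days.
    """

    horizons: tuple = (0.5, 1.0, 2.0, 3.0, 4.0)
    steps_per_stage: int = 100

    def __post_init__(self):
        h = tuple(float(v) for v in self.horizons)
        object.__setattr__(self, "horizons", h)
        if not h:
            raise ConfigError("curriculum must contain at least one horizon")
        if any(v <= 0 for v in h) or any(b <= a for a, b in zip(h, h[1:])):
            raise ConfigError("curriculum horizons must be positive and strictly increasing")
        if self.steps_per_stage < 1:
            raise ConfigError("steps_per_stage must be >= 1")

    @property
    def final_horizon(self) -> float:
        return self.horizons[-1]


def hill_state(y, S: float = 1.0e3):
    """Internal-state transform y~ = y^2 / (S^2 + y^2) in [0, 1).

    Monotone in y, 0 at zero abundance, exactly 0.5 at the state-switch
    threshold S.
    """
    y = np.asarray(y, dtype=float)
    out = y * y / (S * S + y * y)
    return out if out.ndim else float(out)


def hill_state_grad(y, S: float = 1.0e3):
    """d(y~)/dy, used by the adjoint pass of the trainer."""
    y = np.asarray(y, dtype=float)
    denom = S * S + y * y
    return 2.0 * y * S * S / (denom * denom)


def target_transform(v, half: float = 0.25):
    """Target transform v~ = v^2 / (c + v^2) with c = 0.25 by default,
    placing the half-point at v = 0.5 to mirror the state transform."""
    v = np.asarray(v, dtype=float)
    out = v * v / (half + v * v)
    return out if out.ndim else float(out)


def loss_grid(horizon: float, sample_dt: float = 0.02) -> np.ndarray:
    """Loss sampling times 0, dt, 2 dt, ... on the half-open [0, horizon)."""
    if not sample_dt > 0:
        raise ConfigError("sample_dt must be positive")
    if not horizon > 0:
        raise ConfigError("horizon must be positive")
    npts = int(np.ceil(horizon / sample_dt - 1e-9))
    return np.arange(npts) * sample_dt


def _grid_indices(times: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Map loss-grid times onto trajectory save points, requiring exact
    (to rounding) alignment — the integrator's save grid must contain the
    loss grid so no interpolation error enters the loss."""
    if times.shape[0] < 2:
        raise CoverageError("trajectory has fewer than two save points")
    dt = times[1] - times[0]
    idx = np.rint((grid - times[0]) / dt).astype(int)
    if np.any(idx < 0) or np.any(idx >= times.shape[0]):
        raise CoverageError("loss grid extends beyond the trajectory time range")
    if np.max(np.abs(times[idx] - grid)) > 1e-9 + 1e-6 * dt:
        raise CoverageError(
            "loss-grid times do not coincide with trajectory save points; "
            "choose sample_dt as an integer multiple of the integration dt"
        )
    return idx


def tracking_loss(
    traj: Trajectory,
    target: CircadianTarget | None = None,
    cfg: ObjectiveConfig | None = None,
    horizon: float | None = None,
) -> float:
    """Sum of squared Hill-gap deviations over the loss grid.

    The grid spans [0, horizon) with ``horizon`` defaulting to the
    trajectory's end time.  Zero iff the transformed readout matches the
    transformed target at every grid point.
    """
    target = target or CircadianTarget()
    cfg = cfg or ObjectiveConfig()
    end = horizon if horizon is not None else float(traj.times[-1]) + 1e-12
    grid = loss_grid(end, cfg.sample_dt)
    idx = _grid_indices(traj.times, grid)
    y = traj.y[idx, cfg.readout_gene - 1]
    gap = hill_state(y, cfg.S) - target_transform(target.value(grid), cfg.target_half)
    return float(np.sum(gap * gap))
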