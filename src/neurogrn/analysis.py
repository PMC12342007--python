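"""Post-hoc analytics: tracking deviations and input-output surfaces.

The headline statistic is the daily signed crossing-time deviation: each
day the external target enters daytime when its rhythm crosses 0.5
upward (dawn, at half-integer days); the cell enters its internal
daytime state when the readout TF abundance crosses the state-switch
threshold S upward.  The deviation is (cell crossing - dawn) converted
to hours — negative when the cell runs early.  Days on which the cell
produces no upward crossing within +/- 12 h of dawn are censored.

Ensembles of stochastic realizations yield 5/25/50/75/95 percentile
summaries of the deviation distribution, and the learned regulatory
logic is exposed as input-output surfaces: grids of f_gene over two TF
abundances at fixed levels of the remaining TFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dynamics import (
    KineticParams,
    SimConfig,
    SystemState,
    Trajectory,
    _simulate_batch,
)
from .environment import CircadianTarget, LightConfig, eval_target, sample_light_schedule
from .exceptions import ConfigError, CoverageError, SummaryError
from .objective import ObjectiveConfig
from .regulatory_net import NetParams, net_forward
from .training import Checkpoint

__all__ = [
    "DeviationSample",
    "PercentileSummary",
    "SurfaceGrid",
    "crossing_times",
    "daily_deviations",
    "ensemble_deviations",
    "summarize",
    "io_surface",
]

WINDOW_HOURS = 12.0  # pairing window around each dawn


@dataclass(frozen=True)
class DeviationSample:
    """Signed crossing-time deviation of one realization on one day.

    ``deviation`` is in hours and None when censored (no internal dawn
    crossing within the +/- 12 h window).
    """

    realization_id: int
    day: int
    deviation: float | None
    censored: bool = False

    def __post_init__(self):
        if self.censored and self.deviation is not None:
            raise ConfigError("censored samples carry no deviation value")
        if not self.censored and abs(self.deviation) > WINDOW_HOURS + 1e-9:
            raise ConfigError("uncensored deviation outside the +/-12 h window")


@dataclass(frozen=True)
class PercentileSummary:
    p5: float
    p25: float
    p50: float
    p75: float
    p95: float
    n_samples: int
    n_censored: int

    def __post_init__(self):
        q = (self.p5, self.p25, self.p50, self.p75, self.p95)
        if any(b < a - 1e-12 for a, b in zip(q, q[1:])):
            raise ConfigError("percentiles must be nondecreasing")

    def to_dict(self) -> dict:
        return {
            "p5": self.p5, "p25": self.p25, "p50": self.p50,
            "p75": self.p75, "p95": self.p95,
            "n_samples": self.n_samples, "n_censored": self.n_censored,
        }


def crossing_times(
    times: np.ndarray,
    values: np.ndarray,
    threshold: float,
    direction: str = "up",
) -> np.ndarray:
    """Linearly interpolated threshold crossings of a sampled series.

    A strict-crossing convention is used: an up-crossing needs
    ``values[i] < threshold <= values[i+1]``, so a series sitting exactly
    on the threshold produces none.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise ConfigError("times and values must be aligned")
    if direction == "up":
        lo, hi = values[:-1], values[1:]
        mask = (lo < threshold) & (hi >= threshold)
    elif direction == "down":
        lo, hi = values[:-1], values[1:]
        mask = (lo > threshold) & (hi <= threshold)
    else:
        raise ConfigError(f"direction must be 'up' or 'down', got {direction!r}")
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return np.empty(0)
    frac = (threshold - values[idx]) / (values[idx + 1] - values[idx])
    return times[idx] + frac * (times[idx + 1] - times[idx])


def _deviations_from_series(
    times: np.ndarray,
    readout: np.ndarray,
    S: float,
    dawns: np.ndarray,
    realization_id: int,
) -> list[DeviationSample]:
    cross = crossing_times(times, readout, S, "up")
    out = []
    half_window = WINDOW_HOURS / 24.0
    for day, dawn in enumerate(dawns, start=1):
        if cross.size:
            gaps = cross - dawn
            j = int(np.argmin(np.abs(gaps)))
            gap = gaps[j]
        else:
            gap = np.inf
        if abs(gap) <= half_window:
            out.append(DeviationSample(realization_id, day, float(gap * 24.0)))
        else:
            out.append(DeviationSample(realization_id, day, None, censored=True))
    return out


def daily_deviations(
    traj: Trajectory,
    target: CircadianTarget | None = None,
    obj_cfg: ObjectiveConfig | None = None,
    realization_id: int = 0,
) -> list[DeviationSample]:
    """Per-day deviations of one trajectory; exactly d samples for a
    trajectory spanning d whole days (censored days included)."""
    target = target or CircadianTarget()
    obj_cfg = obj_cfg or ObjectiveConfig()
    span = float(traj.times[-1] - traj.times[0])
    d = int(round(span))
    if d < 1 or abs(span - d) > 1e-6:
        raise CoverageError(
            f"trajectory must span a whole number of days >= 1, got {span:g}"
        )
    dawns = target.dawn_times(d)
    return _deviations_from_series(
        traj.times, traj.y[:, obj_cfg.readout_gene - 1], obj_cfg.S, dawns,
        realization_id,
    )


def ensemble_deviations(
    ckpt: Checkpoint,
    d: int,
    n_reps: int,
    light_cfg: LightConfig | None = None,
    seed: int = 0,
    sim_cfg: SimConfig | None = None,
    obj_cfg: ObjectiveConfig | None = None,
    init: SystemState | None = None,
    target: CircadianTarget | None = None,
    chunk: int = 250,
) -> list[DeviationSample]:
    """Deviations of ``n_reps`` independent stochastic realizations over
    d days each: exactly ``n_reps * d`` samples, censored included.

    Replicates are integrated in vectorized chunks, each with its own
    light schedule and Wiener path; reproducible given ``seed``.
    Realizations whose integration fails are recorded as fully censored
    rather than aborting the ensemble.
    """
    if n_reps < 1 or d < 1:
        raise ConfigError("n_reps and d must be >= 1")
    light_cfg = light_cfg or LightConfig()
    sim_cfg = sim_cfg or SimConfig()
    obj_cfg = obj_cfg or ObjectiveConfig()
    target = target or CircadianTarget()
    n = ckpt.kin.n
    init_vec = (init or SystemState.constant(n)).as_vector()
    horizon = float(d)
    dawns = target.dawn_times(d)

    rng = np.random.default_rng(seed)
    dt = sim_cfg.dt
    nsteps = int(round(horizon / dt))
    t_left = np.arange(nsteps) * dt
    base = light_cfg.amplitude * eval_target(t_left) ** light_cfg.sharpness_exponent

    samples: list[DeviationSample] = []
    rep0 = 0
    while rep0 < n_reps:
        B = min(chunk, n_reps - rep0)
        u = np.empty((nsteps, B))
        for b in range(B):
            sched = sample_light_schedule(
                light_cfg, horizon, seed=int(rng.integers(2 ** 31))
            )
            u[:, b] = np.where(sched.is_on(t_left), base, 0.0)
        noise = (
            rng.standard_normal((nsteps, B, 2 * n)) * np.sqrt(dt)
            if sim_cfg.noise_on
            else None
        )
        try:
            times, readout, _ = _simulate_batch(
                init_vec, ckpt.kin, ckpt.net, None, sim_cfg, horizon,
                batch=B, noise=noise, store="readout",
                readout_idx=obj_cfg.readout_gene - 1, u_matrix=u,
            )
            series = readout
        except Exception:
            # salvage per replicate: rerun one at a time, censoring failures
            times = np.arange(nsteps + 1) * dt
            series = np.full((nsteps + 1, B), np.nan)
            for b in range(B):
                try:
                    _, rb, _ = _simulate_batch(
                        init_vec, ckpt.kin, ckpt.net, None, sim_cfg, horizon,
                        batch=1,
                        noise=None if noise is None else noise[:, b:b + 1],
                        store="readout", readout_idx=obj_cfg.readout_gene - 1,
                        u_matrix=u[:, b:b + 1],
                    )
                    series[:, b] = rb[:, 0]
                except Exception:
                    pass
        for b in range(B):
            col = series[:, b]
            if np.all(np.isfinite(col)):
                samples.extend(
                    _deviations_from_series(times, col, obj_cfg.S, dawns, rep0 + b)
                )
            else:
                samples.extend(
                    DeviationSample(rep0 + b, day, None, censored=True)
                    for day in range(1, d + 1)
                )
        rep0 += B
    return samples


def summarize(samples: Sequence[DeviationSample]) -> PercentileSummary:
    """5/25/50/75/95 percentiles of the uncensored deviations (hours)."""
    values = np.asarray(
        [s.deviation for s in samples if not s.censored], dtype=float
    )
    n_censored = sum(1 for s in samples if s.censored)
    if values.size == 0:
        raise SummaryError("all samples are censored; no deviations to summarize")
    p5, p25, p50, p75, p95 = np.percentile(values, [5, 25, 50, 75, 95])
    return PercentileSummary(
        float(p5), float(p25), float(p50), float(p75), float(p95),
        n_samples=len(samples), n_censored=n_censored,
    )


def deviations_to_csv(samples: Sequence[DeviationSample], path):
    import pandas as pd

    pd.DataFrame(
        {
            "realization_id": [s.realization_id for s in samples],
            "day": [s.day for s in samples],
            "deviation_hours": [
                "" if s.censored else repr(s.deviation) for s in samples
            ],
            "censored": [int(s.censored) for s in samples],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# input-output surfaces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurfaceGrid:
    """Grid specification for input-output surfaces.

    Axes run on the log10(1 + z) abundance scale from 0 to
    log10(1 + max_abundance), so zero abundance is included naturally.
    ``x_gene``/``y_gene`` vary within a panel; ``row_gene``/``col_gene``
    set the outer levels (1-based indices).
    """

    x_gene: int = 1
    y_gene: int = 2
    row_gene: int = 3
    col_gene: int = 4
    max_abundance: float = 1.0e4
    n_grid: int = 20
    n_levels: int = 3

    def __post_init__(self):
        if not self.max_abundance > 0:
            raise ConfigError("max_abundance must be positive on a log axis")
        if self.n_grid < 2 or self.n_levels < 1:
            raise ConfigError("n_grid must be >= 2 and n_levels >= 1")

    def inner_axis(self) -> np.ndarray:
        u = np.linspace(0.0, np.log10(1.0 + self.max_abundance), self.n_grid)
        return 10.0 ** u - 1.0

    def outer_levels(self) -> np.ndarray:
        u = np.linspace(0.0, np.log10(1.0 + self.max_abundance), self.n_levels)
        return 10.0 ** u - 1.0


def io_surface(net, gene: int, grid: SurfaceGrid | None = None) -> np.ndarray:
    """Stack of f_gene matrices over the abundance grid.

    Returns an array of shape (n_levels, n_levels, n_grid, n_grid):
    entry [i, j] is the matrix over (x_gene rows? no — first inner axis
    is the x_gene abundance, second the y_gene abundance) at row-gene
    level i and column-gene level j.  ``net`` may be a NetParams or any
    callable mapping abundance vectors to rate fractions.
    """
    grid = grid or SurfaceGrid()
    if isinstance(net, NetParams):
        n = net.n
        fn = lambda y: net_forward(net, y)
    else:
        fn = net
        n = max(grid.x_gene, grid.y_gene, grid.row_gene, grid.col_gene)
    axes_idx = [grid.x_gene - 1, grid.y_gene - 1, grid.row_gene - 1, grid.col_gene - 1]
    if len(set(axes_idx)) != 4 or max(axes_idx) >= n:
        raise ConfigError("grid genes must be four distinct valid 1-based indices")
    if not 1 <= gene <= n:
        raise ConfigError(f"gene must be in 1..{n}")

    inner = grid.inner_axis()
    levels = grid.outer_levels()
    out = np.empty((grid.n_levels, grid.n_levels, grid.n_grid, grid.n_grid))
    X, Y = np.meshgrid(inner, inner, indexing="ij")
    pts = np.zeros((grid.n_grid, grid.n_grid, n))
    for i, lvl_row in enumerate(levels):
        for j, lvl_col in enumerate(levels):
            pts[:] = 0.0
            pts[..., axes_idx[0]] = X
            pts[..., axes_idx[1]] = Y
            pts[..., axes_idx[2]] = lvl_row
            pts[..., axes_idx[3]] = lvl_col
            out[i, j] = fn(pts)[..., gene - 1]
    return out


def surface_to_csvs(stack: np.ndarray, grid: SurfaceGrid, gene: int, out_dir):
    """Write each (row, col) level matrix as CSV plus an index JSON."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = {
        "gene": gene,
        "x_gene": grid.x_gene,
        "y_gene": grid.y_gene,
        "row_gene": grid.row_gene,
        "col_gene": grid.col_gene,
        "inner_axis": grid.inner_axis().tolist(),
        "outer_levels": grid.outer_levels().tolist(),
        "files": [],
    }
    for i in range(stack.shape[0]):
        for j in range(stack.shape[1]):
            name = f"surface_gene{gene}_row{i}_col{j}.csv"
            np.savetxt(out_dir / name, stack[i, j], delimiter=",")
            index["files"].append(
                {"row_level_index": i, "col_level_index": j, "file": name}
            )
    (out_dir / f"surface_gene{gene}_index.json").write_text(json.dumps(index, indent=1))
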