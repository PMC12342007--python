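"""Gradient-based optimization of the network and kinetic parameters.

The trainer minimizes the expected circadian tracking loss over batches
of stochastic realizations, following a growing-horizon curriculum: it
first fits part of the first day, then lengthens the fitted time range
stage by stage (default final horizon 4 days).  Per gradient step, fresh
light schedules and Wiener paths are sampled and then held fixed while
the solver path is differentiated (pathwise / reparameterized
gradients); the reverse sweep lives in :mod:`neurogrn._adjoint`.

Kinetic rates are optimized in log space so they remain strictly
positive.  Adam is the optimizer (learning rate 1e-2 by default).
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field

import numpy as np

from ._adjoint import (
    Adam,
    PathwiseProblem,
    loss_and_grad,
    theta_from_parts,
)
from .dynamics import KineticParams, SimConfig, SystemState, _simulate_batch
from .environment import CircadianTarget, LightConfig, eval_target, sample_light_schedule
from .exceptions import ConfigError
from .objective import CurriculumSchedule, ObjectiveConfig, loss_grid, target_transform, tracking_loss
from .regulatory_net import NetParams, init_params

__all__ = ["TrainConfig", "Checkpoint", "train", "evaluate"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    batch : stochastic replicate trajectories averaged per gradient step.
    optimize_kinetics : also train the kinetic rates (in log space).
    pretrain_deterministic : run a noise-off warmup on the first
    curriculum horizon before stochastic fitting begins.
    max_minutes : wall-clock budget; exceeded -> graceful stop returning
    the best checkpoint so far.
    """

    curriculum: CurriculumSchedule = field(default_factory=CurriculumSchedule)
    learning_rate: float = 1.0e-2
    batch: int = 1
    seed: int = 0
    optimize_kinetics: bool = True
    pretrain_deterministic: bool = True
    max_minutes: float | None = None

    def __post_init__(self):
        if not self.learning_rate > 0:
            raise ConfigError("learning_rate must be positive")
        if self.batch < 1:
            raise ConfigError("batch must be >= 1")


@dataclass
class Checkpoint:
    """Best-so-far parameter snapshot produced by the trainer."""

    net: NetParams
    kin: KineticParams
    stage: int
    loss_estimate: float
    rng_state: dict | None = None

    def __post_init__(self):
        if self.loss_estimate < 0:
            raise ConfigError("loss_estimate must be nonnegative")


def _theta_to_models(theta: dict, input_transform: str) -> tuple[NetParams, KineticParams]:
    net = NetParams.from_dense(
        theta["W1"], theta["b1"], theta["W2"], theta["b2"], input_transform
    )
    kin = KineticParams(
        np.exp(theta["log_m"]), np.exp(theta["log_delta"]),
        np.exp(theta["log_s"]), np.exp(theta["log_gamma"]),
    )
    return net, kin


def _build_problem(
    theta_n: int,
    horizon: float,
    sim_cfg: SimConfig,
    obj_cfg: ObjectiveConfig,
    light_cfg: LightConfig,
    target: CircadianTarget,
    init: np.ndarray,
    batch: int,
    rng: np.random.Generator,
    noise_on: bool,
) -> PathwiseProblem:
    dt = sim_cfg.dt
    nsteps = int(round(horizon / dt))
    grid = loss_grid(horizon, obj_cfg.sample_dt)
    grid_idx = np.rint(grid / dt).astype(int)
    if np.max(np.abs(grid_idx * dt - grid)) > 1e-9:
        raise ConfigError(
            "sample_dt must be an integer multiple of the integration dt"
        )
    vtilde = target_transform(target.value(grid), obj_cfg.target_half)

    # fresh light schedules per replicate, frozen for this gradient step
    t_left = np.arange(nsteps) * dt
    u = np.empty((nsteps, batch))
    base = eval_target(t_left) ** light_cfg.sharpness_exponent
    for b in range(batch):
        sched = sample_light_schedule(
            light_cfg, horizon, seed=int(rng.integers(2 ** 31))
        )
        on = sched.is_on(t_left)
        u[:, b] = np.where(on, light_cfg.amplitude * base, 0.0)

    noise = None
    if noise_on:
        noise = rng.standard_normal((nsteps, batch, 2 * theta_n)) * np.sqrt(dt)

    return PathwiseProblem(
        n=theta_n,
        dt=dt,
        nsteps=nsteps,
        init=init,
        u=u,
        noise=noise,
        grid_idx=grid_idx,
        vtilde=vtilde,
        S=obj_cfg.S,
        readout_idx=obj_cfg.readout_gene - 1,
        light_idx=sim_cfg.light_target_gene - 1,
        floor=sim_cfg.abundance_floor,
        noise_threshold=sim_cfg.noise_threshold,
        noise_scale=sim_cfg.noise_scale,
        batch=batch,
    )


def train(
    cfg: TrainConfig,
    sim_cfg: SimConfig | None = None,
    obj_cfg: ObjectiveConfig | None = None,
    light_cfg: LightConfig | None = None,
    *,
    n: int = 4,
    net0: NetParams | None = None,
    kin0: KineticParams | None = None,
    init: SystemState | None = None,
    target: CircadianTarget | None = None,
    log_fn=None,
):
    """Optimize all free parameters under the growing-horizon curriculum.

    Returns ``(best_checkpoint, history)`` where history is a list of
    dicts with keys step, stage, horizon_days, loss.  Fully reproducible
    given ``cfg.seed``.  A non-finite loss or gradient aborts the current
    stage (recorded in the history); exceeding ``cfg.max_minutes`` stops
    gracefully with the best checkpoint so far.
    """
    sim_cfg = sim_cfg or SimConfig()
    obj_cfg = obj_cfg or ObjectiveConfig()
    light_cfg = light_cfg or LightConfig()
    target = target or CircadianTarget()

    rng = np.random.default_rng(cfg.seed)
    if net0 is None:
        net0 = init_params(n, seed=int(rng.integers(2 ** 31)))
    n = net0.n
    if kin0 is None:
        kin0 = KineticParams.uniform(n)
    if kin0.n != n:
        raise ConfigError("network and kinetics disagree on system size")
    init_vec = (init or SystemState.constant(n)).as_vector()

    W1, b1, W2, b2 = net0.dense()
    theta = theta_from_parts(W1, b1, W2, b2, kin0.m, kin0.delta, kin0.s, kin0.gamma)
    keys = ("W1", "b1", "W2", "b2")
    if cfg.optimize_kinetics:
        keys = keys + ("log_m", "log_delta", "log_s", "log_gamma")
    opt = Adam(theta, lr=cfg.learning_rate, keys=keys)

    history: list[dict] = []
    best_loss = np.inf
    best_theta = {k: v.copy() for k, v in theta.items()}
    best_stage = 0
    t0 = _time.monotonic()
    step_counter = 0
    stopped = False

    stages = []
    if cfg.pretrain_deterministic and sim_cfg.noise_on:
        stages.append((cfg.curriculum.horizons[0], cfg.curriculum.steps_per_stage, False))
    for h in cfg.curriculum.horizons:
        stages.append((h, cfg.curriculum.steps_per_stage, sim_cfg.noise_on))

    for stage_idx, (horizon, steps, noisy) in enumerate(stages):
        for _ in range(steps):
            if cfg.max_minutes is not None and (
                _time.monotonic() - t0
            ) > 60.0 * cfg.max_minutes:
                stopped = True
                break
            prob = _build_problem(
                n, horizon, sim_cfg, obj_cfg, light_cfg, target,
                init_vec, cfg.batch, rng, noisy,
            )
            loss, grads = loss_and_grad(theta, prob)
            finite = np.isfinite(loss) and all(
                np.all(np.isfinite(grads[k])) for k in keys
            )
            history.append(
                {
                    "step": step_counter,
                    "stage": stage_idx,
                    "horizon_days": horizon,
                    "loss": float(loss),
                }
            )
            step_counter += 1
            if not finite:
                if log_fn:
                    log_fn(f"stage {stage_idx}: non-finite loss/gradient, aborting stage")
                break
            if loss < best_loss:
                best_loss = float(loss)
                best_theta = {k: v.copy() for k, v in theta.items()}
                best_stage = stage_idx
            theta = opt.step(theta, grads)
            if log_fn:
                log_fn(
                    f"stage {stage_idx} horizon {horizon:g}d step "
                    f"{step_counter}: loss {loss:.6g}"
                )
        if stopped:
            break

    net, kin = _theta_to_models(best_theta, net0.input_transform)
    ckpt = Checkpoint(
        net=net,
        kin=kin,
        stage=best_stage,
        loss_estimate=float(best_loss) if np.isfinite(best_loss) else 0.0,
        rng_state=rng.bit_generator.state,
    )
    return ckpt, history


def evaluate(
    ckpt: Checkpoint,
    n_reps: int,
    horizon: float,
    light_cfg: LightConfig | None = None,
    seed: int = 0,
    sim_cfg: SimConfig | None = None,
    obj_cfg: ObjectiveConfig | None = None,
    init: SystemState | None = None,
    target: CircadianTarget | None = None,
) -> list[float]:
    """Tracking losses of ``n_reps`` independent stochastic realizations.

    Each replicate gets its own light schedule and Wiener path derived
    from ``seed``; deterministic given the seed.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    light_cfg = light_cfg or LightConfig()
    sim_cfg = sim_cfg or SimConfig()
    obj_cfg = obj_cfg or ObjectiveConfig()
    target = target or CircadianTarget()
    n = ckpt.kin.n
    init = init or SystemState.constant(n)

    ss = np.random.SeedSequence(seed)
    losses = []
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        sched = sample_light_schedule(
            light_cfg, horizon, seed=int(rng.integers(2 ** 31))
        )
        rep_cfg = SimConfig(
            dt=sim_cfg.dt,
            noise_on=sim_cfg.noise_on,
            noise_threshold=sim_cfg.noise_threshold,
            abundance_floor=sim_cfg.abundance_floor,
            light_target_gene=sim_cfg.light_target_gene,
            scheme=sim_cfg.scheme,
            seed=int(rng.integers(2 ** 31)),
            noise_scale=sim_cfg.noise_scale,
        )
        times, states, _ = _simulate_batch(
            init.as_vector(), ckpt.kin, ckpt.net, sched, rep_cfg, horizon,
            batch=1, rng=np.random.default_rng(rep_cfg.seed),
            light_cfg=light_cfg,
        )
        from .dynamics import Trajectory

        traj = Trajectory(times, states[:, 0, :n], states[:, 0, n:],
                          np.zeros(times.shape[0], dtype=bool))
        losses.append(tracking_loss(traj, target, obj_cfg, horizon=horizon))
    return losses
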