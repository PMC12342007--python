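"""mRNA/protein dynamics: drift, chemical-Langevin noise, SDE integration.

For gene i with mRNA count x_i and protein count y_i,

    dx_i = (m_i f_i(y) - delta_i x_i) dt + g(x_i) dW
    dy_i = (s_i x_i - gamma_i y_i [+ u(t) if i is the light gene]) dt + g(y_i) dW

where f is the regulatory input-output function (a :class:`NetParams`
network or any callable y -> (0,1)^n), u(t) the external light forcing,
and g the abundance-dependent noise amplitude: sqrt(z) for z above a
threshold (default 16 molecules) and z/4 below, which keeps relative
fluctuations bounded as counts approach zero.  Each of the 2n state
variables receives its own independent Wiener increment.

The default integrator is Euler-Maruyama with post-step clamping at the
abundance floor; a drift-implicit variant (fixed-point iteration on the
implicit step) is available for stiff parameter regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Union

import numpy as np

from .environment import LightConfig, LightSchedule, eval_target
from .exceptions import ConfigError, CoverageError, IntegrationError, ShapeError
from .regulatory_net import NetParams, net_forward

__all__ = [
    "KineticParams",
    "SystemState",
    "SimConfig",
    "Trajectory",
    "drift",
    "noise_amplitude",
    "simulate",
]

RegulatoryFunction = Union[NetParams, Callable[[np.ndarray], np.ndarray]]


@dataclass
class KineticParams:
    """Per-gene kinetic rates, all in units of /day (m in molecules/day).

    m : max mRNA production rate; delta : mRNA decay; s : protein
    production per mRNA; gamma : protein decay.
    """

    m: np.ndarray
    delta: np.ndarray
    s: np.ndarray
    gamma: np.ndarray

    def __post_init__(self):
        for name in ("m", "delta", "s", "gamma"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            setattr(self, name, v)
        n = self.m.shape[0]
        for name in ("delta", "s", "gamma"):
            if getattr(self, name).shape != (n,):
                raise ShapeError("kinetic rate vectors must share one length")
        for name in ("m", "delta", "s", "gamma"):
            if not np.all(getattr(self, name) > 0):
                raise ConfigError(f"kinetic rates must be strictly positive ({name})")

    @property
    def n(self) -> int:
        return self.m.shape[0]

    @classmethod
    def uniform(cls, n: int, m=2.0e4, delta=8.0, s=4.0, gamma=2.0) -> "KineticParams":
        """Identical rates for every gene; defaults put protein counts on
        the 10^3-molecule scale of the state-switch threshold."""
        ones = np.ones(n)
        return cls(m * ones, delta * ones, s * ones, gamma * ones)

    def to_dict(self) -> dict:
        return {
            "m": self.m.tolist(),
            "delta": self.delta.tolist(),
            "s": self.s.tolist(),
            "gamma": self.gamma.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        return cls(np.asarray(d["m"]), np.asarray(d["delta"]),
                   np.asarray(d["s"]), np.asarray(d["gamma"]))


@dataclass
class SystemState:
    """Molecular state: mRNA counts x and protein counts y, length n each."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape:
            raise ShapeError("x and y must have the same length")
        if np.any(self.x < 0) or np.any(self.y < 0):
            raise ConfigError("abundances must be nonnegative")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.x, self.y])

    @classmethod
    def constant(cls, n: int, value: float = 10.0) -> "SystemState":
        return cls(np.full(n, float(value)), np.full(n, float(value)))


@dataclass(frozen=True)
class SimConfig:
    """Integration settings.

    dt : step size (days).  noise_on : include the Langevin term.
    noise_threshold : molecule count below which the noise amplitude
    switches to the linear z/4 branch.  abundance_floor : post-step clamp.
    light_target_gene : 1-based index of the TF whose production the
    external light boosts.  noise_scale multiplies the whole diffusion
    term (1 = model noise, 0 = deterministic limit).
    """

    dt: float = 1.0e-3
    noise_on: bool = True
    noise_threshold: float = 16.0
    abundance_floor: float = 0.0
    light_target_gene: int = 2
    scheme: str = "euler_maruyama"
    seed: int = 0
    noise_scale: float = 1.0

    def __post_init__(self):
        if not self.dt > 0:
            raise ConfigError(f"dt must be positive, got {self.dt}")
        if not self.noise_threshold > 0:
            raise ConfigError("noise_threshold must be positive")
        if self.light_target_gene < 1:
            raise ConfigError("light_target_gene is a 1-based gene index")
        if self.scheme not in ("euler_maruyama", "implicit_em"):
            raise ConfigError(f"unknown integration scheme {self.scheme!r}")


@dataclass
class Trajectory:
    """Time-indexed state paths plus the light state series.

    times : (nt,) strictly increasing; x, y : (nt, n); light_on : (nt,).
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    light_on: np.ndarray

    @property
    def n(self) -> int:
        return self.x.shape[1]

    def state_at(self, idx: int) -> SystemState:
        return SystemState(self.x[idx].copy(), self.y[idx].copy())

    def to_csv(self, path):
        """CSV export: time_days, x1..xn, y1..yn, light_on (full precision)."""
        import pandas as pd

        n = self.n
        cols = {"time_days": self.times}
        for i in range(n):
            cols[f"x{i + 1}"] = self.x[:, i]
        for i in range(n):
            cols[f"y{i + 1}"] = self.y[:, i]
        cols["light_on"] = self.light_on.astype(int)
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        import pandas as pd

        df = pd.read_csv(path)
        xcols = [c for c in df.columns if c.startswith("x") and c[1:].isdigit()]
        ycols = [c for c in df.columns if c.startswith("y") and c[1:].isdigit()]
        return cls(
            df["time_days"].to_numpy(),
            df[sorted(xcols, key=lambda c: int(c[1:]))].to_numpy(),
            df[sorted(ycols, key=lambda c: int(c[1:]))].to_numpy(),
            df["light_on"].to_numpy().astype(bool),
        )


def _as_function(net: RegulatoryFunction) -> Callable[[np.ndarray], np.ndarray]:
    if isinstance(net, NetParams):
        return lambda y: net_forward(net, y)
    if callable(net):
        return net
    raise TypeError("net must be NetParams or a callable y -> f(y)")


def noise_amplitude(z, threshold: float = 16.0):
    """Noise standard-deviation scale g(z).

    sqrt(z) for z > threshold, z / 4 for z <= threshold; the two branches
    meet at the default threshold of 16 molecules (sqrt(16) = 16/4 = 4).
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ConfigError("noise amplitude is defined for nonnegative abundance only")
    out = np.where(z > threshold, np.sqrt(np.maximum(z, 0.0)), z / 4.0)
    return out if out.ndim else float(out)


def drift(
    state: SystemState,
    kin: KineticParams,
    net: RegulatoryFunction,
    u: float = 0.0,
    light_target_gene: int = 2,
) -> np.ndarray:
    """Deterministic time derivative of the concatenated state (length 2n).

    The light forcing u (molecules/day) enters only the protein equation
    of the light-coupled gene.
    """
    if u < 0:
        raise ConfigError("light input u must be nonnegative")
    f = _as_function(net)(state.y)
    if np.shape(f)[-1] != kin.n or state.n != kin.n:
        raise ShapeError("state, kinetics, and regulatory function sizes disagree")
    dx = kin.m * f - kin.delta * state.x
    dy = kin.s * state.x - kin.gamma * state.y
    dy = dy.copy()
    dy[light_target_gene - 1] += u
    return np.concatenate([dx, dy])


def _step_batch(state, kin, f_fn, u_k, cfg, noise_k, light_idx, n):
    """One EM (or drift-implicit) step for state of shape (B, 2n)."""
    x = state[:, :n]
    y = state[:, n:]

    def drift_of(xv, yv):
        f = f_fn(yv)
        dx = kin.m * f - kin.delta * xv
        dy = kin.s * xv - kin.gamma * yv
        dy[:, light_idx] += u_k
        return dx, dy

    dx, dy = drift_of(x, y)
    det = np.concatenate([dx, dy], axis=1)
    if cfg.scheme == "implicit_em":
        # drift-implicit: solve s' = s + F(s') dt (+ noise) by fixed point,
        # seeded with the explicit prediction
        base = state.copy()
        if noise_k is not None:
            base += noise_k * noise_amplitude(
                np.maximum(state, 0.0), cfg.noise_threshold
            ) * cfg.noise_scale
        new = state + det * cfg.dt
        for _ in range(4):
            xs = np.maximum(new[:, :n], 0.0)
            ys = np.maximum(new[:, n:], 0.0)
            dxi, dyi = drift_of(xs, ys)
            new = base + np.concatenate([dxi, dyi], axis=1) * cfg.dt
    else:
        new = state + det * cfg.dt
        if noise_k is not None:
            g = noise_amplitude(np.maximum(state, 0.0), cfg.noise_threshold)
            new = new + cfg.noise_scale * g * noise_k
    return np.maximum(new, cfg.abundance_floor)


def _simulate_batch(
    init: np.ndarray,
    kin: KineticParams,
    net: RegulatoryFunction,
    schedule: LightSchedule,
    cfg: SimConfig,
    horizon: float,
    batch: int = 1,
    rng: np.random.Generator | None = None,
    noise: np.ndarray | None = None,
    store: str = "full",
    readout_idx: int = 0,
    light_cfg: LightConfig | None = None,
    u_matrix: np.ndarray | None = None,
):
    """Batched integration core.

    ``store='full'`` returns states (nsteps+1, B, 2n); ``store='readout'``
    keeps only the readout protein series (nsteps+1, B).  A pre-drawn
    noise array (nsteps, B, 2n) of sqrt(dt)-scaled Wiener increments may
    be supplied; otherwise one is drawn from ``rng``.  ``u_matrix``
    ((nsteps,) or (nsteps, B)) overrides the schedule-derived forcing,
    allowing a different light realization per replicate.
    """
    n = kin.n
    if not horizon > 0:
        raise ConfigError("horizon must be positive")
    if cfg.dt >= horizon:
        raise ConfigError(f"dt = {cfg.dt} must be smaller than horizon = {horizon}")
    nsteps = int(round(horizon / cfg.dt))
    if abs(nsteps * cfg.dt - horizon) > 1e-9 * max(1.0, horizon):
        nsteps = int(np.ceil(horizon / cfg.dt - 1e-12))
    f_fn = _as_function(net)
    light_idx = cfg.light_target_gene - 1
    if light_idx >= n:
        raise ConfigError("light_target_gene exceeds system size")

    if u_matrix is not None:
        u = u_matrix
        on_save = np.zeros(nsteps + 1, dtype=bool)
    else:
        if schedule.horizon < nsteps * cfg.dt - 1e-12:
            raise CoverageError(
                f"light schedule horizon {schedule.horizon} does not cover {horizon} days"
            )
        u, on_save = _forcing_arrays(nsteps, cfg.dt, schedule, light_cfg)

    state = np.broadcast_to(np.asarray(init, dtype=float), (batch, 2 * n)).copy()
    use_noise = cfg.noise_on
    if use_noise and noise is None:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        sqdt = np.sqrt(cfg.dt)
        draw = lambda: rng.standard_normal((batch, 2 * n)) * sqdt
    elif use_noise:
        draw = None
    else:
        draw = None

    if store == "full":
        out = np.empty((nsteps + 1, batch, 2 * n))
        out[0] = state
    else:
        out = np.empty((nsteps + 1, batch))
        out[0] = state[:, n + readout_idx]

    for k in range(nsteps):
        if use_noise:
            noise_k = noise[k] if noise is not None else draw()
        else:
            noise_k = None
        state = _step_batch(state, kin, f_fn, u[k], cfg, noise_k, light_idx, n)
        if not np.all(np.isfinite(state)):
            raise IntegrationError(
                f"non-finite state at t = {(k + 1) * cfg.dt:.6f} days",
                time=(k + 1) * cfg.dt,
            )
        if store == "full":
            out[k + 1] = state
        else:
            out[k + 1] = state[:, n + readout_idx]

    times = np.arange(nsteps + 1) * cfg.dt
    return times, out, on_save


def _forcing_arrays(
    nsteps: int, dt: float, schedule: LightSchedule,
    light_cfg: LightConfig | None = None,
):
    """u(t) at each step's left endpoint plus the light state at every
    save point (right-continuous convention)."""
    if light_cfg is None:
        light_cfg = LightConfig()
    t_left = np.arange(nsteps) * dt
    on = schedule.is_on(np.minimum(t_left, schedule.horizon))
    u = np.where(
        on,
        light_cfg.amplitude * eval_target(t_left) ** light_cfg.sharpness_exponent,
        0.0,
    )
    t_save = np.arange(nsteps + 1) * dt
    on_save = schedule.is_on(np.minimum(t_save, schedule.horizon))
    return u, np.asarray(on_save, dtype=bool)


def simulate(
    init: SystemState,
    kin: KineticParams,
    net: RegulatoryFunction,
    schedule: LightSchedule,
    cfg: SimConfig,
    horizon: float,
    light_cfg: LightConfig | None = None,
) -> Trajectory:
    """Integrate the full system over [0, horizon] days.

    With ``cfg.noise_on`` false this is the deterministic ODE; otherwise
    each state variable receives independent Wiener increments scaled by
    its own noise amplitude.  Bitwise reproducible given ``cfg.seed``.
    ``light_cfg`` supplies the amplitude/exponent of the light forcing
    (defaults used when omitted).
    """
    rng = np.random.default_rng(cfg.seed)
    times, states, on_save = _simulate_batch(
        init.as_vector(), kin, net, schedule, cfg, horizon, batch=1, rng=rng,
        light_cfg=light_cfg,
    )
    n = kin.n
    return Trajectory(
        times=times,
        x=states[:, 0, :n],
        y=states[:, 0, n:],
        light_on=on_save,
    )
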