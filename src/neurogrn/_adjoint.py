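"""Pathwise reverse-mode differentiation through the SDE unroll.

Training needs d(loss)/d(parameters) where the loss is evaluated on a
trajectory produced by Euler-Maruyama integration of the neural-network
SDE.  With the Wiener increments and the light schedule frozen
(reparameterization), the unrolled integration is a smooth map from
parameters to the trajectory, so the gradient can be accumulated by a
single reverse sweep over the stored states — the discrete adjoint of
the integrator.  Only the forward states are cached; layer activations
are recomputed during the sweep.

Parameters are carried as a dict of arrays:

    W1 (n, H, n), b1 (n, H), W2 (n, H), b2 (n,)      dense network form
    log_m, log_delta, log_s, log_gamma (n,)           kinetic rates, log space

The log parameterization keeps optimized rates strictly positive.  The
post-step clamp at the abundance floor back-propagates a zero gradient
through clamped entries (the subgradient of max).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .objective import hill_state, hill_state_grad
from .regulatory_net import mish, mish_grad

__all__ = ["PathwiseProblem", "simulate_tape", "loss_and_grad", "Adam",
           "theta_from_parts", "flatten_theta", "unflatten_theta"]

_NET_KEYS = ("W1", "b1", "W2", "b2")
_KIN_KEYS = ("log_m", "log_delta", "log_s", "log_gamma")
ALL_KEYS = _NET_KEYS + _KIN_KEYS


def theta_from_parts(W1, b1, W2, b2, m, delta, s, gamma) -> dict:
    return {
        "W1": np.asarray(W1, float).copy(),
        "b1": np.asarray(b1, float).copy(),
        "W2": np.asarray(W2, float).copy(),
        "b2": np.asarray(b2, float).copy(),
        "log_m": np.log(np.asarray(m, float)),
        "log_delta": np.log(np.asarray(delta, float)),
        "log_s": np.log(np.asarray(s, float)),
        "log_gamma": np.log(np.asarray(gamma, float)),
    }


def flatten_theta(theta: dict) -> np.ndarray:
    return np.concatenate([theta[k].ravel() for k in ALL_KEYS])


def unflatten_theta(vec: np.ndarray, template: dict) -> dict:
    out = {}
    ofs = 0
    for k in ALL_KEYS:
        size = template[k].size
        out[k] = vec[ofs:ofs + size].reshape(template[k].shape).copy()
        ofs += size
    return out


@dataclass
class PathwiseProblem:
    """Frozen-randomness training problem for one gradient evaluation.

    u : light forcing per step, shape (nsteps,) or (nsteps, batch).
    noise : sqrt(dt)-scaled Wiener increments, (nsteps, batch, 2n), or
        None for the deterministic system.
    grid_idx : save-point indices of the loss grid.
    vtilde : transformed target values at the loss grid.
    """

    n: int
    dt: float
    nsteps: int
    init: np.ndarray          # (2n,)
    u: np.ndarray             # (nsteps,) or (nsteps, B)
    noise: np.ndarray | None  # (nsteps, B, 2n)
    grid_idx: np.ndarray
    vtilde: np.ndarray
    S: float = 1.0e3
    readout_idx: int = 0
    light_idx: int = 1
    floor: float = 0.0
    noise_threshold: float = 16.0
    noise_scale: float = 1.0
    batch: int = 1

    def u_at(self, k: int):
        return self.u[k]


def _g(z, thr):
    return np.where(z > thr, np.sqrt(np.maximum(z, 1e-300)), z / 4.0)


def _g_prime(z, thr):
    return np.where(z > thr, 0.5 / np.sqrt(np.maximum(z, 1e-300)), 0.25)


def _net_eval(theta, y):
    """Hidden/output activations for batched protein vector y (B, n)."""
    r = np.log1p(y)
    z = np.einsum("ghk,bk->bgh", theta["W1"], r) + theta["b1"]
    h = mish(z)
    a = np.einsum("gh,bgh->bg", theta["W2"], h) + theta["b2"]
    f = expit(a)
    return r, z, h, f


def simulate_tape(theta: dict, prob: PathwiseProblem) -> np.ndarray:
    """Forward integration, returning all states (nsteps+1, B, 2n)."""
    n, B = prob.n, prob.batch
    m = np.exp(theta["log_m"])
    delta = np.exp(theta["log_delta"])
    s = np.exp(theta["log_s"])
    gamma = np.exp(theta["log_gamma"])
    states = np.empty((prob.nsteps + 1, B, 2 * n))
    state = np.broadcast_to(prob.init, (B, 2 * n)).copy()
    states[0] = state
    for k in range(prob.nsteps):
        x = state[:, :n]
        y = state[:, n:]
        _, _, _, f = _net_eval(theta, y)
        Fx = m * f - delta * x
        Fy = s * x - gamma * y
        uk = prob.u_at(k)
        Fy[:, prob.light_idx] += uk
        pre = state + np.concatenate([Fx, Fy], axis=1) * prob.dt
        if prob.noise is not None:
            pre = pre + prob.noise_scale * _g(state, prob.noise_threshold) * prob.noise[k]
        state = np.maximum(pre, prob.floor)
        states[k + 1] = state
    return states


def loss_from_states(states: np.ndarray, prob: PathwiseProblem) -> float:
    y1 = states[prob.grid_idx, :, prob.n + prob.readout_idx]  # (G, B)
    gap = hill_state(y1, prob.S) - prob.vtilde[:, None]
    return float(np.mean(np.sum(gap * gap, axis=0)))


def loss_and_grad(theta: dict, prob: PathwiseProblem):
    """Loss (batch mean) and its gradient with respect to every key in theta."""
    n, B = prob.n, prob.batch
    m = np.exp(theta["log_m"])
    delta = np.exp(theta["log_delta"])
    s = np.exp(theta["log_s"])
    gamma = np.exp(theta["log_gamma"])

    states = simulate_tape(theta, prob)
    loss = loss_from_states(states, prob)

    # direct dL/d(readout protein) at each grid save point
    y1 = states[prob.grid_idx, :, prob.n + prob.readout_idx]
    gap = hill_state(y1, prob.S) - prob.vtilde[:, None]
    dLdy1 = 2.0 * gap * hill_state_grad(y1, prob.S) / B  # (G, B)
    direct = {int(gi): dLdy1[j] for j, gi in enumerate(prob.grid_idx)}

    grads = {k: np.zeros_like(theta[k]) for k in ALL_KEYS}
    lam = np.zeros((B, 2 * n))
    dt = prob.dt

    for k in range(prob.nsteps - 1, -1, -1):
        contrib = direct.get(k + 1)
        if contrib is not None:
            lam[:, n + prob.readout_idx] += contrib
        # clamp subgradient: zero where the stored state sits on the floor
        mu = np.where(states[k + 1] > prob.floor, lam, 0.0)
        mux = mu[:, :n]
        muy = mu[:, n:]

        state = states[k]
        x = state[:, :n]
        y = state[:, n:]
        r, z, h, f = _net_eval(theta, y)

        # ----- parameter gradients ------------------------------------
        c = mux * m * f * (1.0 - f)                     # (B, n)
        grads["b2"] += dt * c.sum(axis=0)
        grads["W2"] += dt * np.einsum("bg,bgh->gh", c, h)
        T = c[:, :, None] * theta["W2"][None] * mish_grad(z)  # (B, n, H)
        grads["b1"] += dt * T.sum(axis=0)
        grads["W1"] += dt * np.einsum("bgh,bk->ghk", T, r)
        grads["log_m"] += dt * (mux * f).sum(axis=0) * m
        grads["log_delta"] += dt * (mux * (-x)).sum(axis=0) * delta
        grads["log_s"] += dt * (muy * x).sum(axis=0) * s
        grads["log_gamma"] += dt * (muy * (-y)).sum(axis=0) * gamma

        # ----- state adjoint ------------------------------------------
        new_x = mux * (1.0 - delta * dt) + dt * s * muy
        f_jac = np.einsum("bgh,ghk->bk", T, theta["W1"]) / (1.0 + y)
        new_y = muy * (1.0 - gamma * dt) + dt * f_jac
        lam_new = np.concatenate([new_x, new_y], axis=1)
        if prob.noise is not None:
            lam_new += mu * prob.noise[k] * prob.noise_scale * _g_prime(
                state, prob.noise_threshold
            )
        lam = lam_new

    return loss, grads


class Adam:
    """Minimal Adam optimizer over a dict of parameter arrays."""

    def __init__(self, theta: dict, lr: float = 1e-2, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 keys: tuple | None = None):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.keys = tuple(keys) if keys is not None else tuple(theta)
        self.m = {k: np.zeros_like(theta[k]) for k in self.keys}
        self.v = {k: np.zeros_like(theta[k]) for k in self.keys}
        self.t = 0

    def step(self, theta: dict, grads: dict) -> dict:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        out = dict(theta)
        for k in self.keys:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            out[k] = theta[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return out
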