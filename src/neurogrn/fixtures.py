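"""Synthetic regulatory systems for testing and demonstration.

Everything here is constructed analytically — no optimization run or
external download is needed.  The central fixture is the repressilator:
a ring of genes in which each gene is repressed by its predecessor,
encoded as classical Hill rules.  An odd ring (n = 3) with steep
repression and strong maximal expression sustains limit-cycle
oscillations; the even 4-ring carries no such guarantee and is used for
static input-output tests only.

Hill rules can stand in directly for the regulatory function f (every
simulator entry point accepts a callable), or be distilled into the
two-layer network form via :func:`fit_net_to_rules`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .dynamics import KineticParams, Trajectory
from .environment import eval_target
from .exceptions import ConfigError, FitError
from .objective import ObjectiveConfig, target_transform
from .regulatory_net import NetParams, net_forward

__all__ = [
    "HillRule",
    "hill_rule_eval",
    "rules_to_function",
    "make_repressilator",
    "repressilator_kinetics",
    "fit_net_to_rules",
    "make_shifted_tracking_trajectory",
]


@dataclass(frozen=True)
class HillRule:
    """Single-regulator Hill control of one gene.

    regulator : 1-based index of the controlling TF.
    K : half-max abundance (molecules); h : Hill coefficient.
    """

    regulator: int
    K: float
    h: float
    mode: str = "repression"

    def __post_init__(self):
        if not self.K > 0 or not self.h > 0:
            raise ConfigError("Hill K and h must be positive")
        if self.mode not in ("repression", "activation"):
            raise ConfigError(f"mode must be repression or activation, got {self.mode!r}")


def hill_rule_eval(rule: HillRule, y) -> np.ndarray:
    """Evaluate one Hill rule on abundance vector(s) y (last axis = genes)."""
    y = np.asarray(y, dtype=float)
    z = y[..., rule.regulator - 1]
    zh = (z / rule.K) ** rule.h
    out = 1.0 / (1.0 + zh) if rule.mode == "repression" else zh / (1.0 + zh)
    return out if np.ndim(out) else float(out)


def rules_to_function(rules: Sequence[HillRule]):
    """Bundle per-gene rules into a regulatory function y -> (0,1)^n."""
    rules = list(rules)

    def f(y):
        y = np.asarray(y, dtype=float)
        return np.stack([hill_rule_eval(r, y) for r in rules], axis=-1)

    return f


def make_repressilator(n: int = 3, K: float = 500.0, h: float = 4.0) -> list[HillRule]:
    """Cyclic repression ring: gene i is repressed by gene i-1 (mod n).

    With the documented default kinetics (:func:`repressilator_kinetics`)
    the odd 3-ring sustains deterministic oscillations with protein
    counts spanning roughly 10^1-10^4 molecules.  The even 4-ring may
    settle to a fixed point and is supplied for surface tests only.
    """
    if n not in (3, 4):
        raise ConfigError("repressilator fixture supports n = 3 or 4")
    return [
        HillRule(regulator=((i - 2) % n) + 1, K=K, h=h, mode="repression")
        for i in range(1, n + 1)
    ]


def repressilator_kinetics(n: int = 3) -> KineticParams:
    """Documented fixture kinetics: m = 4e4 molecules/day and decay /
    translation rates of 8/day for every gene.

    The maximal protein level m*s/(delta*gamma) = 5e3 sits an order of
    magnitude above the default K = 500, so repression swings through
    its full range, and the matched mRNA/protein timescales minimize the
    instability threshold of the ring — together with the steep default
    Hill coefficient (h = 4) this guarantees a deep limit cycle with
    protein counts spanning roughly 10^1-10^4 molecules.
    """
    return KineticParams.uniform(n, m=4.0e4, delta=8.0, s=8.0, gamma=8.0)


def repressilator_init(n: int = 3) -> "SystemState":
    """Asymmetric initial state near the limit cycle's basin.

    One gene starts dominant (2000 molecules) so the trajectory joins
    the cycle within the first day instead of lingering near the
    unstable symmetric fixed point (a symmetric start would stay on the
    symmetric invariant manifold forever in the deterministic system).
    """
    from .dynamics import SystemState

    v = np.full(n, 10.0)
    v[-1] = 2000.0
    return SystemState(v.copy(), v.copy())


def _fit_grid(n: int, rng: np.random.Generator, n_random: int = 600,
              n_sweep: int = 30, max_abundance: float = 1.0e4) -> np.ndarray:
    """Log-spaced sweep along each axis plus log-uniform random fill."""
    umax = np.log10(1.0 + max_abundance)
    pts = [10.0 ** (rng.uniform(0.0, umax, (n_random, n))) - 1.0]
    sweep = 10.0 ** np.linspace(0.0, umax, n_sweep) - 1.0
    for k in range(n):
        block = 10.0 ** (rng.uniform(0.0, umax, (n_sweep, n))) - 1.0
        block[:, k] = sweep
        pts.append(block)
    return np.concatenate(pts, axis=0)


def fit_net_to_rules(
    rules: Sequence[HillRule],
    n: int,
    seed: int = 0,
    tol: float = 0.05,
    width_mult: int = 5,
    max_abundance: float = 1.0e4,
    n_restarts: int = 3,
    ridge: float = 3.0e-3,
) -> NetParams:
    """Distill Hill rules into the two-layer network architecture.

    Per gene, dense weights are fitted by nonlinear least squares
    (Levenberg-Marquardt with an analytic Jacobian) so the network
    output matches the rule over a log-spaced abundance grid.  A small
    ridge penalty on the weights keeps the interpolant tame between grid
    points — without it LM drives the training residual to machine
    precision and the network oscillates wildly off-grid.  Raises
    :class:`FitError` (carrying the achieved error) if the max-abs
    residual on the grid exceeds ``tol`` after all restarts.
    Deterministic given the seed.
    """
    rules = list(rules)
    if len(rules) != n:
        raise ConfigError(f"need one rule per gene: got {len(rules)} rules for n = {n}")
    rng = np.random.default_rng(seed)
    width = width_mult * n
    grid = _fit_grid(n, rng, max_abundance=max_abundance)
    r_in = np.log1p(grid)  # (P, n)

    W1 = np.empty((n, width, n))
    b1 = np.empty((n, width))
    W2 = np.empty((n, width))
    b2 = np.empty(n)
    worst = 0.0
    for g in range(n):
        target = np.asarray(hill_rule_eval(rules[g], grid))

        def _unpack(p):
            w1 = p[: width * n].reshape(width, n)
            bb1 = p[width * n: width * n + width]
            w2 = p[width * n + width: width * n + 2 * width]
            bb2 = p[-1]
            return w1, bb1, w2, bb2

        def residual(p):
            w1, bb1, w2, bb2 = _unpack(p)
            z = r_in @ w1.T + bb1
            hmid = z * np.tanh(np.logaddexp(0.0, z))
            a = hmid @ w2 + bb2
            return np.concatenate([expit(a) - target, ridge * p])

        def jacobian(p):
            from .regulatory_net import mish_grad

            w1, bb1, w2, bb2 = _unpack(p)
            z = r_in @ w1.T + bb1           # (P, width)
            hmid = z * np.tanh(np.logaddexp(0.0, z))
            a = hmid @ w2 + bb2
            sig = expit(a)
            sp = (sig * (1.0 - sig))[:, None]          # (P, 1)
            dz = mish_grad(z) * w2 * sp                # (P, width)
            J = np.empty((r_in.shape[0], p.size))
            J[:, : width * n] = (dz[:, :, None] * r_in[:, None, :]).reshape(
                r_in.shape[0], width * n
            )
            J[:, width * n: width * n + width] = dz
            J[:, width * n + width: width * n + 2 * width] = sp * hmid
            J[:, -1] = sp[:, 0]
            return np.vstack([J, ridge * np.eye(p.size)])

        best = None
        for attempt in range(n_restarts):
            p0 = rng.normal(0.0, 0.5 if attempt == 0 else 1.0,
                            width * n + 2 * width + 1)
            sol = least_squares(residual, p0, jac=jacobian, method="lm", max_nfev=4000)
            err = float(np.max(np.abs(sol.fun[: grid.shape[0]])))
            if best is None or err < best[0]:
                best = (err, sol.x)
            if err <= tol:
                break
        err, p = best
        worst = max(worst, err)
        if err > tol:
            raise FitError(
                f"gene {g + 1}: fit residual {err:.4f} exceeds tol {tol}",
                achieved=err,
            )
        W1[g] = p[: width * n].reshape(width, n)
        b1[g] = p[width * n: width * n + width]
        W2[g] = p[width * n + width: width * n + 2 * width]
        b2[g] = p[-1]
    return NetParams.from_dense(W1, b1, W2, b2, input_transform="log1p")


def make_shifted_tracking_trajectory(
    shift_hours: float,
    d: int,
    obj_cfg: ObjectiveConfig | None = None,
    dt: float = 1.0e-3,
    n: int = 4,
    other_level: float = 10.0,
) -> Trajectory:
    """Trajectory whose readout TF tracks the target with a pure time shift.

    The readout protein series is constructed so its Hill state equals
    the transformed target evaluated at t - shift/24 exactly; all other
    genes (and all mRNAs) are held constant.  With shift 0 the tracking
    loss is exactly zero; daily deviation analysis recovers the shift on
    every day (negative shifts mean the cell runs early).
    """
    if abs(shift_hours) > 12.0:
        raise ConfigError("|shift| must be at most 12 hours")
    obj_cfg = obj_cfg or ObjectiveConfig()
    if d < 1:
        raise ConfigError("d must be >= 1")
    nsteps = int(round(d / dt))
    times = np.arange(nsteps + 1) * dt
    c = target_transform(eval_target(times - shift_hours / 24.0), obj_cfg.target_half)
    c = np.clip(c, 0.0, 1.0 - 1e-12)
    readout = obj_cfg.S * np.sqrt(c / (1.0 - c))
    x = np.full((nsteps + 1, n), other_level)
    y = np.full((nsteps + 1, n), other_level)
    y[:, obj_cfg.readout_gene - 1] = readout
    return Trajectory(times, x, y, np.zeros(nsteps + 1, dtype=bool))
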