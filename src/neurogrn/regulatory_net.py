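"""Per-gene neural networks encoding the TF input-output functions f_i.

Each of the n genes carries its own two-layer network.  Gene i takes the
log-transformed protein abundance vector as input; a hidden layer of 5n
nodes applies, per (node, input) edge, an affine map ``alpha + beta * r``
whose per-edge contributions are summed and passed through the mish
activation; a head layer sums per-node affine maps and applies the
logistic sigmoid, yielding the relative transcription rate f_i in (0, 1).

The per-edge ``alpha`` parameters collapse algebraically to a single bias
per node (the sum over inputs), so the network is a standard dense MLP;
the per-edge storage is kept as the canonical parameter layout (10n^3 +
10n^2 scalars in total) and the dense form is used for evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

from .exceptions import ConfigError, SchemaError, ShapeError

__all__ = ["NetParams", "mish", "sigmoid", "net_forward", "init_params"]

_SCHEMA = "neurogrn-net-v1"


def mish(r):
    """Self-gated activation mish(r) = r * tanh(softplus(r)).

    Uses log1p/exp via logaddexp so large |r| stays finite: softplus is
    computed as logaddexp(0, r).
    """
    r = np.asarray(r, dtype=float)
    out = r * np.tanh(np.logaddexp(0.0, r))
    return out if out.ndim else float(out)


def mish_grad(r):
    """Derivative of mish, used by the pathwise adjoint pass."""
    r = np.asarray(r, dtype=float)
    sp = np.logaddexp(0.0, r)
    t = np.tanh(sp)
    return t + r * (1.0 - t * t) * expit(r)


def sigmoid(r):
    """Logistic function 1 / (1 + exp(-r)), strictly in (0, 1)."""
    out = expit(np.asarray(r, dtype=float))
    return out if out.ndim else float(out)


def _transform_input(y, kind: str):
    y = np.asarray(y, dtype=float)
    if kind == "log1p":
        return np.log1p(y)
    if kind == "log":
        return np.log(y)
    raise ConfigError(f"unknown input transform {kind!r}")


@dataclass
class NetParams:
    """Weights of all n per-gene networks, stored in per-edge form.

    layer1_alpha, layer1_beta : (n, width, n)
        Per-edge affine parameters of the hidden layer; entry [i, j, k]
        belongs to gene i, hidden node j, input k.
    head_alpha, head_beta : (n, width)
        Per-node affine parameters of the output head of each gene.
    input_transform : {"log1p", "log"}
        Abundance transform applied before the first layer.  log(1 + y)
        is the default so zero abundance stays finite; the offset merely
        reparameterizes the learned weights.
    """

    n: int
    layer1_alpha: np.ndarray
    layer1_beta: np.ndarray
    head_alpha: np.ndarray
    head_beta: np.ndarray
    input_transform: str = "log1p"

    def __post_init__(self):
        self.layer1_alpha = np.asarray(self.layer1_alpha, dtype=float)
        self.layer1_beta = np.asarray(self.layer1_beta, dtype=float)
        self.head_alpha = np.asarray(self.head_alpha, dtype=float)
        self.head_beta = np.asarray(self.head_beta, dtype=float)
        n, w = self.n, self.width
        if self.layer1_alpha.shape != (n, w, n) or self.layer1_beta.shape != (n, w, n):
            raise ShapeError(
                f"layer-1 parameter blocks must have shape {(n, w, n)}, got "
                f"{self.layer1_alpha.shape} / {self.layer1_beta.shape}"
            )
        if self.head_alpha.shape != (n, w) or self.head_beta.shape != (n, w):
            raise ShapeError("head parameter blocks must have shape (n, width)")
        for block in (self.layer1_alpha, self.layer1_beta, self.head_alpha, self.head_beta):
            if not np.all(np.isfinite(block)):
                raise ConfigError("network parameters must be finite")

    @property
    def width(self) -> int:
        return self.head_alpha.shape[1] if self.head_alpha.ndim == 2 else 5 * self.n

    @property
    def n_parameters(self) -> int:
        return int(
            self.layer1_alpha.size + self.layer1_beta.size
            + self.head_alpha.size + self.head_beta.size
        )

    # -- dense equivalent -------------------------------------------------
    def dense(self):
        """Collapse per-edge alphas into node biases.

        Returns (W1, b1, W2, b2) with shapes (n, width, n), (n, width),
        (n, width), (n,).  Hidden pre-activation for gene i is
        ``W1[i] @ r + b1[i]``; head pre-activation is
        ``W2[i] . h + b2[i]``.
        """
        return (
            self.layer1_beta,
            self.layer1_alpha.sum(axis=2),
            self.head_beta,
            self.head_alpha.sum(axis=1),
        )

    @classmethod
    def from_dense(cls, W1, b1, W2, b2, input_transform: str = "log1p") -> "NetParams":
        """Build per-edge storage from dense weights.

        Node biases are split evenly across the per-edge alphas (any split
        summing to the bias is equivalent).
        """
        W1 = np.asarray(W1, dtype=float)
        b1 = np.asarray(b1, dtype=float)
        W2 = np.asarray(W2, dtype=float)
        b2 = np.asarray(b2, dtype=float)
        n = W1.shape[0]
        width = W1.shape[1]
        l1a = np.repeat(b1[:, :, None] / n, n, axis=2)
        ha = np.repeat(b2[:, None] / width, width, axis=1)
        return cls(n, l1a, W1.copy(), ha, W2.copy(), input_transform)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema": _SCHEMA,
            "n": self.n,
            "width": self.width,
            "input_transform": self.input_transform,
            "genes": [
                {
                    "layer1_alpha": self.layer1_alpha[i].tolist(),
                    "layer1_beta": self.layer1_beta[i].tolist(),
                    "head_alpha": self.head_alpha[i].tolist(),
                    "head_beta": self.head_beta[i].tolist(),
                }
                for i in range(self.n)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetParams":
        if d.get("schema") != _SCHEMA:
            raise SchemaError(
                f"expected network schema {_SCHEMA!r}, got {d.get('schema')!r}"
            )
        genes = d["genes"]
        return cls(
            n=int(d["n"]),
            layer1_alpha=np.asarray([g["layer1_alpha"] for g in genes]),
            layer1_beta=np.asarray([g["layer1_beta"] for g in genes]),
            head_alpha=np.asarray([g["head_alpha"] for g in genes]),
            head_beta=np.asarray([g["head_beta"] for g in genes]),
            input_transform=d.get("input_transform", "log1p"),
        )

    def to_json(self, path):
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path) -> "NetParams":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def __call__(self, y):
        return net_forward(self, y)


def net_forward(params: NetParams, y) -> np.ndarray:
    """Relative transcription rates f(y) in (0, 1)^n.

    ``y`` is the protein abundance vector (length n, elementwise >= 0);
    leading batch dimensions are broadcast.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != params.n:
        raise ShapeError(
            f"abundance vector has length {y.shape[-1]}, network expects {params.n}"
        )
    W1, b1, W2, b2 = params.dense()
    r = _transform_input(y, params.input_transform)
    z = np.einsum("ghk,...k->...gh", W1, r) + b1
    h = mish(z)
    a = np.einsum("gh,...gh->...g", W2, h) + b2
    return expit(a)


def net_forward_edgewise(params: NetParams, y) -> np.ndarray:
    """Literal per-edge evaluation (sum of alpha + beta*r over edges).

    Mathematically identical to :func:`net_forward`; retained as the
    reference form for the dense-equivalence check.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != params.n:
        raise ShapeError("dimension mismatch")
    r = _transform_input(y, params.input_transform)
    z = np.einsum("ghk,...k->...gh", params.layer1_beta, r) + params.layer1_alpha.sum(2)
    h = mish(z)
    a = (params.head_beta * h).sum(-1) + params.head_alpha.sum(-1)
    return expit(a)


def init_params(
    n: int, seed: int = 0, scale: float = 0.1, width_mult: int = 5,
    input_transform: str = "log1p",
) -> NetParams:
    """Random small-weight initialization near the f = 0.5 regime.

    alpha and beta entries are i.i.d. normal with standard deviation
    ``scale``; with scale 0 every gene outputs exactly 0.5.
    """
    if n < 1:
        raise ConfigError(f"system size n must be >= 1, got {n}")
    if scale < 0:
        raise ConfigError("initialization scale must be nonnegative")
    rng = np.random.default_rng(seed)
    w = width_mult * n
    return NetParams(
        n=n,
        layer1_alpha=rng.normal(0.0, scale, (n, w, n)),
        layer1_beta=rng.normal(0.0, scale, (n, w, n)),
        head_alpha=rng.normal(0.0, scale, (n, w)),
        head_beta=rng.normal(0.0, scale, (n, w)),
        input_transform=input_transform,
    )
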