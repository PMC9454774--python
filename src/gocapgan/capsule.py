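"""Capsule-network primitives: squash, affine votes, dynamic routing, lengths.

A capsule is a small group of neurons whose activity *vector* represents one
entity; the vector's norm encodes the probability that the entity is present
and its direction encodes instantiation parameters.  A layer of ``J_in``
input capsules sends an affine "vote" to each of ``K_out`` output capsules,

    vote(j, k) = W[j, k] @ x[j] + B[j, k],

and routing-by-agreement iteratively concentrates each input capsule's
coupling coefficients ``c[j, :]`` (a softmax over output capsules) on the
outputs its votes agree with.  Output vectors are passed through the squash
nonlinearity, which maps norms into [0, 1) while preserving direction.

Functions here operate both on plain NumPy arrays and on autodiff
:class:`~gocapgan.tensor.Tensor` objects; the batched Tensor path is what
the GAN critic uses, the unbatched NumPy path is the reference API.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import tensor as T
from .tensor import Tensor

__all__ = [
    "CapsuleLayerParams",
    "RoutingState",
    "squash",
    "compute_votes",
    "dynamic_route",
    "capsule_lengths",
    "squash_t",
    "route_t",
]

_NORM_EPS = 1e-8  # guards the division in squash; never appears in the output value


@dataclass
class CapsuleLayerParams:
    """Affine vote parameters between two capsule layers.

    W has shape (J_in, K_out, d_out, d_in); B has shape (J_in, K_out, d_out)
    (``bias_mode='per_pair'``) or (K_out, d_out) broadcast over input capsules
    (``bias_mode='per_output'``).
    """

    W: np.ndarray
    B: np.ndarray
    bias_mode: str = "per_pair"

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64)
        self.B = np.asarray(self.B, dtype=np.float64)
        if self.W.ndim != 4:
            raise ValueError(f"W must be 4-D (J_in, K_out, d_out, d_in), got shape {self.W.shape}")
        j, k, d_out, _ = self.W.shape
        if self.bias_mode == "per_pair":
            expect = (j, k, d_out)
        elif self.bias_mode == "per_output":
            expect = (k, d_out)
        else:
            raise ValueError(f"unknown bias_mode {self.bias_mode!r}")
        if self.B.shape != expect:
            raise ValueError(f"B shape {self.B.shape} incompatible with bias_mode "
                             f"{self.bias_mode!r}; expected {expect}")

    @property
    def J_in(self) -> int:
        return self.W.shape[0]

    @property
    def K_out(self) -> int:
        return self.W.shape[1]

    @property
    def d_in(self) -> int:
        return self.W.shape[3]

    @property
    def d_out(self) -> int:
        return self.W.shape[2]

    @classmethod
    def init_random(cls, J_in, K_out, d_in, d_out, rng, scale=0.1, bias_mode="per_pair"):
        W = rng.normal(0.0, scale, size=(J_in, K_out, d_out, d_in))
        bshape = (J_in, K_out, d_out) if bias_mode == "per_pair" else (K_out, d_out)
        return cls(W=W, B=np.zeros(bshape), bias_mode=bias_mode)


@dataclass
class RoutingState:
    """Final state of routing-by-agreement.

    logits b and coupling c have shape (J_in, K_out); s and v have shape
    (K_out, d_out).  Coupling rows sum to one over output capsules.
    """

    logits: np.ndarray
    coupling: np.ndarray
    s: np.ndarray
    v: np.ndarray
    iteration: int = 0

    def check(self, atol: float = 1e-9) -> None:
        rows = self.coupling.sum(axis=-1)
        if not np.allclose(rows, 1.0, atol=atol):
            raise AssertionError("coupling rows do not sum to 1")
        norms = np.linalg.norm(self.v, axis=-1)
        if not np.all(norms < 1.0):
            raise AssertionError("squashed capsule norm reached 1")


# -- core math (Tensor path; NumPy wrappers below) ---------------------------


def squash_t(s: Tensor, axis: int = -1) -> Tensor:
    """Squash along ``axis``: s * ||s||^2 / ((1 + ||s||^2) ||s||)."""
    ssq = T.tsum(T.power(s, 2.0), axis=axis, keepdims=True)
    norm = T.sqrt(ssq + _NORM_EPS**2)
    scale = T.mul(T.mul(ssq, T.power(1.0 + ssq, -1.0)), T.power(norm, -1.0))
    return T.mul(s, scale)


def route_t(votes: Tensor, iterations: int = 3, cap_axis: int = -1):
    """Dynamic routing on a votes tensor shaped (..., J, K, d).

    Returns (coupling, s, v, logits) as Tensors; coupling/logits are
    (..., J, K), s and v are (..., K, d).  Logits start at zero; each round
    takes the softmax over output capsules, forms the weighted vote sum,
    squashes it, and (except after the last round) adds the vote-output
    agreement back onto the logits.
    """
    if iterations < 1:
        raise ValueError("routing needs at least one iteration")
    lead = votes.data.shape[:-3]
    n = votes.data.ndim
    J, K, d = votes.data.shape[-3:]
    # (..., K, J, d) view: lets the routing contractions run as stacked matmuls
    votes_t = T.transpose(votes, tuple(range(n - 3)) + (n - 2, n - 3, n - 1))
    b = T.constant(np.zeros(lead + (J, K)))
    c = s = v = None
    for r in range(iterations):
        c = T.softmax(b, axis=-1)
        c_t = T.reshape(T.transpose(c, tuple(range(n - 3)) + (n - 2, n - 3)),
                        lead + (K, 1, J))
        s = T.reshape(T.matmul(c_t, votes_t), lead + (K, d))
        v = squash_t(s, axis=cap_axis)
        if r + 1 < iterations:
            agree = T.matmul(votes_t, T.reshape(v, lead + (K, d, 1)))
            agree = T.transpose(T.reshape(agree, lead + (K, J)),
                                tuple(range(n - 3)) + (n - 2, n - 3))
            b = T.add(b, agree)
    return c, s, v, b


def lengths_t(v: Tensor, axis: int = -1) -> Tensor:
    ssq = T.tsum(T.power(v, 2.0), axis=axis)
    return T.sqrt(ssq + 1e-30)


# -- NumPy reference API ------------------------------------------------------


def squash(s: np.ndarray) -> np.ndarray:
    """Squash a single vector; the zero vector maps exactly to itself."""
    s = np.asarray(s, dtype=np.float64)
    n = np.linalg.norm(s)
    if n == 0.0:
        return np.zeros_like(s)
    return (n * n / (1.0 + n * n)) * (s / n)


def compute_votes(inputs: np.ndarray, params: CapsuleLayerParams) -> np.ndarray:
    """Affine votes: vote[j, k] = W[j, k] @ x[j] + B[j, k]; shape (J, K, d_out)."""
    x = np.asarray(inputs, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] != params.J_in:
        raise ValueError(
            f"inputs must have shape (J_in={params.J_in}, d_in={params.d_in}); got {x.shape}"
        )
    if x.shape[1] != params.d_in:
        raise ValueError(
            f"input capsule dimension mismatch: expected d_in={params.d_in}, got {x.shape[1]}"
        )
    votes = np.einsum("jkoi,ji->jko", params.W, x)
    if params.bias_mode == "per_pair":
        votes = votes + params.B
    else:
        votes = votes + params.B[None, :, :]
    return votes


def dynamic_route(votes: np.ndarray, iterations: int = 3) -> RoutingState:
    """Routing-by-agreement over votes shaped (J, K, d_out)."""
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    votes = np.asarray(votes, dtype=np.float64)
    if votes.ndim != 3:
        raise ValueError(f"votes must be 3-D (J, K, d_out); got shape {votes.shape}")
    vt = T.constant(votes)
    c, s, v, b = route_t(vt, iterations=iterations)
    return RoutingState(
        logits=b.data.copy(),
        coupling=c.data.copy(),
        s=s.data.copy(),
        v=v.data.copy(),
        iteration=iterations,
    )


def capsule_lengths(state: RoutingState) -> np.ndarray:
    """Norm of each output capsule vector; in [0, 1) by the squash bound."""
    return np.linalg.norm(state.v, axis=-1)
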