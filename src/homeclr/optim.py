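"""Contrastive loss, optimizers, learning-rate schedule, and SAM.

NT-Xent (normalized temperature-scaled cross-entropy) drives contrastive
pre-training: for 2N projected embeddings holding N positive pairs,

    l(i, j) = -log( exp(sim(i,j)/tau) / sum_{k != i} exp(sim(i,k)/tau) )

averaged over both orderings of every pair, with cosine similarity and
temperature tau. Sharpness-aware minimization (SAM) replaces the plain
gradient step by a two-step procedure: first ascend to the worst-case
point ``w + rho * g / ||g||_2`` inside the rho-ball, then apply the base
optimizer (SGD or Adam) with the gradient taken there; an optional
``lambda * ||w||^2`` weight-decay term completes the objective.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "cosine_similarity",
    "nt_xent_loss",
    "softmax_cross_entropy",
    "cosine_decay_lr",
    "SGD",
    "Adam",
    "SAMConfig",
    "SAM",
    "sam_update",
]


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u| |v|), in [-1, 1]; zero vectors are an error."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(u @ v / (nu * nv))


def nt_xent_loss(Z: Tensor, temperature: float) -> Tensor:
    """NT-Xent over interleaved embeddings (rows 2k, 2k+1 are a pair).

    Computed in matrix form: row-normalize Z, build the full pairwise
    cosine-similarity matrix scaled by 1/temperature, exclude self-pairs
    from each row's log-sum-exp (the stabilized softmax denominator), and
    average ``lse_i - sim(i, partner(i))`` over all 2N rows — identical to
    averaging l(2k-1, 2k) and l(2k, 2k-1) over the N pairs.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    two_n = Z.shape[0]
    if two_n < 2 or two_n % 2:
        raise ValueError("need an even number (>= 2) of embeddings")
    norms = (Z**2).sum(axis=1, keepdims=True) ** 0.5
    Zn = Z / norms
    S = (Zn @ Zn.transpose()) * (1.0 / temperature)
    S = S + Tensor(np.diag(np.full(two_n, -1e30)))  # exclude k == i
    lse = logsumexp(S, axis=-1).reshape(two_n)
    partner = np.arange(two_n) ^ 1  # 0<->1, 2<->3, ...
    pos = (Zn * Zn[partner]).sum(axis=1) * (1.0 / temperature)
    return (lse - pos).mean()


def softmax_cross_entropy(logits: Tensor, y: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer targets under a softmax over logits."""
    n = logits.shape[0]
    lse = logsumexp(logits, axis=-1).reshape(n)
    picked = logits[np.arange(n), np.asarray(y)]
    return (lse - picked).mean()


def cosine_decay_lr(
    step: int, initial: float = 0.1, decay_steps: int = 1000, alpha: float = 0.0
) -> float:
    """Cosine-annealed learning rate, clamped at ``initial * alpha`` after decay."""
    if step < 0:
        raise ValueError("step must be >= 0")
    if step >= decay_steps:
        return initial * alpha
    cosine = 0.5 * (1.0 + math.cos(math.pi * step / decay_steps))
    return initial * ((1.0 - alpha) * cosine + alpha)


class _Optimizer:
    def __init__(self, params: list[Tensor], weight_decay: float = 0.0):
        self.params = list(params)
        self.weight_decay = float(weight_decay)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def _grad(self, p: Tensor) -> np.ndarray:
        g = p.grad if p.grad is not None else np.zeros_like(p.data)
        if self.weight_decay:
            g = g + self.weight_decay * p.data
        return g

    def step(self):
        raise NotImplementedError


class SGD(_Optimizer):
    """Plain gradient descent; ``lr`` may be reassigned per step (schedules)."""

    def __init__(self, params, lr: float = 0.1, weight_decay: float = 0.0):
        super().__init__(params, weight_decay)
        self.lr = lr

    def step(self):
        for p in self.params:
            p.data = p.data - self.lr * self._grad(p)


class Adam(_Optimizer):
    def __init__(
        self,
        params,
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-7,
        weight_decay: float = 0.0,
    ):
        super().__init__(params, weight_decay)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = self._grad(p)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass(frozen=True)
class SAMConfig:
    """rho = 0.05 is the canonical neighborhood radius; rho = 0 disables SAM."""

    rho: float = 0.05
    weight_decay: float = 0.0

    def __post_init__(self):
        if self.rho < 0 or self.weight_decay < 0:
            raise ValueError("rho and weight_decay must be >= 0")


class SAM:
    """Sharpness-aware wrapper around a base optimizer.

    ``step(loss_fn)`` evaluates the loss twice: once at ``w`` to find the
    ascent direction (epsilon scaled from the *global* gradient 2-norm over
    all parameters jointly), once at ``w + epsilon`` to obtain the descent
    gradient actually applied by the base optimizer. With rho = 0 the
    trajectory is bit-identical to the base optimizer alone.
    """

    def __init__(self, base: _Optimizer, config: SAMConfig = SAMConfig()):
        self.base = base
        self.config = config
        base.weight_decay = max(base.weight_decay, config.weight_decay)

    @property
    def params(self):
        return self.base.params

    def zero_grad(self):
        self.base.zero_grad()

    def step(self, loss_fn) -> float:
        params = self.base.params
        self.zero_grad()
        loss = loss_fn()
        loss.backward()
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in params]
        norm = math.sqrt(sum(float((g**2).sum()) for g in grads))
        if self.config.rho > 0 and norm > 0:
            eps = [self.config.rho * g / norm for g in grads]
            for p, e in zip(params, eps):
                p.data = p.data + e
            self.zero_grad()
            loss_fn().backward()  # gradient at the ascent point
            for p, e in zip(params, eps):
                p.data = p.data - e
        elif self.config.rho > 0:
            logger.info("zero gradient norm: SAM falls back to a plain step")
        self.base.step()
        return float(loss.data)


def sam_update(params, loss_fn, config: SAMConfig, base_step: _Optimizer) -> float:
    """Functional form of one SAM update; returns the (pre-step) loss."""
    return SAM(base_step, config).step(loss_fn)
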