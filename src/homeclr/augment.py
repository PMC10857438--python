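"""Stochastic view generation for contrastive pre-training.

Five candidate window transforms: random signal inverting, time reversing,
time warping, additive random noise, and multiplicative scaling. The
default is channel-wise scaling with sigma = 0.1, the strongest performer
in the augmentation comparison. Each call to :func:`make_views` produces
two independently transformed copies of a batch; views of the same window
form the positive pair, all other pairs in the batch are negatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AugmentationSpec",
    "scaling",
    "inverting",
    "reversing",
    "random_noise",
    "time_warp",
    "apply_augmentation",
    "make_views",
    "AUGMENTATIONS",
]


@dataclass(frozen=True)
class AugmentationSpec:
    """Which transform to apply and how strongly."""

    name: str = "scaling"
    magnitude: float = 0.1
    n_knots: int = 4  # interior knots for time warping

    def __post_init__(self):
        if self.magnitude < 0:
            raise ValueError("augmentation magnitude must be >= 0")
        if self.name not in AUGMENTATIONS:
            raise ValueError(f"unknown augmentation {self.name!r}")


def scaling(x: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Multiply each feature channel by a factor ~ N(1, sigma^2).

    One factor per (window, channel), shared across the window's timesteps:
    per-element factors at sigma = 0.1 would reduce to unstructured noise.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    B, _, F = x.shape
    factors = rng.normal(1.0, sigma, size=(B, 1, F))
    return x * factors


def inverting(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Flip the sign of a whole window with probability 0.5 per window."""
    flips = rng.random(size=(x.shape[0], 1, 1)) < 0.5
    return np.where(flips, -x, x)


def reversing(x: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
    """Reverse the time axis (an involution; rng accepted for uniformity)."""
    return x[:, ::-1, :].copy()


def random_noise(x: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Add elementwise Gaussian jitter with sd sigma."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return x + rng.normal(0.0, sigma, size=x.shape)


def time_warp(
    x: np.ndarray,
    strength: float,
    rng: np.random.Generator,
    n_knots: int = 4,
) -> np.ndarray:
    """Smooth monotone re-timing of the window's time axis.

    A random monotone warp curve is built per window by perturbing the
    increments between ``n_knots`` interior knots (log-normal multipliers
    with sd ``strength``), then each channel is linearly re-sampled back to
    the original T grid. ``strength = 0`` is the identity warp.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    B, T, F = x.shape
    out = np.empty_like(x)
    grid = np.arange(T, dtype=float)
    knot_pos = np.linspace(0, T - 1, n_knots + 2)
    for b in range(B):
        increments = np.exp(rng.normal(0.0, strength, size=n_knots + 1))
        knot_vals = np.concatenate([[0.0], np.cumsum(increments)])
        knot_vals *= (T - 1) / knot_vals[-1]  # pin endpoints to [0, T-1]
        warped = np.interp(grid, knot_pos, knot_vals)  # monotone warp curve
        for f in range(F):
            out[b, :, f] = np.interp(warped, grid, x[b, :, f])
    return out


AUGMENTATIONS = {
    "scaling": lambda x, spec, rng: scaling(x, spec.magnitude, rng),
    "inverting": lambda x, spec, rng: inverting(x, rng),
    "reversing": lambda x, spec, rng: reversing(x, rng),
    "random_noise": lambda x, spec, rng: random_noise(x, spec.magnitude, rng),
    "time_warp": lambda x, spec, rng: time_warp(x, spec.magnitude, rng, spec.n_knots),
}


def apply_augmentation(
    x: np.ndarray, spec: AugmentationSpec, rng: np.random.Generator
) -> np.ndarray:
    if x.ndim != 3:
        raise ValueError(f"expected a (batch, T, F) array, got shape {x.shape}")
    return AUGMENTATIONS[spec.name](x, spec, rng)


def make_views(
    batch: np.ndarray, spec: AugmentationSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two independently augmented copies of every window in the batch."""
    return apply_augmentation(batch, spec, rng), apply_augmentation(batch, spec, rng)
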