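"""Encoder, attention, projection head, and classifier heads.

The encoder maps a standardized window (10 timesteps x F features) to a
64-dimensional embedding:

    conv1d(32 filters, kernel 3, ReLU, dropout 0.1)
    -> conv1d(64 filters, kernel 3, ReLU, dropout 0.1)
    -> LSTM(64 units, all hidden states)
    -> multiplicative self-attention over the hidden-state sequence
    -> global max-pool over the time axis

Multiplicative attention scores every pair of hidden states,
``e[t, t'] = h_t^T W_a h_t' + b_a``, softmax-normalizes each row into
weights, and mixes the states into context vectors
``c_t = sum_t' alpha[t, t'] h_t'``.

For contrastive pre-training a 3-layer projection head (256 -> 128 -> 64,
ReLU on the hidden layers) maps the embedding into the loss space; it is
discarded afterwards. Downstream classification uses either a single
dense softmax layer (linear probe) or a 2-layer MLP head (fine-tuning).

Convolutions use same-padding so the attention layer always sees the full
10-step sequence; padding does not change parameter counts. For F = 84
input features the encoder plus projection head has exactly 109,217
trainable parameters; F = 80 gives 108,833 (only the first convolution's
kernel changes, by 4 * 3 * 32 = 384).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, softmax, stack

__all__ = [
    "EncoderConfig",
    "Dense",
    "Conv1DSame",
    "LSTM",
    "MultiplicativeAttention",
    "Encoder",
    "ProjectionHead",
    "LinearProbe",
    "MLPHead",
    "PretrainModel",
    "count_trainable_parameters",
    "parameter_size_kb",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters (defaults pin the reference network)."""

    n_features: int = 84
    n_timesteps: int = 10
    conv_filters: tuple[int, int] = (32, 64)
    kernel_size: int = 3
    conv_dropout: float = 0.1
    l2_strength: float = 1e-4
    lstm_units: int = 64
    attention_regularizer: float = 1e-4
    use_attention: bool = True  # False ablates the attention layer entirely
    projection_dims: tuple[int, int, int] = (256, 128, 64)

    def __post_init__(self):
        if self.n_features <= 0 or self.n_timesteps <= 0:
            raise ValueError("input shape entries must be positive")
        if min(self.conv_filters) <= 0 or self.kernel_size <= 0 or self.lstm_units <= 0:
            raise ValueError("layer sizes must be positive")


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Module:
    """Tiny parameter-container convention shared by all layers."""

    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()


class Dense(Module):
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class Conv1DSame(Module):
    """1-D convolution over the time axis with same padding.

    Kernel shape (K, F_in, F_out); implemented as a sum of shifted
    matrix products, which keeps the whole op inside the autodiff tape.
    """

    def __init__(self, rng, n_in: int, n_out: int, kernel_size: int):
        self.kernel_size = kernel_size
        self.W = _glorot(
            rng, (kernel_size, n_in, n_out), kernel_size * n_in, kernel_size * n_out
        )
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        K = self.kernel_size
        left = (K - 1) // 2
        xp = x.pad_axis(1, left, K - 1 - left)
        out = None
        for k in range(K):
            term = xp[:, k : k + T, :] @ self.W[k]
            out = term if out is None else out + term
        return out + self.b

    def parameters(self):
        return [self.W, self.b]


class LSTM(Module):
    """Single-layer LSTM returning all hidden states (B, T, H).

    Standard gate formulation (input, forget, cell, output), biases, no
    peepholes: 4 * ((F_in + H) * H + H) parameters.
    """

    def __init__(self, rng, n_in: int, n_units: int):
        self.n_units = n_units
        self.Wx = _glorot(rng, (n_in, 4 * n_units), n_in, 4 * n_units)
        self.Wh = _glorot(rng, (n_units, 4 * n_units), n_units, 4 * n_units)
        b = np.zeros(4 * n_units)
        b[n_units : 2 * n_units] = 1.0  # forget-gate bias init
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        H = self.n_units
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        states = []
        for t in range(T):
            z = x[:, t, :] @ self.Wx + h @ self.Wh + self.b
            i = z[:, 0:H].sigmoid()
            f = z[:, H : 2 * H].sigmoid()
            g = z[:, 2 * H : 3 * H].tanh()
            o = z[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            states.append(h)
        return stack(states, axis=1)

    def parameters(self):
        return [self.Wx, self.Wh, self.b]


class MultiplicativeAttention(Module):
    """Pairwise multiplicative self-attention over a hidden-state sequence.

    ``W_a`` is (H, H) and the bias is a single scalar; the layer has no
    output projection.
    """

    def __init__(self, rng, n_units: int):
        self.Wa = _glorot(rng, (n_units, n_units), n_units, n_units)
        self.ba = Tensor(np.zeros(()), requires_grad=True)

    def __call__(self, H: Tensor) -> tuple[Tensor, Tensor]:
        """Return (A, C): attention weights (.., T, T) and contexts (.., T, H)."""
        scores = (H @ self.Wa) @ H.swapaxes(-1, -2) + self.ba
        A = softmax(scores, axis=-1)
        C = A @ H
        return A, C

    def parameters(self):
        return [self.Wa, self.ba]


def _dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rng is None or rate <= 0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


class Encoder(Module):
    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        c1, c2 = config.conv_filters
        self.conv1 = Conv1DSame(rng, config.n_features, c1, config.kernel_size)
        self.conv2 = Conv1DSame(rng, c1, c2, config.kernel_size)
        self.lstm = LSTM(rng, c2, config.lstm_units)
        self.attention = (
            MultiplicativeAttention(rng, config.lstm_units) if config.use_attention else None
        )

    def __call__(
        self, x: Tensor, training: bool = False, rng: np.random.Generator | None = None
    ) -> Tensor:
        if x.shape[1:] != (self.config.n_timesteps, self.config.n_features):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match configured "
                f"({self.config.n_timesteps}, {self.config.n_features})"
            )
        drop_rng = rng if training else None
        h = _dropout(self.conv1(x).relu(), self.config.conv_dropout, drop_rng)
        h = _dropout(self.conv2(h).relu(), self.config.conv_dropout, drop_rng)
        H = self.lstm(h)
        if self.attention is not None:
            _, H = self.attention(H)  # context sequence replaces hidden states
        return H.max(axis=1)  # global max-pool over time

    def l2_penalty(self) -> Tensor:
        """Regularization: conv kernels and the attention weight matrix."""
        cfg = self.config
        pen = (self.conv1.W**2).sum() * cfg.l2_strength
        pen = pen + (self.conv2.W**2).sum() * cfg.l2_strength
        if self.attention is not None:
            pen = pen + (self.attention.Wa**2).sum() * cfg.attention_regularizer
        return pen

    def parameters(self):
        params = (
            self.conv1.parameters() + self.conv2.parameters() + self.lstm.parameters()
        )
        if self.attention is not None:
            params = params + self.attention.parameters()
        return params


class ProjectionHead(Module):
    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        d0, d1, d2 = config.projection_dims
        self.fc0 = Dense(rng, config.lstm_units, d0)
        self.fc1 = Dense(rng, d0, d1)
        self.fc2 = Dense(rng, d1, d2)

    def __call__(self, s: Tensor) -> Tensor:
        return self.fc2(self.fc1(self.fc0(s).relu()).relu())

    def parameters(self):
        return self.fc0.parameters() + self.fc1.parameters() + self.fc2.parameters()


class LinearProbe(Module):
    """Single dense layer; softmax is folded into the cross-entropy loss."""

    def __init__(self, rng, n_in: int, n_classes: int):
        self.fc = Dense(rng, n_in, n_classes)

    def __call__(self, s: Tensor) -> Tensor:
        return self.fc(s)

    def parameters(self):
        return self.fc.parameters()


class MLPHead(Module):
    """Two-layer prediction head: dense-ReLU then dense (softmax in the loss)."""

    def __init__(self, rng, n_in: int, n_classes: int, hidden: int = 64):
        self.fc1 = Dense(rng, n_in, hidden)
        self.fc2 = Dense(rng, hidden, n_classes)

    def __call__(self, s: Tensor) -> Tensor:
        return self.fc2(self.fc1(s).relu())

    def parameters(self):
        return self.fc1.parameters() + self.fc2.parameters()


class PretrainModel(Module):
    """Encoder plus projection head, as trained by the contrastive loss."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        self.encoder = Encoder(config, rng)
        self.projection = ProjectionHead(config, rng)

    def __call__(self, x: Tensor, training: bool = False, rng=None) -> Tensor:
        return self.projection(self.encoder(x, training=training, rng=rng))

    def parameters(self):
        return self.encoder.parameters() + self.projection.parameters()


def count_trainable_parameters(module: Module) -> int:
    """Exact number of trainable scalars in a module."""
    return int(sum(p.size for p in module.parameters()))


def parameter_size_kb(n_params: int) -> float:
    """Model size in KB at 4 bytes (float32) per parameter."""
    return n_params * 4 / 1024


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(path: str | Path, module: Module, config: EncoderConfig) -> None:
    """Persist weights plus architecture config (versioned npz container)."""
    arrays = {f"param_{i}": a for i, a in enumerate(module.state_arrays())}
    meta = json.dumps({"version": CHECKPOINT_VERSION, "config": asdict(config)})
    np.savez(path, __meta__=np.array(meta), **arrays)


def load_checkpoint(
    path: str | Path, factory=None
) -> tuple[Module, EncoderConfig]:
    """Rebuild a module from a checkpoint; default factory is PretrainModel."""
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        arrays = [archive[f"param_{i}"] for i in range(len(archive.files) - 1)]
    if meta["version"] != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta['version']}")
    cfg_dict = meta["config"]
    for key in ("conv_filters", "projection_dims"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = EncoderConfig(**cfg_dict)
    module = (factory or PretrainModel)(config, np.random.default_rng(0))
    module.load_state_arrays(arrays)
    return module, config
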