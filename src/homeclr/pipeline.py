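"""Experimental protocols: contrastive pre-training, linear evaluation,
semi-supervised fine-tuning, and cross-home transfer.

Default budgets follow the reference configuration: pre-training for 100
epochs at batch 512 with SGD under a cosine-decayed learning rate (0.1,
1000 decay steps) and NT-Xent at temperature 0.1; linear evaluation for
300 epochs and fine-tuning for 200 epochs, both with Adam at 1e-3 and
batch 128 under cross-entropy. SAM can wrap the optimizer in any phase, so
the four model variants (plain contrastive, +SAM, +attention, +both) are
all expressible. Reports carry F1 / accuracy / precision / recall (weighted
averages, in percent), a per-class table, and the confusion matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
)

from .augment import AugmentationSpec, make_views
from .autodiff import Tensor
from .features import WindowedDataset
from .model import (
    Encoder,
    EncoderConfig,
    LinearProbe,
    MLPHead,
    PretrainModel,
)
from .optim import SAM, Adam, SAMConfig, SGD, cosine_decay_lr, nt_xent_loss, softmax_cross_entropy

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "EvalReport",
    "compute_metrics",
    "pretrain",
    "encode_windows",
    "linear_evaluate",
    "fine_tune",
    "transfer_protocol",
    "majority_baseline",
]


@dataclass(frozen=True)
class TrainConfig:
    """One phase's training budget and optimizer settings."""

    phase: str = "pretrain"
    epochs: int = 100
    batch_size: int = 512
    optimizer: str = "sgd"
    learning_rate: float = 0.1
    decay_steps: int = 1000  # cosine decay horizon (SGD phases only)
    temperature: float = 0.1
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    sam: bool = True
    sam_rho: float = 0.05
    weight_decay: float = 0.0
    label_fraction: float = 1.0
    seed: int = 0

    @classmethod
    def for_pretraining(cls, **overrides) -> "TrainConfig":
        return replace(cls(), **overrides)

    @classmethod
    def for_linear_eval(cls, **overrides) -> "TrainConfig":
        base = cls(
            phase="linear_eval", epochs=300, batch_size=128, optimizer="adam",
            learning_rate=1e-3,
        )
        return replace(base, **overrides)

    @classmethod
    def for_fine_tuning(cls, **overrides) -> "TrainConfig":
        base = cls(
            phase="fine_tune", epochs=200, batch_size=128, optimizer="adam",
            learning_rate=1e-3,
        )
        return replace(base, **overrides)


@dataclass
class EvalReport:
    """Classification quality of one protocol run (percentages in [0, 100])."""

    f1: float
    accuracy: float
    precision: float
    recall: float
    per_class: pd.DataFrame
    confusion: np.ndarray
    classes: list[str]
    phase: str = ""
    label_fraction: float = 1.0

    def summary(self) -> str:
        lines = [
            f"phase: {self.phase or 'n/a'}   label fraction: {self.label_fraction:.0%}",
            f"F1 (weighted): {self.f1:.2f}%   accuracy: {self.accuracy:.2f}%",
            f"precision: {self.precision:.2f}%   recall: {self.recall:.2f}%",
            "",
            self.per_class.to_string(),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "label_fraction": self.label_fraction,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
        }


def compute_metrics(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    classes: Sequence[str] | None = None,
    *,
    average: str = "weighted",
    phase: str = "",
    label_fraction: float = 1.0,
) -> EvalReport:
    """Accuracy plus (weighted by default) F1/precision/recall, in percent."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if not y_true or len(y_true) != len(y_pred):
        raise ValueError("need equal-length, non-empty label sequences")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    classes = list(classes)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average=None, zero_division=0
    )
    w_prec, w_rec, w_f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average=average, zero_division=0
    )
    per_class = pd.DataFrame(
        {
            "precision": prec * 100,
            "recall": rec * 100,
            "f1": f1 * 100,
            "support": support,
        },
        index=classes,
    )
    return EvalReport(
        f1=float(w_f1) * 100,
        accuracy=float(accuracy_score(y_true, y_pred)) * 100,
        precision=float(w_prec) * 100,
        recall=float(w_rec) * 100,
        per_class=per_class,
        confusion=confusion_matrix(y_true, y_pred, labels=classes),
        classes=classes,
        phase=phase,
        label_fraction=label_fraction,
    )


def majority_baseline(
    train_labels: Sequence[str], test_labels: Sequence[str]
) -> EvalReport:
    """Predict the most frequent training class everywhere."""
    majority = pd.Series(list(train_labels)).value_counts().idxmax()
    return compute_metrics(
        list(test_labels), [majority] * len(test_labels), phase="majority_baseline"
    )


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def pretrain(
    dataset: WindowedDataset,
    config: TrainConfig,
    encoder_config: EncoderConfig | None = None,
) -> tuple[PretrainModel, list[float]]:
    """Contrastive pre-training; labels are never read.

    Returns the trained model and the per-epoch mean NT-Xent loss.
    """
    if len(dataset) < 2:
        raise ValueError("pre-training needs at least 2 windows")
    enc_cfg = encoder_config or EncoderConfig(
        n_features=dataset.n_features, n_timesteps=dataset.data.shape[1]
    )
    rng_init, rng_aug, rng_batch, rng_drop = _rngs(config.seed, 4)
    model = PretrainModel(enc_cfg, rng_init)
    base = SGD(model.parameters(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    sam = SAM(base, SAMConfig(rho=config.sam_rho if config.sam else 0.0))
    X = dataset.data
    step = 0
    epoch_losses: list[float] = []
    for epoch in range(config.epochs):
        losses = []
        for idx in _batches(len(X), config.batch_size, rng_batch):
            if len(idx) < 2:
                continue
            vi, vj = make_views(X[idx], config.augmentation, rng_aug)
            paired = np.empty((2 * len(idx),) + X.shape[1:])
            paired[0::2], paired[1::2] = vi, vj
            xt = Tensor(paired)
            drop_state = rng_drop.bit_generator.state

            def loss_fn():
                # replay the same dropout masks on SAM's second pass
                rng_drop.bit_generator.state = drop_state
                z = model(xt, training=True, rng=rng_drop)
                return nt_xent_loss(z, config.temperature) + model.encoder.l2_penalty()

            base.lr = cosine_decay_lr(step, config.learning_rate, config.decay_steps)
            losses.append(sam.step(loss_fn))
            step += 1
        epoch_losses.append(float(np.mean(losses)))
        logger.info("pretrain epoch %d/%d loss %.4f", epoch + 1, config.epochs,
                    epoch_losses[-1])
    return model, epoch_losses


def encode_windows(
    encoder: Encoder, data: np.ndarray, batch_size: int = 512
) -> np.ndarray:
    """Frozen-encoder embeddings (dropout off), computed in chunks."""
    outs = [
        encoder(Tensor(data[start : start + batch_size])).data
        for start in range(0, len(data), batch_size)
    ]
    return np.concatenate(outs, axis=0) if outs else np.empty((0, encoder.config.lstm_units))


def _class_index(train_ds: WindowedDataset, test_ds: WindowedDataset) -> list[str]:
    train_classes = {lab for lab in train_ds.labels if lab is not None}
    test_classes = {lab for lab in test_ds.labels if lab is not None}
    unseen = test_classes - train_classes
    if unseen:
        logger.warning("test split contains class(es) unseen in training: %s "
                       "(they will be scored as errors)", sorted(unseen))
    return sorted(train_classes | test_classes)


def linear_evaluate(
    model: PretrainModel | Encoder,
    train_ds: WindowedDataset,
    test_ds: WindowedDataset,
    config: TrainConfig,
) -> EvalReport:
    """Linear probe on the frozen encoder (projection head dropped).

    The encoder is never updated: train and test windows are embedded once
    and only the single dense softmax layer is trained.
    """
    encoder = model.encoder if isinstance(model, PretrainModel) else model
    train_ds = train_ds.labeled_subset()
    if len(train_ds) == 0:
        raise ValueError("linear evaluation needs labeled training windows")
    classes = _class_index(train_ds, test_ds)
    class_to_idx = {c: i for i, c in enumerate(classes)}
    emb_train = encode_windows(encoder, train_ds.data)
    emb_test = encode_windows(encoder, test_ds.data)
    y_train = np.array([class_to_idx[lab] for lab in train_ds.labels])

    rng_init, rng_batch = _rngs(config.seed, 2)
    probe = LinearProbe(rng_init, encoder.config.lstm_units, len(classes))
    base = Adam(probe.parameters(), lr=config.learning_rate,
                weight_decay=config.weight_decay)
    sam = SAM(base, SAMConfig(rho=config.sam_rho if config.sam else 0.0))
    for _ in range(config.epochs):
        for idx in _batches(len(emb_train), config.batch_size, rng_batch):
            xt, yt = Tensor(emb_train[idx]), y_train[idx]
            sam.step(lambda: softmax_cross_entropy(probe(xt), yt))
    pred_idx = np.argmax(probe(Tensor(emb_test)).data, axis=1)
    y_pred = [classes[i] for i in pred_idx]
    return compute_metrics(
        list(test_ds.labels), y_pred, classes,
        phase="linear_eval", label_fraction=config.label_fraction,
    )


def _clone_encoder(encoder: Encoder) -> Encoder:
    clone = Encoder(encoder.config, np.random.default_rng(0))
    clone.load_state_arrays(encoder.state_arrays())
    return clone


def fine_tune(
    model: PretrainModel | Encoder,
    train_ds: WindowedDataset,
    test_ds: WindowedDataset,
    config: TrainConfig,
    head_hidden: int = 64,
) -> EvalReport:
    """Unfreeze the (copied) encoder and train it with a 2-layer MLP head."""
    source = model.encoder if isinstance(model, PretrainModel) else model
    encoder = _clone_encoder(source)  # the caller's encoder stays frozen
    train_ds = train_ds.labeled_subset()
    if len(train_ds) == 0:
        raise ValueError("fine-tuning needs a non-empty labeled subset")
    classes = _class_index(train_ds, test_ds)
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y_train = np.array([class_to_idx[lab] for lab in train_ds.labels])

    rng_init, rng_batch, rng_drop = _rngs(config.seed, 3)
    head = MLPHead(rng_init, encoder.config.lstm_units, len(classes), hidden=head_hidden)
    params = encoder.parameters() + head.parameters()
    base = Adam(params, lr=config.learning_rate, weight_decay=config.weight_decay)
    sam = SAM(base, SAMConfig(rho=config.sam_rho if config.sam else 0.0))
    X = train_ds.data
    for _ in range(config.epochs):
        for idx in _batches(len(X), config.batch_size, rng_batch):
            xt, yt = Tensor(X[idx]), y_train[idx]
            drop_state = rng_drop.bit_generator.state

            def loss_fn():
                rng_drop.bit_generator.state = drop_state
                logits = head(encoder(xt, training=True, rng=rng_drop))
                return softmax_cross_entropy(logits, yt) + encoder.l2_penalty()

            sam.step(loss_fn)
    logits = head(Tensor(encode_windows(encoder, test_ds.data)))
    y_pred = [classes[i] for i in np.argmax(logits.data, axis=1)]
    return compute_metrics(
        list(test_ds.labels), y_pred, classes,
        phase="fine_tune", label_fraction=config.label_fraction,
    )


def transfer_protocol(
    source_ds: WindowedDataset,
    target_train: WindowedDataset,
    target_test: WindowedDataset,
    pretrain_config: TrainConfig,
    probe_config: TrainConfig,
    finetune_config: TrainConfig,
) -> tuple[EvalReport, EvalReport]:
    """Pre-train on the (unlabeled) source home, evaluate on the target home.

    Returns (linear-evaluation report, fine-tuning report), both tagged
    ``transfer``; the same pre-trained encoder backs both downstream runs.
    """
    if source_ds.n_features != target_train.n_features:
        raise ValueError(
            f"feature dimensionality mismatch: source {source_ds.n_features} "
            f"vs target {target_train.n_features}"
        )
    model, _ = pretrain(source_ds, pretrain_config)
    probe_report = linear_evaluate(model, target_train, target_test, probe_config)
    ft_report = fine_tune(model, target_train, target_test, finetune_config)
    probe_report.phase = "transfer_linear_eval"
    ft_report.phase = "transfer_fine_tune"
    return probe_report, ft_report
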