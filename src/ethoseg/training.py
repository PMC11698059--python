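"""Loss functions and the seeded training loop with best-on-validation
checkpointing.

The Generalized Dice loss weights each class by the inverse square of its
target volume, which keeps gradient pressure on minority behaviors in a
heavily imbalanced ethogram; cross-entropy is used for the human-activity
U-Net family.  Training regenerates a fresh balanced window batch every
epoch (epoch-derived seed) while validation windows stay fixed so that
checkpoint comparisons across epochs are on identical data; the weights at
the best validation macro F1 are restored at the end.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .metrics import macro_f1_score
from .nn.layers import Adam
from .nn.models import SegModel
from .windows import WindowBatch

GDL_EPS = 1e-6


class TrainingDivergedError(RuntimeError):
    """Non-finite loss encountered (reports the epoch index)."""


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def generalized_dice_loss(targets: np.ndarray, probs: np.ndarray,
                          eps: float = GDL_EPS) -> float:
    """GDL = 1 - 2 (sum_l w_l sum_n r_ln p_ln) / (sum_l w_l sum_n (r_ln + p_ln))
    with w_l = 1 / (sum_n r_ln + eps)^2.

    ``targets`` is one-hot, ``probs`` rows are probability distributions;
    both are (n_samples, C) after flattening any leading axes.  0 at perfect
    prediction.  Classes absent from the targets are given weight 0 (their
    eps-guarded inverse-square weight would otherwise dominate the sums and
    flatten the loss to 1 with vanishing gradients); the loss stays finite
    and in [0, 1].
    """
    loss, _ = _gdl_value_grad(targets, probs, eps)
    return loss


def _gdl_value_grad(targets: np.ndarray, probs: np.ndarray,
                    eps: float = GDL_EPS) -> tuple[float, np.ndarray]:
    r = np.asarray(targets, dtype=np.float64).reshape(-1, targets.shape[-1])
    p = np.asarray(probs, dtype=np.float64).reshape(-1, probs.shape[-1])
    if r.shape != p.shape:
        raise ValueError(f"shape mismatch: targets {r.shape} vs probs {p.shape}")
    r_sum = r.sum(axis=0)
    # classes absent from the batch get weight 0: the eps-guarded weight
    # 1/eps^2 would otherwise dwarf every present class and kill the
    # gradient signal for the whole batch
    w = np.where(r_sum > 0, 1.0 / (r_sum + eps) ** 2, 0.0)
    num = float(np.sum(w * np.sum(r * p, axis=0)))
    den = float(np.sum(w * np.sum(r + p, axis=0)))
    loss = 1.0 - 2.0 * num / den
    # d/dp_ln = -2 (w_l r_ln den - num w_l) / den^2
    grad = -2.0 * (w[None, :] * r * den - num * w[None, :]) / den**2
    return loss, grad.reshape(probs.shape)


def cross_entropy_loss(targets: np.ndarray, probs: np.ndarray,
                       eps: float = 1e-12) -> float:
    """Mean per-timestep categorical cross-entropy."""
    r = np.asarray(targets, dtype=np.float64).reshape(-1, targets.shape[-1])
    p = np.asarray(probs, dtype=np.float64).reshape(-1, probs.shape[-1])
    if r.shape != p.shape:
        raise ValueError(f"shape mismatch: targets {r.shape} vs probs {p.shape}")
    return float(-np.mean(np.sum(r * np.log(p + eps), axis=1)))


def loss_and_dlogits(loss_name: str, targets: np.ndarray, logits: np.ndarray
                     ) -> tuple[float, np.ndarray]:
    """Loss value and gradient w.r.t. logits for a (n, C, ws) logit batch.

    ``targets`` is (n, ws, C) one-hot.  The softmax over the class axis is
    folded into the gradient.
    """
    z = logits.transpose(0, 2, 1).astype(np.float64)  # (n, ws, C)
    z = z - z.max(axis=2, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=2, keepdims=True)
    if loss_name == "gdl":
        loss, dp = _gdl_value_grad(targets, p)
        inner = np.sum(dp * p, axis=2, keepdims=True)
        dz = p * (dp - inner)
    elif loss_name == "xent":
        n_samples = p.shape[0] * p.shape[1]
        loss = cross_entropy_loss(targets, p)
        dz = (p - targets) / n_samples
    else:
        raise ValueError(f"unknown loss {loss_name!r}")
    return loss, dz.transpose(0, 2, 1).astype(np.float32)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Hyperparameters for one training/fine-tuning run."""

    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-4
    loss: str = "gdl"  # "gdl" | "xent"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate < 0:
            raise ValueError("epochs/batch_size >= 1, learning_rate >= 0")


#: Pre-training and fine-tuning configurations at full study scale.
PAPER_PRETRAIN_VNET = TrainConfig(epochs=30, batch_size=32,
                                  learning_rate=1e-4, loss="gdl")
PAPER_PRETRAIN_UNET = TrainConfig(epochs=50, batch_size=32,
                                  learning_rate=1e-3, loss="xent")
PAPER_FINETUNE = TrainConfig(epochs=20, batch_size=32,
                             learning_rate=1e-4, loss="gdl")


@dataclass
class RunRecord:
    """Per-epoch curves and the best-on-validation checkpoint."""

    train_loss: list[float] = field(default_factory=list)
    val_metric: list[float] = field(default_factory=list)  # macro F1 (%)
    best_epoch: int = -1
    best_weights: dict[str, np.ndarray] = field(default_factory=dict)
    wall_time_s: float = 0.0  # informational only

    @property
    def best_val_metric(self) -> float:
        return self.val_metric[self.best_epoch] if self.val_metric else float("nan")


def _validation_macro_f1(model: SegModel, val_batch: WindowBatch,
                         batch_size: int) -> float:
    preds, trues = [], []
    for i in range(0, len(val_batch), batch_size):
        probs = model.predict_proba(val_batch.inputs[i:i + batch_size])
        preds.append(probs.argmax(axis=2).ravel())
        trues.append(val_batch.targets[i:i + batch_size].argmax(axis=2).ravel())
    classes = list(range(model.spec.nb_behaviors))
    return macro_f1_score(np.concatenate(trues), np.concatenate(preds), classes)


def train(model: SegModel,
          train_source: Callable[[int], WindowBatch],
          val_source: WindowBatch,
          config: TrainConfig) -> tuple[SegModel, RunRecord]:
    """Optimize the model's trainable parameters; checkpoint on best
    validation macro F1 and restore those weights before returning.

    ``train_source(epoch)`` must yield a fresh (epoch-seeded) WindowBatch;
    any freeze plan must already be applied.  Fully reproducible for a given
    (model seed, config.seed, sources).
    """
    t0 = time.perf_counter()
    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    opt = Adam(params, lr=config.learning_rate)
    record = RunRecord()
    best_metric = -np.inf

    for epoch in range(config.epochs):
        batch = train_source(epoch)
        order = rng.permutation(len(batch))
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, len(batch), config.batch_size):
            sel = order[i:i + config.batch_size]
            logits = model.forward(batch.inputs[sel])
            loss, dz = loss_and_dlogits(config.loss, batch.targets[sel], logits)
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(dz)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        record.train_loss.append(epoch_loss / max(n_batches, 1))
        metric = _validation_macro_f1(model, val_source, config.batch_size)
        record.val_metric.append(metric)
        if metric > best_metric:
            best_metric = metric
            record.best_epoch = epoch
            record.best_weights = model.get_weights()

    if record.best_weights:
        model.set_weights(record.best_weights)
    record.wall_time_s = time.perf_counter() - t0
    return model, record


def repeat_runs(run_fn: Callable[[int], RunRecord], n_runs: int,
                master_seed: int = 0) -> list[RunRecord]:
    """Repeat an experiment with run-index-derived seeds.

    ``run_fn(seed)`` performs one full run; seeds are spawned from the
    master seed so the list of records is reproducible as a whole.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(master_seed).spawn(n_runs)]
    return [run_fn(seed) for seed in seeds]
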