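"""Phase I supervised training against binary segment masks.

The network is trained to reproduce the three reference segment masks with
a binary cross-entropy loss, on a seeded 70/30 train/validation split.
Each training example is re-drawn every epoch with a fresh random time
offset (up to +/-100 ms) so the model does not overfit one beat/window
synchronization.  Training stops early when the validation loss has not
improved for ``patience`` epochs and the parameters of the best
(minimum-validation-loss) epoch are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._nn import Adam
from .beat_model import masks_from_fiducials
from .nets import NetworkModel, make_input
from .synth import random_time_offset

__all__ = ["TrainConfig", "TrainingRecord", "bce_loss", "split_dataset",
           "train", "sweep_learning_rates", "LEARNING_RATE_SWEEP"]

EPS = 1e-7  # probability clip keeping the log finite

#: learning rates compared when selecting a training configuration
LEARNING_RATE_SWEEP = (0.0001, 0.0005, 0.001, 0.005, 0.01)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.005
    max_epochs: int = 1000
    patience: int = 150
    val_fraction: float = 0.30
    batch_size: int = 64
    augment_shift_ms: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


@dataclass
class TrainingRecord:
    """Per-epoch losses plus the best/stopped epoch (1-based)."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0


def bce_loss(pred: np.ndarray, ref) -> float:
    """Mean binary cross-entropy over all entries.

    ``pred`` holds probabilities (clipped into ``[1e-7, 1-1e-7]``), ``ref``
    binary targets of the same shape (a SegmentMasks is accepted).
    """
    ref_values = getattr(ref, "values", ref)
    p = np.asarray(pred, dtype=np.float64)
    x = np.asarray(ref_values, dtype=np.float64)
    if p.shape != x.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs ref {x.shape}")
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(-np.mean(x * np.log(p) + (1.0 - x) * np.log1p(-p)))


def split_dataset(dataset, val_fraction: float, seed: int):
    """Seeded shuffled split into (train, val); |val| = round(fraction*n)."""
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    n_val = int(round(val_fraction * n))
    order = np.random.default_rng(seed).permutation(n)
    val = [dataset[i] for i in order[:n_val]]
    tr = [dataset[i] for i in order[n_val:]]
    return tr, val


def _tensors(items, augment_rng=None, shift_ms: float = 0.0):
    """Stack inputs and targets, optionally with a fresh time offset each."""
    xs, ts = [], []
    for beat, fids in items:
        if augment_rng is not None and shift_ms > 0:
            beat, fids = random_time_offset(beat, fids, max_shift_ms=shift_ms,
                                            rng=augment_rng)
        xs.append(make_input(beat).values)
        ts.append(masks_from_fiducials(fids).values)
    return np.stack(xs), np.stack(ts)


def train(model: NetworkModel, dataset, cfg: TrainConfig):
    """Fit ``model`` on annotated ``(beat, FiducialSet)`` pairs.

    Returns ``(model, TrainingRecord)``; the model carries the parameters
    of the minimum-validation-loss epoch.  Fully reproducible given
    ``cfg.seed``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_shuffle, rng_augment, rng_dropout = map(np.random.default_rng,
                                                ss.spawn(3))
    train_set, val_set = split_dataset(dataset, cfg.val_fraction, cfg.seed)
    if not train_set or not val_set:
        raise ValueError("split produced an empty subset")

    x_fit, _ = _tensors(train_set)
    model.fit_normalizer(x_fit)
    model.set_dropout_rng(rng_dropout)
    x_val, t_val = _tensors(val_set)

    opt = Adam(cfg.learning_rate)
    record = TrainingRecord()
    best_loss = np.inf
    best_state = model.get_state()
    n_train = len(train_set)

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng_shuffle.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, cfg.batch_size):
            batch = [train_set[i] for i in order[start:start + cfg.batch_size]]
            xb, tb = _tensors(batch, rng_augment, cfg.augment_shift_ms)
            probs = model.forward_batch(xb, train=True)
            loss = bce_loss(probs, tb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss}")
            epoch_loss += loss * len(batch)
            model.zero_grads()
            model.backward_from_logits((probs - tb) / probs.size)
            opt.step(model.parameters(), model.gradients())
        record.train_loss.append(epoch_loss / n_train)

        val_probs = model.forward_batched(x_val, chunk=cfg.batch_size)
        val_loss = bce_loss(val_probs, t_val)
        record.val_loss.append(val_loss)
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.get_state()
            record.best_epoch = epoch
        record.stopped_epoch = epoch
        if epoch - record.best_epoch > cfg.patience:
            break

    model.set_state(best_state)
    return model, record


def sweep_learning_rates(config, dataset, cfg: TrainConfig,
                         rates=LEARNING_RATE_SWEEP, seed: int = 0):
    """Train one fresh model per learning rate under identical conditions.

    Returns ``{rate: (model, TrainingRecord)}``; every run starts from the
    same initialization and data split, so records are comparable.
    """
    from .nets import build
    results = {}
    for rate in rates:
        model = build(config, seed=seed)
        results[rate] = train(model, dataset,
                              replace(cfg, learning_rate=rate))
    return results
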