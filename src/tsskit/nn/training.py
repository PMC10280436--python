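"""Training protocol: Adam, batch 32, lr 0.001, binary cross-entropy,
at most 100 epochs with early stopping after 10 epochs without validation
improvement, restoring the best-validation weights."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..dataset import DatasetSplit
from ..encoding import encode_batch
from ..errors import ConfigurationError
from .core import Adam, Network, bce_with_logits


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def validate(self) -> None:
        if min(self.batch_size, self.max_epochs, self.patience) < 1 or self.learning_rate <= 0:
            raise ConfigurationError("training config fields must be positive")
        if self.patience >= self.max_epochs:
            raise ConfigurationError("patience must be smaller than max_epochs")
        if self.optimizer != "adam":
            raise ConfigurationError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    stopped_epoch: int = 0  # 1-based epoch at which training stopped
    best_epoch: int = 0  # 1-based epoch of the best validation loss


def stopped_epoch_from_trace(val_losses, patience: int) -> int:
    """Epoch (1-based) at which early stopping halts for a given loss trace.

    Stops after ``patience`` consecutive epochs without strict improvement
    over the best validation loss seen so far; returns the full trace length
    if the budget is never exhausted.
    """
    best = np.inf
    stale = 0
    for epoch, loss in enumerate(val_losses, start=1):
        if loss < best:
            best = loss
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                return epoch
    return len(val_losses)


def train_arrays(
    model: Network,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainingConfig = TrainingConfig(),
) -> TrainingHistory:
    """Train in place on pre-encoded arrays; returns the epoch history."""
    config.validate()
    if len(X_train) == 0 or len(X_val) == 0:
        raise ConfigurationError("train and validation partitions must be non-empty")
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.params, lr=config.learning_rate)
    history = TrainingHistory()
    best_val = np.inf
    best_weights = model.get_weights()
    stale = 0
    y_train = np.asarray(y_train, dtype=np.float64)
    y_val = np.asarray(y_val, dtype=np.float64)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(X_train))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward_logits(X_train[idx], train=True)
            loss, grad = bce_with_logits(logits, y_train[idx])
            model.backward(grad)
            optimizer.step(model.grads)
            epoch_loss += loss * len(idx)
        history.train_loss.append(epoch_loss / len(X_train))

        val_logits_parts = [
            model.forward_logits(X_val[i : i + 256], train=False)
            for i in range(0, len(X_val), 256)
        ]
        val_loss, _ = bce_with_logits(np.concatenate(val_logits_parts), y_val)
        history.val_loss.append(val_loss)

        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
            history.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                history.stopped_epoch = epoch
                break
        history.stopped_epoch = epoch
    model.set_weights(best_weights)
    return history


def train(model: Network, split: DatasetSplit, config: TrainingConfig = TrainingConfig()) -> TrainingHistory:
    """Train on a chromosome-holdout split (one-hot encoding done here)."""
    if len(split.train) == 0 or len(split.validation) == 0:
        raise ConfigurationError("split must have non-empty train and validation partitions")
    X_train = encode_batch(split.train.sequences())
    X_val = encode_batch(split.validation.sequences())
    return train_arrays(
        model, X_train, split.train.labels(), X_val, split.validation.labels(), config
    )


def predict_proba(model: Network, instances) -> np.ndarray:
    """Probabilities for one-hot encoded arrays or raw sequence lists."""
    if len(instances) == 0:
        return np.zeros(0)
    if isinstance(instances[0], str):
        instances = encode_batch(list(instances))
    return model.predict_proba(np.asarray(instances, dtype=np.float64))
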