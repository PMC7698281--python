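"""Seeded mini-batch training loop with plateau learning-rate decay."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .losses import sigmoid_binary_cross_entropy, softmax_cross_entropy
from .network import Network
from .optim import Optimizer, ReduceLROnPlateau


class TrainingDivergedError(RuntimeError):
    """Raised when a non-finite loss is encountered during training."""


@dataclass
class TrainingHistory:
    """Per-epoch train/val loss and the learning rate in effect."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_dict(self) -> dict:
        return {"train_loss": self.train_loss, "val_loss": self.val_loss, "lr": self.lr}


def _loss_fn(output: str):
    return sigmoid_binary_cross_entropy if output == "sigmoid" else softmax_cross_entropy


def evaluate_loss(net: Network, x: np.ndarray, y: np.ndarray, batch_size: int = 64) -> float:
    """Mean loss over a dataset in inference mode."""
    fn = _loss_fn(net.output)
    total, count = 0.0, 0
    for i in range(0, x.shape[0], batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        logits = net.forward(xb, training=False)
        loss, _ = fn(logits, yb)
        n = yb.size
        total += loss * n
        count += n
    return total / max(count, 1)


def fit_network(
    net: Network,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None,
    y_val: np.ndarray | None,
    optimizer: Optimizer,
    epochs: int = 50,
    batch_size: int = 32,
    seed: int = 0,
    plateau_patience: int = 3,
    plateau_factor: float = 10.0,
    plateau_min_delta: float = 1e-4,
    verbose: int = 0,
) -> TrainingHistory:
    """Train a network with seeded shuffling and plateau lr decay.

    Identical inputs and seed produce identical histories and parameters.
    Raises :class:`TrainingDivergedError` on a non-finite batch loss.
    """
    if x_train.shape[0] == 0:
        raise ValueError("training set is empty")
    ss = np.random.SeedSequence(seed)
    shuffle_seq, dropout_seq = ss.spawn(2)
    shuffle_rng = np.random.default_rng(shuffle_seq)
    net.set_dropout_rng(dropout_seq)

    fn = _loss_fn(net.output)
    scheduler = ReduceLROnPlateau(
        optimizer, plateau_factor, plateau_patience, plateau_min_delta
    )
    history = TrainingHistory()
    n = x_train.shape[0]
    for epoch in range(epochs):
        perm = shuffle_rng.permutation(n)
        batch_losses = []
        for i in range(0, n, batch_size):
            idx = perm[i : i + batch_size]
            logits = net.forward(x_train[idx], training=True)
            loss, dlogits = fn(logits, y_train[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss {loss} at epoch {epoch}, batch {i // batch_size}"
                )
            net.backward(dlogits)
            optimizer.step(net.layers)
            batch_losses.append(loss)
        history.train_loss.append(float(np.mean(batch_losses)))
        if x_val is not None and x_val.shape[0]:
            vl = evaluate_loss(net, x_val, y_val, batch_size)
            if not np.isfinite(vl):
                raise TrainingDivergedError(f"non-finite validation loss at epoch {epoch}")
        else:
            vl = history.train_loss[-1]
        history.val_loss.append(float(vl))
        history.lr.append(float(optimizer.lr))
        scheduler.update(float(vl))
        if verbose:
            print(
                f"epoch {epoch + 1}/{epochs} train={history.train_loss[-1]:.4f} "
                f"val={vl:.4f} lr={optimizer.lr:g}"
            )
    return history
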