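"""Cross-entropy losses computed from logits, with gradients.

Both losses return ``(mean_loss, dlogits)`` where the gradient is already
divided by the number of predictions, so layer backprop receives d(mean
loss)/d(logits) directly.
"""

from __future__ import annotations

import numpy as np


def _log_softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def softmax(z: np.ndarray) -> np.ndarray:
    return np.exp(_log_softmax(z))


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Categorical cross-entropy from logits.

    ``logits`` is ``(N, C)`` or ``(N, T, C)``; ``y`` holds integer class
    indices of shape ``(N,)`` or ``(N, T)``. For per-second sequence
    labeling every (segment, second) pair counts as one prediction.
    """
    y = np.asarray(y)
    if logits.shape[:-1] != y.shape:
        raise ValueError(f"logits {logits.shape} incompatible with labels {y.shape}")
    logp = _log_softmax(logits)
    picked = np.take_along_axis(logp, y[..., None], axis=-1)[..., 0]
    n = y.size
    loss = float(-picked.sum() / n)
    dlogits = np.exp(logp)
    np.subtract.at(dlogits, (*np.indices(y.shape), y), 1.0)
    return loss, (dlogits / n).astype(logits.dtype)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid_binary_cross_entropy(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Binary cross-entropy from a single logit per sample.

    ``logits`` is ``(N,)`` or ``(N, 1)``; ``y`` holds 0/1 targets.
    """
    z = logits.reshape(-1).astype(np.float64)
    t = np.asarray(y, dtype=np.float64).reshape(-1)
    if z.shape != t.shape:
        raise ValueError("logits and targets must have equal length")
    # log(1 + exp(-|z|)) formulation for numerical stability
    loss = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - t) / z.size
    return loss, dz.reshape(logits.shape).astype(logits.dtype)
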