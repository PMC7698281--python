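"""Sequential network container with layer audits and serialization."""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm1D,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    Layer,
    MaxPool1D,
    ReLU,
    ResidualBlock1D,
    TimeDistributedDense,
)
from .losses import sigmoid, softmax


class Network:
    """A sequential stack of layers ending in logits.

    ``output`` names the output activation ('sigmoid' or 'softmax') applied
    by :meth:`predict_proba`; training losses work on the raw logits.
    """

    def __init__(self, layers: list[Layer], output: str = "softmax") -> None:
        if output not in ("sigmoid", "softmax"):
            raise ValueError("output must be 'sigmoid' or 'softmax'")
        self.layers = layers
        self.output = output

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        chunks = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i : i + batch_size], training=False)
            chunks.append(sigmoid(logits) if self.output == "sigmoid" else softmax(logits))
        return np.concatenate(chunks, axis=0)

    # -- audits -----------------------------------------------------------

    def param_count(self) -> int:
        return sum(layer.param_count() for layer in self.layers)

    def layer_counts(self) -> dict[str, int]:
        """Count layers by kind, descending into residual blocks.

        'fc' counts dense plus time-distributed-dense layers; 'total'
        counts conv + batch-norm + activation + pool + fc layers, the
        bookkeeping used when quoting an overall network depth.
        """
        counts = {"conv": 0, "fc": 0, "batchnorm": 0, "relu": 0, "pool": 0,
                  "dropout": 0, "residual_blocks": 0, "projection_conv": 0}

        def visit(layer: Layer) -> None:
            if isinstance(layer, ResidualBlock1D):
                counts["residual_blocks"] += 1
                counts["conv"] += 2
                counts["batchnorm"] += 2
                counts["relu"] += 2  # in-block ReLU plus the post-add ReLU
                if layer.projection is not None:
                    counts["projection_conv"] += 1
            elif isinstance(layer, Conv1D):
                counts["conv"] += 1
            elif isinstance(layer, (Dense, TimeDistributedDense)):
                counts["fc"] += 1
            elif isinstance(layer, BatchNorm1D):
                counts["batchnorm"] += 1
            elif isinstance(layer, ReLU):
                counts["relu"] += 1
            elif isinstance(layer, MaxPool1D):
                counts["pool"] += 1
            elif isinstance(layer, Dropout):
                counts["dropout"] += 1
            elif isinstance(layer, Flatten):
                pass

        for layer in self.layers:
            visit(layer)
        counts["total"] = (
            counts["conv"] + counts["fc"] + counts["batchnorm"]
            + counts["relu"] + counts["pool"]
        )
        return counts

    def set_dropout_rng(self, seed_sequence: np.random.SeedSequence) -> None:
        """Reseed every dropout layer so training is reproducible."""
        drops = [l for l in self.layers if isinstance(l, Dropout)]
        for drop, child in zip(drops, seed_sequence.spawn(max(len(drops), 1))):
            drop.rng = np.random.default_rng(child)

    # -- serialization ----------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}

        def visit(layer: Layer, prefix: str) -> None:
            subs = layer.sublayers
            if subs:
                for j, sub in enumerate(subs):
                    visit(sub, f"{prefix}.{j}")
                return
            for name, p in layer.params.items():
                arrays[f"{prefix}.{name}"] = p
            if isinstance(layer, BatchNorm1D):
                arrays[f"{prefix}.running_mean"] = layer.running_mean
                arrays[f"{prefix}.running_var"] = layer.running_var

        for i, layer in enumerate(self.layers):
            visit(layer, f"layer{i}")
        return arrays

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        missing = set(own) - set(arrays)
        if missing:
            raise ValueError(f"missing arrays in state: {sorted(missing)[:5]} ...")
        for key, target in own.items():
            src = np.asarray(arrays[key])
            if src.shape != target.shape:
                raise ValueError(f"shape mismatch for {key}: {src.shape} vs {target.shape}")
            target[...] = src
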