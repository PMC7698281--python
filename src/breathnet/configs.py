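"""Architecture and training configurations for the three models.

Two scale presets are provided everywhere:

* ``paper``: the full-size architectures (6-conv/4-FC classifier with
  kernel 100; detector with first kernel 384 and residual widths
  64->512, ~2x10^8 parameters). Intended for GPU-scale runs; only
  described analytically in routine tests.
* ``desk``: structurally identical but narrow variants that train in
  minutes on a single CPU while preserving every shape relation
  (input length = per-second outputs x 125).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .channels import SAMPLE_RATE

WINDOW_S = 7
WINDOW_SAMPLES = WINDOW_S * SAMPLE_RATE


@dataclass
class ClassifierConfig:
    """6-convolutional-layer / 4-fully-connected 1D-CNN classifier.

    The stack is conv -> batch-norm -> max-pool (x6), flatten, then three
    dense+dropout layers and the output layer (sigmoid for binary,
    softmax over six classes for multi-event). L2 weight decay defaults to
    0.1 for the binary head and 0.001 for the multi head.
    """

    output: str = "multi"  # 'binary' or 'multi'
    n_conv_layers: int = 6
    n_fc_layers: int = 4
    conv_filters: tuple[int, ...] = (32, 64, 96, 96, 64, 64)
    conv_kernel: int = 100
    pool_size: int = 2
    fc_widths: tuple[int, ...] = (256, 128, 64)
    l2: float | None = None
    dropout_fc: float = 0.5
    optimizer: str = "rmsprop"
    lr: float = 1e-3
    window_s: float = WINDOW_S
    n_channels: int = 12
    scale: str = "paper"

    def __post_init__(self) -> None:
        if self.output not in ("binary", "multi"):
            raise ValueError("output must be 'binary' or 'multi'")
        if self.l2 is None:
            self.l2 = (0.1 if self.output == "binary" else 1e-3) if self.scale == "paper" else 1e-4
        if len(self.conv_filters) != self.n_conv_layers:
            raise ValueError("conv_filters length must equal n_conv_layers")
        if len(self.fc_widths) != self.n_fc_layers - 1:
            raise ValueError("fc_widths length must equal n_fc_layers - 1")
        if self.l2 < 0:
            raise ValueError("l2 must be non-negative")
        if not 0 <= self.dropout_fc < 1:
            raise ValueError("dropout_fc must lie in [0, 1)")
        if (self.window_s * SAMPLE_RATE) % 1:
            raise ValueError("window_s * 125 must be an integer")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * SAMPLE_RATE))

    @property
    def n_outputs(self) -> int:
        return 1 if self.output == "binary" else 6

    @classmethod
    def paper(cls, output: str = "multi") -> "ClassifierConfig":
        return cls(output=output, scale="paper")

    @classmethod
    def desk(cls, output: str = "multi") -> "ClassifierConfig":
        return cls(
            output=output,
            conv_filters=(8, 8, 12, 12, 12, 12),
            conv_kernel=25,
            fc_widths=(48, 24, 16),
            scale="desk",
        )


@dataclass
class DetectorConfig:
    """Residual 1D-CNN emitting one six-class softmax per second.

    An initial wide convolution (kernel 384 at paper scale, viewing ~3 s of
    signal) is followed by four residual blocks of two convolutions each,
    widths doubling from ``base_filters``, with strided convolutions
    downsampling time by a total factor of 125 so a 30-s segment (3750
    samples) yields 30 per-second outputs.
    """

    first_kernel: int = 384
    first_stride: int = 1
    block_kernel: int = 384
    n_residual_blocks: int = 4
    convs_per_block: int = 2
    base_filters: int = 64
    block_strides: tuple[int, ...] = (5, 5, 5, 1)
    segment_s: int = 30
    n_classes: int = 6
    n_channels: int = 12
    optimizer: str = "adam"
    lr: float = 1e-3
    plateau_factor: float = 10.0
    plateau_patience: int = 3
    l2: float = 0.0
    scale: str = "paper"

    def __post_init__(self) -> None:
        if len(self.block_strides) != self.n_residual_blocks:
            raise ValueError("block_strides length must equal n_residual_blocks")
        total = self.first_stride
        for s in self.block_strides:
            total *= s
        if total != SAMPLE_RATE:
            raise ValueError(
                f"block strides must downsample by {SAMPLE_RATE} total "
                f"(input length = outputs x {SAMPLE_RATE}), got {total}"
            )
        if self.segment_s <= 0:
            raise ValueError("segment_s must be positive")

    @property
    def block_filters(self) -> tuple[int, ...]:
        return tuple(self.base_filters * 2**i for i in range(self.n_residual_blocks))

    @property
    def input_samples(self) -> int:
        return self.segment_s * SAMPLE_RATE

    @property
    def per_second_outputs(self) -> int:
        return self.segment_s

    @classmethod
    def paper(cls) -> "DetectorConfig":
        return cls(scale="paper")

    @classmethod
    def desk(cls, segment_s: int = 30) -> "DetectorConfig":
        return cls(
            first_kernel=128,
            first_stride=5,
            block_kernel=17,
            base_filters=8,
            block_strides=(5, 5, 1, 1),
            segment_s=segment_s,
            scale="desk",
        )


@dataclass
class SearchSpace:
    """Candidate sets for the seeded random hyper-parameter search."""

    batch_sizes: tuple[int, ...] = (16, 32, 64)
    learning_rates: tuple[float, ...] = (1e-2, 1e-3, 1e-4)
    losses: tuple[str, ...] = ("cross_entropy",)
    window_lengths_s: tuple[float, ...] = (WINDOW_S,)

    def __post_init__(self) -> None:
        for name in ("batch_sizes", "learning_rates", "losses", "window_lengths_s"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")


def config_to_yaml(config) -> str:
    return yaml.safe_dump({"type": type(config).__name__, **asdict(config)})


def config_from_yaml(text: str):
    payload = yaml.safe_load(text)
    kind = payload.pop("type")
    types = {
        "ClassifierConfig": ClassifierConfig,
        "DetectorConfig": DetectorConfig,
        "SearchSpace": SearchSpace,
    }
    if kind not in types:
        raise ValueError(f"unknown config type {kind!r}")
    for key in ("conv_filters", "fc_widths", "block_strides", "batch_sizes",
                "learning_rates", "losses", "window_lengths_s"):
        if key in payload and isinstance(payload[key], list):
            payload[key] = tuple(payload[key])
    return types[kind](**payload)
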