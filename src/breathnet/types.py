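"""Core containers: annotations, recordings, and subject morphology profiles."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .channels import CLASSES, ChannelLayout


@dataclass(frozen=True)
class EventAnnotation:
    """Half-open labeled span ``[start_sample, end_sample)`` in a recording."""

    label: str
    start_sample: int
    end_sample: int

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}; expected one of {CLASSES}")
        if not (0 <= self.start_sample < self.end_sample):
            raise ValueError(
                f"invalid span [{self.start_sample}, {self.end_sample}): "
                "need 0 <= start < end"
            )

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class Recording:
    """A T x 12 IMU signal matrix with channel identities and annotations.

    Accelerometer channels are in g, gyroscope channels in deg/s.
    Annotations are kept sorted, non-overlapping, and inside ``[0, T)``.
    """

    data: np.ndarray
    layout: ChannelLayout = field(default_factory=ChannelLayout)
    subject_id: str = "s000"
    annotations: list[EventAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[1] != 12:
            raise ValueError(f"data must be T x 12, got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        self.annotations = sorted(self.annotations, key=lambda a: a.start_sample)
        t = self.data.shape[0]
        prev_end = 0
        for ann in self.annotations:
            if ann.end_sample > t:
                raise ValueError(f"annotation {ann} extends past recording length {t}")
            if ann.start_sample < prev_end:
                raise ValueError(f"annotation {ann} overlaps a previous annotation")
            prev_end = ann.end_sample

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.layout.sample_rate

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, self.layout.index(name)]


def default_event_amplitude_scales() -> dict[str, float]:
    # Multipliers on breath_amplitude for each event class; csa suppresses
    # respiratory motion entirely (breath hold), cough is a violent burst.
    return {"csa": 0.0, "cough": 4.0, "osa": 1.5, "sigh": 2.5, "yawn": 2.0}


@dataclass(frozen=True)
class SubjectProfile:
    """Morphology knobs for one simulated subject.

    Parameters
    ----------
    breathing_rate
        Resting respiratory rate, breaths/min.
    breath_amplitude
        Peak respiratory excursion on the dominant accelerometer axis, g.
    noise_sd
        Standard deviation of additive Gaussian sensor noise, g.
    phase_offset_abdomen
        Abdomen-vs-chest respiratory phase offset during normal breathing,
        radians (small: the two sites move together in health).
    event_amplitude_scales
        Per-class multipliers applied to breath_amplitude inside event clips.
    osa_phase_shift
        Thorax-abdomen phase shift during obstructed effort, radians. The
        default pi encodes the hallmark anti-phase (paradoxical) motion of
        obstructive apnea.
    """

    breathing_rate: float = 15.0
    breath_amplitude: float = 0.05
    noise_sd: float = 0.004
    phase_offset_abdomen: float = 0.1
    event_amplitude_scales: dict[str, float] = field(
        default_factory=default_event_amplitude_scales
    )
    osa_phase_shift: float = float(np.pi)

    def __post_init__(self) -> None:
        if self.breathing_rate <= 0:
            raise ValueError("breathing_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.breath_amplitude < 0:
            raise ValueError("breath_amplitude must be non-negative")
        if not (0 < self.osa_phase_shift < 2 * np.pi):
            raise ValueError("osa_phase_shift must lie in (0, 2*pi)")

    def with_(self, **kwargs) -> "SubjectProfile":
        return replace(self, **kwargs)
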