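"""Channel layout and label vocabulary for two-site IMU breathing recordings.

Two skin-worn inertial sensors (chest and upper abdomen) each record a
tri-axial accelerometer (units of g) and a tri-axial angular-rate gyroscope
(deg/s) at 125 Hz, giving 12 signal channels per recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SAMPLE_RATE = 125
"""Sampling rate in Hz shared by every channel."""

SITES = ("chest", "abdomen")
MODALITIES = ("accel", "gyro")
AXES = ("x", "y", "z")

#: Six-class label vocabulary: normal breathing plus the five event classes.
CLASSES = ("normal", "csa", "cough", "osa", "sigh", "yawn")
EVENT_CLASSES = CLASSES[1:]

CLASS_TO_INDEX = {c: i for i, c in enumerate(CLASSES)}


def default_channel_names() -> list[str]:
    """Canonical channel order: site-major, modality, then axis."""
    return [f"{site}_{mod}_{axis}" for site in SITES for mod in MODALITIES for axis in AXES]


@dataclass(frozen=True)
class ChannelLayout:
    """Identity and ordering of the 12 IMU channels.

    Parameters
    ----------
    names
        Ordered channel identifiers ``<site>_<modality>_<axis>`` with
        site in {chest, abdomen}, modality in {accel, gyro}, axis in
        {x, y, z}. Must contain exactly 12 distinct names.
    sample_rate
        Sampling frequency in Hz, identical for all channels.
    """

    names: tuple[str, ...] = field(default_factory=lambda: tuple(default_channel_names()))
    sample_rate: float = SAMPLE_RATE

    def __post_init__(self) -> None:
        if len(self.names) != 12:
            raise ValueError(f"expected 12 channel names, got {len(self.names)}")
        if len(set(self.names)) != 12:
            raise ValueError("channel names must be distinct")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        valid = set(default_channel_names())
        for name in self.names:
            if name not in valid:
                raise ValueError(f"unknown channel name {name!r}")

    def index(self, name: str) -> int:
        return self.names.index(name)

    def site_indices(self, site: str, modality: str | None = None) -> list[int]:
        """Column indices belonging to a sensor site (optionally one modality)."""
        out = []
        for i, name in enumerate(self.names):
            s, mod, _ = name.split("_")
            if s == site and (modality is None or mod == modality):
                out.append(i)
        return out
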