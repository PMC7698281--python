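"""Synthetic 12-channel IMU breathing-signal generator.

Emulates the data-collection protocol the downstream pipeline expects:
per-subject sessions containing five minutes of normal breathing, one 30-s
breath hold (central sleep apnea, CSA), and five repetitions each of
coughs, sighs, yawns, and Mueller maneuvers (obstructive sleep apnea, OSA),
in randomized order with normal-breathing gaps in between.

The waveform model is deliberately simple — a quasi-sinusoidal respiratory
component (cycle-to-cycle rate and amplitude jitter plus a weak second
harmonic) riding on a constant gravity offset, with additive Gaussian
sensor noise — but it encodes the discriminative structure each event class
carries in real chest/abdomen IMU data:

* CSA: respiratory motion ceases (near-flat signal, noise only);
* OSA: chest and abdomen move in anti-phase (paradoxical effort against an
  occluded airway), with continued or increased effort;
* cough: short bursts of 10-25 Hz content far above breathing amplitude;
* sigh: a single exaggerated breath (one fast, large cycle);
* yawn: a single slow (>= 4 s) large inspiration with gradual release.

Accelerometer channels are in g, gyroscope channels in deg/s. All public
functions are deterministic given (profile, seed).
"""

from __future__ import annotations

import numpy as np

from .channels import EVENT_CLASSES, SAMPLE_RATE, ChannelLayout
from .types import EventAnnotation, Recording, SubjectProfile

#: Events other than CSA must fit in a classification window / segment half.
MAX_NON_CSA_DURATION_S = 14.0

# Per-channel baseline offsets (g for accel, deg/s for gyro): accelerometer
# z-axes sit roughly normal to the body surface and carry the 1-g gravity
# component; all other channels are zero-mean.
_BASELINES = np.array([0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0])

# Respiratory coupling of each channel, relative to breath_amplitude.
# Order: chest accel xyz, chest gyro xyz, abdomen accel xyz, abdomen gyro xyz.
# The z accelerometers dominate; gyro couplings are scaled to deg/s.
_CHEST_COUPLING = np.array([0.30, 0.20, 1.00, 8.0, 12.0, 4.0, 0, 0, 0, 0, 0, 0])
_ABDOMEN_COUPLING = np.array([0, 0, 0, 0, 0, 0, 0.35, 0.25, 1.00, 6.0, 10.0, 5.0])

# Noise scale per channel relative to profile.noise_sd (gyro noise larger
# in its own units).
_NOISE_SCALE = np.array([1, 1, 1, 15, 15, 15, 1, 1, 1, 15, 15, 15], dtype=float)

_RATE_JITTER = 0.06    # sd of per-cycle breathing-rate jitter (fractional)
_AMP_JITTER = 0.10     # sd of per-cycle amplitude jitter (fractional)
_HARMONIC = 0.15       # second-harmonic fraction (breath asymmetry)


def _n_samples(duration_s: float) -> int:
    return int(round(duration_s * SAMPLE_RATE))


def _quasi_sinusoid(
    n: int, rate_hz: float, rng: np.random.Generator, jitter: bool = True
) -> np.ndarray:
    """Unit-amplitude respiratory waveform with per-cycle rate/amp jitter."""
    t = np.arange(n) / SAMPLE_RATE
    total = n / SAMPLE_RATE
    mean_period = 1.0 / rate_hz
    starts = [0.0]
    while starts[-1] < total:
        d = mean_period
        if jitter:
            d *= float(np.clip(1.0 + _RATE_JITTER * rng.standard_normal(), 0.6, 1.4))
        starts.append(starts[-1] + d)
    starts_arr = np.array(starts)
    phase = np.interp(t, starts_arr, 2 * np.pi * np.arange(len(starts_arr)))
    amps = np.ones(len(starts_arr))
    if jitter:
        amps = np.clip(1.0 + _AMP_JITTER * rng.standard_normal(len(starts_arr)), 0.5, 1.5)
    amp = np.interp(t, starts_arr, amps)
    return amp * (np.sin(phase) + _HARMONIC * np.sin(2 * phase))


def _assemble(
    chest_wave: np.ndarray,
    abdomen_wave: np.ndarray,
    amplitude: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mix site waveforms into the 12-channel matrix with baselines + noise."""
    n = chest_wave.shape[0]
    data = np.tile(_BASELINES, (n, 1))
    data += amplitude * chest_wave[:, None] * _CHEST_COUPLING[None, :]
    data += amplitude * abdomen_wave[:, None] * _ABDOMEN_COUPLING[None, :]
    if noise_sd > 0:
        data += noise_sd * _NOISE_SCALE[None, :] * rng.standard_normal((n, 12))
    return data


def _normal_data(
    n: int, profile: SubjectProfile, rng: np.random.Generator
) -> np.ndarray:
    rate_hz = profile.breathing_rate / 60.0
    chest = _quasi_sinusoid(n, rate_hz, rng)
    # Abdomen tracks the chest with a small mechanical phase offset,
    # approximated by a time shift of the same waveform.
    shift = int(round(profile.phase_offset_abdomen / (2 * np.pi * rate_hz) * SAMPLE_RATE))
    abdomen = np.roll(chest, shift) if shift else chest
    return _assemble(chest, abdomen, profile.breath_amplitude, profile.noise_sd, rng)


def simulate_normal_breathing(
    duration_s: float, profile: SubjectProfile | None = None, seed: int = 0
) -> Recording:
    """Simulate quiet normal breathing.

    Parameters
    ----------
    duration_s
        Positive duration in seconds; the output has
        ``round(duration_s * 125)`` samples.
    profile
        Subject morphology; defaults to :class:`SubjectProfile()`.
    seed
        Seed for the internal random generator; identical (profile, seed)
        pairs produce identical recordings.
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    profile = profile or SubjectProfile()
    rng = np.random.default_rng(seed)
    n = _n_samples(duration_s)
    data = _normal_data(n, profile, rng)
    ann = [EventAnnotation("normal", 0, n)]
    return Recording(data=data, layout=ChannelLayout(), annotations=ann)


def _event_waves(
    label: str, n: int, profile: SubjectProfile, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Chest and abdomen unit waveforms (pre-amplitude) for an event clip."""
    rate_hz = profile.breathing_rate / 60.0
    scale = profile.event_amplitude_scales.get(label, 1.0)
    t = np.arange(n) / SAMPLE_RATE
    dur = n / SAMPLE_RATE
    if label == "csa":
        # Breath hold at functional residual capacity: no respiratory motion.
        wave = scale * _quasi_sinusoid(n, rate_hz, rng)
        return wave, wave.copy()
    if label == "osa":
        # Obstructed inspiratory effort: higher rate and amplitude, with the
        # abdomen shifted anti-phase relative to the chest.
        eff_rate = 1.3 * rate_hz
        chest = scale * _quasi_sinusoid(n, eff_rate, rng)
        shift = int(round(profile.osa_phase_shift / (2 * np.pi * eff_rate) * SAMPLE_RATE))
        abdomen = np.roll(chest, shift)
        return chest, abdomen
    if label == "cough":
        # Suppressed breathing plus one burst of 10-25 Hz content per ~0.7 s.
        base = 0.3 * _quasi_sinusoid(n, rate_hz, rng)
        wave = base.copy()
        n_bursts = max(1, int(dur / 0.7))
        for _ in range(n_bursts):
            width = rng.uniform(0.20, 0.35)
            f0 = rng.uniform(12.0, 22.0)
            start = rng.uniform(0.0, max(dur - width, 1e-6))
            mask = (t >= start) & (t < start + width)
            tau = t[mask] - start
            envelope = np.sin(np.pi * tau / width) ** 2
            wave[mask] += scale * envelope * np.sin(2 * np.pi * f0 * tau)
        return wave, wave.copy()
    if label == "sigh":
        # One exaggerated full breath cycle spanning the clip.
        wave = scale * np.sin(2 * np.pi * t / dur)
        return wave, wave.copy()
    if label == "yawn":
        # Slow large inspiration (>= 4 s) followed by a faster release.
        t_insp = max(4.0, 0.7 * dur)
        t_insp = min(t_insp, dur)
        wave = np.empty(n)
        rising = t < t_insp
        wave[rising] = 0.5 * (1 - np.cos(np.pi * t[rising] / t_insp))
        rel = ~rising
        t_rel = max(dur - t_insp, 1e-6)
        wave[rel] = 0.5 * (1 + np.cos(np.pi * (t[rel] - t_insp) / t_rel))
        return scale * wave, scale * wave.copy()
    raise ValueError(f"unknown event label {label!r}")


def simulate_event_clip(
    label: str,
    duration_s: float,
    profile: SubjectProfile | None = None,
    seed: int = 0,
) -> Recording:
    """Simulate a single labeled breathing-event clip.

    ``label`` must be one of the five event classes; cough/sigh/yawn/osa
    clips are limited to 14 s (longer maneuvers are not part of the
    protocol), while CSA breath holds may run to 30 s.
    """
    if label not in EVENT_CLASSES:
        raise ValueError(f"label must be one of {EVENT_CLASSES}, got {label!r}")
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    if label != "csa" and duration_s > MAX_NON_CSA_DURATION_S:
        raise ValueError(
            f"{label} clips are limited to {MAX_NON_CSA_DURATION_S:.0f} s, "
            f"got {duration_s} s"
        )
    profile = profile or SubjectProfile()
    rng = np.random.default_rng(seed)
    n = _n_samples(duration_s)
    chest, abdomen = _event_waves(label, n, profile, rng)
    data = _assemble(chest, abdomen, profile.breath_amplitude, profile.noise_sd, rng)
    ann = [EventAnnotation(label, 0, n)]
    return Recording(data=data, layout=ChannelLayout(), annotations=ann)


#: Per-class (low, high) duration ranges, seconds, for session repetitions.
_SESSION_DURATIONS = {
    "cough": (1.0, 1.8),
    "sigh": (3.0, 5.0),
    "yawn": (4.5, 7.0),
    "osa": (6.0, 10.0),
}
_GAP_RANGE_S = (5.0, 15.0)
_NORMAL_BLOCK_S = 300.0
_CSA_HOLD_S = 30.0


def simulate_subject_session(
    profile: SubjectProfile | None = None,
    seed: int = 0,
    subject_id: str = "s000",
) -> Recording:
    """Simulate one subject's full annotated protocol session.

    The session contains, in seeded-random order: a 300-s normal-breathing
    block, one 30-s CSA breath hold, and five repetitions each of cough,
    sigh, yawn, and OSA, separated by 5-15 s normal-breathing gaps. Every
    span (including gaps) is annotated.
    """
    profile = profile or SubjectProfile()
    rng = np.random.default_rng(seed)

    items: list[tuple[str, float]] = [("normal", _NORMAL_BLOCK_S), ("csa", _CSA_HOLD_S)]
    for label in ("yawn", "cough", "sigh", "osa"):
        lo, hi = _SESSION_DURATIONS[label]
        items.extend((label, float(rng.uniform(lo, hi))) for _ in range(5))
    order = rng.permutation(len(items))
    items = [items[i] for i in order]

    blocks: list[np.ndarray] = []
    annotations: list[EventAnnotation] = []
    cursor = 0

    def _append(label: str, block: np.ndarray) -> None:
        nonlocal cursor
        blocks.append(block)
        annotations.append(EventAnnotation(label, cursor, cursor + block.shape[0]))
        cursor += block.shape[0]

    for i, (label, dur) in enumerate(items):
        n = _n_samples(dur)
        if label == "normal":
            _append("normal", _normal_data(n, profile, rng))
        else:
            chest, abdomen = _event_waves(label, n, profile, rng)
            _append(
                label,
                _assemble(chest, abdomen, profile.breath_amplitude, profile.noise_sd, rng),
            )
        if i < len(items) - 1:
            gap_n = _n_samples(float(rng.uniform(*_GAP_RANGE_S)))
            _append("normal", _normal_data(gap_n, profile, rng))

    data = np.concatenate(blocks, axis=0)
    return Recording(
        data=data,
        layout=ChannelLayout(),
        subject_id=subject_id,
        annotations=annotations,
    )


def simulate_cohort(
    n_subjects: int, seed: int = 0, profile_jitter: float = 0.15
) -> list[Recording]:
    """Simulate a cohort of annotated sessions with varied subject profiles.

    Each subject draws an individual breathing rate and amplitude around the
    defaults (fractional sd ``profile_jitter``), then runs the full protocol.
    """
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    ss = np.random.SeedSequence(seed)
    profile_rng = np.random.default_rng(ss.spawn(1)[0])
    session_seeds = profile_rng.integers(0, 2**31 - 1, size=n_subjects)
    base = SubjectProfile()
    sessions = []
    for i in range(n_subjects):
        rate = base.breathing_rate * float(
            np.clip(1 + profile_jitter * profile_rng.standard_normal(), 0.6, 1.5)
        )
        amp = base.breath_amplitude * float(
            np.clip(1 + profile_jitter * profile_rng.standard_normal(), 0.5, 1.6)
        )
        profile = base.with_(breathing_rate=rate, breath_amplitude=amp)
        sessions.append(
            simulate_subject_session(
                profile, seed=int(session_seeds[i]), subject_id=f"s{i:03d}"
            )
        )
    return sessions
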