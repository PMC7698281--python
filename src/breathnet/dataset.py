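"""Dataset construction: event pools, segment injection, labels, and splits.

The detection dataset is built by excising annotated event clips from the
cohort recordings, then re-injecting randomly drawn clips into 30-s spans of
normal breathing (3750 samples at 125 Hz), with one class label per second
(30 labels per segment).

Injection rules
---------------
* A segment receives 0, 1 or 2 events (proportions are a config parameter).
* Single-event segments place the event uniformly at any feasible integer
  start second; a single injected CSA draws its duration from {10, 20, 23} s.
* Two-event segments place the first event entirely inside the first 15 s
  and the second entirely inside the second 15 s (so they can never
  overlap); a CSA drawn for a two-event segment uses durations {10, 11, 13} s.
* Non-CSA events keep their full clip duration, rounded up to whole seconds
  (the remainder of the final second keeps normal-breathing samples) and
  capped at 14 s.
* Boundary smoothing: on every channel, the first and last sample of the
  injected clip are replaced by their average with the adjacent sample; the
  smoothed samples keep the event label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .channels import CLASSES, EVENT_CLASSES, SAMPLE_RATE
from .types import Recording

SEGMENT_S = 30
SEGMENT_SAMPLES = SEGMENT_S * SAMPLE_RATE  # 3750
SINGLE_CSA_DURATIONS = (10, 20, 23)
DOUBLE_CSA_DURATIONS = (10, 11, 13)
MAX_EVENT_S = 14
HALF_S = 15
SPLIT_FRACTIONS = (0.6, 0.2, 0.2)
WINDOW_S = 7
WINDOW_SAMPLES = WINDOW_S * SAMPLE_RATE  # 875


@dataclass
class EventClip:
    """An excised labeled event waveform (T' x 12, at least one second)."""

    label: str
    data: np.ndarray
    source_subject: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.label == "normal" or self.label not in CLASSES:
            raise ValueError(f"clip label must be an event class, got {self.label!r}")
        if self.data.ndim != 2 or self.data.shape[1] != 12:
            raise ValueError(f"clip data must be T x 12, got {self.data.shape}")
        if self.data.shape[0] < SAMPLE_RATE:
            raise ValueError(
                f"clip must be at least 1 s ({SAMPLE_RATE} samples), "
                f"got {self.data.shape[0]}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / SAMPLE_RATE


@dataclass
class EventPool:
    """Event clips grouped by class plus a reservoir of normal-breathing spans."""

    clips_by_class: dict[str, list[EventClip]]
    normal_reservoir: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cls in EVENT_CLASSES:
            self.clips_by_class.setdefault(cls, [])
        unknown = set(self.clips_by_class) - set(EVENT_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in pool: {sorted(unknown)}")

    def counts(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.clips_by_class.items()}

    def require(self, label: str) -> list[EventClip]:
        clips = self.clips_by_class.get(label, [])
        if not clips:
            raise ValueError(f"event pool has no clips for class {label!r}")
        return clips


def extract_event_pool(recordings: list[Recording]) -> EventPool:
    """Excise every annotated event span into the pool; normal spans feed
    the reservoir. Recordings without annotations are skipped with a warning.
    """
    clips: dict[str, list[EventClip]] = {c: [] for c in EVENT_CLASSES}
    reservoir: list[np.ndarray] = []
    for rec in recordings:
        if not rec.annotations:
            warnings.warn(
                f"recording {rec.subject_id!r} has no annotations; skipped",
                stacklevel=2,
            )
            continue
        for ann in rec.annotations:
            span = rec.data[ann.start_sample : ann.end_sample]
            if ann.label == "normal":
                reservoir.append(span)
            else:
                clips[ann.label].append(
                    EventClip(label=ann.label, data=span, source_subject=rec.subject_id)
                )
    return EventPool(clips_by_class=clips, normal_reservoir=reservoir)


@dataclass(frozen=True)
class PlanEntry:
    label: str
    start_second: int
    duration_s: int
    clip_index: int


@dataclass
class InjectionPlan:
    """Where and what to inject into one 30-s segment (0, 1 or 2 events)."""

    entries: list[PlanEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.entries) > 2:
            raise ValueError("at most two events per segment")
        ends = []
        for e in self.entries:
            if e.label not in EVENT_CLASSES:
                raise ValueError(f"plan entry has non-event label {e.label!r}")
            if e.start_second < 0 or e.start_second + e.duration_s > SEGMENT_S:
                raise ValueError(f"entry {e} does not fit in [0, {SEGMENT_S})")
            ends.append((e.start_second, e.start_second + e.duration_s))
        ends.sort()
        for (s0, e0), (s1, _) in zip(ends, ends[1:]):
            if s1 < e0:
                raise ValueError("plan entries overlap")
        if len(self.entries) == 2:
            first, second = sorted(self.entries, key=lambda e: e.start_second)
            if not (first.start_second < HALF_S <= second.start_second):
                raise ValueError(
                    "two-event plans need the first event in the first 15 s "
                    "and the second in the second 15 s"
                )

    @property
    def n_events(self) -> int:
        return len(self.entries)

    def labels(self) -> list[str]:
        """The 30 per-second labels implied by the plan."""
        labels = ["normal"] * SEGMENT_S
        for e in self.entries:
            for s in range(e.start_second, e.start_second + e.duration_s):
                labels[s] = e.label
        return labels


def _draw_entry(
    pool: EventPool,
    rng: np.random.Generator,
    csa_durations: tuple[int, ...],
    window: tuple[int, int],
) -> PlanEntry:
    """Draw one (class, clip, duration, placement) entry inside a window."""
    lo, hi = window
    for _ in range(100):
        label = str(rng.choice(EVENT_CLASSES))
        clips = pool.require(label)
        clip_index = int(rng.integers(len(clips)))
        if label == "csa":
            duration = int(rng.choice(csa_durations))
        else:
            duration = min(int(np.ceil(clips[clip_index].duration_s)), MAX_EVENT_S)
        if duration <= hi - lo:
            start = lo + int(rng.integers(hi - lo - duration + 1))
            return PlanEntry(label, start, duration, clip_index)
    raise RuntimeError(f"could not place an event inside [{lo}, {hi}) after 100 draws")


def draw_injection_plan(
    n_events: int, pool: EventPool, rng_seed: int | np.random.Generator = 0
) -> InjectionPlan:
    """Draw a seeded injection plan with 0, 1 or 2 events.

    Classes are drawn uniformly from the five event classes; see the module
    docstring for duration and placement rules.
    """
    if n_events not in (0, 1, 2):
        raise ValueError(f"n_events must be 0, 1 or 2, got {n_events}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if n_events == 0:
        return InjectionPlan()
    if n_events == 1:
        return InjectionPlan(
            [_draw_entry(pool, rng, SINGLE_CSA_DURATIONS, (0, SEGMENT_S))]
        )
    first = _draw_entry(pool, rng, DOUBLE_CSA_DURATIONS, (0, HALF_S))
    second = _draw_entry(pool, rng, DOUBLE_CSA_DURATIONS, (HALF_S, SEGMENT_S))
    return InjectionPlan([first, second])


def smooth_boundary(segment_data: np.ndarray, span: tuple[int, int]) -> np.ndarray:
    """Average the first/last sample of an injected span with its neighbor.

    On each of the 12 channels the first sample of ``span`` is replaced by
    its mean with the preceding sample and the last sample by its mean with
    the following sample; a span touching a segment edge is smoothed only on
    its interior side. Returns a modified copy.
    """
    a, b = span
    t = segment_data.shape[0]
    if not (0 <= a < b <= t):
        raise ValueError(f"span [{a}, {b}) outside data of length {t}")
    out = segment_data.copy()
    if a > 0:
        out[a] = (segment_data[a] + segment_data[a - 1]) / 2.0
    if b < t:
        out[b - 1] = (segment_data[b - 1] + segment_data[b]) / 2.0
    return out


@dataclass
class LabeledSegment:
    """A 3750 x 12 segment with 30 per-second labels and its injection plan."""

    data: np.ndarray
    labels: list[str]
    plan: InjectionPlan
    segment_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != (SEGMENT_SAMPLES, 12):
            raise ValueError(
                f"segment data must be {SEGMENT_SAMPLES} x 12, got {self.data.shape}"
            )
        if len(self.labels) != SEGMENT_S:
            raise ValueError(f"expected {SEGMENT_S} labels, got {len(self.labels)}")
        if self.labels != self.plan.labels():
            raise ValueError("labels disagree with the injection plan")


def inject_events(
    base: np.ndarray | Recording,
    plan: InjectionPlan,
    pool: EventPool,
    rng_seed: int | np.random.Generator = 0,
    segment_id: str = "",
) -> LabeledSegment:
    """Replace planned spans of a 30-s normal segment with event clips.

    CSA clips are cropped to the drawn duration; shorter non-CSA clips leave
    the tail of their final (rounded-up) second as normal-breathing samples.
    Boundary smoothing is applied to the actually replaced sample range.
    """
    data = base.data if isinstance(base, Recording) else np.asarray(base, dtype=float)
    if data.shape != (SEGMENT_SAMPLES, 12):
        raise ValueError(f"base must be {SEGMENT_SAMPLES} x 12, got {data.shape}")
    out = data.copy()
    for e in plan.entries:
        clip = pool.require(e.label)[e.clip_index]
        span_samples = e.duration_s * SAMPLE_RATE
        if e.label == "csa":
            if clip.n_samples < span_samples:
                raise ValueError(
                    f"CSA clip from {clip.source_subject!r} is {clip.duration_s:.1f} s, "
                    f"shorter than the drawn duration {e.duration_s} s"
                )
            insert = clip.data[:span_samples]
        else:
            insert = clip.data[: min(clip.n_samples, span_samples)]
        a = e.start_second * SAMPLE_RATE
        b = a + insert.shape[0]
        out[a:b] = insert
        out = smooth_boundary(out, (a, b))
    return LabeledSegment(data=out, labels=plan.labels(), plan=plan, segment_id=segment_id)


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test id lists (60/20/20 by default)."""

    train: list[str]
    validation: list[str]
    test: list[str]
    fractions: tuple[float, float, float] = SPLIT_FRACTIONS

    def __post_init__(self) -> None:
        all_ids = self.train + self.validation + self.test
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("split id lists are not disjoint")

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))


def split_ids(
    ids: list[str],
    fractions: tuple[float, float, float] = SPLIT_FRACTIONS,
    seed: int | np.random.Generator = 0,
) -> DatasetSplit:
    """Seeded uniform random partition of ids into train/validation/test."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    n = len(ids)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_val = min(n_val, n - n_train)
    return DatasetSplit(
        train=perm[:n_train],
        validation=perm[n_train : n_train + n_val],
        test=perm[n_train + n_val :],
        fractions=fractions,
    )


DEFAULT_EVENT_MIX = (0.1, 0.6, 0.3)


@dataclass
class SegmentPlanRecord:
    """Lightweight plan-level segment description (no waveform)."""

    segment_id: str
    plan: InjectionPlan
    labels: list[str]


def _draw_base(
    pool: EventPool, rng: np.random.Generator
) -> np.ndarray:
    """Draw a random 30-s normal-breathing span from the reservoir."""
    eligible = [s for s in pool.normal_reservoir if s.shape[0] >= SEGMENT_SAMPLES]
    if not eligible:
        raise ValueError(
            "normal reservoir has no span of at least "
            f"{SEGMENT_SAMPLES} samples ({SEGMENT_S} s)"
        )
    span = eligible[int(rng.integers(len(eligible)))]
    offset = int(rng.integers(span.shape[0] - SEGMENT_SAMPLES + 1))
    return span[offset : offset + SEGMENT_SAMPLES]


def build_detection_dataset(
    pool: EventPool,
    n_segments: int,
    event_mix: tuple[float, float, float] = DEFAULT_EVENT_MIX,
    seed: int = 0,
    materialize: bool = True,
) -> tuple[list[LabeledSegment] | list[SegmentPlanRecord], DatasetSplit]:
    """Build the per-second detection dataset and its 60/20/20 split.

    With ``materialize=False`` only injection plans and per-second labels are
    drawn (the full 40,000-segment corpus would occupy several GB of
    waveforms); the ids, plans, labels and split are identical to the
    materialized build for the same seed.
    """
    if n_segments <= 0:
        raise ValueError(f"n_segments must be positive, got {n_segments}")
    if abs(sum(event_mix) - 1.0) > 1e-9 or min(event_mix) < 0:
        raise ValueError("event_mix must be non-negative proportions summing to 1")
    for cls in EVENT_CLASSES:
        pool.require(cls)
    ss = np.random.SeedSequence(seed)
    plan_rng, base_rng, split_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    counts = plan_rng.choice(3, size=n_segments, p=event_mix)
    out: list = []
    for i in range(n_segments):
        seg_id = f"seg{i:06d}"
        plan = draw_injection_plan(int(counts[i]), pool, plan_rng)
        if materialize:
            base = _draw_base(pool, base_rng)
            out.append(inject_events(base, plan, pool, segment_id=seg_id))
        else:
            out.append(SegmentPlanRecord(seg_id, plan, plan.labels()))
    split = split_ids([s.segment_id for s in out], SPLIT_FRACTIONS, split_rng)
    return out, split


@dataclass
class ClassificationWindow:
    """A 875 x 12 (7-s) window carrying a single class label."""

    data: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != (WINDOW_SAMPLES, 12):
            raise ValueError(
                f"window data must be {WINDOW_SAMPLES} x 12, got {self.data.shape}"
            )
        if self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}")


def _event_window(
    clip: EventClip, n_window: int, pool: EventPool, rng: np.random.Generator
) -> np.ndarray:
    """Center a fixed-length window on an event clip.

    Events longer than the window are center-cropped (with a warning);
    shorter events are padded symmetrically with normal-breathing context
    drawn from the reservoir, since excised clips carry none of their own.
    """
    t = clip.n_samples
    if t >= n_window:
        if t > n_window:
            warnings.warn(
                f"{clip.label} clip of {clip.duration_s:.1f} s cropped to "
                f"{n_window / SAMPLE_RATE:.0f} s window",
                stacklevel=2,
            )
        a = (t - n_window) // 2
        return clip.data[a : a + n_window]
    pad_total = n_window - t
    pad_left = pad_total // 2
    context = _draw_normal_window(pool, n_window, rng)
    out = context.copy()
    out[pad_left : pad_left + t] = clip.data
    return smooth_boundary(out, (pad_left, pad_left + t))


def _draw_normal_window(
    pool: EventPool, n_window: int, rng: np.random.Generator
) -> np.ndarray:
    eligible = [s for s in pool.normal_reservoir if s.shape[0] >= n_window]
    if not eligible:
        raise ValueError("normal reservoir has no span long enough for a window")
    span = eligible[int(rng.integers(len(eligible)))]
    off = int(rng.integers(span.shape[0] - n_window + 1))
    return span[off : off + n_window]


def build_classification_dataset(
    pool: EventPool,
    window_s: float = WINDOW_S,
    balance: bool = False,
    seed: int = 0,
    n_normal: int | None = None,
) -> tuple[list[ClassificationWindow], DatasetSplit]:
    """Build fixed-length windows (default 7 s = 875 samples) per event.

    One window per pooled event occurrence, centered on the event, plus
    normal-breathing windows drawn from the reservoir (by default as many as
    the mean event-class count). With ``balance=True`` every class is
    down-sampled to the minimum class count, mirroring clip-level balancing.
    """
    n_window = window_s * SAMPLE_RATE
    if abs(n_window - round(n_window)) > 1e-9:
        raise ValueError(f"window_s * {SAMPLE_RATE} must be an integer, got {n_window}")
    n_window = int(round(n_window))
    ss = np.random.SeedSequence(seed)
    rng, split_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    by_class: dict[str, list[np.ndarray]] = {c: [] for c in CLASSES}
    for cls in EVENT_CLASSES:
        for clip in pool.clips_by_class[cls]:
            by_class[cls].append(_event_window(clip, n_window, pool, rng))
    event_counts = [len(by_class[c]) for c in EVENT_CLASSES]
    n_norm = n_normal if n_normal is not None else int(round(np.mean(event_counts)))
    by_class["normal"] = [_draw_normal_window(pool, n_window, rng) for _ in range(n_norm)]

    if balance:
        n_min = min(len(v) for v in by_class.values())
        for cls, wins in by_class.items():
            if len(wins) > n_min:
                keep = rng.choice(len(wins), size=n_min, replace=False)
                by_class[cls] = [wins[i] for i in sorted(keep)]

    windows = [
        ClassificationWindow(data=w, label=cls)
        for cls in CLASSES
        for w in by_class[cls]
    ]
    ids = [f"win{i:06d}" for i in range(len(windows))]
    split = split_ids(ids, SPLIT_FRACTIONS, split_rng)
    return windows, split
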