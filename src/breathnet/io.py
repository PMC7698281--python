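"""Readers and writers: recording CSV + JSON annotations, datasets, models.

A recording is stored as a 13-column CSV (``t`` in seconds followed by the
12 signal channels in canonical order) with an optional JSON sidecar
holding the annotation list. Round-trip fidelity: write -> read reproduces
the signal to better than 1e-9 and the annotations exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import SAMPLE_RATE, ChannelLayout, default_channel_names
from .dataset import InjectionPlan, LabeledSegment, PlanEntry
from .models import TrainedModel
from .nn import TrainingHistory
from .types import EventAnnotation, Recording


def annotations_path(csv_path: Path | str) -> Path:
    p = Path(csv_path)
    return p.with_suffix(".annotations.json")


def write_recording(recording: Recording, path: Path | str) -> Path:
    """Write the CSV (+ JSON sidecar when annotations exist); returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(recording.n_samples) / recording.layout.sample_rate
    df = pd.DataFrame(recording.data, columns=list(recording.layout.names))
    df.insert(0, "t", t)
    df.to_csv(path, index=False)
    if recording.annotations:
        payload = {
            "subject_id": recording.subject_id,
            "sample_rate": recording.layout.sample_rate,
            "annotations": [
                {"label": a.label, "start_sample": a.start_sample, "end_sample": a.end_sample}
                for a in recording.annotations
            ],
        }
        annotations_path(path).write_text(json.dumps(payload, indent=1))
    return path


def read_recording(path: Path | str) -> Recording:
    """Read a 13-column recording CSV, with diagnostics for malformed files."""
    path = Path(path)
    df = pd.read_csv(path)
    expected = ["t"] + default_channel_names()
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing channel columns: {missing}")
        if extra:
            parts.append(f"unexpected columns: {extra}")
        raise ValueError(f"{path}: " + "; ".join(parts))
    data = df[expected[1:]].to_numpy()
    if not np.issubdtype(data.dtype, np.number) or not np.all(np.isfinite(data)):
        bad = df[expected[1:]].apply(pd.to_numeric, errors="coerce")
        rows, cols = np.where(~np.isfinite(bad.to_numpy(dtype=float)))
        r, c = int(rows[0]), expected[1:][int(cols[0])]
        raise ValueError(f"{path}: non-numeric or non-finite value at row {r}, column {c!r}")
    subject_id, annotations = "unknown", []
    ann_path = annotations_path(path)
    if ann_path.exists():
        payload = json.loads(ann_path.read_text())
        subject_id = payload.get("subject_id", subject_id)
        annotations = [
            EventAnnotation(a["label"], int(a["start_sample"]), int(a["end_sample"]))
            for a in payload["annotations"]
        ]
    return Recording(
        data=data.astype(float),
        layout=ChannelLayout(),
        subject_id=subject_id,
        annotations=annotations,
    )


# -- labeled segments -------------------------------------------------------

def write_segment(segment: LabeledSegment, directory: Path | str) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / f"{segment.segment_id}.csv"
    pd.DataFrame(segment.data, columns=default_channel_names()).to_csv(csv_path, index=False)
    sidecar = {
        "segment_id": segment.segment_id,
        "labels": segment.labels,
        "plan": [
            {"label": e.label, "start_second": e.start_second,
             "duration_s": e.duration_s, "clip_index": e.clip_index}
            for e in segment.plan.entries
        ],
    }
    (directory / f"{segment.segment_id}.json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_segment(directory: Path | str, segment_id: str) -> LabeledSegment:
    directory = Path(directory)
    data = pd.read_csv(directory / f"{segment_id}.csv").to_numpy()
    sidecar = json.loads((directory / f"{segment_id}.json").read_text())
    plan = InjectionPlan([PlanEntry(**e) for e in sidecar["plan"]])
    return LabeledSegment(
        data=data, labels=sidecar["labels"], plan=plan, segment_id=segment_id
    )


# -- trained models ---------------------------------------------------------

def save_trained_model(model: TrainedModel, path: Path | str) -> Path:
    """Serialize architecture id, seed, history, and weights to one .npz."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = json.dumps(
        {
            "architecture": model.architecture,
            "seed": model.seed,
            "classes": list(model.classes),
            "history": model.history.to_dict(),
            "extra": model.extra,
        }
    )
    arrays = {f"w::{k}": v for k, v in model.network.state_arrays().items()}
    np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)
    return path


def load_trained_model_into(network, path: Path | str) -> TrainedModel:
    """Load weights saved by :func:`save_trained_model` into a compatible network."""
    with np.load(Path(path)) as payload:
        meta = json.loads(bytes(payload["meta"].tobytes()).decode())
        arrays = {k[3:]: payload[k] for k in payload.files if k.startswith("w::")}
    network.load_state_arrays(arrays)
    history = TrainingHistory(**meta["history"])
    return TrainedModel(
        architecture=meta["architecture"],
        network=network,
        history=history,
        seed=meta["seed"],
        classes=tuple(meta["classes"]),
        extra=meta.get("extra", {}),
    )


def model_content_hash(model: TrainedModel) -> str:
    """Deterministic digest of the weight arrays (independent of container
    metadata such as archive timestamps)."""
    h = hashlib.sha256()
    for key in sorted(model.network.state_arrays()):
        h.update(key.encode())
        h.update(np.ascontiguousarray(model.network.state_arrays()[key]).tobytes())
    return h.hexdigest()


def sha256_file(path: Path | str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
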