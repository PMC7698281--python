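"""Shared fixtures: a small simulated cohort, its event pool, and the
trained desk-scale detector reused by the learnability-dependent tests."""

from __future__ import annotations

import numpy as np
import pytest

import breathnet as bn


@pytest.fixture(scope="session")
def profile() -> bn.SubjectProfile:
    return bn.SubjectProfile()


@pytest.fixture(scope="session")
def cohort() -> list[bn.Recording]:
    return bn.simulate_cohort(3, seed=11)


@pytest.fixture(scope="session")
def pool(cohort) -> bn.EventPool:
    return bn.extract_event_pool(cohort)


@pytest.fixture(scope="session")
def single_session() -> bn.Recording:
    return bn.simulate_subject_session(seed=42, subject_id="s042")


@pytest.fixture(scope="session")
def learnability_run():
    """The 500-segment desk-scale detector run (trained once per session)."""
    report, detector, split = bn.learnability_experiment(
        n_segments=500, seed=7, n_subjects=10, epochs=15
    )
    return report, detector, split


def segments_to_arrays(segments, ids):
    by_id = {s.segment_id: s for s in segments}
    x = np.stack([by_id[i].data for i in ids]).astype(np.float32)
    y = np.array([by_id[i].labels for i in ids])
    return x, y
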