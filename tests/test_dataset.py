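"""Dataset builder contracts: pool extraction, injection-plan rules,
boundary smoothing vs a brute-force oracle, label bookkeeping, splits, and
the CSA duration distribution."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from scipy.stats import chisquare

import breathnet as bn
from breathnet.dataset import (
    DOUBLE_CSA_DURATIONS,
    SINGLE_CSA_DURATIONS,
    PlanEntry,
    SegmentPlanRecord,
)


class TestEventPool:
    def test_single_session_pool_counts(self, single_session):
        pool = bn.extract_event_pool([single_session])
        assert pool.counts() == {"csa": 1, "cough": 5, "sigh": 5, "yawn": 5, "osa": 5}

    def test_clips_keep_all_12_channels(self, pool):
        for clips in pool.clips_by_class.values():
            assert all(c.data.shape[1] == 12 for c in clips)

    def test_clip_counts_scale_with_sessions(self):
        sessions = bn.simulate_cohort(4, seed=5)
        pool = bn.extract_event_pool(sessions)
        assert len(pool.clips_by_class["cough"]) == 4 * 5

    def test_unannotated_recording_skipped_with_warning(self, single_session):
        bare = bn.Recording(data=single_session.data[:500], subject_id="bare")
        with pytest.warns(UserWarning, match="no annotations"):
            pool = bn.extract_event_pool([bare])
        assert sum(pool.counts().values()) == 0

    def test_empty_class_errors_at_injection_time(self, single_session):
        pool = bn.extract_event_pool([single_session])
        pool.clips_by_class["cough"] = []
        with pytest.raises(ValueError, match="cough"):
            pool.require("cough")


class TestInjectionPlans:
    def test_zero_event_plan_is_all_normal(self, pool):
        plan = bn.draw_injection_plan(0, pool, rng_seed=1)
        assert plan.n_events == 0
        assert plan.labels() == ["normal"] * 30

    def test_single_csa_durations_within_admissible_set(self, pool):
        rng = np.random.default_rng(2)
        durations = {
            e.duration_s
            for _ in range(3000)
            for e in bn.draw_injection_plan(1, pool, rng).entries
            if e.label == "csa"
        }
        assert durations <= set(SINGLE_CSA_DURATIONS)
        assert durations == set(SINGLE_CSA_DURATIONS)

    def test_two_event_halves_and_non_overlap(self, pool):
        rng = np.random.default_rng(3)
        for _ in range(3000):
            plan = bn.draw_injection_plan(2, pool, rng)
            first, second = sorted(plan.entries, key=lambda e: e.start_second)
            assert first.start_second + first.duration_s <= 15
            assert second.start_second >= 15
            assert second.start_second + second.duration_s <= 30
            if first.label == "csa":
                assert first.duration_s in DOUBLE_CSA_DURATIONS
            if second.label == "csa":
                assert second.duration_s in DOUBLE_CSA_DURATIONS

    def test_csa_duration_distribution_uniform(self, pool):
        """Empirical single-CSA duration distribution over >= 10^4 draws is
        uniform over {10, 20, 23} (chi-square p > 0.01)."""
        rng = np.random.default_rng(4)
        counts = Counter()
        draws = 0
        while draws < 10_000:
            plan = bn.draw_injection_plan(1, pool, rng)
            draws += 1
            for e in plan.entries:
                if e.label == "csa":
                    counts[e.duration_s] += 1
        observed = [counts[d] for d in SINGLE_CSA_DURATIONS]
        assert chisquare(observed).pvalue > 0.01

    def test_invalid_n_events_rejected(self, pool):
        with pytest.raises(ValueError):
            bn.draw_injection_plan(3, pool)

    def test_plan_validation_rejects_overlap(self):
        with pytest.raises(ValueError, match="overlap"):
            bn.InjectionPlan(
                [PlanEntry("cough", 5, 4, 0), PlanEntry("sigh", 7, 4, 0)]
            )


class TestSmoothing:
    def brute_force(self, data, span):
        """Independent re-derivation: explicit per-channel averaging."""
        a, b = span
        out = data.copy()
        for ch in range(12):
            if a > 0:
                out[a, ch] = (data[a, ch] + data[a - 1, ch]) / 2.0
            if b < data.shape[0]:
                out[b - 1, ch] = (data[b - 1, ch] + data[b, ch]) / 2.0
        return out

    @pytest.mark.parametrize("span", [(625, 1250), (0, 500), (3000, 3750), (1, 3749)])
    def test_matches_brute_force_bit_for_bit(self, span):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((3750, 12))
        assert np.array_equal(
            bn.smooth_boundary(data, span), self.brute_force(data, span)
        )

    def test_boundary_average_arithmetic(self):
        data = np.zeros((100, 12))
        data[:10] = 2.0   # normal context
        data[10:20] = 4.0  # injected event
        out = bn.smooth_boundary(data, (10, 20))
        assert np.all(out[10] == 3.0)   # (4 + 2) / 2
        assert np.all(out[19] == 2.0)   # (4 + 0) / 2
        assert np.all(out[11:19] == 4.0)

    def test_equal_values_unchanged(self):
        data = np.full((50, 12), 1.5)
        assert np.array_equal(bn.smooth_boundary(data, (10, 20)), data)

    def test_edge_spans_smooth_interior_side_only(self):
        rng = np.random.default_rng(9)
        data = rng.standard_normal((200, 12))
        left = bn.smooth_boundary(data, (0, 50))
        assert np.array_equal(left[0], data[0])            # no exterior smoothing
        assert not np.array_equal(left[49], data[49])
        right = bn.smooth_boundary(data, (150, 200))
        assert np.array_equal(right[199], data[199])
        assert not np.array_equal(right[150], data[150])


class TestInjection:
    def make_base(self):
        return bn.simulate_normal_breathing(30, seed=77).data

    def test_label_bookkeeping(self, pool):
        plan = bn.InjectionPlan([PlanEntry("cough", 5, 2, 0)])
        seg = bn.inject_events(self.make_base(), plan, pool)
        assert seg.labels[5] == seg.labels[6] == "cough"
        assert sum(lab == "normal" for lab in seg.labels) == 28

    def test_shape_conserved_for_any_plan(self, pool):
        rng = np.random.default_rng(10)
        for n_events in (0, 1, 2):
            plan = bn.draw_injection_plan(n_events, pool, rng)
            seg = bn.inject_events(self.make_base(), plan, pool)
            assert seg.data.shape == (3750, 12)
            assert len(seg.labels) == 30

    def test_empty_plan_identity(self, pool):
        base = self.make_base()
        seg = bn.inject_events(base, bn.InjectionPlan(), pool)
        assert np.array_equal(seg.data, base)

    def test_non_normal_seconds_exactly_cover_plan(self, pool):
        rng = np.random.default_rng(11)
        for _ in range(50):
            plan = bn.draw_injection_plan(int(rng.integers(0, 3)), pool, rng)
            seg = bn.inject_events(self.make_base(), plan, pool, rng)
            expected = plan.labels()
            assert seg.labels == expected

    def test_csa_clip_cropped_to_drawn_duration(self, pool):
        plan = bn.InjectionPlan([PlanEntry("csa", 0, 10, 0)])
        base = self.make_base()
        seg = bn.inject_events(base, plan, pool)
        clip = pool.clips_by_class["csa"][0]
        # interior of the injected span matches the clip's first 10 s
        assert np.allclose(seg.data[1 : 10 * 125 - 1], clip.data[1 : 10 * 125 - 1])

    def test_short_clip_error_names_the_clip(self, single_session):
        pool = bn.extract_event_pool([single_session])
        short = pool.clips_by_class["csa"][0]
        pool.clips_by_class["csa"] = [
            bn.EventClip("csa", short.data[: 5 * 125], short.source_subject)
        ]
        plan = bn.InjectionPlan([PlanEntry("csa", 0, 10, 0)])
        with pytest.raises(ValueError, match="shorter"):
            bn.inject_events(self.make_base(), plan, pool)


class TestDetectionDataset:
    def test_split_partition_and_sizes(self, pool):
        segments, split = bn.build_detection_dataset(pool, 50, seed=3)
        ids = {s.segment_id for s in segments}
        assert set(split.train) | set(split.validation) | set(split.test) == ids
        assert split.sizes == (30, 10, 10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_split_partition_property(self, pool, seed):
        _, split = bn.build_detection_dataset(pool, 17, seed=seed, materialize=False)
        all_ids = split.train + split.validation + split.test
        assert len(all_ids) == len(set(all_ids)) == 17

    def test_labeled_seconds_total(self, pool):
        records, _ = bn.build_detection_dataset(pool, 200, seed=1, materialize=False)
        assert sum(len(r.labels) for r in records) == 200 * 30

    def test_deterministic_given_seed(self, pool):
        a, sa = bn.build_detection_dataset(pool, 10, seed=9)
        b, sb = bn.build_detection_dataset(pool, 10, seed=9)
        assert [s.segment_id for s in a] == [s.segment_id for s in b]
        assert all(x.labels == y.labels for x, y in zip(a, b))
        assert np.array_equal(a[0].data, b[0].data)
        assert sa.train == sb.train

    def test_plan_level_build_matches_materialized(self, pool):
        full, s1 = bn.build_detection_dataset(pool, 12, seed=4)
        lite, s2 = bn.build_detection_dataset(pool, 12, seed=4, materialize=False)
        assert all(isinstance(r, SegmentPlanRecord) for r in lite)
        assert [f.labels for f in full] == [l.labels for l in lite]
        assert s1.train == s2.train

    def test_rejects_non_positive_n(self, pool):
        with pytest.raises(ValueError):
            bn.build_detection_dataset(pool, 0)


class TestClassificationDataset:
    def test_window_shape_and_feature_count(self, pool):
        windows, _ = bn.build_classification_dataset(pool, seed=0)
        assert all(w.data.shape == (875, 12) for w in windows)
        assert windows[0].data.size == 10_500

    def test_balance_downsamples_to_minimum(self, pool):
        windows, _ = bn.build_classification_dataset(pool, balance=True, seed=1)
        counts = Counter(w.label for w in windows)
        assert len(set(counts.values())) == 1
        unbalanced, _ = bn.build_classification_dataset(pool, balance=False, seed=1)
        assert min(counts.values()) == min(
            Counter(w.label for w in unbalanced).values()
        )

    def test_balance_off_keeps_counts(self, pool):
        windows, _ = bn.build_classification_dataset(pool, balance=False, seed=2)
        counts = Counter(w.label for w in windows)
        for cls in bn.EVENT_CLASSES:
            assert counts[cls] == len(pool.clips_by_class[cls])

    def test_long_event_cropped_with_warning(self, pool):
        with pytest.warns(UserWarning, match="cropped"):
            bn.build_classification_dataset(pool, seed=3)

    def test_non_integral_window_rejected(self, pool):
        with pytest.raises(ValueError, match="integer"):
            bn.build_classification_dataset(pool, window_s=0.33)
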