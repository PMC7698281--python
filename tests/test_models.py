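"""Architecture audits, estimator contracts, determinism, channel masking,
random search, and the scale-equivariance shape relation."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.base import clone

import breathnet as bn
from breathnet.configs import ClassifierConfig, DetectorConfig, config_from_yaml, config_to_yaml
from breathnet.models import (
    build_classifier,
    build_detector,
    describe_classifier,
    describe_detector,
    random_search,
)


class TestArchitectureAudit:
    @pytest.mark.parametrize("output", ["binary", "multi"])
    def test_classifier_has_6_conv_and_4_fc_layers(self, output):
        for config in (ClassifierConfig.paper(output), ClassifierConfig.desk(output)):
            desc = describe_classifier(config)
            assert desc.n_conv_layers == 6
            assert desc.n_fc_layers == 4
            net = build_classifier(config if config.scale == "desk" else ClassifierConfig.desk(output))
            counts = net.layer_counts()
            assert counts["conv"] == 6 and counts["fc"] == 4

    def test_detector_trunk_is_1_plus_8_convs(self):
        desc = describe_detector(DetectorConfig.desk())
        assert desc.n_conv_layers == 9  # initial conv + 4 blocks x 2
        net = build_detector(DetectorConfig.desk())
        assert net.layer_counts()["conv"] == 9
        assert net.layer_counts()["residual_blocks"] == 4

    def test_detector_block_widths_double(self):
        assert DetectorConfig.paper().block_filters == (64, 128, 256, 512)
        assert DetectorConfig.desk().block_filters == (8, 16, 32, 64)

    def test_paper_detector_parameter_count_exceeds_1e8(self):
        assert describe_detector(DetectorConfig.paper()).total_params > 1e8

    def test_desk_description_matches_materialized_network(self):
        config = DetectorConfig.desk()
        desc = describe_detector(config)
        assert build_detector(config).param_count() == desc.total_params
        cconfig = ClassifierConfig.desk()
        assert build_classifier(cconfig).param_count() == describe_classifier(
            cconfig
        ).total_params

    def test_invalid_stride_schedule_rejected(self):
        with pytest.raises(ValueError, match="downsample"):
            DetectorConfig(block_strides=(5, 5, 2, 1))

    def test_scale_equivariance_shape_relation(self):
        # a 10-s desk variant preserves input length = outputs x 125
        for seconds in (10, 30):
            config = DetectorConfig.desk(segment_s=seconds)
            assert config.input_samples == config.per_second_outputs * 125
            net = build_detector(config)
            x = np.random.default_rng(0).standard_normal(
                (2, config.input_samples, 12)
            ).astype(np.float32)
            assert net.forward(x).shape == (2, seconds, 6)

    def test_config_yaml_roundtrip(self):
        config = DetectorConfig.desk()
        assert config_from_yaml(config_to_yaml(config)) == config


class TestClassifierEstimator:
    def make_windows(self, n_per_class=6, classes=("normal", "csa"), seed=0):
        xs, ys = [], []
        for i, cls in enumerate(classes):
            for j in range(n_per_class):
                s = seed + 100 * i + j
                if cls == "normal":
                    rec = bn.simulate_normal_breathing(7, seed=s)
                else:
                    rec = bn.simulate_event_clip(cls, 7 if cls != "csa" else 7, seed=s)
                xs.append(rec.data)
                ys.append(cls)
        return np.stack(xs).astype(np.float32), np.array(ys)

    def test_binary_scores_lie_in_unit_interval(self):
        x, y = self.make_windows()
        clf = bn.BreathingEventClassifier(mode="binary", epochs=3, seed=0)
        clf.fit(x, y)
        scores = clf.decision_scores(x)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_multi_probabilities_normalize(self):
        x, y = self.make_windows(classes=("normal", "csa", "cough"), n_per_class=4)
        clf = bn.BreathingEventClassifier(mode="multi", epochs=2, seed=1)
        clf.fit(x, y)
        p = clf.predict_proba(x)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_flattened_input_accepted(self):
        x, y = self.make_windows(n_per_class=3)
        clf = bn.BreathingEventClassifier(mode="binary", epochs=1, seed=2)
        clf.fit(x.reshape(len(x), -1), y)
        assert clf.predict(x.reshape(len(x), -1)).shape == (len(x),)

    def test_sklearn_clone_and_get_params(self):
        clf = bn.BreathingEventClassifier(mode="binary", epochs=5, seed=3)
        cloned = clone(clf)
        assert cloned.get_params()["epochs"] == 5

    def test_binary_mode_requires_two_classes(self):
        x, y = self.make_windows(classes=("normal", "csa", "cough"), n_per_class=2)
        with pytest.raises(ValueError, match="2 classes"):
            bn.BreathingEventClassifier(mode="binary", epochs=1).fit(x, y)

    def test_learns_csa_vs_normal(self):
        x, y = self.make_windows(n_per_class=12, seed=50)
        xt, yt = self.make_windows(n_per_class=6, seed=900)
        clf = bn.BreathingEventClassifier(
            mode="binary", epochs=8, batch_size=8, seed=4, validation_fraction=0.0
        )
        clf.fit(x, y)
        assert clf.score(xt, yt) >= 0.9


@pytest.fixture(scope="module")
def tiny_data(pool):
    segments, _ = bn.build_detection_dataset(pool, 16, seed=21)
    x = np.stack([s.data for s in segments]).astype(np.float32)
    y = np.array([s.labels for s in segments])
    return x, y


class TestDetectorEstimator:
    def test_predicts_30_labels_with_normalized_rows(self, tiny_data):
        x, y = tiny_data
        det = bn.BreathingEventDetector(epochs=1, batch_size=8, seed=0,
                                        validation_fraction=0.0)
        det.fit(x, y)
        probs = det.predict_proba(x[:3])
        assert probs.shape == (3, 30, 6)
        np.testing.assert_allclose(probs.sum(axis=2), 1.0, atol=1e-6)
        labels, p = bn.predict_segment_labels(det.model_, det._prepare(
            bn.estimators._as_3d(x[:1], 3750), fit_stats=False)[0])
        assert len(labels) == 30

    def test_same_seed_identical_fit(self, tiny_data):
        x, y = tiny_data
        hists = []
        for _ in range(2):
            det = bn.BreathingEventDetector(epochs=2, batch_size=8, seed=5,
                                            validation_fraction=0.25)
            det.fit(x, y)
            hists.append((det.history_.train_loss, det.history_.val_loss))
        assert hists[0] == hists[1]

    def test_wrong_label_shape_rejected(self, tiny_data):
        x, y = tiny_data
        det = bn.BreathingEventDetector(epochs=1)
        with pytest.raises(ValueError, match="shape"):
            det.fit(x, y[:, :10])

    def test_channel_mask_accepts_accel_only(self, tiny_data):
        x, y = tiny_data
        accel = [n for n in bn.ChannelLayout().names if "accel" in n]
        det = bn.BreathingEventDetector(epochs=1, batch_size=8, seed=1,
                                        channel_mask=accel, validation_fraction=0.0)
        det.fit(x, y)
        assert det.predict(x[:2]).shape == (2, 30)


class TestRandomSearch:
    def test_budget_determinism_and_min_selection(self):
        space = bn.SearchSpace(batch_sizes=(8, 16), learning_rates=(1e-2, 1e-3))
        calls = []

        def train_fn(params):
            calls.append(params)
            return params["lr"] * params["batch_size"]

        best, trials = bn.random_search(space, budget=7, train_fn=train_fn, seed=3)
        assert len(trials) == 7 == len(calls)
        assert best == min(trials, key=lambda t: t.val_loss).params
        best2, trials2 = bn.random_search(
            space, budget=7, train_fn=lambda p: p["lr"] * p["batch_size"], seed=3
        )
        assert [t.params for t in trials] == [t.params for t in trials2]

    def test_zero_budget_rejected(self):
        with pytest.raises(ValueError):
            bn.random_search(bn.SearchSpace(), 0, lambda p: 0.0)
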