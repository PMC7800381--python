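"""Burst grouping, feature algebra, reference normalization, and the SOM
classifier: oracle equivalences and end-to-end label recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lfpburst import bursts as bc
from lfpburst import detect, simulate
from lfpburst.bursts import (
    Burst,
    ReferenceScaler,
    SOMBurstClassifier,
    assign_node_classes,
    classify_burst,
    compute_features,
    group_bursts,
    normalize_features,
    quantization_error,
    train_som,
)


def brute_force_group(times, max_isi):
    """Independent single-pass gap scan."""
    groups, current = [], [times[0]] if len(times) else []
    for prev, t in zip(times, times[1:]):
        if t - prev < max_isi:
            current.append(t)
        else:
            groups.append(current)
            current = [t]
    if current:
        groups.append(current)
    return groups


class TestGrouping:
    def test_gap_splitting_example(self):
        bursts, loose = group_bursts(np.array([0, 1, 2, 10, 11.0]),
                                     max_isi_s=2.5, min_spikes=2)
        assert [(b.start_s, b.end_s) for b in bursts] == [(0, 2), (10, 11)]
        assert loose.size == 0

    def test_empty_input(self):
        bursts, loose = group_bursts(np.empty(0))
        assert bursts == [] and loose.size == 0

    def test_runs_below_min_spikes_become_loose_spikes(self):
        bursts, loose = group_bursts(np.array([0.0, 1.0, 10.0, 11.0, 12.0]),
                                     min_spikes=3)
        assert len(bursts) == 1 and bursts[0].n_spikes == 3
        assert loose.tolist() == [0.0, 1.0]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            group_bursts(np.array([1.0, 0.5]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_gap_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        times = np.sort(rng.uniform(0, 300, 1000))
        bursts, loose = group_bursts(times, 2.5, min_spikes=1)
        expected = brute_force_group(times, 2.5)
        assert len(bursts) == len(expected)
        for b, e in zip(bursts, expected):
            np.testing.assert_allclose(b.spike_times, e)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(0, 100, 200))
        bursts, _ = group_bursts(times, 2.5, min_spikes=1)
        for b in bursts:
            again, loose = group_bursts(b.spike_times, 2.5, min_spikes=1)
            assert len(again) == 1 and loose.size == 0
            np.testing.assert_allclose(again[0].spike_times, b.spike_times)

    def test_boundary_gap_exactly_at_threshold_splits_when_strict(self):
        times = np.array([0.0, 2.5, 5.0])
        bursts, _ = group_bursts(times, 2.5, min_spikes=1, strict=True)
        assert len(bursts) == 3
        bursts, _ = group_bursts(times, 2.5, min_spikes=1, strict=False)
        assert len(bursts) == 1


class TestFeatures:
    @pytest.mark.parametrize("n,isi,expected", [
        (10, 0.5, [1.0, np.log10(0.5), 0.0]),
        (100, 0.1, [2.0, -1.0, 0.0]),
    ])
    def test_constant_isi_cases(self, n, isi, expected):
        b = Burst(np.arange(n) * isi)
        np.testing.assert_allclose(compute_features(b), expected, atol=1e-12)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(7)
        times = np.sort(rng.uniform(0, 30, 40))
        y = compute_features(Burst(times))
        isis = np.diff(times)
        np.testing.assert_allclose(
            y, [np.log10(40), np.log10(isis.mean()), isis.std(ddof=1)])

    def test_too_few_spikes_unclassifiable(self):
        with pytest.raises(ValueError, match="3 spikes"):
            compute_features(Burst(np.array([0.0, 1.0])))


class TestReferenceScaler:
    def test_mean_of_two_vectors(self):
        s = ReferenceScaler().fit(np.array([[0, 0, 0], [2, 2, 2.0]]))
        np.testing.assert_allclose(s.mean_, [1, 1, 1])

    def test_self_normalization_moments(self, reference_corpus):
        X, _ = reference_corpus
        s = ReferenceScaler().fit(X)
        Xn = s.transform(X)
        np.testing.assert_allclose(Xn.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(Xn.std(axis=0, ddof=1), [2, 2, 1],
                                   atol=1e-9)

    def test_unit_deviation_maps_to_weights(self, reference_corpus):
        X, _ = reference_corpus
        s = ReferenceScaler().fit(X)
        np.testing.assert_allclose(
            normalize_features(s.mean_ + s.scale_, s), [2, 2, 1], atol=1e-12)
        np.testing.assert_allclose(normalize_features(s.mean_, s), [0, 0, 0],
                                   atol=1e-12)

    def test_elementwise_formula(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 3))
        s = ReferenceScaler().fit(X)
        y = rng.normal(size=3)
        expected = [(y[d] - s.mean_[d]) / s.scale_[d] * [2, 2, 1][d]
                    for d in range(3)]
        np.testing.assert_allclose(normalize_features(y, s), expected)

    def test_inverse_roundtrip(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        s = ReferenceScaler().fit(X)
        Y = rng.normal(size=(10, 3))
        np.testing.assert_allclose(s.inverse_transform(s.transform(Y)), Y,
                                   atol=1e-12)

    def test_zero_variance_dimension_named(self):
        X = np.array([[1, 0, 1], [1, 1, 2], [1, 2, 3.0]])
        with pytest.raises(ValueError, match="dimension 0"):
            ReferenceScaler().fit(X)


class TestSOM:
    def test_identical_corpus_collapses_prototypes(self):
        v = np.array([1.5, -0.5, 2.0])
        X = np.tile(v, (50, 1))
        protos, _ = train_som(X, (3, 3), epochs=30, seed=0)
        assert np.all(np.abs(protos - v) < 1e-6)

    def test_separated_clusters_claim_nearest_nodes(self):
        rng = np.random.default_rng(4)
        centers = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0.0]])
        X = np.vstack([c + 0.3 * rng.normal(size=(40, 3)) for c in centers])
        protos, _ = train_som(X, (6, 6), epochs=40, seed=1)
        for c in centers:
            bmu = np.argmin(((protos - c) ** 2).sum(1))
            d = np.linalg.norm(protos[bmu] - centers, axis=1)
            assert np.argmin(d) == np.flatnonzero(
                (centers == c).all(axis=1))[0]

    def test_same_seed_identical_prototypes(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 3))
        a, _ = train_som(X, (4, 4), epochs=10, seed=3)
        b, _ = train_som(X, (4, 4), epochs=10, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_quantization_error_bounded(self, reference_corpus, som_model):
        X, _ = reference_corpus
        Xn = som_model.scaler_.transform(X)
        assert quantization_error(Xn, som_model.prototypes_) < 1.0

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_som(np.empty((0, 3)), (3, 3))


class TestNodeClasses:
    def test_threshold_rule_on_backtransformed_count(self, reference_corpus):
        X, _ = reference_corpus
        s = ReferenceScaler().fit(X)
        protos = s.transform(np.array([[np.log10(5), 0, 0.1],
                                       [np.log10(50), 0, 0.1],
                                       [np.log10(500), 0, 0.1]]))
        classes, log = assign_node_classes(protos, s, (10.0, 100.0))
        assert classes.tolist() == ["low", "medium", "high"]
        assert log == []

    def test_identical_prototypes_same_class(self, reference_corpus):
        X, _ = reference_corpus
        s = ReferenceScaler().fit(X)
        protos = np.tile(s.transform(np.array([[1.0, 0, 0.1]]))[0], (4, 1))
        classes, _ = assign_node_classes(protos, s, (12.0, 80.0))
        assert len(set(classes)) == 1

    def test_label_mode_recovers_heldout_cluster_classes(self):
        feats, labels = simulate.generate_reference_corpus(400, seed=31)
        X, y = feats.to_numpy(), labels
        train_idx = np.arange(0, len(X), 2)
        test_idx = np.arange(1, len(X), 2)
        model = SOMBurstClassifier(grid_shape=(8, 8), epochs=30,
                                   random_state=2)
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        assert (pred == y[test_idx]).mean() >= 0.9


class TestClassification:
    def test_prototype_vector_gets_node_class(self, som_model):
        for i in (0, 17, 63):
            assert classify_burst(som_model.prototypes_[i],
                                  som_model.prototypes_,
                                  som_model.node_classes_) == \
                som_model.node_classes_[i]

    def test_equidistant_tie_breaks_to_lowest_index(self):
        protos = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        classes = np.array(["low", "high"], dtype=object)
        assert classify_burst(np.zeros(3), protos, classes) == "low"

    def test_matches_exhaustive_scan(self, som_model):
        rng = np.random.default_rng(8)
        Y = rng.normal(0, 3, size=(500, 3))
        pred = som_model.predict(som_model.scaler_.inverse_transform(Y))
        for y, p in zip(Y, pred):
            d = np.linalg.norm(som_model.prototypes_ - y, axis=1)
            assert p == som_model.node_classes_[np.argmin(d)]

    def test_non_finite_vector_rejected(self, som_model):
        with pytest.raises(ValueError, match="finite"):
            classify_burst(np.array([np.nan, 0, 0]),
                           som_model.prototypes_, som_model.node_classes_)

    def test_order_invariance(self, som_model, reference_corpus):
        X, _ = reference_corpus
        perm = np.random.default_rng(0).permutation(len(X))
        a = som_model.predict(X)
        b = som_model.predict(X[perm])
        np.testing.assert_array_equal(a[perm], b)

    def test_json_roundtrip(self, som_model, tmp_path):
        p = tmp_path / "som.json"
        som_model.to_json(p)
        loaded = SOMBurstClassifier.from_json(p)
        np.testing.assert_array_equal(loaded.prototypes_,
                                      som_model.prototypes_)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3)) + [1.5, -0.3, 0.2]
        np.testing.assert_array_equal(loaded.predict(X),
                                      som_model.predict(X))


class TestEndToEndRecovery:
    def test_detected_bursts_inherit_generating_class(self, som_model):
        """>= 90% of detected bursts get their generating load class."""
        correct = total = 0
        for seed in range(10):
            plan = simulate.SessionPlan(
                [simulate.SubSessionPlan(
                    "pre", 240.0,
                    {"low": 0.008, "medium": 0.004, "high": 0.001})],
                seed=100 + seed, fs=2000.0)
            rec, _, gt, _ = simulate.generate_session(plan)
            train = detect.detect_spikes(rec.channel("idHC"), rec.fs)
            bursts, _ = group_bursts(train.times)
            som_model.classify_bursts(bursts)
            truth = {round(b.start_s, 1): b.intended_class
                     for b in gt.bursts}
            for b in bursts:
                match = [c for s, c in truth.items()
                         if abs(s - b.start_s) < 1.5]
                if match:
                    total += 1
                    correct += match[0] == b.label
        assert total >= 20
        assert correct / total >= 0.9
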