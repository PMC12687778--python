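"""Classifier contracts: determinism, protocol enforcement, hybrids, slices."""

import dataclasses

import numpy as np
import pytest

from salnet import (
    ModelConfig,
    ProtocolError,
    SizingError,
    TrainSpec,
    ValidationError,
    build_classifier,
    classify_controls,
    hybrid_classify,
    make_split,
    slice_range_evaluation,
    to_feature_model,
    train_classifier,
)

FAST = dict(epochs=5, batch_size=8, learning_rate=2e-3)


def tiny_model(seed=0, head="softmax", feature_dim=None):
    return build_classifier(ModelConfig(
        dimensionality=3, depth_preset="tiny", width_scale=0.25,
        head=head, feature_dim=feature_dim, seed=seed))


@pytest.fixture(scope="module")
def trained(small_cohort):
    records, volumes, _, _ = small_cohort
    train_ids, test_ids = make_split(records, 6, seed=7)
    spec = TrainSpec(train_ids=train_ids, test_ids=test_ids, seed=7, **FAST)
    model, result = train_classifier(tiny_model(seed=7), volumes, records, spec)
    return model, result, spec


class TestBuild:
    def test_same_config_gives_identical_initial_parameters(self):
        a, b = tiny_model(seed=3), tiny_model(seed=3)
        for (pa, _), (pb, _) in zip(a.params(), b.params()):
            assert np.array_equal(pa, pb)

    def test_feature_head_outputs_requested_width(self, small_cohort):
        _, volumes, _, _ = small_cohort
        m = tiny_model(head="feature", feature_dim=64)
        out = m.forward_volumes(volumes[:2])
        assert out.shape == (2, 64)

    def test_width_scale_quarters_channels_squares_parameters(self):
        full = build_classifier(ModelConfig(depth_preset="tiny", width_scale=1.0))
        quarter = build_classifier(ModelConfig(depth_preset="tiny", width_scale=0.25))
        from salnet import nn
        convs_f = [l for l in _iter_convs(full)]
        convs_q = [l for l in _iter_convs(quarter)]
        assert len(convs_f) == len(convs_q)
        ratios = [q.W.size / f.W.size for f, q in zip(convs_f, convs_q)]
        # stem has a fixed single input channel -> ratio 0.25; every inner
        # conv scales both fan-in and fan-out -> ratio 0.25 ** 2
        assert ratios[0] == pytest.approx(0.25)
        for r in ratios[1:]:
            assert r == pytest.approx(0.0625)

    def test_grid_below_downsampling_raises(self, small_cohort):
        m = tiny_model()
        with pytest.raises(SizingError):
            m.logits(np.zeros((1, 1, 4, 4, 4), dtype=np.float32))

    def test_feature_dim_required_iff_feature_head(self):
        with pytest.raises(ValidationError):
            ModelConfig(head="feature")
        with pytest.raises(ValidationError):
            ModelConfig(head="softmax", feature_dim=10)


def _iter_convs(model):
    from salnet import nn
    stack = list(model.body.layers)
    while stack:
        l = stack.pop(0)
        if isinstance(l, nn.Conv):
            yield l
        elif isinstance(l, nn.Bottleneck):
            stack = l.main.layers + (l.skip.layers if l.skip else []) + stack
        elif isinstance(l, nn.Sequential):
            stack = l.layers + stack


class TestProtocol:
    def test_control_subject_in_training_set_rejected(self, small_cohort):
        records, volumes, _, _ = small_cohort
        ctrl = next(r.subject_id for r in records if r.group == "control")
        train_ids, test_ids = make_split(records, 6, seed=1)
        spec = TrainSpec(train_ids=train_ids + [ctrl], test_ids=test_ids, **FAST)
        with pytest.raises(ProtocolError, match="control"):
            train_classifier(tiny_model(), volumes, records, spec)

    def test_overlapping_train_test_ids_rejected(self, small_cohort):
        records, volumes, _, _ = small_cohort
        train_ids, test_ids = make_split(records, 6, seed=1)
        spec = TrainSpec(train_ids=train_ids, test_ids=test_ids + train_ids[:1],
                         **FAST)
        with pytest.raises(ProtocolError, match="overlap"):
            train_classifier(tiny_model(), volumes, records, spec)

    def test_single_group_test_set_rejected(self, small_cohort):
        records, volumes, _, _ = small_cohort
        train_ids, _ = make_split(records, 6, seed=1)
        highs = [r.subject_id for r in records if r.group == "high"
                 and r.subject_id not in train_ids]
        spec = TrainSpec(train_ids=train_ids, test_ids=highs, **FAST)
        with pytest.raises(ProtocolError):
            train_classifier(tiny_model(), volumes, records, spec)


class TestTraining:
    def test_training_is_deterministic_and_beats_chance(self, small_cohort, trained):
        records, volumes, _, _ = small_cohort
        model, result, spec = trained
        assert result.accuracy > 0.5  # strongly separable small cohort
        model2, result2 = train_classifier(tiny_model(seed=7), volumes, records,
                                           dataclasses.replace(spec))
        assert result2.accuracy == result.accuracy
        assert result2.predictions == result.predictions

    def test_history_is_logged(self, trained):
        _, result, spec = trained
        assert len(result.history) == spec.epochs
        assert {"epoch", "loss", "train_accuracy"} <= set(result.history[0])


class TestHybrid:
    def test_requires_feature_head(self, small_cohort, trained):
        records, volumes, _, _ = small_cohort
        model, _, spec = trained
        with pytest.raises(ValidationError, match="feature"):
            hybrid_classify(model, volumes, records, spec)

    def test_k_validation(self, small_cohort, trained):
        records, volumes, _, _ = small_cohort
        model, _, spec = trained
        fm = to_feature_model(model, 16, seed=1)
        with pytest.raises(ValidationError, match="exceeds"):
            hybrid_classify(fm, volumes, records, spec, k=999)
        with pytest.raises(ValidationError, match="odd"):
            hybrid_classify(fm, volumes, records, spec, k=4)

    def test_nearest_neighbour_identity_at_k1(self, small_cohort, trained):
        # a test volume byte-identical to a training volume has an identical
        # feature vector, so 1-NN must return that training subject's label
        records, volumes, _, _ = small_cohort
        model, _, spec = trained
        fm = to_feature_model(model, 16, seed=1)
        by_id = {r.subject_id: r for r in records}
        donor = spec.train_ids[0]
        volumes2 = list(volumes)
        ids = [r.subject_id for r in records]
        target = spec.test_ids[0]
        volumes2[ids.index(target)] = volumes[ids.index(donor)]
        res = hybrid_classify(fm, volumes2, records, spec, k=1)
        assert res.predictions[target] == by_id[donor].group

    def test_invariant_to_training_subject_order(self, small_cohort, trained):
        records, volumes, _, _ = small_cohort
        model, _, spec = trained
        fm = to_feature_model(model, 16, seed=1)
        res1 = hybrid_classify(fm, volumes, records, spec, k=3)
        shuffled = dataclasses.replace(
            spec, train_ids=list(reversed(spec.train_ids)))
        res2 = hybrid_classify(fm, volumes, records, shuffled, k=3)
        assert res1.predictions == res2.predictions

    def test_svm_head_runs(self, small_cohort, trained):
        records, volumes, _, _ = small_cohort
        model, _, spec = trained
        fm = to_feature_model(model, 16, seed=1)
        res = hybrid_classify(fm, volumes, records, spec, head="svm")
        assert 0.0 <= res.accuracy <= 1.0
        assert res.variant == "hybrid-svm"


class TestControls:
    def test_empty_control_set_rejected(self, trained):
        model, _, _ = trained
        with pytest.raises(ValidationError, match="empty"):
            classify_controls(model, [])

    def test_fraction_matches_model_predictions_on_same_volumes(
            self, small_cohort, trained):
        records, volumes, _, _ = small_cohort
        model, _, spec = trained
        low_train = [v for r, v in zip(records, volumes)
                     if r.subject_id in spec.train_ids and r.group == "low"]
        frac = classify_controls(model, low_train)
        preds = model.predict_labels(low_train)
        assert frac == pytest.approx(np.mean([p == "low" for p in preds]))


class TestCheckpoints:
    def test_save_load_round_trip_preserves_predictions(self, small_cohort,
                                                        trained, tmp_path):
        from salnet.classifiers import load_model, save_model
        records, volumes, _, _ = small_cohort
        model, _, spec = trained
        p = tmp_path / "model.npz"
        save_model(model, p)
        back = load_model(p)
        test_vols = [v for r, v in zip(records, volumes)
                     if r.subject_id in spec.test_ids]
        assert back.predict_labels(test_vols) == model.predict_labels(test_vols)


class TestHeadComparison:
    def test_reports_all_three_heads_under_identical_seeds(self, small_cohort):
        from salnet import compare_heads
        records, volumes, _, _ = small_cohort
        train_ids, test_ids = make_split(records, 6, seed=4)
        spec = TrainSpec(train_ids=train_ids, test_ids=test_ids, seed=4,
                         epochs=2, batch_size=8, learning_rate=2e-3)
        base = ModelConfig(depth_preset="tiny", width_scale=0.25, seed=4)
        out = compare_heads(volumes, records, spec, base=base)
        assert set(out) == {"softmax", "tanh", "sigmoid"}
        for head, res in out.items():
            assert res.variant == head
            assert 0.0 <= res.accuracy <= 1.0


class TestSliceRanges:
    def test_group_count_and_leakage_guard(self, small_cohort):
        records, volumes, _, _ = small_cohort
        train_ids, test_ids = make_split(records, 6, seed=2)
        spec = TrainSpec(train_ids=train_ids, test_ids=test_ids, seed=2,
                         epochs=2, batch_size=16, learning_rate=2e-3)
        res = slice_range_evaluation(volumes, records, "sagittal", spec,
                                     start=4, stop=19, group_size=8)
        assert len(res) == (19 - 4 + 1) // 8 == 2
        assert all(0.0 <= r["accuracy"] <= 1.0 for r in res)
        with pytest.raises(ValidationError):
            slice_range_evaluation(volumes, records, "sagittal", spec,
                                   start=4, stop=18, group_size=8)
        with pytest.raises(ValidationError, match="slices"):
            slice_range_evaluation(volumes, records, "axial", spec,
                                   start=24, stop=103, group_size=8)

    def test_left_confined_effect_peaks_in_left_slice_groups(self):
        from conftest import small_config
        from salnet import generate_cohort
        cfg = small_config(affected_left_fraction=1.0,
                           affected_subcortical_per_block=0,
                           asymmetry_factor=1.0,
                           n_high=14, n_low=14, n_control=1, seed=9)
        records, volumes, _, _ = generate_cohort(cfg)
        train_ids, test_ids = make_split(records, 8, seed=9)
        spec = TrainSpec(train_ids=train_ids, test_ids=test_ids, seed=9,
                         epochs=6, batch_size=16, learning_rate=2e-3)
        # grid 24: sagittal indices 0-11 are the right hemisphere, 12-23 left
        res = slice_range_evaluation(volumes, records, "sagittal", spec,
                                     start=4, stop=19, group_size=8)
        right, left = res[0]["accuracy"], res[1]["accuracy"]
        assert left > right
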