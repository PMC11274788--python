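"""Training-lattice fit, Hamming prediction, rules, and audits."""

import numpy as np
import pytest

from fcakit.classifier import (
    TrainedModel,
    TrainingSet,
    extract_rules,
    feature_class_summary,
    fit,
    hamming,
    predict,
)
from fcakit.context import ContextError
from fcakit.datasets import demo_context, demo_labels


@pytest.fixture
def demo_model() -> TrainedModel:
    ctx = demo_context()
    y = demo_labels()
    return fit(
        TrainingSet(
            ctx.incidence,
            [y[o] for o in ctx.objects],
            attributes=ctx.attributes,
            object_ids=ctx.objects,
        )
    )


def concept_by_intent(model, intent):
    (c,) = [c for c in model.lattice.concepts if c.intent == intent]
    return c


class TestFit:
    def test_duplicates_collapse_with_label_multiset(self, demo_model):
        # images 2 and 3 share the vector (1,1,0,0): one unique object,
        # both labels retained
        assert demo_model.unique_ids == ("1", "2", "4", "5", "6")
        i = demo_model.unique_ids.index("2")
        assert demo_model.label_multisets[i] == (1, 1)

    def test_hand_trace_concept_labels(self, demo_model):
        m = demo_model
        c_ab = concept_by_intent(m, ("a", "b"))
        assert m.concept_labels[c_ab.index] == 1
        assert m.concept_counts[c_ab.index] == {1: 4}
        c_ac = concept_by_intent(m, ("a", "c"))
        assert m.concept_counts[c_ac.index] == {0: 1, 1: 1}
        # 1:1 tie resolved to the smallest class label and logged
        assert m.concept_labels[c_ac.index] == 0
        assert c_ac.index in m.tie_log

    def test_empty_extent_concept_unlabeled(self, demo_model):
        bottom = demo_model.lattice.bottom_index
        assert demo_model.lattice.concepts[bottom].extent == ()
        assert demo_model.concept_labels[bottom] is None

    def test_label_conservation_at_top(self, demo_model):
        top = demo_model.lattice.top_index
        assert sum(demo_model.concept_counts[top].values()) == 6
        assert demo_model.n_training_rows == 6

    def test_all_rows_identical(self):
        X = np.ones((4, 3), int)
        with pytest.warns(UserWarning, match="single class"):
            m = fit(TrainingSet(X, ["b"] * 4))
        assert len(m.unique_ids) == 1
        for c in m.lattice.concepts:
            if m.concept_labels[c.index] is not None:
                assert m.concept_labels[c.index] == "b"

    def test_permutation_invariance_of_labels(self, demo_model):
        ctx = demo_context()
        y = demo_labels()
        rng = np.random.default_rng(3)
        perm = rng.permutation(6)
        m2 = fit(
            TrainingSet(
                ctx.incidence[perm],
                [y[ctx.objects[i]] for i in perm],
                attributes=ctx.attributes,
                object_ids=[ctx.objects[i] for i in perm],
            )
        )
        a = {c.intent: demo_model.concept_labels[c.index]
             for c in demo_model.lattice.concepts}
        b = {c.intent: m2.concept_labels[c.index] for c in m2.lattice.concepts}
        assert a == b

    def test_rejects_non_binary_and_empty(self):
        with pytest.raises(ContextError, match="binary"):
            TrainingSet(np.array([[2, 0]]), ["x"])
        with pytest.raises(ContextError, match="empty"):
            TrainingSet(np.zeros((0, 2), int), [])


class TestHamming:
    def test_indicator_of_own_intent_is_zero(self):
        assert hamming([1, 1, 0, 0], ("a", "b"), ("a", "b", "c", "d")) == 0

    def test_two_position_difference(self):
        assert hamming([1, 0, 1, 0], ("a", "b"), ("a", "b", "c", "d")) == 2

    def test_all_ones_vs_empty_intent(self):
        assert hamming([1, 1, 1, 1], (), ("a", "b", "c", "d")) == 4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContextError, match="length"):
            hamming([1, 0], ("a",), ("a", "b", "c"))


class TestPredict:
    def test_zero_distance_to_ab_gives_class_1(self, demo_model):
        (p,) = predict(demo_model, [[1, 1, 0, 0]])
        assert p.label == 1 and p.distance == 0
        winner = demo_model.lattice.concepts[p.concept_index]
        assert winner.intent == ("a", "b")

    def test_tie_broken_ac_vector_gives_class_0(self, demo_model):
        (p,) = predict(demo_model, [[1, 0, 1, 0]])
        assert p.label == 0 and p.distance == 0

    def test_zero_distance_dominance(self):
        X = np.array([[1, 1, 0], [0, 0, 1]])
        m = fit(TrainingSet(X, ["pos", "neg"]))
        (p,) = predict(m, [[0, 0, 1]])
        assert p.label == "neg" and p.distance == 0

    def test_output_order_and_ids(self, demo_model):
        preds = predict(demo_model, [[1, 0, 0, 0], [1, 1, 1, 0]],
                        object_ids=["u", "v"])
        assert [p.object_id for p in preds] == ["u", "v"]

    def test_distance_bounds_and_label_consistency(self, demo_model):
        rng = np.random.default_rng(5)
        X = (rng.random((40, 4)) < 0.5).astype(int)
        for p in predict(demo_model, X):
            assert 0 <= p.distance <= 4
            assert p.n_tied >= 1
            assert p.label == demo_model.concept_labels[p.concept_index]

    def test_distance_tie_prefers_larger_extent(self, demo_model):
        # (1,0,0,1) is at distance 1 from intents {a} (extent size 5) and
        # {a,b,d} (extent size 1): the better-supported concept wins
        (p,) = predict(demo_model, [[1, 0, 0, 1]])
        winner = demo_model.lattice.concepts[p.concept_index]
        assert p.distance == 1
        assert p.n_tied == 2
        assert winner.intent == ("a",)
        assert p.label == 1

    def test_training_vector_with_unambiguous_own_concept(self):
        X = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]])
        m = fit(TrainingSet(X, ["a", "a", "b"]))
        (p,) = predict(m, [[1, 1, 0]])
        assert p.label == "a"

    def test_column_mismatch_rejected(self, demo_model):
        with pytest.raises(ContextError, match="columns"):
            predict(demo_model, [[1, 0]])
        with pytest.raises(ContextError, match="attribute"):
            predict(demo_model, [[1, 0, 0, 0]], attributes=("x", "y", "z", "w"))


class TestRules:
    def test_demo_rules(self, demo_model):
        rules = extract_rules(demo_model)
        assert len(rules) == 5  # one per labeled concept
        top_rule = rules[0]
        assert top_rule.intent == ("a", "b")
        assert top_rule.label == 1
        assert top_rule.support == 4
        assert top_rule.confidence == 1.0

    def test_pure_extent_gives_confidence_one(self):
        X = np.array([[1, 0], [1, 0], [0, 1]])
        m = fit(TrainingSet(X, [0, 0, 1]))
        for r in extract_rules(m):
            if r.intent == ("f0",):
                assert r.confidence == 1.0 and r.label == 0

    def test_no_rule_for_unlabeled_concepts(self, demo_model):
        indices = {r.concept_index for r in extract_rules(demo_model)}
        assert demo_model.lattice.bottom_index not in indices

    def test_sorted_by_confidence_then_support(self, demo_model):
        rules = extract_rules(demo_model)
        keys = [(-r.confidence, -r.support) for r in rules]
        assert keys == sorted(keys)


class TestFeatureClassSummary:
    def test_attribute_in_single_class_intents(self):
        X = np.array([[1, 0], [0, 1]])
        m = fit(TrainingSet(X, ["neg", "pos"]))
        s = feature_class_summary(m)
        # f1 appears only in intents of concepts labeled pos
        assert s.association.loc["f1", "pos"] > 0
        assert s.association.loc["f1", "neg"] == 0

    def test_demo_cooccurrence(self, demo_model):
        s = feature_class_summary(demo_model)
        assert s.cooccurrence.loc["b", "c"] > 0  # share intent {a,b,c}
        assert ("c", "d") in s.never_cooccur


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, demo_model, tmp_path):
        path = tmp_path / "model.json"
        demo_model.save(path)
        loaded = TrainedModel.load(path)
        assert loaded.concept_labels == demo_model.concept_labels
        assert loaded.tie_log == demo_model.tie_log
        assert loaded.label_multisets == demo_model.label_multisets
        X = [[1, 1, 0, 0], [1, 0, 1, 0], [0, 0, 0, 1]]
        assert predict(loaded, X) == predict(demo_model, X)

    def test_schema_version_checked(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"schema": "other/9"}')
        with pytest.raises(ValueError, match="schema"):
            TrainedModel.load(path)
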