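"""Predictors: baseline, SVM training, policies, and streaming traces."""

import numpy as np
import pytest

from gazeintent.events import TargetKind
from gazeintent.features import CandidateFeatures, candidate_list_at
from gazeintent.predict import (
    ABSTAIN,
    SVMConfig,
    always_predict,
    attention_predict,
    classify_episode,
    load_model,
    save_model,
    stream_predict,
    traditional_predict,
    train_svm,
)
from gazeintent.synth import GeneratorConfig, generate_episode

from conftest import make_episode


class TestAttentionBaseline:
    def test_returns_last_ingredient(self):
        ep = make_episode([(0, 300, "B"), (400, 600, "A"), (700, 900, "PARTNER")])
        state = candidate_list_at(ep, ep.request_onset_ms)
        assert attention_predict(state) == "A"

    def test_abstains_without_ingredient_glances(self):
        ep = make_episode([(0, 300, "PARTNER")], requested="A", available={"A"})
        state = candidate_list_at(ep, ep.request_onset_ms)
        assert attention_predict(state) == ABSTAIN


def _separable_toy(n=12):
    rng = np.random.default_rng(0)
    pos = np.column_stack(
        [rng.integers(3, 6, n), rng.uniform(200, 400, n),
         rng.uniform(2000, 3000, n), np.ones(n)]
    )
    neg = np.column_stack(
        [rng.integers(1, 3, n), rng.uniform(50, 150, n),
         rng.uniform(100, 400, n), np.zeros(n)]
    )
    X = np.vstack([pos, neg])
    y = np.array([1] * n + [-1] * n)
    return X, y


class TestTrainSVM:
    def test_separable_toy_training_accuracy(self):
        X, y = _separable_toy()
        model = train_svm(X, y, SVMConfig(seed=0))
        pred = model.svc.predict(model.scaler.transform(X))
        assert (pred == y).all()
        # calibrated probabilities point the same way
        p = model.probabilities(X)
        assert (p[y == 1] > p[y == -1].max()).all()

    def test_duplicated_data_same_decision_function(self):
        # hard-margin regime: duplicating every vector (equivalent to
        # doubling C) leaves the separable solution unchanged
        X, y = _separable_toy()
        big = SVMConfig(C=1e4, seed=0)
        m1 = train_svm(X, y, big)
        m2 = train_svm(np.vstack([X, X]), np.concatenate([y, y]), big)
        np.testing.assert_allclose(
            m1.decision_values(X), m2.decision_values(X), atol=1e-6
        )

    def test_single_class_rejected(self):
        X = np.ones((4, 4))
        with pytest.raises(ValueError):
            train_svm(X, np.ones(4, dtype=int))

    def test_model_roundtrip(self, tmp_path, small_model):
        save_model(small_model, tmp_path / "m.bin")
        back = load_model(tmp_path / "m.bin")
        X = np.array([[2.0, 300.0, 800.0, 1.0]])
        assert back.probabilities(X) == pytest.approx(
            small_model.probabilities(X)
        )


class _StubModel:
    """Fixed-probability stand-in for testing decision logic in isolation."""

    def __init__(self, probs):
        self._probs = probs

    def candidate_probabilities(self, entries):
        return {ing: self._probs[ing] for ing in entries}


def _entries(*names):
    return {
        n: CandidateFeatures(1, 100.0, 100.0, i == 0)
        for i, n in enumerate(names)
    }


class TestPolicies:
    def test_classification_threshold_is_strict(self):
        model = _StubModel({"A": 0.51, "B": 0.50})
        _, labels = classify_episode(model, _entries("A", "B"))
        assert labels == {"A": 1, "B": -1}

    def test_empty_candidates(self):
        model = _StubModel({})
        probs, labels = classify_episode(model, {})
        assert probs == {} and labels == {}
        assert traditional_predict({}) == ABSTAIN
        assert always_predict({}) == ABSTAIN

    def test_traditional_argmax_and_abstain(self):
        assert traditional_predict({"A": 0.7, "B": 0.6}) == "A"
        assert traditional_predict({"A": 0.4, "B": 0.3}) == ABSTAIN

    def test_always_argmax_below_threshold(self):
        assert always_predict({"A": 0.4, "B": 0.3}) == "A"

    def test_tie_breaks_to_earliest_insertion(self):
        assert traditional_predict({"A": 0.7, "B": 0.7}) == "A"
        assert always_predict({"B": 0.7, "A": 0.7}) == "B"

    @pytest.mark.parametrize("seed", range(20))
    def test_always_agrees_when_traditional_predicts(self, seed):
        rng = np.random.default_rng(seed)
        probs = {f"i{k}": float(rng.uniform()) for k in range(rng.integers(1, 8))}
        trad = traditional_predict(probs)
        if trad != ABSTAIN:
            assert always_predict(probs) == trad


class TestStreamPredict:
    def test_single_glance_trace(self, small_model):
        ep = make_episode([(0, 300, "A")], request_onset_ms=400)
        trace = stream_predict(small_model, ep, policy="always")
        assert [e.t_ms for e in trace.events] == [300, 400]
        assert trace.final == "A"
        assert trace.events[0].predicted == "A"

    def test_final_event_matches_batch_classification(self, small_model,
                                                      small_dataset):
        for ep in small_dataset.episodes[:12]:
            entries = candidate_list_at(ep, ep.request_onset_ms).entries
            probs, _ = classify_episode(small_model, entries)
            for policy, decide in (
                ("traditional", traditional_predict),
                ("always", always_predict),
            ):
                trace = stream_predict(small_model, ep, policy=policy)
                assert trace.final == decide(probs)
                assert trace.events[-1].probs == pytest.approx(probs)

    def test_probabilities_insertion_order_invariant(self, small_model):
        entries = {
            "A": CandidateFeatures(2, 300.0, 700.0, False),
            "B": CandidateFeatures(1, 200.0, 200.0, True),
        }
        fwd = small_model.candidate_probabilities(entries)
        rev = small_model.candidate_probabilities(
            dict(reversed(list(entries.items())))
        )
        assert fwd == pytest.approx(rev)

    def test_no_intended_glance_episode_never_correct(self, small_model):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(9)
        for i in range(10):
            ep, _ = generate_episode("NO_INTENDED_GLANCE", cfg, rng, f"n{i}")
            for policy in ("traditional", "always"):
                trace = stream_predict(small_model, ep, policy=policy)
                assert all(e.predicted != ep.requested for e in trace.events)

    def test_timestamps_strictly_increasing(self, small_model, small_dataset):
        for ep in small_dataset.episodes[:10]:
            trace = stream_predict(small_model, ep)
            ts = [e.t_ms for e in trace.events]
            assert ts == sorted(ts) and len(set(ts)) == len(ts)
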