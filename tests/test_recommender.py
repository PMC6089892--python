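"""Scoring, ranking/thresholding, and the estimator surface."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone
from sklearn.exceptions import NotFittedError

from locrec import (
    InteractionVector,
    NetworkRecommender,
    PairScoreTable,
    TableSimilarity,
    predict_for_query,
    predict_scores,
    rank_and_threshold,
)


class TestPredictScores:
    def test_hand_dot_product(self, micro_matrices):
        _, _, r = micro_matrices
        assert np.allclose(predict_scores(np.array([0.5, 1.0]), r), [1.625, 0.875])

    def test_zero_vector_gives_zero_scores(self, micro_matrices):
        _, _, r = micro_matrices
        assert predict_scores(np.zeros(2), r).tolist() == [0.0, 0.0]

    def test_indicator_recovers_row(self, micro_matrices):
        _, _, r = micro_matrices
        assert np.allclose(predict_scores(np.array([0.0, 1.0]), r), r.scores[1])

    def test_length_mismatch_rejected(self, micro_matrices):
        _, _, r = micro_matrices
        with pytest.raises(ValueError, match="does not match"):
            predict_scores(np.ones(3), r)

    def test_scale_covariance(self, micro_matrices, rng):
        _, _, r = micro_matrices
        s = rng.random(2)
        c = 3.7
        assert np.allclose(predict_scores(c * s, r), c * predict_scores(s, r))


class TestRankAndThreshold:
    def test_micro_example_tau_03(self):
        pred = rank_and_threshold(np.array([1.625, 0.875]), ["l1", "l2"], 0.3)
        assert pred.locations == ("l1", "l2")
        assert pred.entries[0][2] == 1.0
        assert pred.entries[1][2] == pytest.approx(0.5385, abs=1e-4)

    def test_micro_example_tau_06_drops_second(self):
        pred = rank_and_threshold(np.array([1.625, 0.875]), ["l1", "l2"], 0.6)
        assert pred.locations == ("l1",)

    def test_all_zero_scores_cold_start(self):
        pred = rank_and_threshold(np.zeros(2), ["l1", "l2"], 0.3)
        assert pred.cold_start and pred.locations == ()

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            rank_and_threshold(np.array([1.0]), ["l1"], 1.5)

    def test_tau_one_keeps_only_tied_maxima(self):
        pred = rank_and_threshold(np.array([2.0, 1.0, 2.0]), ["a", "b", "c"], 1.0)
        assert pred.locations == ("a", "c")

    def test_ties_broken_by_vocabulary_order(self):
        pred = rank_and_threshold(np.array([1.0, 1.0, 2.0]), ["z_loc", "a_loc", "m"], 0.3)
        assert pred.locations == ("m", "z_loc", "a_loc")

    @given(
        raw=st.lists(st.floats(0.0, 100.0), min_size=1, max_size=8),
        scale=st.floats(0.01, 50.0),
        tau=st.floats(0.0, 1.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_invariant_to_positive_rescaling(self, raw, scale, tau):
        raw = np.asarray(raw)
        locs = [f"l{i}" for i in range(len(raw))]
        a = rank_and_threshold(raw, locs, tau)
        b = rank_and_threshold(scale * raw, locs, tau)
        assert a.locations == b.locations
        assert np.allclose([e[2] for e in a.entries], [e[2] for e in b.entries])

    @given(
        tau=st.tuples(st.floats(0.0, 1.0), st.floats(0.0, 1.0)),
        seed=st.integers(0, 2**16),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_threshold_monotonicity(self, tau, seed):
        """Raising τ only shortens the list; the shared prefix is unchanged."""
        t1, t2 = min(tau), max(tau)
        raw = np.random.default_rng(seed).random(7)
        locs = [f"l{i}" for i in range(7)]
        lo = rank_and_threshold(raw, locs, t1)
        hi = rank_and_threshold(raw, locs, t2)
        assert set(hi.locations) <= set(lo.locations)
        assert lo.locations[: len(hi.locations)] == hi.locations


class TestNetworkRecommender:
    def test_fit_sets_fitted_attributes(self, micro_net):
        model = NetworkRecommender().fit([("p1", {"l1"}), ("p2", {"l1", "l2"})])
        assert model.locations_ == ("l1", "l2")
        assert model.n_features_in_ == 2
        assert np.allclose(model.transfer_matrix_.weights, [[0.75, 0.5], [0.25, 0.5]])

    def test_unfitted_raises(self):
        with pytest.raises(NotFittedError):
            NetworkRecommender().decision_function([[0.5, 1.0]])

    def test_decision_function_matrix(self):
        model = NetworkRecommender().fit([("p1", {"l1"}), ("p2", {"l1", "l2"})])
        out = model.decision_function([[0.5, 1.0], [0.0, 0.0]])
        assert np.allclose(out, [[1.625, 0.875], [0.0, 0.0]])

    def test_predict_returns_ranked_predictions(self):
        model = NetworkRecommender(tau=0.3).fit([("p1", {"l1"}), ("p2", {"l1", "l2"})])
        preds = model.predict([[0.5, 1.0]], query_ids=["q"])
        assert preds[0].query_id == "q"
        assert preds[0].locations == ("l1", "l2")

    def test_sklearn_param_interface(self):
        model = NetworkRecommender(tau=0.55, min_similarity=0.2)
        assert model.get_params() == {"tau": 0.55, "min_similarity": 0.2}
        cloned = clone(model)
        assert cloned.get_params()["tau"] == 0.55
        model.set_params(tau=0.7)
        assert model.tau == 0.7

    def test_invalid_tau_rejected_at_fit(self):
        with pytest.raises(ValueError, match="tau"):
            NetworkRecommender(tau=2.0).fit([("p1", {"l1"})])

    def test_leakage_guard_refuses_training_protein(self, fitted_model):
        model, sim = fitted_model
        with pytest.raises(ValueError, match="leakage"):
            model.predict_query(model.network_.proteins[0], sim)

    def test_min_similarity_zeroes_weak_scores(self):
        model = NetworkRecommender(tau=0.3, min_similarity=0.6).fit(
            [("p1", {"l1"}), ("p2", {"l2"})]
        )
        # p1's weak 0.5 link is floored away, leaving only p2's contribution
        out = model.decision_function([0.5, 0.9])
        assert out[0] == 0.0 and out[1] > 0


class TestPredictForQuery:
    def test_composition_of_steps(self, micro_matrices):
        net, _, r = micro_matrices
        table = PairScoreTable.from_pairs([("q", "p1", 0.5), ("q", "p2", 1.0)])
        pred = predict_for_query("q", TableSimilarity(table), net, r, 0.3)
        assert pred.locations == ("l1", "l2")

    def test_unknown_query_is_cold_start(self, micro_matrices):
        net, _, r = micro_matrices
        table = PairScoreTable.from_pairs([("a", "b", 0.4)])
        pred = predict_for_query("q", TableSimilarity(table), net, r, 0.3)
        assert pred.cold_start

    def test_training_protein_refused(self, micro_matrices):
        net, _, r = micro_matrices
        table = PairScoreTable.from_pairs([("p1", "p2", 0.4)])
        with pytest.raises(ValueError, match="leakage"):
            predict_for_query("p1", TableSimilarity(table), net, r, 0.3)
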