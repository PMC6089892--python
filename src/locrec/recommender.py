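"""Ranked multi-label location prediction from interaction-weighted spreading.

A query protein with no annotations of its own is scored by weighting the
training proteins' recommendation rows with its interaction similarities:
``Pred(p) = S(p) · R``.  Scores are normalized by the maximum, sorted, and cut
at a reliability threshold τ to yield the reported location list.

The scikit-learn style estimator :class:`NetworkRecommender` bundles the whole
pipeline (network construction, transfer/recommendation matrices, scoring,
ranking); the module-level functions expose the individual steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .network import (
    AnnotationNetwork,
    RecommenderMatrix,
    TransferMatrix,
    build_network,
    compute_recommender_matrix,
    compute_transfer_matrix,
)

__all__ = [
    "RankedPrediction",
    "predict_scores",
    "rank_and_threshold",
    "predict_for_query",
    "NetworkRecommender",
]


@dataclass(frozen=True)
class RankedPrediction:
    """Ordered location list with raw and max-normalized reliability scores.

    ``entries`` holds ``(location, raw_score, normalized_score)`` triples in
    non-increasing normalized-score order; every retained entry has
    normalized score >= ``tau`` and the first entry (when any) scores exactly
    1.0.  ``cold_start`` marks queries whose raw scores were all zero — no
    location can honestly be recommended, so the list is empty.
    """

    query_id: str
    entries: tuple[tuple[str, float, float], ...]
    tau: float
    cold_start: bool = False

    @property
    def locations(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def predict_scores(s: np.ndarray, r: RecommenderMatrix) -> np.ndarray:
    """Raw location scores ``Pred_j = Σ_i s_i · r_ij`` for one query.

    ``s`` must be aligned to the recommender's training-protein order;
    entries must be nonnegative (they are interaction scores or positive
    rescalings thereof).
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 1 or s.shape[0] != len(r.proteins):
        raise ValueError(
            f"interaction vector length {s.shape} does not match "
            f"{len(r.proteins)} training proteins"
        )
    if (s < 0).any():
        raise ValueError("interaction scores must be nonnegative")
    return s @ r.scores


def rank_and_threshold(
    raw: np.ndarray,
    locations: Sequence[str],
    tau: float,
    query_id: str = "query",
) -> RankedPrediction:
    """Normalize raw scores by their maximum, sort, and cut at τ.

    Ties are broken by location-vocabulary order so output is deterministic.
    An all-zero score vector yields an empty, cold-start prediction; the top
    location always survives any τ <= 1 because its normalized score is 1.0.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"threshold tau must lie in [0, 1], got {tau}")
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.shape[0] != len(locations):
        raise ValueError("score vector length does not match location vocabulary")
    if (raw < 0).any():
        raise ValueError("raw scores must be nonnegative")
    top = raw.max() if raw.size else 0.0
    if top <= 0.0:
        return RankedPrediction(query_id, (), tau, cold_start=True)
    norm = raw / top
    order = sorted(range(len(locations)), key=lambda j: (-norm[j], j))
    entries = tuple(
        (locations[j], float(raw[j]), float(norm[j])) for j in order if norm[j] >= tau
    )
    return RankedPrediction(query_id, entries, tau, cold_start=False)


def predict_for_query(
    query_id: str,
    provider,
    net: AnnotationNetwork,
    r: RecommenderMatrix,
    tau: float,
) -> RankedPrediction:
    """Score one held-out query via a similarity provider and rank at τ.

    The provider must map ``(query_id, training protein order)`` to an
    interaction vector (missing pairs scored 0).  A query that is itself part
    of the training network is refused: leaving it in would leak its own
    annotations into the recommendation (a jackknife must remove it first).
    """
    if query_id in net:
        raise ValueError(
            f"query {query_id!r} is part of the training network; "
            "remove it before predicting (leakage guard)"
        )
    vec = provider.vector(query_id, net.proteins)
    return rank_and_threshold(predict_scores(vec.scores, r), net.locations, tau, query_id)


class NetworkRecommender(BaseEstimator):
    """Bipartite-network recommender for ranked multi-label localization.

    Training consists of building the protein–location annotation network and
    the two-step resource-spreading matrices; prediction weights the training
    rows by a query's interaction scores and reports every location whose
    max-normalized score reaches the reliability threshold ``tau``.

    Parameters
    ----------
    tau : float, default=0.3
        Reliability threshold on max-normalized scores in [0, 1].
    min_similarity : float, default=0.0
        Optional confidence floor applied to interaction scores before
        scoring; entries below it are zeroed (off by default).

    Attributes
    ----------
    network_ : AnnotationNetwork
        Pruned bipartite incidence with vocabularies.
    transfer_matrix_ : TransferMatrix
        Column-stochastic m×m location transfer weights.
    recommender_matrix_ : RecommenderMatrix
        n×m per-protein recommendation scores.
    locations_ : tuple of str
        Location vocabulary (columns of the score matrices).
    n_features_in_ : int
        Number of training proteins = expected interaction-vector length.

    Examples
    --------
    >>> model = NetworkRecommender(tau=0.3)
    >>> model.fit([("p1", {"l1"}), ("p2", {"l1", "l2"})])
    NetworkRecommender()
    >>> model.decision_function([[0.5, 1.0]])
    array([[1.625, 0.875]])
    """

    def __init__(self, tau: float = 0.3, min_similarity: float = 0.0):
        self.tau = tau
        self.min_similarity = min_similarity

    def fit(self, X: Iterable[tuple[str, Iterable[str]]], y=None, vocabulary=None):
        """Build the annotation network and spreading matrices.

        ``X`` is an iterable of ``(protein id, location labels)`` pairs; the
        multi-label targets are part of X itself, so ``y`` is ignored (kept
        for scikit-learn API compatibility).
        """
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must lie in [0, 1], got {self.tau}")
        if self.min_similarity < 0 or self.min_similarity > 1:
            raise ValueError("min_similarity must lie in [0, 1]")
        net = build_network(X, vocabulary=vocabulary)
        self.network_ = net
        self.transfer_matrix_ = compute_transfer_matrix(net)
        self.recommender_matrix_ = compute_recommender_matrix(net, self.transfer_matrix_)
        self.locations_ = net.locations
        self.n_features_in_ = net.n_proteins
        return self

    def _filter(self, s: np.ndarray) -> np.ndarray:
        if self.min_similarity > 0:
            s = np.where(s >= self.min_similarity, s, 0.0)
        return s

    def decision_function(self, S) -> np.ndarray:
        """Raw location scores for queries given interaction vectors.

        ``S`` is ``(n_queries, n_training_proteins)`` (a single 1-D vector is
        accepted and treated as one query).
        """
        check_is_fitted(self, "recommender_matrix_")
        S = np.asarray(S, dtype=float)
        single = S.ndim == 1
        if single:
            S = S[None, :]
        if S.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected interaction vectors of length {self.n_features_in_}, "
                f"got {S.shape[1]}"
            )
        if (S < 0).any():
            raise ValueError("interaction scores must be nonnegative")
        out = self._filter(S) @ self.recommender_matrix_.scores
        return out[0] if single else out

    def predict(self, S, query_ids: Sequence[str] | None = None) -> list[RankedPrediction]:
        """Ranked, thresholded predictions for each interaction vector in S."""
        check_is_fitted(self, "recommender_matrix_")
        S = np.asarray(S, dtype=float)
        if S.ndim == 1:
            S = S[None, :]
        raw = self.decision_function(S)
        if query_ids is None:
            query_ids = [f"query{i}" for i in range(S.shape[0])]
        if len(query_ids) != S.shape[0]:
            raise ValueError("query_ids length does not match number of rows in S")
        return [
            rank_and_threshold(raw[i], self.locations_, self.tau, query_ids[i])
            for i in range(S.shape[0])
        ]

    def predict_query(self, query_id: str, provider) -> RankedPrediction:
        """Predict for a named query using a similarity provider (leakage-guarded)."""
        check_is_fitted(self, "recommender_matrix_")
        if query_id in self.network_:
            raise ValueError(
                f"query {query_id!r} is part of the training network; "
                "remove it before predicting (leakage guard)"
            )
        vec = provider.vector(query_id, self.network_.proteins)
        raw = predict_scores(self._filter(vec.scores), self.recommender_matrix_)
        return rank_and_threshold(raw, self.locations_, self.tau, query_id)
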