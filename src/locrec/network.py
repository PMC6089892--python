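"""Bipartite protein–location annotation networks and resource spreading.

The annotation network is the bipartite graph ``G = (P ∪ L, E)`` linking each
training protein to its known subcellular locations.  A two-step
resource-allocation walk on this graph — every location splits one unit of
resource equally among its annotated proteins, every protein then splits what
it received equally among its locations — defines the m×m location-to-location
transfer matrix

    w_ij = (1 / d(l_j)) * Σ_t  a_ti * a_tj / d(p_t)

where ``A = [a_ij]`` is the n×m incidence matrix and ``d(·)`` are vertex
degrees.  Because every degree is positive, each column of W sums to one
(column-stochasticity), and the per-protein recommendation matrix
``R = A · Wᵀ`` conserves mass: row k of R sums to the degree of protein k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationNetwork",
    "TransferMatrix",
    "RecommenderMatrix",
    "build_network",
    "compute_transfer_matrix",
    "compute_recommender_matrix",
]


@dataclass(frozen=True)
class AnnotationNetwork:
    """Binary protein×location incidence with ordered vocabularies.

    Invariants (enforced at construction): identifiers are unique, the
    incidence is 0/1, and every protein row and location column has degree
    at least one.  Use :func:`build_network` to construct one from raw
    annotation pairs — it prunes zero-degree entries before validation.
    """

    proteins: tuple[str, ...]
    locations: tuple[str, ...]
    incidence: np.ndarray

    def __post_init__(self) -> None:
        inc = np.ascontiguousarray(np.asarray(self.incidence, dtype=float))
        object.__setattr__(self, "incidence", inc)
        if inc.ndim != 2:
            raise ValueError("incidence must be a 2-D array")
        n, m = inc.shape
        if n != len(self.proteins) or m != len(self.locations):
            raise ValueError("incidence shape does not match vocabularies")
        if len(set(self.proteins)) != n:
            raise ValueError("protein identifiers are not unique")
        if len(set(self.locations)) != m:
            raise ValueError("location labels are not unique")
        if not np.isin(inc, (0.0, 1.0)).all():
            raise ValueError("incidence entries must be 0 or 1")
        if n == 0 or m == 0:
            raise ValueError("network must contain at least one protein and one location")
        if (inc.sum(axis=1) < 1).any():
            raise ValueError("every protein must have degree >= 1")
        if (inc.sum(axis=0) < 1).any():
            raise ValueError("every location must have degree >= 1")
        object.__setattr__(self, "_protein_index", {p: i for i, p in enumerate(self.proteins)})

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    @property
    def protein_degrees(self) -> np.ndarray:
        """d(p_i): number of locations annotated to each protein."""
        return self.incidence.sum(axis=1)

    @property
    def location_degrees(self) -> np.ndarray:
        """d(l_j): number of proteins annotated to each location."""
        return self.incidence.sum(axis=0)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._protein_index  # type: ignore[attr-defined]

    def protein_row(self, protein_id: str) -> np.ndarray:
        """The annotation profile f(p) of one protein (initial resource vector)."""
        try:
            i = self._protein_index[protein_id]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"protein {protein_id!r} not in network") from None
        return self.incidence[i]

    def annotations(self) -> list[tuple[str, frozenset[str]]]:
        """Back-conversion to (protein id, location set) pairs."""
        out = []
        for i, pid in enumerate(self.proteins):
            labels = frozenset(loc for j, loc in enumerate(self.locations) if self.incidence[i, j])
            out.append((pid, labels))
        return out


@dataclass(frozen=True)
class TransferMatrix:
    """m×m location-to-location resource-transfer weights W (column-stochastic)."""

    weights: np.ndarray
    locations: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.ascontiguousarray(np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "weights", w)
        m = len(self.locations)
        if w.shape != (m, m):
            raise ValueError("transfer matrix must be m×m over the location vocabulary")
        if (w < -1e-12).any() or (w > 1 + 1e-12).any():
            raise ValueError("transfer weights must lie in [0, 1]")
        col = w.sum(axis=0)
        if not np.allclose(col, 1.0, atol=1e-9):
            raise ValueError("transfer matrix columns must sum to 1")


@dataclass(frozen=True)
class RecommenderMatrix:
    """n×m per-protein recommendation scores R; row k sums to d(p_k)."""

    scores: np.ndarray
    proteins: tuple[str, ...]
    locations: tuple[str, ...]

    def __post_init__(self) -> None:
        r = np.ascontiguousarray(np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "scores", r)
        if r.shape != (len(self.proteins), len(self.locations)):
            raise ValueError("recommender matrix shape does not match vocabularies")
        if (r < -1e-12).any():
            raise ValueError("recommendation scores must be nonnegative")


def build_network(
    annotations: Iterable[tuple[str, Iterable[str]]],
    vocabulary: Sequence[str] | None = None,
) -> AnnotationNetwork:
    """Assemble an :class:`AnnotationNetwork` from (protein, locations) pairs.

    Proteins with an empty location set are pruned with a logged warning, as
    are vocabulary locations no retained protein uses (their degree would be
    zero, leaving the transfer weights undefined).  Location order follows
    ``vocabulary`` when given, else is lexicographic; protein order follows
    the input.

    Raises
    ------
    ValueError
        If the input is empty, a protein id recurs with conflicting location
        sets, or an annotation uses a label missing from ``vocabulary``.
    """
    merged: dict[str, frozenset[str]] = {}
    for pid, labels in annotations:
        labelset = frozenset(labels)
        if pid in merged:
            if merged[pid] != labelset:
                raise ValueError(f"conflicting annotations for duplicate protein {pid!r}")
            continue
        merged[pid] = labelset
    if not merged:
        raise ValueError("no annotations provided")

    empty = [pid for pid, labels in merged.items() if not labels]
    if empty:
        logger.warning(
            "pruning %d protein(s) with no locations: %s", len(empty), ", ".join(empty[:10])
        )
    kept = {pid: labels for pid, labels in merged.items() if labels}
    if not kept:
        raise ValueError("every protein has an empty location set")

    used = frozenset().union(*kept.values())
    if vocabulary is not None:
        vocab = list(vocabulary)
        if len(set(vocab)) != len(vocab):
            raise ValueError("location vocabulary contains duplicates")
        missing = used - set(vocab)
        if missing:
            raise ValueError(f"annotations use labels absent from vocabulary: {sorted(missing)}")
        unused = [loc for loc in vocab if loc not in used]
        if unused:
            logger.warning("pruning %d zero-degree location(s): %s", len(unused), ", ".join(unused))
        locations = tuple(loc for loc in vocab if loc in used)
    else:
        locations = tuple(sorted(used))

    col = {loc: j for j, loc in enumerate(locations)}
    proteins = tuple(kept)
    incidence = np.zeros((len(proteins), len(locations)))
    for i, pid in enumerate(proteins):
        for loc in kept[pid]:
            incidence[i, col[loc]] = 1.0
    return AnnotationNetwork(proteins, locations, incidence)


def compute_transfer_matrix(net: AnnotationNetwork) -> TransferMatrix:
    """Two-step resource-spreading transfer matrix W of the network.

    ``w_ij`` is the fraction of one unit of resource placed on location
    ``l_i`` that ends on ``l_j`` after the location→protein→location
    equal-split walk; network invariants guarantee all degrees are positive.
    """
    a = net.incidence
    d_p = net.protein_degrees
    d_l = net.location_degrees
    w = (a / d_p[:, None]).T @ a / d_l[None, :]
    return TransferMatrix(w, net.locations)


def compute_recommender_matrix(net: AnnotationNetwork, w: TransferMatrix) -> RecommenderMatrix:
    """Per-protein recommendation matrix: row k is f(p_k) · Wᵀ."""
    if w.locations != net.locations:
        raise ValueError("transfer matrix and network use different location vocabularies")
    r = net.incidence @ w.weights.T
    return RecommenderMatrix(r, net.proteins, net.locations)
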