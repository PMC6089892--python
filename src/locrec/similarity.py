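"""Interaction/similarity vector providers.

The recommender consumes, for each query protein p, the vector
``S(p) = [s_pp1, …, s_ppn]`` of interaction scores against the training
proteins.  Two sources are supported:

* a precomputed pairwise score table (plain TSV in [0, 1], or a STRING-export
  dialect whose integer ``combined_score`` in 0–1000 is divided by 1000);
* on-the-fly Smith–Waterman sequence similarity from a FASTA file, for
  datasets where interaction evidence is too sparse.

Missing pairs score 0 by contract; the query itself is never included.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .alignment import AlignmentParams, sw_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionVector",
    "PairScoreTable",
    "load_pair_scores",
    "read_fasta",
    "TableSimilarity",
    "SequenceSimilarity",
    "interaction_vector",
]


@dataclass(frozen=True)
class InteractionVector:
    """Similarity scores of one query against an ordered training set."""

    query_id: str
    scores: np.ndarray
    coverage: int

    def __post_init__(self) -> None:
        s = np.ascontiguousarray(np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "scores", s)
        if s.ndim != 1:
            raise ValueError("interaction vector must be 1-D")
        if (s < -1e-12).any() or (s > 1 + 1e-12).any():
            raise ValueError("interaction scores must lie in [0, 1]")


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PairScoreTable:
    """Symmetric (protein, protein) → score map with scores in [0, 1]."""

    scores: Mapping[tuple[str, str], float]
    provenance: str = "table"

    def get(self, a: str, b: str) -> float:
        """Stored score of an unordered pair, 0.0 when unobserved."""
        return self.scores.get(_pair_key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def protein_ids(self) -> frozenset[str]:
        ids: set[str] = set()
        for a, b in self.scores:
            ids.add(a)
            ids.add(b)
        return frozenset(ids)

    @staticmethod
    def from_pairs(
        pairs: Iterable[tuple[str, str, float]], provenance: str = "table"
    ) -> "PairScoreTable":
        store: dict[tuple[str, str], float] = {}
        for a, b, s in pairs:
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"score {s} for pair ({a}, {b}) outside [0, 1]")
            key = _pair_key(a, b)
            if key in store and abs(store[key] - s) > 1e-9:
                raise ValueError(f"conflicting duplicate scores for pair {key}")
            store[key] = float(s)
        return PairScoreTable(store, provenance)


def _open_text(path: str | Path):
    """Open a possibly gzip-compressed text file."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def load_pair_scores(path: str | Path, dialect: str = "plain") -> PairScoreTable:
    """Read a 3-column pair-score TSV (``protein  protein  score``).

    ``plain`` scores must already lie in [0, 1]; ``string_export`` carries a
    STRING ``combined_score`` integer in 0–1000 that is divided by 1000.
    Duplicate unordered pairs must agree within 1e-9; asymmetric singletons
    are symmetrized.  Errors carry the offending 1-based line number.
    """
    if dialect not in ("plain", "string_export"):
        raise ValueError(f"unknown pair-score dialect {dialect!r}")
    store: dict[tuple[str, str], float] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:  # tolerate whitespace-separated exports
                parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, raw = parts
            try:
                value = float(raw)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed score {raw!r}") from None
            if dialect == "string_export":
                if not 0 <= value <= 1000:
                    raise ValueError(
                        f"{path}:{lineno}: combined_score {raw} outside 0–1000"
                    )
                score = value / 1000.0
            else:
                if not 0.0 <= value <= 1.0:
                    raise ValueError(f"{path}:{lineno}: score {raw} outside [0, 1]")
                score = value
            key = _pair_key(a, b)
            if key in store and abs(store[key] - score) > 1e-9:
                raise ValueError(
                    f"{path}:{lineno}: conflicting duplicate score for pair {key}"
                )
            store[key] = score
    return PairScoreTable(store, provenance="string_export" if dialect == "string_export" else "table")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into id → sequence (id = header up to whitespace)."""
    path = Path(path)
    records: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate FASTA record id {rec.id!r}")
            records[rec.id] = str(rec.seq)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


class TableSimilarity:
    """Similarity provider backed by a precomputed pair-score table."""

    def __init__(self, table: PairScoreTable):
        self.table = table

    def score(self, a: str, b: str) -> float:
        return self.table.get(a, b)

    def vector(self, query_id: str, order: Sequence[str]) -> InteractionVector:
        scores = np.array([self.table.get(query_id, p) for p in order], dtype=float)
        return InteractionVector(query_id, scores, int(np.count_nonzero(scores)))


class SequenceSimilarity:
    """Similarity provider computing normalized Smith–Waterman scores on demand.

    Pairwise similarities are cached, so a jackknife over n proteins costs
    n·(n−1)/2 alignments total rather than per fold.
    """

    def __init__(self, sequences: Mapping[str, str], params: AlignmentParams | None = None):
        if not sequences:
            raise ValueError("no sequences provided")
        self.sequences = dict(sequences)
        self.params = params if params is not None else AlignmentParams()
        self._cache: dict[tuple[str, str], float] = {}

    def score(self, a: str, b: str) -> float:
        if a not in self.sequences or b not in self.sequences:
            return 0.0
        key = _pair_key(a, b)
        if key not in self._cache:
            self._cache[key] = sw_similarity(
                self.sequences[key[0]], self.sequences[key[1]], self.params
            )
        return self._cache[key]

    def vector(self, query_id: str, order: Sequence[str]) -> InteractionVector:
        scores = np.array([self.score(query_id, p) for p in order], dtype=float)
        return InteractionVector(query_id, scores, int(np.count_nonzero(scores)))


def interaction_vector(query_id: str, order: Sequence[str], source) -> InteractionVector:
    """Build S(p) for a query against the fixed training order.

    ``source`` may be a provider (anything with ``.vector``), a
    :class:`PairScoreTable`, or an id → sequence mapping.
    """
    if hasattr(source, "vector"):
        return source.vector(query_id, order)
    if isinstance(source, PairScoreTable):
        return TableSimilarity(source).vector(query_id, order)
    if isinstance(source, Mapping):
        return SequenceSimilarity(source).vector(query_id, order)
    raise TypeError(f"unsupported similarity source type {type(source).__name__}")
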