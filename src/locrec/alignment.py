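"""Smith–Waterman local alignment as an interaction-score surrogate.

When interaction evidence is unavailable or too sparse (multi-species data),
pairwise sequence similarity stands in for it.  The local-alignment dynamic
program is implemented for both a linear gap model

    H[i,j] = max(0, H[i-1,j-1] + s(a_i, b_j), H[i-1,j] - g, H[i,j-1] - g)

and the affine (Gotoh three-state) model where a gap of length L costs
``open + L·extend``.  The returned score is the maximum cell value, i.e. the
best-scoring local alignment; the empty alignment floors it at 0.

Similarity in [0, 1] divides the raw cross-score by the smaller of the two
self-alignment scores, so identical sequences score exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

__all__ = ["AlignmentParams", "smith_waterman", "sw_similarity"]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for local alignment.

    Parameters
    ----------
    matrix : str or None
        Name of a substitution matrix (loaded from Biopython, e.g.
        ``"BLOSUM62"``).  ``None`` selects a simple match/mismatch scheme —
        handy for small, hand-checkable test alphabets.
    match, mismatch : float
        Simple-scheme scores (used only when ``matrix`` is None);
        ``match`` must be positive.
    gap_model : {"affine", "linear"}
        Affine gaps cost ``gap_open + L·gap_extend`` for length L; linear
        gaps cost ``gap · L``.
    gap, gap_open, gap_extend : float
        Gap costs, expressed as positive penalties.

    Defaults are the field-standard protein settings: BLOSUM62 with affine
    gap open 11 / extend 1.
    """

    matrix: str | None = "BLOSUM62"
    match: float = 2.0
    mismatch: float = -1.0
    gap_model: str = "affine"
    gap: float = 1.0
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_model not in ("affine", "linear"):
            raise ValueError(f"unknown gap model {self.gap_model!r}")
        if self.matrix is None and self.match <= 0:
            raise ValueError("match score must be positive")
        if self.gap_model == "linear" and self.gap <= 0:
            raise ValueError("linear gap penalty must be positive")
        if self.gap_model == "affine" and (self.gap_open < 0 or self.gap_extend <= 0):
            raise ValueError("affine gap penalties must be positive")

    def substitution(self, a: str, b: str) -> float:
        if self.matrix is None:
            return self.match if a == b else self.mismatch
        mat = _load_matrix(self.matrix)
        try:
            return float(mat[a, b])
        except (KeyError, IndexError):
            bad = a if a not in mat.alphabet else b
            raise ValueError(f"unknown residue {bad!r} for matrix {self.matrix}") from None


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


def _validate(seq: str, params: AlignmentParams) -> None:
    if not seq:
        raise ValueError("cannot align an empty sequence")
    if params.matrix is not None:
        alphabet = set(_load_matrix(params.matrix).alphabet)
        for ch in seq:
            if ch not in alphabet:
                raise ValueError(f"unknown residue {ch!r} for matrix {params.matrix}")


def smith_waterman(seq1: str, seq2: str, params: AlignmentParams | None = None) -> float:
    """Raw local-alignment score of two sequences.

    Pure dynamic program, O(len1·len2); adequate for desk-scale similarity
    matrices (hundreds of residues, thousands of pairs).
    """
    if params is None:
        params = AlignmentParams()
    _validate(seq1, params)
    _validate(seq2, params)
    n, m = len(seq1), len(seq2)
    sub = params.substitution
    best = 0.0
    if params.gap_model == "linear":
        g = params.gap
        prev = [0.0] * (m + 1)
        for i in range(1, n + 1):
            cur = [0.0] * (m + 1)
            ai = seq1[i - 1]
            for j in range(1, m + 1):
                h = max(
                    0.0,
                    prev[j - 1] + sub(ai, seq2[j - 1]),
                    prev[j] - g,
                    cur[j - 1] - g,
                )
                cur[j] = h
                if h > best:
                    best = h
            prev = cur
        return best
    # affine (Gotoh): H best ending in a match, E gap in seq1 (left), F gap in seq2 (up)
    first = params.gap_open + params.gap_extend
    ext = params.gap_extend
    neg = float("-inf")
    prev_h = [0.0] * (m + 1)
    prev_f = [neg] * (m + 1)
    for i in range(1, n + 1):
        cur_h = [0.0] * (m + 1)
        cur_f = [neg] * (m + 1)
        e = neg
        ai = seq1[i - 1]
        for j in range(1, m + 1):
            e = max(cur_h[j - 1] - first, e - ext)
            f = max(prev_h[j] - first, prev_f[j] - ext)
            h = max(0.0, prev_h[j - 1] + sub(ai, seq2[j - 1]), e, f)
            cur_h[j] = h
            cur_f[j] = f
            if h > best:
                best = h
        prev_h, prev_f = cur_h, cur_f
    return best


def sw_similarity(seq1: str, seq2: str, params: AlignmentParams | None = None) -> float:
    """Normalized local-alignment similarity in [0, 1].

    ``SW(a,b) / min(SW(a,a), SW(b,b))`` — identical sequences score 1, and
    the ratio is clipped into [0, 1] defensively.  Invariant to uniformly
    rescaling all substitution and gap scores by a positive constant.
    """
    if params is None:
        params = AlignmentParams()
    raw = smith_waterman(seq1, seq2, params)
    self1 = smith_waterman(seq1, seq1, params)
    self2 = smith_waterman(seq2, seq2, params)
    denom = min(self1, self2)
    if denom <= 0:
        return 0.0
    return float(np.clip(raw / denom, 0.0, 1.0))
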