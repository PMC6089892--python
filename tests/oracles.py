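"""Independent naive oracles used to cross-check the implementation.

Everything here is written as literal loops over the defining formulas (or
exhaustive enumeration), deliberately ignoring the vectorized/DP code paths
it validates.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


# ---------------------------------------------------------------- spreading

def spread_two_steps(incidence: np.ndarray, start: np.ndarray) -> np.ndarray:
    """Explicit two-step resource allocation over the bipartite edges.

    Step 1: every location splits its resource equally among its proteins;
    step 2: every protein splits what it received equally among its
    locations.  Pure edge-enumeration loops.
    """
    a = np.asarray(incidence, dtype=float)
    n, m = a.shape
    d_p = a.sum(axis=1)
    d_l = a.sum(axis=0)
    protein_res = np.zeros(n)
    for t in range(n):
        for j in range(m):
            if a[t, j]:
                protein_res[t] += start[j] / d_l[j]
    location_res = np.zeros(m)
    for t in range(n):
        for j in range(m):
            if a[t, j]:
                location_res[j] += protein_res[t] / d_p[t]
    return location_res


def transfer_matrix_by_spreading(incidence: np.ndarray) -> np.ndarray:
    """W column i = spreading of a unit resource placed on location i."""
    m = incidence.shape[1]
    w = np.zeros((m, m))
    for i in range(m):
        start = np.zeros(m)
        start[i] = 1.0
        w[:, i] = spread_two_steps(incidence, start)
    return w


def recommender_by_spreading(incidence: np.ndarray) -> np.ndarray:
    """R row k = spreading started from protein k's annotation profile."""
    n = incidence.shape[0]
    return np.array([spread_two_steps(incidence, incidence[k]) for k in range(n)])


def random_incidence(rng: np.random.Generator, n_max: int = 20, m_max: int = 20) -> np.ndarray:
    """Random binary incidence with all row/column degrees >= 1."""
    while True:
        n = int(rng.integers(1, n_max + 1))
        m = int(rng.integers(1, m_max + 1))
        a = (rng.random((n, m)) < rng.uniform(0.15, 0.7)).astype(float)
        a = a[a.sum(axis=1) >= 1][:, a.sum(axis=0) >= 1] if a.size else a
        if a.size and a.shape[0] >= 1 and a.shape[1] >= 1:
            if (a.sum(axis=1) >= 1).all() and (a.sum(axis=0) >= 1).all():
                return a


# ----------------------------------------------------------------- metrics

def naive_precision(instances) -> float:
    total = 0.0
    for inst in instances:
        if len(inst.prediction) == 0:
            continue
        hits = 0
        for y in inst.prediction:
            if y in inst.truth:
                hits += 1
        total += hits / len(inst.prediction)
    return total / len(instances)


def naive_recall(instances) -> float:
    total = 0.0
    for inst in instances:
        hits = 0
        for x in inst.truth:
            if x in inst.prediction:
                hits += 1
        total += hits / len(inst.truth)
    return total / len(instances)


def naive_delta(t: int, k: int) -> int:
    if t >= k:
        return sum(t - j for j in range(k))
    return sum(range(1, t + 1))


def naive_ordered_precision(instances) -> float:
    total = 0.0
    for inst in instances:
        t = len(inst.prediction)
        if t == 0:
            continue
        k = len(inst.truth)
        num = 0
        for pos, y in enumerate(inst.prediction, start=1):
            if y in inst.truth:
                num += t - pos + 1
        total += num / naive_delta(t, k)
    return total / len(instances)


def naive_per_location(instances, universe):
    out = {}
    for c in universe:
        pre_terms = []
        rec_terms = []
        for inst in instances:
            hits = len([y for y in inst.prediction if y in inst.truth])
            if c in inst.prediction:
                pre_terms.append(hits / len(inst.prediction))
            if c in inst.truth:
                rec_terms.append(hits / len(inst.truth))
        pre = sum(pre_terms) / len(pre_terms) if pre_terms else 0.0
        rec = sum(rec_terms) / len(rec_terms) if rec_terms else 0.0
        if pre_terms and rec_terms and pre + rec > 0:
            f1 = 2 * pre * rec / (pre + rec)
        else:
            f1 = 0.0
        out[c] = (pre, rec, f1)
    macro = sum(v[2] for v in out.values()) / len(universe)
    return out, macro


def naive_measure3(instances, universe):
    n = len(instances)
    acc = sum(
        len(set(i.prediction) & i.truth) / len(set(i.prediction) | i.truth)
        for i in instances
    ) / n
    atr = sum(1 for i in instances if set(i.prediction) == i.truth) / n
    afr = sum(
        len(set(i.prediction) | i.truth) - len(set(i.prediction) & i.truth)
        for i in instances
    ) / (n * len(universe))
    return acc, atr, afr


def naive_measure4(instances, universe):
    uni = set(universe)
    n = len(instances)
    return sum(
        (len(set(i.prediction) & i.truth) + len(uni - (i.truth | set(i.prediction))))
        / len(uni)
        for i in instances
    ) / n


# ------------------------------------------------------- local alignment

def brute_force_local_alignment(a: str, b: str, match: float, mismatch: float, gap: float) -> float:
    """Best local alignment score by enumerating all substring pairs and all
    monotone global alignments of each pair (linear gap costs)."""

    @lru_cache(maxsize=None)
    def best_global(x: str, y: str) -> float:
        if not x and not y:
            return 0.0
        cands = []
        if x and y:
            s = match if x[0] == y[0] else mismatch
            cands.append(s + best_global(x[1:], y[1:]))
        if x:
            cands.append(-gap + best_global(x[1:], y))
        if y:
            cands.append(-gap + best_global(x, y[1:]))
        return max(cands)

    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(best, best_global(a[i1:i2], b[j1:j2]))
    best_global.cache_clear()
    return best
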