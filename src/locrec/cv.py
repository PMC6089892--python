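"""Jackknife and repeated k-fold evaluation of the network recommender.

Each fold rebuilds the annotation network, transfer matrix and recommender
matrix from the training split alone (locations whose degree drops to zero
are pruned from that fold's vocabulary — their transfer weights would be
undefined — and simply never get predicted).  The held-out protein's
interaction vector is formed against the remaining proteins only, so its own
annotations can never leak into its prediction.

Per repeat, metrics are computed over the pooled held-out predictions, then
averaged across repeats; the jackknife is the k = |D| special case and yields
a single report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .metrics import EvaluationInstance, MetricsReport, evaluate
from .recommender import NetworkRecommender, RankedPrediction

logger = logging.getLogger(__name__)

__all__ = ["FoldPlan", "CVResult", "plan_folds", "jackknife", "kfold"]

Annotations = Sequence[tuple[str, frozenset[str]]]


@dataclass(frozen=True)
class FoldPlan:
    """Reproducible assignment of proteins to folds.

    ``assignments[r][i]`` is the fold index of protein i in repeat r.  Folds
    partition the proteins and their sizes differ by at most one.
    """

    protocol: str
    k: int
    repeats: int
    seed: int
    assignments: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        for rep in self.assignments:
            counts = np.bincount(np.asarray(rep), minlength=self.k)
            if len(counts) != self.k or counts.max() - counts.min() > 1 or counts.min() < 1:
                raise ValueError("fold sizes must differ by at most one and be non-empty")


def plan_folds(
    n: int,
    k: int,
    repeats: int,
    seed: int,
    protocol: str = "kfold",
    strata: Sequence[str] | None = None,
) -> FoldPlan:
    """Derive per-repeat fold assignments from a single integer seed.

    With ``strata`` (one key per protein), each stratum is shuffled and dealt
    round-robin so every fold sees a similar label mix; otherwise folds are a
    plain shuffled split.  Repeat r uses the spawned sub-seed (seed, r), so a
    plan is bit-reproducible from (n, k, repeats, seed).
    """
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    assignments = []
    for r in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(r,)))
        fold = np.empty(n, dtype=int)
        if strata is None:
            perm = rng.permutation(n)
            for pos, idx in enumerate(perm):
                fold[idx] = pos % k
        else:
            if len(strata) != n:
                raise ValueError("strata length must equal the number of proteins")
            pos = 0
            start = int(rng.integers(k))
            by_key: dict[str, list[int]] = {}
            for i, key in enumerate(strata):
                by_key.setdefault(key, []).append(i)
            for key in sorted(by_key):
                idxs = np.asarray(by_key[key])
                rng.shuffle(idxs)
                for idx in idxs:
                    fold[idx] = (start + pos) % k
                    pos += 1
        assignments.append(tuple(int(f) for f in fold))
    return FoldPlan(protocol, k, repeats, seed, tuple(assignments))


@dataclass(frozen=True)
class CVResult:
    """Per-repeat metric reports plus their mean/sd aggregate."""

    protocol: str
    tau: float
    reports: tuple[MetricsReport, ...]
    cold_start_counts: tuple[int, ...]
    plan: FoldPlan | None = None

    @property
    def mean(self) -> dict[str, float]:
        keys = self.reports[0].scalar_dict().keys()
        return {
            key: float(np.mean([rep.scalar_dict()[key] for rep in self.reports]))
            for key in keys
        }

    @property
    def std(self) -> dict[str, float]:
        keys = self.reports[0].scalar_dict().keys()
        return {
            key: float(np.std([rep.scalar_dict()[key] for rep in self.reports]))
            for key in keys
        }

    @property
    def report(self) -> MetricsReport:
        """The single report (valid when there is exactly one repeat)."""
        if len(self.reports) != 1:
            raise ValueError("result has multiple repeats; use .reports or .mean")
        return self.reports[0]

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "tau": self.tau,
            "repeats": len(self.reports),
            "cold_start_counts": list(self.cold_start_counts),
            "mean": self.mean,
            "std": self.std,
            "per_repeat": [rep.to_dict() for rep in self.reports],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def _as_annotations(dataset) -> list[tuple[str, frozenset[str]]]:
    return [(pid, frozenset(labels)) for pid, labels in dataset]


def _evaluate_split(
    train: Annotations,
    test: Annotations,
    similarity,
    tau: float,
    min_similarity: float,
) -> tuple[list[EvaluationInstance], int]:
    """Fit on the training split, predict every held-out protein."""
    model = NetworkRecommender(tau=tau, min_similarity=min_similarity)
    model.fit(train)
    instances = []
    cold = 0
    for pid, truth in test:
        pred: RankedPrediction = model.predict_query(pid, similarity)
        if pred.cold_start:
            cold += 1
        instances.append(EvaluationInstance(pid, truth, pred.locations))
    return instances, cold


def jackknife(
    dataset,
    similarity,
    tau: float = 0.3,
    min_similarity: float = 0.0,
    macro_denominator: str = "universe",
) -> CVResult:
    """Leave-one-out evaluation: every protein is held out once.

    The model (network, W, R) is rebuilt on the other |D|−1 proteins for
    every fold; the report pools all |D| (truth, prediction) pairs.  The
    location universe C is fixed to the full dataset's vocabulary so
    |C|-normalized metrics are comparable across folds.
    """
    data = _as_annotations(dataset)
    if len(data) < 2:
        raise ValueError("jackknife requires at least 2 proteins")
    universe = sorted(frozenset().union(*(labels for _, labels in data)))
    instances: list[EvaluationInstance] = []
    cold = 0
    for i in range(len(data)):
        train = data[:i] + data[i + 1 :]
        fold_instances, fold_cold = _evaluate_split(
            train, [data[i]], similarity, tau, min_similarity
        )
        instances.extend(fold_instances)
        cold += fold_cold
    instances.sort(key=lambda inst: inst.protein_id)
    report = evaluate(instances, universe, macro_denominator)
    logger.info(
        "jackknife: |D|=%d |C|=%d tau=%.2f cold_start=%d recall=%.3f",
        len(data), len(universe), tau, cold, report.recall,
    )
    return CVResult("jackknife", tau, (report,), (cold,))


def kfold(
    dataset,
    similarity,
    tau: float = 0.3,
    k: int = 10,
    repeats: int = 30,
    seed: int = 0,
    min_similarity: float = 0.0,
    stratify: bool = False,
    macro_denominator: str = "universe",
) -> CVResult:
    """Repeated k-fold cross-validation.

    Each repeat reshuffles proteins into k folds (sizes within one of each
    other), trains on each complement and predicts the held-out fold; the
    repeat's metrics pool all |D| predictions, and the aggregate is the mean
    across repeats.  ``stratify`` deals proteins fold-round-robin within
    groups sharing the same sorted label set.
    """
    data = _as_annotations(dataset)
    if k > len(data):
        raise ValueError(f"k={k} exceeds dataset size {len(data)}")
    universe = sorted(frozenset().union(*(labels for _, labels in data)))
    strata = None
    if stratify:
        strata = [";".join(sorted(labels)) for _, labels in data]
    plan = plan_folds(len(data), k, repeats, seed, protocol="kfold", strata=strata)
    reports = []
    cold_counts = []
    for rep_assign in plan.assignments:
        instances: list[EvaluationInstance] = []
        cold = 0
        for fold in range(k):
            test = [data[i] for i, f in enumerate(rep_assign) if f == fold]
            train = [data[i] for i, f in enumerate(rep_assign) if f != fold]
            fold_instances, fold_cold = _evaluate_split(
                train, test, similarity, tau, min_similarity
            )
            instances.extend(fold_instances)
            cold += fold_cold
        # pool in protein-id order so metrics are invariant to fold layout
        instances.sort(key=lambda inst: inst.protein_id)
        reports.append(evaluate(instances, universe, macro_denominator))
        cold_counts.append(cold)
    result = CVResult("kfold", tau, tuple(reports), tuple(cold_counts), plan)
    logger.info(
        "kfold: |D|=%d k=%d repeats=%d tau=%.2f mean recall=%.3f",
        len(data), k, repeats, tau, result.mean["Recall"],
    )
    return result
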