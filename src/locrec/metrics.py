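"""Multi-label evaluation measures for ranked localization predictions.

Given ground-truth location sets l(p) and ordered predicted lists l′(p) over
a location universe C, four measurement families are computed:

1. Dataset Precision / Recall / F plus a rank-aware OrderedPrecision that
   rewards correct locations placed earlier in the list (with the Δ(t, k)
   normalizer), their harmonic means, and MP = (Precision+OrderedPrecision)/2.
2. Per-location precision/recall/F1 (each protein contributes its whole
   |l′∩l|/|l′| or |l′∩l|/|l| ratio to every location it predicts / holds),
   plus the macro F1 averaged over the universe.
3. Mean Jaccard accuracy ACC′, exact-set-match rate ATR, and the mean
   symmetric-difference rate AFR (normalized by |D|·|C|).
4. Label-wise accuracy ACC, which also credits true negatives.

A protein whose prediction is empty (cold start) contributes 0 to every
precision-like term but stays in |D|, penalizing the failure rather than
hiding it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "EvaluationInstance",
    "MetricsReport",
    "delta",
    "precision_recall_f",
    "ordered_precision",
    "per_location_metrics",
    "measure3",
    "measure4_acc",
    "evaluate",
]


@dataclass(frozen=True)
class EvaluationInstance:
    """One (truth set, ordered prediction) pair for a protein."""

    protein_id: str
    truth: frozenset[str]
    prediction: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "truth", frozenset(self.truth))
        object.__setattr__(self, "prediction", tuple(self.prediction))
        if not self.truth:
            raise ValueError(f"protein {self.protein_id!r} has an empty truth set")
        if len(set(self.prediction)) != len(self.prediction):
            raise ValueError(f"prediction for {self.protein_id!r} contains duplicates")


def _harmonic(a: float, b: float) -> float:
    return 2.0 * a * b / (a + b) if (a + b) > 0 else 0.0


def _check_nonempty(instances: Sequence[EvaluationInstance]) -> None:
    if not instances:
        raise ValueError("cannot evaluate an empty instance list")


def delta(t: int, k: int) -> int:
    """Rank normalizer Δ(t, k) for a t-long prediction against k true labels.

    The maximum attainable sum of (t − position + 1) over correct hits: the
    top min(t, k) ranks.
    """
    if t < 1 or k < 1:
        raise ValueError(f"delta requires positive arguments, got t={t}, k={k}")
    if t >= k:
        return t * k - k * (k - 1) // 2
    return t * (t + 1) // 2


def precision_recall_f(
    instances: Sequence[EvaluationInstance],
) -> tuple[float, float, float]:
    """Dataset-mean Precision, Recall and their F-measure (order-blind)."""
    _check_nonempty(instances)
    n = len(instances)
    prec = 0.0
    rec = 0.0
    for inst in instances:
        hits = len(set(inst.prediction) & inst.truth)
        if inst.prediction:
            prec += hits / len(inst.prediction)
        rec += hits / len(inst.truth)
    prec /= n
    rec /= n
    return prec, rec, _harmonic(prec, rec)


def ordered_precision(
    instances: Sequence[EvaluationInstance],
) -> tuple[float, float, float, float]:
    """Rank-aware precision family: (OrderedPrecision, F_ordered, MP, F_MP).

    Per protein, Pre_p = Σ_j (t − i_j + 1) / Δ(t, k) over the 1-based
    positions i_j of correctly predicted locations; an empty prediction
    scores 0.
    """
    _check_nonempty(instances)
    prec, rec, _ = precision_recall_f(instances)
    total = 0.0
    for inst in instances:
        t = len(inst.prediction)
        if t == 0:
            continue
        k = len(inst.truth)
        num = sum(t - i + 1 for i, loc in enumerate(inst.prediction, start=1) if loc in inst.truth)
        total += num / delta(t, k)
    op = total / len(instances)
    f_ordered = _harmonic(op, rec)
    mp = (prec + op) / 2.0
    f_mp = _harmonic(mp, rec)
    return op, f_ordered, mp, f_mp


def per_location_metrics(
    instances: Sequence[EvaluationInstance],
    universe: Sequence[str],
    macro_denominator: str = "universe",
) -> tuple[dict[str, dict[str, float]], float]:
    """Per-location precision/recall/F1 and the macro-averaged F1.

    Each protein predicting location c contributes its whole-prediction
    ratio |l′∩l|/|l′| to Pre_c (and analogously |l′∩l|/|l| to Rec_c) — the
    per-location figures are conditional averages of the protein-level
    ratios, not one-vs-rest indicator counts.  Locations never predicted
    (Pre_c undefined) or with Pre_c + Rec_c = 0 get F1 = 0 but remain in the
    macro denominator when ``macro_denominator="universe"``; pass
    ``"defined"`` to average only over locations with a nonzero F1 basis
    (both Pre_c and Rec_c defined).
    """
    _check_nonempty(instances)
    if not universe:
        raise ValueError("location universe must be non-empty")
    if macro_denominator not in ("universe", "defined"):
        raise ValueError(f"unknown macro_denominator {macro_denominator!r}")
    table: dict[str, dict[str, float]] = {}
    defined = 0
    macro_sum = 0.0
    for c in universe:
        pred_ratios = []
        true_ratios = []
        for inst in instances:
            hits = len(set(inst.prediction) & inst.truth)
            if c in inst.prediction:
                pred_ratios.append(hits / len(inst.prediction))
            if c in inst.truth:
                true_ratios.append(hits / len(inst.truth))
        pre_c = sum(pred_ratios) / len(pred_ratios) if pred_ratios else 0.0
        rec_c = sum(true_ratios) / len(true_ratios) if true_ratios else 0.0
        f1_c = _harmonic(pre_c, rec_c) if pred_ratios and true_ratios else 0.0
        table[c] = {"precision": pre_c, "recall": rec_c, "f1": f1_c}
        if pred_ratios and true_ratios:
            defined += 1
            macro_sum += f1_c
    if macro_denominator == "universe":
        macro = sum(v["f1"] for v in table.values()) / len(universe)
    else:
        macro = macro_sum / defined if defined else 0.0
    return table, macro


def measure3(
    instances: Sequence[EvaluationInstance], universe: Sequence[str]
) -> tuple[float, float, float, float, float]:
    """(Recall, Precision, ACC′, ATR, AFR) for multi-label set agreement.

    ACC′ is the mean Jaccard index of truth vs. predicted set; ATR the
    exact-set-match rate; AFR the mean symmetric-difference size divided by
    |D|·|C|.
    """
    _check_nonempty(instances)
    if not universe:
        raise ValueError("location universe must be non-empty")
    prec, rec, _ = precision_recall_f(instances)
    n = len(instances)
    acc_prime = 0.0
    atr = 0.0
    sym_diff = 0.0
    for inst in instances:
        pred = set(inst.prediction)
        inter = len(pred & inst.truth)
        union = len(pred | inst.truth)
        acc_prime += inter / union  # union >= |truth| >= 1
        if pred == inst.truth:
            atr += 1.0
        sym_diff += union - inter
    return rec, prec, acc_prime / n, atr / n, sym_diff / (n * len(universe))


def measure4_acc(
    instances: Sequence[EvaluationInstance], universe: Sequence[str]
) -> float:
    """Label-wise accuracy ACC = mean (|l′∩l| + |C − (l ∪ l′)|) / |C|."""
    _check_nonempty(instances)
    if not universe:
        raise ValueError("location universe must be non-empty")
    uni = set(universe)
    total = 0.0
    for inst in instances:
        pred = set(inst.prediction)
        inter = len(pred & inst.truth)
        tn = len(uni - (pred | inst.truth))
        total += (inter + tn) / len(uni)
    return total / len(instances)


@dataclass(frozen=True)
class MetricsReport:
    """All four measurement families over one instance set (dataset or fold)."""

    precision: float
    recall: float
    f_measure: float
    ordered_precision: float
    f_ordered: float
    mp: float
    f_mp: float
    per_location: Mapping[str, Mapping[str, float]]
    f1_macro: float
    acc_prime: float
    atr: float
    afr: float
    acc: float
    n_instances: int
    n_locations: int
    n_empty_predictions: int

    #: column order of the TSV serialization
    TSV_COLUMNS = (
        "Recall",
        "Precision",
        "OrderedPrecision",
        "MP",
        "F_measure",
        "F_ordered_measure",
        "F_MP_measure",
        "F1_score",
        "ACC_prime",
        "ATR",
        "AFR",
        "ACC",
        "n_proteins",
        "n_locations",
        "n_empty_predictions",
    )

    def scalar_dict(self) -> dict[str, float]:
        """The headline metrics keyed by their conventional names."""
        return {
            "Recall": self.recall,
            "Precision": self.precision,
            "OrderedPrecision": self.ordered_precision,
            "MP": self.mp,
            "F_measure": self.f_measure,
            "F_ordered_measure": self.f_ordered,
            "F_MP_measure": self.f_mp,
            "F1_score": self.f1_macro,
            "ACC_prime": self.acc_prime,
            "ATR": self.atr,
            "AFR": self.afr,
            "ACC": self.acc,
        }

    def to_dict(self) -> dict[str, float]:
        """Flat JSON-ready document (per-location figures under prefixed keys)."""
        out: dict[str, float] = dict(self.scalar_dict())
        out["n_proteins"] = self.n_instances
        out["n_locations"] = self.n_locations
        out["n_empty_predictions"] = self.n_empty_predictions
        for loc in sorted(self.per_location):
            vals = self.per_location[loc]
            out[f"Pre_c[{loc}]"] = vals["precision"]
            out[f"Rec_c[{loc}]"] = vals["recall"]
            out[f"F1_score_c[{loc}]"] = vals["f1"]
        return out

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_tsv_row(self) -> str:
        vals = self.scalar_dict()
        vals["n_proteins"] = self.n_instances
        vals["n_locations"] = self.n_locations
        vals["n_empty_predictions"] = self.n_empty_predictions
        return "\t".join(_format_cell(vals[c]) for c in self.TSV_COLUMNS)

    @classmethod
    def tsv_header(cls) -> str:
        return "\t".join(cls.TSV_COLUMNS)


def _format_cell(v) -> str:
    if isinstance(v, int):
        return str(v)
    return f"{v:.6f}"


def evaluate(
    instances: Sequence[EvaluationInstance],
    universe: Iterable[str] | None = None,
    macro_denominator: str = "universe",
) -> MetricsReport:
    """Compute every measurement family at once.

    ``universe`` fixes C (and therefore |C|, which AFR, ACC and the macro F1
    depend on); when omitted it defaults to the union of all truth and
    prediction labels.  Labels outside an explicit universe are an error —
    they would silently distort |C|-normalized quantities.
    """
    instances = list(instances)
    _check_nonempty(instances)
    seen: set[str] = set()
    for inst in instances:
        seen |= inst.truth
        seen |= set(inst.prediction)
    if universe is None:
        uni = tuple(sorted(seen))
    else:
        uni = tuple(dict.fromkeys(universe))
        stray = seen - set(uni)
        if stray:
            raise ValueError(f"labels outside the location universe: {sorted(stray)}")
    prec, rec, f_meas = precision_recall_f(instances)
    op, f_ord, mp, f_mp = ordered_precision(instances)
    per_loc, macro = per_location_metrics(instances, uni, macro_denominator)
    _, _, acc_prime, atr, afr = measure3(instances, uni)
    acc = measure4_acc(instances, uni)
    return MetricsReport(
        precision=prec,
        recall=rec,
        f_measure=f_meas,
        ordered_precision=op,
        f_ordered=f_ord,
        mp=mp,
        f_mp=f_mp,
        per_location=per_loc,
        f1_macro=macro,
        acc_prime=acc_prime,
        atr=atr,
        afr=afr,
        acc=acc,
        n_instances=len(instances),
        n_locations=len(uni),
        n_empty_predictions=sum(1 for i in instances if not i.prediction),
    )
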