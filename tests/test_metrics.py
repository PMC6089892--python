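"""Multi-label metric families against literal naive re-implementations."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locrec import (
    EvaluationInstance,
    delta,
    evaluate,
    measure3,
    measure4_acc,
    ordered_precision,
    per_location_metrics,
    precision_recall_f,
)

from oracles import (
    naive_delta,
    naive_measure3,
    naive_measure4,
    naive_ordered_precision,
    naive_per_location,
    naive_precision,
    naive_recall,
)


def random_instances(rng, n_max=12, universe_size=6):
    universe = [f"L{i}" for i in range(universe_size)]
    n = int(rng.integers(1, n_max + 1))
    out = []
    for i in range(n):
        k = int(rng.integers(1, universe_size + 1))
        truth = frozenset(rng.choice(universe, size=k, replace=False).tolist())
        t = int(rng.integers(0, universe_size + 1))
        pred = tuple(rng.choice(universe, size=t, replace=False).tolist())
        out.append(EvaluationInstance(f"p{i}", truth, pred))
    return out, universe


class TestInstanceValidation:
    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError, match="empty truth"):
            EvaluationInstance("p", frozenset(), ("A",))

    def test_duplicate_prediction_rejected(self):
        with pytest.raises(ValueError, match="duplicates"):
            EvaluationInstance("p", frozenset({"A"}), ("A", "A"))


class TestDelta:
    @pytest.mark.parametrize("t,k,expected", [(3, 2, 5), (2, 3, 3), (1, 1, 1), (5, 2, 9)])
    def test_known_values(self, t, k, expected):
        assert delta(t, k) == expected

    def test_branches_coincide_at_t_equals_k(self):
        for t in range(1, 11):
            assert delta(t, t) == t * (t + 1) // 2

    @given(t=st.integers(1, 30), k=st.integers(1, 30))
    @settings(deadline=None, derandomize=True)
    def test_matches_direct_summation(self, t, k):
        assert delta(t, k) == naive_delta(t, k)

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(ValueError):
            delta(0, 1)


class TestMeasure1:
    def test_worked_example(self):
        inst = [EvaluationInstance("p", {"A"}, ("A", "B"))]
        p, r, f = precision_recall_f(inst)
        assert (p, r) == (0.5, 1.0)
        assert f == pytest.approx(2 / 3)

    def test_perfect_predictions(self):
        inst = [EvaluationInstance("p", {"A", "B"}, ("A", "B"))]
        assert precision_recall_f(inst) == (1.0, 1.0, 1.0)

    def test_all_empty_predictions_degenerate(self):
        inst = [EvaluationInstance("p", {"A"}, ())]
        assert precision_recall_f(inst) == (0.0, 0.0, 0.0)

    def test_empty_instance_list_rejected(self):
        with pytest.raises(ValueError):
            precision_recall_f([])

    def test_ordered_precision_rewards_early_hits(self):
        a = [EvaluationInstance("p", {"A", "C"}, ("A", "C", "B"))]
        b = [EvaluationInstance("p", {"A", "C"}, ("B", "A", "C"))]
        assert ordered_precision(a)[0] == 1.0
        # hits at positions 2 and 3 of a 3-long list: (2 + 1) / Δ(3,2) = 0.6
        assert ordered_precision(b)[0] == pytest.approx(0.6)

    def test_ordered_precision_worked_positions(self):
        inst = [EvaluationInstance("p", {"A", "C"}, ("A", "B", "C"))]
        assert ordered_precision(inst)[0] == pytest.approx(0.8)

    def test_exact_match_any_order_scores_one(self):
        inst = [EvaluationInstance("p", {"A", "B"}, ("B", "A"))]
        assert ordered_precision(inst)[0] == 1.0

    def test_mp_is_mean_of_precisions(self):
        inst = [EvaluationInstance("p", {"A"}, ("B", "A"))]
        p, r, _ = precision_recall_f(inst)
        op, _, mp, _ = ordered_precision(inst)
        assert mp == pytest.approx((p + op) / 2)


class TestMeasure2:
    def test_single_instance_macro(self):
        inst = [EvaluationInstance("p", {"A"}, ("A",))]
        table, macro = per_location_metrics(inst, ["A", "B"])
        assert table["A"] == {"precision": 1.0, "recall": 1.0, "f1": 1.0}
        assert table["B"]["f1"] == 0.0
        assert macro == 0.5

    def test_unseen_location_still_counted_in_universe(self):
        inst = [EvaluationInstance("p", {"A"}, ("A",))]
        _, macro_uni = per_location_metrics(inst, ["A", "B", "C"])
        _, macro_def = per_location_metrics(inst, ["A", "B", "C"], macro_denominator="defined")
        assert macro_uni == pytest.approx(1 / 3)
        assert macro_def == 1.0

    def test_whole_prediction_ratio_not_indicator(self):
        # the protein predicts (A, B) with truth {A}: location B's precision
        # term is the whole ratio 1/2, not the indicator 0
        inst = [EvaluationInstance("p", {"A"}, ("A", "B"))]
        table, _ = per_location_metrics(inst, ["A", "B"])
        assert table["B"]["precision"] == 0.5


class TestMeasure3And4:
    def test_worked_example(self):
        inst = [EvaluationInstance("p", {"A"}, ("A", "B"))]
        rec, prec, acc_p, atr, afr = measure3(inst, ["A", "B", "X"])
        assert (rec, prec) == (1.0, 0.5)
        assert acc_p == 0.5 and atr == 0.0
        assert afr == pytest.approx(1 / 3)
        assert measure4_acc(inst, ["A", "B", "X"]) == pytest.approx(2 / 3)

    def test_exact_set_match(self):
        inst = [EvaluationInstance("p", {"A", "B"}, ("B", "A"))]
        _, _, acc_p, atr, afr = measure3(inst, ["A", "B", "C"])
        assert (acc_p, atr, afr) == (1.0, 1.0, 0.0)

    def test_disjoint_sets(self):
        inst = [EvaluationInstance("p", {"A"}, ("B",))]
        _, _, acc_p, atr, afr = measure3(inst, ["A", "B", "C"])
        assert (acc_p, atr) == (0.0, 0.0)
        assert afr == pytest.approx(2 / 3)

    def test_acc_full_coverage_match(self):
        inst = [EvaluationInstance("p", {"A", "B"}, ("A", "B"))]
        assert measure4_acc(inst, ["A", "B"]) == 1.0

    def test_acc_complement_prediction_is_zero(self):
        inst = [EvaluationInstance("p", {"A"}, ("B", "C"))]
        assert measure4_acc(inst, ["A", "B", "C"]) == 0.0


class TestOracleSuite:
    def test_all_metrics_match_naive_reimplementations(self, rng):
        """Vectorized metrics equal literal formula loops on random data."""
        for _ in range(200):
            instances, universe = random_instances(rng)
            p, r, _ = precision_recall_f(instances)
            assert p == pytest.approx(naive_precision(instances), abs=1e-12)
            assert r == pytest.approx(naive_recall(instances), abs=1e-12)
            op = ordered_precision(instances)[0]
            assert op == pytest.approx(naive_ordered_precision(instances), abs=1e-12)
            table, macro = per_location_metrics(instances, universe)
            ntable, nmacro = naive_per_location(instances, universe)
            for c in universe:
                assert table[c]["precision"] == pytest.approx(ntable[c][0], abs=1e-12)
                assert table[c]["recall"] == pytest.approx(ntable[c][1], abs=1e-12)
                assert table[c]["f1"] == pytest.approx(ntable[c][2], abs=1e-12)
            assert macro == pytest.approx(nmacro, abs=1e-12)
            _, _, acc_p, atr, afr = measure3(instances, universe)
            nacc, natr, nafr = naive_measure3(instances, universe)
            assert acc_p == pytest.approx(nacc, abs=1e-12)
            assert atr == pytest.approx(natr, abs=1e-12)
            assert afr == pytest.approx(nafr, abs=1e-12)
            assert measure4_acc(instances, universe) == pytest.approx(
                naive_measure4(instances, universe), abs=1e-12
            )

    def test_prediction_order_only_affects_rank_aware_family(self, rng):
        for _ in range(20):
            instances, universe = random_instances(rng)
            shuffled = [
                EvaluationInstance(
                    i.protein_id, i.truth,
                    tuple(rng.permutation(list(i.prediction)).tolist()),
                )
                for i in instances
            ]
            a, b = evaluate(instances, universe), evaluate(shuffled, universe)
            for key, val in a.scalar_dict().items():
                if key in ("OrderedPrecision", "MP", "F_ordered_measure", "F_MP_measure"):
                    continue
                assert val == pytest.approx(b.scalar_dict()[key], abs=1e-12), key

    def test_appending_correct_location_never_hurts_recall_acc(self, rng):
        for _ in range(40):
            instances, universe = random_instances(rng)
            inst = instances[0]
            missing = sorted(inst.truth - set(inst.prediction))
            if not missing:
                continue
            extended = EvaluationInstance(
                inst.protein_id, inst.truth, inst.prediction + (missing[0],)
            )
            base, ext = (
                evaluate([inst], universe),
                evaluate([extended], universe),
            )
            assert ext.recall >= base.recall
            assert ext.acc >= base.acc
            assert ext.acc_prime >= base.acc_prime

    def test_bounds_invariants(self, rng):
        for _ in range(50):
            instances, universe = random_instances(rng)
            rep = evaluate(instances, universe)
            for key, val in rep.scalar_dict().items():
                assert -1e-12 <= val <= 1 + 1e-12, key
            assert rep.atr <= rep.acc_prime + 1e-12


class TestReportSerialization:
    def test_flat_json_and_tsv_round_values(self):
        inst = [EvaluationInstance("p", {"A"}, ("A", "B"))]
        rep = evaluate(inst, ["A", "B", "X"])
        doc = json.loads(rep.to_json())
        assert doc["Precision"] == 0.5
        assert doc["Recall"] == 1.0
        assert doc["ACC_prime"] == 0.5
        assert doc["ACC"] == pytest.approx(2 / 3)
        assert doc["AFR"] == pytest.approx(1 / 3)
        assert doc["n_empty_predictions"] == 0
        assert "F1_score_c[A]" in doc
        row = rep.to_tsv_row().split("\t")
        assert len(row) == len(rep.TSV_COLUMNS)

    def test_stray_label_outside_universe_rejected(self):
        inst = [EvaluationInstance("p", {"A"}, ("Z",))]
        with pytest.raises(ValueError, match="outside"):
            evaluate(inst, ["A", "B"])
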