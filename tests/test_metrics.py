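"""Confusion-matrix metrics, UAR, and direction/severity roll-ups.

The frozen expected values come from a published per-class benchmark table
for the ten-class (and pooled-ADL seven-class) task; they pin down the
aggregation semantics: UAR is the plain mean of per-class recalls,
direction roll-ups average 2 fall classes, severity roll-ups average 3,
and the falls-only figure averages all 6.
"""

import numpy as np
import pytest

from fallwatch.metrics import (
    ClassMetrics,
    confusion,
    direction_uar,
    evaluate,
    falls_only_average,
    per_class_metrics,
    round2,
    severity_uar,
    uar,
)

# Benchmark per-class test recalls (%), ten-class experiment.
TEN_CLASS_RECALL = {
    "BHF": 75.00, "FHF": 88.89, "LHF": 75.00, "BSF": 95.83, "FSF": 77.08,
    "LSF": 95.83, "J": 96.71, "S": 96.77, "SB": 83.78, "W": 97.63,
}
# Same benchmark, falls vs pooled-ADL experiment.
SEVEN_CLASS_RECALL = {
    "BHF": 91.67, "FHF": 97.22, "LHF": 66.67, "BSF": 95.83, "FSF": 81.25,
    "LSF": 89.58, "ADL": 100.0,
}


def metrics_from_recalls(recalls: dict) -> ClassMetrics:
    classes = tuple(recalls)
    zeros = {c: 0.0 for c in classes}
    return ClassMetrics(classes=classes, precision=zeros, recall=dict(recalls),
                        specificity=zeros, f1=zeros)


class TestConfusion:
    def test_perfect_diagonal(self):
        cm = confusion(["A", "B"], ["A", "B"], ("A", "B"))
        assert cm.counts.tolist() == [[1, 0], [0, 1]]

    def test_single_misclassification_off_diagonal(self):
        cm = confusion(["A"], ["B"], ("A", "B"))
        assert cm.counts.tolist() == [[0, 1], [0, 0]]

    def test_total_equals_sample_count(self, rng):
        labels = ["A", "B", "C"]
        y_true = rng.choice(labels, size=57).tolist()
        y_pred = rng.choice(labels, size=57).tolist()
        assert confusion(y_true, y_pred, tuple(labels)).total == 57

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["A"], ["Z"], ("A", "B"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(["A", "B"], ["A"], ("A", "B"))


class TestPerClassMetrics:
    def test_f1_from_printed_precision_recall(self):
        """P=100, R=75.00 gives F1=85.71 (one-vs-rest arithmetic)."""
        # 3 true positives of class X, 1 missed, nothing else predicted X
        cm = confusion(["X"] * 4 + ["Y"], ["X"] * 3 + ["Y", "Y"], ("X", "Y"))
        m = per_class_metrics(cm)
        assert m.precision["X"] == pytest.approx(100.0)
        assert m.recall["X"] == pytest.approx(75.0)
        assert round2(m.f1["X"]) == 85.71

    def test_counts_arithmetic(self):
        from fallwatch.metrics import ConfusionMatrix

        cm = ConfusionMatrix(counts=np.array([[8, 2], [1, 9]]), classes=("A", "B"))
        m = per_class_metrics(cm)
        assert m.recall["A"] == pytest.approx(80.0)
        assert m.precision["A"] == pytest.approx(100 * 8 / 9, abs=0.01)  # 88.89
        assert m.specificity["A"] == pytest.approx(90.0)

    def test_perfect_matrix_all_hundred(self):
        cm = confusion(["A", "B"] * 5, ["A", "B"] * 5, ("A", "B"))
        m = per_class_metrics(cm)
        for d in (m.precision, m.recall, m.specificity, m.f1):
            assert all(v == pytest.approx(100.0) for v in d.values())

    def test_zero_denominator_reports_zero(self):
        # class B never occurs and is never predicted
        cm = confusion(["A", "A"], ["A", "A"], ("A", "B"))
        m = per_class_metrics(cm)
        assert m.recall["B"] == 0.0
        assert m.precision["B"] == 0.0
        assert m.f1["B"] == 0.0


class TestUar:
    def test_ten_class_benchmark_average(self):
        assert round2(uar(TEN_CLASS_RECALL.values())) == 88.25

    def test_seven_class_benchmark_average(self):
        assert round2(uar(SEVEN_CLASS_RECALL.values())) == 88.89

    def test_single_class_is_identity(self):
        assert uar([73.5]) == pytest.approx(73.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            uar([])

    def test_order_invariant(self, rng):
        vals = rng.uniform(0, 100, size=9)
        assert uar(vals) == pytest.approx(uar(vals[::-1]))

    def test_unweighted_under_class_duplication(self):
        """Duplicating every window of one class leaves UAR unchanged."""
        y_true = ["A"] * 4 + ["B"] * 10
        y_pred = ["A", "A", "A", "B"] + ["B"] * 9 + ["A"]
        base = evaluate(y_true, y_pred, ("A", "B")).uar
        dup = evaluate(y_true + ["A"] * 4, y_pred + ["A", "A", "A", "B"], ("A", "B")).uar
        assert dup == pytest.approx(base)


class TestFallRollups:
    def test_direction_benchmark_values(self):
        d = direction_uar(metrics_from_recalls(TEN_CLASS_RECALL))
        assert d["forward"] == pytest.approx(82.99, abs=0.01)
        assert d["backward"] == pytest.approx(85.42, abs=0.01)
        assert d["lateral"] == pytest.approx(85.42, abs=0.01)

    def test_severity_benchmark_values(self):
        s = severity_uar(metrics_from_recalls(TEN_CLASS_RECALL))
        assert s["hard"] == pytest.approx(79.63, abs=0.01)
        assert s["soft"] == pytest.approx(89.58, abs=0.01)

    def test_falls_only_benchmark_values(self):
        assert falls_only_average(metrics_from_recalls(TEN_CLASS_RECALL)) == \
            pytest.approx(84.60, abs=0.01)
        assert falls_only_average(metrics_from_recalls(SEVEN_CLASS_RECALL)) == \
            pytest.approx(87.04, abs=0.01)

    def test_equal_recalls_collapse(self):
        flat = metrics_from_recalls({c: 60.0 for c in
                                     ("FHF", "BHF", "LHF", "FSF", "BSF", "LSF")})
        assert all(v == pytest.approx(60.0) for v in direction_uar(flat).values())
        assert all(v == pytest.approx(60.0) for v in severity_uar(flat).values())

    def test_severity_mean_equals_falls_only(self):
        """hard and soft each cover 3 of the 6 fall classes, so their plain
        mean equals the falls-only average."""
        m = metrics_from_recalls(TEN_CLASS_RECALL)
        s = severity_uar(m)
        assert (s["hard"] + s["soft"]) / 2 == pytest.approx(falls_only_average(m))

    def test_missing_fall_class_rejected(self):
        m = metrics_from_recalls({"FHF": 50.0, "BHF": 50.0})
        with pytest.raises(ValueError):
            direction_uar(m)


class TestEvalReport:
    def test_report_round_trip_and_rollups(self):
        classes = ("W", "J", "S", "SB", "FHF", "BHF", "LHF", "FSF", "BSF", "LSF")
        y = [c for c in classes for _ in range(3)]
        rep = evaluate(y, y, classes)
        d = rep.to_dict()
        assert d["uar"] == 100.0
        assert d["direction_uar"] == {"forward": 100.0, "backward": 100.0, "lateral": 100.0}
        assert d["severity_uar"] == {"hard": 100.0, "soft": 100.0}
        assert d["falls_only_average"] == 100.0
        assert "Average" in rep.to_table()

    def test_round2_half_up(self):
        assert round2(85.715) == 85.72
        assert round2(88.885) == 88.89
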