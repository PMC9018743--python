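"""MoA benchmarking, combination rating, sensitivity association."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugnetstrat.compare import SeparationMatrix
from drugnetstrat.enrichment import EnrichmentRecord
from drugnetstrat.evaluate import (
    classify_pairs,
    metrics_from_counts,
    predict_combinations,
    sensitivity_association,
    sweep_thresholds,
    tanimoto,
)


def small_matrix(scores, cell_lines, drugs, moas):
    ids = list(scores.index)
    meta = pd.DataFrame(
        {"cell_line": cell_lines, "drug": drugs, "moa": moas}, index=ids
    )
    return SeparationMatrix(scores=scores, meta=meta)


def mcc_oracle(tp, fp, fn, tn):
    num = tp * tn - fp * fn
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return num / den if den else 0.0


class TestMetricsFromCounts:
    def test_imbalanced_benchmark_worked_example(self):
        """200 same-MoA vs 6017 different-MoA pairs at sensitivity 0.400 and
        specificity 0.917 imply the confusion matrix (80, 500, 120, 5517)."""
        m = metrics_from_counts(tp=80, fp=500, fn=120, tn=5517)
        assert round(m.precision, 3) == 0.138
        assert round(m.recall, 3) == 0.400
        assert round(m.accuracy, 3) == 0.900
        assert round(m.specificity, 3) == 0.917
        assert round(m.fpr, 3) == 0.083
        assert round(m.f1, 3) == 0.205
        assert round(m.mcc, 3) == 0.192

    def test_perfect_classifier(self):
        m = metrics_from_counts(tp=10, fp=0, fn=0, tn=20)
        assert m.mcc == 1.0 and m.f1 == 1.0

    def test_no_positive_predictions_degenerate(self):
        m = metrics_from_counts(tp=0, fp=0, fn=5, tn=5)
        assert m.degenerate and m.precision == 0.0 and m.mcc == 0.0

    def test_mcc_invariant_under_class_swap(self, rng):
        """Swapping the two classes (and the prediction sense) transposes the
        confusion matrix tp<->tn, fp<->fn; MCC is invariant."""
        for _ in range(50):
            tp, fp, fn, tn = (int(x) for x in rng.integers(0, 40, size=4))
            a = metrics_from_counts(tp, fp, fn, tn).mcc
            b = metrics_from_counts(tn, fn, fp, tp).mcc
            assert a == pytest.approx(b, abs=1e-12)
            assert a == pytest.approx(mcc_oracle(tp, fp, fn, tn), abs=1e-12)


def four_condition_matrix():
    """Two MoA classes; same-class pairs overlap (negative s), cross separated."""
    ids = ["c1", "c2", "c3", "c4"]
    s = np.array(
        [
            [0.0, -0.5, 0.8, 0.9],
            [-0.5, 0.0, 0.7, 0.8],
            [0.8, 0.7, 0.0, -0.4],
            [0.9, 0.8, -0.4, 0.0],
        ]
    )
    scores = pd.DataFrame(s, index=ids, columns=ids)
    return small_matrix(
        scores,
        cell_lines=["A", "A", "A", "A"],
        drugs=["d1", "d2", "d3", "d4"],
        moas=["m1", "m1", "m2", "m2"],
    )


class TestClassifyAndSweep:
    def test_perfectly_separable_matrix_gives_mcc_one(self):
        m = four_condition_matrix()
        assert classify_pairs(m, threshold=0.0).mcc == 1.0

    def test_threshold_below_all_scores_degenerate(self):
        m = four_condition_matrix()
        res = classify_pairs(m, threshold=-10.0)
        assert res.degenerate and res.tp == 0 and res.fp == 0

    def test_similarity_threshold_is_strict(self):
        m = four_condition_matrix()
        res = classify_pairs(m, threshold=-0.4)  # s=-0.4 is NOT < -0.4
        assert res.tp == 1  # only the -0.5 pair

    def test_single_threshold_sweep(self):
        m = four_condition_matrix()
        res = sweep_thresholds(m, [0.0])
        assert res.best.threshold == 0.0

    def test_best_by_mcc_with_tie_to_smaller_threshold(self):
        m = four_condition_matrix()
        res = sweep_thresholds(m, [-0.45, 0.0, 0.5, 2.0])
        assert res.best.mcc == 1.0
        assert res.best.threshold == 0.0  # -0.45 misses the -0.4 pair
        assert res.auc == 1.0

    def test_roc_monotone_along_sweep(self, pipeline_result):
        table = pipeline_result.sweep.table.sort_values("threshold")
        assert (np.diff(table["tpr"]) >= -1e-12).all()
        assert (np.diff(table["fpr"]) >= -1e-12).all()

    def test_single_class_labels_flagged(self):
        ids = ["c1", "c2"]
        scores = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=ids, columns=ids)
        m = small_matrix(scores, ["A", "A"], ["d1", "d2"], ["m1", "m1"])
        res = sweep_thresholds(m, [0.0])
        assert res.degenerate_labels and np.isnan(res.auc)


class TestTanimoto:
    def test_identical(self):
        assert tanimoto({1, 2, 3}, {1, 2, 3}) == 1.0

    def test_disjoint(self):
        assert tanimoto({1, 2}, {3, 4}) == 0.0

    def test_half(self):
        assert tanimoto({1, 2, 3}, {2, 3, 4}) == 0.5

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            tanimoto(set(), set())

    @settings(derandomize=True, max_examples=60)
    @given(st.sets(st.integers(0, 15)), st.sets(st.integers(0, 15)))
    def test_bounds_symmetry_and_identity(self, a, b):
        if not (a | b):
            return
        s = tanimoto(a, b)
        assert 0.0 <= s <= 1.0
        assert s == tanimoto(b, a)
        assert (s == 1.0) == (a == b)


@settings(derandomize=True, max_examples=60)
@given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
def test_metric_ranges_hold_for_any_confusion_matrix(tp, fp, fn, tn):
    m = metrics_from_counts(tp, fp, fn, tn)
    for name in ("precision", "recall", "accuracy", "specificity", "tpr", "fpr", "f1"):
        assert 0.0 <= getattr(m, name) <= 1.0
    assert -1.0 <= m.mcc <= 1.0
    assert m.tp + m.fn == tp + fn and m.fp + m.tn == fp + tn


def sig_rec(name):
    return EnrichmentRecord(name, 5, 10, 50, 300, 0.01, True)


class TestPredictCombinations:
    def build(self, s_ab, size_a, size_b, shared_paths, shared_driver):
        ids = ["x", "y"]
        scores = pd.DataFrame(
            [[0.0, s_ab], [s_ab, 0.0]], index=ids, columns=ids
        )
        m = small_matrix(scores, ["A", "A"], ["d1", "d2"], ["m1", "m2"])
        driver = {"DRV"} if shared_driver else set()
        nets = {
            "x": {f"a{i}" for i in range(size_a - 1)} | {"DRV"},
            "y": {f"b{i}" for i in range(size_b - 1)} | {"DRV"},
        }
        common = [sig_rec("MAPK signaling pathway")] if shared_paths else []
        enr = {
            "x": common + [sig_rec("Jak-STAT signaling pathway")],
            "y": common + [sig_rec("VEGF signaling pathway")],
        }
        return predict_combinations(nets, enr, m, {"DRV"} if shared_driver else {"NOPE"})

    def test_separated_large_networks_with_shared_driver_pass_both(self):
        [c] = self.build(0.69, 120, 60, shared_paths=False, shared_driver=True)
        assert c.passes_rating and c.passes_driver_rule
        assert c.shared_drivers == 1

    def test_overlapping_networks_fail_both(self):
        [c] = self.build(-0.2, 120, 60, shared_paths=False, shared_driver=True)
        assert not c.passes_rating and not c.passes_driver_rule

    def test_small_network_fails_rating(self):
        [c] = self.build(0.5, 35, 150, shared_paths=False, shared_driver=False)
        assert not c.passes_rating

    def test_two_shared_pathways_fail_rating(self):
        ids = ["x", "y"]
        scores = pd.DataFrame([[0.0, 0.5], [0.5, 0.0]], index=ids, columns=ids)
        m = small_matrix(scores, ["A", "A"], ["d1", "d2"], ["m1", "m2"])
        nets = {"x": {f"a{i}" for i in range(150)}, "y": {f"b{i}" for i in range(150)}}
        shared = [sig_rec("MAPK signaling pathway"), sig_rec("Ras signaling pathway")]
        enr = {"x": shared, "y": shared}
        [c] = predict_combinations(nets, enr, m, set())
        assert c.shared_pathways == 2 and not c.passes_rating

    def test_ranked_by_descending_separation(self, pipeline_result, default_cohort):
        combos = pipeline_result.combinations
        assert len(combos) > 1
        s = [c.s_ab for c in combos]
        assert s == sorted(s, reverse=True)
        for c in combos:  # flags recomputable from recorded fields
            expected = (
                c.s_ab > 0 and c.shared_pathways < 2
                and min(c.n_nodes_a, c.n_nodes_b) > 40
                and max(c.n_nodes_a, c.n_nodes_b) > 100
            )
            assert c.passes_rating == expected


class TestSensitivityAssociation:
    def matrix(self, s_vals):
        ids = [f"c{i}" for i in range(len(s_vals))]
        n = len(ids)
        scores = pd.DataFrame(np.zeros((n, n)), index=ids, columns=ids)
        for i in range(n):
            for j in range(i + 1, n):
                scores.iloc[i, j] = scores.iloc[j, i] = (s_vals[i] + s_vals[j]) / 2
        meta = pd.DataFrame(
            {
                "cell_line": ["A"] * n,
                "drug": [f"d{i}" for i in range(n)],
                "moa": ["m"] * n,
            },
            index=ids,
        )
        return SeparationMatrix(scores=scores, meta=meta)

    def test_excludes_same_sign_pairs(self):
        m = self.matrix([1.0, 2.0, 3.0])
        sens = {("A", f"d{i}"): -1.0 for i in range(3)}  # all sensitive
        with pytest.raises(ValueError):
            sensitivity_association(m, sens)

    def test_perfectly_linear_data_gives_r_one(self):
        ids = ["c0", "c1", "c2", "c3"]
        scores = pd.DataFrame(0.0, index=ids, columns=ids)
        # mixed-sign z pairs with s_ab exactly linear in |dz|
        z = {("A", "d0"): -1.0, ("A", "d1"): 1.0, ("A", "d2"): 2.0, ("A", "d3"): 3.0}
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                za, zb = z[("A", a.replace("c", "d"))], z[("A", b.replace("c", "d"))]
                scores.loc[a, b] = scores.loc[b, a] = 0.1 * abs(za - zb)
        meta = pd.DataFrame(
            {"cell_line": ["A"] * 4, "drug": [f"d{i}" for i in range(4)], "moa": ["m"] * 4},
            index=ids,
        )
        m = SeparationMatrix(scores=scores, meta=meta)
        res = sensitivity_association(m, z, ss_floor=-10.0)
        assert res.n == 3  # only d0 pairs mix signs
        assert res.r == pytest.approx(1.0)

    def test_planted_cohort_positive_association(self, pipeline_result):
        """Planted sensitivity coupling: separation grows with |dz|."""
        assert pipeline_result.regression is not None
        assert pipeline_result.regression.r > 0
        assert pipeline_result.regression.n >= 3
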