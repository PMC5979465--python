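"""Confusion-matrix measures, GC2 and class-size normalization.

The worked examples reuse published confusion counts from a three-class
stability benchmark (blind-test and tool-comparison matrices), which pin
the arithmetic of CPR, normalization factors and one-vs-rest measures.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protstab.metrics import (BinaryCounts, ConfusionMatrix,
                              binary_metrics, full_report,
                              matrix_from_margins, round_half_up)

CLASSES = ["increase", "decrease", "no_effect"]

# Blind-test column: TP (3, 66, 22), FN (20, 26, 28), FP (16, 36, 22)
BLIND = dict(tp=[3, 66, 22], fn=[20, 26, 28], fp=[16, 36, 22])
# Tool-comparison column of a published structure-free predictor
TOOL = dict(tp=[0, 22, 2], fn=[6, 4, 6], fp=[1, 11, 4])


@pytest.fixture(scope="module")
def blind_matrix():
    return matrix_from_margins(classes=CLASSES, **BLIND)


class TestBinaryMetrics:
    def test_published_decrease_column(self):
        c = BinaryCounts(tp=22, tn=3, fp=11, fn=4)
        m = binary_metrics(c)
        assert round_half_up(m["tpr"], 2) == 0.85
        assert round_half_up(m["ppv"], 2) == 0.67

    def test_perfect_prediction(self):
        m = binary_metrics(BinaryCounts(tp=10, tn=10, fp=0, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_no_association(self):
        m = binary_metrics(BinaryCounts(tp=25, tn=25, fp=25, fn=25))
        assert m["mcc"] == 0.0 and m["accuracy"] == 0.5

    def test_zero_denominators_are_nan_not_zero(self):
        m = binary_metrics(BinaryCounts(tp=0, tn=5, fp=0, fn=5))
        assert np.isnan(m["ppv"]) and np.isnan(m["mcc"])
        assert m["tnr"] == 1.0


class TestCPR:
    def test_diagonal_matrix(self):
        m = ConfusionMatrix(np.diag([5, 7, 9]), CLASSES)
        assert m.cpr() == 1.0

    def test_blind_test_value(self, blind_matrix):
        assert round_half_up(blind_matrix.cpr(), 3) == 0.552

    def test_tool_comparison_value(self):
        m = matrix_from_margins(classes=CLASSES, **TOOL)
        assert round_half_up(m.cpr(), 2) == 0.60


class TestGC2:
    def test_perfect_balanced_prediction(self):
        m = ConfusionMatrix(np.eye(3) * 10, CLASSES)
        assert m.gc2() == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        z = np.outer([10, 20, 30], [15, 25, 20]) / 60.0
        m = ConfusionMatrix(z, CLASSES)
        assert m.gc2() == pytest.approx(0.0, abs=1e-12)

    def test_chi_square_oracle(self):
        from scipy.stats import chi2_contingency

        z = np.array([[8, 1, 1], [2, 6, 2], [1, 1, 8]], dtype=float)
        m = ConfusionMatrix(z, CLASSES)
        chi2 = chi2_contingency(z, correction=False).statistic
        assert m.gc2() == pytest.approx(chi2 / (z.sum() * 2))

    def test_zero_margin_flagged_undefined(self):
        # nothing predicted increase: GC2 cannot be computed
        z = np.array([[0, 5, 4], [0, 9, 0], [0, 2, 7]], dtype=float)
        assert np.isnan(ConfusionMatrix(z, CLASSES).gc2())

    @given(tp=st.integers(1, 30), fp=st.integers(1, 30),
           fn=st.integers(1, 30), tn=st.integers(1, 30))
    @settings(max_examples=60, deadline=None)
    def test_equals_mcc_squared_on_2x2(self, tp, fp, fn, tn):
        z = np.array([[tp, fn], [fp, tn]], dtype=float)
        m = ConfusionMatrix(z, ["pos", "neg"])
        mcc = binary_metrics(m.one_vs_rest("pos"))["mcc"]
        assert m.gc2() == pytest.approx(mcc ** 2, abs=1e-10)

    def test_invariant_under_class_permutation(self, blind_matrix):
        permuted = blind_matrix.permuted(["no_effect", "increase",
                                          "decrease"])
        assert permuted.gc2() == pytest.approx(blind_matrix.gc2())
        assert permuted.cpr() == pytest.approx(blind_matrix.cpr())


class TestNormalization:
    def test_published_scaled_counts(self, blind_matrix):
        norm = blind_matrix.normalize_to_reference("no_effect")
        dec = norm.one_vs_rest("decrease")
        inc = norm.one_vs_rest("increase")
        assert round_half_up(dec.tp, 1) == 35.9   # 66 * 50/92
        assert round_half_up(inc.fn, 1) == 43.5   # 20 * 50/23
        # reference row untouched
        ref_row = blind_matrix.z[CLASSES.index("no_effect")]
        np.testing.assert_allclose(norm.z[CLASSES.index("no_effect")],
                                   ref_row)

    def test_row_proportions_and_sums_to_machine_precision(self,
                                                           blind_matrix):
        norm = blind_matrix.normalize_to_reference("no_effect")
        rows = norm.z.sum(axis=1)
        np.testing.assert_allclose(rows, rows[0], rtol=1e-15)
        for i in range(3):
            np.testing.assert_allclose(
                norm.z[i] / norm.z[i].sum(),
                blind_matrix.z[i] / blind_matrix.z[i].sum(), rtol=1e-12)

    def test_normalized_cpr(self, blind_matrix):
        norm = blind_matrix.normalize_to_reference("no_effect")
        assert round_half_up(norm.cpr(), 3) == 0.429

    def test_zero_row_is_error(self):
        z = np.array([[0, 0, 0], [1, 5, 1], [0, 1, 8]], dtype=float)
        with pytest.raises(ValueError, match="empty row"):
            ConfusionMatrix(z, CLASSES).normalize_to_reference("no_effect")


class TestOneVsRest:
    def test_collapse_conserves_n(self, blind_matrix):
        for cls in CLASSES:
            c = blind_matrix.one_vs_rest(cls)
            assert c.n == pytest.approx(blind_matrix.n)

    def test_blind_diagonal_recovered(self, blind_matrix):
        for cls, tp in zip(CLASSES, BLIND["tp"]):
            assert blind_matrix.one_vs_rest(cls).tp == pytest.approx(tp)


class TestMarginReconstruction:
    def test_margins_reproduced(self, blind_matrix):
        for cls, tp, fn, fp in zip(CLASSES, BLIND["tp"], BLIND["fn"],
                                   BLIND["fp"]):
            c = blind_matrix.one_vs_rest(cls)
            assert (c.tp, c.fn, c.fp) == pytest.approx((tp, fn, fp))

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            matrix_from_margins([1, 1, 1], [5, 5, 5], [1, 1, 1], CLASSES)


class TestFullReport:
    def test_blind_column_end_to_end(self, blind_matrix):
        report = full_report(blind_matrix, reference_class="no_effect")
        assert round_half_up(report.cpr_raw, 3) == 0.552
        assert round_half_up(report.cpr_normalized, 3) == 0.429
        tpr = report.per_class.loc[("tpr", "decrease"), "raw"]
        assert round_half_up(tpr, 3) == 0.717
        # sensitivity is row-derived: unchanged by row normalization
        assert report.per_class.loc[("tpr", "decrease"),
                                    "normalized"] == pytest.approx(tpr)

    def test_binary_input_includes_mcc(self):
        m = ConfusionMatrix(np.array([[8., 2.], [3., 7.]]), ["pos", "neg"])
        report = full_report(m, reference_class="neg")
        assert ("mcc", "pos") in report.per_class.index

    def test_relabeling_equivariance(self, blind_matrix):
        report = full_report(blind_matrix, "no_effect")
        permuted = full_report(blind_matrix.permuted(
            ["decrease", "no_effect", "increase"]), "no_effect")
        a = report.per_class.loc[("ppv", "decrease"), "raw"]
        b = permuted.per_class.loc[("ppv", "decrease"), "raw"]
        assert a == pytest.approx(b)

    def test_tsv_renders_na_markers(self, tmp_path):
        z = np.array([[0, 5, 4], [0, 9, 0], [0, 2, 7]], dtype=float)
        report = full_report(ConfusionMatrix(z, CLASSES), "no_effect")
        path = tmp_path / "report.tsv"
        report.to_tsv(path)
        assert "NA" in path.read_text()


class TestRounding:
    @pytest.mark.parametrize("x,nd,expected", [
        (0.365, 2, 0.37), (0.5515, 3, 0.552), (0.4285, 2, 0.43),
        (-0.125, 2, -0.13),
    ])
    def test_half_up(self, x, nd, expected):
        assert round_half_up(x, nd) == expected
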