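import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctcpheno import crosstab as ct, reference
from ctcpheno.core import CellAnnotation, ContingencyTable
from ctcpheno.errors import DegenerateTableError, JoinError


def proportional_table():
    # rank-1 counts: perfectly independent margins
    counts = np.outer([1, 2, 3], [2, 3, 4, 1])
    return ContingencyTable(("High", "Middle", "Low"), ct.CROSSTAB_COLS,
                            counts)


class TestCrossTabulate:
    def test_empty_annotations_all_zero(self):
        table = ct.cross_tabulate([])
        assert table.counts.sum() == 0
        assert table.counts.shape == (3, 4)

    def test_reported_59_cell_fixture(self):
        table = ct.cross_tabulate(reference.crosstab_annotations())
        assert table.counts.tolist() == [[7, 0, 1, 0], [0, 0, 7, 3],
                                         [0, 9, 4, 28]]
        assert table.n == 59

    def test_total_conserved(self, cells_500):
        from ctcpheno import phenotyping, qc
        matrix, _ = cells_500
        retained = matrix.subset_cells(
            [r.cell_id for r in qc.run_qc(matrix) if r.retained])
        annotations = phenotyping.annotate_cells(retained)
        assert ct.cross_tabulate(annotations).n == len(annotations)


def _chi_square_oracle(counts):
    """Direct-summation Pearson statistic, independent of the implementation."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    stat = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            e = counts[i].sum() * counts[:, j].sum() / n
            stat += (counts[i, j] - e) ** 2 / e
    return stat


class TestChiSquare:
    def test_df_for_3x4(self):
        assert ct.chi_square_test(reference.reported_crosstab())["df"] == 6

    def test_proportional_table_is_null(self):
        res = ct.chi_square_test(proportional_table())
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_statistic_matches_direct_summation(self):
        table = reference.reported_crosstab()
        res = ct.chi_square_test(table)
        assert res["statistic"] == pytest.approx(
            _chi_square_oracle(table.counts), abs=1e-9)

    def test_agrees_with_scipy(self):
        from scipy.stats import chi2_contingency
        table = reference.reported_crosstab()
        res = ct.chi_square_test(table)
        sp = chi2_contingency(table.counts, correction=False)
        assert res["statistic"] == pytest.approx(sp.statistic, rel=1e-12)
        assert res["p"] == pytest.approx(sp.pvalue, rel=1e-9)

    def test_transposition_invariance(self):
        table = reference.reported_crosstab()
        transposed = ContingencyTable(table.col_labels, table.row_labels,
                                      table.counts.T)
        assert ct.chi_square_test(table)["statistic"] == pytest.approx(
            ct.chi_square_test(transposed)["statistic"])

    def test_zero_margin_rejected(self):
        counts = np.array([[1, 0], [2, 0]])
        with pytest.raises(DegenerateTableError):
            ct.chi_square_test(ContingencyTable(("a", "b"), ("x", "y"),
                                                counts))


class TestAdjustedResiduals:
    def test_proportional_table_all_ns(self):
        residuals = ct.adjusted_residuals(proportional_table())
        assert all(r.significance == "ns" for r in residuals)
        assert all(abs(r.adjusted_residual) < 1e-9 for r in residuals)

    def test_top_left_cell_formula(self):
        """(High, HighStem): O=7, E=8*7/59; Haberman residual ~ 7.1."""
        residuals = ct.adjusted_residuals(reference.reported_crosstab())
        cell = residuals[0]
        e = 8 * 7 / 59
        denom = math.sqrt(e * (1 - 8 / 59) * (1 - 7 / 59))
        assert cell.observed == 7
        assert cell.expected == pytest.approx(e)
        assert cell.adjusted_residual == pytest.approx((7 - e) / denom)
        assert cell.adjusted_residual == pytest.approx(7.1, abs=0.05)
        assert cell.significance == "high_p01"

    def test_reported_significance_pattern(self):
        """The full 12-cell signed pattern of the published cross-tab."""
        residuals = ct.adjusted_residuals(reference.reported_crosstab())
        pattern = {(r.row, r.col): r.significance for r in residuals}
        assert pattern == {
            ("High", "HighStem_LowEMT"): "high_p01",
            ("High", "LowStem_MiddleEMT"): "ns",
            ("High", "LowStem_LowEMT"): "ns",
            ("High", "LowStem_HighEMT"): "low_p01",
            ("Middle", "HighStem_LowEMT"): "ns",
            ("Middle", "LowStem_MiddleEMT"): "ns",
            ("Middle", "LowStem_LowEMT"): "high_p01",
            ("Middle", "LowStem_HighEMT"): "ns",
            ("Low", "HighStem_LowEMT"): "low_p01",
            ("Low", "LowStem_MiddleEMT"): "high_p05",
            ("Low", "LowStem_LowEMT"): "low_p01",
            ("Low", "LowStem_HighEMT"): "high_p01",
        }

    def test_residual_margins_sum_to_zero(self):
        table = reference.reported_crosstab()
        residuals = ct.adjusted_residuals(table)
        diff = np.array([r.observed - r.expected
                         for r in residuals]).reshape(3, 4)
        assert np.allclose(diff.sum(axis=0), 0, atol=1e-9)
        assert np.allclose(diff.sum(axis=1), 0, atol=1e-9)

    def test_count_significant(self):
        residuals = ct.adjusted_residuals(reference.reported_crosstab())
        high = ct.count_significant(residuals, "high", 0.05)
        low = ct.count_significant(residuals, "low", 0.05)
        ns = sum(r.significance == "ns" for r in residuals)
        assert (high, low, ns) == (4, 3, 5)
        assert high + low + ns == 12
        assert ct.count_significant(residuals, "high", 0.01) == 3

    def test_count_significant_null_table(self):
        residuals = ct.adjusted_residuals(proportional_table())
        assert ct.count_significant(residuals, "high", 0.05) == 0
        assert ct.count_significant(residuals, "low", 0.05) == 0


class TestCategories:
    @pytest.mark.parametrize("epi,es,expected", [
        ("High", "HighStem_LowEMT", 1),
        ("Low", "LowStem_MiddleEMT", 2),
        ("Middle", "LowStem_LowEMT", 3),
        ("Low", "LowStem_HighEMT", 4),
        ("High", "LowStem_HighEMT", "other"),
        ("Middle", "HighStem_LowEMT", "other"),
    ])
    def test_category_mapping(self, epi, es, expected):
        (a,) = ct.assign_categories([CellAnnotation(
            "c", "P1", epithelial_group=epi, emt_stem_group=es)])
        assert a.category == expected


class TestPatientPositivity:
    def test_reported_rates(self):
        annotations, clinical = reference.detection_fixture()
        table = ct.patient_positivity(annotations, clinical)
        assert table.positive == {"epithelial": 8, "emt": 20,
                                  "epithelial_or_emt": 24}
        assert (table.rate_pct("epithelial"),
                table.rate_pct("emt"),
                table.rate_pct("epithelial_or_emt")) == (30, 74, 89)
        assert table.negative("epithelial") == 19

    def test_combined_at_least_max(self, cells_500):
        from ctcpheno import phenotyping, qc
        matrix, _ = cells_500
        retained = matrix.subset_cells(
            [r.cell_id for r in qc.run_qc(matrix) if r.retained])
        annotations = phenotyping.annotate_cells(retained)
        from ctcpheno.core import PatientRecord
        clinical = [PatientRecord(p, 2)
                    for p in sorted({a.patient_id for a in annotations})]
        table = ct.patient_positivity(annotations, clinical)
        assert table.positive["epithelial_or_emt"] >= max(
            table.positive["epithelial"], table.positive["emt"])

    def test_unknown_patient_rejected(self):
        annotations, clinical = reference.detection_fixture()
        with pytest.raises(JoinError):
            ct.patient_positivity(annotations, clinical[:5])


def _fisher_oracle(a, b, c, d):
    """Independent enumeration via the factorial form of the hypergeometric."""
    def table_prob(a_, b_, c_, d_):
        n = a_ + b_ + c_ + d_
        num = (math.factorial(a_ + b_) * math.factorial(c_ + d_)
               * math.factorial(a_ + c_) * math.factorial(b_ + d_))
        den = (math.factorial(n) * math.factorial(a_) * math.factorial(b_)
               * math.factorial(c_) * math.factorial(d_))
        return Fraction(num, den)

    p_obs = table_prob(a, b, c, d)
    row1, row2, col1 = a + b, c + d, a + c
    total = Fraction(0)
    for k in range(max(0, col1 - row2), min(col1, row1) + 1):
        p_k = table_prob(k, row1 - k, col1 - k, row2 - col1 + k)
        if p_k <= p_obs:
            total += p_k
    return float(total)


class TestFisherExact:
    def test_reported_comparison(self):
        p = ct.fisher_exact_2x2([[8, 19], [20, 7]])
        assert p == pytest.approx(0.0024, abs=5e-5)
        assert p == pytest.approx(_fisher_oracle(8, 19, 20, 7), abs=1e-15)

    def test_symmetric_table(self):
        assert ct.fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.tuples(st.integers(0, 15), st.integers(0, 15),
                     st.integers(0, 15), st.integers(0, 15)).filter(
                         lambda t: sum(t) > 0))
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        assert ct.fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
            _fisher_oracle(a, b, c, d), abs=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateTableError):
            ct.fisher_exact_2x2([[0, 0], [0, 0]])

    def test_mcnemar_variant(self):
        assert ct.mcnemar_2x2(0, 0) == 1.0
        assert ct.mcnemar_2x2(10, 0) < 0.01


class TestHeterogeneity:
    @staticmethod
    def _annotations(category_sets):
        annotations = []
        for pid, cats in category_sets.items():
            for i, cat in enumerate(cats):
                annotations.append(CellAnnotation(
                    f"{pid}_{i}", pid, epithelial_group="Low",
                    emt_stem_group="LowStem_HighEMT"))
                annotations[-1].category = cat
        return annotations

    def test_example_combination(self):
        annotations = self._annotations(
            {"P1": [2, 4], "P2": [3], "P3": [2, 4]})
        summary = ct.heterogeneity_summary(annotations)
        assert summary["n_multi_category"] == 2
        assert summary["combo_fractions"] == {(2, 4): 1.0}

    def test_single_category_patients(self):
        annotations = self._annotations({"P1": [1], "P2": [2], "P3": ["other"]})
        summary = ct.heterogeneity_summary(annotations)
        assert summary["n_multi_category"] == 0
        assert summary["combo_fractions"] == {}

    def test_other_counts_as_category(self):
        annotations = self._annotations({"P1": [4, "other"]})
        summary = ct.heterogeneity_summary(annotations)
        assert summary["n_multi_category"] == 1

    def test_matches_set_cardinality_oracle(self):
        rng = np.random.default_rng(3)
        category_sets = {
            f"P{i}": list(rng.choice([1, 2, 3, 4, "other"],
                                     size=rng.integers(1, 6)))
            for i in range(30)
        }
        summary = ct.heterogeneity_summary(self._annotations(category_sets))
        expected = sum(len(set(v)) >= 2 for v in category_sets.values())
        assert summary["n_multi_category"] == expected
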