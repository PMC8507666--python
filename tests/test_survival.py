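import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ctcpheno import synthetic
from ctcpheno.core import PatientRecord
from ctcpheno.errors import CardinalityError
from ctcpheno.survival import (DEFAULT_RULES, StratificationRule,
                               SurvivalSample, gehan_wilcoxon_test,
                               km_estimate, stratify, survival_report)


def S(pid, t, event):
    return SurvivalSample(pid, t, event)


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        est = km_estimate([S(f"p{i}", 10.0 * (i + 1), False)
                           for i in range(5)])
        assert est.median is None
        assert all(v == 1.0 for v in est.survival)

    def test_hand_product_limit(self):
        est = km_estimate([S(f"p{i}", t, True)
                           for i, t in enumerate((10, 20, 30, 40))])
        assert est.survival_at(10) == pytest.approx(0.75)
        assert est.survival_at(20) == pytest.approx(0.50)
        assert est.median == pytest.approx(20.0)

    def test_single_event_drops_to_zero(self):
        est = km_estimate([S("p", 42.0, True)])
        assert est.survival_at(42.0) == 0.0
        assert est.median == pytest.approx(42.0)

    def test_curve_monotone_right_continuous(self):
        rng = np.random.default_rng(0)
        samples = [S(f"p{i}", t, bool(e))
                   for i, (t, e) in enumerate(zip(
                       rng.exponential(50, 40), rng.random(40) < 0.7))]
        est = km_estimate(samples)
        assert est.survival_at(0) == 1.0
        assert (np.diff(est.survival) <= 1e-12).all()

    def test_empty_rejected(self):
        with pytest.raises(CardinalityError):
            km_estimate([])


def _gehan_permutation_oracle(a, b):
    """Exhaustive permutation p, recomputing W per split from raw pairs."""
    pooled = a + b
    n_a = len(a)
    times = [s.time_days for s in pooled]
    events = [s.event for s in pooled]

    def w_of(indices_a):
        in_a = set(indices_a)
        w = 0
        for i in in_a:
            for j in range(len(pooled)):
                if j == i:
                    continue
                # +1 when i definitely earlier than j, -1 when later
                if events[i] and (times[i] < times[j]
                                  or (times[i] == times[j] and not events[j])):
                    w += 1
                if events[j] and (times[j] < times[i]
                                  or (times[j] == times[i] and not events[i])):
                    w -= 1
        return w

    observed = abs(w_of(range(n_a)))
    total = extreme = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        extreme += abs(w_of(idx)) >= observed
    return extreme / total


class TestGehanWilcoxon:
    def test_identical_strata_null(self):
        a = [S("a1", 5, True), S("a2", 9, False)]
        b = [S("b1", 5, True), S("b2", 9, False)]
        res = gehan_wilcoxon_test(a, b)
        assert res["statistic"] == 0.0
        assert res["p"] == pytest.approx(1.0)

    def test_small_sample_equals_six_split_enumeration(self):
        a = [S("a1", 1, True), S("a2", 2, True)]
        b = [S("b1", 10, True), S("b2", 11, True)]
        res = gehan_wilcoxon_test(a, b)
        assert res["method"] == "exact"
        assert res["p"] == pytest.approx(2 / 6)
        assert res["p"] == pytest.approx(_gehan_permutation_oracle(a, b))

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_permutation_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n_a = int(rng.integers(2, 6))
        n_b = int(rng.integers(2, 11 - n_a))
        a = [S(f"a{i}", float(t), bool(e)) for i, (t, e) in enumerate(zip(
            rng.exponential(50, n_a), rng.random(n_a) < 0.7))]
        b = [S(f"b{i}", float(t), bool(e)) for i, (t, e) in enumerate(zip(
            rng.exponential(30, n_b), rng.random(n_b) < 0.7))]
        res = gehan_wilcoxon_test(a, b)
        assert abs(res["p"] - _gehan_permutation_oracle(a, b)) <= 0.02

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a = [S(f"a{i}", float(t), True)
             for i, t in enumerate(rng.exponential(50, 6))]
        b = [S(f"b{i}", float(t), True)
             for i, t in enumerate(rng.exponential(20, 5))]
        fwd = gehan_wilcoxon_test(a, b)
        rev = gehan_wilcoxon_test(b, a)
        assert fwd["statistic"] == -rev["statistic"]
        assert fwd["p"] == pytest.approx(rev["p"])

    def test_reduces_to_wilcoxon_without_censoring(self):
        """With all events and distinct times, |W| = 2 |rank-sum - mean|."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            n_a = int(rng.integers(2, 5))
            n_b = int(rng.integers(2, 5))
            a = [S(f"a{i}", float(t), True)
                 for i, t in enumerate(rng.uniform(0, 100, n_a))]
            b = [S(f"b{i}", float(t), True)
                 for i, t in enumerate(rng.uniform(0, 100, n_b))]
            res = gehan_wilcoxon_test(a, b)
            pooled = sorted(s.time_days for s in a + b)
            ranks = {t: r + 1 for r, t in enumerate(pooled)}
            rank_sum = sum(ranks[s.time_days] for s in a)
            centered = rank_sum - n_a * (n_a + n_b + 1) / 2
            assert abs(res["statistic"]) == pytest.approx(2 * abs(centered))

    def test_empty_stratum_rejected(self):
        with pytest.raises(CardinalityError):
            gehan_wilcoxon_test([], [S("b", 1, True)])

    def test_zero_variance_null(self):
        a = [S("a1", 5, False)]
        b = [S("b1", 5, False)]
        res = gehan_wilcoxon_test(a, b, method="asymptotic")
        assert res["p"] == 1.0


class TestStratify:
    @staticmethod
    def _counts(rows):
        return pd.DataFrame(rows, columns=["patient_id", "epithelial", "emt",
                                           "epithelial_or_emt"])

    def test_exclusive_emt_rule(self):
        patients = [PatientRecord(p, 2) for p in ("P1", "P2", "P3")]
        counts = self._counts([("P1", 0, 3, 3), ("P2", 0, 1, 1),
                               ("P3", 2, 0, 2)])
        pos, neg = stratify(patients, counts,
                            StratificationRule("emt", 2, exclusive=True))
        assert [p.patient_id for p in pos] == ["P1"]
        assert [p.patient_id for p in neg] == ["P2", "P3"]

    def test_all_ctc_free_cohort(self):
        patients = [PatientRecord(f"P{i}", 2) for i in range(4)]
        counts = self._counts([])
        pos, neg = stratify(patients, counts, StratificationRule("emt", 1))
        assert pos == [] and len(neg) == 4

    def test_line_filter_restricts_cohort(self):
        patients = [PatientRecord("P1", 1), PatientRecord("P2", 2)]
        counts = self._counts([("P1", 0, 5, 5), ("P2", 0, 5, 5)])
        pos, neg = stratify(patients, counts, StratificationRule("emt", 1),
                            line_filter=2)
        assert [p.patient_id for p in pos] == ["P2"] and neg == []

    def test_matches_generator_truth(self):
        _, records, truth = synthetic.generate_cohort(
            synthetic.CohortSpec(n_patients=60, seed=4),
            with_expression=False)
        counts = truth.rename(columns={
            "emt_ctc_count": "emt",
            "epithelial_ctc_count": "epithelial"})
        counts["epithelial_or_emt"] = counts["emt"] + counts["epithelial"]
        pos, _ = stratify(records, counts, StratificationRule("emt", 2),
                          line_filter=1)
        assert {p.patient_id for p in pos} == set(
            truth.loc[truth.emt_high_burden, "patient_id"])


class TestSurvivalReport:
    def test_high_emt_burden_shortens_survival(self):
        _, records, truth = synthetic.generate_cohort(
            synthetic.CohortSpec(n_patients=200, hazard_ratio_emt=3.0,
                                 seed=7),
            with_expression=False)
        counts = pd.DataFrame({
            "patient_id": truth.patient_id,
            "epithelial": truth.epithelial_ctc_count,
            "emt": truth.emt_ctc_count,
            "epithelial_or_emt": (truth.epithelial_ctc_count
                                  + truth.emt_ctc_count),
        })
        report = survival_report(records, counts, line_filter=1)
        emt2 = report[(report["rule"] == "emt") & (report["threshold"] == 2)
                      & (report["endpoint"] == "pfs")]
        pos = emt2[emt2.stratum == "positive"].iloc[0]
        neg = emt2[emt2.stratum == "negative"].iloc[0]
        assert pos["median"] < neg["median"]
        assert pos["p_value"] < 0.05

    def test_single_patient_p_not_computable(self):
        records = [PatientRecord("P1", 2, pfs_days=40, pfs_event=True,
                                 os_days=100, os_event=True)]
        counts = pd.DataFrame({"patient_id": ["P1"], "epithelial": [0],
                               "emt": [3], "epithelial_or_emt": [3]})
        report = survival_report(records, counts,
                                 rules=[StratificationRule("emt", 2)])
        assert report["p_value"].isna().all()
        pos_rows = report[report.stratum == "positive"]
        assert (pos_rows["median"].notna()).all()

    def test_identical_strata_p_one(self):
        records = [PatientRecord(f"P{i}", 2, pfs_days=t, pfs_event=True,
                                 os_days=t + 5, os_event=True)
                   for i, t in enumerate((30, 30, 60, 60))]
        counts = pd.DataFrame({
            "patient_id": [r.patient_id for r in records],
            "epithelial": [0, 0, 0, 0],
            "emt": [2, 0, 2, 0],
            "epithelial_or_emt": [2, 0, 2, 0],
        })
        report = survival_report(records, counts,
                                 rules=[StratificationRule("emt", 2)])
        assert report["p_value"].tolist() == pytest.approx([1.0] * 4)

    def test_default_rules_cover_published_layout(self):
        assert [(r.ctc_type, r.min_count) for r in DEFAULT_RULES] == [
            ("emt", 1), ("emt", 2), ("epithelial", 1), ("epithelial", 2),
            ("epithelial_or_emt", 1), ("epithelial_or_emt", 2)]
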