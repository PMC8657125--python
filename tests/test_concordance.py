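import numpy as np
import pandas as pd
import pytest

import rorprep as rp
from rorprep.concordance import (
    per_gene_cross_correlation,
    risk_group_discordance,
    score_agreement,
    subtype_confusion,
)
from rorprep.ror import RiskThresholds, RORResult, categorize_risk


def _ror_result(scores, nodes="pN0", thresholds=None):
    samples = list(scores.keys())
    vals = np.array([scores[s] for s in samples], dtype=float)
    node = np.repeat(nodes, len(samples)).astype(object)
    thresholds = thresholds or RiskThresholds()
    return RORResult(samples, np.zeros(len(samples)), vals,
                     np.zeros(len(samples), dtype=int), node,
                     categorize_risk(vals, node, thresholds), thresholds=thresholds)


def _clinical(samples, nodes="pN0"):
    return rp.ClinicalTable(pd.DataFrame({
        "sample_id": samples, "nodes": [nodes] * len(samples),
        "size_gt_2cm": [False] * len(samples)}))


class TestScoreAgreement:
    def test_identical_sets_agree_perfectly(self):
        s = pd.Series([10.0, 50.0, 90.0], index=list("abc"))
        ag = score_agreement(s, s)
        assert ag.r_squared == pytest.approx(1.0)
        assert ag.mean_abs_diff == 0.0

    def test_symmetry_under_argument_swap(self, rng):
        a = pd.Series(rng.uniform(0, 100, 20), index=[f"s{i}" for i in range(20)])
        b = a + rng.normal(0, 10, 20)
        ab, ba = score_agreement(a, b), score_agreement(b, a)
        assert ab.r_squared == pytest.approx(ba.r_squared)
        assert ab.signed_diff_max == pytest.approx(-ba.signed_diff_min)
        assert ab.mean_abs_diff == pytest.approx(ba.mean_abs_diff)

    def test_runs_on_sample_intersection(self, rng):
        a = pd.Series(rng.uniform(0, 100, 10), index=[f"s{i}" for i in range(10)])
        b = pd.Series(rng.uniform(0, 100, 10), index=[f"s{i}" for i in range(5, 15)])
        with pytest.warns(UserWarning, match="shared samples"):
            ag = score_agreement(a, b)
        assert ag.n == 5

    def test_degenerate_inputs_rejected(self):
        small = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="3 shared"):
            score_agreement(small, small)
        flat = pd.Series([5.0, 5.0, 5.0], index=list("abc"))
        varying = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ValueError, match="zero variance"):
            score_agreement(flat, varying)


class TestSubtypeConfusion:
    def test_identical_calls_are_diagonal(self):
        calls = pd.Series(["LumA", "Basal", "Her2"], index=list("abc"))
        cm = subtype_confusion(calls, calls)
        assert cm.concordance == 1.0
        assert np.trace(cm.counts.to_numpy()) == 3

    def test_hand_counted_example(self):
        a = pd.Series(["LumA", "LumA", "Basal"], index=list("abc"))
        b = pd.Series(["LumA", "LumB", "Basal"], index=list("abc"))
        cm = subtype_confusion(a, b)
        assert cm.counts.at["Basal", "Basal"] == 1
        assert cm.counts.at["LumA", "LumA"] == 1
        assert cm.counts.at["LumA", "LumB"] == 1
        assert cm.total == 3

    def test_trace_complements_discordant_fraction(self, rng):
        subs = np.array(rp.SUBTYPES, dtype=object)
        idx = [f"s{i}" for i in range(60)]
        a = pd.Series(rng.choice(subs, 60), index=idx)
        b = pd.Series(rng.choice(subs, 60), index=idx)
        cm = subtype_confusion(a, b)
        discordant = float(np.mean(a.to_numpy() != b.to_numpy()))
        assert cm.concordance == pytest.approx(1.0 - discordant)

    def test_disjoint_samples_rejected(self):
        a = pd.Series(["LumA"], index=["x"])
        b = pd.Series(["LumA"], index=["y"])
        with pytest.raises(ValueError, match="no shared"):
            with pytest.warns(UserWarning):
                subtype_confusion(a, b)


class TestRiskGroupDiscordance:
    def test_identical_sets_yield_no_records(self):
        r = _ror_result({"a": 30.0, "b": 70.0, "c": 50.0})
        assert risk_group_discordance(r, r, _clinical(list("abc"))) == []

    def test_hand_worked_two_sample_case(self):
        a = _ror_result({"a": 39.0, "b": 50.0})
        b = _ror_result({"a": 45.0, "b": 50.0})
        records = risk_group_discordance(a, b, _clinical(list("ab")))
        assert len(records) == 1
        rec = records[0]
        assert (rec.sample_id, rec.category_A, rec.category_B) == ("a", "low", "intermediate")
        assert rec.signed_diff == pytest.approx(-6.0)

    def test_sorted_by_signed_difference_descending(self):
        a = _ror_result({"a": 39.0, "b": 70.0, "c": 41.0})
        b = _ror_result({"a": 45.0, "b": 50.0, "c": 39.0})
        diffs = [r.signed_diff for r in
                 risk_group_discordance(a, b, _clinical(list("abc")))]
        assert diffs == sorted(diffs, reverse=True)

    def test_threshold_table_mismatch_rejected(self):
        a = _ror_result({"a": 30.0, "b": 70.0, "c": 50.0})
        b = _ror_result({"a": 30.0, "b": 70.0, "c": 50.0},
                        thresholds=RiskThresholds(pN0=(30.0, 70.0)))
        with pytest.raises(ValueError, match="threshold"):
            risk_group_discordance(a, b, _clinical(list("abc")))

    def test_eligibility_subset_filters_samples(self):
        clin = rp.ClinicalTable(pd.DataFrame({
            "sample_id": list("abcd"),
            "nodes": ["pN0", "pN0", "pN1_3", "pN0"],
            "size_gt_2cm": [False] * 4,
            "er_status": ["ER_pos", "ER_neg", "ER_pos", "ER_pos"],
            "her2_status": ["neg", "neg", "neg", "pos"],
        }))
        a = _ror_result({s: 39.0 for s in "abcd"})
        b = _ror_result({s: 45.0 for s in "abcd"})
        records = risk_group_discordance(a, b, clin, subset="er_pos_her2_neg_pn0")
        assert [r.sample_id for r in records] == ["a"]


class TestPerGeneCrossCorrelation:
    def test_affine_transform_gives_unit_correlation(self, cohort):
        _, macro, _, _ = cohort
        twin = rp.ExpressionMatrix(macro.genes, macro.samples,
                                   2.0 * macro.values + 1.0)
        df = per_gene_cross_correlation(macro, twin)
        np.testing.assert_allclose(df["r"], 1.0, atol=1e-12)
        assert not df["flagged"].any()
        assert df["is_proliferation"].sum() == 18

    def test_independent_gene_has_near_zero_correlation(self, cohort, rng):
        _, macro, _, _ = cohort
        noise = rp.ExpressionMatrix(macro.genes, macro.samples,
                                    rng.normal(size=macro.values.shape))
        df = per_gene_cross_correlation(macro, noise)
        assert (df["r"].abs() < 0.3).mean() > 0.95

    def test_zero_variance_gene_flagged_not_raised(self, cohort):
        _, macro, _, _ = cohort
        vals = macro.values.copy()
        vals[0, :] = 1.0
        flat = rp.ExpressionMatrix(macro.genes, macro.samples, vals)
        df = per_gene_cross_correlation(flat, macro).set_index("gene")
        first = macro.genes[0]
        assert np.isnan(df.at[first, "r"])
        assert df.at[first, "flagged"]
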