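import numpy as np
import pandas as pd
import pytest

import rorprep as rp
from rorprep.ror import categorize_risk, proliferation_score, ror_score


def _prolif_matrix(values_by_sample):
    """Matrix holding given per-sample values on all 18 proliferation genes."""
    genes = list(rp.PROLIFERATION_GENES) + ["ESR1", "PGR"]
    n = len(values_by_sample[0]) if isinstance(values_by_sample[0], (list, np.ndarray)) else 1
    cols = np.asarray(values_by_sample, dtype=float)
    if cols.ndim == 1:
        cols = cols[:, None]
    extra = np.zeros((2, cols.shape[1]))
    return rp.ExpressionMatrix(genes, [f"s{i}" for i in range(cols.shape[1])],
                               np.vstack([cols, extra]))


def _subtype_result(corrs):
    return rp.SubtypeResult([f"s{i}" for i in range(len(corrs))],
                            np.asarray(corrs, dtype=float))


def _ror(corrs, prolif, T):
    res = _subtype_result(corrs)
    p = pd.Series(prolif, index=res.samples)
    return ror_score(res, p, T={s: t for s, t in zip(res.samples, T)},
                     categorize=False).ror_continuous


class TestProliferationScore:
    def test_constant_values_give_that_constant(self):
        em = _prolif_matrix(np.full(18, 0.5))
        assert proliferation_score(em).iloc[0] == pytest.approx(0.5)

    def test_hand_arithmetic_mean(self):
        em = _prolif_matrix(np.arange(1.0, 19.0))
        assert proliferation_score(em).iloc[0] == pytest.approx(9.5)

    def test_gene_order_symmetry(self, rng):
        vals = rng.normal(size=18)
        em = _prolif_matrix(vals)
        perm = rng.permutation(18)
        genes = [rp.PROLIFERATION_GENES[i] for i in perm] + ["ESR1", "PGR"]
        em2 = rp.ExpressionMatrix(genes, ["s0"],
                                  np.concatenate([vals[perm], [0, 0]])[:, None])
        assert proliferation_score(em2).iloc[0] == pytest.approx(
            proliferation_score(em).iloc[0])

    def test_missing_gene_is_hard_error(self):
        genes = list(rp.PROLIFERATION_GENES[:-1]) + ["ESR1", "PGR"]
        em = rp.ExpressionMatrix(genes, ["s0"], np.zeros((19, 1)))
        with pytest.raises(ValueError, match=rp.PROLIFERATION_GENES[-1]):
            proliferation_score(em)


class TestRORFormula:
    def test_all_zero_inputs_give_scaled_intercept(self):
        ror = _ror([[0, 0, 0, 0, 0]], [0.0], [0])
        assert ror[0] == pytest.approx(54.7690 * 0.8826, abs=1e-4)

    def test_size_indicator_adds_fixed_increment(self, rng):
        corr = rng.uniform(-1, 1, size=(1, 5))
        p = rng.normal(size=1)
        delta = _ror(corr, p, [1])[0] - _ror(corr, p, [0])[0]
        assert delta == pytest.approx(54.7690 * 0.1133, abs=1e-4)

    def test_pure_luma_correlation_hand_value(self):
        ror = _ror([[0, 0, 1.0, 0, 0]], [0.0], [0])
        assert ror[0] == pytest.approx(54.7690 * (-0.3172 + 0.8826), abs=1e-4)

    def test_normal_like_correlation_never_enters(self, rng):
        corr = rng.uniform(-1, 1, size=(1, 5))
        altered = corr.copy()
        altered[0, rp.SUBTYPES.index("Normal")] = -corr[0, rp.SUBTYPES.index("Normal")]
        assert _ror(corr, [0.3], [1])[0] == _ror(altered, [0.3], [1])[0]

    @pytest.mark.parametrize("component,direction", [
        ("Her2", +1), ("LumB", +1), ("LumA", -1), ("Basal", -1)])
    def test_monotone_in_each_correlation(self, component, direction, rng):
        idx = rp.SUBTYPES.index(component)
        for _ in range(20):
            corr = rng.uniform(-0.9, 0.9, size=(1, 5))
            bumped = corr.copy()
            bumped[0, idx] += 0.05
            diff = _ror(bumped, [0.1], [0])[0] - _ror(corr, [0.1], [0])[0]
            assert np.sign(diff) == direction

    def test_monotone_increasing_in_proliferation(self, rng):
        corr = rng.uniform(-1, 1, size=(1, 5))
        assert _ror(corr, [0.5], [0])[0] > _ror(corr, [0.2], [0])[0]

    def test_clipped_flag_marks_out_of_range_scores(self):
        res = ror_score(_subtype_result([[0, 1, -1, 1, 0]]),
                        pd.Series([5.0], index=["s0"]), T={"s0": 1}, categorize=False)
        assert res.ror_continuous[0] > 100
        assert res.clipped[0]


class TestRiskCategorization:
    @pytest.mark.parametrize("score,node,expected", [
        (39.94, "pN0", "low"),          # published categorized score
        (60.06, "pN0", "high"),         # published categorized score
        (54.86, "pN0", "intermediate"), # published categorized score
        (40.0, "pN0", "low"),           # boundary: low includes the cutoff
        (60.0, "pN0", "intermediate"),
        (15.0, "pN1_3", "low"),
        (40.0, "pN1_3", "intermediate"),
        (40.01, "pN1_3", "high"),
        (0.0, "pN4plus", "high"),       # automatic high at any score
        (99.0, "pN4plus", "high"),
    ])
    def test_boundary_convention(self, score, node, expected):
        assert categorize_risk(score, node) == expected

    def test_monotone_within_node_class(self, rng):
        order = {"low": 0, "intermediate": 1, "high": 2}
        for node in ("pN0", "pN1_3", "pN4plus"):
            scores = np.sort(rng.uniform(0, 100, size=50))
            cats = [order[c] for c in categorize_risk(scores, node)]
            assert cats == sorted(cats)

    def test_unknown_node_class_rejected(self):
        with pytest.raises(ValueError, match="node class"):
            categorize_risk(50.0, "pN9")

    def test_non_finite_score_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            categorize_risk(float("nan"), "pN0")


class TestRORScoreWiring:
    def test_clinical_table_supplies_T_and_nodes(self, cohort, centroids):
        config, macro, _, truth = cohort
        clin = truth.clinical()
        scores = rp.score_cohort(macro, clin, centroids, seed=config.seed)
        res = scores.ror
        np.testing.assert_array_equal(
            res.T, truth.table["T"].to_numpy())
        np.testing.assert_array_equal(
            res.category, categorize_risk(res.ror_continuous, res.node_class))

    def test_missing_T_errors(self):
        res = _subtype_result([[0, 0, 0, 0, 0]])
        with pytest.raises(ValueError, match="T required"):
            ror_score(res, pd.Series([0.0], index=res.samples), categorize=False)
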