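import numpy as np
import pandas as pd
import pytest

from morphshift.config import ClassificationParams
from morphshift.de import (
    Comparison,
    annotate_chromosome,
    bh_adjust,
    classify_morph_bias,
    classify_tissue_bias,
    estimate_common_dispersion,
    nb_exact_test,
)


def _two_group_frames(a_counts, b_counts, size=1e5):
    ca = pd.DataFrame(np.atleast_2d(a_counts), columns=[f"a{i}" for i in
                                                        range(len(a_counts[0]))])
    cb = pd.DataFrame(np.atleast_2d(b_counts), columns=[f"b{i}" for i in
                                                        range(len(b_counts[0]))])
    sa = pd.Series(size, index=ca.columns)
    sb = pd.Series(size, index=cb.columns)
    return ca, cb, sa, sb


class TestCommonDispersion:
    def test_poisson_data_estimates_near_zero(self, rng):
        mu = np.exp(rng.normal(4, 1.2, 5000))
        y = rng.poisson(mu[:, None], size=(5000, 4))
        df = pd.DataFrame(y, columns=list("abcd"))
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        assert estimate_common_dispersion(df, groups) < 0.01

    def test_recovers_true_dispersion_within_20pct(self, rng):
        phi, r = 0.1, 10.0
        mu = np.exp(rng.normal(4, 1.2, 5000))
        y = rng.negative_binomial(r, r / (r + mu[:, None]), size=(5000, 4))
        df = pd.DataFrame(y, columns=list("abcd"))
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        est = estimate_common_dispersion(df, groups)
        assert est == pytest.approx(phi, rel=0.2)

    def test_identical_counts_hit_zero_boundary(self):
        df = pd.DataFrame([[7, 7, 7, 7]], columns=list("abcd"))
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        assert estimate_common_dispersion(df, groups) == 0.0

    def test_all_zero_matrix_rejected(self):
        df = pd.DataFrame(np.zeros((3, 4)), columns=list("abcd"))
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        with pytest.raises(ValueError):
            estimate_common_dispersion(df, groups)


class TestExactTest:
    def test_symmetric_groups_give_p_one_and_zero_lfc(self):
        ca, cb, sa, sb = _two_group_frames([[5, 5]], [[5, 5]])
        res = nb_exact_test(ca, cb, sa, sb, 0.1)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)
        assert res["log2_fold_change"].iloc[0] == pytest.approx(0.0)

    def test_label_swap_flips_lfc_and_keeps_p(self):
        ca, cb, sa, sb = _two_group_frames([[12, 9]], [[3, 1]])
        fwd = nb_exact_test(ca, cb, sa, sb, 0.2)
        rev = nb_exact_test(cb, ca, sb, sa, 0.2)
        assert fwd["p_value"].iloc[0] == pytest.approx(rev["p_value"].iloc[0])
        assert fwd["log2_fold_change"].iloc[0] == pytest.approx(
            -rev["log2_fold_change"].iloc[0]
        )

    def test_poisson_limit_matches_binomial_closed_form(self):
        """{10,10} vs {0,0} at phi=0: conditional binomial of 20/20 at 1/2."""
        ca, cb, sa, sb = _two_group_frames([[10, 10]], [[0, 0]])
        res = nb_exact_test(ca, cb, sa, sb, 0.0)
        assert res["p_value"].iloc[0] == pytest.approx(2 * 0.5**20)

    def test_non_integer_counts_rejected(self):
        ca, cb, sa, sb = _two_group_frames([[1.5, 2.0]], [[1.0, 1.0]])
        with pytest.raises(ValueError, match="round"):
            nb_exact_test(ca, cb, sa, sb, 0.1)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_step_up_hand_cases(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert np.allclose(bh_adjust([0.05, 1.0]), [0.10, 1.0])

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=50)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _comparison(a, b, genes, lfc, adj_p):
    table = pd.DataFrame(
        {"log2_fold_change": lfc, "p_value": adj_p, "adj_p": adj_p}, index=genes
    )
    return Comparison(a, b, table)


class TestMorphClassification:
    GENES = ["strong", "limited", "one_sided", "flat", "tie"]

    def _comparisons(self):
        # lfc oriented B over A; male is group_b in both male comparisons here
        m_vs_p = _comparison(
            "parthenogenetic_female", "male", self.GENES,
            [1.5, 2.5, 1.8, 0.1, 1.0], [0.01, 0.001, 0.01, 0.9, 0.01],
        )
        f_vs_p = _comparison(
            "parthenogenetic_female", "sexual_female", self.GENES,
            [0.0, 0.1, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0, 1.0],
        )
        f_vs_m = _comparison(
            "sexual_female", "male", self.GENES,
            [1.5, 2.1, 0.2, -0.1, 1.0], [0.01, 0.001, 0.8, 0.9, 0.01],
        )
        return [m_vs_p, f_vs_p, f_vs_m]

    def test_dual_comparison_rule(self):
        out = classify_morph_bias(self._comparisons())
        assert out.loc["strong", "morph_bias"] == "male"
        assert out.loc["strong", "degree"] == "+"
        assert out.loc["limited", "morph_bias"] == "male"
        assert out.loc["limited", "degree"] == "++"
        # significant in only one of the two male comparisons -> unbiased
        assert out.loc["one_sided", "morph_bias"] == "unbiased"
        assert out.loc["flat", "morph_bias"] == "unbiased"
        # |lfc| exactly at the threshold -> not biased (strict inequality)
        assert out.loc["tie", "morph_bias"] == "unbiased"

    def test_degree_none_iff_unbiased(self):
        out = classify_morph_bias(self._comparisons())
        assert ((out["degree"] == "none") == (out["morph_bias"] == "unbiased")).all()

    def test_missing_comparison_rejected(self):
        with pytest.raises(ValueError):
            classify_morph_bias(self._comparisons()[:2])


class TestTissueClassification:
    def test_gonad_bias_requires_both_comparisons(self):
        genes = ["gonad", "partial", "flat"]
        h_vs_l = _comparison("head", "legs", genes, [0.0, 0.0, 0.0], [1, 1, 1])
        h_vs_g = _comparison(
            "head", "gonads", genes, [2.0, 2.0, 0.0], [0.01, 0.01, 1.0]
        )
        l_vs_g = _comparison(
            "legs", "gonads", genes, [2.0, 0.0, 0.0], [0.01, 1.0, 1.0]
        )
        out = classify_tissue_bias({"male": [h_vs_l, h_vs_g, l_vs_g]})
        assert out.loc["gonad", "male"] == "gonads"
        assert out.loc["partial", "male"] == "none"
        assert out.loc["flat", "male"] == "none"

    def test_missing_tissue_rejected(self):
        genes = ["g"]
        c = _comparison("head", "legs", genes, [0.0], [1.0])
        with pytest.raises(ValueError):
            classify_tissue_bias({"male": [c, c, c]})


def test_annotate_chromosome_labels_and_warning():
    ann = pd.Series({"g1": "X", "g2": "A1"})
    with pytest.warns(UserWarning, match="unplaced"):
        out = annotate_chromosome(pd.Index(["g1", "g2", "g3"]), ann)
    assert list(out) == ["X", "autosome", "unplaced"]
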