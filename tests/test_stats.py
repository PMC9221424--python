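"""Hand-authored rank statistics against oracles and scipy cross-checks."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from liqbio.stats import (
    _u_null_pmf,
    benjamini_hochberg,
    compare_cohorts,
    correlate_clinical,
    encode_ordinal,
    rank_sum_test,
    spearman_rho,
)
from .oracles import rank_sum_exact_p, spearman_perm_p


class TestNullPmf:
    @pytest.mark.parametrize("m,n", [(1, 1), (2, 3), (4, 4), (5, 3)])
    def test_pmf_sums_to_one_and_is_symmetric(self, m, n):
        pmf = _u_null_pmf(m, n)
        assert pmf.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(pmf, pmf[::-1])

    def test_smallest_case_by_hand(self):
        # m = n = 1: U is 0 or 1 with probability 1/2 each
        np.testing.assert_allclose(_u_null_pmf(1, 1), [0.5, 0.5])

    def test_m2_n2_by_hand(self):
        # 6 assignments; U in {0,1,2,3,4} with counts 1,1,2,1,1
        np.testing.assert_allclose(_u_null_pmf(2, 2),
                                   np.array([1, 1, 2, 1, 1]) / 6)


class TestRankSumExact:
    def test_matches_enumeration_oracle_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            m = int(rng.integers(2, 6))
            n = int(rng.integers(2, 6))
            a = rng.normal(size=m)
            b = rng.normal(size=n)
            res = rank_sum_test(a, b)
            assert res.method == "exact"
            assert res.p == pytest.approx(rank_sum_exact_p(list(a), list(b)),
                                          abs=1e-12)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.normal(size=6)
            b = rng.normal(size=8)
            res = rank_sum_test(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="exact")
            assert res.u == pytest.approx(ref.statistic)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_extreme_separation_gives_minimal_p(self):
        res = rank_sum_test([10, 11, 12], [1, 2, 3])
        # most extreme of C(6,3) = 20 equally likely splits, two-sided
        assert res.p == pytest.approx(2 / 20)
        assert res.z > 0

    def test_sign_convention(self):
        hi_first = rank_sum_test([5, 6, 7, 8], [1, 2, 3, 4])
        lo_first = rank_sum_test([1, 2, 3, 4], [5, 6, 7, 8])
        assert hi_first.z > 0 > lo_first.z
        assert hi_first.p == pytest.approx(lo_first.p)


class TestRankSumApprox:
    def test_ties_fall_back_to_corrected_normal(self):
        a = [1.0, 2.0, 2.0, 3.0]
        b = [2.0, 4.0, 5.0, 6.0]
        res = rank_sum_test(a, b)
        assert res.method == "normal_approx"
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_samples_match_scipy_asymptotic(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.8, 1, 20)
        b = rng.normal(0, 1, 50)
        res = rank_sum_test(a, b)
        assert res.method == "normal_approx"
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_identical_values_give_p_one(self):
        res = rank_sum_test([1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.p == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestSpearman:
    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(11)
        for n in (3, 4, 5, 6):
            for _ in range(6):
                x = rng.normal(size=n)
                y = rng.normal(size=n)
                res = spearman_rho(x, y, exact_n_max=6)
                rho_o, p_o = spearman_perm_p(list(x), list(y))
                assert res.method == "permutation"
                assert res.rho == pytest.approx(rho_o, abs=1e-12)
                assert res.p == pytest.approx(p_o, abs=1e-12)

    def test_oracle_agreement_with_ties(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0]
        y = [3.0, 1.0, 4.0, 4.0, 2.0]
        res = spearman_rho(x, y, exact_n_max=6)
        rho_o, p_o = spearman_perm_p(x, y)
        assert res.rho == pytest.approx(rho_o, abs=1e-12)
        assert res.p == pytest.approx(p_o, abs=1e-12)

    def test_t_approximation_matches_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        y = 0.6 * x + rng.normal(size=40)
        res = spearman_rho(x, y)
        ref = sps.spearmanr(x, y)
        assert res.method == "t_approx"
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_perfect_monotone(self):
        res = spearman_rho([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert res.rho == pytest.approx(1.0)
        # the observed ordering is one of n! equally likely; both perfect
        # orderings are equally extreme
        assert res.p == pytest.approx(2 / 120)

    def test_constant_input_returns_none(self):
        assert spearman_rho([1, 1, 1, 1], [1, 2, 3, 4]) is None

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [3, 4])


class TestBenjaminiHochberg:
    def test_known_example(self):
        p = np.array([0.01, 0.04, 0.03, 0.005])
        adj = benjamini_hochberg(p)
        # sorted: 0.005, 0.01, 0.03, 0.04 -> 0.02, 0.02, 0.04, 0.04
        np.testing.assert_allclose(adj, [0.02, 0.04, 0.04, 0.02])

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


def _rates_frame(cohort, values):
    return pd.DataFrame({
        "sample_id": [f"{cohort}-{i}" for i in range(len(values))],
        "cohort": cohort, "volume_ml": 1.3, "total": values,
    })


class TestCohortComparison:
    def test_orders_by_p_and_flags_significance(self):
        rng = np.random.default_rng(12)
        utuc = _rates_frame("UTUC", rng.normal(170, 40, 20))
        nd = _rates_frame("ND", rng.normal(34, 15, 50))
        out = compare_cohorts(utuc, nd)
        assert list(out["category"]) == ["total"]
        assert out["significant"].iloc[0]
        assert out["utuc_median"].iloc[0] > out["nd_median"].iloc[0]

    def test_empty_cohort_rejected(self):
        utuc = _rates_frame("UTUC", [1.0, 2.0])
        with pytest.raises(ValueError):
            compare_cohorts(utuc, utuc.iloc[:0])


class TestClinicalCorrelation:
    def _tables(self, n=20, seed=4):
        rng = np.random.default_rng(seed)
        ids = [f"UTUC-{i:03d}" for i in range(n)]
        analytes = pd.DataFrame({
            "sample_id": ids, "cohort": "UTUC", "volume_ml": 1.3,
            "epi.CTC": rng.gamma(2.0, 2.0, n),
        })
        clinical = pd.DataFrame({
            "sample_id": ids,
            "age": 60 + 10 * sps.rankdata(analytes["epi.CTC"]) / n
            + rng.normal(0, 1, n),
            "smoking": rng.choice(["never", "former", "current"], n),
            "rare_flag": [1, 1] + [0] * (n - 2),
        })
        return analytes, clinical

    def test_continuous_uses_spearman(self):
        analytes, clinical = self._tables()
        out = correlate_clinical(analytes, clinical, {"age": "continuous"})
        assert (out["method"] == "spearman").all()
        assert out.loc[out["variable"] == "age", "statistic"].iloc[0] > 0.5

    def test_ordinal_encoding(self):
        enc = encode_ordinal(pd.Series(["never", "current", "former"]),
                             "smoking")
        assert list(enc) == [0.0, 2.0, 1.0]

    def test_small_binary_group_flagged_suppressed(self):
        analytes, clinical = self._tables()
        out = correlate_clinical(analytes, clinical,
                                 {"rare_flag": "binary"}, min_group=4)
        assert out["suppressed"].all()
        out2 = correlate_clinical(analytes, clinical,
                                  {"rare_flag": "binary"}, min_group=2)
        assert not out2["suppressed"].any()

    def test_unknown_type_rejected(self):
        analytes, clinical = self._tables()
        with pytest.raises(ValueError):
            correlate_clinical(analytes, clinical, {"age": "interval"})
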