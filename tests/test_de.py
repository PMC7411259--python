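"""Unit tests for normalization, dispersion, the exact test and screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncscreen import de
from lncscreen.types import CountMatrix


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        df = pd.DataFrame({"a": [5, 3, 9], "b": [5, 3, 9]})
        assert de.estimate_size_factors(df).tolist() == [1.0, 1.0]

    def test_hand_median_of_ratios_on_doubled_sample(self):
        # rows (2,4),(4,8),(6,12): geometric means are k1*sqrt(2), so the
        # ratio medians are exactly 1/sqrt(2) and sqrt(2)
        df = pd.DataFrame({"s1": [2, 4, 6], "s2": [4, 8, 12]})
        sf = de.estimate_size_factors(df)
        assert abs(sf["s1"] - 2**-0.5) < 1e-12
        assert abs(sf["s2"] - 2**0.5) < 1e-12

    def test_all_zero_matrix_errors(self):
        df = pd.DataFrame(np.zeros((3, 2), dtype=int), columns=["a", "b"])
        with pytest.raises(ValueError):
            de.estimate_size_factors(df)
        with pytest.raises(ValueError):
            de.estimate_size_factors(df, fallback=True)

    def test_no_all_positive_gene_needs_fallback(self):
        df = pd.DataFrame({"a": [4, 0], "b": [0, 9]})
        with pytest.raises(ValueError, match="fallback"):
            de.estimate_size_factors(df)
        sf = de.estimate_size_factors(df, fallback=True)
        assert (sf > 0).all()

    def test_equivariance_of_factor_ratios(self, rng):
        # scaling one sample by c multiplies s_j by c^(1-1/m) and the other
        # factors by c^(-1/m): the ratio s_j / s_l therefore scales by c
        k = rng.integers(1, 500, size=(40, 3))
        df = pd.DataFrame(k, columns=list("abc"))
        base = de.estimate_size_factors(df)
        c = 5.0
        scaled = df.copy()
        scaled["b"] = k[:, 1] * 5
        sf = de.estimate_size_factors(scaled)
        np.testing.assert_allclose(
            (sf["b"] / sf["a"]), c * base["b"] / base["a"], rtol=1e-10
        )
        np.testing.assert_allclose(sf["b"], base["b"] * c ** (2 / 3), rtol=1e-10)
        np.testing.assert_allclose(sf["a"], base["a"] * c ** (-1 / 3), rtol=1e-10)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

class TestDispersions:
    def test_poisson_matrix_yields_near_zero_dispersion(self, rng):
        mu = np.exp(rng.uniform(np.log(100), np.log(10000), 2000))
        k = rng.poisson(mu[:, None], size=(2000, 4))
        df = pd.DataFrame(k, columns=list("abcd"))
        fit = de.estimate_dispersions(df, de.estimate_size_factors(df))
        assert float(fit.alpha.median()) <= 0.05

    def test_nb_trend_intercept_recovers_alpha(self, rng):
        alpha = 0.2
        mu = np.exp(rng.uniform(np.log(100), np.log(10000), 2000))
        r = 1 / alpha
        k = rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 4))
        df = pd.DataFrame(k, columns=list("abcd"))
        fit = de.estimate_dispersions(df, de.estimate_size_factors(df))
        assert 0.1 <= fit.trend[1] <= 0.3

    def test_constant_gene_gets_trend_value(self):
        df = pd.DataFrame(
            {"a": [10, 100, 120], "b": [10, 140, 80], "c": [10, 90, 130]}
        )
        sf = pd.Series(1.0, index=df.columns)
        fit = de.estimate_dispersions(df, sf, sharing="maximum")
        assert fit.alpha_hat.iloc[0] == 0.0
        assert fit.alpha.iloc[0] == pytest.approx(fit.trend_at(np.array([10.0]))[0])

    def test_single_sample_errors(self):
        df = pd.DataFrame({"a": [1, 2, 3]})
        with pytest.raises(ValueError):
            de.estimate_dispersions(df, pd.Series({"a": 1.0}))

    def test_fit_only_ignores_inflated_gene_estimates(self, rng):
        mu = np.full(500, 1000.0)
        k = rng.poisson(mu[:, None], size=(500, 4))
        k[0] = [100, 5000, 100, 5000]  # one wildly variable gene
        df = pd.DataFrame(k, columns=list("abcd"))
        sf = pd.Series(1.0, index=df.columns)
        fit = de.estimate_dispersions(df, sf, sharing="fit_only")
        fit_max = de.estimate_dispersions(df, sf, sharing="maximum")
        assert fit.alpha.iloc[0] < 0.1
        assert fit_max.alpha.iloc[0] > 1.0


# ---------------------------------------------------------------------------
# the exact test
# ---------------------------------------------------------------------------

def enumeration_oracle(kA, kB, sA=1.0, sB=1.0, alpha=0.0):
    """Direct linear-space enumeration of the conditioned test definition."""
    q = 0.5 * (kA / sA + kB / sB)
    K = kA + kB
    if K == 0:
        return 1.0

    def pmf(k, mu):
        if alpha == 0:
            return stats.poisson.pmf(k, mu)
        r = 1 / alpha
        return stats.nbinom.pmf(k, r, r / (r + mu))

    a = np.arange(K + 1)
    terms = pmf(a, q * sA) * pmf(K - a, q * sB)
    obs = terms[kA]
    return float(terms[terms <= obs * (1 + 1e-12)].sum() / terms.sum())


class TestNBExactTest:
    def test_symmetric_split_is_modal(self):
        for alpha in (0.0, 0.1, 1.0):
            assert de.nb_exact_test(5, 5, 1, 1, alpha) == 1.0

    def test_zero_total_returns_one(self):
        assert de.nb_exact_test(0, 0) == 1.0

    @pytest.mark.parametrize(
        "kA,kB,sA,sB,alpha",
        [
            (10, 0, 1.0, 1.0, 0.0),
            (25, 3, 1.0, 0.5, 0.1),
            (7, 19, 2.0, 1.0, 1.0),
            (0, 12, 1.0, 1.0, 0.3),
        ],
    )
    def test_matches_enumeration_oracle(self, kA, kB, sA, sB, alpha):
        got = de.nb_exact_test(kA, kB, sA, sB, alpha)
        want = enumeration_oracle(kA, kB, sA, sB, alpha)
        assert got == pytest.approx(want, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            de.nb_exact_test(-1, 3)
        with pytest.raises(ValueError):
            de.nb_exact_test(1, 3, sA=0)
        with pytest.raises(ValueError):
            de.nb_exact_test(1, 3, alpha=-0.1)


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------

class TestBH:
    def test_single_p_unchanged(self):
        assert de.bh_adjust([0.03]).tolist() == [0.03]

    def test_hand_step_up(self):
        np.testing.assert_allclose(
            de.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_empty_input(self):
        assert de.bh_adjust([]).size == 0

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(de.bh_adjust(p)[perm], de.bh_adjust(p[perm]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# screening and intersection
# ---------------------------------------------------------------------------

def _table(rows):
    df = pd.DataFrame(
        rows, columns=["gene", "base_mean", "log2fc", "p", "fdr"]
    ).set_index("gene")
    return df


class TestScreen:
    def test_fc_boundary_is_strict(self):
        t = _table([("g1", 10, 1.0, 0.01, 0.01)])  # FC exactly 2
        up, down = de.screen_contrast(t)
        assert up == frozenset() and down == frozenset()

    def test_all_three_thresholds_must_hold(self):
        t = _table([("g1", 10, 2.0, 0.04, 0.06)])  # fdr fails
        up, down = de.screen_contrast(t)
        assert not up and not down

    def test_up_and_down_called(self):
        t = _table(
            [("u", 10, 2.0, 0.001, 0.001), ("d", 10, -2.0, 0.001, 0.001),
             ("n", 10, 0.1, 0.8, 0.9)]
        )
        up, down = de.screen_contrast(t)
        assert up == {"u"} and down == {"d"}
        assert t.loc["n", "direction"] == "ns"

    def test_empty_table(self):
        t = _table([])
        up, down = de.screen_contrast(t)
        assert up == frozenset() and down == frozenset()


class TestIntersect:
    def test_set_algebra(self):
        screened = [({1, 2}, set()), ({2, 3}, set()), ({2, 4}, set())]
        cs = de.intersect_contrasts(screened)
        assert cs.common_up == {2}
        assert cs.common_down == frozenset()

    def test_mixed_direction_gene(self):
        screened = [({"g"}, set()), ({"g"}, set()), (set(), {"g"})]
        cs = de.intersect_contrasts(screened)
        assert cs.mixed == {"g"}
        assert not cs.common_up and not cs.common_down

    def test_partition_of_everywhere_significant(self, rng):
        genes = [f"g{i}" for i in range(50)]
        screened = []
        for _ in range(3):
            up = set(rng.choice(genes, 15, replace=False))
            down = set(rng.choice(sorted(set(genes) - up), 10, replace=False))
            screened.append((up, down))
        cs = de.intersect_contrasts(screened)
        everywhere = set.intersection(*[set(u) | set(d) for u, d in screened])
        assert cs.common_up | cs.common_down | cs.mixed == everywhere
        assert len(cs.common_up) + len(cs.common_down) + len(cs.mixed) == len(
            everywhere
        )

    def test_venn_counts_cover_union(self):
        screened = [({1, 2}, {9}), ({2, 3}, {9}), ({2, 4}, set())]
        cs = de.intersect_contrasts(screened, names=["a", "b", "c"])
        assert sum(cs.venn_counts.values()) == len({1, 2, 3, 4, 9})

    def test_requires_two_contrasts(self):
        with pytest.raises(ValueError):
            de.intersect_contrasts([({1}, set())])


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

class TestHierarchicalCluster:
    def test_identical_rows_merge_first_at_zero(self):
        expr = pd.DataFrame(
            [[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]],
            index=["a", "b", "c"],
        )
        res = de.hierarchical_cluster(expr)
        # first merge joins rows 0 and 1 (a, b) at distance ~0
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_pair_merges_last(self):
        expr = pd.DataFrame(
            [[1, 2, 3, 4], [4, 3, 2, 1], [1, 3, 2, 4]],
            index=["x", "y", "z"],
        )
        res = de.hierarchical_cluster(expr)
        # the final merge is at the largest distance, near 2 (r = -1)
        assert res.linkage[-1, 2] > res.linkage[0, 2]

    def test_row_permutation_invariance(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(8, 5)), index=[f"g{i}" for i in range(8)]
        )
        res1 = de.hierarchical_cluster(expr)
        res2 = de.hierarchical_cluster(expr.sample(frac=1, random_state=0))
        assert res1.leaf_order == res2.leaf_order

    def test_constant_row_dropped_with_warning(self, caplog):
        expr = pd.DataFrame(
            [[1, 1, 1], [1, 2, 3], [3, 2, 1]], index=["flat", "a", "b"]
        )
        res = de.hierarchical_cluster(expr)
        assert res.dropped == ["flat"]
        assert "flat" not in res.leaf_order


# ---------------------------------------------------------------------------
# contrast wiring
# ---------------------------------------------------------------------------

class TestRunContrast:
    def test_zero_count_genes_excluded_from_testing(self):
        counts = CountMatrix(
            counts=pd.DataFrame(
                {"t0": [0, 10, 100], "t1": [0, 80, 100]},
                index=["z", "g", "h"],
            ),
            sample_meta=pd.DataFrame(
                {"timepoint": ["0h", "8h"]}, index=["t0", "t1"]
            ),
        )
        sf = pd.Series({"t0": 1.0, "t1": 1.0})
        alpha = pd.Series(0.0, index=counts.counts.index)
        res = de.run_contrast(counts, sf, alpha, "0h", "8h")
        assert np.isnan(res.table.loc["z", "p"])
        assert res.table.loc["z", "direction"] == "ns"
        assert res.table.loc["g", "p"] < 0.05

    def test_biotype_groups_adjusted_separately(self):
        counts = CountMatrix(
            counts=pd.DataFrame(
                {"t0": [10, 10, 10, 10], "t1": [100, 11, 100, 9]},
                index=["l1", "l2", "m1", "m2"],
            ),
            sample_meta=pd.DataFrame(
                {"timepoint": ["0h", "8h"]}, index=["t0", "t1"]
            ),
        )
        sf = pd.Series({"t0": 1.0, "t1": 1.0})
        alpha = pd.Series(0.0, index=counts.counts.index)
        biotypes = pd.Series(
            {"l1": "lncRNA", "l2": "lncRNA", "m1": "coding", "m2": "coding"}
        )
        res = de.run_contrast(counts, sf, alpha, "0h", "8h", biotypes=biotypes)
        t = res.table
        # within each biotype the BH denominator is 2, so the significant
        # gene's fdr is min(2 * p, other p) computed within its own group
        assert t.loc["l1", "fdr"] == pytest.approx(
            de.bh_adjust(t.loc[["l1", "l2"], "p"].to_numpy())[0]
        )
        assert t.loc["m1", "fdr"] == pytest.approx(
            de.bh_adjust(t.loc[["m1", "m2"], "p"].to_numpy())[0]
        )
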