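import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import binomtest, combine_pvalues, kendalltau

from hubrate.stats import (
    TaxonRateData,
    connectivity_rate_analysis,
    fisher_combined,
    holm_adjust,
    kendall_tau_b,
    permutation_pvalue,
    sign_test,
)


class TestKendallTau:
    def test_perfect_concordance_and_reversal(self):
        x = np.arange(10.0)
        assert kendall_tau_b(x, 2 * x + 1) == pytest.approx(1.0)
        assert kendall_tau_b(x, -x) == pytest.approx(-1.0)

    def test_four_point_example(self):
        # 5 concordant, 1 discordant of 6 pairs, no ties -> tau = 2/3
        assert kendall_tau_b([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(2 / 3)

    @given(seed=st.integers(min_value=0, max_value=200))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        x = rng.integers(0, 6, n).astype(float)
        y = rng.integers(0, 6, n).astype(float)
        if np.unique(x).size < 2 or np.unique(y).size < 2:
            return
        assert kendall_tau_b(x, y) == pytest.approx(
            kendalltau(x, y).statistic, abs=1e-12
        )

    def test_symmetry_and_sign_flip(self, rng):
        x, y = rng.random(25), rng.random(25)
        assert kendall_tau_b(x, y) == pytest.approx(kendall_tau_b(y, x))
        assert kendall_tau_b(x, -y) == pytest.approx(-kendall_tau_b(x, y))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            kendall_tau_b([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPermutationPvalue:
    def test_add_one_lower_bound(self, rng):
        x, y = rng.random(20), rng.random(20)
        _, p = permutation_pvalue(x, y, n_permutations=99, seed=0)
        assert p >= 1 / 100

    def test_strong_signal_near_minimal_p(self):
        x = np.arange(30.0)
        y = x**2 + 1
        _, p = permutation_pvalue(x, y, n_permutations=10000, seed=1)
        assert p <= 0.001

    def test_reproducible_for_fixed_seed(self, rng):
        x, y = rng.random(40), rng.random(40)
        p1 = permutation_pvalue(x, y, 500, seed=42)
        p2 = permutation_pvalue(x, y, 500, seed=42)
        assert p1 == p2

    def test_matches_naive_permutation_loop(self, rng):
        # same permutations drawn from the same generator state, tau computed
        # naively per permutation
        x, y = rng.integers(0, 5, 15).astype(float), rng.integers(0, 5, 15).astype(float)
        tau_obs, p = permutation_pvalue(x, y, n_permutations=200, seed=7, chunk=64)
        gen = np.random.default_rng(7)
        hits = 0
        done = 0
        while done < 200:
            m = min(64, 200 - done)
            perms = np.argsort(gen.random((m, 15)), axis=1)
            for row in perms:
                hits += abs(kendall_tau_b(x, y[row])) >= abs(tau_obs) - 1e-12
            done += m
        assert p == pytest.approx((1 + hits) / 201)

    def test_bad_inputs(self, rng):
        with pytest.raises(ValueError):
            permutation_pvalue(rng.random(10), rng.random(10), n_permutations=0)


class TestHolm:
    def test_single_p_reduces_to_plain_test(self):
        assert holm_adjust([0.01], alpha=0.05).tolist() == [True]

    def test_stepwise_all_rejected(self):
        assert holm_adjust([0.01, 0.02, 0.04], alpha=0.05).tolist() == [True, True, True]

    def test_stepwise_stops_at_first_failure(self):
        assert holm_adjust([0.03, 0.04], alpha=0.05).tolist() == [False, False]

    def test_decisions_in_input_order(self):
        assert holm_adjust([0.04, 0.01, 0.02], alpha=0.05).tolist() == [True, True, True]

    @given(seed=st.integers(min_value=0, max_value=100))
    def test_between_bonferroni_and_unadjusted(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(8)
        holm = holm_adjust(p, alpha=0.05)
        bonf = p <= 0.05 / p.size
        raw = p <= 0.05
        assert (holm | ~bonf).all()  # Holm rejects a superset of Bonferroni
        assert (~holm | raw).all()  # ... and a subset of unadjusted

    @given(seed=st.integers(min_value=0, max_value=100))
    def test_matches_statsmodels(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.random(6)
        ours = holm_adjust(p, alpha=0.05)
        ref = multipletests(p, alpha=0.05, method="holm")[0]
        assert ours.tolist() == ref.tolist()


class TestFisherCombined:
    def test_degenerate_all_ones(self):
        res = fisher_combined([1.0, 1.0, 1.0])
        assert res.statistic == 0.0 and res.p_combined == pytest.approx(1.0)

    def test_single_p_identity(self):
        res = fisher_combined([0.037])
        assert res.p_combined == pytest.approx(0.037, abs=1e-12)

    def test_hand_computed_pair(self):
        res = fisher_combined([0.05, 0.05])
        assert res.statistic == pytest.approx(11.983, abs=1e-3)
        assert res.df == 4
        assert res.p_combined == pytest.approx(0.01748, abs=1e-5)

    def test_permutation_invariant_and_matches_scipy(self, rng):
        p = rng.random(5)
        a = fisher_combined(p)
        b = fisher_combined(p[::-1])
        assert a.statistic == pytest.approx(b.statistic)
        stat_ref, p_ref = combine_pvalues(p, method="fisher")
        assert a.statistic == pytest.approx(stat_ref)
        assert a.p_combined == pytest.approx(p_ref)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            fisher_combined([0.0, 0.5])


class TestSignTest:
    def test_seven_of_seven(self):
        assert sign_test(7, 7) == pytest.approx(2 * 0.5**7)
        assert sign_test(7, 7) == 0.015625

    def test_balanced_case_capped_at_one(self):
        assert sign_test(1, 2) == 1.0

    def test_symmetry(self):
        assert sign_test(0, 7) == sign_test(7, 7)

    @pytest.mark.parametrize("k,n", [(0, 5), (3, 10), (8, 9), (5, 5), (2, 12)])
    def test_matches_scipy_binomtest(self, k, n):
        ref = binomtest(k, n, 0.5, alternative="two-sided").pvalue
        assert sign_test(k, n) == pytest.approx(ref, abs=1e-12)


class TestConnectivityRateAnalysis:
    def make_dataset(self, rng, n=40, planted="perfect"):
        k = pd.Series(
            rng.permutation(np.arange(1.0, n + 1)), index=[f"g{i}" for i in range(n)]
        )
        if planted == "perfect":
            dn = 1.0 / k  # strictly decreasing in connectivity
        else:
            dn = pd.Series(rng.random(n), index=k.index)
        rates = pd.DataFrame({"dN": dn, "dS": rng.random(n) + 0.1, "omega": dn * 2})
        return TaxonRateData(connectivity=k, rates=rates)

    def test_planted_perfect_signal(self, rng):
        datasets = {f"t{i}": self.make_dataset(rng) for i in range(3)}
        results, combined = connectivity_rate_analysis(
            datasets, n_permutations=999, seed=0
        )
        dn = results[results["metric"] == "dN"]
        assert np.allclose(dn["tau"], -1.0)
        assert dn["significant_holm"].all()
        assert np.allclose(dn["p_perm"], 1 / 1000)
        row = combined[combined["metric"] == "dN"].iloc[0]
        assert row["n_negative_tau"] == 3
        assert row["sign_test_p"] == 0.25

    def test_null_signal_mostly_insignificant(self, rng):
        datasets = {f"t{i}": self.make_dataset(rng, planted="null") for i in range(8)}
        results, _ = connectivity_rate_analysis(datasets, n_permutations=499, seed=1)
        dn = results[results["metric"] == "dN"]
        assert dn["significant_raw"].sum() <= 2

    def test_ortholog_connectivity_metric(self, rng):
        base = self.make_dataset(rng)
        out_k = pd.Series(
            base.connectivity.to_numpy() + rng.normal(0, 2, len(base.connectivity)),
            index=[f"o{i}" for i in range(len(base.connectivity))],
        )
        pairs = pd.DataFrame(
            {"gene_a": base.connectivity.index, "gene_b": out_k.index}
        )
        data = TaxonRateData(
            connectivity=base.connectivity, rates=base.rates,
            outgroup_connectivity=out_k, pairs=pairs,
        )
        results, _ = connectivity_rate_analysis({"t": data}, n_permutations=499, seed=2)
        oc = results[results["metric"] == "ortholog_connectivity"]
        assert len(oc) == 1 and oc["tau"].iloc[0] > 0.5
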