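import itertools

import numpy as np
import pytest

from clinezone import (
    allele_frequencies,
    diversity_summary,
    g_statistic,
    holm_correction,
    hwe_exact_enumeration,
    hwe_test,
    ld_test,
    pairwise_fst,
    private_alleles,
    wc_theta,
)
from clinezone.popgen_stats import _rarefied_richness

from conftest import make_matrix


class TestAlleleFrequencies:
    def test_direct_counts(self):
        gm = make_matrix({"P": [[(1, 1)], [(1, 3)]]})
        ft = allele_frequencies(gm, "P")
        assert ft.freqs["L1"].to_dict() == {1: 0.75, 3: 0.25}
        assert ft.gene_counts["L1"] == 4

    def test_all_missing_locus_flagged(self):
        gm = make_matrix({"P": [[(1, 1), (0, 0)], [(1, 2), (0, 0)]]})
        ft = allele_frequencies(gm, "P")
        assert ft.missing_loci == ["L2"]
        assert "L2" not in ft.freqs

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(11)
        calls = [
            [tuple(rng.integers(1, 5, size=2)) for _ in range(3)]
            for _ in range(10)
        ]
        gm = make_matrix({"P": calls})
        ft = allele_frequencies(gm, "P")
        for k, locus in enumerate(gm.loci):
            tally = {}
            for ind in calls:
                for a in ind[k]:
                    tally[a] = tally.get(a, 0) + 1
            total = sum(tally.values())
            for allele, c in tally.items():
                assert ft.freqs[locus][allele] == pytest.approx(c / total)


class TestDiversity:
    def test_monomorphic_locus_degenerate_values(self):
        gm = make_matrix({"P": [[(5, 5)], [(5, 5)], [(5, 5)]]})
        t = diversity_summary(gm, rarefaction_g=2)
        assert t.loc["P", "H_e"] == 0.0
        assert t.loc["P", "eff_num_alleles"] == 1.0
        assert np.isnan(t.loc["P", "G_IS"])

    def test_gis_zero_when_het_matches_expectation(self):
        # p = 0.5 with Ho = 0.5 gives He = Ho under the uncorrected estimator
        gm = make_matrix({"P": [[(1, 2)], [(1, 2)], [(1, 1)], [(2, 2)]]})
        t = diversity_summary(gm, rarefaction_g=2, unbiased_he=False)
        assert t.loc["P", "G_IS"] == pytest.approx(0.0, abs=1e-12)

    def test_unbiased_he_correction_factor(self):
        gm = make_matrix({"P": [[(1, 2)], [(1, 2)]]})
        # n = 2 individuals, 4 genes, sum p^2 = 0.5: He = (4/3) * 0.5
        t = diversity_summary(gm, rarefaction_g=2)
        assert t.loc["P", "H_e"] == pytest.approx(4 / 3 * 0.5)

    def test_rarefaction_matches_exhaustive_subsampling(self):
        # 5 individuals, 10 genes, alleles with counts 5, 3, 2
        genes = [1] * 5 + [2] * 3 + [3] * 2
        counts = np.array([5, 3, 2])
        for g in (2, 3, 5, 8, 10):
            expected = np.mean(
                [len(set(c)) for c in itertools.combinations(genes, g)]
            )
            assert _rarefied_richness(counts, g) == pytest.approx(expected)
        # monotone in g, exact count at g = 2n
        vals = [_rarefied_richness(counts, g) for g in range(1, 11)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(3.0)

    def test_rarefaction_g_too_large(self):
        gm = make_matrix({"P": [[(1, 2)], [(2, 2)]]})
        with pytest.raises(ValueError, match="rarefaction_g"):
            diversity_summary(gm, rarefaction_g=5)

    def test_effective_alleles_bounded_by_observed(self, simulated_zone):
        _, _, gm, _, _ = simulated_zone
        t = diversity_summary(gm, rarefaction_g=4)
        assert (t["eff_num_alleles"] <= t["num_alleles"] + 1e-9).all()
        assert ((0 <= t["H_o"]) & (t["H_o"] <= 1)).all()
        assert ((0 <= t["H_e"]) & (t["H_e"] <= 1)).all()


class TestPrivateAlleles:
    def test_set_difference_oracle(self):
        gm = make_matrix(
            {
                "W": [[(1, 2), (10, 10)], [(2, 3), (10, 12)]],
                "E": [[(3, 4), (12, 12)], [(4, 4), (12, 14)]],
            }
        )
        out = private_alleles(gm, {"W": "west", "E": "east"})
        # locus 1: W = {1,2,3}, E = {3,4}: private W = {1,2}, E = {4}
        assert out.loc["L1", "west"] == 2
        assert out.loc["L1", "east"] == 1
        # locus 2: W = {10,12}, E = {12,14}
        assert out.loc["L2", "west"] == 1
        assert out.loc["L2", "east"] == 1
        assert out.loc["total", "west"] == 3

    def test_unassigned_population_policy(self):
        gm = make_matrix({"W": [[(1, 1)]], "H": [[(2, 2)]]})
        with pytest.raises(Exception, match="without species assignment"):
            private_alleles(gm, {"W": "west"})
        out = private_alleles(gm, {"W": "west"},
                              require_full_assignment=False)
        assert out.loc["L1", "west"] == 1  # allele 2 never counted


class TestHolm:
    def test_matches_brute_force_ordering_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.random(rng.integers(1, 12))
            adj, reject = holm_correction(p, alpha=0.05)
            # oracle: step-down walk in sorted order
            order = np.argsort(p)
            m = p.size
            expected_reject = np.zeros(m, bool)
            for rank, i in enumerate(order):
                if p[i] * (m - rank) <= 0.05:
                    expected_reject[i] = True
                else:
                    break
            assert np.array_equal(reject, expected_reject)
            # rejections are a subset of unadjusted rejections
            assert np.all(adj >= p - 1e-15)

    def test_nan_entries_ignored(self):
        adj, reject = holm_correction([0.01, np.nan, 0.5])
        assert np.isnan(adj[1]) and not reject[1]
        assert adj[0] == pytest.approx(0.02)


class TestHWE:
    def test_equilibrium_composition_not_rejected(self):
        calls = [[(1, 1)]] * 25 + [[(1, 2)]] * 50 + [[(2, 2)]] * 25
        gm = make_matrix({"P": calls})
        out = hwe_test(gm, reps=2000, seed=1)
        assert out.loc[0, "p_value"] > 0.5

    def test_total_heterozygote_deficit_rejected(self):
        calls = [[(1, 1)]] * 50 + [[(2, 2)]] * 50
        gm = make_matrix({"P": calls})
        out = hwe_test(gm, reps=10_000, seed=1)
        assert out.loc[0, "p_value"] < 0.001

    def test_monomorphic_flagged_not_applicable(self):
        gm = make_matrix({"P": [[(1, 1)], [(1, 1)], [(1, 1)]]})
        out = hwe_test(gm, reps=1000, seed=0)
        assert not out.loc[0, "applicable"]
        assert np.isnan(out.loc[0, "p_value"])

    @pytest.mark.parametrize(
        "genos",
        [
            {(0, 0): 2, (0, 1): 1, (1, 1): 2},
            {(0, 0): 3, (1, 1): 2},
            {(0, 1): 4, (1, 1): 1},
        ],
    )
    def test_monte_carlo_agrees_with_enumeration(self, genos):
        reps = 20_000
        p_exact = hwe_exact_enumeration(genos)
        calls = []
        for (a, b), c in genos.items():
            calls.extend([[(a + 1, b + 1)]] * c)
        gm = make_matrix({"P": calls})
        out = hwe_test(gm, reps=reps, seed=3)
        p_mc = out.loc[0, "p_value"]
        se = np.sqrt(p_exact * (1 - p_exact) / reps)
        assert abs(p_mc - p_exact) <= 3 * se + 2 / reps


class TestLD:
    def test_g_matches_hand_computation(self):
        # 2x2 table: G = 2 sum O ln(O/E)
        table = np.array([[10.0, 2.0], [3.0, 9.0]])
        total = table.sum()
        expected = 0.0
        for i in range(2):
            for j in range(2):
                e = table[i].sum() * table[:, j].sum() / total
                expected += 2 * table[i, j] * np.log(table[i, j] / e)
        assert g_statistic(table) == pytest.approx(expected)

    def test_duplicated_locus_hits_permutation_floor(self):
        rng = np.random.default_rng(8)
        pairs = [tuple(sorted(rng.integers(1, 4, 2))) for _ in range(30)]
        calls = [[p, p] for p in pairs]  # locus 2 duplicates locus 1
        gm = make_matrix({"P": calls})
        out = ld_test(gm, reps=1000, seed=2)
        assert out.loc[0, "p_value"] == pytest.approx(1 / 1001)

    def test_monomorphic_pair_skipped(self):
        gm = make_matrix({"P": [[(1, 1), (2, 3)], [(1, 1), (3, 3)]]})
        out = ld_test(gm, reps=1000, seed=0)
        assert not out.loc[0, "applicable"]

    def test_independent_loci_rejection_near_nominal(self):
        rng = np.random.default_rng(15)
        rejections = 0
        n_fixtures = 30
        for _ in range(n_fixtures):
            calls = [
                [tuple(sorted(rng.integers(1, 4, 2))),
                 tuple(sorted(rng.integers(1, 4, 2)))]
                for _ in range(40)
            ]
            gm = make_matrix({"P": calls})
            out = ld_test(gm, reps=1000, seed=int(rng.integers(2**31)))
            rejections += int(out.loc[0, "p_value"] < 0.05)
        # binomial(30, 0.05): P(X > 7) < 1e-4
        assert rejections <= 7


class TestFst:
    def test_identical_populations_near_zero(self):
        # theta's unbiased correction makes it slightly negative for
        # identical multisets; it shrinks toward 0 with sample size
        calls = ([[(1, 2)], [(1, 1)], [(2, 2)], [(1, 2)]] * 3)
        gm = make_matrix({"P1": calls, "P2": calls})
        res = pairwise_fst(gm, reps=99, seed=0)
        assert -0.12 < res.theta.loc["P1", "P2"] <= 0.0
        assert res.pairs.loc[0, "p_value"] > 0.3

    def test_fixed_differences_give_theta_one(self):
        gm = make_matrix(
            {"P1": [[(1, 1), (3, 3)]] * 5, "P2": [[(2, 2), (4, 4)]] * 5}
        )
        res = pairwise_fst(gm, reps=99, seed=0)
        assert res.theta.loc["P1", "P2"] == pytest.approx(1.0)

    def test_theta_matches_hand_computed_components(self):
        # one locus, two populations of 2: P1 = {AA, AB}, P2 = {BB, BB}
        gm = make_matrix({"P1": [[(1, 1)], [(1, 2)]], "P2": [[(2, 2)], [(2, 2)]]})
        r, n1, n2 = 2, 2.0, 2.0
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        num = den = 0.0
        for p1, p2, h1, h2 in [(0.75, 0.0, 0.5, 0.0), (0.25, 1.0, 0.5, 0.0)]:
            pbar = (n1 * p1 + n2 * p2) / (r * nbar)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            num += a
            den += a + b + hbar / 2
        assert wc_theta(gm) == pytest.approx(num / den)

    def test_permutation_p_within_mc_error_of_enumeration(self):
        # 2 + 2 individuals: only 6 distinct equal-size splits
        gm = make_matrix({"P1": [[(1, 1)], [(1, 2)]], "P2": [[(2, 2)], [(2, 2)]]})
        reps = 4000
        res = pairwise_fst(gm, reps=reps, seed=9)
        t_obs = res.theta.loc["P1", "P2"]
        calls = list(gm.calls[:, 0, :])
        exceed = total = 0
        for combo in itertools.permutations(range(4)):
            grp1 = [calls[i] for i in combo[:2]]
            grp2 = [calls[i] for i in combo[2:]]
            gm_perm = make_matrix(
                {"P1": [[tuple(c)] for c in grp1],
                 "P2": [[tuple(c)] for c in grp2]}
            )
            total += 1
            if wc_theta(gm_perm) >= t_obs - 1e-12:
                exceed += 1
        pi = exceed / total
        p_mc = res.pairs.loc[0, "p_value"]
        se = np.sqrt(pi * (1 - pi) / reps)
        assert abs(p_mc - pi) <= 3 * se + 2 / reps

    def test_singleton_population_estimate_without_pvalue(self):
        gm = make_matrix({"P1": [[(1, 1)]], "P2": [[(2, 2)], [(1, 2)]]})
        with pytest.warns(UserWarning, match="single-individual"):
            res = pairwise_fst(gm, reps=99, seed=0)
        assert np.isnan(res.pairs.loc[0, "p_value"])
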