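"""ML fits: recovery, nesting, consistency between model variants."""

import numpy as np
import pytest

from selcontrast.alignment import CodonAlignment
from selcontrast.models import (
    BranchOmegaModel,
    BranchSiteModel,
    RelaxModel,
    SingleOmegaModel,
    cap_omega,
    fit_branch_three_omega,
    fit_model_a,
    fit_model_a_null,
    fit_relax,
    fit_relax_pdm,
    fit_single_omega,
)
from selcontrast.models.matrices import uniform_frequencies
from selcontrast.orthogroup import MissingPartitionError, OrthoGroup
from selcontrast.simulate import simulate_codon_alignment, regime_classes


@pytest.fixture(scope="module")
def pa_og(request):
    """300-codon alignment simulated under a single omega on the 8-taxon
    present/absent tree (module-scoped: several tests share it)."""
    from selcontrast.trees import LabeledTree

    nwk = ("(((a:0.3,b:0.3):0.2,(c:0.3,d:0.3):0.2):0.2,"
           "((e:0.3,f:0.3):0.2,(g:0.3,h:0.3):0.2):0.2);")
    traits = {t: "present" for t in "abcdefgh"}
    for t in "bdf":
        traits[t] = "absent"
    tree = LabeledTree.from_newick(nwk, traits=traits)
    pi = uniform_frequencies()
    classes = regime_classes("m0", {"omega": 0.2}, pi=pi, kappa=2.0)
    aln, _ = simulate_codon_alignment(
        tree, classes, 300, seed=101, pi=pi, kappa=2.0, branch_scale=1.0
    )
    return OrthoGroup("m0og", aln.select_taxa(sorted(tree.taxa)), tree)


class TestSingleOmega:
    def test_recovery_within_quarter(self, pa_og):
        res = fit_single_omega(pa_og)
        assert res.converged
        assert 0.15 <= res.params["omega"] <= 0.25
        assert 1.4 <= res.params["kappa"] <= 2.8

    def test_lnl_improves_over_start(self, pa_og):
        model = SingleOmegaModel(pa_og.alignment, pa_og.tree)
        start = model._start()
        res = model.fit()
        assert res.lnL >= model.loglike(start)

    def test_synonymous_only_alignment_hits_lower_bound(self, code):
        # two sequences differing only at synonymous third positions
        from selcontrast.trees import LabeledTree

        rows = {
            "a": "GGA" * 30 + "CCA" * 30,
            "b": "GGG" * 30 + "CCG" * 30,
            "c": "GGC" * 30 + "CCC" * 30,
            "d": "GGT" * 30 + "CCT" * 30,
        }
        aln = CodonAlignment.from_sequences(rows)
        tree = LabeledTree.from_newick("(a:0.2,b:0.2,(c:0.2,d:0.2):0.1);")
        res = SingleOmegaModel(aln, tree).fit()
        assert res.params["omega"] < 0.01
        assert cap_omega(res.params["omega"]) == 0.01

    def test_reporting_caps_do_not_touch_mles(self, pa_og):
        res = fit_single_omega(pa_og)
        raw = res.params["omega"]
        assert res.omega_reported["omega"] == cap_omega(raw)
        assert res.params["omega"] == raw

    def test_summary_mentions_key_fields(self, pa_og):
        text = fit_single_omega(pa_og).summary()
        assert "log-likelihood" in text
        assert "omega" in text and "kappa" in text


class TestBranchOmega:
    def test_collapsed_labels_reproduce_single_omega(self, pa_og):
        m0 = fit_single_omega(pa_og)
        model = BranchOmegaModel(pa_og.alignment, pa_og.tree)
        # evaluate the branch model at equal omegas taken from the M0 fit
        x = np.concatenate([[m0.x[0]], np.repeat(m0.x[1], len(model.omega_labels)),
                            m0.x[2:]])
        assert model.loglike(x) == pytest.approx(m0.lnL, abs=1e-6)

    def test_nesting_against_single_omega(self, pa_og):
        m0 = fit_single_omega(pa_og)
        model = BranchOmegaModel(pa_og.alignment, pa_og.tree)
        res = model.fit()
        assert res.lnL >= m0.lnL - 1e-4

    def test_three_state_requirement(self, pa_og):
        # the present/absent orthogroup lacks reduced-bristle species
        with pytest.raises(MissingPartitionError):
            fit_branch_three_omega(pa_og)

    def test_rank_order_recovery(self, tree6_threestate):
        pi = uniform_frequencies()
        classes = regime_classes(
            "branch3",
            {"omega_present": 0.1, "omega_reduced": 0.3, "omega_absent": 0.9},
            pi=pi, kappa=2.0,
        )
        aln, _ = simulate_codon_alignment(
            tree6_threestate, classes, 500, seed=55, pi=pi, kappa=2.0,
            branch_scale=1.0, labels_by_taxon=tree6_threestate.terminal_labels(),
        )
        og = OrthoGroup("b3", aln.select_taxa(sorted(tree6_threestate.taxa)),
                        tree6_threestate)
        res = fit_branch_three_omega(og, start_from=fit_single_omega(og))
        omegas = dict(zip(res.params["labels"], res.params["omega_by_label"]))
        assert omegas[0] < omegas[1] < omegas[2]


class TestBranchSite:
    def test_null_parameter_count(self, pa_og):
        null = BranchSiteModel(
            pa_og.alignment, pa_og.tree, contrast="present-absent",
            foreground_label=1, fix_omega2=True,
        )
        alt = BranchSiteModel(
            pa_og.alignment, pa_og.tree, contrast="present-absent",
            foreground_label=1, fix_omega2=False,
        )
        # free params: kappa, two simplex coords, omega0 (+ omega2) + scale
        assert len(null._start()) == 5
        assert len(alt._start()) == 6

    def test_null_is_alt_at_omega2_one(self, pa_og):
        null = fit_model_a_null(pa_og, "absent")
        alt_model = BranchSiteModel(
            pa_og.alignment, pa_og.tree, contrast="present-absent",
            foreground_label=1, fix_omega2=False,
        )
        x = np.insert(np.asarray(null.x), 4, -25.0)  # omega2 = 1 + 1e-11
        assert alt_model.loglike(x) == pytest.approx(null.lnL, abs=1e-5)

    def test_alt_nests_null(self, pa_og):
        null = fit_model_a_null(pa_og, "absent")
        alt = fit_model_a(pa_og, "absent", start_from=null)
        assert alt.lnL >= null.lnL - 1e-4
        assert alt.params["omega2"] >= 1.0

    def test_proportions_sum_to_one(self, pa_og):
        res = fit_model_a_null(pa_og, "absent")
        total = res.params["p0"] + res.params["p1"] + res.params["p2a"] + res.params["p2b"]
        assert total == pytest.approx(1.0, abs=1e-9)


class TestSitePosteriors:
    def test_posteriors_normalized_and_constant_sites_unflagged(self, tree8_pa):
        from selcontrast.models import site_posteriors

        pi = uniform_frequencies()
        classes = regime_classes(
            "modelA", {"p0": 0.6, "p1": 0.25, "omega0": 0.1, "omega2": 4.0},
            pi=pi, kappa=2.0,
        )
        aln, _ = simulate_codon_alignment(
            tree8_pa, classes, 200, seed=77, pi=pi, kappa=2.0, branch_scale=1.0,
            labels_by_taxon=tree8_pa.terminal_labels("present-absent"),
        )
        # overwrite the first five columns with an invariant codon
        aln.codons[:, :5] = 13
        og = OrthoGroup("bs", aln.select_taxa(sorted(tree8_pa.taxa)), tree8_pa)
        alt = fit_model_a(og, "absent")
        post, flagged = site_posteriors(alt)
        assert post.shape == (200, 4)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)
        assert not (set(range(5)) & set(flagged.tolist()))


class TestRelax:
    def test_neutral_category_fixed_point(self):
        from selcontrast.models.relax import relax_classes

        pi = uniform_frequencies()
        classes = relax_classes((0.2, 1.0, 1.5), (0.4, 0.4, 0.2), 0.3,
                                pi=pi, kappa=2.0)
        # omega = 1 categories are invariant under the exponent
        assert classes[1].omega(1) == pytest.approx(1.0)

    def test_null_alt_pdm_nesting_chain(self, tree8_pa):
        pi = uniform_frequencies()
        classes = regime_classes(
            "relax",
            {"omegas": (0.05, 0.4, 1.5), "proportions": (0.5, 0.4, 0.1), "k": 0.4},
            pi=pi, kappa=2.0,
        )
        aln, _ = simulate_codon_alignment(
            tree8_pa, classes, 200, seed=91, pi=pi, kappa=2.0, branch_scale=1.0,
            labels_by_taxon=tree8_pa.terminal_labels("present-absent"),
        )
        og = OrthoGroup("rx", aln.select_taxa(sorted(tree8_pa.taxa)), tree8_pa)
        null = fit_relax(og, "absent", fix_k=1.0)
        alt = fit_relax(og, "absent", start_from=null)
        pdm = fit_relax_pdm(og, "absent", start_from=alt)
        assert alt.lnL >= null.lnL - 1e-4
        assert pdm.lnL >= alt.lnL - 1e-4
        assert alt.params["k"] < 1.0  # strong relaxation simulated
        assert sum(pdm.params["proportions"]) == pytest.approx(1.0, abs=1e-9)
        w0, w1, w2 = alt.params["omega_reference"]
        assert w0 <= w1 <= 1.0 + 1e-9 <= w2 + 1e-9

    def test_k_bound_flagging(self, pa_og):
        res = fit_relax(pa_og, "absent")
        assert "k_at_bound" in res.params
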