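"""Homolog-tree pruning cascade and RT / MI ortholog extraction."""

import itertools

import numpy as np
import pytest

from selcontrast.orthology import (
    HomologTree,
    PruningConfig,
    cut_deep_paralogs,
    extract_orthologs_mi,
    extract_orthologs_rt,
    mask_monophyletic_duplicates,
    prune_homolog_tree,
    trim_long_tips,
    union_orthogroups,
)
from selcontrast.simulate import StudyDesign, simulate_homolog_tree, simulate_species_tree
from selcontrast.trees import species_of


class TestTrimLongTips:
    def test_absolute_cutoff(self):
        ht = HomologTree.from_newick("((A@1:0.1,B@1:2.5):0.1,(C@1:0.1,D@1:0.1):0.1);")
        assert sorted(trim_long_tips(ht).tips) == ["A@1", "C@1", "D@1"]

    def test_relative_cutoff(self):
        ht = HomologTree.from_newick("((A@1:0.05,B@1:0.6):0.1,(C@1:0.1,D@1:0.1):0.1);")
        assert sorted(trim_long_tips(ht).tips) == ["A@1", "C@1", "D@1"]

    def test_too_few_tips_flagged(self):
        ht = HomologTree.from_newick("(A@1:2.5,B@1:2.6);")
        out = trim_long_tips(ht)
        assert out.failure_reason is not None

    def test_random_fixture_post_hoc_audit(self):
        cfg = PruningConfig()
        rng = np.random.default_rng(11)
        tree = simulate_species_tree(StudyDesign(n_species=20), seed=3)
        # inflate a few terminal branches to force violations
        ht = HomologTree(tree=tree.copy().tree)
        leaves = list(ht.tree.leaf_node_iter())
        for lf in rng.choice(leaves, size=5, replace=False):
            lf.edge.length = float(rng.uniform(2.1, 4.0))
        out = trim_long_tips(ht, cfg)
        # audit: no surviving tip violates either rule
        for leaf in out.tree.leaf_node_iter():
            assert (leaf.edge.length or 0.0) <= cfg.abs_tip_cutoff
            parent = leaf.parent_node
            for sib in parent.child_nodes():
                if sib is leaf or not sib.is_leaf():
                    continue
                assert (leaf.edge.length or 0.0) <= (
                    cfg.relative_tip_factor * (sib.edge.length or 0.0)
                )


class TestMaskDuplicates:
    def test_keeps_most_aligned_sequence(self):
        ht = HomologTree.from_newick(
            "(((spA@t1:0.1,spA@t2:0.1):0.1,B@1:0.2):0.1,C@1:0.3);",
            {"spA@t1": 300, "spA@t2": 150, "B@1": 100, "C@1": 100},
        )
        assert sorted(mask_monophyletic_duplicates(ht).tips) == ["B@1", "C@1", "spA@t1"]

    def test_no_single_species_clades_is_identity(self):
        ht = HomologTree.from_newick("((A@1:0.1,B@1:0.1):0.1,C@1:0.2);")
        assert sorted(mask_monophyletic_duplicates(ht).tips) == sorted(ht.tips)

    def test_nested_clades_collapse_to_maximal(self):
        ht = HomologTree.from_newick(
            "(((A@1:0.1,A@2:0.1):0.1,(A@3:0.1,A@4:0.1):0.1):0.2,(B@1:0.1,C@1:0.1):0.1);",
            {"A@1": 100, "A@2": 400, "A@3": 200, "A@4": 300, "B@1": 50, "C@1": 50},
        )
        out = mask_monophyletic_duplicates(ht)
        # brute-force clade enumeration: the maximal single-species clade is
        # all four A sequences; the survivor maximizes aligned columns
        assert sorted(out.tips) == ["A@2", "B@1", "C@1"]

    def test_tie_breaks_lexicographically(self):
        ht = HomologTree.from_newick(
            "((A@x:0.1,A@b:0.1):0.1,(B@1:0.1,C@1:0.1):0.1);",
            {"A@x": 100, "A@b": 100, "B@1": 1, "C@1": 1},
        )
        assert "A@b" in mask_monophyletic_duplicates(ht).tips


class TestCutDeepParalogs:
    def test_long_internal_branch_splits(self):
        left = "(" + ",".join(f"s{i}@a:0.1" for i in range(1, 6)) + ",s6@a:0.1)"
        right = "(" + ",".join(f"t{i}@b:0.1" for i in range(1, 6)) + ",t6@b:0.1)"
        ht = HomologTree.from_newick(f"({left}:0.1,{right}:3.0);")
        parts = cut_deep_paralogs(ht)
        assert len(parts) == 2
        assert {frozenset(p.species) for p in parts} == {
            frozenset({f"s{i}" for i in range(1, 7)}),
            frozenset({f"t{i}" for i in range(1, 7)}),
        }

    def test_small_parts_dropped(self):
        left = "(" + ",".join(f"s{i}@a:0.1" for i in range(1, 7)) + ")"
        right = "((t1@b:0.1,t2@b:0.1):0.1,t3@b:0.1)"
        ht = HomologTree.from_newick(f"({left}:0.1,{right}:3.0);")
        parts = cut_deep_paralogs(ht)
        assert len(parts) == 1
        assert len(parts[0].species) == 6

    def test_no_long_branch_is_identity(self):
        ht = HomologTree.from_newick(
            "(" + ",".join(f"s{i}@a:0.1" for i in range(1, 7)) + ");"
        )
        parts = cut_deep_paralogs(ht)
        assert len(parts) == 1 and sorted(parts[0].tips) == sorted(ht.tips)


class TestRootedIngroups:
    def test_no_duplications_single_og(self):
        ht = HomologTree.from_newick(
            "((A@1:0.1,B@1:0.1):0.1,(C@1:0.1,OUT@1:0.3):0.1);"
        )
        ogs = extract_orthologs_rt(ht, {"OUT"})
        assert ogs == [frozenset({"A@1", "B@1", "C@1"})]

    def test_duplication_splits_into_two_candidates(self):
        ht = HomologTree.from_newick(
            "(((A@1:0.1,B@1:0.1):0.1,(A@2:0.1,C@1:0.1):0.1):0.1,OUT@1:0.2);"
        )
        ogs = extract_orthologs_rt(ht, {"OUT"})
        assert sorted(sorted(s) for s in ogs) == [["A@1", "B@1"], ["A@2", "C@1"]]

    def test_unrootable_without_outgroup(self):
        ht = HomologTree.from_newick("((A@1:0.1,B@1:0.1):0.1,C@1:0.2);")
        assert extract_orthologs_rt(ht, {"ZZZ"}) == []

    def test_never_two_tips_of_same_species(self):
        tree = simulate_species_tree(StudyDesign(n_species=12), seed=5)
        for seed in range(30):
            ht, _ = simulate_homolog_tree(tree, dup_rate=0.3, loss_rate=0.1, seed=seed)
            for og in extract_orthologs_rt(ht, {"out01", "out02"}):
                spp = [species_of(t) for t in og]
                assert len(spp) == len(set(spp))


class TestMaximumInclusion:
    def test_duplication_free_tree_single_og(self):
        ht = HomologTree.from_newick(
            "((A@1:0.1,B@1:0.1):0.1,(C@1:0.1,D@1:0.1):0.1);"
        )
        ogs = extract_orthologs_mi(ht, PruningConfig(min_og_species=2))
        assert ogs[0] == frozenset({"A@1", "B@1", "C@1", "D@1"})

    def test_matches_exhaustive_search(self):
        # 10 tips, species A and B duplicated
        nwk = ("(((A@1:0.1,B@1:0.1):0.1,(C@1:0.1,D@1:0.1):0.1):0.1,"
               "(((A@2:0.1,B@2:0.1):0.1,E@1:0.1):0.1,(F@1:0.1,G@1:0.1):0.1):0.1);")
        cols = {t: 100 for t in
                ["A@1", "B@1", "C@1", "D@1", "A@2", "B@2", "E@1", "F@1", "G@1"]}
        ht = HomologTree.from_newick(nwk, cols)
        ogs = extract_orthologs_mi(ht, PruningConfig(min_og_species=3))
        # exhaustive: best bipartition side with <= 1 per species
        first = ogs[0]
        from selcontrast.orthology import _bipartition_sides

        best_size = max(
            len(s) for s in _bipartition_sides(ht.tree)
            if len({species_of(t) for t in s}) == len(s)
        )
        assert len(first) == best_size

    def test_extracted_ogs_disjoint(self):
        tree = simulate_species_tree(StudyDesign(n_species=10), seed=6)
        for seed in range(10):
            ht, _ = simulate_homolog_tree(tree, dup_rate=0.4, loss_rate=0.1, seed=seed)
            ogs = extract_orthologs_mi(ht, PruningConfig(min_og_species=3))
            for a, b in itertools.combinations(ogs, 2):
                assert not (a & b)
            all_tips = set(ht.tips)
            assert set().union(*ogs) <= all_tips if ogs else True


class TestUnion:
    def test_rt_wins_on_overlap(self):
        rt = [frozenset({"A@1", "B@1", "C@1"})]
        mi = [frozenset({"A@1", "B@1"})]
        assert union_orthogroups(rt, mi) == rt

    def test_mi_passes_when_disjoint(self):
        mi = [frozenset({"X@1", "Y@1"})]
        assert union_orthogroups([], mi) == mi

    def test_every_output_is_rt_or_disjoint_mi(self):
        tree = simulate_species_tree(StudyDesign(n_species=12), seed=8)
        for seed in range(10):
            ht, _ = simulate_homolog_tree(tree, dup_rate=0.3, loss_rate=0.1, seed=seed)
            rt = extract_orthologs_rt(ht, {"out01", "out02"})
            mi = extract_orthologs_mi(ht, PruningConfig(min_og_species=3))
            rt_tips = set().union(*rt) if rt else set()
            for og in union_orthogroups(rt, mi):
                assert og in rt or (og in mi and not og & rt_tips)


class TestFullCascade:
    def test_final_ogs_satisfy_invariants(self):
        tree = simulate_species_tree(StudyDesign(n_species=12), seed=9)
        cfg = PruningConfig(min_og_species=4)
        for seed in range(10):
            ht, _ = simulate_homolog_tree(tree, dup_rate=0.2, loss_rate=0.1, seed=seed)
            ogs, log = prune_homolog_tree(ht, {"out01", "out02"}, cfg)
            for og in ogs:
                spp = [species_of(t) for t in og]
                assert len(spp) == len(set(spp))
                assert len(spp) >= cfg.min_og_species

    def test_perfect_recall_on_duplication_free_trees(self):
        tree = simulate_species_tree(StudyDesign(n_species=10), seed=10)
        for seed in range(5):
            ht, truth = simulate_homolog_tree(tree, dup_rate=0.0, loss_rate=0.0, seed=seed)
            ogs, _ = prune_homolog_tree(ht, {"out01", "out02"}, PruningConfig())
            assert len(ogs) == 1
            # all ingroup species present (outgroups may root and drop out)
            spp = {species_of(t) for t in ogs[0]}
            assert {f"sp{i + 1:02d}" for i in range(10)} <= spp

    def test_cascade_idempotent(self):
        tree = simulate_species_tree(StudyDesign(n_species=12), seed=12)
        ht, _ = simulate_homolog_tree(tree, dup_rate=0.2, loss_rate=0.05, seed=1)
        cfg = PruningConfig()
        trimmed = trim_long_tips(ht, cfg)
        masked = mask_monophyletic_duplicates(trimmed)
        again = mask_monophyletic_duplicates(trim_long_tips(masked, cfg))
        assert sorted(again.tips) == sorted(masked.tips)
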