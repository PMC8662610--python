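"""Tree-based orthology inference from homolog gene trees.

Homolog trees contain paralogs, isoforms and assembly redundancy; tips are
labeled ``species@transcript``.  The pruning cascade converts them into
orthogroups with at most one sequence per species:

1. trim suspiciously long tips (absolute and relative-to-sister cutoffs),
2. collapse single-species clades to the best-aligned sequence,
3. cut trees at long internal branches (deep paralogs),
4. extract orthologs with the rooted-ingroups (RT) and maximum-inclusion
   (MI) algorithms and take their union, preferring RT on overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import dendropy

from .trees import LabeledTree, _parse_newick, species_of

logger = logging.getLogger(__name__)


@dataclass
class PruningConfig:
    abs_tip_cutoff: float = 2.0  # substitutions per site
    relative_tip_factor: float = 10.0
    internal_branch_cutoff: float = 2.0
    min_subtree_species: int = 5
    min_og_species: int = 4

    def __post_init__(self):
        for name in ("abs_tip_cutoff", "relative_tip_factor", "internal_branch_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class HomologTree:
    tree: dendropy.Tree
    aligned_columns: dict[str, int] = field(default_factory=dict)
    failure_reason: str | None = None

    @classmethod
    def from_newick(cls, source, aligned_columns=None) -> "HomologTree":
        return cls(
            tree=LabeledTree.from_newick(source).tree,
            aligned_columns=dict(aligned_columns or {}),
        )

    def copy(self) -> "HomologTree":
        return replace(self, tree=_parse_newick(self.tree.as_string(schema="newick")))

    @property
    def tips(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def species(self) -> set[str]:
        return {species_of(t) for t in self.tips}

    def n_tips(self) -> int:
        return len(self.tips)


def _prune_tips(tree: dendropy.Tree, labels) -> None:
    tree.prune_taxa_with_labels(list(labels), suppress_unifurcations=True)


def _leaf_species(node) -> set[str]:
    return {species_of(lf.taxon.label) for lf in node.leaf_iter()}


def trim_long_tips(htree: HomologTree, cfg: PruningConfig | None = None) -> HomologTree:
    """Remove tips longer than the absolute cutoff or more than
    ``relative_tip_factor`` times their sister tip, iterated to a fixed
    point (removals can expose new violating cherries)."""
    cfg = cfg or PruningConfig()
    out = htree.copy()
    while True:
        to_remove = set()
        for leaf in out.tree.leaf_node_iter():
            length = leaf.edge.length or 0.0
            if length > cfg.abs_tip_cutoff:
                to_remove.add(leaf.taxon.label)
                continue
            parent = leaf.parent_node
            if parent is None:
                continue
            sisters = [c for c in parent.child_nodes() if c is not leaf and c.is_leaf()]
            for sis in sisters:
                sis_len = sis.edge.length or 0.0
                if length > cfg.relative_tip_factor * sis_len and length > 0:
                    to_remove.add(leaf.taxon.label)
                    break
        if not to_remove:
            break
        if len(out.tips) - len(to_remove) < 2:
            out.failure_reason = "fewer_than_2_tips_after_trimming"
            return out
        _prune_tips(out.tree, to_remove)
    return out


def mask_monophyletic_duplicates(htree: HomologTree) -> HomologTree:
    """Collapse clades made of sequences from a single species, keeping the
    sequence with the most aligned columns (ties: lexicographically smallest
    transcript id, for determinism)."""
    out = htree.copy()
    cols = out.aligned_columns
    while True:
        removed = set()
        for node in out.tree.postorder_internal_node_iter():
            leaves = [lf.taxon.label for lf in node.leaf_iter()]
            if len(leaves) < 2 or len({species_of(t) for t in leaves}) != 1:
                continue
            parent = node.parent_node
            if parent is not None and len(_leaf_species(parent)) == 1:
                continue  # not maximal; handle at the parent
            keep = max(leaves, key=lambda t: (cols.get(t, 0), _neg_lex(t)))
            removed.update(t for t in leaves if t != keep)
        if not removed:
            return out
        _prune_tips(out.tree, removed)


class _NegLex:
    __slots__ = ("s",)

    def __init__(self, s):
        self.s = s

    def __lt__(self, other):  # reversed ordering: smaller string wins under max()
        return self.s > other.s

    def __eq__(self, other):
        return self.s == other.s


def _neg_lex(s: str) -> _NegLex:
    return _NegLex(s)


def cut_deep_paralogs(htree: HomologTree, cfg: PruningConfig | None = None) -> list[HomologTree]:
    """Split the tree at internal branches longer than the cutoff (deep
    paralogs) and keep subtrees with at least ``min_subtree_species``
    distinct species."""
    cfg = cfg or PruningConfig()
    work = [htree.copy()]
    done: list[HomologTree] = []
    while work:
        current = work.pop()
        long_edge = None
        for edge in current.tree.preorder_edge_iter():
            head = edge.head_node
            if head is current.tree.seed_node or head.is_leaf():
                continue
            if edge.length is not None and edge.length > cfg.internal_branch_cutoff:
                long_edge = edge
                break
        if long_edge is None:
            done.append(current)
            continue
        below = [lf.taxon.label for lf in long_edge.head_node.leaf_iter()]
        above = [t for t in current.tips if t not in set(below)]
        for part in (below, above):
            if len(part) < 2:
                continue
            sub = current.copy()
            _prune_tips(sub.tree, set(sub.tips) - set(part))
            work.append(sub)
    kept = [t for t in done if len(t.species) >= cfg.min_subtree_species]
    kept.sort(key=lambda t: sorted(t.tips))
    return kept


# ---------------------------------------------------------------------------
# RT: rooted ingroups
# ---------------------------------------------------------------------------

def _has_duplicates(node) -> bool:
    labels = [species_of(lf.taxon.label) for lf in node.leaf_iter()]
    return len(labels) != len(set(labels))


def _find_deepest_duplication(root):
    """Deepest node whose child subtrees share at least one species."""
    best = None
    for node in root.postorder_internal_node_iter():
        kids = node.child_nodes()
        if len(kids) < 2:
            continue
        sets = [_leaf_species(k) for k in kids]
        overlap = any(sets[i] & sets[j] for i in range(len(sets)) for j in range(i + 1, len(sets)))
        if overlap:
            return node  # postorder: first hit is deepest
    return best


def extract_orthologs_rt(
    htree: HomologTree, outgroup_species, min_species: int = 1
) -> list[frozenset]:
    """Rooted-ingroups ortholog extraction.

    The tree is rooted on the longest-path outgroup tip; outgroup sequences
    are then discarded and duplication nodes (nodes whose child subtrees
    share a species) are split bottom-up, the detached side re-entering the
    queue as its own candidate.  Every returned tip-set has at most one
    sequence per species.
    """
    outgroup_species = set(outgroup_species)
    og_tips = [t for t in htree.tips if species_of(t) in outgroup_species]
    if not og_tips:
        logger.info("unrootable homolog tree: no outgroup species present")
        return []
    work = htree.copy()
    # root on the outgroup tip with the longest root-to-tip path
    depth = {}
    for lf in work.tree.leaf_node_iter():
        d, node = 0.0, lf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depth[lf.taxon.label] = d
    root_tip = max(og_tips, key=lambda t: (depth.get(t, 0.0), t))
    leaf = next(
        lf for lf in work.tree.leaf_node_iter() if lf.taxon.label == root_tip
    )
    if leaf.edge.length:
        work.tree.reroot_at_edge(leaf.edge, update_bipartitions=False)
    ingroup_tips = [t for t in work.tips if species_of(t) not in outgroup_species]
    if len(ingroup_tips) < 2:
        return [frozenset(ingroup_tips)] if len(ingroup_tips) == 1 else []
    _prune_tips(work.tree, set(work.tips) - set(ingroup_tips))

    results: list[frozenset] = []
    queue = [work.tree]
    cols = htree.aligned_columns
    while queue:
        tree = queue.pop()
        root = tree.seed_node
        if not _has_duplicates(root):
            tips = frozenset(lf.taxon.label for lf in root.leaf_iter())
            if tips:
                results.append(tips)
            continue
        dup = _find_deepest_duplication(root)
        if dup is None:  # duplicates without an overlapping node cannot occur
            continue
        kids = sorted(
            dup.child_nodes(),
            key=lambda k: (
                sum(1 for _ in k.leaf_iter()),
                sum(cols.get(lf.taxon.label, 0) for lf in k.leaf_iter()),
                min(lf.taxon.label for lf in k.leaf_iter()),
            ),
        )
        smaller = kids[0]
        detached_tips = [lf.taxon.label for lf in smaller.leaf_iter()]
        sub = _parse_newick(tree.as_string(schema="newick"))
        keep = set(detached_tips)
        if len(keep) >= 2:
            _prune_tips(sub, set(lf.taxon.label for lf in sub.leaf_node_iter()) - keep)
            queue.append(sub)
        else:
            results.append(frozenset(keep))
        remaining = [t for t in (lf.taxon.label for lf in root.leaf_iter()) if t not in set(detached_tips)]
        if len(remaining) >= 2:
            _prune_tips(tree, detached_tips)
            queue.append(tree)
        elif remaining:
            results.append(frozenset(remaining))
    out = [s for s in results if len({species_of(t) for t in s}) >= min_species]
    out.sort(key=lambda s: (-len(s), sorted(s)))
    return out


# ---------------------------------------------------------------------------
# MI: maximum inclusion
# ---------------------------------------------------------------------------

def _bipartition_sides(tree: dendropy.Tree):
    """All tip-sets obtainable as one side of an edge of the (unrooted)
    tree, plus the full tip-set."""
    all_tips = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    sides = {all_tips}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        sides.add(clade)
        sides.add(all_tips - clade)
    return [s for s in sides if s]


def extract_orthologs_mi(
    htree: HomologTree, cfg: PruningConfig | None = None
) -> list[frozenset]:
    """Maximum-inclusion ortholog extraction.

    Iteratively takes the largest unrooted subtree (bipartition side) with
    at most one sequence per species, removes its tips, and repeats until no
    candidate with at least ``min_og_species`` species remains.  Ties are
    broken by total aligned columns, then lexicographically.
    """
    cfg = cfg or PruningConfig()
    work = htree.copy()
    cols = htree.aligned_columns
    results: list[frozenset] = []
    while work.n_tips() >= 2:
        candidates = []
        for side in _bipartition_sides(work.tree):
            spp = [species_of(t) for t in side]
            if len(spp) != len(set(spp)):
                continue
            if len(set(spp)) < cfg.min_og_species:
                continue
            candidates.append(side)
        if not candidates:
            break
        best = max(
            candidates,
            key=lambda s: (len(s), sum(cols.get(t, 0) for t in s), _neg_lex("|".join(sorted(s)))),
        )
        results.append(best)
        remaining = set(work.tips) - best
        if len(remaining) < 2:
            if len(remaining) == 1 and cfg.min_og_species <= 1:
                results.append(frozenset(remaining))
            break
        _prune_tips(work.tree, best)
    results.sort(key=lambda s: (-len(s), sorted(s)))
    return results


def union_orthogroups(rt: list[frozenset], mi: list[frozenset]) -> list[frozenset]:
    """Union of RT and MI orthogroups: keep every RT orthogroup, and those
    MI orthogroups sharing no tip with any RT orthogroup."""
    rt_tips = set().union(*rt) if rt else set()
    out = list(rt)
    for og in mi:
        if not (og & rt_tips):
            out.append(og)
    out.sort(key=lambda s: (-len(s), sorted(s)))
    return out


def prune_homolog_tree(
    htree: HomologTree,
    outgroup_species,
    cfg: PruningConfig | None = None,
) -> tuple[list[frozenset], list[dict]]:
    """Full cascade: trim tips -> mask duplicates -> cut deep paralogs ->
    RT + MI extraction -> union, with a per-step log.

    Returns (orthogroups, log records); every orthogroup has at most one
    sequence per species and at least ``min_og_species`` species.
    """
    cfg = cfg or PruningConfig()
    log: list[dict] = []
    step = trim_long_tips(htree, cfg)
    log.append({"rule": "trim_long_tips", "tips_removed": htree.n_tips() - step.n_tips()})
    if step.failure_reason:
        log.append({"rule": "abort", "reason": step.failure_reason})
        return [], log
    masked = mask_monophyletic_duplicates(step)
    log.append({"rule": "mask_duplicates", "tips_removed": step.n_tips() - masked.n_tips()})
    subtrees = cut_deep_paralogs(masked, cfg)
    log.append({"rule": "cut_deep_paralogs", "subtrees": len(subtrees)})
    ogs: list[frozenset] = []
    for sub in subtrees:
        sub = replace(sub, aligned_columns=htree.aligned_columns)
        rt = extract_orthologs_rt(sub, outgroup_species)
        mi = extract_orthologs_mi(sub, cfg)
        merged = union_orthogroups(rt, mi)
        ogs.extend(
            og for og in merged if len({species_of(t) for t in og}) >= cfg.min_og_species
        )
    ogs.sort(key=lambda s: (-len(s), sorted(s)))
    log.append({"rule": "extract", "orthogroups": len(ogs)})
    return ogs, log
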