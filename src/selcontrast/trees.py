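"""Labeled phylogenies: newick I/O, trait states, branch partitions.

A :class:`LabeledTree` wraps a dendropy tree together with (i) per-species
trait states (sperm-bristle state: present / reduced / absent), and (ii)
trait-transition marks — branches of the species tree on which an
independent loss or reduction of the trait occurred, recorded as the set of
tip labels subtended by the marked branch.  Codon models consume the tree
through per-branch partition labels derived from the trait states of
terminal branches (internal branches are always background).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy

STATES = ("present", "reduced", "absent")
STATE_LABEL = {"present": 0, "reduced": 1, "absent": 2}
EVENT_STATE = {"loss": "absent", "reduction": "reduced"}

DEFAULT_DELIMITER = "@"


def species_of(tip_label: str, delimiter: str = DEFAULT_DELIMITER) -> str:
    """Species identifier = tip label up to the first delimiter
    (homolog-tree tips carry transcript suffixes, ``species@transcript``)."""
    return tip_label.split(delimiter, 1)[0]


def _parse_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=text,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )


@dataclass
class LabeledTree:
    tree: dendropy.Tree
    traits: dict[str, str] = field(default_factory=dict)  # species -> state
    transitions: list[tuple[str, frozenset]] = field(default_factory=list)

    # -- construction / I/O ------------------------------------------------
    @classmethod
    def from_newick(cls, source, traits=None, transitions=None) -> "LabeledTree":
        if hasattr(source, "read"):
            text = source.read()
        else:
            try:
                with open(source) as fh:
                    text = fh.read()
            except (OSError, ValueError):
                text = str(source)
        tree = _parse_newick(text)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")
        return cls(tree=tree, traits=dict(traits or {}), transitions=list(transitions or []))

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", unquoted_underscores=True).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def copy(self) -> "LabeledTree":
        return LabeledTree(
            tree=_parse_newick(self.to_newick()),
            traits=dict(self.traits),
            transitions=list(self.transitions),
        )

    # -- basic accessors ---------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def require_branch_lengths(self) -> None:
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("tree has branches without lengths; required for model fitting")

    def state_of(self, taxon: str) -> str:
        return self.traits.get(taxon, "present")

    def terminal_labels(self, contrast: str | None = None) -> dict[str, int]:
        """Partition label per tip.

        Three-state labelling (default): present=0, reduced=1, absent=2.
        For two-partition contrasts (``"present-absent"`` or
        ``"present-reduced"``) the derived state is foreground (1) and
        present is background (0); taxa of the third state should have been
        removed before calling.
        """
        labels = {}
        for t in self.taxa:
            state = self.state_of(t)
            if contrast is None:
                labels[t] = STATE_LABEL[state]
            elif contrast == "present-absent":
                labels[t] = 1 if state == "absent" else 0
            elif contrast == "present-reduced":
                labels[t] = 1 if state == "reduced" else 0
            else:
                raise ValueError(f"unknown contrast {contrast!r}")
        return labels

    def states_present(self) -> set[str]:
        return {self.state_of(t) for t in self.taxa}

    # -- traits / transitions serialization ---------------------------------
    def write_traits(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("species\tstate\n")
            for sp, st in sorted(self.traits.items()):
                fh.write(f"{sp}\t{st}\n")

    def write_transitions(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("event\tclade_tips\n")
            for event, clade in self.transitions:
                fh.write(f"{event}\t{','.join(sorted(clade))}\n")

    @staticmethod
    def read_traits(path) -> dict[str, str]:
        traits = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                sp, st = line.rstrip("\n").split("\t")
                traits[sp] = st
        return traits

    @staticmethod
    def read_transitions(path) -> list[tuple[str, frozenset]]:
        out = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                event, tips = line.rstrip("\n").split("\t")
                out.append((event, frozenset(tips.split(","))))
        return out


def read_newick(path, traits=None, transitions=None) -> LabeledTree:
    """Read a newick tree (file path, handle, or literal string)."""
    return LabeledTree.from_newick(path, traits=traits, transitions=transitions)


def prune_species_tree(species_tree: LabeledTree, taxa) -> LabeledTree:
    """Induced subtree on the given taxa.

    Unary nodes created by pruning are collapsed with their branch lengths
    summed, so patristic distances among retained taxa are preserved.
    Transition marks are restricted to those whose clade still intersects
    the retained taxa.
    """
    taxa = list(taxa)
    tips = set(species_tree.taxa)
    missing = [t for t in taxa if t not in tips]
    if missing:
        raise ValueError(f"taxa absent from species tree: {', '.join(missing)}")
    pruned = species_tree.copy()
    if set(taxa) != tips:
        pruned.tree.retain_taxa_with_labels(taxa)
        # dendropy can leave a unary seed node whose child edge carries the
        # stranded root-path length; collapse it.
        seed = pruned.tree.seed_node
        while len(seed.child_nodes()) == 1 and not seed.is_leaf():
            child = seed.child_nodes()[0]
            pruned.tree.seed_node = child
            child.parent_node = None
            child.edge.length = None
            seed = child
    pruned.traits = {t: species_tree.state_of(t) for t in taxa}
    keep = set(taxa)
    pruned.transitions = [
        (event, clade) for event, clade in species_tree.transitions if clade & keep
    ]
    return pruned


def patristic_distance(ltree: LabeledTree, a: str, b: str) -> float:
    pdm = ltree.tree.phylogenetic_distance_matrix()
    ta = ltree.tree.taxon_namespace.get_taxon(a)
    tb = ltree.tree.taxon_namespace.get_taxon(b)
    return pdm.patristic_distance(ta, tb)


def count_independent_transitions(
    og_taxa, species_tree: LabeledTree, event: str
) -> int:
    """Number of phylogenetically independent losses / reductions covered by
    an orthogroup.

    A transition mark counts when at least one orthogroup taxon of the
    derived state descends from the marked branch (i.e. the branch lies on
    the root-to-tip path of that taxon).
    """
    if event not in EVENT_STATE:
        raise ValueError(f"event must be 'loss' or 'reduction', got {event!r}")
    derived_state = EVENT_STATE[event]
    tips = set(species_tree.taxa)
    for t in og_taxa:
        if t not in tips:
            raise ValueError(f"taxon {t!r} absent from species tree")
    derived = {t for t in og_taxa if species_tree.state_of(t) == derived_state}
    count = 0
    for ev, clade in species_tree.transitions:
        if ev == event and clade & derived:
            count += 1
    return count
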