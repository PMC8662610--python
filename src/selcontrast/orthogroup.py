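"""Orthogroups: one validated alignment plus its pruned, trait-labeled tree."""

from __future__ import annotations

from dataclasses import dataclass, replace

from .alignment import CodonAlignment
from .trees import LabeledTree, prune_species_tree


class MissingPartitionError(ValueError):
    """An analysis needs a branch partition the orthogroup does not cover."""


@dataclass
class OrthoGroup:
    og_id: str
    alignment: CodonAlignment
    tree: LabeledTree
    annotation_group: str | None = None
    n_independent_losses: int = 0
    n_independent_reductions: int = 0

    def __post_init__(self):
        if set(self.alignment.taxa) != set(self.tree.taxa):
            raise ValueError(
                f"{self.og_id}: alignment taxa and tree tips do not coincide"
            )

    @property
    def taxa(self) -> list[str]:
        return list(self.alignment.taxa)

    def states_present(self) -> set[str]:
        return self.tree.states_present()

    def subset_for_contrast(self, contrast: str) -> "OrthoGroup":
        """Restrict to the two bristle states of a contrast.

        ``"present-absent"`` keeps present+absent species, ``"present-reduced"``
        keeps present+reduced; both states must remain represented.
        """
        derived = {"present-absent": "absent", "present-reduced": "reduced"}[contrast]
        keep = [t for t in self.taxa if self.tree.state_of(t) in ("present", derived)]
        states = {self.tree.state_of(t) for t in keep}
        if "present" not in states or derived not in states:
            raise MissingPartitionError(
                f"{self.og_id}: contrast {contrast} needs both 'present' and {derived!r} taxa"
            )
        if len(keep) == len(self.taxa):
            return self
        return replace(
            self,
            alignment=self.alignment.select_taxa(keep),
            tree=prune_species_tree(self.tree, keep),
        )

    def require_three_states(self) -> None:
        missing = {"present", "reduced", "absent"} - self.states_present()
        if missing:
            raise MissingPartitionError(
                f"{self.og_id}: three-state branch model needs all bristle states, "
                f"missing {sorted(missing)}"
            )
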