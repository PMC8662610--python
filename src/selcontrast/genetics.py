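"""Genetic code and codon state-space utilities.

Codon substitution models operate on the 61 sense codons of the standard
genetic code; stop codons are excluded from the state space.  This module
provides the canonical codon ordering, translation, and the precomputed
single-nucleotide neighbour structure (transition / transversion,
synonymous / nonsynonymous) that the rate-matrix builders consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
GAP_STATE = -1  # sentinel for gap / missing / ambiguous codons

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True if the nucleotide change a->b is a transition (purine<->purine
    or pyrimidine<->pyrimidine)."""
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code restricted to its sense codons.

    Attributes
    ----------
    codon_to_aa : dict
        Maps all 64 codons to a one-letter amino acid or ``'*'`` for stops.
    sense_codons : tuple of str
        The sense codons in lexicographic order; their positions define the
        integer codon state used throughout the package.
    """

    codon_to_aa: dict[str, str]
    sense_codons: tuple[str, ...]
    codon_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "codon_index", {c: i for i, c in enumerate(self.sense_codons)}
        )

    @property
    def n_states(self) -> int:
        return len(self.sense_codons)

    def translate_codon(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def translate(self, seq: str) -> str:
        """Translate an ungapped nucleotide sequence codon by codon.

        Codons containing non-ACGT characters translate to 'X'.
        """
        if len(seq) % 3:
            raise ValueError(f"sequence length {len(seq)} not divisible by 3")
        out = []
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            out.append(self.codon_to_aa.get(codon, "X"))
        return "".join(out)

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(codon) == "*"

    def neighbour_arrays(self):
        """Single-nucleotide-difference structure over sense codons.

        Returns (i, j, ts, syn): parallel integer/boolean arrays listing every
        ordered pair of sense codons differing at exactly one position,
        whether the change is a transition, and whether it is synonymous.
        """
        return _neighbour_arrays(self.sense_codons, tuple(sorted(self.codon_to_aa.items())))

    def aa_to_codons(self) -> dict[str, list[str]]:
        """Synonymous families: amino acid -> list of its sense codons."""
        fam: dict[str, list[str]] = {}
        for c in self.sense_codons:
            fam.setdefault(self.codon_to_aa[c], []).append(c)
        return fam


@lru_cache(maxsize=4)
def _neighbour_arrays(sense_codons, code_items):
    codon_to_aa = dict(code_items)
    idx = {c: i for i, c in enumerate(sense_codons)}
    ii, jj, ts, syn = [], [], [], []
    for a in sense_codons:
        for b in sense_codons:
            if a == b:
                continue
            diffs = [(x, y) for x, y in zip(a, b) if x != y]
            if len(diffs) != 1:
                continue
            ii.append(idx[a])
            jj.append(idx[b])
            ts.append(is_transition(*diffs[0]))
            syn.append(codon_to_aa[a] == codon_to_aa[b])
    return (
        np.asarray(ii, dtype=np.intp),
        np.asarray(jj, dtype=np.intp),
        np.asarray(ts, dtype=bool),
        np.asarray(syn, dtype=bool),
    )


@lru_cache(maxsize=1)
def standard_genetic_code() -> GeneticCode:
    """The standard genetic code (61 sense codons, 3 stops)."""
    table = CodonTable.unambiguous_dna_by_id[1]
    codon_to_aa = dict(table.forward_table)
    for stop in table.stop_codons:
        codon_to_aa[stop] = "*"
    all_codons = ["".join((a, b, c)) for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES]
    sense = tuple(c for c in all_codons if codon_to_aa[c] != "*")
    return GeneticCode(codon_to_aa=codon_to_aa, sense_codons=sense)
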