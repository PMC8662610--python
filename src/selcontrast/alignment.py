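"""Codon alignments: container, validation rules and preparation steps.

A :class:`CodonAlignment` stores one integer codon state per taxon per codon
column; the 61 sense codons map to 0..60 and anything unresolvable (gap
codon ``---``, partially gapped codons, IUPAC-ambiguous codons) is the
missing state.  Preparation mirrors the alignment pipeline used for
transcriptome-derived orthogroups: back-translate a protein alignment
against its coding sequences, drop unreliable columns, drop fragmentary
sequences, then validate (no internal stops, >= 80 nt, >= 4 taxa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetics import GAP_STATE, GeneticCode, standard_genetic_code
from .seqio import read_fasta, write_fasta

# rejection rule identifiers
RULE_INTERNAL_STOP = "internal_stop"
RULE_MIN_LENGTH = "min_length_80nt"
RULE_MIN_TAXA = "min_4_species"

MIN_LENGTH_NT = 80
MIN_TAXA = 4


@dataclass
class Rejection:
    """Rule-based rejection of an alignment, with the rule that fired."""

    rule: str
    detail: str = ""

    def __bool__(self):  # rejections are falsy so `if validated:` reads well
        return False


@dataclass
class CodonAlignment:
    taxa: list[str]
    codons: np.ndarray  # (n_taxa, n_columns) int8/int16, GAP_STATE = missing
    code: GeneticCode = field(default_factory=standard_genetic_code)

    def __post_init__(self):
        self.codons = np.asarray(self.codons, dtype=np.int16)
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise ValueError("codon matrix shape does not match taxa")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return self.codons.shape[1]

    @property
    def length_nt(self) -> int:
        return 3 * self.n_columns

    # -- construction ------------------------------------------------------
    @classmethod
    def from_sequences(cls, sequences: dict[str, str], code: GeneticCode | None = None):
        """Build from aligned nucleotide strings (lengths equal, 3|length).

        Codons with gaps or ambiguity codes become the missing state; stop
        codons are preserved as a dedicated marker so that validation can
        report them (they are never legal model states).
        """
        code = code or standard_genetic_code()
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences have unequal lengths")
        (length,) = lengths
        if length % 3:
            raise ValueError(f"alignment length {length} not divisible by 3")
        taxa = list(sequences)
        n_col = length // 3
        mat = np.full((len(taxa), n_col), GAP_STATE, dtype=np.int16)
        for r, t in enumerate(taxa):
            seq = sequences[t].upper().replace("U", "T")
            for c in range(n_col):
                codon = seq[3 * c : 3 * c + 3]
                state = code.codon_index.get(codon)
                if state is not None:
                    mat[r, c] = state
                elif code.codon_to_aa.get(codon) == "*":
                    mat[r, c] = STOP_STATE
        return cls(taxa=taxa, codons=mat, code=code)

    def to_sequences(self) -> dict[str, str]:
        out = {}
        for r, t in enumerate(self.taxa):
            parts = []
            for state in self.codons[r]:
                if state == GAP_STATE:
                    parts.append("---")
                elif state == STOP_STATE:
                    parts.append("TAA")
                else:
                    parts.append(self.code.sense_codons[state])
            out[t] = "".join(parts)
        return out

    def write_fasta(self, path):
        write_fasta(path, self.to_sequences())

    @classmethod
    def read_fasta(cls, path, code: GeneticCode | None = None):
        return cls.from_sequences(read_fasta(path), code=code)

    # -- views -------------------------------------------------------------
    def select_columns(self, keep: np.ndarray) -> "CodonAlignment":
        return CodonAlignment(list(self.taxa), self.codons[:, keep], self.code)

    def select_taxa(self, taxa: list[str]) -> "CodonAlignment":
        index = {t: i for i, t in enumerate(self.taxa)}
        rows = [index[t] for t in taxa]
        return CodonAlignment(list(taxa), self.codons[rows], self.code)

    def nongap_counts(self) -> np.ndarray:
        return (self.codons >= 0).sum(axis=1)


STOP_STATE = -2  # internal marker; never a legal likelihood state


def validate_codon_alignment(
    aln: CodonAlignment,
    min_length_nt: int = MIN_LENGTH_NT,
    min_taxa: int = MIN_TAXA,
):
    """Apply the alignment acceptance rules.

    Returns the alignment unchanged when it passes, otherwise a
    :class:`Rejection` naming the first rule that failed: internal stop
    codons, trimmed length below 80 nt, or fewer than four taxa.
    """
    if (aln.codons == STOP_STATE).any():
        rows = [aln.taxa[r] for r in np.unique(np.where(aln.codons == STOP_STATE)[0])]
        return Rejection(RULE_INTERNAL_STOP, detail=",".join(rows))
    if aln.length_nt < min_length_nt:
        return Rejection(RULE_MIN_LENGTH, detail=f"{aln.length_nt}nt")
    if aln.n_taxa < min_taxa:
        return Rejection(RULE_MIN_TAXA, detail=f"{aln.n_taxa} taxa")
    return aln


def backtranslate(
    aa_alignment: dict[str, str],
    cds: dict[str, str],
    code: GeneticCode | None = None,
) -> CodonAlignment:
    """Thread coding sequences onto a protein alignment, codon per residue.

    Each amino-acid column becomes one codon column; alignment gaps become
    gap codons.  A terminal stop codon on the CDS is tolerated and stripped.
    The translated CDS must equal the ungapped protein row; the first
    discordant position is reported otherwise.
    """
    code = code or standard_genetic_code()
    rows: dict[str, str] = {}
    for name, aa_row in aa_alignment.items():
        if name not in cds:
            raise ValueError(f"no CDS for {name}")
        nt = cds[name].upper().replace("U", "T")
        if len(nt) % 3:
            raise ValueError(f"{name}: CDS length {len(nt)} not divisible by 3")
        if len(nt) >= 3 and code.is_stop(nt[-3:]):
            nt = nt[:-3]
        aa_ungapped = aa_row.replace("-", "")
        if len(nt) != 3 * len(aa_ungapped):
            raise ValueError(
                f"{name}: CDS encodes {len(nt) // 3} residues, protein row has {len(aa_ungapped)}"
            )
        translated = code.translate(nt)
        for pos, (a, b) in enumerate(zip(translated, aa_ungapped)):
            if a != b and a != "X" and b != "X":
                raise ValueError(
                    f"{name}: translation mismatch at residue {pos + 1}: CDS gives {a}, alignment has {b}"
                )
        out = []
        k = 0
        for ch in aa_row:
            if ch == "-":
                out.append("---")
            else:
                out.append(nt[3 * k : 3 * k + 3])
                k += 1
        rows[name] = "".join(out)
    return CodonAlignment.from_sequences(rows, code=code)


def trim_columns_by_score(
    aln: CodonAlignment, scores, threshold: float = 3.0
) -> CodonAlignment:
    """Drop codon columns whose amino-acid column score is <= threshold.

    Scores come from an external per-column reliability scorer (one score per
    amino-acid column, hence per codon column); remaining column order is
    preserved.
    """
    scores = np.asarray(list(scores), dtype=float)
    if scores.size != aln.n_columns:
        raise ValueError(
            f"{scores.size} scores for {aln.n_columns} codon columns"
        )
    return aln.select_columns(scores > threshold)


def drop_short_sequences(aln: CodonAlignment, min_fraction: float = 0.5) -> CodonAlignment:
    """Remove rows whose gap-less length is below min_fraction of the
    alignment length (fragmentary transcripts)."""
    frac = aln.nongap_counts() / max(aln.n_columns, 1)
    keep = [t for t, f in zip(aln.taxa, frac) if f >= min_fraction]
    if len(keep) == aln.n_taxa:
        return aln
    return aln.select_taxa(keep)
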