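"""Counting-method synonymous divergence (Nei-Gojobori 1986 style).

Used as an alignment diagnostic: a systematic difference in average
pairwise dS between species groups would confound dN/dS comparisons.
Sites are partitioned into synonymous and nonsynonymous fractions per
codon position, multi-position codon differences are averaged over
mutational pathways (pathways through stop codons are skipped), and the
proportion of synonymous differences is Jukes-Cantor corrected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .alignment import CodonAlignment
from .genetics import NUCLEOTIDES, GeneticCode, standard_genetic_code

SATURATION_P = 0.75


@lru_cache(maxsize=None)
def _synonymous_sites(codon: str, code_id: int = 1) -> float:
    """Synonymous site count of a codon (out of 3), stops excluded from
    the possible-change sets."""
    code = standard_genetic_code()
    aa = code.codon_to_aa[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if code.codon_to_aa[alt] == "*":
                continue
            valid += 1
            if code.codon_to_aa[alt] == aa:
                syn += 1
        if valid:
            total += syn / valid
    return total


@lru_cache(maxsize=None)
def _pairwise_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons,
    averaged over mutational pathways that avoid stop codons."""
    code = standard_genetic_code()
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    syn_counts = []
    for order in itertools.permutations(positions):
        current = c1
        syn = 0.0
        ok = True
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if code.codon_to_aa[nxt] == "*":
                ok = False
                break
            if code.codon_to_aa[current] == code.codon_to_aa[nxt]:
                syn += 1.0
            current = nxt
        if ok:
            syn_counts.append(syn)
    if not syn_counts:  # every pathway passes a stop; count all as nonsynonymous
        return 0.0, float(len(positions))
    mean_syn = sum(syn_counts) / len(syn_counts)
    return mean_syn, len(positions) - mean_syn


def pairwise_ds(seq1_states, seq2_states, code: GeneticCode) -> float | None:
    """NG86 dS between two rows of codon states; None when saturated or
    when no synonymous sites are shared."""
    s_sites = 0.0
    s_diff = 0.0
    for a, b in zip(seq1_states, seq2_states):
        if a < 0 or b < 0:
            continue
        ca, cb = code.sense_codons[a], code.sense_codons[b]
        s_sites += 0.5 * (_synonymous_sites(ca) + _synonymous_sites(cb))
        sd, _ = _pairwise_differences(ca, cb)
        s_diff += sd
    if s_sites == 0:
        return None
    ps = s_diff / s_sites
    if ps >= SATURATION_P:
        return None
    return float(-0.75 * np.log(1.0 - 4.0 * ps / 3.0))


@dataclass
class MeanPairwiseDS:
    mean: float | None
    n_pairs: int
    n_saturated: int


def pairwise_ds_ng86(alignment: CodonAlignment) -> MeanPairwiseDS:
    """Mean pairwise dS over all sequence pairs of an alignment.

    Saturated pairs (proportion of synonymous differences >= 0.75) are
    excluded from the mean and counted; an all-saturated alignment yields
    mean None.
    """
    if alignment.n_taxa < 2:
        raise ValueError("need at least two sequences")
    values = []
    saturated = 0
    for i, j in itertools.combinations(range(alignment.n_taxa), 2):
        ds = pairwise_ds(alignment.codons[i], alignment.codons[j], alignment.code)
        if ds is None:
            saturated += 1
        else:
            values.append(ds)
    n_pairs = saturated + len(values)
    mean = float(np.mean(values)) if values else None
    return MeanPairwiseDS(mean=mean, n_pairs=n_pairs, n_saturated=saturated)
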