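"""GY94-style codon rate matrices and their matrix exponentials.

The generator over the 61 sense codons has off-diagonal entries only
between codons differing at a single nucleotide position:

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

Matrices are scaled so the expected substitution rate at equilibrium is 1,
putting branch lengths in expected substitutions per codon.  For site-class
mixtures a *common* scale must be used across classes (scaling each class
to rate 1 would erase the dN differences between classes that carry the
signal); :func:`mixture_scale` computes the proportion-weighted mean rate.

Time-reversibility makes the symmetrized generator amenable to a single
eigendecomposition per (kappa, omega) from which P(t) for every branch is
cheap; :class:`EigenSystem` caches that decomposition.
"""

from __future__ import annotations

import numpy as np

from ..genetics import GeneticCode, standard_genetic_code


def build_rate_matrix(
    pi: np.ndarray,
    kappa: float,
    omega: float,
    code: GeneticCode | None = None,
    scale: bool = True,
):
    """GY94 generator for one omega class.

    Returns (Q, rate) where ``rate`` is the expected substitution rate at
    equilibrium of the *unscaled* matrix; if ``scale`` the returned Q is
    divided by it (rows always sum to zero).
    """
    code = code or standard_genetic_code()
    pi = np.asarray(pi, dtype=float)
    n = code.n_states
    ii, jj, ts, syn = code.neighbour_arrays()
    rates = pi[jj].copy()
    rates[ts] *= kappa
    rates[~syn] *= omega
    Q = np.zeros((n, n))
    Q[ii, jj] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = float(-(pi * np.diag(Q)).sum())
    if scale:
        if rate <= 0:
            raise ValueError("degenerate rate matrix (zero equilibrium rate)")
        Q = Q / rate
    return Q, rate


def equilibrium_rate(pi, kappa, omega, code=None) -> float:
    """Expected substitutions per codon per unit time of the unscaled
    generator — the scaling constant for this omega class."""
    _, rate = build_rate_matrix(pi, kappa, omega, code=code, scale=False)
    return rate


def mixture_scale(pi, kappa, omegas, proportions, code=None) -> float:
    """Common scaling constant for a site-class mixture: the
    proportion-weighted mean equilibrium rate across classes."""
    total = 0.0
    for w, p in zip(omegas, proportions):
        total += p * equilibrium_rate(pi, kappa, w, code=code)
    return total


class EigenSystem:
    """Spectral decomposition of a reversible generator.

    With D = diag(pi), the matrix S = D^1/2 Q D^-1/2 is symmetric; from its
    eigenpairs, P(t) = D^-1/2 U exp(L t) U' D^1/2 for any t >= 0.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        sqrt_pi = np.sqrt(pi)
        S = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        S = 0.5 * (S + S.T)  # enforce exact symmetry against round-off
        lam, U = np.linalg.eigh(S)
        self.lam = lam
        self.left = U / sqrt_pi[:, None]          # D^-1/2 U
        self.right = (U * sqrt_pi[:, None]).T     # U' D^1/2
        self.pi = pi

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError(f"negative branch length {t}")
        # positive round-off eigenvalues of huge-rate generators can
        # overflow exp at large t; the true eigenvalues are all <= 0
        P = (self.left * np.exp(np.minimum(self.lam * t, 0.0))) @ self.right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def transition_probabilities(Q: np.ndarray, t: float, pi: np.ndarray | None = None) -> np.ndarray:
    """P(t) = exp(Qt).

    Uses the reversible eigendecomposition when pi is supplied, otherwise a
    direct Pade matrix exponential.
    """
    if t < 0:
        raise ValueError(f"negative time {t}")
    if pi is not None:
        return EigenSystem(Q, pi).transition_matrix(t)
    from scipy.linalg import expm

    P = expm(Q * t)
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def estimate_f3x4(alignment, pseudocount: float = 0.5) -> np.ndarray:
    """F3x4 equilibrium codon frequencies from an alignment.

    Nucleotide frequencies are tallied separately for the three codon
    positions (with a pseudocount per nucleotide per position so no sense
    codon gets zero mass), multiplied per codon, stop codons zeroed, and
    the result renormalized over the 61 sense codons.
    """
    code = alignment.code
    counts = np.full((3, 4), pseudocount, dtype=float)
    nt_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    states = alignment.codons
    for s in states[states >= 0]:
        codon = code.sense_codons[s]
        for pos, ch in enumerate(codon):
            counts[pos, nt_index[ch]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.empty(code.n_states)
    for i, codon in enumerate(code.sense_codons):
        pi[i] = freqs[0, nt_index[codon[0]]] * freqs[1, nt_index[codon[1]]] * freqs[2, nt_index[codon[2]]]
    return pi / pi.sum()


def uniform_frequencies(code: GeneticCode | None = None) -> np.ndarray:
    code = code or standard_genetic_code()
    return np.full(code.n_states, 1.0 / code.n_states)
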