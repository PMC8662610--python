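"""Felsenstein pruning over compressed site patterns for mixture models.

The engine evaluates, for each site class of a mixture, the per-pattern
likelihood by postorder pruning with branch-partition-specific transition
matrices, using per-node rescaling to avoid underflow.  A site class is a
proportion together with, for every branch partition label, the omega that
applies there and the scaling constant that converts the branch length into
time for the unscaled generator (see :mod:`.matrices` for why mixtures need
a common scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..alignment import CodonAlignment
from ..genetics import GAP_STATE
from ..trees import LabeledTree
from .matrices import EigenSystem, build_rate_matrix


@dataclass
class SiteClass:
    """One class of a site mixture.

    ``omega_by_label`` maps branch partition labels to the omega in force on
    branches of that partition; ``rho_by_label`` gives the rate-scaling
    divisor for the same branches (equal across labels for site mixtures,
    per-label for pure branch models).
    """

    proportion: float
    omega_by_label: dict[int, float]
    rho_by_label: dict[int, float]

    def omega(self, label: int) -> float:
        return self.omega_by_label.get(label, self.omega_by_label[0])

    def rho(self, label: int) -> float:
        return self.rho_by_label.get(label, self.rho_by_label[0])


class TreeIndex:
    """Array representation of a labeled tree for fast pruning.

    Nodes are numbered in postorder (root last).  Terminal branches carry
    the partition label of their tip; internal branches are background (0).
    """

    def __init__(self, ltree: LabeledTree, labels_by_taxon: dict[str, int] | None = None):
        ltree.require_branch_lengths()
        labels_by_taxon = labels_by_taxon or {}
        nodes = list(ltree.tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.children: list[list[int]] = [[] for _ in nodes]
        self.lengths = np.zeros(self.n_nodes)
        self.labels = np.zeros(self.n_nodes, dtype=int)
        self.taxon_of: dict[int, str] = {}
        self.tip_node: dict[str, int] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                self.lengths[i] = nd.edge.length or 0.0
            for child in nd.child_nodes():
                self.children[i].append(index[id(child)])
            if nd.is_leaf():
                name = nd.taxon.label
                self.taxon_of[i] = name
                self.tip_node[name] = i
                self.labels[i] = labels_by_taxon.get(name, 0)
        self.root = self.n_nodes - 1
        self.postorder_internal = [i for i in range(self.n_nodes) if self.children[i]]

    @property
    def taxa(self) -> list[str]:
        return sorted(self.tip_node)


def compress_patterns(alignment: CodonAlignment):
    """Unique site patterns with multiplicities.

    Returns (patterns, counts, column_to_pattern): patterns is
    (n_patterns, n_taxa) of codon states with GAP_STATE for missing.
    """
    cols = np.ascontiguousarray(alignment.codons.T)
    patterns, inverse, counts = np.unique(
        cols, axis=0, return_inverse=True, return_counts=True
    )
    return patterns, counts.astype(float), inverse.ravel()


def class_pattern_loglikes(
    tindex: TreeIndex,
    patterns: np.ndarray,
    taxa: list[str],
    pi: np.ndarray,
    kappa: float,
    site_class: SiteClass,
    branch_scale: float = 1.0,
    code=None,
    eigen_cache: dict | None = None,
) -> np.ndarray:
    """Log-likelihood of every pattern under a single site class."""
    n_states = pi.shape[0]
    n_patterns = patterns.shape[0]
    col_of = {t: j for j, t in enumerate(taxa)}

    eigens = eigen_cache if eigen_cache is not None else {}

    def eigen_for(omega: float) -> EigenSystem:
        key = (kappa, omega)
        if key not in eigens:
            if len(eigens) > 512:
                eigens.clear()
            Q, _ = build_rate_matrix(pi, kappa, omega, code=code, scale=False)
            eigens[key] = EigenSystem(Q, pi)
        return eigens[key]

    partials = {}
    log_scale = np.zeros(n_patterns)
    for node in range(tindex.n_nodes):
        if not tindex.children[node]:
            states = patterns[:, col_of[tindex.taxon_of[node]]]
            L = np.zeros((n_patterns, n_states))
            observed = states >= 0
            L[~observed, :] = 1.0
            L[np.nonzero(observed)[0], states[observed]] = 1.0
            partials[node] = L

    for node in tindex.postorder_internal:
        L = np.ones((n_patterns, n_states))
        for child in tindex.children[node]:
            label = int(tindex.labels[child]) if not tindex.children[child] else 0
            omega = site_class.omega(label)
            t = tindex.lengths[child] * branch_scale / site_class.rho(label)
            P = eigen_for(omega).transition_matrix(t)
            L *= partials.pop(child) @ P.T
        scale = L.max(axis=1)
        scale[scale == 0] = 1.0
        L /= scale[:, None]
        log_scale += np.log(scale)
        partials[node] = L

    root_L = partials[tindex.root]
    site_like = root_L @ pi
    with np.errstate(divide="ignore"):
        return np.log(site_like) + log_scale


def mixture_pattern_loglikes(
    tindex, patterns, taxa, pi, kappa, classes, branch_scale=1.0, code=None,
    eigen_cache: dict | None = None,
) -> np.ndarray:
    """(n_classes, n_patterns) matrix of per-class pattern log-likelihoods."""
    return np.vstack(
        [
            class_pattern_loglikes(
                tindex, patterns, taxa, pi, kappa, c, branch_scale, code=code,
                eigen_cache=eigen_cache,
            )
            for c in classes
        ]
    )


def mixture_loglike(class_logl: np.ndarray, proportions, counts) -> float:
    """Total lnL = sum_p m_p * ln sum_c w_c L_p(c), in log space."""
    w = np.asarray(proportions, dtype=float)
    logw = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf)
    a = class_logl + logw[:, None]
    amax = a.max(axis=0)
    total = amax + np.log(np.exp(a - amax).sum(axis=0))
    return float((counts * total).sum())


def log_likelihood(
    alignment: CodonAlignment,
    ltree: LabeledTree,
    classes: list[SiteClass],
    pi: np.ndarray,
    kappa: float,
    labels_by_taxon=None,
    branch_scale: float = 1.0,
) -> float:
    """Convenience one-shot mixture log-likelihood of an alignment on a tree."""
    if set(alignment.taxa) != set(ltree.taxa):
        raise ValueError("alignment taxa and tree tips do not coincide")
    tindex = TreeIndex(ltree, labels_by_taxon)
    patterns, counts, _ = compress_patterns(alignment)
    class_logl = mixture_pattern_loglikes(
        tindex, patterns, alignment.taxa, pi, kappa, classes, branch_scale,
        code=alignment.code,
    )
    return mixture_loglike(class_logl, [c.proportion for c in classes], counts)
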