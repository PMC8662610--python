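"""Synthetic study generator.

Produces every input the analysis pipeline consumes — a species tree with
labeled trait transitions, per-orthogroup codon data evolved under the
package's own substitution models, alignment-reliability scores, and an
annotation table with expression levels — together with a ground-truth
manifest, so each downstream inference is testable as a recovery problem.

The generator emulates the statistical structure the analysis assumes:
reproduction-related annotation groups evolve faster than ubiquitously
expressed ones, lineages that lost or reduced the trait evolve faster than
those retaining it (or, under the ``relax`` regime, have their omega
distribution flattened by k < 1), and expression level is negatively
rank-correlated with omega.  It does not emulate assembly artifacts
(chimeras, fragmented transcripts) beyond optional uniform gap injection.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .alignment import CodonAlignment
from .genetics import standard_genetic_code
from .models.branch import branch_omega_classes, single_omega_class
from .models.branchsite import model_a_classes
from .models.likelihood import SiteClass, TreeIndex
from .models.matrices import EigenSystem, build_rate_matrix, uniform_frequencies
from .models.relax import relax_classes
from .orthology import HomologTree
from .seqio import AnnotationTable, ensure_dir, write_column_scores, write_fasta
from .trees import LabeledTree, _parse_newick

REFERENCE_SPECIES = "sp01"  # annotation donor; always bristles-present


@dataclass
class StudyDesign:
    """Parameters of the synthetic mini-study.

    Omega means are lognormal medians for the bristles-present state; the
    reduced/absent multipliers impose the faster evolution in derived
    lineages; under the ``relax`` regime derived terminal branches instead
    get the three-category omega distribution raised to ``relax_k``.
    """

    n_species: int = 16
    n_outgroup: int = 2
    n_losses: int = 3
    n_reductions: int = 2
    n_ogs: dict = field(
        default_factory=lambda: {
            "testis-region": 40, "ovary-region": 10, "tail-region": 10, "ubiquitous": 20,
        }
    )
    omega_group_median: dict = field(
        default_factory=lambda: {
            "testis-region": 0.22, "ovary-region": 0.20, "tail-region": 0.20, "ubiquitous": 0.08,
        }
    )
    omega_sigma: float = 0.35          # lognormal sd on the log scale
    reduced_multiplier: float = 1.6
    absent_multiplier: float = 2.5
    regime: str = "branch3"            # or "relax"
    relax_k: float = 1.0
    relax_omegas: tuple = (0.05, 0.4, 1.5)
    relax_proportions: tuple = (0.5, 0.4, 0.1)
    kappa: float = 2.0
    n_codons: int = 300
    tree_height: float = 0.5           # expected substitutions/codon, root to tip
    species_dropout: float = 0.1       # per-OG chance a non-reference species is absent
    low_score_fraction: float = 0.1
    expression_rho: float = -0.6
    gap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 4 or self.n_outgroup < 1:
            raise ValueError("need >= 4 ingroup species and >= 1 outgroup")
        for v in self.n_ogs.values():
            if v < 1:
                raise ValueError("n_ogs counts must be >= 1")


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def _yule_newick(names: list[str], rng: np.random.Generator, height: float) -> str:
    """Ultrametric pure-birth tree over the given tips, scaled to height."""
    if len(names) == 1:
        return f"{names[0]}:{height:.6f}"
    # grow: start with two lineages, split a random lineage at each event
    events = [0.0, 0.0]
    times = [0.0]
    t = 0.0
    n = 2
    while n < len(names):
        t += rng.exponential(1.0 / n)
        times.append(t)
        n += 1
    t_end = t + rng.exponential(1.0 / n)
    # recursive construction over (sorted) split times
    def build(tips: list[str], start: float, splits: list[float]) -> str:
        if len(tips) == 1:
            return f"{tips[0]}:{(t_end - start) * height / t_end:.6f}"
        split = splits[0]
        k = 1 + rng.integers(0, len(tips) - 1)
        left_tips, right_tips = tips[:k], tips[k:]
        remaining = splits[1:]
        left_splits, right_splits = _distribute(remaining, len(left_tips), len(right_tips), rng)
        left = build(left_tips, split, left_splits)
        right = build(right_tips, split, right_splits)
        stem = (split - start) * height / t_end
        return f"({left},{right}):{stem:.6f}"

    shuffled = list(names)
    rng.shuffle(shuffled)
    body = build(shuffled, 0.0, sorted(times))
    return body.rsplit(":", 1)[0]  # strip the zero-length root stem


def _distribute(splits, n_left, n_right, rng):
    splits = sorted(splits)
    need_left, need_right = n_left - 1, n_right - 1
    left, right = [], []
    for s in splits:
        if len(left) < need_left and len(right) < need_right:
            (left if rng.random() < 0.5 else right).append(s)
        elif len(left) < need_left:
            left.append(s)
        else:
            right.append(s)
    return left, right


def simulate_species_tree(design: StudyDesign, seed: int | None = None) -> LabeledTree:
    """Pure-birth ingroup scaled to height 1, outgroup attached basally,
    with loss/reduction transition marks on non-nested ingroup branches."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    ingroup = [f"sp{i + 1:02d}" for i in range(design.n_species)]
    outgroup = [f"out{i + 1:02d}" for i in range(design.n_outgroup)]
    in_nwk = _yule_newick(ingroup, rng, 0.75)
    out_nwk = _yule_newick(outgroup, rng, 0.25)
    newick = f"(({in_nwk}):0.25,({out_nwk}):0.75);"
    ltree = LabeledTree.from_newick(newick)

    # candidate transition branches: ingroup clades that exclude the
    # reference species; non-nested and mutually disjoint
    tree = ltree.tree
    candidates = []
    max_clade = max(1, design.n_species // 4)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        tips = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if REFERENCE_SPECIES in tips or any(t.startswith("out") for t in tips):
            continue
        if len(tips) <= max_clade:
            candidates.append(tips)
    order = rng.permutation(len(candidates))
    chosen: list[frozenset] = []
    needed = design.n_losses + design.n_reductions
    for idx in order:
        if len(chosen) == needed:
            break
        clade = candidates[idx]
        if all(not (clade & c) for c in chosen):
            chosen.append(clade)
    if len(chosen) < needed:
        raise ValueError(
            f"cannot place {needed} non-nested transitions on {design.n_species} species"
        )
    transitions = [("loss", c) for c in chosen[: design.n_losses]] + [
        ("reduction", c) for c in chosen[design.n_losses :]
    ]
    traits = {t: "present" for t in ingroup + outgroup}
    for event, clade in transitions:
        state = "absent" if event == "loss" else "reduced"
        for t in clade:
            traits[t] = state
    ltree.traits = traits
    ltree.transitions = transitions
    return ltree


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def simulate_codon_alignment(
    ltree: LabeledTree,
    classes: list[SiteClass],
    n_codons: int,
    seed: int,
    *,
    pi: np.ndarray | None = None,
    kappa: float = 2.0,
    branch_scale: float = 1.0,
    labels_by_taxon: dict | None = None,
    code=None,
):
    """Evolve codons along the tree under a site-class mixture.

    Returns (CodonAlignment over the tree's tips, per-site class indices).
    The site class is sampled once per site and applies on every branch —
    the same structure the likelihood engine assumes.
    """
    code = code or standard_genetic_code()
    rng = np.random.default_rng(seed)
    pi = uniform_frequencies(code) if pi is None else np.asarray(pi, dtype=float)
    if labels_by_taxon is None:
        labels_by_taxon = ltree.terminal_labels()
    tindex = TreeIndex(ltree, labels_by_taxon)
    props = np.array([c.proportion for c in classes], dtype=float)
    props = props / props.sum()
    site_class = rng.choice(len(classes), size=n_codons, p=props)

    eigens: dict[float, EigenSystem] = {}

    def eigen_for(w: float) -> EigenSystem:
        if w not in eigens:
            Q, _ = build_rate_matrix(pi, kappa, w, code=code, scale=False)
            eigens[w] = EigenSystem(Q, pi)
        return eigens[w]

    states = {tindex.root: rng.choice(pi.size, size=n_codons, p=pi / pi.sum())}
    for node in reversed(range(tindex.n_nodes)):  # preorder: root first
        if node not in states:
            continue
        parent_states = states[node]
        for child in tindex.children[node]:
            label = int(tindex.labels[child]) if not tindex.children[child] else 0
            child_states = np.empty(n_codons, dtype=np.int64)
            for ci, cls in enumerate(classes):
                sites = np.nonzero(site_class == ci)[0]
                if sites.size == 0:
                    continue
                t = tindex.lengths[child] * branch_scale / cls.rho(label)
                P = eigen_for(cls.omega(label)).transition_matrix(t)
                cum = np.cumsum(P, axis=1)
                u = rng.random(sites.size)
                child_states[sites] = np.array(
                    [
                        np.searchsorted(cum[parent_states[s]], uu, side="right")
                        for s, uu in zip(sites, u)
                    ]
                )
            np.clip(child_states, 0, pi.size - 1, out=child_states)
            states[child] = child_states

    taxa = sorted(tindex.tip_node)
    mat = np.vstack([states[tindex.tip_node[t]] for t in taxa]).astype(np.int16)
    aln = CodonAlignment(taxa=taxa, codons=mat, code=code)
    return aln, site_class


def regime_classes(regime: str, params: dict, pi=None, kappa: float = 2.0, code=None):
    """Site classes for a named simulation regime, built with the same
    constructors the models fit with."""
    code = code or standard_genetic_code()
    pi = uniform_frequencies(code) if pi is None else pi
    if regime == "m0":
        return single_omega_class(params["omega"], pi, kappa, code)
    if regime == "branch3":
        omegas = {0: params["omega_present"], 1: params["omega_reduced"], 2: params["omega_absent"]}
        return branch_omega_classes(omegas, pi, kappa, code)
    if regime == "modelA":
        return model_a_classes(
            params["p0"], params["p1"], params["omega0"], params["omega2"],
            pi, kappa, params.get("foreground_label", 1), code,
        )
    if regime == "relax":
        return relax_classes(
            params["omegas"], params["proportions"], params["k"],
            params.get("test_label", 1), pi=pi, kappa=kappa, code=code,
        )
    raise ValueError(f"unknown regime {regime!r}")


# ---------------------------------------------------------------------------
# homolog trees (fixtures for the ortholog pruner)
# ---------------------------------------------------------------------------

@dataclass
class GeneTreeTruth:
    """Ground truth of a simulated gene tree.

    ``partition``: the tip-sets obtained by splitting the gene tree at
    duplication nodes (each has at most one copy per species).
    ``paralog_pairs``: every tip pair whose MRCA is a duplication node; an
    inferred orthogroup is paralog-free iff it contains none of them.
    """

    partition: list[frozenset]
    paralog_pairs: set[frozenset]

    def is_ortholog_set(self, og) -> bool:
        og = list(og)
        for i in range(len(og)):
            for j in range(i + 1, len(og)):
                if frozenset((og[i], og[j])) in self.paralog_pairs:
                    return False
        return True


class _GeneNode:
    __slots__ = ("children", "length", "label", "is_dup")

    def __init__(self, length=0.0, label=None):
        self.children = []
        self.length = length
        self.label = label
        self.is_dup = False

    def newick(self):
        if not self.children:
            return f"{self.label}:{self.length:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.6f}"


def simulate_homolog_tree(
    species_tree: LabeledTree,
    dup_rate: float = 0.1,
    loss_rate: float = 0.05,
    seed: int = 0,
    max_attempts: int = 10,
):
    """Gene tree evolved within the species tree by Poisson birth-death of
    copies (rates per species-tree branch).

    Returns (HomologTree, true ortholog partition) where the partition is
    the gene tree split at duplication nodes — each part has at most one
    copy per species.  Tips are ``species@cN``; aligned_columns are drawn
    uniformly from [100, 400].
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    sp_root = species_tree.tree.seed_node
    counter = [0]
    p_loss = 1.0 - np.exp(-loss_rate) if loss_rate > 0 else 0.0

    def evolve(sp_node, length):
        """One gene lineage entering the branch above sp_node; None if the
        whole downstream is lost."""
        if sp_node.is_leaf():
            counter[0] += 1
            node = _GeneNode(length=length)
            node.label = f"{sp_node.taxon.label}@c{counter[0]}"
            return node
        gnode = _GeneNode(length=length)
        for child in sp_node.child_nodes():
            blen = child.edge.length or 0.0
            n_copies = 1 + rng.poisson(dup_rate)
            subs = []
            for _ in range(n_copies):
                if rng.random() < p_loss:
                    continue
                sub = evolve(child, blen * rng.uniform(0.6, 1.0))
                if sub is not None:
                    subs.append(sub)
            if not subs:
                continue
            # chain surviving copies through duplication nodes on the branch
            lineage = subs[0]
            for twin in subs[1:]:
                dup = _GeneNode(length=blen * rng.uniform(0.0, 0.4))
                dup.is_dup = True
                dup.children = [lineage, twin]
                lineage = dup
            gnode.children.append(lineage)
        return gnode if gnode.children else None

    for attempt in range(max_attempts):
        counter[0] = 0
        root = evolve(sp_root, 0.0)
        if root is None:
            continue

        def squash(node):
            # collapse unary passthrough nodes, summing lengths; a unary
            # duplication is unobservable and loses its flag
            while len(node.children) == 1:
                child = node.children[0]
                child.length += node.length
                node = child
            node.children = [squash(c) for c in node.children]
            return node

        root = squash(root)

        def tips(node):
            if not node.children:
                return [node.label]
            return [t for c in node.children for t in tips(c)]

        all_tips = tips(root)
        if len(all_tips) >= 2:
            break
    else:
        raise RuntimeError("all gene lineages lost in every attempt")

    def partition(node):
        """(open part reachable upward without crossing a duplication,
        list of closed parts)."""
        if not node.children:
            return [node.label], []
        opens, closed = [], []
        for child in node.children:
            o, c = partition(child)
            opens.append(o)
            closed.extend(c)
        if node.is_dup:
            closed.extend(o for o in opens if o)
            return [], closed
        return [t for o in opens for t in o], closed

    open_part, closed_parts = partition(root)
    parts = ([open_part] if open_part else []) + closed_parts
    true_orthologs = [frozenset(p) for p in parts]

    # all pairs of tips whose gene-tree MRCA is a duplication node: any
    # orthogroup containing such a pair has merged paralogs
    paralog_pairs: set[frozenset] = set()

    def collect_dup_pairs(node):
        if not node.children:
            return [node.label]
        child_tips = [collect_dup_pairs(c) for c in node.children]
        if node.is_dup:
            for a in child_tips[0]:
                for b in child_tips[1]:
                    paralog_pairs.add(frozenset((a, b)))
        return [t for ct in child_tips for t in ct]

    collect_dup_pairs(root)
    aligned_columns = {t: int(rng.integers(100, 401)) for t in all_tips}
    htree = HomologTree.from_newick(root.newick() + ";", aligned_columns)
    return htree, GeneTreeTruth(partition=true_orthologs, paralog_pairs=paralog_pairs)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def _gaussian_rank(values, rng):
    noise = rng.normal(0, 1e-9, size=len(values))
    order = np.argsort(np.asarray(values) + noise)
    ranks = np.empty(len(values))
    ranks[order] = np.arange(1, len(values) + 1)
    from scipy.stats import norm

    return norm.ppf(ranks / (len(values) + 1))


def generate_study(design: StudyDesign, outdir, seed: int | None = None) -> dict:
    """Write a complete synthetic study to ``outdir`` and return the manifest.

    Layout: species_tree.nwk, traits.tsv, transitions.tsv, annotation.tsv,
    manifest.json, and per orthogroup ogs/<og>.aa.fasta (aligned protein),
    ogs/<og>.cds.fasta (unaligned CDS), ogs/<og>.scores.tsv.
    """
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    code = standard_genetic_code()
    pi = uniform_frequencies(code)
    outdir = ensure_dir(outdir)
    ogdir = ensure_dir(os.path.join(outdir, "ogs"))

    species_tree = simulate_species_tree(design, seed=seed)
    species_tree.write_newick(os.path.join(outdir, "species_tree.nwk"))
    species_tree.write_traits(os.path.join(outdir, "traits.tsv"))
    species_tree.write_transitions(os.path.join(outdir, "transitions.tsv"))

    ingroup = [f"sp{i + 1:02d}" for i in range(design.n_species)]
    manifest: dict = {"design_seed": seed, "regime": design.regime, "ogs": {}}
    annotation = AnnotationTable()
    og_records = []
    og_num = 0
    for group, count in design.n_ogs.items():
        for _ in range(count):
            og_num += 1
            og_id = f"og{og_num:04d}"
            og_records.append((og_id, group))

    true_omegas = []
    for og_id, group in og_records:
        base = design.omega_group_median[group] * float(
            np.exp(rng.normal(0.0, design.omega_sigma))
        )
        base = min(base, 2.0)
        true_omegas.append(base)

    # expression negatively rank-correlated with the present-state omega
    z_omega = _gaussian_rank(true_omegas, rng)
    rho = design.expression_rho
    z_expr = rho * z_omega + np.sqrt(max(1 - rho**2, 0.0)) * rng.normal(size=len(true_omegas))
    expression = np.exp(5.0 + 1.2 * z_expr)

    from .trees import prune_species_tree

    for i, (og_id, group) in enumerate(og_records):
        og_seed = int(rng.integers(0, 2**31 - 1))
        og_rng = np.random.default_rng(og_seed)
        keep = [REFERENCE_SPECIES] + [
            sp for sp in ingroup if sp != REFERENCE_SPECIES
            and og_rng.random() > design.species_dropout
        ]
        subtree = prune_species_tree(species_tree, keep)
        w_present = true_omegas[i]
        entry = {"group": group, "taxa": keep, "seed": og_seed}
        if design.regime == "branch3":
            w_reduced = min(w_present * design.reduced_multiplier, 5.0)
            w_absent = min(w_present * design.absent_multiplier, 5.0)
            classes = regime_classes(
                "branch3",
                {"omega_present": w_present, "omega_reduced": w_reduced, "omega_absent": w_absent},
                pi=pi, kappa=design.kappa, code=code,
            )
            entry.update(
                omega_present=w_present, omega_reduced=w_reduced, omega_absent=w_absent
            )
            labels = subtree.terminal_labels()
        elif design.regime == "relax":
            classes = regime_classes(
                "relax",
                {"omegas": design.relax_omegas, "proportions": design.relax_proportions,
                 "k": design.relax_k},
                pi=pi, kappa=design.kappa, code=code,
            )
            entry.update(
                omega_present=w_present, k=design.relax_k,
                omegas=list(design.relax_omegas), proportions=list(design.relax_proportions),
            )
            labels = subtree.terminal_labels("present-absent")
        else:
            raise ValueError(f"unknown study regime {design.regime!r}")
        aln, site_class = simulate_codon_alignment(
            subtree, classes, design.n_codons, og_seed,
            pi=pi, kappa=design.kappa, branch_scale=design.tree_height,
            labels_by_taxon=labels, code=code,
        )
        if design.gap_fraction > 0:
            mask = og_rng.random(aln.codons.shape) < design.gap_fraction
            aln.codons[mask] = -1
        seqs = aln.to_sequences()
        cds = {f"{t}@{og_id}": seqs[t].replace("-", "") for t in aln.taxa}
        aa = {}
        for t in aln.taxa:
            row = seqs[t]
            aa_row = []
            for c in range(0, len(row), 3):
                codon = row[c : c + 3]
                aa_row.append("-" if "-" in codon else code.codon_to_aa.get(codon, "X"))
            aa[f"{t}@{og_id}"] = "".join(aa_row)
        write_fasta(os.path.join(ogdir, f"{og_id}.cds.fasta"), cds)
        write_fasta(os.path.join(ogdir, f"{og_id}.aa.fasta"), aa)
        n_col = design.n_codons
        low = og_rng.random(n_col) < design.low_score_fraction
        scores = np.where(
            low, og_rng.integers(1, 4, size=n_col), og_rng.integers(4, 11, size=n_col)
        )
        write_column_scores(os.path.join(ogdir, f"{og_id}.scores.tsv"), scores)
        ref_transcript = f"{REFERENCE_SPECIES}@{og_id}"
        annotation.group[ref_transcript] = group
        annotation.expression[ref_transcript] = float(expression[i])
        manifest["ogs"][og_id] = entry

    annotation.write(os.path.join(outdir, "annotation.tsv"))
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
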