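# selcontrast

Maximum-likelihood codon models for contrasting selection regimes across
lineages, with the tree-based orthology and statistics layers needed to run
the contrast genome-wide.

## The problem

Comparative transcriptomics of lineages that differ in a morphological
trait — here, sperm-bristle state (present / reduced / absent) across a
genus of free-living flatworms, a proxy for mating strategy — asks whether
molecular sequence evolution differs systematically between trait states.
The signal of interest lives in ω = dN/dS, the ratio of nonsynonymous to
synonymous substitution rates of a protein-coding gene: ω < 1 indicates
purifying selection, ω ≈ 1 neutrality, ω > 1 positive selection.
`selcontrast` implements the full desk-side analysis:

* **Orthology**: prune homolog gene trees (paralogs, isoforms, assembly
  redundancy) into one-sequence-per-species orthogroups via long-tip
  trimming, single-species-clade masking, deep-paralog cutting, and the
  rooted-ingroups (RT) + maximum-inclusion (MI) extraction algorithms.
* **Alignment preparation**: back-translation of protein alignments to
  codon alignments, reliability-score column trimming, fragmentary-sequence
  and stop-codon/length/taxon-count filters, species-tree pruning.
* **Codon models** (GY94 rate matrix, F3x4 frequencies, Felsenstein pruning
  with site-pattern compression): single-ω; branch models with one ω per
  trait state on terminal branches (LRT, 2 df); branch-site model A and its
  null (site classes 0/1/2a/2b, ω2 ≥ 1 on foreground branches only, with
  empirical-Bayes identification of selected sites at posterior > 0.95);
  and selection-intensity models in which the test branches' three-category
  ω distribution is the reference distribution raised to an exponent k
  (k < 1 relaxed, k > 1 intensified; LRT, 1 df), plus a partitioned
  descriptive variant.
* **Statistics**: Storey q-values with π0 estimation, Kruskal–Wallis and
  Dwass–Steele–Critchlow–Fligner all-pairs contrasts across annotation
  groups, χ² tests of significant-count distributions against expectations,
  ω-trajectory pattern classes, independent-transition stratification,
  Karlin–Mrázek codon-usage bias, NG86 pairwise dS diagnostics, and
  expression–ω rank correlations.
* **Synthetic studies**: a generator that emulates the full study design
  (species tree with labeled trait transitions, per-orthogroup codon
  alignments under any of the model regimes, annotation groups with
  expression levels) and records all ground truth, so every inference is
  testable as a recovery problem.

Models follow a statsmodels-like shape: a model class is built from data
(`SingleOmegaModel(alignment, tree)`), `fit()` returns a results object with
the maximized log-likelihood, estimates, convergence diagnostics and a
`summary()`.

## Worked example

Simulate one orthogroup on an 8-taxon tree in which three species lost
their bristles and their branches evolve under relaxed selection (k = 0.3),
then fit the single-ω model and the selection-intensity pair:

```python
from selcontrast import LabeledTree, OrthoGroup, fit_single_omega, fit_relax
from selcontrast.simulate import simulate_codon_alignment, regime_classes
from selcontrast.models.matrices import uniform_frequencies
from selcontrast.stats import lrt

newick = ("(((a:0.3,b:0.3):0.2,(c:0.3,d:0.3):0.2):0.2,"
          "((e:0.3,f:0.3):0.2,(g:0.3,h:0.3):0.2):0.2);")
traits = {t: "present" for t in "abcdefgh"} | {t: "absent" for t in "bdf"}
tree = LabeledTree.from_newick(newick, traits=traits)

pi = uniform_frequencies()
classes = regime_classes(
    "relax",
    {"omegas": (0.05, 0.4, 1.5), "proportions": (0.5, 0.4, 0.1), "k": 0.3},
    pi=pi, kappa=2.0,
)
aln, _ = simulate_codon_alignment(
    tree, classes, 300, seed=7, pi=pi, kappa=2.0, branch_scale=1.0,
    labels_by_taxon=tree.terminal_labels("present-absent"),
)
og = OrthoGroup("demo", aln.select_taxa(sorted(tree.taxa)), tree)

m0 = fit_single_omega(og)
print(m0.summary())
null = fit_relax(og, test="absent", fix_k=1.0)
alt = fit_relax(og, test="absent", start_from=null)
test = lrt(null.lnL, alt.lnL, df=1)
print(f"LRT: stat={test.statistic:.2f}, p={test.p:.3g}, k-hat={alt.params['k']:.3f}")
```

which prints

```
SingleOmegaModel fit
==============================================
  log-likelihood       -5339.147190
  free parameters 3    converged: True
  iterations 14  restarts used 0
----------------------------------------------
  kappa              2.1226
  omega              0.3855
  branch_scale       1.0997

LRT: stat=79.94, p=3.86e-19, k-hat=0.306
```

The single-ω fit averages over the mixture (ω̂ ≈ 0.39 with κ̂ ≈ 2.12, close
to the simulated κ = 2); the selection-intensity LRT rejects k = 1
decisively and recovers k̂ ≈ 0.31 against the simulated 0.3 — the derived
lineages' ω distribution is flattened toward 1, the signature of relaxed
selection.

A full study runs from the command line:

```bash
selcontrast simulate --seed 42 --out study/           # synthetic inputs + ground truth
selcontrast run-study --study study/ --out results/ \
    --models m0,branch3,modelA,relax --seed 1
```

producing per-orthogroup fit JSONs, branch/branch-site/selection-intensity
summary tables (significant counts, percentages and totals per annotation
group), and a statistics report (Kruskal–Wallis + post-hoc contrasts, χ²
expected-distribution tests, q-values, ω-pattern splits, codon-usage bias,
expression correlation).

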