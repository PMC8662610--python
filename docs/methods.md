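# Methods

`selcontrast` re-implements, as a tested library, a comparative analysis of
protein-coding sequence evolution across lineages that differ in a binary-ish
morphological trait (here: sperm bristles present / reduced / absent, a proxy
for mating strategy in free-living flatworms).  The analysis asks three
questions per orthogroup (OG): does the average dN/dS ratio (ω) differ
between trait states (branch models), is there site-specific positive
selection restricted to derived-state lineages (branch-site models), and is
the whole distribution of ω flattened or sharpened on derived-state branches
(selection-intensity models)?  A statistics layer then contrasts the
per-OG answers across functional annotation groups.

## Substitution model

All likelihoods use a GY94-style codon model on the 61 sense codons of the
standard genetic code.  The generator has off-diagonal entries only between
codons differing at one nucleotide position,

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous],

with equilibrium codon frequencies `pi` (F3x4 per OG by default: per-position
nucleotide frequencies multiplied per codon, stops zeroed, renormalized, with
a 0.5 pseudocount per nucleotide per position; a uniform-frequency option
exists), transition/transversion ratio `kappa`, and `omega` = dN/dS.
Gap codons, partially gapped codons, and codons containing ambiguity codes
are treated as fully missing (the likelihood sums over all 61 states) — the
least-biased treatment when data are absent.

**Scaling.**  Single-class models scale each generator so the expected
substitution rate at equilibrium is 1; branch lengths are then expected
substitutions per codon.  For pure branch models each partition's matrix is
scaled to rate 1 individually (the codeml convention: a branch length means
the same thing whatever the branch's ω).  For site mixtures the classes
share one scaling constant — the proportion-weighted mean rate over classes
computed on the background/reference generators — because scaling each class
separately would erase precisely the rate differences between classes that
carry the signal.  The simulator builds its matrices through the same
constructors, so simulation and inference agree by construction.

**Likelihood.**  Felsenstein pruning over compressed site patterns, with
per-node rescaling of partial likelihoods.  Time-reversibility lets each
(kappa, omega) pair be eigendecomposed once (`D^1/2 Q D^-1/2` is symmetric),
after which P(t) for every branch is two matrix products; decompositions are
cached across optimizer steps, which matters because finite-difference
gradients revisit most coordinates unchanged.

## The model families

* **Single ω (M0).**  One ω, one κ, shared by all branches and sites.
* **Branch model.**  One ω per branch partition.  Partition labels apply to
  *terminal* branches only, derived from the per-species trait state
  (present = background; reduced and absent labeled separately); internal
  branches are background.  The three-state fit is compared with M0 by an
  LRT with 2 df.
* **Branch-site model A / A-null.**  Four site classes (0, 1, 2a, 2b) with
  proportions (p0, p1, p2a, p2b), p2a = (1−p0−p1)·p0/(p0+p1) and
  correspondingly for p2b.  Background ω per class: (ω0, 1, ω0, 1);
  foreground: (ω0, 1, ω2, ω2) with 0 < ω0 < 1 ≤ ω2.  The null fixes
  ω2 = 1.  The default LRT uses 2 df, reproducing the analysis convention
  this package follows; `branch_site_df=1` switches to the usual 1-df
  (conservative-mixture) choice.  Sites are flagged as positively selected
  when the naive empirical-Bayes posterior P(2a)+P(2b) at the MLEs exceeds
  0.95.  No Bayes-empirical-Bayes integration over parameter uncertainty is
  attempted (a documented divergence from codeml's BEB).
* **Selection-intensity (RELAX-style).**  A three-category discrete ω
  distribution ω0 ≤ ω1 ≤ 1 ≤ ω2 with free proportions on reference
  branches; test branches use ω_i^k.  k < 1 pulls the distribution toward
  1 (relaxed selection), k > 1 spreads it (intensified).  Null: k = 1;
  LRT with 1 df.  **Site categories are shared across the whole tree**
  (a site keeps its category on every branch).  This matches the package's
  simulator and its likelihood contract but differs from HyPhy's RELAX,
  which uses branch-site random effects (independent category draws per
  branch); k retains the same interpretation.  k is bounded to
  [1e-3, 50] and boundary hits are flagged as non-informative.
* **Partitioned descriptive model (PDM).**  The k link is replaced by three
  free test-branch ω values (reference ordering constraint retained,
  category proportions shared between partitions so that the shared-category
  structure — and with it the nesting
  lnL(PDM) ≥ lnL(alternative) ≥ lnL(null) — is preserved).  Descriptive
  only; no test attached.

## Optimization

Bounded L-BFGS-B on transformed parameters: log for κ, ω, k and the tree
scale; additive-logistic for proportions; log(ω2−1) for the branch-site ω2
(≥1) and a log-difference chain for the ordered RELAX triple.  Starting
values κ = 2 and ω = 0.001 follow the conventional codeml settings; mixture
fits start at moderate interior points.  Convergence uses `ftol = 1e-11`
(|ΔlnL| well below 1e-8); up to three jittered restarts trigger when the
canonical start fails.  Alternative fits are seeded from their null fits
(with ω2 started at 1.5 rather than at the boundary, where the transformed
gradient vanishes), and a fallback second start runs whenever the seeded fit
lands below its null — this is what makes the nested-likelihood ordering
hold in practice.

**Branch lengths.**  Input trees carry branch lengths (substitutions/site
for real data, expected substitutions/codon for simulated data); every
model profiles a single multiplicative tree-scale factor rather than
re-estimating each branch length.  One parameter absorbs the unit
difference, keeps mixture fits stable, and keeps the full pipeline within
desktop runtimes; `branch_lengths="fixed"` trusts the input lengths
instead.  Relative branch lengths are therefore taken as known — an
approximation that is exact for the synthetic studies (which simulate on
the tree being fitted) and standard practice when lengths come from a
well-estimated species tree.

## Ortholog pruning

Homolog trees (tips `species@transcript`) are reduced to one-per-species
orthogroups by: (1) removing tips longer than 2 substitutions/site or
longer than 10× their sister tip, iterated to a fixed point; (2) collapsing
clades of a single species to the sequence with the most aligned columns
(ties: lexicographically smallest id, for determinism); (3) cutting at
internal branches longer than a configurable cutoff (default 2.0,
mirroring the absolute tip cutoff — the source analysis states no number)
and keeping parts with ≥5 species; (4) extracting orthologs by
rooted-ingroups (RT: root on the longest-path outgroup tip, then split
bottom-up at nodes whose child subtrees share a species, both sides
surviving as candidates) and maximum-inclusion (MI: repeatedly take the
largest bipartition side with ≤1 sequence per species, ties broken by total
aligned columns then lexicographically), then the union with RT preferred
on any overlap.  Final orthogroups need ≥4 species.

## Alignment preparation

Fixed order (the order is part of the contract): back-translate the
protein alignment against its CDS (terminal stop codons tolerated and
stripped) → drop codon columns whose external per-column reliability score
is ≤3 (scores are consumed as input on an assumed 1–10 scale; the scorer
itself is out of scope) → drop sequences whose gap-free length is <50% of
the alignment → validate (no internal stops, ≥80 nt, ≥4 taxa) → prune the
species tree to the alignment's taxa (path lengths preserved).  An OG whose
reference-species sequence is lost in filtering keeps its annotation.

## Statistics layer

LRT p-values come from the χ² survival function (negative deviances from
optimizer jitter clipped at 0).  FDR control converts p to Storey q-values:
π0 estimated over the λ-grid 0.05…0.95 by a cubic smoothing spline
evaluated at λ = 0.95 (a bootstrap variant is available; the canonical
smoother's estimate carries sampling noise of roughly ±0.1 at 1000 tests —
see tests), q monotone in p and capped at π̂0; below 10 p-values π0 falls
back to 1, making q the Benjamini–Hochberg adjustment.  Group contrasts use
Kruskal–Wallis with tie correction and the Dwass–Steele–Critchlow–Fligner
all-pairs post-hoc referred to the large-sample studentized-range
distribution (no exact small-sample tables).  Enrichment of significant OGs
across annotation groups uses a χ² goodness-of-fit against expectations
proportional to each group's total tested.  The ω trajectory across states
is classified coarse (sign of ω_absent − ω_present) and fine (the two step
signs), exact ties counting as "+" with a flag.  Codon-usage bias is
Karlin–Mrázek B of each derived-state sequence against the pooled
bristles-present reference rows of the same alignment; synonymous
divergence diagnostics use NG86 counting with Jukes–Cantor correction,
pathway-averaged for multi-position codon differences and stop-avoiding,
pairs with pS ≥ 0.75 reported saturated.  Spearman correlations use exact
permutation p below n = 10 and the t-approximation above.  Contrast tables
are built from raw LRT p < 0.05 (q-values reported alongside), and
branch-site results can be stratified by the number of phylogenetically
independent losses/reductions covered (default ≥3), counted as marked
species-tree branches ancestral to at least one derived-state OG taxon.

## Synthetic studies

`generate_study` writes every input the pipeline reads.  A pure-birth
ingroup (default 16 species) scaled to height 1 carries 3 independent
losses and 2 reductions on non-nested clades (≤ n/4 species each, never
containing the reference species); outgroups attach basally.  Per OG
(defaults 40/10/10/20 across testis/ovary/tail/ubiquitous), the
present-state ω is lognormal with group medians 0.22/0.20/0.20/0.08
(reproduction-related > ubiquitous, the structure the analysis is meant to
detect) and σ = 0.35; derived states multiply ω by 1.6 (reduced) and 2.5
(absent), capped at 5.  Under the `relax` regime derived branches instead
get the reference distribution (0.05, 0.4, 1.5) with proportions
(0.5, 0.4, 0.1) raised to a configurable k.  Alignments (default 300
codons, tree height 0.5 substitutions/codon root-to-tip, κ = 2, uniform π)
evolve by sampling the site class once per site and drawing child states
from the same transition matrices the models fit with.  Expression levels
are lognormal, rank-coupled to ω through a Gaussian copula at target
Spearman ρ = −0.6.  Per-column scores are uniform on 4–10 with a 10%
low-score (1–3) fraction.  Species drop out of an OG with probability 0.1
(never the reference).  Everything is reproducible from (design, seed), and
a manifest records all ground truth.

What the generator does **not** emulate: assembly artifacts (chimeras,
fragmented transcripts beyond optional uniform gap injection), codon-usage
heterogeneity between lineages, rate variation beyond the modeled classes,
alignment error, or annotation mislabeling.  Passing recovery tests
therefore demonstrate correctness of the estimators under their own
assumptions, not robustness to real transcriptome pathologies.

## Problem sizes used in the test and acceptance runs

Chosen so the default suite runs on one CPU in well under half an hour:
likelihood-oracle checks on quartets with six sites; LRT type-I calibration
with 200 null replicates at 6 taxa × 100 codons (band [0.02, 0.09] at
α = 0.05); single-ω recovery at 8 taxa × 500 codons × 20 replicates (±25%);
selection-intensity direction recovery at k = 0.3, 8 taxa × 300 codons × 20
replicates; branch-site site-flag enrichment on pooled 2 × 300-codon
simulations; ortholog recovery over 100 gene trees at duplication rate 0.1;
and one end-to-end study at the full default scale (16 species, 80 OGs,
300 codons) fitting the single-ω family, which is what the across-group
contrast consumes.

## Known limitations

* Shared-category selection-intensity model differs from the
  random-effects formulation of the original RELAX method (see above);
  k estimates are comparable in direction and rough magnitude but not
  numerically identical to HyPhy's.
* Site posteriors are naive empirical Bayes; with few foreground branches
  they understate uncertainty near ω2 ≈ 1.
* The 2-df branch-site LRT convention is anticonservative relative to the
  1-df mixture null; both are available, neither is "corrected" here.
* F3x4 is the only data-driven frequency model; no F61 / MutSel.
* The tree-scale approximation assumes input branch lengths are
  proportionally correct; badly misestimated input trees propagate into ω.
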