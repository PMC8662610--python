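"""Statistical layer: LRTs, FDR q-values, nonparametric contrasts,
expected-distribution chi-square tests, omega-pattern classes, and
codon-usage bias.

Everything downstream of the likelihood fits lives here: the chi-square
survival p-values come from scipy, while the pieces scipy does not provide
(Storey q-values with pi0 estimation, the Dwass-Steele-Critchlow-Fligner
all-pairs post-hoc, the Karlin-Mrazek codon-usage bias B) are implemented
directly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .genetics import GeneticCode, standard_genetic_code


@dataclass
class TestResult:
    statistic: float
    df: int
    p: float
    q: float | None = None

    def __iter__(self):  # allows tuple-unpacking in reports
        yield from (self.statistic, self.df, self.p)


def lrt(lnl_null: float, lnl_alt: float, df: int) -> TestResult:
    """Likelihood-ratio test of nested fits against chi-square with df.

    Small negative statistics from optimizer jitter are clipped to zero.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (lnl_alt - lnl_null)
    if stat < 0:
        if stat < -1e-2:
            warnings.warn(
                f"alternative lnL below null by {-stat / 2:.4g}; check convergence"
            )
        stat = 0.0
    return TestResult(statistic=stat, df=df, p=float(sps.chi2.sf(stat, df)))


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def estimate_pi0(pvals: np.ndarray, method: str = "smoother") -> float:
    """Proportion of true nulls, estimated over the lambda grid 0.05..0.95.

    ``smoother``: cubic-spline smoothing of pi0(lambda), evaluated at the
    largest lambda.  ``bootstrap``: Storey's bootstrap selection minimizing
    estimated MSE.  Result clamped to (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if method == "smoother":
        from scipy.interpolate import UnivariateSpline

        spline = UnivariateSpline(lambdas, pi0_lambda, k=3)
        pi0 = float(spline(lambdas[-1]))
    elif method == "bootstrap":
        min_pi0 = pi0_lambda.min()
        rng = np.random.default_rng(0)
        mse = np.zeros_like(lambdas)
        for _ in range(100):
            pb = rng.choice(p, size=m, replace=True)
            pi0_b = np.array([(pb > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
            mse += (pi0_b - min_pi0) ** 2
        pi0 = float(pi0_lambda[np.argmin(mse)])
    else:
        raise ValueError(f"unknown pi0 method {method!r}")
    return float(min(max(pi0, 1.0 / m), 1.0))


def qvalues(pvals, pi0: float | None = None, method: str = "smoother"):
    """Storey q-values.

    Returns (q, pi0).  With fewer than 10 p-values pi0 falls back to 1
    (making q the Benjamini-Hochberg adjusted p) with a warning.  q is
    monotone in p and bounded by pi0.
    """
    p = np.asarray(list(pvals), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if m < 10:
            warnings.warn("fewer than 10 p-values; using pi0 = 1 (BH-equivalent)")
            pi0 = 1.0
        else:
            pi0 = estimate_pi0(p, method=method)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, pi0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, float(pi0)


# ---------------------------------------------------------------------------
# Rank-based group contrasts
# ---------------------------------------------------------------------------

def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis rank-sum test with tie correction.

    All observations identical gives H = 0, p = 1 (degenerate but defined).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(groups)
    if pooled.size < 2:
        raise ValueError("need at least two observations")
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=0.0, df=len(groups) - 1, p=1.0)
    stat, p = sps.kruskal(*groups)
    return TestResult(statistic=float(stat), df=len(groups) - 1, p=float(p))


def dscf_posthoc(groups) -> np.ndarray:
    """Dwass-Steele-Critchlow-Fligner all-pairs post-hoc p-value matrix.

    For each pair, the two-sample rank-sum statistic is standardized (with
    tie correction from the pairwise pooled sample) and referred to the
    studentized range distribution with k groups and infinite df.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 3:
        raise ValueError("need at least three groups for the all-pairs post-hoc")
    for g in groups:
        if g.size < 2:
            raise ValueError("every group needs at least two observations")
    pmat = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        x, y = groups[i], groups[j]
        n1, n2 = x.size, y.size
        n = n1 + n2
        ranks = sps.rankdata(np.concatenate([x, y]))
        r1 = ranks[:n1].sum()
        expected = n1 * (n + 1) / 2.0
        _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts) / (n - 1)).sum()
        var = n1 * n2 / 12.0 * (n + 1 - tie_term / n)
        if var <= 0:
            pmat[i, j] = pmat[j, i] = 1.0
            continue
        z = (r1 - expected) / np.sqrt(var)
        q = abs(z) * np.sqrt(2.0)
        p = float(sps.studentized_range.sf(q, k, np.inf))
        pmat[i, j] = pmat[j, i] = min(max(p, 0.0), 1.0)
    return pmat


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with ties; exact permutation p for n <= 9,
    t-approximation otherwise.  The statistic is rho (df reported as n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero variance in ranks")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= 9:
        count = 0
        total = 0
        observed = abs(rho)
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            total += 1
            if abs(r) >= observed - 1e-12:
                count += 1
        p = count / total
    else:
        t = rho * np.sqrt((n - 2) / max(1.0 - rho**2, 1e-12))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return TestResult(statistic=rho, df=n - 2, p=min(p, 1.0))


# ---------------------------------------------------------------------------
# Contrast tables and chi-square against expected distributions
# ---------------------------------------------------------------------------

@dataclass
class ContrastTable:
    """Observed significant counts and totals tested per annotation group."""

    groups: list[str]
    observed: np.ndarray
    total: np.ndarray

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        if np.any(self.observed > self.total):
            raise ValueError("observed significant counts exceed totals tested")
        if np.any(self.total <= 0):
            raise ValueError("totals tested must be positive")

    @property
    def percent(self) -> np.ndarray:
        return 100.0 * self.observed / self.total


def chi_square_expected(table: ContrastTable) -> TestResult:
    """Goodness-of-fit of significant counts against the distribution of
    all tested orthogroups across annotation groups:
    E_g = (sum O) * T_g / (sum T)."""
    O = table.observed
    T = table.total
    if O.sum() <= 0:
        raise ValueError("no significant orthogroups to test")
    E = O.sum() * T / T.sum()
    if np.any(E == 0):
        raise ValueError("zero expected count")
    stat = float(((O - E) ** 2 / E).sum())
    df = O.size - 1
    return TestResult(statistic=stat, df=df, p=float(sps.chi2.sf(stat, df)))


def classify_omega_pattern(w_present: float, w_reduced: float, w_absent: float):
    """Coarse (+/-) and fine (-/-, -/+, +/-, +/+) omega trajectory classes.

    Coarse compares absent to present; fine tracks the two steps
    present->reduced and reduced->absent.  Exact ties classify as "+" and
    set the tie flag.
    """
    tie = w_absent == w_present or w_reduced == w_present or w_absent == w_reduced
    coarse = "+" if w_absent >= w_present else "-"
    fine = ("+" if w_reduced >= w_present else "-") + "/" + (
        "+" if w_absent >= w_reduced else "-"
    )
    return coarse, fine, tie


# ---------------------------------------------------------------------------
# Codon usage bias (Karlin-Mrazek B)
# ---------------------------------------------------------------------------

def _family_frequencies(counts: dict[str, float], code: GeneticCode):
    """Within-synonymous-family codon frequencies and amino-acid totals."""
    fam = code.aa_to_codons()
    freq: dict[str, dict[str, float]] = {}
    aa_total: dict[str, float] = {}
    for aa, codons in fam.items():
        total = sum(counts.get(c, 0.0) for c in codons)
        aa_total[aa] = total
        if total > 0:
            freq[aa] = {c: counts.get(c, 0.0) / total for c in codons}
    return freq, aa_total


def codon_usage_bias_b(
    gene_codons: dict[str, float],
    reference_codons: dict[str, float],
    code: GeneticCode | None = None,
) -> float:
    """Karlin-Mrazek codon-usage bias of a gene against a reference set.

    B = sum_a f_a(gene) * sum_{c in codons(a)} |p(c|a,gene) - p(c|a,ref)|
    with f_a the amino-acid frequency in the gene; single-codon families
    contribute nothing.  The reference must cover every amino acid used by
    the gene.
    """
    code = code or standard_genetic_code()
    if not gene_codons or sum(gene_codons.values()) == 0:
        raise ValueError("empty gene")
    gfreq, gtot = _family_frequencies(gene_codons, code)
    rfreq, rtot = _family_frequencies(reference_codons, code)
    total_aa = sum(gtot.values())
    b = 0.0
    for aa, fa in gtot.items():
        if fa == 0:
            continue
        if aa not in rfreq:
            raise ValueError(f"reference set lacks amino acid {aa!r} used by the gene")
        codons = code.aa_to_codons()[aa]
        if len(codons) < 2:
            continue
        l1 = sum(abs(gfreq[aa][c] - rfreq[aa][c]) for c in codons)
        b += (fa / total_aa) * l1
    return b


def codon_counts(alignment, taxa) -> dict[str, float]:
    """Pooled codon usage counts over the given rows of a codon alignment."""
    index = {t: i for i, t in enumerate(alignment.taxa)}
    counts: dict[str, float] = {}
    for t in taxa:
        row = alignment.codons[index[t]]
        for s in row[row >= 0]:
            c = alignment.code.sense_codons[s]
            counts[c] = counts.get(c, 0.0) + 1.0
    return counts
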