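import numpy as np
import pytest

from selcontrast.genetics import standard_genetic_code
from selcontrast.models.matrices import EigenSystem, build_rate_matrix, uniform_frequencies
from selcontrast.trees import LabeledTree


@pytest.fixture(scope="session")
def code():
    return standard_genetic_code()


@pytest.fixture(scope="session")
def pi_uniform():
    return uniform_frequencies()


@pytest.fixture()
def tree8_pa():
    """Balanced 8-taxon tree, three absent-bristle terminals on long-ish
    branches (adequate foreground length for branch-site signal)."""
    nwk = ("(((a:0.3,b:0.3):0.2,(c:0.3,d:0.3):0.2):0.2,"
           "((e:0.3,f:0.3):0.2,(g:0.3,h:0.3):0.2):0.2);")
    traits = {t: "present" for t in "abcdefgh"}
    for t in "bdf":
        traits[t] = "absent"
    return LabeledTree.from_newick(nwk, traits=traits)


@pytest.fixture()
def tree6_threestate():
    """Six taxa covering all three bristle states."""
    nwk = "(((a:0.25,b:0.25):0.2,c:0.45):0.15,(d:0.3,(e:0.2,f:0.2):0.1):0.3);"
    traits = dict(a="present", b="reduced", c="absent",
                  d="present", e="absent", f="reduced")
    return LabeledTree.from_newick(nwk, traits=traits)


# ---------------------------------------------------------------------------
# independent brute-force likelihood oracle (explicit enumeration over
# internal-node states on the fixed topology (a,b,(c,d)) )
# ---------------------------------------------------------------------------

def brute_force_loglike(states, lengths, classes, pi, kappa, labels, branch_scale=1.0):
    """lnL of a codon matrix on the quartet (a:t0, b:t1, (c:t2, d:t3):t4)
    by explicit summation over the two internal nodes, mixing site classes.

    ``states``: (4, n_sites) codon states (row order a, b, c, d; -1 missing);
    ``labels``: partition label per terminal branch (length 4; internal
    branch is always background 0).
    """
    code = standard_genetic_code()
    n = pi.size
    total = 0.0
    n_sites = states.shape[1]
    site_likes = np.zeros(n_sites)
    for cls in classes:
        Ps = []
        for b in range(4):
            w = cls.omega(labels[b])
            Q, _ = build_rate_matrix(pi, kappa, w, code=code, scale=False)
            Ps.append(EigenSystem(Q, pi).transition_matrix(
                lengths[b] * branch_scale / cls.rho(labels[b])))
        Q, _ = build_rate_matrix(pi, kappa, cls.omega(0), code=code, scale=False)
        Pint = EigenSystem(Q, pi).transition_matrix(
            lengths[4] * branch_scale / cls.rho(0))

        def tipvec(P, s):
            return P[:, s] if s >= 0 else P.sum(axis=1)

        for site in range(n_sites):
            a, b, c, d = states[:, site]
            like = 0.0
            inner = np.zeros(n)
            for m in range(n):
                inner[m] = tipvec(Ps[2], c)[m] * tipvec(Ps[3], d)[m]
            for r in range(n):
                like += (
                    pi[r] * tipvec(Ps[0], a)[r] * tipvec(Ps[1], b)[r]
                    * float(Pint[r] @ inner)
                )
            site_likes[site] += cls.proportion * like
    total = float(np.log(site_likes).sum())
    return total


@pytest.fixture(scope="session")
def quartet_oracle():
    return brute_force_loglike


def quartet_tree(lengths, traits):
    t0, t1, t2, t3, t4 = lengths
    nwk = f"(a:{t0},b:{t1},(c:{t2},d:{t3}):{t4});"
    return LabeledTree.from_newick(nwk, traits=traits)


@pytest.fixture(scope="session")
def make_quartet():
    return quartet_tree
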