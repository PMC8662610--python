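"""ML codon models and the orthogroup-level fitting helpers.

The class layer (``SingleOmegaModel`` and friends) binds a model to one
alignment+tree; the functions below wrap them for OrthoGroup inputs,
handle contrast subsetting, and chain alternative fits from their null
fits so nested likelihoods are well ordered.
"""

from __future__ import annotations

import numpy as np

from ..orthogroup import MissingPartitionError, OrthoGroup
from .base import CodonModel, CodonModelResults, cap_omega
from .branch import BranchOmegaModel, SingleOmegaModel, branch_omega_classes, single_omega_class
from .branchsite import BranchSiteModel, model_a_classes, site_posteriors
from .likelihood import SiteClass, TreeIndex, compress_patterns, log_likelihood
from .matrices import (
    EigenSystem,
    build_rate_matrix,
    equilibrium_rate,
    estimate_f3x4,
    mixture_scale,
    transition_probabilities,
    uniform_frequencies,
)
from .relax import RelaxModel, relax_classes

__all__ = [
    "CodonModel", "CodonModelResults", "SingleOmegaModel", "BranchOmegaModel",
    "BranchSiteModel", "RelaxModel", "SiteClass", "TreeIndex",
    "build_rate_matrix", "transition_probabilities", "estimate_f3x4",
    "uniform_frequencies", "equilibrium_rate", "mixture_scale", "EigenSystem",
    "log_likelihood", "compress_patterns", "site_posteriors", "cap_omega",
    "single_omega_class", "branch_omega_classes", "model_a_classes",
    "relax_classes", "fit_single_omega", "fit_branch_three_omega",
    "fit_model_a", "fit_model_a_null", "fit_relax", "fit_relax_pdm",
    "MissingPartitionError",
]

_CONTRAST_OF = {"absent": "present-absent", "reduced": "present-reduced"}


def _contrast_og(og: OrthoGroup, foreground: str) -> tuple[OrthoGroup, str]:
    if foreground not in _CONTRAST_OF:
        raise ValueError(f"foreground must be 'absent' or 'reduced', got {foreground!r}")
    contrast = _CONTRAST_OF[foreground]
    return og.subset_for_contrast(contrast), contrast


def fit_single_omega(og: OrthoGroup, **fit_kwargs) -> CodonModelResults:
    """ML fit of a single omega (and kappa, tree scale) for the orthogroup."""
    return SingleOmegaModel(og.alignment, og.tree).fit(**fit_kwargs)


def fit_branch_three_omega(
    og: OrthoGroup,
    start_from: CodonModelResults | None = None,
    **fit_kwargs,
) -> CodonModelResults:
    """Separate omegas for present / reduced / absent terminal branches.

    Requires all three bristle states among the orthogroup's species;
    raises MissingPartitionError otherwise.  When a single-omega fit is
    supplied the search starts from it (the models are nested: equal
    omegas reproduce the single-omega likelihood).
    """
    og.require_three_states()
    model = BranchOmegaModel(og.alignment, og.tree)
    if start_from is None:
        return model.fit(**fit_kwargs)
    x = np.asarray(start_from.x, dtype=float)
    n_labels = len(model.omega_labels)
    seeded = np.concatenate([x[:1], np.repeat(x[1], n_labels), x[2:]])
    res = model.fit(start=seeded, **fit_kwargs)
    if res.lnL < start_from.lnL - 1e-6:
        res2 = model.fit(**fit_kwargs)
        res = res2 if res2.lnL > res.lnL else res
    return res


def fit_model_a_null(og: OrthoGroup, foreground: str = "absent", **fit_kwargs) -> CodonModelResults:
    """Branch-site A_null (omega2 fixed at 1) on the chosen contrast."""
    sub, contrast = _contrast_og(og, foreground)
    model = BranchSiteModel(
        sub.alignment, sub.tree, contrast=contrast, foreground_label=1, fix_omega2=True
    )
    return model.fit(**fit_kwargs)


def fit_model_a(
    og: OrthoGroup,
    foreground: str = "absent",
    start_from: CodonModelResults | None = None,
    **fit_kwargs,
) -> CodonModelResults:
    """Branch-site model A on the chosen contrast.

    The search is seeded from the A_null solution (given or refit here)
    with omega2 just above 1, so lnL(A) >= lnL(A_null) up to optimizer
    tolerance.
    """
    sub, contrast = _contrast_og(og, foreground)
    if start_from is None:
        start_from = fit_model_a_null(og, foreground, **fit_kwargs)
    model = BranchSiteModel(
        sub.alignment, sub.tree, contrast=contrast, foreground_label=1, fix_omega2=False
    )
    # seed away from the omega2=1 boundary (where the gradient in
    # log(omega2-1) vanishes); fall back to the boundary seed if needed
    seeded = np.insert(np.asarray(start_from.x, dtype=float), 4, np.log(0.5))
    res = model.fit(start=seeded, **fit_kwargs)
    if res.lnL < start_from.lnL - 1e-6:
        res2 = model.fit(start=np.insert(np.asarray(start_from.x, dtype=float), 4, -12.0),
                         **fit_kwargs)
        res = res2 if res2.lnL > res.lnL else res
    return res


def fit_relax(
    og: OrthoGroup,
    test: str = "absent",
    fix_k: float | None = None,
    start_from: CodonModelResults | None = None,
    **fit_kwargs,
) -> CodonModelResults:
    """RELAX-style fit on the chosen contrast (``fix_k=1`` for the null).

    The free-k alternative is seeded from the null solution at k = 1.
    """
    sub, contrast = _contrast_og(og, test)
    model = RelaxModel(
        sub.alignment, sub.tree, contrast=contrast, test_label=1, fix_k=fix_k
    )
    if fix_k is not None:
        return model.fit(**fit_kwargs)
    if start_from is None:
        start_from = fit_relax(og, test, fix_k=1.0, **fit_kwargs)
    seeded = np.insert(np.asarray(start_from.x, dtype=float), 6, 0.0)
    res = model.fit(start=seeded, **fit_kwargs)
    if res.lnL < start_from.lnL - 1e-6:
        res2 = model.fit(**fit_kwargs)
        res = res2 if res2.lnL > res.lnL else res
    return res


def fit_relax_pdm(
    og: OrthoGroup,
    test: str = "absent",
    start_from: CodonModelResults | None = None,
    **fit_kwargs,
) -> CodonModelResults:
    """Partitioned descriptive model: free test-branch omega categories.

    Seeded from the alternative RELAX fit (given or refit here) by mapping
    its k onto the test triple, preserving the nesting
    lnL(PDM) >= lnL(alternative) >= lnL(null).
    """
    sub, contrast = _contrast_og(og, test)
    model = RelaxModel(
        sub.alignment, sub.tree, contrast=contrast, test_label=1, pdm=True
    )
    if start_from is None:
        start_from = fit_relax(og, test, **fit_kwargs)
    x = np.asarray(start_from.x, dtype=float)
    if x.size >= 7 and "k" in start_from.params:  # alternative fit: k at slot 6
        k = start_from.params["k"]
        e1, e0, v2 = x[3], x[4], x[5]
        test_triple = np.clip(
            [k * e1, k * e0, k * v2],
            [0.0, 0.0, 0.0],
            [12.0, 12.0, np.log(50.0) - 1e-9],
        )
        seeded = np.concatenate([x[:6], test_triple, x[7:]])
    else:
        seeded = np.concatenate([x[:6], x[3:6], x[6:]])
    res = model.fit(start=seeded, **fit_kwargs)
    if res.lnL < start_from.lnL - 1e-6:
        res2 = model.fit(**fit_kwargs)
        res = res2 if res2.lnL > res.lnL else res
    return res
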