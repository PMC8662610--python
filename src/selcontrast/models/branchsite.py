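"""Branch-site model A and its null, plus empirical-Bayes site posteriors.

Four site classes:

  class 0  : 0 < omega0 < 1 everywhere
  class 1  : omega = 1 everywhere
  class 2a : omega0 on background branches, omega2 >= 1 on foreground
  class 2b : 1 on background branches, omega2 on foreground

with proportions (p0, p1, p2a, p2b) where p2a = (1-p0-p1) p0/(p0+p1) and
p2b = (1-p0-p1) p1/(p0+p1).  The null fixes omega2 = 1 (sites released
from constraint evolve neutrally on the foreground).  Site classes are
mixed identically across sites; posteriors are naive empirical Bayes at
the MLEs (no integration over parameter uncertainty).
"""

from __future__ import annotations

import numpy as np

from .base import _LOG_KAPPA_BOUNDS, KAPPA_INIT, CodonModel
from .likelihood import SiteClass, mixture_pattern_loglikes
from .matrices import equilibrium_rate

_LOGIT_W0_BOUNDS = (-12.0, -1e-8)  # log omega0, omega0 in (0,1)
_LOG_W2M1_BOUNDS = (-25.0, np.log(49.0))  # omega2 = 1 + exp(v)
_SIMPLEX_BOUNDS = (-12.0, 12.0)


def model_a_proportions(p0: float, p1: float) -> tuple[float, float, float, float]:
    rest = max(1.0 - p0 - p1, 0.0)
    denom = p0 + p1
    if denom <= 0:
        return 0.0, 0.0, rest / 2, rest / 2
    return p0, p1, rest * p0 / denom, rest * p1 / denom


def model_a_classes(
    p0, p1, omega0, omega2, pi, kappa, foreground_label: int = 1, code=None
) -> list[SiteClass]:
    """The four site classes of model A.

    The common scaling constant is the proportion-weighted mean rate of the
    background-branch generators, so branch lengths read as expected
    substitutions per codon on background branches.
    """
    props = model_a_proportions(p0, p1)
    bg = (omega0, 1.0, omega0, 1.0)
    fg = (omega0, 1.0, omega2, omega2)
    rho = sum(
        p * equilibrium_rate(pi, kappa, w, code=code) for p, w in zip(props, bg)
    )
    classes = []
    for p, wb, wf in zip(props, bg, fg):
        classes.append(
            SiteClass(p, {0: wb, foreground_label: wf}, {0: rho, foreground_label: rho})
        )
    return classes


class BranchSiteModel(CodonModel):
    """Branch-site model A (``fix_omega2=False``) or A_null (``True``).

    ``foreground_label`` selects the branch partition allowed positive
    selection; with a two-partition contrast labelling this is 1.
    """

    def __init__(self, alignment, tree, *, foreground_label: int = 1,
                 fix_omega2: bool = False, **kwargs):
        super().__init__(alignment, tree, **kwargs)
        if foreground_label not in self.labels_by_taxon.values():
            raise ValueError(
                f"foreground label {foreground_label} absent from tree labelling"
            )
        self.foreground_label = foreground_label
        self.fix_omega2 = fix_omega2

    # free params: log kappa, z0, z1 (simplex), log omega0, [log(omega2-1)], [log scale]
    def _start(self):
        s, _ = self._scale_slot()
        x = [np.log(KAPPA_INIT), np.log(0.75 / 0.1), np.log(0.15 / 0.1), np.log(0.1)]
        if not self.fix_omega2:
            x.append(np.log(0.5))  # omega2 init 1.5
        return x + s

    def _bounds(self):
        _, sb = self._scale_slot()
        b = [_LOG_KAPPA_BOUNDS, _SIMPLEX_BOUNDS, _SIMPLEX_BOUNDS, _LOGIT_W0_BOUNDS]
        if not self.fix_omega2:
            b.append(_LOG_W2M1_BOUNDS)
        return b + sb

    def _interpret(self, x):
        kappa = float(np.exp(x[0]))
        p0, p1, _ = self._softmax_simplex(x[1:3])
        omega0 = float(np.exp(x[3]))
        if self.fix_omega2:
            omega2, offset = 1.0, 4
        else:
            omega2, offset = 1.0 + float(np.exp(x[4])), 5
        s, _ = self._scale_from(x, offset)
        classes = model_a_classes(
            p0, p1, omega0, omega2, self.pi, kappa, self.foreground_label, self.code
        )
        props = model_a_proportions(p0, p1)
        params = {
            "kappa": kappa,
            "p0": float(p0),
            "p1": float(p1),
            "p2a": props[2],
            "p2b": props[3],
            "omega0": omega0,
            "omega2": omega2,
            "branch_scale": s,
        }
        return kappa, classes, s, params


def site_posteriors(results, prob_threshold: float = 0.95):
    """Naive empirical-Bayes posteriors over the four site classes.

    Returns (posterior matrix of shape (n_columns, 4), flagged site indices)
    where flagged sites have P(class 2a) + P(class 2b) > ``prob_threshold``
    — the sites inferred under positive selection on the foreground.
    """
    model = results.model
    kappa, classes, s, _ = model._interpret(results.x)
    class_logl = mixture_pattern_loglikes(
        model.tindex, model.patterns, model.alignment.taxa, model.pi, kappa,
        classes, s, code=model.code,
    )
    w = np.array([c.proportion for c in classes])
    with np.errstate(divide="ignore"):
        a = class_logl + np.log(np.maximum(w, 1e-300))[:, None]
    a -= a.max(axis=0, keepdims=True)
    post = np.exp(a)
    post /= post.sum(axis=0, keepdims=True)
    per_column = post[:, model.column_to_pattern].T  # (n_columns, 4)
    p_positive = per_column[:, 2] + per_column[:, 3]
    flagged = np.nonzero(p_positive > prob_threshold)[0]
    return per_column, flagged
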