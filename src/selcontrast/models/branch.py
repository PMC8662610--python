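"""Branch models: a single omega, or one omega per branch partition.

The three-partition variant assigns separate omegas to terminal branches of
species with reduced and with absent bristles (internal branches and
present-state terminals share the background omega), the null being a
single omega for the whole tree; the two are compared by LRT with 2 df.
"""

from __future__ import annotations

import numpy as np

from .base import (
    _LOG_KAPPA_BOUNDS,
    _LOG_OMEGA_BOUNDS,
    KAPPA_INIT,
    OMEGA_INIT,
    CodonModel,
)
from .likelihood import SiteClass
from .matrices import equilibrium_rate


def single_omega_class(omega, pi, kappa, code=None) -> list[SiteClass]:
    rho = equilibrium_rate(pi, kappa, omega, code=code)
    return [SiteClass(1.0, {0: omega}, {0: rho})]


def branch_omega_classes(omega_by_label: dict[int, float], pi, kappa, code=None) -> list[SiteClass]:
    """One class; every branch partition has its own omega and its own
    per-matrix scaling, so branch lengths stay in expected substitutions
    per codon on every partition (codeml's branch-model convention)."""
    rho = {
        lab: equilibrium_rate(pi, kappa, w, code=code) for lab, w in omega_by_label.items()
    }
    return [SiteClass(1.0, dict(omega_by_label), rho)]


class SingleOmegaModel(CodonModel):
    """M0: one omega shared by all branches and sites."""

    param_names = ("kappa", "omega")

    def _start(self):
        s, _ = self._scale_slot()
        return [np.log(KAPPA_INIT), np.log(OMEGA_INIT)] + s

    def _bounds(self):
        _, sb = self._scale_slot()
        return [_LOG_KAPPA_BOUNDS, _LOG_OMEGA_BOUNDS] + sb

    def _interpret(self, x):
        kappa = float(np.exp(x[0]))
        omega = float(np.exp(x[1]))
        s, _ = self._scale_from(x, 2)
        classes = single_omega_class(omega, self.pi, kappa, self.code)
        return kappa, classes, s, {"kappa": kappa, "omega": omega, "branch_scale": s}


class BranchOmegaModel(CodonModel):
    """One omega per branch partition present in the tree labelling."""

    def __init__(self, alignment, tree, **kwargs):
        super().__init__(alignment, tree, **kwargs)
        self.omega_labels = self.labels_present  # sorted, 0 first

    def _start(self):
        s, _ = self._scale_slot()
        return [np.log(KAPPA_INIT)] + [np.log(OMEGA_INIT)] * len(self.omega_labels) + s

    def _bounds(self):
        _, sb = self._scale_slot()
        return [_LOG_KAPPA_BOUNDS] + [_LOG_OMEGA_BOUNDS] * len(self.omega_labels) + sb

    def _interpret(self, x):
        kappa = float(np.exp(x[0]))
        omegas = {
            lab: float(np.exp(x[1 + i])) for i, lab in enumerate(self.omega_labels)
        }
        s, _ = self._scale_from(x, 1 + len(self.omega_labels))
        classes = branch_omega_classes(omegas, self.pi, kappa, self.code)
        params = {"kappa": kappa, "branch_scale": s}
        params["omega_by_label"] = [omegas[lab] for lab in self.omega_labels]
        params["labels"] = list(self.omega_labels)
        return kappa, classes, s, params
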