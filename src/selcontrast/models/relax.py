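"""Selection-intensity (RELAX-style) models.

A three-category discrete omega distribution (omega0 <= omega1 <= 1 <=
omega2) with estimated proportions describes the reference branches; test
branches use the same categories raised to the selection-intensity exponent
k (omega_i^k).  k < 1 flattens the distribution toward 1 (relaxed
selection), k > 1 spreads it (intensified selection); the null fixes k = 1
and the LRT has 1 df.  Site categories are shared across the tree — each
site keeps one category on every branch — which is also how the simulator
generates k-scaled data.

The partitioned descriptive model (PDM) frees the test-branch omega values
from the k link (three unconstrained omegas on the test partition, shared
category proportions), nesting the alternative model inside it.
"""

from __future__ import annotations

import numpy as np

from .base import _LOG_KAPPA_BOUNDS, KAPPA_INIT, CodonModel
from .likelihood import SiteClass
from .matrices import equilibrium_rate

K_BOUNDS = (1e-3, 50.0)
_SIMPLEX_BOUNDS = (-12.0, 12.0)
# omega triple parametrized as omega1 = exp(-e1), omega0 = omega1*exp(-e0),
# omega2 = exp(v2) with e0, e1, v2 >= 0 enforcing omega0<=omega1<=1<=omega2
_E_BOUNDS = (0.0, 12.0)
_V2_BOUNDS = (0.0, np.log(50.0))


def _omega_triple(e1, e0, v2):
    w1 = float(np.exp(-e1))
    w0 = w1 * float(np.exp(-e0))
    w2 = float(np.exp(v2))
    return w0, w1, w2


def relax_classes(
    omegas, proportions, k, test_label: int = 1, *, pi, kappa,
    test_omegas=None, code=None,
) -> list[SiteClass]:
    """Site classes for the RELAX-style mixture.

    Reference branches (label 0) use ``omegas``; test branches use
    ``omega_i ** k`` unless explicit ``test_omegas`` are given (PDM).  The
    common scale is the mixture-mean rate on the reference branches.
    """
    omegas = [float(w) for w in omegas]
    if test_omegas is None:
        # clip the k-scaled values: at extreme k the likelihood is flat in
        # omega anyway and huge rates only cause numerical trouble
        test_omegas = [float(np.clip(w**k, 1e-6, 100.0)) for w in omegas]
    rho = sum(
        p * equilibrium_rate(pi, kappa, w, code=code)
        for p, w in zip(proportions, omegas)
    )
    return [
        SiteClass(p, {0: wr, test_label: wt}, {0: rho, test_label: rho})
        for p, wr, wt in zip(proportions, omegas, test_omegas)
    ]


class RelaxModel(CodonModel):
    """RELAX-style selection-intensity model.

    ``fix_k=1.0`` gives the null; ``fix_k=None`` (default) estimates k;
    ``pdm=True`` fits the partitioned descriptive model (k replaced by free
    test-branch omegas).
    """

    def __init__(self, alignment, tree, *, test_label: int = 1,
                 fix_k: float | None = None, pdm: bool = False, **kwargs):
        super().__init__(alignment, tree, **kwargs)
        if test_label not in self.labels_by_taxon.values():
            raise ValueError(f"test label {test_label} absent from tree labelling")
        self.test_label = test_label
        self.fix_k = fix_k
        self.pdm = pdm
        if pdm and fix_k is not None:
            raise ValueError("pdm and fix_k are mutually exclusive")

    # x layout: log kappa, z0, z1, e1, e0, v2, [log k | test triple], [log scale]
    def _start(self):
        s, _ = self._scale_slot()
        x = [np.log(KAPPA_INIT), np.log(0.6 / 0.1), np.log(0.3 / 0.1),
             0.3, 1.5, np.log(1.5)]
        if self.pdm:
            x += [0.3, 1.5, np.log(1.5)]
        elif self.fix_k is None:
            x.append(0.0)  # k init 1
        return x + s

    def _bounds(self):
        _, sb = self._scale_slot()
        b = [_LOG_KAPPA_BOUNDS, _SIMPLEX_BOUNDS, _SIMPLEX_BOUNDS,
             _E_BOUNDS, _E_BOUNDS, _V2_BOUNDS]
        if self.pdm:
            b += [_E_BOUNDS, _E_BOUNDS, _V2_BOUNDS]
        elif self.fix_k is None:
            b.append((np.log(K_BOUNDS[0]), np.log(K_BOUNDS[1])))
        return b + sb

    def _interpret(self, x):
        kappa = float(np.exp(x[0]))
        proportions = tuple(float(p) for p in self._softmax_simplex(x[1:3]))
        omegas = _omega_triple(x[3], x[4], x[5])
        offset = 6
        test_omegas = None
        k = 1.0
        if self.pdm:
            test_omegas = _omega_triple(x[6], x[7], x[8])
            offset = 9
        elif self.fix_k is None:
            k = float(np.exp(x[6]))
            offset = 7
        else:
            k = float(self.fix_k)
        s, _ = self._scale_from(x, offset)
        classes = relax_classes(
            omegas, proportions, k, self.test_label,
            pi=self.pi, kappa=kappa, test_omegas=test_omegas, code=self.code,
        )
        params = {
            "kappa": kappa,
            "omega_reference": list(omegas),
            "proportions": list(proportions),
            "branch_scale": s,
        }
        if self.pdm:
            params["omega_test"] = list(test_omegas)
        else:
            params["k"] = k
            params["omega_test"] = [w**k for w in omegas]
            params["k_at_bound"] = bool(
                k <= K_BOUNDS[0] * 1.0001 or k >= K_BOUNDS[1] * 0.9999
            )
        return kappa, classes, s, params
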