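"""Model / Results scaffolding for ML codon-model fits.

Concrete models subclass :class:`CodonModel`, declaring their free
parameters on a transformed (unconstrained-or-box-bounded) scale and a
mapping from transformed parameters to the site-class mixture the
likelihood engine consumes.  ``fit()`` runs bounded quasi-Newton
optimization (L-BFGS-B on log / logistic transformed parameters) with
optional jittered restarts and returns a :class:`CodonModelResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ..alignment import CodonAlignment
from ..trees import LabeledTree
from .likelihood import TreeIndex, compress_patterns, mixture_loglike, mixture_pattern_loglikes
from .matrices import estimate_f3x4, uniform_frequencies

OMEGA_REPORT_CAP = (0.01, 10.0)  # reporting convention; stored MLEs uncapped

# initial values for the ML searches (matching common codeml practice)
KAPPA_INIT = 2.0
OMEGA_INIT = 0.001

_LOG_KAPPA_BOUNDS = (np.log(0.05), np.log(100.0))
_LOG_OMEGA_BOUNDS = (np.log(1e-4), np.log(50.0))
_LOG_SCALE_BOUNDS = (np.log(1e-4), np.log(1e4))


def cap_omega(value: float) -> float:
    lo, hi = OMEGA_REPORT_CAP
    return min(max(value, lo), hi)


@dataclass
class CodonModelResults:
    """Outcome of one ML fit: maximized lnL, estimates, diagnostics."""

    model: "CodonModel"
    lnL: float
    params: dict
    x: np.ndarray
    converged: bool
    n_iter: int
    n_restarts: int
    branch_scale: float = 1.0

    @property
    def df_model(self) -> int:
        return self.x.size

    @property
    def omega_reported(self) -> dict:
        """Omega estimates capped to [0.01, 10] for reporting."""
        out = {}
        for key, val in self.params.items():
            if key.startswith("omega") or key == "w":
                if isinstance(val, (list, tuple)):
                    out[key] = [cap_omega(v) for v in val]
                else:
                    out[key] = cap_omega(val)
        return out

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} fit",
            "=" * 46,
            f"  log-likelihood {self.lnL:18.6f}",
            f"  free parameters {self.df_model:d}    converged: {self.converged}",
            f"  iterations {self.n_iter}  restarts used {self.n_restarts}",
            "-" * 46,
        ]
        for key, val in self.params.items():
            if isinstance(val, (list, tuple)):
                val = "[" + ", ".join(f"{v:.5g}" for v in val) + "]"
            elif isinstance(val, float):
                val = f"{val:.5g}"
            lines.append(f"  {key:<18} {val}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": type(self.model).__name__,
            "lnL": self.lnL,
            "params": {
                k: (list(v) if isinstance(v, (list, tuple, np.ndarray)) else v)
                for k, v in self.params.items()
            },
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "n_restarts": int(self.n_restarts),
            "omega_reported": self.omega_reported,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


class CodonModel:
    """Base class: a codon substitution model bound to one alignment+tree.

    Parameters
    ----------
    alignment, tree :
        The codon alignment and the labeled tree on the same taxa.
    contrast : str or None
        None keeps the three-state labelling; "present-absent" or
        "present-reduced" collapse to background/foreground.
    frequencies : "F3x4" | "uniform"
        Equilibrium codon frequency model (ignored when ``pi`` is given).
    branch_lengths : "scale" | "fixed"
        "scale" profiles a single multiplier of the input branch lengths as
        a free parameter; "fixed" trusts the input lengths.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: LabeledTree,
        *,
        contrast: str | None = None,
        frequencies: str = "F3x4",
        pi: np.ndarray | None = None,
        branch_lengths: str = "scale",
    ):
        if set(alignment.taxa) != set(tree.taxa):
            raise ValueError("alignment taxa and tree tips do not coincide")
        if branch_lengths not in ("scale", "fixed"):
            raise ValueError("branch_lengths must be 'scale' or 'fixed'")
        self.alignment = alignment
        self.tree = tree
        self.contrast = contrast
        self.labels_by_taxon = tree.terminal_labels(contrast)
        self.labels_present = sorted(set(self.labels_by_taxon.values()) | {0})
        self.tindex = TreeIndex(tree, self.labels_by_taxon)
        self.patterns, self.counts, self.column_to_pattern = compress_patterns(alignment)
        if pi is not None:
            self.pi = np.asarray(pi, dtype=float)
        elif frequencies == "F3x4":
            self.pi = estimate_f3x4(alignment)
        elif frequencies == "uniform":
            self.pi = uniform_frequencies(alignment.code)
        else:
            raise ValueError(f"unknown frequency model {frequencies!r}")
        self.branch_lengths = branch_lengths
        self.code = alignment.code
        self._eigen_cache: dict = {}

    # ---- subclass contract -------------------------------------------------
    def _start(self) -> list[float]:
        raise NotImplementedError

    def _bounds(self) -> list[tuple[float, float]]:
        raise NotImplementedError

    def _interpret(self, x: np.ndarray):
        """Transformed vector -> (kappa, classes, branch_scale, params dict)."""
        raise NotImplementedError

    # scale-parameter helpers shared by subclasses
    def _scale_slot(self):
        return ([np.log(1.0)], [_LOG_SCALE_BOUNDS]) if self.branch_lengths == "scale" else ([], [])

    def _scale_from(self, x, offset):
        if self.branch_lengths == "scale":
            return float(np.exp(x[offset])), offset + 1
        return 1.0, offset

    # ---- likelihood --------------------------------------------------------
    def loglike(self, x) -> float:
        kappa, classes, s, _ = self._interpret(np.asarray(x, dtype=float))
        class_logl = mixture_pattern_loglikes(
            self.tindex, self.patterns, self.alignment.taxa, self.pi, kappa,
            classes, s, code=self.code, eigen_cache=self._eigen_cache,
        )
        return mixture_loglike(class_logl, [c.proportion for c in classes], self.counts)

    def _negloglike(self, x) -> float:
        try:
            ll = self.loglike(x)
        except (ValueError, FloatingPointError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    # ---- fitting -----------------------------------------------------------
    def fit(
        self,
        start: np.ndarray | None = None,
        maxiter: int = 500,
        n_restarts: int = 3,
        seed: int = 0,
        jitter: float = 0.5,
    ) -> CodonModelResults:
        """Maximize the likelihood by bounded quasi-Newton.

        One run from the canonical start (or ``start``), then up to
        ``n_restarts`` jittered restarts whenever a run fails to converge
        or a restart might improve a boundary solution; the best run wins.
        """
        x0 = np.asarray(start if start is not None else self._start(), dtype=float)
        bounds = self._bounds()
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        rng = np.random.default_rng(seed)

        best = None
        used = 0
        for attempt in range(1 + n_restarts):
            if attempt == 0:
                xs = x0
            else:
                used += 1
                xs = np.clip(x0 + rng.normal(0.0, jitter, size=x0.size), lo, hi)
            res = minimize(
                self._negloglike,
                np.clip(xs, lo, hi),
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
            )
            if best is None or res.fun < best.fun - 1e-9:
                best = res
            if attempt == 0 and best.success and np.isfinite(best.fun):
                break  # canonical start converged; restarts are a fallback
        kappa, classes, s, params = self._interpret(best.x)
        return CodonModelResults(
            model=self,
            lnL=-float(best.fun),
            params=params,
            x=np.asarray(best.x),
            converged=bool(best.success),
            n_iter=int(best.nit),
            n_restarts=used,
            branch_scale=s,
        )

    # ---- shared simplex transform ------------------------------------------
    @staticmethod
    def _softmax_simplex(z):
        """Additive-logistic: len(z) free values -> len(z)+1 proportions."""
        z = np.concatenate([np.asarray(z, dtype=float), [0.0]])
        e = np.exp(z - z.max())
        return e / e.sum()
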