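"""Model comparison: AIC differences, Akaike weights, gene-flow family
weights and likelihood-ratio tests between nested fits.

The Akaike weight of model *i* among *R* compared models is

    W_i = exp(-dAIC_i / 2) / sum_j exp(-dAIC_j / 2),   dAIC_i = AIC_i - AIC_min,

computed after subtracting the minimum AIC for numerical stability.  The
weight of a gene-flow *family* (isolation-with-migration vs secondary
contact) is the sum of the weights of its member models, which is how
support for a gene-flow scenario is aggregated when several demographic
variants of each scenario are compared at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["akaike_weights", "ModelComparison", "family_weight", "lrt",
           "OptimizationFailure"]


class OptimizationFailure(RuntimeError):
    """Raised when a likelihood-ratio test sees ll_alt < ll_null beyond
    numerical tolerance, i.e. the alternative fit did not converge."""


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """Akaike weights w_i = exp(-dAIC_i/2) normalised to sum to one."""
    aics = np.asarray(aics, dtype=float)
    if aics.size < 2:
        raise ValueError("need at least two AIC values to compare")
    if not np.all(np.isfinite(aics)):
        raise ValueError("non-finite AIC values")
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class ModelComparison:
    """AIC leaderboard over a set of fitted models."""

    names: list[str]
    families: list[str]
    k: list[int]
    loglik: list[float]
    aic: np.ndarray
    delta_aic: np.ndarray = field(init=False)
    weights: np.ndarray = field(init=False)

    def __post_init__(self):
        self.aic = np.asarray(self.aic, dtype=float)
        n = len(self.names)
        if not (len(self.families) == len(self.k) == len(self.loglik) == n
                == self.aic.size):
            raise ValueError("inconsistent comparison table")
        self.delta_aic = self.aic - self.aic.min()
        # a single-model "comparison" is trivial but valid (weight one)
        self.weights = (np.ones(1) if n == 1 else akaike_weights(self.aic))

    @classmethod
    def from_fits(cls, fits: Sequence) -> "ModelComparison":
        """Build from :class:`~jafsim.inference.FitResult` objects (any
        object with ``model``, ``family``, ``k``, ``loglik``, ``aic``)."""
        return cls(
            names=[f.model for f in fits],
            families=[f.family for f in fits],
            k=[f.k for f in fits],
            loglik=[f.loglik for f in fits],
            aic=np.array([f.aic for f in fits]),
        )

    @property
    def best(self) -> str:
        return self.names[int(np.argmin(self.aic))]

    def weight_of(self, name: str) -> float:
        return float(self.weights[self.names.index(name)])

    def family_weights(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for fam, w in zip(self.families, self.weights):
            out[fam] = out.get(fam, 0.0) + float(w)
        return out

    def to_frame(self):
        """Leaderboard as a pandas DataFrame, best model first."""
        import pandas as pd

        df = pd.DataFrame({
            "model": self.names,
            "family": self.families,
            "K": self.k,
            "loglik": self.loglik,
            "AIC": self.aic,
            "dAIC": self.delta_aic,
            "W_AIC": self.weights,
        })
        return df.sort_values("AIC", ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def family_weight(comparison: ModelComparison, family: str) -> float:
    """Summed Akaike weight of all models labelled with ``family``."""
    if family not in comparison.families:
        raise ValueError(f"no model belongs to family {family!r}")
    return comparison.family_weights()[family]


def lrt(null_fit, alt_fit, df: int,
        mixture_weights: Sequence[float] | None = None,
        tol: float = 1e-6) -> tuple[float, float]:
    """Likelihood-ratio test between nested fits.

    D = 2 (ll_alt - ll_null); the p-value comes from a chi-squared
    distribution with ``df`` degrees of freedom, or from a user-supplied
    mixture of chi-squared(0..df) distributions when tested parameters sit
    on the boundary of their space (``mixture_weights[j]`` is the weight of
    the chi-squared with j degrees of freedom).
    """
    if df <= 0:
        raise ValueError("df must be positive (alt must have more parameters)")
    ll0 = null_fit.loglik if hasattr(null_fit, "loglik") else float(null_fit)
    ll1 = alt_fit.loglik if hasattr(alt_fit, "loglik") else float(alt_fit)
    d = 2.0 * (ll1 - ll0)
    if d < -tol * max(1.0, abs(ll0)):
        raise OptimizationFailure(
            f"alternative log-likelihood ({ll1:.4f}) below null ({ll0:.4f}); "
            "re-run the optimization")
    d = max(d, 0.0)
    if mixture_weights is None:
        p = float(stats.chi2.sf(d, df))
    else:
        w = np.asarray(mixture_weights, dtype=float)
        if w.size != df + 1 or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("mixture_weights must have df+1 entries summing to 1")
        p = float(w[0] * (d <= 0.0))
        for j in range(1, df + 1):
            p += float(w[j] * stats.chi2.sf(d, j))
    return d, p
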