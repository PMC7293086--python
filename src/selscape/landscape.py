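"""Slope and curvature of the fitness landscape, and the Lande response.

The slope of the landscape is the vector of directional selection
gradients beta; its curvature is C = gamma - beta betaᵀ, the quantity that
reshapes the additive genetic (co)variance matrix within a generation
(delta-G = G C G).  The curvature uses the regression-scale (undoubled)
quadratic diagonal: the doubled convention is a reporting device for
gamma_ii alone, and only the undoubled diagonal makes C the true Hessian
of the log mean-fitness surface.  A doubled-diagonal variant is exposed
behind a flag for methodological comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .gradients import GradientSet
from .synthdata import TRAITS

__all__ = [
    "SlopeVector",
    "CurvatureMatrix",
    "slope",
    "curvature",
    "curvature_contrast",
    "lande_response",
]


@dataclass
class SlopeVector:
    """Directional-gradient vector (diam, clutch, pref) with optional CIs."""

    beta: np.ndarray
    treatment: str
    ci: Optional[np.ndarray] = None            # (3, 2)
    under_selection: Optional[np.ndarray] = None  # bool flags, CI excludes 0

    @property
    def n_under_selection(self) -> int:
        if self.under_selection is None:
            return 0
        return int(self.under_selection.sum())


@dataclass
class CurvatureMatrix:
    """Symmetric 3x3 curvature of the fitness landscape (z-trait scale)."""

    C: np.ndarray
    treatment: str
    ci: Optional[np.ndarray] = None            # (3, 3, 2)
    doubled_diagonal: bool = False

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, float)
        if self.C.shape != (3, 3) or not np.allclose(self.C, self.C.T, atol=1e-12):
            raise ValueError("curvature matrix must be symmetric 3x3")

    def element(self, trait_i: str, trait_j: str) -> float:
        i, j = TRAITS.index(trait_i), TRAITS.index(trait_j)
        return float(self.C[i, j])


def slope(g: GradientSet) -> SlopeVector:
    """Slope of the landscape; flags traits whose CI excludes zero."""
    flags = None
    if g.beta_ci is not None:
        ci = np.asarray(g.beta_ci, float)
        flags = (ci[:, 0] > 0.0) | (ci[:, 1] < 0.0)
    return SlopeVector(beta=g.beta.copy(), treatment=g.treatment,
                       ci=None if g.beta_ci is None else np.asarray(g.beta_ci, float),
                       under_selection=flags)


def curvature(g: GradientSet, use_doubled: bool = False) -> CurvatureMatrix:
    """C = gamma - beta betaᵀ on the regression (undoubled-diagonal) scale.

    ``use_doubled=True`` substitutes the doubled-diagonal gamma, for
    comparing conventions.
    """
    gamma = g.gamma_doubled if use_doubled else g.gamma_raw
    C = gamma - np.outer(g.beta, g.beta)
    C = 0.5 * (C + C.T)  # exact symmetry against floating-point noise
    return CurvatureMatrix(C=C, treatment=g.treatment, doubled_diagonal=use_doubled)


def curvature_contrast(c_removal: CurvatureMatrix,
                       c_original: CurvatureMatrix) -> CurvatureMatrix:
    """Element-wise removal-minus-original difference."""
    if c_removal.C.shape != c_original.C.shape:
        raise ValueError("curvature matrices have mismatched shapes")
    if c_removal.doubled_diagonal != c_original.doubled_diagonal:
        raise ValueError("curvature matrices use different diagonal conventions")
    return CurvatureMatrix(
        C=c_removal.C - c_original.C,
        treatment=f"{c_removal.treatment}-{c_original.treatment}",
        doubled_diagonal=c_removal.doubled_diagonal)


def lande_response(G: np.ndarray, s: "SlopeVector | np.ndarray") -> np.ndarray:
    """One-generation response to selection, delta-z-bar = G beta."""
    G = np.asarray(G, float)
    beta = s.beta if isinstance(s, SlopeVector) else np.asarray(s, float)
    if G.shape != (len(beta), len(beta)):
        raise ValueError("G must be square and conformable with beta")
    if not np.allclose(G, G.T, atol=1e-8):
        raise ValueError("G must be symmetric")
    return G @ beta


def curvature_ci_from_replicates(C_reps: Sequence[np.ndarray],
                                 level: float = 0.95) -> np.ndarray:
    """Percentile interval per element over bootstrap curvature matrices."""
    arr = np.asarray(list(C_reps), float)
    lo = (1.0 - level) / 2.0
    return np.stack([np.quantile(arr, lo, axis=0),
                     np.quantile(arr, 1.0 - lo, axis=0)], axis=-1)
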