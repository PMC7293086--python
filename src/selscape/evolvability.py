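"""Curvature effects on G-matrix evolvability.

Because the curvature of the fitness landscape changes the additive
genetic (co)variance matrix within a generation (delta-G = G C G), two
selection regimes can be compared by how they reshape a common collection
of plausible G-matrices.  Average evolvability (Hansen-Houle) of a matrix
is E[betaᵀ G beta] over random unit-length selection directions, which
equals tr(G)/k analytically; the Monte-Carlo version with a shared beta
sample is used so that paired regime differences have low variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import CurvatureMatrix

__all__ = [
    "GMatrixEnsemble",
    "EvolvabilityResult",
    "sample_G",
    "sample_unit_betas",
    "delta_G",
    "average_evolvability",
    "fraction_decreased",
]


@dataclass
class EvolvabilityResult:
    """Paired change in average evolvability across a G-matrix ensemble."""

    n_G: int
    n_beta: int
    delta_e: np.ndarray          # removal-scenario minus original-scenario
    fraction_decreased: float
    seed: int
    n_excluded: int = 0
    sampler: str = "onion"

    def to_json_dict(self) -> dict:
        return {
            "fraction_decreased": self.fraction_decreased,
            "n_G": self.n_G, "n_beta": self.n_beta,
            "seed": self.seed, "excluded": self.n_excluded,
            "sampler": self.sampler,
        }


# kept as an alias for the ensemble container: a stack of (n, 3, 3) matrices
GMatrixEnsemble = np.ndarray


def _onion_correlation(rng: np.random.Generator, d: int = 3) -> np.ndarray:
    """Uniform draw from the space of d x d correlation matrices (onion
    method, LKJ shape parameter 1)."""
    R = np.eye(d)
    b = 1.0 + (d - 2) / 2.0
    R[0, 1] = R[1, 0] = 2.0 * rng.beta(b, b) - 1.0
    for k in range(2, d):
        bk = 1.0 + (d - 1 - k) / 2.0
        y = rng.beta(k / 2.0, bk)
        u = rng.normal(size=k)
        u /= np.linalg.norm(u)
        w = np.sqrt(y) * u
        z = np.linalg.cholesky(R[:k, :k]) @ w
        R[:k, k] = z
        R[k, :k] = z
    return R


def sample_G(n: int, vg_max: float = 0.5, seed: int = 0,
             method: str = "onion") -> np.ndarray:
    """Sample ``n`` random 3x3 G-matrices, stacked as (n, 3, 3).

    ``method='onion'`` (default): diagonal variances uniform on
    (0, vg_max) combined with a uniformly random correlation matrix —
    every draw is a valid (PSD) covariance matrix by construction.
    ``method='elementwise'``: variances uniform on (0, vg_max) and
    covariances uniform within their PSD-feasible element-wise bounds,
    accepted by rejection; provided for sensitivity analysis because the
    simulated fraction can depend on the sampling scheme.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if vg_max <= 0:
        raise ValueError("vg_max must be positive")
    rng = np.random.default_rng(seed)
    out = np.empty((n, 3, 3))
    if method == "onion":
        for i in range(n):
            d = rng.uniform(0.0, vg_max, 3)
            s = np.sqrt(d)
            out[i] = _onion_correlation(rng) * np.outer(s, s)
    elif method == "elementwise":
        i = 0
        while i < n:
            d = rng.uniform(0.0, vg_max, 3)
            s = np.sqrt(d)
            G = np.diag(d).astype(float)
            for (a, bb) in ((0, 1), (0, 2), (1, 2)):
                lim = s[a] * s[bb]
                G[a, bb] = G[bb, a] = rng.uniform(-lim, lim)
            if np.linalg.eigvalsh(G)[0] >= -1e-12:
                out[i] = G
                i += 1
    else:
        raise ValueError("method must be 'onion' or 'elementwise'")
    return out


def sample_unit_betas(n: int, seed: int, d: int = 3) -> np.ndarray:
    """Unit vectors uniform on the sphere (normalized iid Gaussians)."""
    rng = np.random.default_rng(seed)
    b = rng.normal(size=(n, d))
    return b / np.linalg.norm(b, axis=1, keepdims=True)


def delta_G(G: np.ndarray, C: "CurvatureMatrix | np.ndarray") -> np.ndarray:
    """Within-generation change of the G-matrix: delta-G = G C G."""
    G = np.asarray(G, float)
    Cm = C.C if isinstance(C, CurvatureMatrix) else np.asarray(C, float)
    if G.shape != Cm.shape or G.shape[0] != G.shape[1]:
        raise ValueError("G and C must be square matrices of the same size")
    return G @ Cm @ G


def average_evolvability(G: np.ndarray, betas: np.ndarray) -> float:
    """Mean of betaᵀ G beta over the supplied unit selection directions."""
    G = np.asarray(G, float)
    betas = np.atleast_2d(np.asarray(betas, float))
    if betas.size == 0:
        raise ValueError("need at least one selection direction")
    norms = np.linalg.norm(betas, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise ValueError("selection directions must have unit Euclidean norm")
    return float(np.einsum("bi,ij,bj->b", betas, G, betas).mean())


def fraction_decreased(Gs: np.ndarray, C_removal, C_original,
                       n_beta: int = 1000, seed: int = 0) -> EvolvabilityResult:
    """Fraction of G-matrices whose average evolvability drops under the
    removal curvature relative to the original curvature.

    For each G the post-selection matrices G'_t = G + G C_t G are compared
    through their Monte-Carlo average evolvability over one shared sample
    of ``n_beta`` unit directions (paired design).  G-matrices whose
    post-selection diagonal goes negative under either regime are excluded
    and counted.
    """
    Gs = np.asarray(Gs, float)
    if Gs.ndim != 3 or Gs.shape[0] < 1:
        raise ValueError("Gs must be a non-empty stack of matrices")
    Cr = C_removal.C if isinstance(C_removal, CurvatureMatrix) else np.asarray(C_removal, float)
    Co = C_original.C if isinstance(C_original, CurvatureMatrix) else np.asarray(C_original, float)
    betas = sample_unit_betas(n_beta, seed, d=Gs.shape[1])

    G_rem = Gs + np.einsum("nij,jk,nkl->nil", Gs, Cr, Gs)
    G_org = Gs + np.einsum("nij,jk,nkl->nil", Gs, Co, Gs)
    diag_ok = ((np.diagonal(G_rem, axis1=1, axis2=2) >= 0).all(axis=1)
               & (np.diagonal(G_org, axis1=1, axis2=2) >= 0).all(axis=1))
    M = G_rem - G_org
    delta_e = np.einsum("bi,nij,bj->nb", betas, M, betas).mean(axis=1)
    delta_e = delta_e[diag_ok]
    n_kept = int(diag_ok.sum())
    if n_kept == 0:
        raise ValueError("every G-matrix was excluded (negative variances)")
    return EvolvabilityResult(
        n_G=n_kept, n_beta=n_beta, delta_e=delta_e,
        fraction_decreased=float((delta_e < 0).sum() / n_kept),
        seed=seed, n_excluded=int(len(Gs) - n_kept))
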