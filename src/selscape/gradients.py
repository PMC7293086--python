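"""Standardized selection gradients from logistic selection surfaces.

Logistic-surface coefficients live on the log-odds scale; the Janzen-Stern
rescaling turns them into Lande-Arnold selection gradients by multiplying
each coefficient by the average of W(z)[1 - W(z)] over the analysis rows
and dividing by mean fitness W-bar, which puts them on the relative-fitness
scale.  Directional gradients come from the linear-only surface, quadratic
and correlational gradients from the full surface.  Quadratic terms are
doubled after rescaling for reporting (the Stinchcombe convention) while
the undoubled, regression-scale diagonal is retained for the curvature
matrix.  The module also implements the expression-bias adjustment for
chamber diameter: within galls that show survival variation, any
survival-diameter association reflects parasitism altering trait
expression rather than selection, and its mean is subtracted from the
diameter coefficient before gradients are computed.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .glmm import SurfaceFit, SurfaceSpec, fit_surface, parametric_bootstrap
from .synthdata import PAIRS

__all__ = [
    "GradientSet",
    "BiasEstimate",
    "janzen_stern",
    "estimate_expression_bias",
    "apply_bias_adjustment",
    "counterfactual_rescale",
]

GRADIENT_NAMES = (
    "beta_diam", "beta_clutch", "beta_pref",
    "gamma_diam_diam", "gamma_clutch_clutch", "gamma_pref_pref",
    "gamma_diam_clutch", "gamma_diam_pref", "gamma_clutch_pref",
)


@dataclass
class GradientSet:
    """Standardized selection gradients for one treatment.

    ``gamma_doubled`` carries the reporting convention (doubled diagonal);
    ``gamma_raw`` keeps the undoubled regression-scale diagonal used for
    the landscape curvature.  Off-diagonals are identical between the two.
    """

    treatment: str
    beta: np.ndarray                  # (3,) directional gradients
    gamma_doubled: np.ndarray         # (3, 3) symmetric, doubled diagonal
    gamma_raw: np.ndarray             # (3, 3) symmetric, undoubled diagonal
    mean_fitness: float               # W-bar of the linear fit's rows
    mean_wq: float                    # mean of W(1-W), linear fit
    mean_fitness_full: float = np.nan
    mean_wq_full: float = np.nan
    bias_adjusted: bool = False
    counterfactual: bool = False
    beta_ci: Optional[np.ndarray] = None        # (3, 2)
    gamma_ci: Optional[np.ndarray] = None       # (3, 3, 2), doubled scale

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, float)
        self.gamma_doubled = np.asarray(self.gamma_doubled, float)
        self.gamma_raw = np.asarray(self.gamma_raw, float)
        if self.beta.shape != (3,):
            raise ValueError("beta must be a 3-vector")
        for g in (self.gamma_doubled, self.gamma_raw):
            if g.shape != (3, 3) or not np.allclose(g, g.T, atol=1e-12):
                raise ValueError("gamma must be symmetric 3x3")
        if not np.allclose(np.diag(self.gamma_doubled),
                           2.0 * np.diag(self.gamma_raw), atol=1e-12):
            raise ValueError("gamma_doubled diagonal must be twice gamma_raw's")
        off = ~np.eye(3, dtype=bool)
        if not np.allclose(self.gamma_doubled[off], self.gamma_raw[off], atol=1e-12):
            raise ValueError("off-diagonal gammas must match between conventions")
        if not 0.0 < self.mean_fitness < 1.0:
            raise ValueError("mean fitness must lie in (0, 1)")

    def as_series(self) -> pd.Series:
        vals = list(self.beta) + list(np.diag(self.gamma_doubled)) + [
            self.gamma_doubled[i, j] for i, j in PAIRS]
        return pd.Series(vals, index=list(GRADIENT_NAMES))


@dataclass
class BiasEstimate:
    """Logit-scale survival-diameter slope in within-gall-varying galls."""

    alpha_diam_bias: dict            # treatment -> point estimate
    ci: dict                         # treatment -> (lo, hi)
    n_rows: dict = field(default_factory=dict)
    method: str = "wald"
    replicates: Optional[pd.DataFrame] = None  # bootstrap draws per treatment


def _scaling(fit: SurfaceFit, treatment: str,
             w_bar_source: str = "fitted") -> tuple[float, float]:
    rows = fit.treatment_rows(treatment)
    if not rows.any():
        raise ValueError(f"fit contains no rows for treatment {treatment!r}")
    p = fit.fitted_p[rows]
    w_bar = float(p.mean()) if w_bar_source == "fitted" else float(fit.y[rows].mean())
    mean_wq = float((p * (1.0 - p)).mean())
    if not 0.0 < w_bar < 1.0:
        raise ValueError("degenerate mean fitness (0 or 1)")
    return w_bar, mean_wq


def janzen_stern(linear_fit: SurfaceFit, full_fit: SurfaceFit, treatment: str,
                 w_bar_source: str = "fitted") -> GradientSet:
    """Rescale surface coefficients to selection gradients for ``treatment``.

    Each coefficient is multiplied by mean(W(1-W))/W-bar computed from the
    fitted probabilities (random effects at zero) of the model it comes
    from: the linear-only fit supplies the directional terms, the full fit
    the quadratic and interaction terms.  ``w_bar_source='observed'``
    switches W-bar to the observed survival fraction.
    """
    if linear_fit.spec.order != "linear" or full_fit.spec.order != "full":
        raise ValueError("janzen_stern needs a linear-only fit and a full fit")
    w_bar, mean_wq = _scaling(linear_fit, treatment, w_bar_source)
    w_bar_f, mean_wq_f = _scaling(full_fit, treatment, w_bar_source)

    a_lin = linear_fit.alpha[treatment]
    a_full = full_fit.alpha[treatment]
    beta = np.array([a_lin[t] for t in ("z_diam", "z_clutch", "z_pref")])
    beta *= mean_wq / w_bar

    quad = np.array([a_full[f"{t}^2"] for t in ("z_diam", "z_clutch", "z_pref")])
    inter = np.array([a_full["z_diam:z_clutch"], a_full["z_diam:z_pref"],
                      a_full["z_clutch:z_pref"]])
    quad = quad * mean_wq_f / w_bar_f        # regression-scale gamma diagonal
    inter = inter * mean_wq_f / w_bar_f
    gamma_raw = np.diag(quad).astype(float)
    for val, (i, j) in zip(inter, PAIRS):
        gamma_raw[i, j] = gamma_raw[j, i] = val
    gamma_doubled = gamma_raw + np.diag(quad)  # doubling after rescaling

    return GradientSet(
        treatment=treatment, beta=beta, gamma_doubled=gamma_doubled,
        gamma_raw=gamma_raw, mean_fitness=w_bar, mean_wq=mean_wq,
        mean_fitness_full=w_bar_f, mean_wq_full=mean_wq_f,
        bias_adjusted=linear_fit.bias_adjusted,
    )


def estimate_expression_bias(table: pd.DataFrame, n_boot: int = 0,
                             seed: int = 0) -> BiasEstimate:
    """Estimate the survival-diameter expression bias per treatment.

    Subsets to galls with within-gall survival variation (0 < mean < 1) and
    fits the nested mixed-logistic model with standardized diameter as the
    only fixed effect, separately per treatment.  The interval is a 95%
    Wald interval, or a percentile parametric-bootstrap interval when
    ``n_boot > 0``.  An empty subset fixes the bias at 0 with a warning.
    """
    if "z_diam" not in table.columns:
        raise ValueError("table must be standardized first")
    frac = table.groupby("gall_id")["survival"].transform("mean")
    subset = table[(frac > 0) & (frac < 1)]
    est, ci, n_rows = {}, {}, {}
    rep_cols = {}
    method = "bootstrap" if n_boot > 0 else "wald"
    for t in sorted(table["treatment"].unique()):
        sub = subset[subset["treatment"] == t]
        n_rows[t] = len(sub)
        levels_ok = (len(sub) > 0
                     and sub["gall_id"].nunique() >= 2
                     and sub["plant_id"].nunique() >= 2
                     and sub["genotype_id"].nunique() >= 2)
        if not levels_ok:
            warnings.warn(
                f"no usable within-gall survival variation in treatment {t!r}; "
                "expression bias fixed at 0", RuntimeWarning)
            est[t] = 0.0
            ci[t] = (0.0, 0.0)
            continue
        spec = _diam_only_spec()
        fit = _fit_diam_only(sub, spec)
        a = fit.alpha[t]["z_diam"]
        se = fit.alpha_se[t]["z_diam"]
        est[t] = float(a)
        if n_boot > 0 and fit.converged:
            dist = parametric_bootstrap(
                fit, n_boot, seed, statistic=lambda f, tt=t: {"bias": f.alpha[tt]["z_diam"]})
            lo, hi = dist.ci().loc["bias"]
            ci[t] = (float(lo), float(hi))
            rep_cols[t] = dist.replicates["bias"]
        else:
            ci[t] = (float(a - 1.96 * se), float(a + 1.96 * se))
    reps = pd.DataFrame(rep_cols) if rep_cols else None
    return BiasEstimate(alpha_diam_bias=est, ci=ci, n_rows=n_rows, method=method,
                        replicates=reps)


def _diam_only_spec() -> SurfaceSpec:
    return SurfaceSpec(response="survival", order="linear", by_treatment=False,
                       terms=("z_diam",))


def _fit_diam_only(sub: pd.DataFrame, spec: SurfaceSpec) -> SurfaceFit:
    return fit_surface(sub, spec)


def apply_bias_adjustment(fit: SurfaceFit, bias: BiasEstimate) -> SurfaceFit:
    """Subtract the mean bias from the linear diameter coefficient.

    Only the linear z_diam term is touched; fitted probabilities are
    recomputed from the adjusted coefficients so downstream W-bar and
    mean W(1-W) stay self-consistent.  Applying the adjustment twice is an
    error.
    """
    if fit.bias_adjusted:
        raise ValueError("bias adjustment already applied to this fit")
    params = fit.params.copy()
    alpha = {t: dict(a) for t, a in fit.alpha.items()}
    # adjust the shared main effect by the baseline treatment's bias and the
    # treatment interaction by the difference, so each treatment's
    # reconstructed coefficient drops by exactly its own mean bias
    treatments = sorted(alpha)
    base = treatments[0]
    b_base = bias.alpha_diam_bias.get(base, 0.0)
    params["z_diam"] = params["z_diam"] - b_base
    if "treat:z_diam" in params.index and "removal" in bias.alpha_diam_bias:
        params["treat:z_diam"] = (params["treat:z_diam"]
                                  - (bias.alpha_diam_bias["removal"] - b_base))
    for t in treatments:
        alpha[t]["z_diam"] = alpha[t]["z_diam"] - bias.alpha_diam_bias.get(t, 0.0)
    from scipy.special import expit  # local to avoid polluting module surface
    fitted_p = fit.fitted_p
    if fit.design is not None:
        fitted_p = expit(fit.design.X @ params.to_numpy())
    return dataclasses.replace(fit, params=params, alpha=alpha,
                               fitted_p=fitted_p, bias_adjusted=True)


def counterfactual_rescale(g: GradientSet, target_mean_fitness: float) -> GradientSet:
    """Recompute gradients as if mean fitness equalled ``target_mean_fitness``.

    mean W(1-W) is held at its fitted value, so every gradient scales by
    W-bar / target.  Used for the what-if contrast in which the removal
    food web's survival is set equal to the original's.
    """
    if not 0.0 < target_mean_fitness < 1.0:
        raise ValueError("target mean fitness must lie in (0, 1)")
    scale_lin = g.mean_fitness / target_mean_fitness
    w_full = g.mean_fitness_full if np.isfinite(g.mean_fitness_full) else g.mean_fitness
    scale_full = w_full / target_mean_fitness
    return dataclasses.replace(
        g,
        beta=g.beta * scale_lin,
        gamma_doubled=g.gamma_doubled * scale_full,
        gamma_raw=g.gamma_raw * scale_full,
        mean_fitness=target_mean_fitness,
        mean_fitness_full=target_mean_fitness,
        counterfactual=not np.isclose(target_mean_fitness, g.mean_fitness)
        or g.counterfactual,
        beta_ci=None, gamma_ci=None,
    )
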