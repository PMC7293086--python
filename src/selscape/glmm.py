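"""Binomial mixed models for selection surfaces, with parametric bootstrap.

The selection-surface model is a logistic regression of larval survival
(or egg parasitism) on standardized traits with Gaussian random intercepts
for gall nested in plant nested in genotype.  Estimation maximizes the
Laplace-approximate marginal likelihood: for candidate random-effect SDs,
the fixed effects and random-effect modes are found jointly by penalized
iteratively reweighted least squares, and the profiled Laplace deviance is
minimized over the (at most three) SD parameters by a bounded
derivative-free search, with the zero-variance boundary handled by
dropping the corresponding block.  Because the grouping factors are
strictly nested, the penalized Hessian of the random effects factorizes by
an exact level-by-level LDL^T elimination (galls, then plants, then
genotypes) whose cost is linear in the number of observations; this is
what makes parametric bootstrapping of the full pipeline affordable.  At
zero variance the fit reduces exactly to ordinary logistic regression,
which the tests exploit as an oracle.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "SurfaceSpec",
    "SurfaceFit",
    "BootstrapDistribution",
    "fit_surface",
    "parametric_bootstrap",
    "contrast",
]

TERM_NAMES = ("z_diam", "z_clutch", "z_pref")
QUAD_NAMES = ("z_diam^2", "z_clutch^2", "z_pref^2")
INTER_NAMES = ("z_diam:z_clutch", "z_diam:z_pref", "z_clutch:z_pref")
#: random-intercept levels, outermost to innermost
GROUP_LEVELS = ("genotype", "plant", "gall")
#: elimination order for the nested factorization, innermost first
ELIM_ORDER = ("gall", "plant", "genotype")

#: coefficient cap beyond which a fit is flagged as separated
SEPARATION_CAP = 10.0
_SIGMA_FLOOR = 1e-8   # below this an RE block is treated as absent
_SIGMA_SNAP = 1e-4    # boundary snap after outer optimization


@dataclass(frozen=True)
class SurfaceSpec:
    """What surface to fit.

    ``order='linear'`` fits only first-order trait terms (the valid basis
    for directional gradients); ``order='full'`` adds the three quadratic
    and three interaction terms.  With ``by_treatment=True`` a single
    joint model with a treatment main effect and treatment-by-term
    interactions is fitted and per-treatment coefficients are
    reconstructed by summing.
    """

    response: str = "survival"
    order: str = "linear"
    by_treatment: bool = True
    terms: tuple[str, ...] = TERM_NAMES

    def __post_init__(self) -> None:
        if self.response not in ("survival", "egg_parasitism"):
            raise ValueError("response must be 'survival' or 'egg_parasitism'")
        if self.order not in ("linear", "full"):
            raise ValueError("order must be 'linear' or 'full'")
        kept = tuple(t for t in TERM_NAMES if t in self.terms)
        if kept != tuple(self.terms):
            raise ValueError(f"terms must be an ordered subset of {TERM_NAMES}")
        if self.order == "full" and kept != TERM_NAMES:
            raise ValueError("a full surface requires all three traits")

    @property
    def term_names(self) -> tuple[str, ...]:
        if self.order == "linear":
            return tuple(self.terms)
        return TERM_NAMES + QUAD_NAMES + INTER_NAMES


@dataclass
class _Design:
    """Frozen design information reused by the parametric bootstrap."""

    X: np.ndarray
    colnames: list[str]
    y: np.ndarray
    codes: dict                      # level -> (n,) group code per row
    group_sizes: dict                # level -> number of groups
    parents: dict                    # "gall"-> plant code per gall, "plant"-> genotype code per plant
    row_treatment: np.ndarray
    index: pd.Index


@dataclass
class SurfaceFit:
    """A fitted selection surface (coefficients on the logit scale)."""

    spec: SurfaceSpec
    params: pd.Series
    cov_params: pd.DataFrame
    alpha: dict                       # treatment -> {name: coefficient}
    alpha_se: dict                    # treatment -> {name: Wald SE}
    re_var: dict                      # level -> variance of random intercept
    fitted_p: np.ndarray              # probabilities with REs at zero
    loglik: float
    converged: bool
    separation: bool
    row_treatment: np.ndarray
    y: np.ndarray
    bias_adjusted: bool = False
    design: _Design = field(repr=False, default=None)

    @property
    def re_sd(self) -> dict:
        return {k: float(np.sqrt(v)) for k, v in self.re_var.items()}

    def treatment_rows(self, treatment: str) -> np.ndarray:
        return self.row_treatment == treatment

    def to_json_dict(self) -> dict:
        return {
            "spec": dataclasses.asdict(self.spec),
            "params": self.params.to_dict(),
            "alpha": self.alpha,
            "alpha_se": self.alpha_se,
            "re_var": self.re_var,
            "loglik": self.loglik,
            "converged": self.converged,
            "separation": self.separation,
            "bias_adjusted": self.bias_adjusted,
        }


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _response_vector(table: pd.DataFrame, response: str) -> np.ndarray:
    if response == "survival":
        return table["survival"].to_numpy(int)
    return (table["fate"] == "egg_parasitized").to_numpy(int)


def _term_columns(table: pd.DataFrame, names: tuple[str, ...]) -> np.ndarray:
    if not names:
        return np.empty((len(table), 0))
    z = table[list(TERM_NAMES)].to_numpy(float)
    cols = {
        "z_diam": z[:, 0], "z_clutch": z[:, 1], "z_pref": z[:, 2],
        "z_diam^2": z[:, 0] ** 2, "z_clutch^2": z[:, 1] ** 2, "z_pref^2": z[:, 2] ** 2,
        "z_diam:z_clutch": z[:, 0] * z[:, 1],
        "z_diam:z_pref": z[:, 0] * z[:, 2],
        "z_clutch:z_pref": z[:, 1] * z[:, 2],
    }
    return np.column_stack([cols[n] for n in names])


def build_design(table: pd.DataFrame, spec: SurfaceSpec) -> _Design:
    for col in TERM_NAMES:
        if col not in table.columns:
            raise ValueError("table must be standardized first (missing z columns)")
    n = len(table)
    y = _response_vector(table, spec.response)
    treat = table["treatment"].to_numpy()
    names = spec.term_names
    T = _term_columns(table, names)

    both = spec.by_treatment and len(np.unique(treat)) == 2
    if both:
        d = (treat == "removal").astype(float)
        X = np.column_stack([np.ones(n), d, T, T * d[:, None]])
        colnames = (["intercept", "treat"] + list(names)
                    + [f"treat:{t}" for t in names])
    else:
        X = np.column_stack([np.ones(n), T])
        colnames = ["intercept"] + list(names)

    codes, sizes = {}, {}
    for level, col in (("genotype", "genotype_id"), ("plant", "plant_id"),
                       ("gall", "gall_id")):
        c, uniques = pd.factorize(table[col], sort=True)
        if len(uniques) < 2:
            raise ValueError(f"need >= 2 levels of {col} to fit random intercepts")
        codes[level] = c
        sizes[level] = len(uniques)
    # nesting maps (consistent by the table invariants): gall -> plant,
    # plant -> genotype
    parents = {}
    g2p = np.zeros(sizes["gall"], dtype=int)
    g2p[codes["gall"]] = codes["plant"]
    parents["gall"] = g2p
    p2g = np.zeros(sizes["plant"], dtype=int)
    p2g[codes["plant"]] = codes["genotype"]
    parents["plant"] = p2g
    return _Design(X=X, colnames=colnames, y=y, codes=codes, group_sizes=sizes,
                   parents=parents, row_treatment=treat, index=table.index)


def design_Z(design: _Design) -> sparse.csr_matrix:
    """Sparse random-effect design matrix (columns ordered gall, plant,
    genotype), used by the simulator and by cross-check tests."""
    n = len(design.y)
    col_idx, off = [], 0
    for level in ELIM_ORDER:
        col_idx.append(design.codes[level] + off)
        off += design.group_sizes[level]
    rows = np.tile(np.arange(n), 3)
    return sparse.csr_matrix(
        (np.ones(3 * n), (rows, np.concatenate(col_idx))), shape=(n, off))


# ---------------------------------------------------------------------------
# nested LDL^T factorization of the penalized random-effect Hessian
# ---------------------------------------------------------------------------

class _NestedFactor:
    """Exact LDL^T of H = Z' W Z + diag(lambda) for strictly nested
    random intercepts, eliminating innermost levels first.

    Every off-diagonal entry of H couples a group with one of its
    ancestors and equals the summed weight of the inner group, so
    elimination preserves the nested sparsity and runs in O(n).
    """

    def __init__(self, design: _Design, sigma: np.ndarray):
        # active levels in elimination order with their precision
        self.levels = []
        sig = {lvl: sigma[GROUP_LEVELS.index(lvl)] for lvl in GROUP_LEVELS}
        for lvl in ELIM_ORDER:
            if sig[lvl] > _SIGMA_FLOOR:
                self.levels.append(lvl)
        self.lam = {lvl: 1.0 / sig[lvl] ** 2 for lvl in self.levels}
        self.codes = {lvl: design.codes[lvl] for lvl in self.levels}
        self.q = {lvl: design.group_sizes[lvl] for lvl in self.levels}
        # ancestor maps between active levels, composed through any
        # inactive intermediate level
        full_parent = {"gall": ("plant", design.parents["gall"]),
                       "plant": ("genotype", design.parents["plant"]),
                       "genotype": (None, None)}
        self.anc: dict[tuple[str, str], np.ndarray] = {}
        for i, lvl in enumerate(self.levels):
            cur, amap = lvl, np.arange(self.q[lvl])
            for outer in self.levels[i + 1:]:
                while cur != outer:
                    nxt, pmap = full_parent[cur]
                    amap = pmap[amap]
                    cur = nxt
                self.anc[(lvl, outer)] = amap
        self.d: dict[str, np.ndarray] = {}
        self.cross: dict[tuple[str, str], np.ndarray] = {}

    @property
    def q_total(self) -> int:
        return sum(self.q.values())

    def factor(self, w: np.ndarray) -> None:
        """Factorize for row weights ``w`` (IRLS working weights)."""
        k = len(self.levels)
        for lvl in self.levels:
            sw = np.bincount(self.codes[lvl], weights=w, minlength=self.q[lvl])
            self.d[lvl] = sw + self.lam[lvl]
            for outer in self.levels[self.levels.index(lvl) + 1:]:
                self.cross[(lvl, outer)] = sw.copy()
        for i in range(k):
            li = self.levels[i]
            inv_d = 1.0 / self.d[li]
            for a in range(i + 1, k):
                m1 = self.levels[a]
                t1 = self.cross[(li, m1)] * inv_d
                for b in range(a, k):
                    m2 = self.levels[b]
                    contrib = t1 * self.cross[(li, m2)]
                    agg = np.bincount(self.anc[(li, m1)], weights=contrib,
                                      minlength=self.q[m1])
                    if m1 == m2:
                        self.d[m1] = self.d[m1] - agg
                    else:
                        self.cross[(m1, m2)] = self.cross[(m1, m2)] - agg

    def logdet(self) -> float:
        return float(sum(np.log(self.d[lvl]).sum() for lvl in self.levels))

    def solve(self, rhs: dict) -> dict:
        """Solve H x = r for a dict of per-level arrays (1-D or 2-D)."""
        k = len(self.levels)
        u = {lvl: np.array(rhs[lvl], dtype=float, copy=True) for lvl in self.levels}
        two_d = any(u[lvl].ndim == 2 for lvl in self.levels)

        def dcol(lvl):
            return self.d[lvl][:, None] if two_d else self.d[lvl]

        def ccol(pair):
            return self.cross[pair][:, None] if two_d else self.cross[pair]

        for i in range(k):          # forward: L u = r
            li = self.levels[i]
            t = u[li] / dcol(li)
            for m in self.levels[i + 1:]:
                np.subtract.at(u[m], self.anc[(li, m)], ccol((li, m)) * t)
        x = {lvl: u[lvl] / dcol(lvl) for lvl in self.levels}  # D solve
        for i in range(k - 2, -1, -1):  # backward: L^T x = v
            li = self.levels[i]
            acc = np.zeros_like(x[li])
            for m in self.levels[i + 1:]:
                acc += ccol((li, m)) * x[m][self.anc[(li, m)]]
            x[li] = x[li] - acc / dcol(li)
        return x


# ---------------------------------------------------------------------------
# PIRLS + Laplace
# ---------------------------------------------------------------------------

def _pirls(design: _Design, fac: _NestedFactor, alpha0: np.ndarray,
           b0: Optional[dict], tol: float = 1e-10, max_iter: int = 100):
    """Joint penalized Newton for (alpha, b) at fixed RE precisions.

    Returns the mode, the Laplace marginal log-likelihood, the
    fixed-effect Schur complement (observed information for alpha) and a
    convergence flag.  The backtracking line search keeps the penalized
    log-likelihood monotone.
    """
    X, y = design.X, design.y
    n, p = X.shape
    levels = fac.levels
    alpha = alpha0.copy()
    b = ({lvl: np.zeros(fac.q[lvl]) for lvl in levels} if b0 is None
         else {lvl: b0[lvl].copy() for lvl in levels})

    def eta_of(a, bb):
        e = X @ a
        for lvl in levels:
            e = e + bb[lvl][fac.codes[lvl]]
        return e

    def f_of(e, bb):
        ll = float(y @ e - np.logaddexp(0.0, e).sum())
        for lvl in levels:
            ll -= 0.5 * fac.lam[lvl] * float(bb[lvl] @ bb[lvl])
        return ll

    eta = eta_of(alpha, b)
    f = f_of(eta, b)
    converged = False
    for _ in range(max_iter):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        r = y - mu
        Xw = X * w[:, None]
        A = X.T @ Xw
        fac.factor(w)
        M = {lvl: np.column_stack([
            np.bincount(fac.codes[lvl], weights=Xw[:, j], minlength=fac.q[lvl])
            for j in range(p)]) for lvl in levels}          # Z_l' W X
        ga = X.T @ r
        gb = {lvl: np.bincount(fac.codes[lvl], weights=r, minlength=fac.q[lvl])
              - fac.lam[lvl] * b[lvl] for lvl in levels}
        if levels:
            HinvM = fac.solve(M)
            S = A - sum(M[lvl].T @ HinvM[lvl] for lvl in levels)
            Hinv_gb = fac.solve(gb)
            rhs = ga - sum(M[lvl].T @ Hinv_gb[lvl] for lvl in levels)
            da = np.linalg.solve(S, rhs)
            db = fac.solve({lvl: gb[lvl] - M[lvl] @ da for lvl in levels})
        else:
            S = A
            da = np.linalg.solve(A, ga)
            db = {}

        step = 1.0
        for _ in range(40):
            a_new = alpha + step * da
            b_new = {lvl: b[lvl] + step * db[lvl] for lvl in levels}
            eta_new = eta_of(a_new, b_new)
            f_new = f_of(eta_new, b_new)
            if f_new >= f - 1e-12:
                break
            step *= 0.5
        improved = f_new - f
        alpha, b, eta, f = a_new, b_new, eta_new, f_new
        if abs(improved) < tol * (1.0 + abs(f)):
            converged = True
            break

    # final factorization at the mode for the Laplace correction and the
    # fixed-effect information
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    Xw = X * w[:, None]
    A = X.T @ Xw
    if levels:
        fac.factor(w)
        logdet = fac.logdet() - sum(fac.q[lvl] * np.log(fac.lam[lvl])
                                    for lvl in levels)
        ll = f - 0.5 * logdet
        M = {lvl: np.column_stack([
            np.bincount(fac.codes[lvl], weights=Xw[:, j], minlength=fac.q[lvl])
            for j in range(p)]) for lvl in levels}
        HinvM = fac.solve(M)
        S = A - sum(M[lvl].T @ HinvM[lvl] for lvl in levels)
    else:
        ll = f
        S = A
    return alpha, b, f, ll, S, converged


class _LaplaceProblem:
    """Profiled Laplace deviance as a function of the RE SDs, with warm
    starts carried between evaluations."""

    def __init__(self, design: _Design):
        self.design = design
        self.alpha = np.zeros(design.X.shape[1])
        self.b: Optional[dict] = None
        self.inner_converged = True
        self._last = None

    def loglik(self, sigma: np.ndarray) -> float:
        fac = _NestedFactor(self.design, np.asarray(sigma, float))
        b0 = None
        if self.b is not None:
            b0 = {lvl: self.b.get(lvl, np.zeros(fac.q[lvl])) for lvl in fac.levels}
        alpha, b, _, ll, S, conv = _pirls(self.design, fac, self.alpha, b0)
        self.alpha, self.b = alpha, b
        self.inner_converged = conv
        self._last = (ll, S)
        return ll


def _laplace_fit(design: _Design, sigma0: Optional[np.ndarray] = None,
                 xtol: float = 1e-4, max_outer: int = 500,
                 sigma_fixed: Optional[np.ndarray] = None):
    """Maximize the Laplace marginal likelihood over (alpha, sigma)."""
    prob = _LaplaceProblem(design)
    if sigma_fixed is not None:
        sigma = np.asarray(sigma_fixed, float)
        outer_success = True
    else:
        s0 = np.full(3, 0.5) if sigma0 is None else np.clip(np.asarray(sigma0, float),
                                                            0.0, 4.0)
        res = minimize(
            lambda s: -prob.loglik(s), s0, method="Powell",
            bounds=[(0.0, 4.0)] * 3,
            options={"xtol": xtol, "ftol": 1e-8, "maxiter": max_outer},
        )
        sigma = np.where(res.x < _SIGMA_SNAP, 0.0, res.x)
        outer_success = bool(res.success)
    ll = prob.loglik(sigma)  # final PIRLS at (snapped) sigma
    _, S = prob._last
    cov = np.linalg.inv(S)
    separation = bool(np.max(np.abs(prob.alpha)) > SEPARATION_CAP)
    converged = bool(outer_success and prob.inner_converged and not separation)
    return {
        "alpha": prob.alpha, "sigma": sigma,
        "loglik": float(ll), "cov": cov,
        "converged": converged, "separation": separation,
    }


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------

def _reconstruct_alpha(params: pd.Series, cov: pd.DataFrame,
                       spec: SurfaceSpec, treatments: list[str]):
    """Per-treatment coefficients (main + treatment interaction) with SEs."""
    names = ["intercept"] + list(spec.term_names)

    def _safe_sqrt(v: float) -> float:
        # near-singular information can yield tiny negative variances
        return float(np.sqrt(v)) if v >= 0 else float("nan")

    alpha, alpha_se = {}, {}
    for t in treatments:
        a, se = {}, {}
        for name in names:
            main = name
            inter = "treat" if name == "intercept" else f"treat:{name}"
            if t == "removal" and inter in params.index:
                a[name] = float(params[main] + params[inter])
                se[name] = _safe_sqrt(cov.loc[main, main] + cov.loc[inter, inter]
                                      + 2.0 * cov.loc[main, inter])
            else:
                a[name] = float(params[main])
                se[name] = _safe_sqrt(cov.loc[main, main])
        alpha[t] = a
        alpha_se[t] = se
    return alpha, alpha_se


def _assemble_fit(design: _Design, spec: SurfaceSpec, out: dict) -> SurfaceFit:
    params = pd.Series(out["alpha"], index=design.colnames)
    cov = pd.DataFrame(out["cov"], index=design.colnames, columns=design.colnames)
    treatments = sorted(np.unique(design.row_treatment))
    alpha, alpha_se = _reconstruct_alpha(params, cov, spec, treatments)
    return SurfaceFit(
        spec=spec, params=params, cov_params=cov, alpha=alpha, alpha_se=alpha_se,
        re_var={lvl: float(out["sigma"][k] ** 2)
                for k, lvl in enumerate(GROUP_LEVELS)},
        fitted_p=expit(design.X @ params.to_numpy()),
        loglik=out["loglik"], converged=out["converged"],
        separation=out["separation"],
        row_treatment=design.row_treatment, y=design.y, design=design,
    )


def fit_surface(table: pd.DataFrame, spec: SurfaceSpec,
                sigma0: Optional[np.ndarray] = None,
                xtol: float = 1e-4,
                sigma_fixed: Optional[np.ndarray] = None) -> SurfaceFit:
    """Fit the mixed-logistic selection surface for ``spec``.

    ``xtol`` is the outer search tolerance on the random-effect SDs; the
    default balances accuracy against the cost of bootstrap refits.
    ``sigma_fixed`` pins the random-effect SDs (genotype, plant, gall
    order) instead of estimating them — with all three at zero the model
    is an ordinary logistic regression.  Returns ``converged=False``
    (rather than raising) when the optimizer stalls or complete
    separation is flagged.
    """
    design = build_design(table, spec)
    out = _laplace_fit(design, sigma0=sigma0, xtol=xtol, sigma_fixed=sigma_fixed)
    return _assemble_fit(design, spec, out)


def refit(fit: SurfaceFit, new_y: np.ndarray, xtol: float = 3e-3) -> SurfaceFit:
    """Refit the same design against a new response vector."""
    d = fit.design
    design = _Design(X=d.X, colnames=d.colnames, y=np.asarray(new_y, int),
                     codes=d.codes, group_sizes=d.group_sizes, parents=d.parents,
                     row_treatment=d.row_treatment, index=d.index)
    sigma0 = np.array([fit.re_sd[lvl] for lvl in GROUP_LEVELS])
    out = _laplace_fit(design, sigma0=np.clip(sigma0, 0.05, None), xtol=xtol)
    return _assemble_fit(design, fit.spec, out)


def simulate_response(fit: SurfaceFit, rng: np.random.Generator) -> np.ndarray:
    """Draw new random intercepts and Bernoulli responses from the fit."""
    d = fit.design
    eta = d.X @ fit.params.to_numpy()
    for level in GROUP_LEVELS:
        sd = fit.re_sd[level]
        if sd > 0:
            draws = rng.normal(0.0, sd, d.group_sizes[level])
            eta = eta + draws[d.codes[level]]
    return (rng.random(len(eta)) < expit(eta)).astype(int)


# ---------------------------------------------------------------------------
# parametric bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapDistribution:
    """Replicate draws of named quantities with percentile intervals."""

    replicates: pd.DataFrame
    n_requested: int
    n_failed: int = 0
    level: float = 0.95

    @property
    def n_reps(self) -> int:
        return len(self.replicates)

    @property
    def point(self) -> pd.Series:
        return self.replicates.mean(axis=0)

    def ci(self, level: Optional[float] = None) -> pd.DataFrame:
        lvl = self.level if level is None else level
        lo = (1.0 - lvl) / 2.0
        out = self.replicates.quantile([lo, 1.0 - lo]).T
        out.columns = ["lo", "hi"]
        return out

    def se(self) -> pd.Series:
        return self.replicates.std(axis=0, ddof=1)


def parametric_bootstrap(fit: SurfaceFit, n_reps: int, seed: int,
                         statistic: Optional[Callable[[SurfaceFit], dict]] = None,
                         xtol: float = 3e-3) -> BootstrapDistribution:
    """Full parametric bootstrap: re-simulate random effects and responses,
    refit, and record ``statistic`` (default: fixed-effect coefficients).

    Replicates are paired by replicate-specific child seeds, so two
    bootstraps run from the same ``seed`` are paired replicate-by-
    replicate even if some replicates fail in one of them.
    """
    if not fit.converged:
        raise ValueError("cannot bootstrap from a non-converged fit")
    if statistic is None:
        statistic = lambda f: f.params.to_dict()
    children = np.random.SeedSequence(seed).spawn(n_reps)
    rows, idx = [], []
    n_failed = 0
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        y_star = simulate_response(fit, rng)
        try:
            f_rep = refit(fit, y_star, xtol=xtol)
        except np.linalg.LinAlgError:
            n_failed += 1
            continue
        if f_rep.separation:
            n_failed += 1
            continue
        rows.append(statistic(f_rep))
        idx.append(i)
    if n_reps and n_failed > 0.1 * n_reps:
        warnings.warn(f"{n_failed}/{n_reps} bootstrap replicates failed to "
                      "converge and were dropped", RuntimeWarning)
    reps = pd.DataFrame(rows, index=idx)
    return BootstrapDistribution(replicates=reps, n_requested=n_reps,
                                 n_failed=n_failed)


def contrast(dist_a: BootstrapDistribution,
             dist_b: BootstrapDistribution) -> BootstrapDistribution:
    """Replicate-wise difference A - B (requires paired replicates)."""
    if list(dist_a.replicates.columns) != list(dist_b.replicates.columns):
        raise ValueError("bootstrap distributions have mismatched quantities")
    if dist_a.n_requested != dist_b.n_requested:
        raise ValueError("bootstrap distributions have mismatched n_reps")
    common = dist_a.replicates.index.intersection(dist_b.replicates.index)
    diff = dist_a.replicates.loc[common] - dist_b.replicates.loc[common]
    return BootstrapDistribution(
        replicates=diff, n_requested=dist_a.n_requested,
        n_failed=dist_a.n_requested - len(common), level=dist_a.level)
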