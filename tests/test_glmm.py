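"""The Laplace mixed-logistic estimator: degenerate-case oracles (plain
GLM at zero variance, closed-form intercept), agreement with lme4's
glmer, monotone inner optimization, and the parametric bootstrap
contract."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import selscape as sel
from selscape.glmm import (SurfaceSpec, _LaplaceProblem, _NestedFactor,
                           build_design, contrast, design_Z, _pirls,
                           parametric_bootstrap)
from selscape.synthdata import SynthConfig, TrueSurface


def _null_table(seed, **kw):
    flat = {"original": TrueSurface(), "removal": TrueSurface()}
    base = dict(seed=seed, true_alpha=flat, re_sd=(0.0, 0.0, 0.0),
                early_death_frac=0.0, incidental_larval_frac=0.0,
                n_genotypes=6, plants_per_genotype=6, galls_per_plant=4,
                larvae_per_gall_mean=3.0)
    base.update(kw)
    df = sel.generate_dataset(SynthConfig(**base))
    table, _ = sel.apply_exclusions(df)
    return sel.standardize_traits(table)


@pytest.mark.parametrize("order", ["linear", "full"])
def test_glmm_equals_glm_at_zero_variance(order):
    """With all random-effect SDs pinned at zero the Laplace fit must
    reproduce an ordinary logistic regression coefficient-for-coefficient."""
    sm = pytest.importorskip("statsmodels.api")
    tz = _null_table(2)
    spec = SurfaceSpec(order=order)
    fit = sel.fit_surface(tz, spec, sigma_fixed=(0.0, 0.0, 0.0))
    d = build_design(tz, spec)
    glm = sm.GLM(d.y, d.X, family=sm.families.Binomial()).fit()
    assert np.abs(glm.params - fit.params.to_numpy()).max() < 1e-3
    assert fit.loglik == pytest.approx(glm.llf, abs=1e-6)
    se = np.sqrt(np.diag(fit.cov_params))
    assert np.allclose(se, glm.bse, atol=1e-4)


def test_intercept_only_recovers_logit_survival_fraction():
    tz = _null_table(5)
    spec = SurfaceSpec(order="linear", by_treatment=False, terms=())
    fit = sel.fit_surface(tz, spec, sigma_fixed=(0.0, 0.0, 0.0))
    p = tz["survival"].mean()
    assert fit.params["intercept"] == pytest.approx(logit(p), abs=1e-6)


def test_fitted_p_is_invlogit_of_fixed_part(surface_fits):
    lin, full = surface_fits
    for fit in (lin, full):
        eta = fit.design.X @ fit.params.to_numpy()
        assert np.allclose(fit.fitted_p, expit(eta))
        assert ((fit.fitted_p > 0) & (fit.fitted_p < 1)).all()


def test_reconstructed_removal_coefficients(surface_fits):
    lin, _ = surface_fits
    p = lin.params
    assert lin.alpha["removal"]["z_diam"] == pytest.approx(
        p["z_diam"] + p["treat:z_diam"])
    assert lin.alpha["original"]["z_diam"] == pytest.approx(p["z_diam"])


def test_nested_factor_matches_generic_sparse_solver(standardized_table):
    """The O(n) nested LDL^T must agree with a generic sparse LU on the
    same penalized Hessian, including zero-variance boundary patterns."""
    from scipy import sparse
    from scipy.sparse.linalg import splu
    d = build_design(standardized_table, SurfaceSpec(order="full"))
    rng = np.random.default_rng(0)
    w = rng.uniform(0.05, 0.25, len(d.y))
    for sigma in ([0.3, 0.3, 0.7], [0.0, 0.5, 0.2], [0.4, 0.0, 0.0]):
        fac = _NestedFactor(d, np.asarray(sigma))
        fac.factor(w)
        Z = design_Z(d)
        mask = np.zeros(Z.shape[1], bool)
        lam = []
        off = 0
        for lvl, sd in zip(("gall", "plant", "genotype"),
                           (sigma[2], sigma[1], sigma[0])):
            q = d.group_sizes[lvl]
            if sd > 0:
                mask[off:off + q] = True
                lam += [1.0 / sd ** 2] * q
            off += q
        Za = Z[:, mask]
        H = (Za.T @ Za.multiply(w[:, None])).tocsc() + sparse.diags(lam)
        lu = splu(H)
        assert fac.logdet() == pytest.approx(
            np.log(np.abs(lu.U.diagonal())).sum(), abs=1e-8)
        r = rng.normal(size=mask.sum())
        rhs, off2 = {}, 0
        for lvl in fac.levels:
            rhs[lvl] = r[off2:off2 + fac.q[lvl]]
            off2 += fac.q[lvl]
        x = np.concatenate([fac.solve(rhs)[lvl] for lvl in fac.levels])
        assert np.allclose(x, lu.solve(r), atol=1e-10)


def test_matches_lme4_glmer(tmp_path, standardized_table):
    """Independent cross-check against R's lme4 on the same data.

    Our estimator profiles the fixed effects at the penalized mode inside
    PIRLS, which is exactly glmer's nAGQ=0 scheme — those fits must agree
    essentially to optimizer precision.  glmer's default (nAGQ=1) moves
    the fixed effects into the outer Laplace objective; that changes
    binary-data estimates by a few hundredths, so it is checked at a
    correspondingly looser tolerance.
    """
    import shutil
    import subprocess
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    csv = tmp_path / "d.csv"
    standardized_table.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        'suppressMessages(library(lme4))\n'
        f'd <- read.csv("{csv}")\n'
        'd$treat <- as.integer(d$treatment == "removal")\n'
        'f <- survival ~ treat*(z_diam + z_clutch + z_pref)'
        ' + (1|genotype_id/plant_id/gall_id)\n'
        'm0 <- suppressWarnings(glmer(f, data=d, family=binomial, nAGQ=0))\n'
        'm1 <- suppressWarnings(glmer(f, data=d, family=binomial))\n'
        'cat(fixef(m0), sep="\\n"); cat("\\n---\\n")\n'
        'cat(unlist(lapply(VarCorr(m0), function(x) attr(x, "stddev"))),'
        ' sep="\\n"); cat("\\n---\\n")\n'
        'cat(fixef(m1), sep="\\n")\n')
    out = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    part0, sd0, part1 = out.stdout.split("---")
    ref0 = np.array([float(v) for v in part0.split()])
    ref_sd = np.array([float(v) for v in sd0.split()])  # gall, plant, genotype
    ref1 = np.array([float(v) for v in part1.split()])
    fit = sel.fit_surface(standardized_table, SurfaceSpec(order="linear"),
                          xtol=1e-5)
    assert np.abs(fit.params.to_numpy() - ref0).max() < 0.01
    ours_sd = np.array([fit.re_sd[k] for k in ("gall", "plant", "genotype")])
    assert np.abs(ours_sd - ref_sd).max() < 0.01
    assert np.abs(fit.params.to_numpy() - ref1).max() < 0.1


def test_pirls_is_monotone(standardized_table):
    """The penalized log-likelihood must be non-decreasing in the inner
    Newton iteration count (line-search contract)."""
    d = build_design(standardized_table, SurfaceSpec(order="linear"))
    sigma = np.array([0.3, 0.3, 0.7])
    vals = []
    for k in range(1, 7):
        fac = _NestedFactor(d, sigma)
        _, _, f, _, _, _ = _pirls(d, fac, np.zeros(d.X.shape[1]), None,
                                  max_iter=k)
        vals.append(f)
    assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))


def test_separation_is_flagged():
    tz = _null_table(8)
    tz = tz.copy()
    tz["survival"] = (tz["z_diam"] > 0).astype(int)
    tz["fate"] = np.where(tz["survival"] == 1, "survived", "egg_parasitized")
    fit = sel.fit_surface(tz, SurfaceSpec(order="linear"))
    assert fit.separation
    assert not fit.converged


def test_parameter_recovery_smoke():
    """Full-surface coefficients land within 3 Wald SEs of the generating
    truth on a moderate dataset (the full study runs in acceptance)."""
    cfg = SynthConfig(seed=77, n_genotypes=8, plants_per_genotype=12,
                      galls_per_plant=6, larvae_per_gall_mean=4.0)
    df = sel.generate_dataset(cfg)
    table, _ = sel.apply_exclusions(df)
    tz = sel.standardize_traits(table)
    fit = sel.fit_surface(tz, SurfaceSpec(order="full"), xtol=1e-3)
    n_in, n_tot = 0, 0
    for t in ("original", "removal"):
        ts = cfg.true_alpha[t]
        truth = dict(zip(
            ["intercept", "z_diam", "z_clutch", "z_pref",
             "z_diam^2", "z_clutch^2", "z_pref^2",
             "z_diam:z_clutch", "z_diam:z_pref", "z_clutch:z_pref"],
            [ts.intercept, *ts.linear, *ts.quadratic, *ts.interaction]))
        for name, val in truth.items():
            n_tot += 1
            n_in += abs(fit.alpha[t][name] - val) <= 3 * fit.alpha_se[t][name]
    assert n_in / n_tot >= 0.9


class TestParametricBootstrap:
    def test_deterministic_given_seed(self, surface_fits):
        lin, _ = surface_fits
        a = parametric_bootstrap(lin, 2, seed=5)
        b = parametric_bootstrap(lin, 2, seed=5)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)

    def test_bootstrap_mean_tracks_point_fit(self, surface_fits):
        lin, _ = surface_fits
        dist = parametric_bootstrap(lin, 40, seed=6)
        se = dist.se()["intercept"]
        assert abs(dist.point["intercept"]
                   - lin.params["intercept"]) < 2.0 * se

    def test_requires_converged_fit(self, surface_fits):
        import dataclasses
        lin, _ = surface_fits
        bad = dataclasses.replace(lin, converged=False)
        with pytest.raises(ValueError, match="non-converged"):
            parametric_bootstrap(bad, 2, seed=1)

    def test_contrast_self_is_zero(self, surface_fits):
        lin, _ = surface_fits
        dist = parametric_bootstrap(lin, 3, seed=9)
        diff = contrast(dist, dist)
        assert (diff.replicates.to_numpy() == 0).all()

    def test_contrast_linearity_and_shape_check(self, surface_fits):
        import dataclasses
        lin, _ = surface_fits
        dist = parametric_bootstrap(lin, 3, seed=9)
        shifted = dataclasses.replace(dist, replicates=dist.replicates + 1.5)
        diff = contrast(shifted, dist)
        assert np.allclose(diff.replicates.to_numpy(), 1.5)
        assert np.allclose(diff.point.to_numpy(), 1.5)
        other = dataclasses.replace(
            dist, replicates=dist.replicates[["intercept"]])
        with pytest.raises(ValueError, match="mismatched"):
            contrast(dist, other)


def test_bootstrap_ci_covers_null_truth():
    """Nominal-level sanity of the percentile bootstrap: with a flat true
    surface the 95% CI for each trait coefficient (and for the treatment
    contrast) should cover zero in most replications."""
    n_sims, n_boot = 12, 30
    cover_main = cover_contrast = 0
    for i in range(n_sims):
        tz = _null_table(500 + i, re_sd=(0.2, 0.2, 0.4),
                         n_genotypes=5, plants_per_genotype=4,
                         galls_per_plant=4)
        fit = sel.fit_surface(tz, SurfaceSpec(order="linear"), xtol=3e-3)
        if not fit.converged:
            continue
        dist = parametric_bootstrap(fit, n_boot, seed=900 + i)
        ci = dist.ci()
        lo, hi = ci.loc["z_diam"]
        cover_main += (lo <= 0.0 <= hi)
        lo, hi = ci.loc["treat:z_diam"]
        cover_contrast += (lo <= 0.0 <= hi)
    assert cover_main >= 0.75 * n_sims
    assert cover_contrast >= 0.75 * n_sims


def test_egg_parasitism_response_switch(standardized_table):
    fit = sel.fit_surface(standardized_table,
                          SurfaceSpec(response="egg_parasitism", order="linear"))
    y = (standardized_table["fate"] == "egg_parasitized").to_numpy(int)
    assert np.array_equal(fit.y, y)
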