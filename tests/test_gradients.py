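"""Janzen-Stern rescaling of logistic surface coefficients to selection
gradients, the quadratic-doubling bookkeeping, the expression-bias
adjustment, and the counterfactual mean-fitness rescaling."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import selscape as sel
from selscape.glmm import SurfaceSpec, SurfaceFit
from selscape.gradients import (BiasEstimate, apply_bias_adjustment,
                                counterfactual_rescale, estimate_expression_bias,
                                janzen_stern)
from selscape.synthdata import SynthConfig, TrueSurface


def make_fit(order, alpha_by_treatment, fitted_p, row_treatment, y=None):
    """Assemble a minimal SurfaceFit for unit-testing the rescaling."""
    spec = SurfaceSpec(order=order)
    names = ["intercept"] + list(spec.term_names)
    params = pd.Series(0.0, index=names)
    return SurfaceFit(
        spec=spec, params=params,
        cov_params=pd.DataFrame(np.eye(len(names)), index=names, columns=names),
        alpha=alpha_by_treatment,
        alpha_se={t: {n: 1.0 for n in names} for t in alpha_by_treatment},
        re_var={"genotype": 0.0, "plant": 0.0, "gall": 0.0},
        fitted_p=np.asarray(fitted_p, float), loglik=0.0, converged=True,
        separation=False, row_treatment=np.asarray(row_treatment),
        y=np.zeros(len(fitted_p), int) if y is None else np.asarray(y),
    )


def _flat_alpha(order, **over):
    names = ["intercept"] + list(SurfaceSpec(order=order).term_names)
    a = {n: 0.0 for n in names}
    a.update(over)
    return a


class TestJanzenSternClosedForms:
    def test_constant_half_probability_scales_by_half(self):
        """With all fitted W = 0.5: mean W(1-W) = 0.25, W-bar = 0.5, so
        every gradient is exactly half its regression coefficient."""
        n = 20
        rows = np.array(["original"] * n)
        lin = make_fit("linear",
                       {"original": _flat_alpha("linear", z_diam=0.8, z_pref=-0.4)},
                       np.full(n, 0.5), rows)
        full = make_fit("full",
                        {"original": _flat_alpha("full", **{"z_diam^2": 0.6,
                                                            "z_clutch:z_pref": 0.2})},
                        np.full(n, 0.5), rows)
        g = janzen_stern(lin, full, "original")
        assert g.mean_wq == pytest.approx(0.25)
        assert g.mean_fitness == pytest.approx(0.5)
        assert g.beta == pytest.approx([0.4, 0.0, -0.2])
        assert g.gamma_raw[0, 0] == pytest.approx(0.3)       # 0.5 * 0.6
        assert g.gamma_doubled[0, 0] == pytest.approx(0.6)   # doubled after
        assert g.gamma_doubled[1, 2] == pytest.approx(0.1)   # 0.5 * 0.2

    def test_zero_coefficient_gives_zero_gradient(self):
        n = 10
        rows = np.array(["removal"] * n)
        lin = make_fit("linear", {"removal": _flat_alpha("linear", z_clutch=0.5)},
                       np.full(n, 0.3), rows)
        full = make_fit("full", {"removal": _flat_alpha("full")},
                        np.full(n, 0.3), rows)
        g = janzen_stern(lin, full, "removal")
        assert g.beta[0] == 0.0 and g.beta[2] == 0.0
        assert np.all(g.gamma_raw == 0.0)

    def test_gradient_sign_matches_coefficient_sign(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.2, 0.8, 30)
        rows = np.array(["original"] * 30)
        a = {"z_diam": 0.7, "z_clutch": -0.3, "z_pref": 0.0}
        lin = make_fit("linear", {"original": _flat_alpha("linear", **a)}, p, rows)
        full = make_fit("full", {"original": _flat_alpha("full")}, p, rows)
        g = janzen_stern(lin, full, "original")
        assert np.sign(g.beta[0]) == 1 and np.sign(g.beta[1]) == -1
        assert g.beta[2] == 0.0

    def test_doubling_relation_exact(self, surface_fits):
        lin, full = surface_fits
        for t in ("original", "removal"):
            g = janzen_stern(lin, full, t)
            assert np.allclose(np.diag(g.gamma_doubled),
                               2.0 * np.diag(g.gamma_raw))
            off = ~np.eye(3, dtype=bool)
            assert np.allclose(g.gamma_doubled[off], g.gamma_raw[off])


def test_beta_equals_numerical_average_derivative():
    """The directional gradient must equal the numerically differentiated
    average slope of relative fitness over the analysis rows."""
    cfg = SynthConfig(seed=50, n_genotypes=3, plants_per_genotype=3,
                      galls_per_plant=2, larvae_per_gall_mean=3.0,
                      re_sd=(0.0, 0.0, 0.0), early_death_frac=0.0,
                      incidental_larval_frac=0.0)
    df = sel.generate_dataset(cfg)
    table, _ = sel.apply_exclusions(df)
    tz = sel.standardize_traits(table)
    lin = sel.fit_surface(tz, SurfaceSpec(order="linear"), sigma_fixed=(0, 0, 0))
    full = sel.fit_surface(tz, SurfaceSpec(order="full"), sigma_fixed=(0, 0, 0))
    for t in ("original", "removal"):
        g = janzen_stern(lin, full, t)
        mask = tz["treatment"].to_numpy() == t
        z = tz.loc[mask, ["z_diam", "z_clutch", "z_pref"]].to_numpy()
        a = lin.alpha[t]
        coef = np.array([a["z_diam"], a["z_clutch"], a["z_pref"]])

        def W(zz):
            return expit(a["intercept"] + zz @ coef)

        w_bar = W(z).mean()
        h = 1e-5
        for i in range(3):
            zp, zm = z.copy(), z.copy()
            zp[:, i] += h
            zm[:, i] -= h
            beta_num = ((W(zp) - W(zm)) / (2 * h)).mean() / w_bar
            assert g.beta[i] == pytest.approx(beta_num, abs=1e-4)


class TestBiasAdjustment:
    def _lin_fit(self):
        n = 10
        rows = np.array(["original"] * 5 + ["removal"] * 5)
        alpha = {"original": _flat_alpha("linear", z_diam=0.7),
                 "removal": _flat_alpha("linear", z_diam=0.5)}
        fit = make_fit("linear", alpha, np.full(n, 0.4), rows)
        fit.params["z_diam"] = 0.7
        fit.params["intercept"] = -0.4
        return fit

    def test_subtraction(self):
        fit = self._lin_fit()
        bias = BiasEstimate(alpha_diam_bias={"original": 0.4, "removal": 0.1},
                            ci={"original": (0.1, 0.7), "removal": (-0.1, 0.3)})
        adj = apply_bias_adjustment(fit, bias)
        assert adj.alpha["original"]["z_diam"] == pytest.approx(0.3)
        assert adj.alpha["removal"]["z_diam"] == pytest.approx(0.4)
        assert adj.bias_adjusted
        # untouched coefficients
        assert adj.alpha["original"]["z_clutch"] == 0.0
        assert adj.alpha["original"]["intercept"] == fit.alpha["original"]["intercept"]

    def test_zero_bias_identity(self):
        fit = self._lin_fit()
        bias = BiasEstimate(alpha_diam_bias={"original": 0.0, "removal": 0.0},
                            ci={"original": (0, 0), "removal": (0, 0)})
        adj = apply_bias_adjustment(fit, bias)
        assert adj.alpha == fit.alpha

    def test_double_application_rejected(self):
        fit = self._lin_fit()
        bias = BiasEstimate(alpha_diam_bias={"original": 0.1, "removal": 0.1},
                            ci={"original": (0, 1), "removal": (0, 1)})
        adj = apply_bias_adjustment(fit, bias)
        with pytest.raises(ValueError, match="already applied"):
            apply_bias_adjustment(adj, bias)


class TestExpressionBiasEstimator:
    def test_homogeneous_galls_warn_and_fix_zero(self):
        # every gall fully survives or fully dies -> empty subset
        recs = []
        rng = np.random.default_rng(1)
        for g in range(8):
            surv = g % 2
            for k in range(3):
                recs.append({
                    "larva_id": f"g{g}L{k}", "gall_id": f"g{g}",
                    "plant_id": f"p{g // 2}", "genotype_id": f"G{g // 4}",
                    "treatment": "original" if g < 4 else "removal",
                    "fate": "survived" if surv else "egg_parasitized",
                    "survival": surv, "diam_mm": 3.0 + rng.normal(0, 0.5),
                    "clutch_size": 2 + g % 3,
                    "pref_density": float(2 + g // 2)})
        tz = sel.standardize_traits(pd.DataFrame(recs))
        with pytest.warns(RuntimeWarning, match="bias fixed at 0"):
            be = estimate_expression_bias(tz)
        assert be.alpha_diam_bias == {"original": 0.0, "removal": 0.0}

    def test_null_data_bias_ci_covers_zero(self):
        flat = {"original": TrueSurface(), "removal": TrueSurface()}
        cfg = SynthConfig(seed=60, true_alpha=flat, re_sd=(0.1, 0.1, 0.3),
                          early_death_frac=0.0, incidental_larval_frac=0.0,
                          n_genotypes=8, plants_per_genotype=6,
                          galls_per_plant=6, larvae_per_gall_mean=4.0)
        df = sel.generate_dataset(cfg)
        table, _ = sel.apply_exclusions(df)
        tz = sel.standardize_traits(table)
        be = estimate_expression_bias(tz)
        for t, (lo, hi) in be.ci.items():
            assert lo <= 0.0 <= hi


class TestCounterfactualRescale:
    def _gset(self):
        from selscape.reference import reference_gradient_set
        return reference_gradient_set("removal")

    def test_identity_at_own_mean_fitness(self):
        g = self._gset()
        out = counterfactual_rescale(g, g.mean_fitness)
        assert np.allclose(out.beta, g.beta)
        assert np.allclose(out.gamma_raw, g.gamma_raw)
        assert not out.counterfactual

    def test_doubling_target_halves_gradients(self):
        g = self._gset()
        out = counterfactual_rescale(g, min(2.0 * g.mean_fitness, 0.99))
        if 2.0 * g.mean_fitness < 1.0:
            assert np.allclose(out.beta, g.beta / 2.0)
            assert np.allclose(out.gamma_doubled, g.gamma_doubled / 2.0)
        assert out.counterfactual

    def test_invalid_target_rejected(self):
        g = self._gset()
        with pytest.raises(ValueError):
            counterfactual_rescale(g, 0.0)
        with pytest.raises(ValueError):
            counterfactual_rescale(g, 1.0)
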