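"""End-to-end analysis orchestration: simulate/load -> filter -> standardize
-> fit surfaces -> gradients -> landscape -> evolvability, with a manifest
recording every seed and convention flag."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evolvability import EvolvabilityResult, fraction_decreased, sample_G
from .glmm import (BootstrapDistribution, SurfaceFit, SurfaceSpec, fit_surface,
                   refit, simulate_response)
from .gradients import (GRADIENT_NAMES, BiasEstimate, apply_bias_adjustment,
                        estimate_expression_bias, janzen_stern)
from .landscape import (curvature, curvature_contrast,
                        curvature_ci_from_replicates)
from .preprocess import apply_exclusions, standardize_traits
from .synthdata import SynthConfig, generate_dataset

log = logging.getLogger("selscape")

__all__ = ["RunConfig", "ReportBundle", "PipelineError", "run_pipeline",
           "bootstrap_gradient_sets", "format_gradient_table"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (seed mandatory)."""

    seed: int
    input_csv: Optional[str] = None           # either a CSV path ...
    synth: Optional[SynthConfig] = None       # ... or a generator config
    response: str = "survival"
    n_bootstrap: int = 1000
    n_G: int = 10_000
    n_beta: int = 1000
    adjust_bias: bool = True
    w_bar_source: str = "fitted"              # or "observed"
    curvature_doubled: bool = False           # diagonal convention for C
    g_sampler: str = "onion"                  # or "elementwise"
    plots: bool = False

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.synth is None):
            raise ValueError("provide exactly one of input_csv or synth")
        if self.w_bar_source not in ("fitted", "observed"):
            raise ValueError("w_bar_source must be 'fitted' or 'observed'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw.get("synth") is not None:
            synth = dict(raw["synth"])
            synth.setdefault("seed", raw.get("seed"))
            raw["synth"] = _synth_from_dict(synth)
        return cls(**raw)


def _synth_from_dict(d: dict) -> SynthConfig:
    import tempfile
    with tempfile.NamedTemporaryFile("w", suffix=".yaml", delete=False) as fh:
        yaml.safe_dump(d, fh)
        path = fh.name
    try:
        return SynthConfig.from_yaml(path)
    finally:
        Path(path).unlink(missing_ok=True)


@dataclass
class ReportBundle:
    table: pd.DataFrame
    exclusion_log: dict
    linear_fit: SurfaceFit
    full_fit: SurfaceFit
    bias: Optional[BiasEstimate]
    gradients: dict                     # treatment -> GradientSet
    gradient_table: pd.DataFrame
    curvatures: dict                    # treatment + contrast -> CurvatureMatrix
    evolvability: Optional[EvolvabilityResult]
    boot: Optional[BootstrapDistribution]
    manifest: dict


def _grad_quantities(lin: SurfaceFit, full: SurfaceFit, treatments,
                     bias_by_treatment: Optional[dict],
                     w_bar_source: str, curvature_doubled: bool) -> dict:
    """Flatten per-treatment gradients + curvature elements into one dict."""
    out = {}
    gsets = {}
    lin_t = lin
    if bias_by_treatment is not None and not lin.bias_adjusted:
        lin_t = apply_bias_adjustment(
            lin, BiasEstimate(alpha_diam_bias=bias_by_treatment,
                              ci={k: (v, v) for k, v in bias_by_treatment.items()}))
    for t in treatments:
        g = janzen_stern(lin_t, full, t, w_bar_source=w_bar_source)
        gsets[t] = g
        for name, val in g.as_series().items():
            out[f"{t}:{name}"] = float(val)
        out[f"{t}:mean_fitness"] = g.mean_fitness
        C = curvature(g, use_doubled=curvature_doubled)
        for i in range(3):
            for j in range(i + 1):
                out[f"{t}:C_{i}{j}"] = float(C.C[i, j])
    if len(treatments) == 2:
        for name in list(GRADIENT_NAMES) + ["mean_fitness"]:
            out[f"contrast:{name}"] = (out[f"removal:{name}"]
                                       - out[f"original:{name}"])
        for i in range(3):
            for j in range(i + 1):
                out[f"contrast:C_{i}{j}"] = (out[f"removal:C_{i}{j}"]
                                             - out[f"original:C_{i}{j}"])
    out["_gsets"] = gsets
    return out


def bootstrap_gradient_sets(table: pd.DataFrame, linear_fit: SurfaceFit,
                            full_fit: SurfaceFit, n_reps: int, seed: int,
                            bias: Optional[BiasEstimate] = None,
                            w_bar_source: str = "fitted",
                            curvature_doubled: bool = False) -> BootstrapDistribution:
    """Parametric bootstrap of the whole gradient/curvature table.

    Each replicate re-simulates random effects and responses from the full
    fit, refits both the linear-only and full surfaces on the simulated
    response, and records every gradient and curvature element per
    treatment plus their contrasts.  When ``bias`` carries bootstrap
    replicates they are paired with the surface replicates; otherwise the
    mean bias is subtracted in every replicate.
    """
    treatments = sorted(np.unique(full_fit.row_treatment))
    children = np.random.SeedSequence(seed).spawn(n_reps)
    rows, idx = [], []
    n_failed = 0
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        y_star = simulate_response(full_fit, rng)
        try:
            full_rep = refit(full_fit, y_star)
            lin_rep = refit(linear_fit, y_star)
        except np.linalg.LinAlgError:
            n_failed += 1
            continue
        if full_rep.separation or lin_rep.separation:
            n_failed += 1
            continue
        bias_vals = None
        if bias is not None:
            if bias.replicates is not None and i in bias.replicates.index:
                bias_vals = {t: float(bias.replicates.loc[i, t])
                             for t in bias.replicates.columns}
            else:
                bias_vals = dict(bias.alpha_diam_bias)
        try:
            q = _grad_quantities(lin_rep, full_rep, treatments, bias_vals,
                                 w_bar_source, curvature_doubled)
        except ValueError:
            n_failed += 1
            continue
        q.pop("_gsets")
        rows.append(q)
        idx.append(i)
    if n_reps and n_failed > 0.1 * n_reps:
        warnings.warn(f"{n_failed}/{n_reps} gradient bootstrap replicates "
                      "dropped (non-convergence)", RuntimeWarning)
    return BootstrapDistribution(replicates=pd.DataFrame(rows, index=idx),
                                 n_requested=n_reps, n_failed=n_failed)


def _fmt(mean: float, lo=None, hi=None) -> str:
    if lo is None:
        return f"{mean:.2f}"
    return f"{mean:.2f} [{lo:.2f}, {hi:.2f}]"


def format_gradient_table(gsets: dict, boot: Optional[BootstrapDistribution]) -> pd.DataFrame:
    """Gradient-table layout: rows = gradient names, columns = original,
    removal, contrast, entries 'mean [lo, hi]'."""
    cols = {}
    treatments = sorted(gsets)
    for t in treatments:
        s = gsets[t].as_series()
        if boot is not None and boot.n_reps > 1:
            ci = boot.ci()
            cols[t] = [
                _fmt(s[name], ci.loc[f"{t}:{name}", "lo"], ci.loc[f"{t}:{name}", "hi"])
                for name in GRADIENT_NAMES]
        else:
            cols[t] = [_fmt(s[name]) for name in GRADIENT_NAMES]
    if len(treatments) == 2:
        diff = gsets["removal"].as_series() - gsets["original"].as_series()
        if boot is not None and boot.n_reps > 1:
            ci = boot.ci()
            cols["contrast"] = [
                _fmt(diff[name], ci.loc[f"contrast:{name}", "lo"],
                     ci.loc[f"contrast:{name}", "hi"])
                for name in GRADIENT_NAMES]
        else:
            cols["contrast"] = [_fmt(diff[name]) for name in GRADIENT_NAMES]
    return pd.DataFrame(cols, index=list(GRADIENT_NAMES))


def run_pipeline(config: RunConfig, outdir: "str | Path | None" = None) -> ReportBundle:
    """Run the full analysis and (optionally) write a report directory."""
    t0 = time.time()
    stage = "load"
    try:
        if config.input_csv is not None:
            raw = pd.read_csv(config.input_csv)
        else:
            raw = generate_dataset(config.synth)
        log.info("loaded %d rows (%.1fs)", len(raw), time.time() - t0)

        stage = "filter"
        table, excl = apply_exclusions(raw)

        stage = "standardize"
        table = standardize_traits(table)

        stage = "fit"
        lin_spec = SurfaceSpec(response=config.response, order="linear")
        full_spec = SurfaceSpec(response=config.response, order="full")
        linear_fit = fit_surface(table, lin_spec)
        full_fit = fit_surface(table, full_spec)
        log.info("surfaces fitted (converged: linear=%s full=%s)",
                 linear_fit.converged, full_fit.converged)

        stage = "bias"
        bias = None
        if config.adjust_bias and config.response == "survival":
            n_boot_bias = min(config.n_bootstrap, 200)
            bias = estimate_expression_bias(table, n_boot=n_boot_bias,
                                            seed=config.seed + 11)
            adj_linear = apply_bias_adjustment(linear_fit, bias)
        else:
            adj_linear = linear_fit

        stage = "gradients"
        treatments = sorted(table["treatment"].unique())
        gsets = {t: janzen_stern(adj_linear, full_fit, t,
                                 w_bar_source=config.w_bar_source)
                 for t in treatments}
        boot = None
        if config.n_bootstrap > 0:
            boot = bootstrap_gradient_sets(
                table, adj_linear, full_fit, config.n_bootstrap,
                config.seed + 23, bias=bias, w_bar_source=config.w_bar_source,
                curvature_doubled=config.curvature_doubled)
            ci = boot.ci()
            for t in treatments:
                gsets[t].beta_ci = np.array(
                    [ci.loc[f"{t}:beta_{tr}"] for tr in ("diam", "clutch", "pref")])
        else:
            warnings.warn("n_bootstrap = 0: gradient table reported without "
                          "confidence intervals", RuntimeWarning)
        grad_table = format_gradient_table(gsets, boot)

        stage = "landscape"
        curvatures = {t: curvature(gsets[t], use_doubled=config.curvature_doubled)
                      for t in treatments}
        if len(treatments) == 2:
            curvatures["removal-original"] = curvature_contrast(
                curvatures["removal"], curvatures["original"])
        if boot is not None and boot.n_reps > 1:
            for key, cm in curvatures.items():
                pref = "contrast" if key == "removal-original" else key
                reps = np.zeros((boot.n_reps, 3, 3))
                for i in range(3):
                    for j in range(i + 1):
                        col = boot.replicates[f"{pref}:C_{i}{j}"].to_numpy()
                        reps[:, i, j] = reps[:, j, i] = col
                cm.ci = curvature_ci_from_replicates(reps)

        stage = "evolvability"
        evo = None
        if len(treatments) == 2 and config.n_G > 0:
            Gs = sample_G(config.n_G, 0.5, seed=config.seed + 37,
                          method=config.g_sampler)
            evo = fraction_decreased(Gs, curvatures["removal"],
                                     curvatures["original"],
                                     n_beta=config.n_beta,
                                     seed=config.seed + 41)

        stage = "report"
        manifest = {
            "selscape_version": __version__,
            "seed": config.seed,
            "stage_seeds": {"bias": config.seed + 11, "bootstrap": config.seed + 23,
                            "g_matrices": config.seed + 37, "betas": config.seed + 41},
            "response": config.response,
            "n_bootstrap": config.n_bootstrap,
            "bootstrap_failed": None if boot is None else boot.n_failed,
            "n_G": config.n_G, "n_beta": config.n_beta,
            "flags": {
                "adjust_bias": config.adjust_bias,
                "w_bar_source": config.w_bar_source,
                "curvature_doubled_diagonal": config.curvature_doubled,
                "g_sampler": config.g_sampler,
                "bootstrap_resimulates_random_effects": True,
            },
            "exclusions": dataclasses.asdict(excl),
            "fits": {"linear": adj_linear.to_json_dict(),
                     "full": full_fit.to_json_dict()},
            "bias": None if bias is None else
                {"estimate": bias.alpha_diam_bias, "ci": bias.ci,
                 "method": bias.method, "n_rows": bias.n_rows},
            "gradients": {t: json.loads(
                gsets[t].as_series().to_json()) for t in treatments},
            "curvature": {k: np.round(cm.C, 10).tolist()
                          for k, cm in curvatures.items()},
            "evolvability": None if evo is None else evo.to_json_dict(),
        }
        bundle = ReportBundle(
            table=table, exclusion_log=dataclasses.asdict(excl),
            linear_fit=adj_linear, full_fit=full_fit, bias=bias,
            gradients=gsets, gradient_table=grad_table, curvatures=curvatures,
            evolvability=evo, boot=boot, manifest=manifest)
        if outdir is not None:
            _write_report(bundle, Path(outdir), config)
        log.info("pipeline finished in %.1fs", time.time() - t0)
        return bundle
    except Exception as exc:  # noqa: BLE001 - stage attribution for the CLI
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc


def _write_report(bundle: ReportBundle, outdir: Path, config: RunConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "exclusions.json").write_text(json.dumps(bundle.exclusion_log) + "\n")
    bundle.gradient_table.to_csv(outdir / "gradient_table.tsv", sep="\t")
    curv = {}
    for key, cm in bundle.curvatures.items():
        entry = {"lower_triangle": [[float(cm.C[i, j]) for j in range(i + 1)]
                                    for i in range(3)]}
        if cm.ci is not None:
            entry["ci_lower_triangle"] = [
                [[float(cm.ci[i, j, 0]), float(cm.ci[i, j, 1])]
                 for j in range(i + 1)] for i in range(3)]
        curv[key] = entry
    (outdir / "curvature.json").write_text(json.dumps(curv, indent=1) + "\n")
    if bundle.evolvability is not None:
        (outdir / "evolvability.json").write_text(
            json.dumps(bundle.evolvability.to_json_dict()) + "\n")
        pd.DataFrame({"delta_e": bundle.evolvability.delta_e}).to_csv(
            outdir / "delta_evolvability.csv", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=1, sort_keys=True) + "\n")
    if config.plots:
        from . import viz
        viz.write_report_plots(bundle, outdir)
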