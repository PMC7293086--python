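"""Plot analogues of the study's figures: one-dimensional selection
surfaces, two-dimensional landscape heatmaps with gradient arrows, and the
change-in-evolvability histogram.  Trait axes are restricted to +/- 1 SD of
the mean phenotype and mean survival is drawn on a natural-log scale, the
region where the landscape is reliably estimated."""

from __future__ import annotations

import numpy as np

from .evolvability import EvolvabilityResult
from .glmm import SurfaceFit
from .synthdata import TRAITS

TREATMENT_COLORS = {"original": "tab:orange", "removal": "tab:blue"}
_TERM = {"diam": "z_diam", "clutch": "z_clutch", "pref": "z_pref"}
LABELS = {"diam": "chamber diameter (SD)", "clutch": "clutch size (SD)",
          "pref": "oviposition preference (SD)"}


def _surface_p(fit: SurfaceFit, treatment: str, z: np.ndarray) -> np.ndarray:
    """Fitted survival over an (n, 3) z grid, random effects at zero."""
    from scipy.special import expit
    a = fit.alpha[treatment]
    eta = np.full(len(z), a["intercept"])
    for k, t in enumerate(TRAITS):
        eta = eta + a.get(_TERM[t], 0.0) * z[:, k]
        eta = eta + a.get(f"{_TERM[t]}^2", 0.0) * z[:, k] ** 2
    for (i, j), name in zip(((0, 1), (0, 2), (1, 2)),
                            ("z_diam:z_clutch", "z_diam:z_pref", "z_clutch:z_pref")):
        eta = eta + a.get(name, 0.0) * z[:, i] * z[:, j]
    return expit(eta)


def plot_fitness_surface(fit: SurfaceFit, trait: str, ax=None):
    """Mean survival (log scale) against one trait, per treatment."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    k = TRAITS.index(trait)
    x = np.linspace(-1.0, 1.0, 101)
    for t, color in TREATMENT_COLORS.items():
        if t not in fit.alpha:
            continue
        z = np.zeros((len(x), 3))
        z[:, k] = x
        ax.plot(x, _surface_p(fit, t, z), color=color, lw=2, label=t)
    ax.set_yscale("log")
    ax.set_xlabel(LABELS[trait])
    ax.set_ylabel("mean survival (log scale)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_landscape_2d(fit: SurfaceFit, trait_x: str, trait_y: str,
                      treatment: str, beta=None, ax=None):
    """Heatmap of log mean survival over two traits with a slope arrow."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.5))
    kx, ky = TRAITS.index(trait_x), TRAITS.index(trait_y)
    g = np.linspace(-1.0, 1.0, 81)
    gx, gy = np.meshgrid(g, g)
    z = np.zeros((gx.size, 3))
    z[:, kx] = gx.ravel()
    z[:, ky] = gy.ravel()
    p = _surface_p(fit, treatment, z).reshape(gx.shape)
    im = ax.pcolormesh(gx, gy, np.log(p), shading="auto", cmap="viridis")
    if beta is not None:
        b = np.asarray(beta, float)
        ax.annotate("", xy=(b[kx], b[ky]), xytext=(0.0, 0.0),
                    arrowprops=dict(arrowstyle="->", color="white", lw=2))
    ax.set_xlabel(LABELS[trait_x])
    ax.set_ylabel(LABELS[trait_y])
    ax.set_title(treatment, fontsize=9)
    ax.figure.colorbar(im, ax=ax, label="ln mean survival")
    return ax


def plot_delta_evolvability(result: EvolvabilityResult, ax=None):
    """Histogram of the paired change in average evolvability."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.hist(result.delta_e, bins=60, color="slategray")
    ax.axvline(0.0, color="black", lw=1)
    ax.set_xlabel("change in average evolvability (removal - original)")
    ax.set_ylabel("G-matrices")
    ax.set_title(f"decreased in {100 * result.fraction_decreased:.0f}% of G-matrices",
                 fontsize=9)
    return ax


def write_report_plots(bundle, outdir) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    for trait in TRAITS:
        ax = plot_fitness_surface(bundle.full_fit, trait)
        ax.figure.savefig(outdir / f"surface_{trait}.png", dpi=120,
                          bbox_inches="tight")
        plt.close(ax.figure)
    for tx, ty in (("diam", "clutch"), ("pref", "clutch"), ("diam", "pref")):
        for t in bundle.gradients:
            ax = plot_landscape_2d(bundle.full_fit, tx, ty, t,
                                   beta=bundle.gradients[t].beta)
            ax.figure.savefig(outdir / f"landscape_{tx}_{ty}_{t}.png", dpi=120,
                              bbox_inches="tight")
            plt.close(ax.figure)
    if bundle.evolvability is not None:
        ax = plot_delta_evolvability(bundle.evolvability)
        ax.figure.savefig(outdir / "delta_evolvability.png", dpi=120,
                          bbox_inches="tight")
        plt.close(ax.figure)
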