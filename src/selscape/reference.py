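"""Published selection-gradient estimates from the gall-midge field study.

These are the reported standardized selection gradients (with 95%
bootstrap CIs) for *Iteomyia salicisverruca* larvae in the original food
web and under experimental removal of the larval-parasitoid guild, plus
the curvature matrices the study derived from them.  They serve as worked
-example inputs and regression anchors: feeding the gradient table through
:mod:`selscape.landscape` reproduces the published curvature matrices, and
the evolvability simulation run on those matrices reproduces the published
fraction of G-matrices with decreased evolvability (~71%).

Diagonal gamma entries follow the doubled reporting convention; the
curvature computation halves them back to the regression scale.
"""

from __future__ import annotations

import numpy as np

from .gradients import GradientSet

__all__ = [
    "REFERENCE_GRADIENTS",
    "REFERENCE_CURVATURE",
    "REFERENCE_FRACTION_DECREASED_PCT",
    "reference_gradient_set",
]

# beta order: (diam, clutch, pref); gamma_diag doubled; gamma_off order:
# (diam:clutch, diam:pref, clutch:pref).  CI bounds as published.
REFERENCE_GRADIENTS = {
    "original": {
        "beta": (0.34, 0.06, -0.13),
        "beta_ci": ((0.22, 0.48), (-0.05, 0.17), (-0.29, 0.05)),
        "gamma_diag": (0.13, -0.05, 0.34),
        "gamma_diag_ci": ((-0.06, 0.33), (-0.27, 0.18), (0.07, 0.63)),
        "gamma_off": (-0.04, -0.13, 0.03),
        "gamma_off_ci": ((-0.16, 0.08), (-0.29, 0.02), (-0.10, 0.18)),
        "mean_fitness": 0.30,   # approximate reported survival level
    },
    "removal": {
        "beta": (0.21, -0.09, -0.16),
        "beta_ci": ((0.12, 0.31), (-0.17, -0.01), (-0.26, -0.06)),
        "gamma_diag": (0.10, -0.11, 0.02),
        "gamma_diag_ci": ((-0.02, 0.23), (-0.28, 0.03), (-0.15, 0.18)),
        "gamma_off": (-0.07, -0.02, 0.0),
        "gamma_off_ci": ((-0.15, 0.02), (-0.10, 0.07), (-0.07, 0.07)),
        "mean_fitness": 0.55,
    },
}

# published curvature matrices (lower triangles as printed, symmetrized)
REFERENCE_CURVATURE = {
    "original": np.array([
        [-0.05, -0.06, -0.09],
        [-0.06, -0.03, 0.04],
        [-0.09, 0.04, 0.15],
    ]),
    "removal": np.array([
        [0.01, -0.05, 0.01],
        [-0.05, -0.06, -0.01],
        [0.01, -0.01, -0.02],
    ]),
    "removal-original": np.array([
        [0.06, 0.02, 0.10],
        [0.02, -0.03, -0.05],
        [0.10, -0.05, -0.17],
    ]),
}

#: published percentage of random G-matrices with decreased evolvability
REFERENCE_FRACTION_DECREASED_PCT = 71.0


def reference_gradient_set(treatment: str) -> GradientSet:
    """Build a :class:`GradientSet` from the published gradient table."""
    ref = REFERENCE_GRADIENTS[treatment]
    diag_doubled = np.asarray(ref["gamma_diag"], float)
    off = ref["gamma_off"]
    gamma_raw = np.diag(diag_doubled / 2.0)
    gamma_raw[0, 1] = gamma_raw[1, 0] = off[0]
    gamma_raw[0, 2] = gamma_raw[2, 0] = off[1]
    gamma_raw[1, 2] = gamma_raw[2, 1] = off[2]
    gamma_doubled = gamma_raw + np.diag(diag_doubled / 2.0)
    w = ref["mean_fitness"]
    return GradientSet(
        treatment=treatment,
        beta=np.asarray(ref["beta"], float),
        gamma_doubled=gamma_doubled,
        gamma_raw=gamma_raw,
        mean_fitness=w,
        mean_wq=w * (1.0 - w),
        bias_adjusted=True,
        beta_ci=np.asarray(ref["beta_ci"], float),
    )
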