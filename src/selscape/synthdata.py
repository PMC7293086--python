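"""Synthetic gall-midge survival datasets with a known selection surface.

The generator emulates the design of a larval-parasitoid removal field
experiment on the willow gall midge *Iteomyia salicisverruca*: plants nested
within willow genotypes, galls nested within plants, and one row per larva.
Survival is drawn from a logistic selection surface evaluated on the
standardized traits (chamber diameter, clutch size, oviposition preference)
plus Gaussian random intercepts for genotype, plant and gall, so every
downstream estimator has a parameter-recovery oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "TrueSurface",
    "TraitModel",
    "SynthConfig",
    "generate_dataset",
    "generate_expression_bias",
]

#: fixed trait order used everywhere: chamber diameter, clutch size, preference
TRAITS = ("diam", "clutch", "pref")
#: fixed pair order for interaction/correlational terms
PAIRS = ((0, 1), (0, 2), (1, 2))

FATES = ("survived", "egg_parasitized", "larval_parasitized", "early_death")

COLUMNS = [
    "larva_id", "gall_id", "plant_id", "genotype_id", "treatment",
    "fate", "survival", "diam_mm", "clutch_size", "pref_density",
]


@dataclass(frozen=True)
class TrueSurface:
    """Coefficients of a logistic selection surface on standardized traits.

    ``linear`` holds the three first-order coefficients, ``quadratic`` the
    raw regression coefficients of z_i**2 (undoubled), ``interaction`` the
    three pairwise product coefficients in the fixed order
    (diam:clutch, diam:pref, clutch:pref).  All on the logit scale.
    """

    intercept: float = 0.0
    linear: tuple[float, float, float] = (0.0, 0.0, 0.0)
    quadratic: tuple[float, float, float] = (0.0, 0.0, 0.0)
    interaction: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vals = [self.intercept, *self.linear, *self.quadratic, *self.interaction]
        if not np.all(np.isfinite(vals)):
            raise ValueError("TrueSurface coefficients must be finite")
        for name in ("linear", "quadratic", "interaction"):
            if len(getattr(self, name)) != 3:
                raise ValueError(f"TrueSurface.{name} must have length 3")

    def eta(self, z: np.ndarray) -> np.ndarray:
        """Linear predictor for an (n, 3) array of standardized traits."""
        z = np.asarray(z, dtype=float)
        out = self.intercept + z @ np.asarray(self.linear)
        out += (z ** 2) @ np.asarray(self.quadratic)
        for coef, (i, j) in zip(self.interaction, PAIRS):
            out += coef * z[:, i] * z[:, j]
        return out


@dataclass(frozen=True)
class TraitModel:
    """Distributional parameters of the three phenotypic traits.

    Chamber diameter (mm) is Gaussian per larva with a gall-level variance
    component; ``diam_gall_var_frac`` is the fraction of total diameter
    variance attributable to gall identity (0.54 in the field data).
    Clutch size is the larval count of the gall (chambers = larvae), whose
    zero-truncated-Poisson rate varies between galls on the log scale with
    SD ``clutch_sd_log``.  Oviposition preference (larvae per 100 shoots) is
    a plant-level trait generated on the square-root scale.
    """

    diam_mean_mm: float = 3.5
    diam_sd_mm: float = 0.9
    diam_gall_var_frac: float = 0.54
    clutch_sd_log: float = 0.3
    pref_mean_sqrt: float = 2.5
    pref_plant_effect_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.diam_gall_var_frac <= 1.0:
            raise ValueError("diam_gall_var_frac must be in [0, 1]")
        if self.diam_sd_mm <= 0 or self.pref_plant_effect_sd < 0 or self.clutch_sd_log < 0:
            raise ValueError("trait SDs must be non-negative (diam_sd_mm > 0)")


def _default_true_alpha() -> dict:
    # Effect sizes emulating the field study: lower survival and disruptive
    # selection on preference in the original food web; all three traits
    # under directional selection after larval-parasitoid removal.
    return {
        "original": TrueSurface(
            intercept=-0.85,
            linear=(0.50, 0.10, -0.20),
            quadratic=(0.20, -0.08, 0.25),
            interaction=(-0.06, -0.20, 0.05),
        ),
        "removal": TrueSurface(
            intercept=0.20,
            linear=(0.45, -0.20, -0.35),
            quadratic=(0.11, -0.12, 0.02),
            interaction=(-0.16, -0.04, 0.0),
        ),
    }


@dataclass
class SynthConfig:
    """Full specification of a synthetic dataset (seed mandatory).

    Defaults mirror the field design: 8 willow genotypes x 16 plants x ~6
    collected galls, ~2.1 larvae per gall, plants split evenly between the
    original and removal food webs, 17% early larval death and <3%
    incidental larval parasitism inside removal bags.
    """

    seed: int
    n_genotypes: int = 8
    plants_per_genotype: int = 16
    galls_per_plant: int = 6
    larvae_per_gall_mean: float = 2.1
    treatment_assignment: float = 0.5
    true_alpha: dict = field(default_factory=_default_true_alpha)
    re_sd: tuple[float, float, float] = (0.3, 0.3, 0.7)
    trait_model: TraitModel = field(default_factory=TraitModel)
    early_death_frac: float = 0.17
    incidental_larval_frac: float = 0.03
    egg_surface: Optional[TrueSurface] = None

    def __post_init__(self) -> None:
        if min(self.n_genotypes, self.plants_per_genotype, self.galls_per_plant) < 1:
            raise ValueError("all counts must be >= 1")
        if self.larvae_per_gall_mean <= 0:
            raise ValueError("larvae_per_gall_mean must be positive")
        if not 0.0 < self.treatment_assignment < 1.0:
            raise ValueError("treatment_assignment must be in (0, 1)")
        if len(self.re_sd) != 3 or any(s < 0 for s in self.re_sd):
            raise ValueError("re_sd must be three non-negative SDs")
        if not 0.0 <= self.early_death_frac < 1.0:
            raise ValueError("early_death_frac must be in [0, 1)")
        if not 0.0 <= self.incidental_larval_frac < 1.0:
            raise ValueError("incidental_larval_frac must be in [0, 1)")
        for t in ("original", "removal"):
            if t not in self.true_alpha:
                raise ValueError(f"true_alpha must provide a surface for '{t}'")

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ValueError("synthetic-data config must specify a seed")
        if "true_alpha" in raw:
            raw["true_alpha"] = {
                t: TrueSurface(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in s.items()})
                for t, s in raw["true_alpha"].items()
            }
        if "egg_surface" in raw and raw["egg_surface"] is not None:
            raw["egg_surface"] = TrueSurface(
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in raw["egg_surface"].items()})
        if "trait_model" in raw:
            raw["trait_model"] = TraitModel(**raw["trait_model"])
        if "re_sd" in raw:
            raw["re_sd"] = tuple(raw["re_sd"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _ztp_lambda(mean: float) -> float:
    """Rate of a zero-truncated Poisson with the given mean."""
    if mean <= 1.0:
        raise ValueError("zero-truncated Poisson mean must exceed 1")
    f = lambda lam: lam / (1.0 - np.exp(-lam)) - mean
    return brentq(f, 1e-9, max(10.0 * mean, 10.0))


def _sample_ztp(rng: np.random.Generator, lam: np.ndarray) -> np.ndarray:
    """Zero-truncated Poisson draws (resample zeros)."""
    out = rng.poisson(lam)
    while True:
        zeros = out == 0
        if not zeros.any():
            return out
        out[zeros] = rng.poisson(lam[zeros])


def _zscore_with(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant trait")
    return (x - np.mean(x)) / sd


def generate_dataset(config: SynthConfig) -> pd.DataFrame:
    """Simulate one observation table (one row per larva).

    Survival is Bernoulli(invlogit(eta)) with eta = treatment's TrueSurface
    evaluated on internally standardized traits plus genotype, plant and
    gall random intercepts.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    tm = config.trait_model

    n_plants = config.n_genotypes * config.plants_per_genotype
    # treatment assigned at the plant level, balanced within genotype
    n_removal = int(round(config.treatment_assignment * config.plants_per_genotype))
    plant_rows = []
    for g in range(config.n_genotypes):
        labels = np.array(["original"] * config.plants_per_genotype, dtype=object)
        idx = rng.permutation(config.plants_per_genotype)[:n_removal]
        labels[idx] = "removal"
        for p, lab in enumerate(labels):
            plant_rows.append((f"G{g + 1:02d}", f"G{g + 1:02d}-P{p + 1:03d}", lab))
    counts = pd.Series([lab for _, _, lab in plant_rows]).value_counts()
    if counts.get("original", 0) < 2 or counts.get("removal", 0) < 2:
        raise ValueError(
            "configuration yields fewer than 2 plants in a treatment; "
            "a treatment contrast would be impossible")

    # per-gall larval counts: zero-truncated Poisson with between-gall
    # log-rate heterogeneity (rate recentred so the marginal mean is kept)
    n_galls = n_plants * config.galls_per_plant
    base_lam = _ztp_lambda(max(config.larvae_per_gall_mean, 1.0 + 1e-6))
    log_mult = rng.normal(0.0, tm.clutch_sd_log, n_galls) - 0.5 * tm.clutch_sd_log ** 2
    gall_lam = base_lam * np.exp(log_mult)
    larvae_per_gall = _sample_ztp(rng, gall_lam)

    # random intercepts on the logit scale
    re_geno = rng.normal(0.0, config.re_sd[0], config.n_genotypes)
    re_plant = rng.normal(0.0, config.re_sd[1], n_plants)
    re_gall = rng.normal(0.0, config.re_sd[2], n_galls)

    # plant-level preference on the sqrt scale (truncated at zero)
    sqrt_pref = np.clip(
        rng.normal(tm.pref_mean_sqrt, tm.pref_plant_effect_sd, n_plants), 0.0, None)
    pref_density = sqrt_pref ** 2

    sd_gall = np.sqrt(tm.diam_gall_var_frac) * tm.diam_sd_mm
    sd_resid = np.sqrt(1.0 - tm.diam_gall_var_frac) * tm.diam_sd_mm
    gall_diam_eff = rng.normal(0.0, sd_gall, n_galls)

    rows: dict[str, list] = {c: [] for c in COLUMNS}
    eta_re = []
    gall_idx = 0
    for plant_i, (geno_id, plant_id, treat) in enumerate(plant_rows):
        geno_i = plant_i // config.plants_per_genotype
        for _ in range(config.galls_per_plant):
            n_larv = int(larvae_per_gall[gall_idx])
            gall_id = f"{plant_id}-g{gall_idx + 1:04d}"
            diam = tm.diam_mean_mm + gall_diam_eff[gall_idx] + rng.normal(0.0, sd_resid, n_larv)
            diam = np.clip(diam, 0.05, None)
            for k in range(n_larv):
                rows["larva_id"].append(f"{gall_id}-L{k + 1}")
                rows["gall_id"].append(gall_id)
                rows["plant_id"].append(plant_id)
                rows["genotype_id"].append(geno_id)
                rows["treatment"].append(treat)
                rows["diam_mm"].append(round(float(diam[k]), 4))
                rows["clutch_size"].append(n_larv)
                rows["pref_density"].append(round(float(pref_density[plant_i]), 4))
                eta_re.append(re_geno[geno_i] + re_plant[plant_i] + re_gall[gall_idx])
            gall_idx += 1

    df = pd.DataFrame({
        "larva_id": rows["larva_id"],
        "gall_id": rows["gall_id"],
        "plant_id": rows["plant_id"],
        "genotype_id": rows["genotype_id"],
        "treatment": rows["treatment"],
        "diam_mm": rows["diam_mm"],
        "clutch_size": rows["clutch_size"],
        "pref_density": rows["pref_density"],
    })
    n = len(df)

    # the true surface is specified on the standardized-trait scale, so
    # standardize internally (same transforms the estimator applies)
    z = np.column_stack([
        _zscore_with(df["diam_mm"].to_numpy(float)),
        _zscore_with(np.log(df["clutch_size"].to_numpy(float))),
        _zscore_with(np.sqrt(df["pref_density"].to_numpy(float))),
    ])
    eta = np.asarray(eta_re)
    treat_arr = df["treatment"].to_numpy()
    for t in ("original", "removal"):
        mask = treat_arr == t
        eta[mask] += config.true_alpha[t].eta(z[mask])
    survival = (rng.random(n) < expit(eta)).astype(int)

    # fates: early death first (independent of the surface), then incidental
    # larval parasitism inside removal bags, then egg/larval split of deaths
    fate = np.where(survival == 1, "survived", "egg_parasitized").astype(object)
    early = rng.random(n) < config.early_death_frac
    incidental = (treat_arr == "removal") & (rng.random(n) < config.incidental_larval_frac)
    died = survival == 0
    if config.egg_surface is not None:
        p_egg = expit(config.egg_surface.eta(z))
    else:
        p_egg = np.full(n, 0.5)
    egg_draw = rng.random(n) < p_egg
    orig_died = died & (treat_arr == "original")
    fate[orig_died & ~egg_draw] = "larval_parasitized"
    # removal-bag deaths are egg parasitism by design (larval guild excluded)
    fate[incidental] = "larval_parasitized"
    survival[incidental] = 0
    fate[early] = "early_death"
    survival[early] = 0

    df["fate"] = fate
    df["survival"] = survival
    return df[COLUMNS]


def generate_expression_bias(table: pd.DataFrame, bias: float,
                             seed: int | None = None) -> pd.DataFrame:
    """Perturb diameters conditional on survival to mimic expression bias.

    Shifts the chamber diameter of each larva in a multi-larva gall by the
    conditional-expectation displacement implied by a logistic model in
    which survival depends on standardized diameter with slope ``bias``
    and a free gall intercept: to first order,
    E[z | outcomes] - E[z] = bias * [v_e (y_i - p0) + v_u sum_j (y_j - p0)],
    where v_e and v_u are the residual and gall-level shares of diameter
    variance and p0 the overall survival fraction.  Survivors are enlarged
    and dead larvae shrunk, both through the within-gall contrast (v_e
    term) and through a gall-level displacement (v_u term), so that the
    mixed-logistic estimator fitted to the within-gall-varying subset
    recovers ``bias`` in expectation.  Single-larva galls are untouched
    (no within-gall contrast exists).  The operation is deterministic;
    ``seed`` is accepted for interface symmetry with the generator.
    """
    if bias == 0.0:
        return table.copy()
    sizes = table.groupby("gall_id")["larva_id"].transform("size")
    if not (sizes > 1).any():
        raise ValueError("table has no multi-larva gall; bias cannot be injected")

    out = table.copy()
    diam = out["diam_mm"].to_numpy(float)
    s_tot = np.std(diam, ddof=1)
    # pooled within-gall variance from galls with >= 2 larvae
    multi = out[sizes > 1]
    dev = multi["diam_mm"] - multi.groupby("gall_id")["diam_mm"].transform("mean")
    dof = len(multi) - multi["gall_id"].nunique()
    s_w2 = float((dev ** 2).sum() / dof)
    v_e = s_w2 / s_tot ** 2          # residual share of diameter variance
    v_u = max(1.0 - v_e, 0.0)        # gall-level share

    y = out["survival"].to_numpy(float)
    p0 = float(y.mean())
    resid = y - p0
    gall_sum = out.assign(_r=resid).groupby("gall_id")["_r"].transform("sum").to_numpy()
    shift_z = bias * (v_e * resid + v_u * gall_sum)
    shift_z = np.where(sizes.to_numpy() > 1, shift_z, 0.0)
    out["diam_mm"] = np.round(np.clip(diam + shift_z * s_tot, 0.01, None), 6)
    return out
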