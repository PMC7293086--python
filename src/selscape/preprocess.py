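"""Filtering rules and trait transformation/standardization.

Two exclusion rules define the analysis population: larvae that died early
(before the gall finished growing) are dropped in both treatments because
early death stunts chamber diameter, and incidental larval parasitism is
dropped only inside the removal treatment, where that guild was supposed to
be excluded.  Clutch size is log-transformed, oviposition preference
square-root transformed, chamber diameter left untransformed; all three are
then z-scored with the pooled (both-treatment) mean and SD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthdata import FATES

__all__ = ["ExclusionLog", "apply_exclusions", "standardize_traits", "validate_table"]

Z_COLS = ("z_diam", "z_clutch", "z_pref")


@dataclass(frozen=True)
class ExclusionLog:
    early_death_dropped: int
    incidental_larval_dropped: int
    rows_retained: int

    def to_json(self) -> str:
        return json.dumps({
            "early_death_dropped": self.early_death_dropped,
            "incidental_larval_dropped": self.incidental_larval_dropped,
            "rows_retained": self.rows_retained,
        })


def validate_table(table: pd.DataFrame) -> None:
    """Check the observation-table invariants; raise ValueError on violation."""
    required = {"larva_id", "gall_id", "plant_id", "genotype_id", "treatment",
                "fate", "survival", "diam_mm", "clutch_size", "pref_density"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    if len(table) == 0:
        return
    if table[list(required)].isna().any().any():
        raise ValueError("observation table contains missing values; "
                         "rows with missing traits are rejected, not imputed")
    bad = ~table["fate"].isin(FATES)
    if bad.any():
        row = table.loc[bad].iloc[0]
        raise ValueError(
            f"unknown fate label {row['fate']!r} (larva_id={row['larva_id']!r})")
    if not ((table["survival"] == 1) == (table["fate"] == "survived")).all():
        raise ValueError("survival must be 1 exactly when fate == 'survived'")
    if (table.groupby("gall_id")["clutch_size"].nunique() > 1).any():
        raise ValueError("clutch_size must be constant within each gall")
    if (table.groupby("plant_id")["pref_density"].nunique() > 1).any():
        raise ValueError("pref_density must be constant within each plant")
    for child, parent in (("gall_id", "plant_id"), ("plant_id", "genotype_id")):
        if (table.groupby(child)[parent].nunique() > 1).any():
            raise ValueError(f"{child} must nest uniquely within {parent}")


def apply_exclusions(raw: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop early deaths (both treatments) and incidental larval parasitism
    (removal treatment only); returns the filtered table and a count log."""
    validate_table(raw)
    early = raw["fate"] == "early_death"
    incidental = (raw["fate"] == "larval_parasitized") & (raw["treatment"] == "removal")
    keep = ~(early | incidental)
    log = ExclusionLog(
        early_death_dropped=int(early.sum()),
        incidental_larval_dropped=int(incidental.sum()),
        rows_retained=int(keep.sum()),
    )
    return raw.loc[keep].reset_index(drop=True), log


def standardize_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Add z_diam, z_clutch, z_pref columns (pooled mean 0, SD 1, ddof=1).

    Transforms first (log clutch size, sqrt preference, diameter untouched),
    then centers and scales with the pooled moments of the supplied —
    normally already filtered — table.  The transform parameters are stored
    in ``result.attrs['standardization']`` so new phenotypes can be mapped
    onto the same scale.
    """
    validate_table(table)
    if len(table) < 2:
        raise ValueError("need at least 2 rows to standardize traits")
    if (table["diam_mm"] <= 0).any():
        raise ValueError("diam_mm must be positive")
    if (table["clutch_size"] < 1).any():
        raise ValueError("clutch_size must be >= 1")
    if (table["pref_density"] < 0).any():
        raise ValueError("pref_density must be non-negative")

    out = table.copy()
    transformed = {
        "z_diam": out["diam_mm"].to_numpy(float),
        "z_clutch": np.log(out["clutch_size"].to_numpy(float)),
        "z_pref": np.sqrt(out["pref_density"].to_numpy(float)),
    }
    params = {}
    for col, x in transformed.items():
        mu = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        if sd == 0.0:
            raise ValueError(f"pooled SD of {col} is zero (constant trait)")
        out[col] = (x - mu) / sd
        params[col] = {"mean": mu, "sd": sd}
    out.attrs["standardization"] = params
    return out
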