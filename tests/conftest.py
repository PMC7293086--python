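import numpy as np
import pandas as pd
import pytest

import selscape as sel


@pytest.fixture(scope="session")
def default_table():
    """A moderate synthetic dataset under the default study conditions."""
    cfg = sel.SynthConfig(seed=42, n_genotypes=8, plants_per_genotype=8,
                          galls_per_plant=5, larvae_per_gall_mean=3.0)
    return sel.generate_dataset(cfg)


@pytest.fixture(scope="session")
def standardized_table(default_table):
    table, _ = sel.apply_exclusions(default_table)
    return sel.standardize_traits(table)


@pytest.fixture(scope="session")
def surface_fits(standardized_table):
    """Linear-only and full surface fits on the session dataset."""
    lin = sel.fit_surface(standardized_table, sel.SurfaceSpec(order="linear"))
    full = sel.fit_surface(standardized_table, sel.SurfaceSpec(order="full"))
    return lin, full


def make_toy_table(rows):
    """Build a tiny observation table from (gall, plant, geno, treat, fate,
    diam, clutch, pref) tuples."""
    recs = []
    for i, (gall, plant, geno, treat, fate, diam, clutch, pref) in enumerate(rows):
        recs.append({
            "larva_id": f"L{i}", "gall_id": gall, "plant_id": plant,
            "genotype_id": geno, "treatment": treat, "fate": fate,
            "survival": int(fate == "survived"), "diam_mm": diam,
            "clutch_size": clutch, "pref_density": pref,
        })
    return pd.DataFrame(recs)


@pytest.fixture
def toy_table():
    rows = [
        ("g1", "p1", "G1", "original", "survived", 3.0, 2, 4.0),
        ("g1", "p1", "G1", "original", "egg_parasitized", 2.5, 2, 4.0),
        ("g2", "p1", "G1", "original", "early_death", 2.0, 1, 4.0),
        ("g3", "p2", "G1", "original", "larval_parasitized", 3.5, 1, 9.0),
        ("g4", "p3", "G2", "removal", "survived", 4.0, 3, 1.0),
        ("g4", "p3", "G2", "removal", "survived", 4.2, 3, 1.0),
        ("g5", "p3", "G2", "removal", "early_death", 2.2, 1, 1.0),
        ("g6", "p4", "G2", "removal", "larval_parasitized", 3.1, 2, 16.0),
        ("g7", "p4", "G2", "removal", "egg_parasitized", 2.9, 1, 16.0),
        ("g8", "p2", "G1", "original", "survived", 3.3, 1, 9.0),
    ]
    return make_toy_table(rows)
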