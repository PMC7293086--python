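"""Simulate a gall-midge survival experiment and fit its selection surfaces.

Generates larvae nested in galls, plants and willow genotypes with a known
logistic selection surface per food-web treatment, applies the exclusion
rules (early deaths everywhere; incidental larval parasitism inside
removal bags), standardizes the traits, and fits the linear-only and full
quadratic mixed-logistic surfaces.
"""

import selscape as sel

cfg = sel.SynthConfig(seed=1)
raw = sel.generate_dataset(cfg)
table, log = sel.apply_exclusions(raw)
tz = sel.standardize_traits(table)
print(f"simulated {len(raw)} larvae; dropped {log.early_death_dropped} early "
      f"deaths and {log.incidental_larval_dropped} incidental larval "
      f"parasitisms -> {log.rows_retained} analysis rows")

linear = sel.fit_surface(tz, sel.SurfaceSpec(order="linear"))
full = sel.fit_surface(tz, sel.SurfaceSpec(order="full"))

print("\nrandom-intercept SDs (logit scale):",
      {k: round(v, 3) for k, v in full.re_sd.items()})
for t in ("original", "removal"):
    a = full.alpha[t]
    print(f"\n{t} food web, full-surface linear coefficients (log-odds per SD):")
    for name in ("z_diam", "z_clutch", "z_pref"):
        truth = cfg.true_alpha[t].linear[("z_diam", "z_clutch", "z_pref").index(name)]
        print(f"  {name:9s} {a[name]:+.3f}  (generating value {truth:+.2f})")
    print(f"  linear-only model's average slopes: "
          + ", ".join(f"{linear.alpha[t][n]:+.3f}"
                      for n in ("z_diam", "z_clutch", "z_pref")))
# Positive z_diam coefficients mean larger gall chambers raise the log-odds
# of surviving to pupation in both food webs; the full-model coefficients
# should sit within sampling error of the generating surface.  The
# linear-only model estimates average slopes instead — under disruptive
# selection (e.g. preference in the original food web) these legitimately
# differ from the generating linear term, and they are what the
# directional gradients are built from.
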