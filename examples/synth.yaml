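# Synthetic-data configuration mirroring the field design:
# 8 willow genotypes x 16 plants, ~6 collected galls per plant, zero-
# truncated-Poisson larval counts, plants split between food webs.
seed: 1
n_genotypes: 8
plants_per_genotype: 16
galls_per_plant: 6
larvae_per_gall_mean: 2.1
treatment_assignment: 0.5
re_sd: [0.3, 0.3, 0.7]          # genotype, plant, gall intercept SDs (logit)
early_death_frac: 0.17
incidental_larval_frac: 0.03
trait_model:
  diam_gall_var_frac: 0.54      # share of chamber-diameter variance at gall level
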