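# Full pipeline configuration: simulate -> filter -> standardize -> fit ->
# gradients (with expression-bias adjustment) -> curvature -> evolvability.
seed: 1
n_bootstrap: 200
n_G: 10000
n_beta: 1000
adjust_bias: true
w_bar_source: fitted            # or: observed
curvature_doubled: false        # doubled-diagonal curvature variant
g_sampler: onion                # or: elementwise
synth:
  n_genotypes: 8
  plants_per_genotype: 16
  galls_per_plant: 6
  larvae_per_gall_mean: 2.1
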