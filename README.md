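# selscape

Fitness-landscape analysis for selection experiments with binary fitness
and nested group structure.

`selscape` was built around a food-web manipulation on the willow gall
midge *Iteomyia salicisverruca*: larvae (whose survival to pupation is the
fitness measure) sit in galls, galls on plants, plants within willow
genotypes, and an experimental treatment either leaves the full parasitoid
community in place ("original") or excludes the larval-parasitoid guild
with mesh bags ("removal"). The package estimates how each food web
selects on three phenotypic traits — gall chamber diameter, clutch size,
and oviposition preference (larval density per 100 shoots) — and what that
selection implies for the population's evolutionary trajectory and
adaptive potential. Everything is exercisable on synthetic data with known
ground truth, so each stage of the pipeline has a parameter-recovery test.

## The analysis

1. **Selection surfaces.** Survival *W* is modeled with a binomial GLMM
   (logit link) on standardized traits *z*, with random intercepts for
   gall ⊂ plant ⊂ genotype. A linear-only model supplies the directional
   coefficients αᵢ; a full model adds quadratic (αᵢᵢ) and interaction
   (αᵢⱼ) terms. The model is fitted by a Laplace-approximate marginal
   likelihood with an exact O(n) nested factorization of the
   random-effect Hessian. Uncertainty comes from a full parametric
   bootstrap (random effects and responses re-simulated, model refitted).
2. **Selection gradients** (Janzen–Stern). Logit-scale coefficients are
   mapped to the relative-fitness scale: each gradient is
   mean(W(1−W))·α/W̄. Quadratic gradients are doubled for reporting
   (γᵢᵢ on the same scale as βᵢ and γᵢⱼ). A bias adjustment subtracts,
   from the diameter coefficient, the survival–diameter slope estimated
   inside galls whose larvae differ in fate — trait *expression* altered
   by parasitism rather than selection.
3. **Slope and curvature of the landscape.** The slope is the vector
   β = (β_Diam, β_Clutch, β_Pref); the curvature is **C = γ − ββᵀ**
   (regression-scale, undoubled γ diagonal), the matrix that changes the
   additive genetic (co)variance matrix within a generation via
   **ΔG = G C G**; the response to selection is Δz̄ = Gβ (Lande).
4. **Adaptive potential.** For 10⁴ random G-matrices (variances uniform
   on [0, 0.5], uniformly random correlation structure) the package
   applies one generation of each treatment's curvature and compares
   Hansen–Houle average evolvability ē = E[βᵀGβ] over 10³ shared random
   unit selection directions, reporting the fraction of G-matrices whose
   evolvability decreases under the removal food web.

## Worked example

```bash
python examples/03_evolvability.py
```

```
G-matrices sampled: 10000; shared selection directions: 1000
mean change in average evolvability (removal - original): -0.0057
fraction of G-matrices with decreased evolvability: 74.2%
```

Starting from the published gradient table of the field experiment, the
removal food web's curvature — which replaces the disruptive selection on
oviposition preference seen in the intact food web with weak stabilizing
selection — lowers the average evolvability of roughly three quarters of
plausible G-matrices: losing a consumer guild tends to *constrain* the
herbivore's adaptive potential. `examples/01_simulate_and_fit.py`,
`02_gradients_and_landscape.py` and `04_expression_bias.py` walk the rest
of the pipeline (simulation → surfaces → gradients → curvature; bias
injection and recovery) with printed output explained inline.

The same pipeline runs from a shell:

```bash
selscape simulate --config synth.yaml --seed 1 --out data.csv
selscape all --config run.yaml --out results/
```

writing an exclusion log, the gradient table with bootstrap CIs, the
curvature matrices and their treatment contrast, the evolvability
simulation, and a manifest recording every seed and convention flag.

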