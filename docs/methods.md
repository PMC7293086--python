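# Methods

## Model

Per-larva survival (or, with the response switched, egg parasitism) is
Bernoulli with a logistic selection surface on standardized traits and
Gaussian random intercepts on the logit scale for the three nested
grouping factors:

    logit P(W = 1 | z, u) = α₀ + Σᵢ αᵢ zᵢ [+ Σᵢ αᵢᵢ zᵢ² + Σ_{i<j} αᵢⱼ zᵢ zⱼ]
                            + u_gall + u_plant + u_genotype,
    u_level ~ N(0, σ²_level)

with traits z = (chamber diameter, log clutch size, √preference), each
centred and scaled to SD 1 (n−1 denominator) pooled across both
treatments on the post-exclusion data. Directional coefficients αᵢ come
from a model *without* nonlinear terms (the Lande–Arnold requirement for
valid linear surfaces); quadratic and interaction coefficients come from
the full model. By default a single joint model carries a treatment main
effect plus treatment-by-term interactions; per-treatment coefficients
are the sums of main and interaction terms.

Gradients use the Janzen–Stern average-gradient rescaling: every
coefficient is multiplied by mean(W(1−W))/W̄, with W(z) the fitted
probability at the observed covariates, random effects set to zero, and
the average taken over the analysis rows of that treatment. Each
coefficient is rescaled with the fitted probabilities of the model it
comes from (linear-only model for β, full model for γ); W̄ can optionally
be the observed survival fraction (`w_bar_source="observed"`). Quadratic
gradients are doubled *after* rescaling for reporting (the Stinchcombe
convention); the undoubled regression-scale diagonal is retained because
it, and only it, enters the curvature.

### Curvature convention

The landscape curvature is C = γ − ββᵀ with the *undoubled* quadratic
diagonal. The doubling convention is a reporting device that puts γᵢᵢ on
the scale of β and γᵢⱼ in a table; the Hessian of the mean-fitness
surface needs the raw regression coefficient. Only this choice reproduces
the published curvature matrices of the gall-midge experiment from its
published gradient table (e.g. 0.34/2 − 0.13² ≈ 0.15, not
0.34 − 0.13² ≈ 0.32) — the source tables themselves mix the two
conventions, which is worth knowing when comparing against other studies.
The doubled-diagonal variant stays available behind
`curvature(..., use_doubled=True)` for comparison.

When curvature matrices are recomputed from a printed gradient table
(inputs rounded to 2 dp), the propagated rounding error can reach ~0.01
on individual elements; regression tests against published matrices use
that bound.

## Estimation

The marginal likelihood is maximized with a Laplace approximation.
For candidate random-effect SDs σ, the fixed effects and random-effect
modes are found jointly by penalized IRLS (damped Newton with a
backtracking line search, convergence at 1e-10 relative change, max 100
iterations); the profiled Laplace deviance is then minimized over σ by
bounded Powell search on [0, 4]³ (default `xtol=1e-4`; bootstrap refits
use 3e-3 with warm starts). SDs ending below 1e-4 are snapped to the
zero boundary and the block is dropped, at which point the model is
*exactly* an ordinary logistic regression — the degenerate-case oracle
used in the tests.

Because gall ⊂ plant ⊂ genotype strictly, every off-diagonal entry of the
penalized random-effect Hessian couples a group with one of its
ancestors, so the Hessian admits an exact level-by-level LDLᵀ elimination
(galls, then plants, then genotypes) with O(n) cost; the tests verify it
against a generic sparse LU to machine precision. This factorization is
what makes bootstrapping the entire gradient/curvature table practical.

Profiling the fixed effects at the penalized mode is the lme4 `nAGQ=0`
scheme; the package reproduces `glmer(..., nAGQ=0)` to ~1e-4 on
coefficients and RE SDs, and sits within a few hundredths of glmer's
default Laplace (`nAGQ=1`) on binary data. Wald covariances for the
fixed effects are the inverse of the profiled observed information (the
Schur complement of the random-effect block). Complete separation is
flagged when any |coefficient| exceeds 10; such fits are reported as
non-converged rather than silently returned.

The parametric bootstrap is *full*: each replicate redraws the random
intercepts from their fitted variances and the Bernoulli responses from
the implied probabilities, then refits (both the linear-only and full
models when gradients are bootstrapped). Replicates are tied to
per-replicate child seeds, so paired treatment contrasts remain paired
even when replicates are dropped for non-convergence (dropped replicates
are counted; >10% triggers a warning). Downstream quantities (gradients,
curvature elements, contrasts) are computed inside each replicate, so
CIs are on the reported scale.

## Expression-bias adjustment

Parasitism can alter chamber diameter (stunted growth) rather than select
on it. Galls whose larvae share a clutch and local environment but differ
in survival isolate this effect: the survival–diameter slope within such
galls (galls with 0 < mean survival < 1), estimated with the same nested
GLMM but diameter as the only fixed effect, is treated as bias and its
mean subtracted from the linear diameter coefficient before gradients are
computed (an idempotency flag prevents double adjustment). When the bias
estimate carries bootstrap replicates they are paired with the surface
bootstrap; otherwise the mean is subtracted in every replicate.

The synthetic counterpart injects a known bias by shifting each larva's
diameter by the conditional-expectation displacement implied by a
logistic within-gall survival model with slope b: to first order
Δz = b·[v_e (yᵢ − p₀) + v_u Σⱼ(yⱼ − p₀)], where v_e and v_u are the
residual and gall-level variance shares of diameter and p₀ the overall
survival fraction. Both components matter: the within-gall contrast
alone would be shrunk away by the mixed model's partial pooling.
Single-larva galls are untouched.

## Synthetic data

The generator mirrors the field design: genotypes × plants × galls ×
larvae with treatment assigned at the plant level (balanced within
genotype). Defaults were chosen once to emulate the study conditions: 8
genotypes × 16 plants, ~6 collected galls per plant, zero-truncated
Poisson larval counts with mean 2.1 (clutch size *is* the per-gall larval
count, as chambers = larvae), 54% of chamber-diameter variance at the
gall level, plant-level preference generated on the square-root scale,
17% early larval death, 3% incidental larval parasitism inside removal
bags, and default treatment surfaces whose implied gradients are of the
magnitude reported for the field system (lower survival and disruptive
selection on preference in the intact web; all three traits under
directional selection after removal). Random-intercept SDs default to
(0.3, 0.3, 0.7) for genotype/plant/gall — gall-level clustering of
parasitism is the strongest in this system. The true surface is specified
on the standardized-trait scale and the generator standardizes
internally, so generating truth and estimates are directly comparable.

What the generator does *not* emulate: phenology, spatial layout,
willow-trait variation, overdispersion beyond the three random
intercepts, non-Gaussian random effects, and any trait–random-effect
correlation. Passing recovery tests therefore show the estimator is
correct *under its own assumptions*, not that those assumptions hold in
any particular field dataset.

## Evolvability simulation

Random G-matrices are built as D^{1/2} R D^{1/2} with diagonal variances
uniform on (0, 0.5) (the typical narrow-sense heritability range when
phenotypic variance is 1) and R drawn uniformly from the space of valid
correlation matrices by the onion method — every draw is positive
semi-definite by construction. An alternative element-wise sampler
(covariances uniform within their feasibility bounds, PSD by rejection)
is exposed because the decreased-evolvability fraction is mildly
scheme-dependent. Unit selection directions are normalized iid Gaussians
(uniform on the sphere) and are *shared* between the two curvature
scenarios, so each G-matrix's change in average evolvability is a paired
difference with low Monte-Carlo variance. Post-selection matrices
G′ = G + GCG with a negative diagonal are excluded and counted (none
occur at the default effect sizes). Mutation and recombination are
ignored — the one-generation curvature effect dominates at this scale.

Analytically ē(G) = tr(G)/3 over uniform directions; the Monte-Carlo
estimate is asserted to converge to it (1% at 10⁵ directions). At the
published curvature matrices, 10⁴ G-matrices and 10³ directions, the
decreased-evolvability fraction is ≈0.74 under the onion sampler, a few
points above the published 71% — consistent with the published value's
unspecified G-sampling scheme.

## Problem sizes and numerical choices in the test-suite studies

Recovery and coverage studies use sizes chosen to make the whole suite a
routine local run while keeping the statistics meaningful: parameter
recovery uses 100 replicate simulations of ~3,000 larvae with a 3-Wald-SE
criterion; bias recovery uses 100 datasets of ~1,150 larvae; bootstrap
coverage sanity uses 12 outer simulations × 30 replicates on small
datasets with a loose binomial bound. Bootstrap CIs in the pipeline
default to 1,000 replicates; examples and tests use fewer. All
simulations are seeded; the pipeline manifest records every stage seed
and convention flag (W̄ source, γ-doubling, G-sampler, bootstrap scheme).

## Known limitations

- The estimator is specialized to binomial/logit with nested random
  intercepts: no crossed random effects, no other families, no REML
  analogue, no random slopes.
- nAGQ=0-style profiling can attenuate fixed effects by a few hundredths
  relative to full Laplace on binary data with large cluster variance.
- The expression-bias injection is first-order in the bias; very large
  injected biases would be recovered with visible shrinkage.
- The 71%-style evolvability fraction depends on the (unidentifiable)
  G-matrix sampling scheme; treat it as a qualitative statement about the
  direction and typical magnitude of the curvature effect.
- The counterfactual mean-fitness rescaling holds mean(W(1−W)) fixed,
  which is an approximation: a real change in W̄ would also move the
  fitted probabilities.
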