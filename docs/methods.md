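# Methods

This note documents the generative models, the analytic machinery, the
defaults, and the design choices behind `grseval`, in the spirit of a
statistical supplement.

## 1. Score constructions

For risk-allele counts `G_si ∈ {0,1,2}` of subject `s` at locus `i`
(`i = 1…I`):

* **SC-GRS**: `Σ_i G_si`. Integer in `[0, 2I]`.
* **OR-GRS**: `Σ_i w_i G_si` with `w_i = log OR_i`. Protective variants
  (OR < 1) keep their negative weight; we document rather than clip this.
* **EV-GRS**: `w_i = (log OR_i)² · 2·MAF_i(1−MAF_i)` — the per-allele
  explained-variance contribution `2pq·β²` of an additive effect `β` on the
  log-odds scale. Non-negative by construction and invariant to
  `OR ↔ 1/OR`.

The EV weight's algebra is genuinely ambiguous in the literature the score
descends from (the printed form can be parsed as `(log OR)²·2pq` or as
`|log OR|·√(2pq)`-type variants). We adopt `(log OR)²·2pq` because it *is*
the explained-variance of the allelic effect, and because it produces the
tight positive association between weight and single-locus heritability
that motivates the score (§5). The choice is isolated in
`grseval.scores.ev_weight`; the alternative reading is a one-line change.

**Rescaling.** Weighted scores are reported rescaled by `I / Σ w_i` so their
range is comparable with the simple count. Rescaling is a positive scalar
multiple whenever `Σ w_i > 0` (enforced; a non-positive weight sum raises an
error rather than silently skipping). Logistic-regression LRT p-values,
C-statistics and AIC are exactly invariant to it; the test suite asserts
this numerically.

**Weight estimation.** OR and EV weights are estimated from training
replicates pooled into one sample: per locus, a univariate logistic
regression of `D` on the 0/1/2 count gives the per-allele log-OR; the MAF is
the pooled allele frequency folded to the minor allele. Pooling (rather
than averaging per-replicate estimates) is chosen for stability; the two are
equivalent in expectation. Case-control ascertainment bias on the MAF is
negligible at the effect sizes simulated here. Monomorphic loci raise an
estimation error naming the locus; non-convergent fits are flagged in the
weight set's `estimation_report`.

## 2. Liability-threshold simulator (epistasis)

Genotypes are sampled independently per locus under Hardy-Weinberg
equilibrium from the risk-allele frequency. The latent trait is

    Y = β₀ + Σ_i β_i G_i + Σ_T c_T Π_{i∈T} G_i + ε,   ε ~ N(0, σ²)

with arbitrary product-interaction terms `T` (|T| ≥ 2), so two-way
(`c₃₄ G₃G₄`) and three-way (`c₃₄₅ G₃G₄G₅`) epistasis are the same mechanism.
A subject is a case iff `Y` strictly exceeds the replicate's empirical
median; ties (probability zero under Gaussian noise) break toward control.
An even subject count therefore yields exactly 50% prevalence in every
replicate — a design property, not a statistical accident.

**Defaults** (the stated study design): β₀ = 20, σ² = 10, 250 cases + 250
controls, 100 replicates. MAF patterns: common 0.4, rare 0.05, or
alternating. Effect sizes: common variants 0.2 (equal) or 0.2/0.5
(unequal); rare variants 0.8 (equal) or 0.2/0.8 (unequal) — rare variants
get larger effects so per-locus heritability stays in the same regime.
Interaction strengths: 0.0 / 0.2 / 0.5 for "negligible / moderate /
strong"; these three values are our choice (the source grid is not
available) spanning zero through a coefficient comparable to the largest
main effect, and are exposed in configuration. All presets keep total
heritability below 5%, the detectable-but-discriminating regime.

**Seeding.** A scenario has one root seed; replicate `r` draws from the
child stream `(root, r)` (NumPy `default_rng([root, r])`), so any replicate
is reproducible in isolation and replicates are mutually independent.
Training collections for weight estimation use a shifted root seed
(default offset 10 000) so training and test draws never share a stream.

## 3. Additive-penetrance simulator (LD)

Two causal loci act additively on penetrance: with baseline `k` and
relative risks `θ_a, θ_b ≥ 1`,

    P(D | g_a, g_b) = k + (θ_a−1)k·g_a/2 + (θ_b−1)k·g_b/2,

so each heterozygote sits halfway between its homozygotes and the 3×3 table
satisfies the additivity identity
`P[a][b] − P[a][0] − P[0][b] + P[0][0] = 0` exactly. Validity requires
`(θ_a+θ_b−1)·k ≤ 1`, checked at construction. Defaults: `k = 0.1`,
`θ ∈ {1.25, 1.5, 1.75}`, 400 subjects balanced, 100 training + 100 test
replicates.

A third, non-causal marker is drawn from a row-stochastic conditional table
`P(G₃ = j | G₂ = i)`. Weak LD: all rows equal the marker's HWE
frequencies (independence). Strong LD: each row places mass 0.8 on
`G₃ = G₂` and spreads the remainder proportionally to the marker's HWE
frequencies — our reconstruction of a "strong correlation" table (the
original conditional frequencies are not available); the table is fully
overridable in configuration. The marker never enters disease generation,
so any performance difference between scoring "true" and "true + marker"
panels is attributable to scoring alone.

Case-control sampling is rejection sampling from the probabilistic disease
model until both quotas fill, with a hard draw cap (default 2×10⁶) that
raises a diagnostic error instead of silently truncating.

This simulator deliberately models LD at the genotype level (a conditional
table), not the haplotype level (r²/D′ on phased haplotypes): the construct
under study is marker-genotype correlation, reproduced as such.

## 4. Heritability decomposition

All heritability is broad-sense on the observed (disease) scale:

    H²_S = Σ_{g∈S} P(g) (P(D|g) − P(D))² / [P(D)(1 − P(D))]

for any locus subset `S`, with penetrances marginalised from the joint.
Under the liability model the joint is available in closed form: the
population threshold `t` solves `Σ_G P(G) Φ((t−μ_G)/σ) = ½` (bracketed
Brent root-finding to |F(t)−½| < 10⁻¹²; `μ_G` is the full linear predictor
including interaction terms), and `P(D|G) = 1 − Φ((t−μ_G)/σ)`. Enumeration
covers up to 8 loci (3⁸ = 6561 cells); beyond that the Monte-Carlo oracle
is the tool. The analytic threshold is the *population* median — model
property — whereas simulation uses the *per-replicate* empirical median;
the two converge as n grows and the test suite checks their agreement.

Components: per-locus marginal `H²_M,i`; pair total `H²_AB`; pairwise
interaction `H²_I,AB = H²_AB − H²_M,A − H²_M,B`; for a three-locus group the
higher-order remainder subtracts all marginals and all pairwise
interactions. Grouping convention: a group whose loci share an interaction
term contributes marginals + interaction remainders; a main-effects-only
group contributes the sum of its marginals. Declaring an interaction term
with coefficient 0 marks a pair as "the interacting unit at zero strength",
whose remainder is then the (≈10⁻⁶) threshold-nonlinearity residue — this
is how the zero-interaction rungs of the heritability ladder are specified.

**Small-effect closed form.** For a single locus at 50% prevalence,
`H² → (2pqβ²/Var Y)·(2/π)` as β → 0; at β = 0.2 the exact value agrees
within 2%, a cross-check frozen in the tests.

**Monte-Carlo oracle.** Empirical penetrances from large simulated draws,
with the plug-in bias of squared penetrance deviations
(`Σ p̂(1−p̂)/(n·P(D)(1−P(D))`) subtracted, agree with the analytic values
within 3 batch-estimated standard errors on every shipped preset.

## 5. Weight-heritability relationship

Sweeping the risk-allele frequency of a single locus (folding RAF > 0.5
through the minor-allele convention) at fixed effect size, with the effect
size used directly as the log odds ratio, the EV weight and the single-locus
heritability rise and fall together (Spearman ρ > 0.99); both vanish at the
monomorphic endpoints and peak at RAF ½. This is the analytic justification
for weighting by `(log OR)²·2pq`.

## 6. Evaluation harness

Per replicate: `logit P(D=1) = α + β·GRS`, maximum likelihood via Newton
iterations; LRT against the intercept-only null on 1 df; C-statistic as the
concordance probability with ties half-credited (trapezoidal AUC);
`AIC = 4 − 2·loglik`. A constant score degenerates cleanly to the null fit
(LRT 0, C = ½). Perfect separation makes the Newton Hessian singular; the
fit is redone with BFGS (which drives the deviance to its supremum), kept in
the aggregates, and flagged non-converged — replicates are never silently
dropped. Power / type-I error is the fraction of replicates with LRT
p < α (α = 0.05 throughout, configurable), reported with a 95% Wilson
interval.

Method contrasts: a two-way OLS of the per-replicate metric on method +
scenario; the three method pairs are compared on the model's residual scale
with the studentized-range (Tukey HSD) distribution, reporting adjusted and
unadjusted p-values and a winner only when adjusted p < α. With a single
scenario this reduces exactly to one-way Tukey HSD, which is the
independent reference in the tests. Rejection rates enter per-scenario (one
value per method per scenario); C-statistic and AIC enter per-replicate,
matching their averaged reporting granularity.

## 7. What the synthetic worlds do and do not establish

The simulators emulate: HWE genotypes, product-term epistasis on a latent
liability, additive penetrance with genotype-level marker correlation,
balanced ascertainment. They do **not** emulate: haplotype-level LD
structure, covariates or gene-environment terms, genotyping error or
missingness, unbalanced or prevalence-realistic ascertainment, weight error
from external meta-analyses. A green test therefore certifies method
behaviour under the stated architectures, not performance on a real cohort;
the CSV interfaces accept real genotype/phenotype tables, but weights and
conclusions then inherit whatever structure those data carry.

Monte-Carlo results at 100 replicates carry binomial noise of ±(4–5)
percentage points on a power estimate near 30%; comparisons against any
single printed power value share that noise floor in both directions.

## 8. Numerical choices and degenerate inputs

* Threshold root-finding: Brent on a bracket of ±12σ around the extreme
  genetic values; tolerance 10⁻¹³, verified to |F(t)−½| < 10⁻¹².
* Median ties: toward control (strict `>` defines a case).
* Genotype coding outside {0,1,2} and status outside {0,1} are hard errors,
  not coerced.
* `Σ w ≤ 0` with rescaling requested: explicit `RescalingError`.
* Rejection-sampling cap exceeded: explicit `SimulationError` with the
  remaining quota and population prevalence in the message.
* Enumeration beyond 8 loci: explicit `CapacityError`.
* Interaction terms require ≥ 2 distinct loci; coefficient 0 is legal and
  meaningful (see §4).

## 9. Known limitations

* The heritability grouping convention treats only pairs and triples as
  interacting units; deeper interactions would need the obvious but
  unimplemented higher-order remainder chain.
* Weight estimation is univariate per locus; joint multi-locus weight
  estimation (which would partially absorb LD) is out of scope by design.
* The strong-LD conditional table and the interaction-strength levels are
  reconstructions (exposed in config), so quantitative results that depend
  on their exact values should be read as representative, not definitive.
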