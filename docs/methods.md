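# Methods

## The model

`snpdiffnet` detects gene pairs whose *joint* distribution of genetic
risk scores differs between cases and controls — differential
interactions, as opposed to single-locus effects.

Each SNP is coded additively (0/1/2 copies of the minor/alternate
allele) and the risk score of gene *i* for a sample is the arithmetic
mean S_i of that sample's codes over the gene's SNPs. For a gene pair
(i, j), let f¹_ij and f⁰_ij be the joint densities of (S_i, S_j) in
cases (Y = 1) and controls (Y = 0). The working model is a penalized
logistic regression (JDINAC):

    logit P(Y=1) = α₀ + Σ_t α_t Z_t
                 + Σ_{i<j} β_ij · ln[ f¹_ij(S_i, S_j) / f⁰_ij(S_i, S_j) ],
    subject to Σ_{i<j} |β_ij| ≤ c.

The log-density-ratio feature is the optimal (likelihood-ratio)
discriminant for the pair; a non-zero β_ij means pair (i, j) carries
class information beyond the other pairs and the covariates Z
(adjustments such as BMI and menopause status, which enter
unpenalized).

Because the same data cannot both estimate the densities and fit the
logistic model without optimism, each of T random splits divides the
cohort in half (stratified by class): densities are fitted on one
half, the penalized model on the other, and the halves then swap
roles. A pair counts as selected in a split if its coefficient is
non-zero in either direction. The importance score

    ω_ij = #{ splits t : β̂_ij,t ≠ 0 },   0 ≤ ω_ij ≤ T,

is a stability-style selection frequency. Pairs with ω_ij ≥ min_score
form the differential network; nodes with degree ≥ 4 in that network
are reported as hub genes.

## Estimation details

**Density estimation.** Bivariate product-Gaussian KDE with
per-dimension Silverman bandwidths h_d = σ̂_d · n^(−1/6). A
zero-variance dimension falls back to 1% of the data range (10⁻³ for a
constant column), with a warning. Both densities are floored at
`density_floor` (default 10⁻¹⁰) before the log, so features are always
finite and a point far outside both supports contributes exactly 0.
Gene scores are means of a few ordinal codes and therefore discrete;
the KDE treats them as continuous, which is the method's intended use
at ≥ 2–3 SNPs per gene.

**Penalized fit.** L1-penalized logistic regression (liblinear
coordinate descent). The intercept and covariates are effectively
unpenalized: covariate columns are inflated by 10⁴ before fitting and
their coefficients deflated afterwards, which is an exact
penalty-factor rescaling for the L1 norm. The penalty grid is
glmnet-style: 20 log-spaced values from λ_max (the smallest penalty
that zeroes every pair coefficient given the covariate-only fit) down
to 0.01·λ_max. λ is chosen by stratified `cv_folds`-fold (default 5)
cross-validated deviance with the **one-standard-error rule**: the
sparsest λ whose mean held-out deviance is within one SE of the
minimum. The 1-SE rule is the package's deliberate default — on null
cohorts (identical dependence in both groups) the deviance-minimizing
rule lets spurious pairs accumulate importance scores up to T/2,
while the 1-SE rule keeps the null importance distribution
concentrated near 0 (measured in `tests/test_acceptance.py`). Feature
standardization before the lasso was evaluated and not adopted: it did
not improve planted-edge or hub recovery, and the raw features share
a natural (log-ratio) scale.

**Determinism.** All randomness flows from configured seeds through
named child streams. Split membership is keyed to sample *identity*
(ids are sorted before permutation), so permuting the row order of the
input leaves every importance score unchanged.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `T` | 20 | random splits; ω ∈ [0, T]. 10 is used in the simulation studies below |
| `split_fraction` | 0.5 | fraction of each class used for density fitting |
| `cv_folds` | 5 | CV folds for the penalty |
| `cv_rule` | `"1se"` | penalty choice rule (`"min"` available) |
| `n_lambdas`, `lambda_min_ratio` | 20, 0.01 | glmnet-style penalty path |
| `density_floor` | 1e-10 | lower clip on both densities before the log |
| `min_score` | ⌈T/4⌉ | ω cutoff for a network edge |
| `min_hub_degree` | 4 | degree threshold for hub calling |
| `penalize_covariates` | false | covariates are adjustments, not candidates |

Per-SNP association (`snp_logistic`) uses the additive genetic model
with maximum-likelihood logistic regression and Wald inference:
OR = exp(β̂), 95% CI = exp(β̂ ± 1.96·SE), two-sided Wald p. The
demographic screen (`epi_stats`) uses the uncorrected Pearson
chi-square (no Yates correction, including 2×2), with numeric factors
binned into right-closed intervals (x ≤ c₁ < x ≤ c₂ …) and each factor
tabulated on its own non-missing subset. Edge validation
(`validate_edge`) is the single-pair version of the split procedure:
densities on one half, one log-ratio feature for the other half, Wald
p-value of that feature in an unpenalized logistic fit.

## The synthetic cohort generator

The generator exists so that every downstream stage is testable with a
known truth. It emulates a hospital-based case–control SNP panel study:
953 cases / 963 controls, 20 candidate genes covered by 100 SNPs with
minor allele frequencies spread over 0.08–0.45, a differential hub, and
two case-associated confounders (a BMI-like normal covariate,
24.36 ± 3.46 in cases vs 24.01 ± 3.11 in controls, and a
menopause-like binary covariate, prevalence 0.335 vs 0.281).

Mechanism: a latent Gaussian copula. Per group, one standard-normal
dimension per SNP with correlation matrix

* within a gene: exchangeable at `within_gene_rho` (default 0.3, a
  local-LD surrogate that makes the gene mean a meaningful aggregate);
* across a planted edge (gene_a, gene_b, ρ_case, ρ_control): the
  exchangeable cross-gene SNP correlation
  c = ρ·√((1+(k_a−1)w)(1+(k_b−1)w)/(k_a·k_b)),
  the unique value making the two *latent gene means* correlate
  exactly ρ in that group;
* zero elsewhere.

Each latent coordinate is discretized at the Hardy–Weinberg thresholds
Φ⁻¹((1−maf)²) and Φ⁻¹(1−maf²), so genotype frequencies are exactly
(1−maf)², 2·maf·(1−maf), maf² marginally, and the two groups differ in
law only on planted edges with ρ_case ≠ ρ_control. Discretization
attenuates the observable score correlation (a latent ρ = 0.6 yields
an observed gene-score correlation ≈ 0.51 at 3 SNPs/gene, maf 0.3).

ρ is defined at the gene-score level rather than the SNP-pair level
because imposing a common cross-SNP correlation equal to ρ is
infeasible for moderate ρ: positive-semidefiniteness caps it at
(1+(k−1)w)/k (≈ 0.53 for k = 3, w = 0.3). Configurations whose implied
latent correlation is not positive definite raise an error naming the
planted edges.

The same PSD constraint limits hubs: a gene correlated ρ with m
mutually independent partners requires |ρ| < 1/√m *for any joint
distribution whatsoever* — a 0.6 star over four partners is
mathematically impossible. `nearest_feasible_star` projects such a
request onto the nearest correlation matrix (Higham projection,
eigenvalue floor 0.01), giving hub–leaf coupling ≈ 0.522 plus a
negligible induced leaf–leaf coupling ≈ 0.037; the simulation studies
use that projected star.

**What the generator does not emulate:** realistic LD block structure,
population stratification, genotyping error or missingness patterns,
covariates correlated with genotypes, X-chromosome dosage. Passing the
simulation-based tests therefore demonstrates correctness and power of
the *method* under a clean dependence model, not performance on any
real cohort.

## Simulation study sizes

The statistical acceptance tests use p = 10 genes, 3 SNPs/gene,
maf 0.3, n = 400/400, T = 10 splits, over 20 master seeds per arm:

* planted-edge recovery — two disjoint edges (ρ 0.6 vs 0) must rank in
  the top 3 by ω in ≥ 80% of seeds;
* null control — with identical dependence in both groups, max ω < T/2
  in ≥ 90% of seeds;
* hub recovery — the projected 0.6 star's hub must be the unique
  degree-≥4 node in ≥ 80% of seeds.

Edge-validation calibration uses 200 null replicates (n = 300/300;
rejection rate at α = 0.05 must lie in the binomial 95% band 0.02–0.08)
and 50 power replicates at biobank-like scale (n = 2000/1750, ρ 0.6
vs 0; power ≥ 90%). `scripts/acceptance.py` re-runs the same designs at
5 seeds per arm plus one full-size (953/963, 20 genes) pipeline pass.

## Known limitations

* Only pairwise interactions are modeled; higher-order structure is
  projected onto pairs.
* ω has no finite-sample selection-error guarantee; `min_score` is a
  screening cutoff, not a significance threshold.
* The KDE treats near-discrete scores as continuous; single-SNP genes
  (3-point support) are at the edge of its intended use.
* Wald inference in sparse 2×2 layouts (rare alleles) can be unstable;
  separation raises an error rather than returning a fragile estimate.
* `validate_edge` spends half the data on density estimation; its
  p-value depends (reproducibly) on the split seed.
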