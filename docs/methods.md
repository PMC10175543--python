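# Methods

## Statistical model

Association between a SNP dosage vector x and the prepared methylation level
y of one CpG site is tested under the linear mixed model

    y = μ + xβ + u + e,   u ~ MVN(0, σu² K),   e ~ MVN(0, σe² I),

with H₀: β = 0 assessed by the Wald statistic (β̂/SE)² against χ²₁. K is a
sample-by-sample relatedness matrix — either the standardized GRM
K = (1/p) Σⱼ zⱼzⱼᵀ with zⱼ = (gⱼ − 2fⱼ)/√(2fⱼ(1−fⱼ)), or a pedigree
expectation (diagonal 1, full siblings 0.5). The random effect u absorbs
family structure and residual polygenic background, which is what keeps the
per-SNP tests calibrated in a sibship cohort.

The fit is exact per SNP. A one-time eigendecomposition K = U D Uᵀ rotates
y, x, and the intercept into independent coordinates with variances
σe²(λdᵢ + 1), λ = σu²/σe². The REML profile in λ is minimized on a log₁₀
grid over [−5, 5] followed by Brent refinement (scalar path) or by
vectorized successive-parabolic refinement (batched cis-scan path; the two
paths agree to ~1e−3 relative or better, tested). Fixed effects come from
closed-form GLS at λ̂; σ̂e² uses the n−p denominator, so with K = I the fit
reduces exactly to ordinary least squares — a tested identity.

### Feature-level significance and FDR

Per CpG, all SNPs within ±`window_bp` (default 50,000; 1-based, inclusive)
that pass the in-sample MAF filter (default 0.01) are tested; the minimum
p-value is the CpG-level statistic, ties broken by smaller |distance| then
lexicographic SNP id. Permuting the phenotype sample labels — one shared
permutation per replicate across all CpGs, preserving the inter-CpG
correlation of the null — and repeating the scan (default 10 permutations)
yields an empirical null of CpG-level minima. For a threshold t swept over
the observed minima,

    FDR̂(t) = [mean over permutations of #{null min-p ≤ t}] / max(1, #{observed ≤ t}),

and t* is the largest t with FDR̂(t) ≤ the target (default 5%). CpGs with
min-p ≤ t* are meCpGs; their argmin SNPs are primary meQTLs; every cis-SNP
with p ≤ t* at an meCpG is an meQTL.

### Conditional discovery

For each meCpG, forward selection repeatedly adds the cis-SNP with the
smallest conditional p-value (all previously selected SNPs as fixed
covariates) while that p-value is ≤ t*; backward elimination then re-tests
each included SNP given the others and drops non-significant ones;
forward/backward alternate to a fixed point. Signals are capped at 20 and
candidates collinear with the current model span (R² > 0.999) are skipped.

### Heritability partitioning

y = μ + g_c + g_t + e with g_c ~ MVN(0, σc² K_cis), g_t ~ MVN(0, σt² K_trans);
K_cis is the standardized GRM of the window SNPs and K_trans that of all
remaining SNPs (or the pedigree matrix when it is the known trans
covariance). Variance components are estimated by average-information REML
with step halving against the REML likelihood and clamping at the zero
boundary; an all-zero component matrix degenerates cleanly to the
single-component model (tested against a dense 1-D grid-search oracle). PVE
fractions weight each component by the mean diagonal of its matrix, making
them invariant to GRM scaling; cis-PVE + trans-PVE = total PVE by
construction.

### Colocalization

Per SNP and trait, evidence is the Wakefield approximate Bayes factor
computed from (β, SE): with z = β/SE, V = SE², r = W/(W+V),
log ABF = ½log(1−r) + z²r/2, with prior effect variance W = 0.15² for
quantitative traits (config-exposed). Everything is carried in log space
(no overflow to |z| ≈ 100, tested). Two-trait posteriors use the standard
five-hypothesis sums (1, p1·S1, p2·S2, p1p2(S1S2−S12), p12·S12) normalized;
the implementation is tested against brute-force enumeration of all causal
assignments on small panels to 1e−10.

Priors derive from discovery counts: p1+p12 and p2+p12 are the fractions of
examined cis-SNPs that are primary QTLs for each trait, and
p12 = frac_shared × (p1+p12). The sharing fraction is chosen by internal
empirical calibration: for each candidate p12, the mean posterior PP4 across
pairs is compared with the mean prior P(H4); the candidate whose ratio is
nearest 1 on the log scale wins. When every ratio is below 1 the data carry
less sharing than the smallest prior admits, and the smallest candidate is
returned with a warning — the expected outcome on null pairs.

The three-trait extension enumerates every assignment of a trait subset to
sharing groups (15 configurations for three traits; Bell-sum counts,
tested). Group evidence at a SNP multiplies the member ABFs; summing over
distinct-SNP assignments across groups uses Möbius inclusion–exclusion over
partitions of the groups. Priors are per-SNP 1e−4/1e−6/1e−7 by sharing
order. Restricting the machinery to two traits with matched priors
reproduces the two-trait posteriors to 1e−8 (tested). Loci need ≥10 shared
SNPs; thinner loci are skipped with a reason.

### Mediation

Two OLS regressions per pair — Y = μ₁ + β₃X + β₁M + ε₁ and
M = μ₂ + β₂X + ε₂ — give the Sobel statistic
t = β₁β₂/√(β₁²σ²_{β₂} + β₂²σ²_{β₁}) with a two-sided normal p-value, and
the mediation proportion ρ = β₁β₂/(β₃ + β₁β₂). Covariates are removed
upstream (prep residualization), so the mediation regressions carry only
intercept, exposure, and mediator. Both directions (SME, SEM) are computed
per pair; q-values are Benjamini–Hochberg within each direction at FDR 0.05.
ρ outside [0, 1] (inconsistent mediation) is reported as-is and flagged.

### Replication and enrichment

π₀(λ) = #{p > λ}/(n(1−λ)) on λ ∈ {0.05, …, 0.95}; the smoother is a cubic
least-squares polynomial through (λ, π₀(λ)) evaluated at max λ — a
deterministic stand-in for the conventional df=3 smoothing spline — and
π₁ = 1 − clamp(π₀). The fixed-λ estimator is also provided and equals the
plug-in formula exactly. Enrichment uses Fisher's exact test (hypergeometric
two-sided p) with OR = ad/bc, Haldane 0.5 correction when a cell is zero,
and the Woolf interval exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)). Feature
annotation converts 1-based CpG positions to 0-based points against
half-open BED intervals and resolves multiple overlaps by the precedence
order TSS200 > TSS1500 > 5′UTR > 1st Exon > Body > 3′UTR > Intergenic.

## The synthetic-data generator

The generator emulates the statistical structure of a family-based
methylation QTL study, not array chemistry.

- **Genotypes.** Families of `sibship_size` siblings descend from two
  simulated parents by gene-dropping: each child inherits one whole
  haplotype per parent. Dosages stay discrete, LD is preserved exactly, the
  expected GRM off-diagonal for siblings is 0.5, and the returned kinship is
  the pedigree expectation — mirroring the common practice of supplying an
  externally estimated relatedness matrix. Haplotypes follow a first-order
  Markov copying process along the SNP index (parameter `ld_decay`;
  adjacent-SNP correlation ≈ ld_decay), with allele frequencies uniform on
  `maf_range` (default 0.05–0.5).
- **Methylation.** Per CpG, M = baseline + cis + u + e. The baseline is a
  draw from a hypo/hyper beta mixture — Beta(2, 18) and Beta(24, 2) with
  weights 0.35/0.65, reproducing the bimodal beta-value pattern of blood
  methylation arrays (modes near 0.1 and 0.96, roughly 30% of sites below
  0.3 and 60% above 0.7) — mapped through the inverse logit₂. A fraction
  `prop_mecpg` of CpGs receives causal cis-SNPs; u is drawn from
  MVN(0, σ²K); each component is rescaled so its in-sample share of the
  total M variance matches the configured targets exactly, which is what
  makes parameter-recovery checks sharp. Options plant effects on the
  standardized scale (`standardized_effects`, matching the GRM-infinitesimal
  assumption of the REML estimator) and with equal magnitudes
  (`equal_causal_effects`, so planted multi-signal loci have comparable
  power).
- **Triplets.** One locus with methylation, expression, and GWAS summary
  statistics under `shared`, `distinct` (two causal SNPs in low LD), or
  `null` scenarios. GWAS statistics come from a separate simulated cohort
  (default N = 20,000) with matched allele frequencies and LD — external
  GWAS are never the QTL samples. A mediated path plants
  E = αM + γg + noise with the implied proportion αβ/(αβ + γ) recorded.

What the generator does **not** emulate: realistic human LD maps and
recombination, imputation uncertainty, probe-type artifacts, detection
p-values, cell-type heterogeneity. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the stated generative
model, not that any particular biological dataset meets those assumptions.

## Study conditions and numerical choices

The validation studies (also run by `scripts/acceptance.py`) use: null
calibration at n = 500 with 2,000 CpGs × 5 cis-SNPs and 10 permutations; FDR
control over 50 replicates of 100 CpGs at n = 200 with 20% planted signals;
conditional recovery over 100 replicates of two equal independent signals at
n = 500; PVE recovery over 200 features at n = 500 with planted (0.30,
0.20); colocalization over 50 replicates per scenario at n = 1,000;
mediation over 100 replicates at n = 800 with planted ρ = 0.5; π₁ over five
independent 10,000-p-value mixtures (a single mixture carries ~0.02–0.04
Monte-Carlo noise in the smoother tail, so accuracy is summarized by the
mean; note the Beta(0.1, 1) alternative keeps ~7% of its mass above p = 0.5,
which any tail-based estimator absorbs into the null, so the expected
estimate sits slightly below the mixing weight).

Numerical details worth knowing: λ is optimized on log₁₀ scale over [−5, 5];
beta values at exactly 0/1 are clipped at 1e−6 before the logit; the
rank-inverse-normal transform uses Blom offsets (rank − 3/8)/(n + 1/4) with
average ranks on ties; batch effects enter residualization as fixed-effect
indicator columns (with few batches the fixed- and random-effect residuals
are near-identical, and the fixed-effect fit is non-iterative); negative
REML variance components are clamped at zero and PVEs renormalized;
degenerate LMM fits (residual variance numerically zero) are flagged and
floored rather than reported as p = 0. The heritability estimator is a
deterministic two-component REML rather than an MCMC sparse-plus-polygenic
model; under the generator's polygenic model the two coincide in
expectation, and determinism makes recovery tests exact to run.

## Known limitations

- Trans-QTL scans are out of scope; only cis windows are tested.
- The conditional model treats selected SNPs as fixed covariates; it does
  not re-estimate the permutation threshold conditionally.
- Sobel tests are conservative in small samples; bootstrap mediation
  intervals are not provided.
- The π₁ smoother is a global cubic, which can differ from a smoothing
  spline by ~0.01–0.02 on irregular π₀ curves.
- The three-trait sharing model documents its own inclusion–exclusion
  likelihood; it verifies the two-trait reduction rather than claiming
  bit-parity with any external implementation.
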