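# meqtlkit

Kinship-aware cis-meQTL mapping and downstream integration of DNA
methylation, gene expression, and GWAS signals — built for family-structured
cohorts (e.g. sibship designs) where ordinary regression is miscalibrated.

Methylation quantitative trait locus (meQTL) mapping asks, for each CpG site,
whether nearby genetic variants are associated with its methylation level.
`meqtlkit` implements the full analysis arc as a tested Python library plus a
thin CLI:

- **prep** — beta→M transform (M = log₂ β/(1−β)), probe exclusion filters,
  covariate residualization and rank-based inverse-normal transform;
- **relate** — standardized genetic relatedness matrix (GRM) and genotype PCs;
- **assoc** — per-CpG cis-window scans under the linear mixed model
  y = μ + xβ + u + e, u ~ MVN(0, σ²ᵤK), e ~ MVN(0, σ²ₑI), with exact per-SNP
  Wald tests, permutation-based empirical FDR on the CpG-level minimum
  p-value, and forward–backward conditional discovery of independent meQTLs;
- **herit** — cis/trans partitioning of methylation heritability by
  two-variance-component AI-REML;
- **colocal / multicoloc** — Wakefield approximate-Bayes-factor
  colocalization of meQTLs with eQTLs (five hypotheses, PP4) and three-trait
  sharing across GWAS/expression/methylation (15 configurations, PPA);
- **mediate** — Sobel tests and mediation proportions
  ρ = β₁β₂/(β₃ + β₁β₂) in both the SNP→methylation→expression (SME) and
  SNP→expression→methylation (SEM) directions;
- **downstream** — Storey's π₁ replication rates and Fisher's-exact
  annotation enrichment with Woolf confidence intervals;
- **synth** — a first-class generator of sibship genotypes with LD, bimodal
  methylation with planted cis/trans effects, expression triplets and
  external-cohort GWAS summary statistics, with full ground truth.

## Worked example

```python
import numpy as np
from meqtlkit.synth import SimConfig, simulate_genotypes, simulate_methylation
from meqtlkit.assoc import permutation_fdr
from meqtlkit.studies import normalize_for_mapping

cfg = SimConfig(n_samples=200, n_cpgs=100, n_snps_per_window=5,
                prop_mecpg=0.2, cis_pve_target=0.3, trans_pve_target=0.1,
                seed=11)
geno, kin = simulate_genotypes(cfg)          # sibship dosages + pedigree K
pheno, truth = simulate_methylation(geno, kin, cfg)
res = permutation_fdr(normalize_for_mapping(pheno), geno, kin,
                      n_perm=10, target_fdr=0.05, seed=5)
print(f"t* = {res.t_star:.3g}; {len(res.mecpgs)} meCpGs called")
true_me = {f for f, v in truth.causal_map.items() if v}
print(f"false calls: {len(set(res.mecpgs) - true_me)}")
```

Output:

```
t* = 9.82e-13; 20 meCpGs called
false calls: 0
```

Twenty CpGs were planted with a cis signal explaining 30% of M-value
variance; the permutation-calibrated threshold recovers all twenty with no
false positives. The same stages are available from the shell:

```bash
meqtl simulate --config sim.yaml --out data/ --seed 1
meqtl relate --geno data/genotypes.tsv --snp-map data/snp_map.tsv --out grm
meqtl run --config run.yaml --out results/
```

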