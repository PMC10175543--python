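"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure of a family-based
methylation QTL study: sibship-structured genotypes with local LD,
bimodally distributed methylation beta values with planted cis effects and a
polygenic (kinship) trans component, expression traits that share or do not
share causal variants with methylation, and GWAS summary statistics computed
from a separate simulated cohort.

Genotypes are produced by gene-dropping: each family has two simulated
parents (four founder haplotypes); each child inherits one whole haplotype
from each parent. This keeps dosages discrete, preserves LD exactly, and
gives siblings an expected GRM off-diagonal of 0.5. LD along the SNP index
follows a first-order Markov copying process with parameter ``ld_decay``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeSet, KinshipMatrix, PhenotypeMatrix
from .prep import beta_to_m, m_to_beta

__all__ = [
    "BetaMixture",
    "SimConfig",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_methylation",
    "simulate_triplet",
    "write_dataset",
]


@dataclass
class BetaMixture:
    """Two-component hypo/hyper beta-value mixture.

    Defaults Beta(2, 18) (hypomethylated, mode ~0.06) and Beta(24, 2)
    (hypermethylated, mode ~0.96) with weights 0.35/0.65, mimicking the
    bimodal distribution seen on methylation arrays where roughly a third of
    CpGs sit below beta 0.3 and two thirds above 0.7.
    """

    hypo_a: float = 2.0
    hypo_b: float = 18.0
    hyper_a: float = 24.0
    hyper_b: float = 2.0
    weight_hypo: float = 0.35

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        hypo = rng.random(size) < self.weight_hypo
        out = np.where(
            hypo,
            rng.beta(self.hypo_a, self.hypo_b, size),
            rng.beta(self.hyper_a, self.hyper_b, size),
        )
        return np.clip(out, 1e-6, 1 - 1e-6)


@dataclass
class SimConfig:
    """Study-design parameters for the simulator.

    The defaults describe a desk-scale sibship study: 500 individuals in
    families of 2, one 50 kb cis window of 20 SNPs per CpG, 20% of CpGs with
    a planted cis signal explaining 30% of M-value variance, and a polygenic
    trans component explaining 20%.
    """

    n_samples: int = 500
    sibship_size: int = 2
    n_snps_per_window: int = 20
    n_cpgs: int = 200
    window_bp: int = 50_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.5
    prop_mecpg: float = 0.2
    n_causal_per_mecpg: int | tuple[int, ...] = 1
    cis_pve_target: float = 0.3
    trans_pve_target: float = 0.2
    beta_mixture: BetaMixture = field(default_factory=BetaMixture)
    m_total_var: float = 1.0  # M-value variance around the baseline
    #: scale causal effects by 1/sqrt(2f(1-f)) so each causal SNP contributes
    #: equally on the standardized scale (the GRM-infinitesimal convention)
    standardized_effects: bool = False
    #: draw effects as random signs (magnitude 1) instead of N(0,1), giving
    #: every causal SNP a comparable share of the planted cis variance
    equal_causal_effects: bool = False
    gwas_n_samples: int = 20_000
    gwas_pve: float = 0.005  # per-locus trait variance in the GWAS cohort
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_samples, self.sibship_size, self.n_snps_per_window,
               self.n_cpgs) <= 0:
            raise ValueError("counts must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.cis_pve_target < 0 or self.trans_pve_target < 0:
            raise ValueError("PVE targets must be non-negative")
        if self.cis_pve_target + self.trans_pve_target >= 1:
            raise ValueError("cis + trans PVE must be < 1")
        if not (0 <= self.ld_decay < 1):
            raise ValueError("ld_decay must lie in [0, 1)")
        if not (0 <= self.prop_mecpg <= 1):
            raise ValueError("prop_mecpg must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth for acceptance testing.

    ``causal_map`` maps each feature to its (SNP id, M-scale effect) list;
    PVE dictionaries hold the exact in-sample variance fractions; triplet
    scenarios record shared-variant flags and any planted mediation
    proportion.
    """

    causal_map: dict = field(default_factory=dict)
    true_cis_pve: dict = field(default_factory=dict)
    true_trans_pve: dict = field(default_factory=dict)
    shared_variant: dict = field(default_factory=dict)
    mediation_proportion: dict = field(default_factory=dict)

    def validate(self, geno: GenotypeSet) -> None:
        known = set(geno.snp_ids)
        for feat, lst in self.causal_map.items():
            for snp, _ in lst:
                if snp not in known:
                    raise ValueError(f"causal SNP {snp} for {feat} not in genotypes")
        for rho in self.mediation_proportion.values():
            if not (0 <= rho <= 1):
                raise ValueError("planted mediation proportion must be in [0, 1]")


# ---------------------------------------------------------------------------
# genotypes


def _markov_haplotypes(
    rng: np.random.Generator, n_hap: int, freqs: np.ndarray, ld_decay: float
) -> np.ndarray:
    """First-order Markov copying process along the SNP index.

    Each haplotype copies its previous allele with probability ``ld_decay``
    and otherwise draws fresh from Bernoulli(f_j), giving adjacent-SNP allele
    correlation of roughly ld_decay (and ~ld_decay^d at index distance d).
    """
    p = freqs.size
    H = np.empty((n_hap, p), dtype=np.int8)
    H[:, 0] = rng.random(n_hap) < freqs[0]
    if p == 1:
        return H
    copy = rng.random((n_hap, p - 1)) < ld_decay
    fresh = rng.random((n_hap, p - 1)) < freqs[1:]
    for j in range(1, p):
        H[:, j] = np.where(copy[:, j - 1], H[:, j - 1], fresh[:, j - 1])
    return H


def _snp_layout(config: SimConfig) -> pd.DataFrame:
    """Non-overlapping cis windows on one chromosome, one window per CpG."""
    spacing = 2 * config.window_bp + 10_000
    rows = []
    for i in range(config.n_cpgs):
        center = (i + 1) * spacing
        pos = np.linspace(
            center - config.window_bp + 1,
            center + config.window_bp - 1,
            config.n_snps_per_window,
        ).astype(int)
        for j, pp in enumerate(pos):
            rows.append((f"snp{i:05d}_{j:03d}", "1", int(pp), "A", "G"))
    df = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "ref", "alt"])
    return df.set_index("snp")


def cpg_positions(config: SimConfig) -> pd.DataFrame:
    spacing = 2 * config.window_bp + 10_000
    ids = [f"cg{i:05d}" for i in range(config.n_cpgs)]
    return pd.DataFrame(
        {"chrom": "1", "pos": [(i + 1) * spacing for i in range(config.n_cpgs)]},
        index=pd.Index(ids, name="feature"),
    )


def simulate_genotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeSet, KinshipMatrix]:
    """Sibship genotypes by gene-dropping plus the pedigree-expected kinship.

    Returns dosages in {0, 1, 2} and the block-diagonal pedigree kinship
    (GRM scale: diagonal 1, full siblings 0.5).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    snp_map = _snp_layout(config)
    p = len(snp_map)
    freqs = rng.uniform(*config.maf_range, size=p)

    n = config.n_samples
    sib = config.sibship_size
    n_fam = -(-n // sib)  # last family padded (possibly smaller)
    # four founder haplotypes per family
    H = _markov_haplotypes(rng, 4 * n_fam, freqs, config.ld_decay)

    dosages = np.empty((n, p), dtype=float)
    fam_of = np.empty(n, dtype=int)
    i = 0
    for fam in range(n_fam):
        hap = H[4 * fam: 4 * fam + 4]
        for _ in range(min(sib, n - i)):
            mat = hap[rng.integers(0, 2)]
            pat = hap[2 + rng.integers(0, 2)]
            dosages[i] = mat + pat
            fam_of[i] = fam
            i += 1
    sample_ids = [f"s{i:05d}" for i in range(n)]

    K = (fam_of[:, None] == fam_of[None, :]).astype(float) * 0.5
    np.fill_diagonal(K, 1.0)
    kin = KinshipMatrix(K, sample_ids, method="pedigree")
    return GenotypeSet(dosages, snp_map, sample_ids), kin


# ---------------------------------------------------------------------------
# methylation


def _scaled(component: np.ndarray, target_var: float) -> np.ndarray:
    """Center and rescale a component so its in-sample variance is exact."""
    c = component - component.mean()
    v = c.var()
    if target_var <= 0 or v <= 0:
        return np.zeros_like(c)
    return c * np.sqrt(target_var / v)


def simulate_methylation(
    geno: GenotypeSet,
    kin: KinshipMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PhenotypeMatrix, GroundTruth]:
    """Beta-value matrix with planted cis effects and a polygenic component.

    Per CpG, M = baseline + cis + u + e where the baseline comes from the
    hypo/hyper beta mixture (via the inverse logit2 map), the cis term sums
    planted SNP effects, u ~ MVN(0, sigma_u^2 K), and e is iid noise. Each
    component is rescaled so its in-sample share of the total M variance
    matches the configured targets exactly; beta values are the inverse
    transform and always lie in (0, 1).
    """
    config.validate()
    if geno.sample_ids != kin.sample_ids:
        raise ValueError("genotype and kinship sample ids do not match")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)

    n = geno.n_samples
    feature_map = cpg_positions(config)
    # one Cholesky shared across CpGs for the polygenic draw
    L = np.linalg.cholesky(kin.K + 1e-8 * np.eye(n))

    n_me = int(round(config.prop_mecpg * config.n_cpgs))
    me_idx = set(rng.choice(config.n_cpgs, size=n_me, replace=False).tolist())

    snp_pos = geno.snp_map["pos"].to_numpy()
    snp_ids = geno.snp_ids.to_numpy()
    total = config.m_total_var
    truth = GroundTruth()
    M = np.empty((config.n_cpgs, n))

    for i, (fid, row) in enumerate(feature_map.iterrows()):
        baseline = beta_to_m(config.beta_mixture.sample(rng, 1))[0]
        in_window = np.abs(snp_pos - row["pos"]) <= config.window_bp

        cis = np.zeros(n)
        causal: list[tuple[str, float]] = []
        cis_target = config.cis_pve_target if i in me_idx else 0.0
        if cis_target > 0 and in_window.any():
            if isinstance(config.n_causal_per_mecpg, int):
                n_causal = config.n_causal_per_mecpg
            else:
                n_causal = int(rng.choice(config.n_causal_per_mecpg))
            n_causal = min(n_causal, int(in_window.sum()))
            pick = rng.choice(np.where(in_window)[0], size=n_causal, replace=False)
            if config.equal_causal_effects:
                effects = rng.choice([-1.0, 1.0], size=n_causal)
            else:
                effects = rng.normal(size=n_causal)
            if config.standardized_effects:
                fq = geno.dosages[:, pick].mean(axis=0) / 2.0
                fq = np.clip(fq, 1e-6, 1 - 1e-6)
                effects = effects / np.sqrt(2.0 * fq * (1.0 - fq))
            raw = geno.dosages[:, pick] @ effects
            if raw.var() > 0:
                cis = _scaled(raw, cis_target * total)
                # the realized per-SNP effect after rescaling
                scale = np.sqrt(cis_target * total / (raw - raw.mean()).var())
                causal = [
                    (str(snp_ids[s]), float(b * scale))
                    for s, b in zip(pick, effects)
                ]
            else:
                cis_target = 0.0

        trans_target = config.trans_pve_target
        u = _scaled(L @ rng.normal(size=n), trans_target * total)
        resid_target = 1.0 - (cis_target if causal else 0.0) - trans_target
        e = _scaled(rng.normal(size=n), resid_target * total)

        M[i] = baseline + cis + u + e
        truth.causal_map[fid] = causal
        truth.true_cis_pve[fid] = cis_target if causal else 0.0
        truth.true_trans_pve[fid] = trans_target

    beta = np.clip(m_to_beta(M), 1e-12, 1 - 1e-12)
    pheno = PhenotypeMatrix(beta, feature_map, list(geno.sample_ids), "beta")
    truth.validate(geno)
    return pheno, truth


# ---------------------------------------------------------------------------
# triplets (methylation + expression + GWAS) for colocalization/mediation


def _marginal_summary_stats(
    G: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-SNP OLS of y on each genotype column (with intercept)."""
    from scipy.stats import norm

    n = y.size
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = (Gc**2).sum(axis=0)
    sxx = np.where(sxx > 0, sxx, np.nan)
    beta = Gc.T @ yc / sxx
    resid_ss = (yc**2).sum() - beta**2 * sxx
    se = np.sqrt(np.maximum(resid_ss, 0) / (n - 2) / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2 * norm.sf(np.abs(z))
    return beta, se, p


def _low_ld_partner(G: np.ndarray, idx: int, r2_max: float = 0.01) -> int:
    """Index of a SNP in lowest LD with ``idx`` (below r2_max if possible)."""
    g = G[:, idx]
    gc = g - g.mean()
    Gc = G - G.mean(axis=0)
    denom = np.sqrt((Gc**2).sum(axis=0) * (gc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.square(Gc.T @ gc / denom)
    r2[idx] = np.inf
    j = int(np.nanargmin(r2))
    return j


def simulate_triplet(
    geno: GenotypeSet,
    scenario: str,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    mediation_rho: float | None = None,
):
    """One locus with methylation, expression, and external-cohort GWAS.

    scenario 'shared': one causal SNP drives methylation, expression, and the
    GWAS trait. 'distinct': two causal SNPs in low LD drive methylation vs
    expression (GWAS driven by the expression SNP). 'null': no causal SNP
    anywhere. When ``mediation_rho`` is given (shared scenario), expression is
    generated as alpha*M + gamma*g + noise so that the planted mediation
    proportion alpha*b/(alpha*b + gamma) equals ``mediation_rho``.

    Returns (methylation, expression, gwas_summary, GroundTruth); the GWAS
    summary statistics come from a separate simulated cohort of
    ``config.gwas_n_samples`` individuals drawn from the same allele
    frequencies and LD process.
    """
    if scenario not in ("shared", "distinct", "null"):
        raise ValueError(f"unknown scenario: {scenario!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)

    G = geno.dosages
    n, p = G.shape
    truth = GroundTruth()
    total = config.m_total_var
    pve = config.cis_pve_target if config.cis_pve_target > 0 else 0.3

    c1 = int(rng.integers(0, p))
    c2 = _low_ld_partner(G, c1) if scenario == "distinct" else c1
    snp1 = str(geno.snp_ids[c1])
    snp2 = str(geno.snp_ids[c2])

    def qtl_trait(causal_idx: int | None) -> np.ndarray:
        if causal_idx is None:
            return _scaled(rng.normal(size=n), total)
        sig = _scaled(G[:, causal_idx].astype(float), pve * total)
        noise = _scaled(rng.normal(size=n), (1 - pve) * total)
        return sig + noise

    if scenario == "null":
        meth = qtl_trait(None)
        expr = qtl_trait(None)
        gwas_causal = None
    else:
        meth = qtl_trait(c1)
        if mediation_rho is not None:
            if not (0 <= mediation_rho <= 1):
                raise ValueError("mediation_rho must lie in [0, 1]")
            g = G[:, c1].astype(float)
            gc = g - g.mean()
            b = float(gc @ (meth - meth.mean()) / (gc**2).sum())  # SNP->M slope
            t_eff = np.sqrt(pve * total) / max(gc.std(), 1e-12)  # total SNP->E
            alpha = mediation_rho * t_eff / b if b != 0 else 0.0
            gamma = (1 - mediation_rho) * t_eff
            direct = alpha * (meth - meth.mean()) + gamma * gc
            noise = _scaled(rng.normal(size=n), max(total - direct.var(), 0.05))
            expr = direct + noise
            truth.mediation_proportion["pair1"] = mediation_rho
        else:
            expr = qtl_trait(c2)
        gwas_causal = c1 if scenario == "shared" else c2

    # external GWAS cohort with matched allele frequencies and LD
    f = geno.allele_freqs()
    n_g = config.gwas_n_samples
    Hg = _markov_haplotypes(rng, 2 * n_g, f, config.ld_decay)
    Gg = (Hg[:n_g] + Hg[n_g:]).astype(float)
    if gwas_causal is None:
        y = rng.normal(size=n_g)
    else:
        sig = _scaled(Gg[:, gwas_causal], config.gwas_pve)
        y = sig + _scaled(rng.normal(size=n_g), 1 - config.gwas_pve)
    gb, gse, gp = _marginal_summary_stats(Gg, y)
    gwas = geno.snp_map.reset_index().rename(columns={"index": "snp"})
    gwas["beta"], gwas["se"], gwas["p"], gwas["n"] = gb, gse, gp, n_g

    fmap = pd.DataFrame(
        {"chrom": geno.snp_map["chrom"].iloc[0], "pos": int(geno.snp_map["pos"].median())},
        index=pd.Index(["cpg1"], name="feature"),
    )
    gmap = fmap.rename(index={"cpg1": "gene1"})
    meth_pm = PhenotypeMatrix(meth[None, :], fmap, list(geno.sample_ids), "M")
    expr_pm = PhenotypeMatrix(expr[None, :], gmap, list(geno.sample_ids), "M")

    if scenario != "null":
        truth.causal_map["cpg1"] = [(snp1, float("nan"))]
        truth.causal_map["gene1"] = [(snp2 if mediation_rho is None else snp1,
                                      float("nan"))]
    truth.shared_variant[("gene1", "cpg1", "gwas")] = scenario == "shared"
    return meth_pm, expr_pm, gwas, truth


# ---------------------------------------------------------------------------
# writers


def write_dataset(
    out_dir: str | Path,
    geno: GenotypeSet,
    kin: KinshipMatrix,
    pheno: PhenotypeMatrix,
    truth: GroundTruth | None = None,
    config: SimConfig | None = None,
) -> Path:
    """Write genotypes (VCF + TSV), kinship, phenotypes, truth and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    write_vcf(out / "genotypes.vcf", geno)
    geno_tsv = pd.DataFrame(
        geno.dosages, index=geno.sample_ids, columns=geno.snp_ids
    )
    geno_tsv.to_csv(out / "genotypes.tsv", sep="\t")
    geno.snp_map.to_csv(out / "snp_map.tsv", sep="\t")
    pd.DataFrame(kin.K, index=kin.sample_ids, columns=kin.sample_ids).to_csv(
        out / "kinship.tsv", sep="\t"
    )
    pd.DataFrame(
        pheno.values, index=pheno.feature_ids, columns=pheno.sample_ids
    ).to_csv(out / "methylation.tsv", sep="\t")
    pheno.feature_map.to_csv(out / "feature_map.tsv", sep="\t")

    if truth is not None:
        rows = []
        for fid, lst in truth.causal_map.items():
            for snp, eff in lst:
                rows.append((fid, snp, eff))
        pd.DataFrame(rows, columns=["feature", "snp", "effect"]).to_csv(
            out / "truth_causal.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {
                "cis_pve": pd.Series(truth.true_cis_pve),
                "trans_pve": pd.Series(truth.true_trans_pve),
            }
        ).rename_axis("feature").to_csv(out / "truth_pve.tsv", sep="\t")

    manifest = {
        "files": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
        "n_samples": geno.n_samples,
        "n_snps": geno.n_snps,
        "n_features": pheno.n_features,
        "config": asdict(config) if config is not None else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def write_vcf(path: str | Path, geno: GenotypeSet) -> None:
    """Minimal VCF 4.2 with GT:DS fields (GT hard-called from the dosage)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids)
            + "\n"
        )
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, (snp, row) in enumerate(geno.snp_map.iterrows()):
            ds = geno.dosages[:, j]
            cells = "\t".join(
                f"{gt_codes[int(round(d))]}:{d:g}" for d in ds
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{snp}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT:DS\t{cells}\n"
            )
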