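"""Reproducible simulation studies exercising each pipeline stage.

Each function simulates data under known conditions, runs the corresponding
method, and returns the summary statistics of interest. Problem sizes are
desk-scale defaults chosen so that each study finishes in minutes on one
core while keeping Monte-Carlo error well inside the margins being checked;
the same drivers back the validation test suite and the reproduction
script.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .assoc import conditional_stepwise, fit_lmm_wald, permutation_fdr, cis_scan
from .colocal import ColocPriors, coloc_pair
from .containers import PhenotypeMatrix
from .herit import cis_trans_grms, partition_pve
from .mediate import fit_mediation
from .multicoloc import moloc_triplet
from .prep import beta_to_m, rank_inverse_normal
from .synth import (
    SimConfig,
    _marginal_summary_stats,
    simulate_genotypes,
    simulate_methylation,
    simulate_triplet,
)

__all__ = [
    "normalize_for_mapping",
    "study_lmm_vs_ols",
    "study_null_calibration",
    "study_fdr_control",
    "study_conditional_recovery",
    "study_pve_recovery",
    "study_coloc_discrimination",
    "study_mediation",
    "study_pi1_mixture",
]

#: feature-level significance threshold reused across conditional studies
#: (the empirical 5% FDR threshold scale typical of permutation calling)
DEFAULT_THRESHOLD = 2.267195e-4


def normalize_for_mapping(pheno: PhenotypeMatrix) -> PhenotypeMatrix:
    """Beta -> M -> per-feature rank-inverse-normal, ready for the scan."""
    M = beta_to_m(pheno.values) if pheno.scale == "beta" else pheno.values
    return PhenotypeMatrix(
        np.apply_along_axis(rank_inverse_normal, 1, M),
        pheno.feature_map, list(pheno.sample_ids), "residual-normalized",
    )


def study_lmm_vs_ols(n_instances: int = 1000, n: int = 60, seed: int = 0) -> dict:
    """Max relative discrepancy between the K=I LMM Wald fit and OLS.

    The oracle is a from-scratch OLS: beta = Sxy/Sxx, SE^2 = RSS/((n-2) Sxx),
    p from the normal reference on beta/SE.
    """
    rng = np.random.default_rng(seed)
    I = np.eye(n)
    worst = 0.0
    for _ in range(n_instances):
        x = rng.normal(size=n)
        y = 0.3 * x * rng.integers(0, 2) + rng.normal(size=n)
        fit = fit_lmm_wald(y, x, I)
        xc = x - x.mean()
        yc = y - y.mean()
        beta = float(xc @ yc / (xc @ xc))
        rss = float(yc @ yc - beta**2 * (xc @ xc))
        se = np.sqrt(rss / (n - 2) / (xc @ xc))
        p = 2 * sps.norm.sf(abs(beta / se))
        worst = max(
            worst,
            abs(fit.beta - beta) / max(abs(beta), 1e-12),
            abs(fit.se - se) / se,
            abs(fit.p - p) / max(p, 1e-12),
        )
    return {"max_rel_err": worst, "n": n_instances}


def study_null_calibration(
    n_samples: int = 500,
    n_cpgs: int = 2000,
    n_snps_per_window: int = 5,
    n_perm: int = 10,
    seed: int = 0,
) -> dict:
    """Global-null scan with sibship kinship: p-value uniformity and the
    number of features called at 5% permutation FDR."""
    cfg = SimConfig(
        n_samples=n_samples, n_cpgs=n_cpgs,
        n_snps_per_window=n_snps_per_window, ld_decay=0.0,
        prop_mecpg=0.0, cis_pve_target=0.0, trans_pve_target=0.2, seed=seed,
    )
    geno, kin = simulate_genotypes(cfg)
    pheno, _ = simulate_methylation(geno, kin, cfg)
    ph = normalize_for_mapping(pheno)
    res = permutation_fdr(
        ph, geno, kin, n_perm=n_perm, target_fdr=0.05, seed=seed + 1
    )
    p = res.scan.records["p"].to_numpy()
    ks = sps.kstest(p, "uniform").statistic
    return {
        "ks_distance": float(ks),
        "n_tests": int(p.size),
        "n_mecpgs": len(res.mecpgs),
        "n_features": int(res.observed_min_p.shape[0]),
        "t_star": res.t_star,
    }


def study_fdr_control(
    n_reps: int = 50,
    n_samples: int = 200,
    n_cpgs: int = 100,
    prop_mecpg: float = 0.2,
    seed: int = 0,
) -> dict:
    """Realized FDR of the 5% permutation-FDR call set with planted signals."""
    n_called = n_false = 0
    for rep in range(n_reps):
        cfg = SimConfig(
            n_samples=n_samples, n_cpgs=n_cpgs, n_snps_per_window=5,
            prop_mecpg=prop_mecpg, cis_pve_target=0.3, trans_pve_target=0.1,
            seed=seed + 1000 + rep,
        )
        geno, kin = simulate_genotypes(cfg)
        pheno, truth = simulate_methylation(geno, kin, cfg)
        ph = normalize_for_mapping(pheno)
        res = permutation_fdr(
            ph, geno, kin, n_perm=10, target_fdr=0.05, seed=seed + rep
        )
        true_me = {f for f, v in truth.causal_map.items() if v}
        called = set(res.mecpgs)
        n_called += len(called)
        n_false += len(called - true_me)
    realized = n_false / max(n_called, 1)
    return {
        "realized_fdr": realized, "n_called": n_called,
        "n_false": n_false, "n_reps": n_reps,
    }


def study_conditional_recovery(
    n_reps: int = 100,
    n_samples: int = 500,
    n_snps: int = 40,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
) -> dict:
    """Fraction of replicates where two planted independent cis signals are
    recovered as exactly two conditional QTLs (planted pairs with r^2 >=
    0.05 are redrawn, mirroring the independent-signal design)."""
    n_exact = n_used = 0
    rep = 0
    while n_used < n_reps and rep < 4 * n_reps:
        cfg = SimConfig(
            n_samples=n_samples, n_cpgs=1, n_snps_per_window=n_snps,
            ld_decay=0.0, prop_mecpg=1.0, n_causal_per_mecpg=2,
            cis_pve_target=0.3, trans_pve_target=0.1,
            standardized_effects=True, equal_causal_effects=True,
            seed=seed + 5000 + rep,
        )
        rep += 1
        geno, kin = simulate_genotypes(cfg)
        pheno, truth = simulate_methylation(geno, kin, cfg)
        causal = truth.causal_map[pheno.feature_ids[0]]
        if len(causal) != 2:
            continue
        idx = [list(geno.snp_ids).index(s) for s, _ in causal]
        g1, g2 = geno.dosages[:, idx[0]], geno.dosages[:, idx[1]]
        if np.corrcoef(g1, g2)[0, 1] ** 2 >= 0.05:
            continue
        ph = normalize_for_mapping(pheno)
        cset = conditional_stepwise(
            pheno.feature_ids[0], ph.values[0], geno, kin, threshold
        )
        n_used += 1
        n_exact += len(cset.snps) == 2
    return {
        "frac_exactly_two": n_exact / max(n_used, 1),
        "n_reps": n_used,
    }


def study_pve_recovery(
    n_features: int = 200,
    n_samples: int = 500,
    cis_pve: float = 0.3,
    trans_pve: float = 0.2,
    seed: int = 0,
) -> dict:
    """Mean estimated cis/trans PVE against planted (cis_pve, trans_pve).

    Generation follows the estimator's own assumptions: polygenic cis
    effects on every window SNP (standardized scale) and a trans component
    drawn from the pedigree kinship, which is also supplied as K_trans.
    """
    n_per_batch = 25
    ests = []
    batches = -(-n_features // n_per_batch)
    for b in range(batches):
        cfg = SimConfig(
            n_samples=n_samples, n_cpgs=n_per_batch, n_snps_per_window=15,
            prop_mecpg=1.0, n_causal_per_mecpg=15, cis_pve_target=cis_pve,
            trans_pve_target=trans_pve, standardized_effects=True,
            seed=seed + 7000 + b,
        )
        geno, kin = simulate_genotypes(cfg)
        pheno, _ = simulate_methylation(geno, kin, cfg)
        M = beta_to_m(pheno.values)
        for i, fid in enumerate(pheno.feature_ids):
            if len(ests) >= n_features:
                break
            row = pheno.feature_map.loc[fid]
            Kc, _ = cis_trans_grms(geno, row["chrom"], row["pos"])
            est = partition_pve(M[i], Kc, kin.K, feature=fid)
            ests.append((est.pve_cis, est.pve_trans))
    arr = np.array(ests)
    return {
        "mean_cis_pve": float(arr[:, 0].mean()),
        "mean_trans_pve": float(arr[:, 1].mean()),
        "true_cis_pve": cis_pve,
        "true_trans_pve": trans_pve,
        "n_features": len(ests),
    }


def study_coloc_discrimination(
    n_reps: int = 50, n_samples: int = 1000, seed: int = 0
) -> dict:
    """Colocalization accuracy on shared / distinct / null loci."""
    cfg = SimConfig(
        n_samples=n_samples, sibship_size=1, n_cpgs=1, n_snps_per_window=50,
        ld_decay=0.5, cis_pve_target=0.05, gwas_pve=0.003, seed=seed,
    )
    geno, _ = simulate_genotypes(cfg)
    priors = ColocPriors(p1=1e-4, p2=1e-3, p12=1e-5)
    rng = np.random.default_rng(seed + 1)
    shared_hit = distinct_hit = null_hit = moloc_hit = 0
    for rep in range(n_reps):
        for scen in ("shared", "distinct", "null"):
            meth, expr, gwas, _ = simulate_triplet(geno, scen, cfg, rng=rng)
            b1, s1, _ = _marginal_summary_stats(geno.dosages, meth.values[0])
            b2, s2, _ = _marginal_summary_stats(geno.dosages, expr.values[0])
            res = coloc_pair(b1, s1, b2, s2, priors)
            if scen == "shared":
                shared_hit += res.pp4 > 0.8
                mres = moloc_triplet(
                    np.vstack([gwas["beta"], b2, b1]),
                    np.vstack([gwas["se"], s2, s1]),
                )
                moloc_hit += mres.ppa_all_shared() > 0.8
            elif scen == "distinct":
                distinct_hit += int(np.argmax(res.pp)) == 3
            else:
                null_hit += int(np.argmax(res.pp)) == 0
    return {
        "shared_pp4_rate": shared_hit / n_reps,
        "distinct_top_pp3_rate": distinct_hit / n_reps,
        "null_top_pp0_rate": null_hit / n_reps,
        "moloc_all_shared_rate": moloc_hit / n_reps,
        "n_reps": n_reps,
    }


def study_mediation(
    n_reps: int = 100, n_samples: int = 800, rho: float = 0.5, seed: int = 0
) -> dict:
    """Recovery of a planted mediation proportion and the null error rate.

    Alternative replicates plant a SNP -> methylation -> expression chain
    with mediation proportion ``rho``; null replicates let the SNP affect
    methylation and expression through independent paths (no mediated
    component), where the Sobel test should stay quiet.
    """
    from statsmodels.stats.multitest import multipletests

    cfg = SimConfig(
        n_samples=n_samples, sibship_size=1, n_cpgs=1, n_snps_per_window=30,
        cis_pve_target=0.1, seed=seed,
    )
    geno, _ = simulate_genotypes(cfg)
    snp_pos = {s: i for i, s in enumerate(geno.snp_ids)}
    rng = np.random.default_rng(seed + 1)
    rhos, alt_p, null_p = [], [], []
    for rep in range(n_reps):
        meth, expr, _, truth = simulate_triplet(
            geno, "shared", cfg, rng=rng, mediation_rho=rho
        )
        j = snp_pos[truth.causal_map["cpg1"][0][0]]
        fit = fit_mediation(geno.dosages[:, j], meth.values[0], expr.values[0])
        rhos.append(fit.rho)
        alt_p.append(fit.p)
        # null: same causal SNP, independent paths
        meth0, expr0, _, truth0 = simulate_triplet(geno, "shared", cfg, rng=rng)
        j0 = snp_pos[truth0.causal_map["cpg1"][0][0]]
        fit0 = fit_mediation(
            geno.dosages[:, j0], meth0.values[0], expr0.values[0]
        )
        null_p.append(fit0.p)
    alt_sig, _, _, _ = multipletests(alt_p, alpha=0.05, method="fdr_bh")
    null_sig, _, _, _ = multipletests(null_p, alpha=0.05, method="fdr_bh")
    return {
        "mean_rho_hat": float(np.mean(rhos)),
        "mean_abs_rho_err": float(np.mean(np.abs(np.array(rhos) - rho))),
        "true_rho": rho,
        "alt_sig_rate": float(np.mean(alt_sig)),
        "null_sig_rate": float(np.mean(null_sig)),
        "n_reps": n_reps,
    }


def study_pi1_mixture(
    n: int = 10_000, pi1_true: float = 0.30, n_reps: int = 5, seed: int = 0
) -> dict:
    """pi1 accuracy on Beta(0.1, 1) / Uniform p-value mixtures.

    The estimate for a single mixture carries Monte-Carlo noise of ~0.02
    (the high-lambda tail counts are small), so accuracy is summarized as
    the mean estimate over ``n_reps`` independent mixtures. Note the
    Beta(0.1, 1) alternative keeps ~7% of its mass above p = 0.5, which any
    tail-based pi0 estimator absorbs into the null; the expected estimate is
    therefore slightly below the mixing weight.
    """
    from .downstream import storey_pi1

    rng = np.random.default_rng(seed)
    n_alt = int(round(pi1_true * n))
    ests = []
    for _ in range(n_reps):
        p = np.concatenate(
            [rng.beta(0.1, 1.0, n_alt), rng.uniform(0, 1, n - n_alt)]
        )
        ests.append(storey_pi1(p).pi1)
    return {
        "pi1_hat": float(np.mean(ests)),
        "pi1_sd": float(np.std(ests)),
        "pi1_true": pi1_true,
        "n": n,
        "n_reps": n_reps,
    }
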