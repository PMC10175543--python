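import numpy as np
import pytest

from meqtlkit.prep import beta_to_m
from meqtlkit.synth import (
    BetaMixture,
    SimConfig,
    simulate_genotypes,
    simulate_methylation,
    simulate_triplet,
)


class TestConfigValidation:
    def test_bad_maf_range(self):
        with pytest.raises(ValueError):
            SimConfig(maf_range=(0.0, 0.5)).validate()
        with pytest.raises(ValueError):
            SimConfig(maf_range=(0.1, 0.6)).validate()

    def test_bad_counts(self):
        with pytest.raises(ValueError):
            SimConfig(n_samples=0).validate()

    def test_pve_budget(self):
        with pytest.raises(ValueError):
            SimConfig(cis_pve_target=0.6, trans_pve_target=0.5).validate()


class TestSimulateGenotypes:
    def test_determinism(self):
        cfg = SimConfig(n_samples=60, n_cpgs=5, seed=9)
        g1, k1 = simulate_genotypes(cfg)
        g2, k2 = simulate_genotypes(cfg)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        np.testing.assert_array_equal(k1.K, k2.K)

    def test_unrelated_independent_case(self):
        cfg = SimConfig(
            n_samples=400, sibship_size=1, n_cpgs=4, n_snps_per_window=25,
            ld_decay=0.0, seed=10,
        )
        geno, kin = simulate_genotypes(cfg)
        # pedigree kinship: no off-diagonal relatedness
        off = kin.K - np.diag(np.diag(kin.K))
        assert np.abs(off).max() == 0
        # adjacent-SNP correlations centered on zero
        G = geno.dosages
        cors = [
            np.corrcoef(G[:, j], G[:, j + 1])[0, 1]
            for w in range(4)
            for j in range(w * 25, w * 25 + 24)
        ]
        assert abs(np.mean(cors)) < 0.02

    def test_ld_decay_produces_adjacent_correlation(self):
        cfg = SimConfig(
            n_samples=500, sibship_size=1, n_cpgs=4, n_snps_per_window=25,
            ld_decay=0.7, maf_range=(0.3, 0.5), seed=11,
        )
        geno, _ = simulate_genotypes(cfg)
        G = geno.dosages
        cors = [
            np.corrcoef(G[:, j], G[:, j + 1])[0, 1]
            for w in range(4)
            for j in range(w * 25, w * 25 + 24)
        ]
        assert np.mean(cors) == pytest.approx(0.7, abs=0.12)

    def test_sibling_grm_sharing(self):
        # Monte-Carlo identity-by-descent: realized GRM off-diagonal within
        # sib pairs averages ~0.5
        from meqtlkit.relate import centered_grm

        cfg = SimConfig(
            n_samples=200, sibship_size=2, n_cpgs=10, n_snps_per_window=100,
            ld_decay=0.0, seed=12,
        )
        geno, kin = simulate_genotypes(cfg)
        grm = centered_grm(geno, maf_min=0.01)
        sib_vals = [
            grm.K[i, i + 1] for i in range(0, 200, 2)
        ]
        assert np.mean(sib_vals) == pytest.approx(0.5, abs=0.1)
        # pedigree expectation encodes exactly 0.5
        assert kin.K[0, 1] == 0.5

    def test_dosages_in_range(self, small_dataset):
        _, geno, _, _, _ = small_dataset
        assert geno.dosages.min() >= 0 and geno.dosages.max() <= 2


class TestSimulateMethylation:
    def test_beta_values_in_unit_interval(self, small_dataset):
        _, _, _, pheno, _ = small_dataset
        assert pheno.values.min() > 0 and pheno.values.max() < 1

    def test_determinism(self):
        cfg = SimConfig(n_samples=50, n_cpgs=8, seed=13)
        geno, kin = simulate_genotypes(cfg)
        p1, _ = simulate_methylation(geno, kin, cfg)
        p2, _ = simulate_methylation(geno, kin, cfg)
        np.testing.assert_array_equal(p1.values, p2.values)

    def test_planted_cis_r2(self):
        # single causal SNP explaining 30% of M variance: in-sample R^2 ~ 0.3
        cfg = SimConfig(
            n_samples=300, n_cpgs=10, prop_mecpg=1.0, n_causal_per_mecpg=1,
            cis_pve_target=0.3, trans_pve_target=0.0, seed=14,
        )
        geno, kin = simulate_genotypes(cfg)
        pheno, truth = simulate_methylation(geno, kin, cfg)
        M = beta_to_m(pheno.values)
        snp_idx = {s: j for j, s in enumerate(geno.snp_ids)}
        r2s = []
        for i, fid in enumerate(pheno.feature_ids):
            (snp, _), = truth.causal_map[fid]
            g = geno.dosages[:, snp_idx[snp]]
            r2s.append(np.corrcoef(g, M[i])[0, 1] ** 2)
        assert np.mean(r2s) == pytest.approx(0.3, abs=0.05)

    def test_variance_bookkeeping(self):
        cfg = SimConfig(n_samples=100, n_cpgs=10, prop_mecpg=0.5, seed=15)
        geno, kin = simulate_genotypes(cfg)
        _, truth = simulate_methylation(geno, kin, cfg)
        for fid in truth.true_cis_pve:
            total = truth.true_cis_pve[fid] + truth.true_trans_pve[fid]
            assert 0 <= total < 1

    def test_degenerate_hypo_mixture(self):
        cfg = SimConfig(
            n_samples=80, n_cpgs=30, prop_mecpg=0.0, trans_pve_target=0.0,
            m_total_var=0.05,
            beta_mixture=BetaMixture(weight_hypo=1.0), seed=16,
        )
        geno, kin = simulate_genotypes(cfg)
        pheno, _ = simulate_methylation(geno, kin, cfg)
        means = pheno.values.mean(axis=1)
        # pure hypomethylated mixture: the hyper mode (>0.7) never appears
        # and nearly every site sits below 0.3 (Beta(2,18) has a thin tail)
        assert (means < 0.5).all()
        assert np.mean(means < 0.3) >= 0.9

    def test_bimodal_defaults(self):
        # default mixture: roughly a third of sites hypomethylated (<0.3),
        # roughly two thirds hypermethylated (>0.7)
        cfg = SimConfig(n_samples=50, n_cpgs=400, prop_mecpg=0.0,
                        trans_pve_target=0.0, m_total_var=0.05, seed=17)
        geno, kin = simulate_genotypes(cfg)
        pheno, _ = simulate_methylation(geno, kin, cfg)
        means = pheno.values.mean(axis=1)
        assert np.mean(means < 0.3) == pytest.approx(0.30, abs=0.10)
        assert np.mean(means > 0.7) == pytest.approx(0.62, abs=0.10)

    def test_mismatched_samples_rejected(self, small_dataset):
        cfg, geno, kin, _, _ = small_dataset
        bad_kin = type(kin)(kin.K, [f"x{i}" for i in range(kin.n_samples)])
        with pytest.raises(ValueError):
            simulate_methylation(geno, bad_kin, cfg)


class TestSimulateTriplet:
    def test_unknown_scenario(self, small_dataset):
        cfg, geno, _, _, _ = small_dataset
        with pytest.raises(ValueError):
            simulate_triplet(geno, "bogus", cfg)

    def test_shared_flag_recorded(self, small_dataset):
        cfg, geno, _, _, _ = small_dataset
        _, _, _, truth = simulate_triplet(geno, "shared", cfg)
        assert truth.shared_variant[("gene1", "cpg1", "gwas")] is True
        _, _, _, truth0 = simulate_triplet(geno, "null", cfg)
        assert truth0.shared_variant[("gene1", "cpg1", "gwas")] is False

    def test_gwas_summary_from_external_cohort(self, small_dataset):
        cfg, geno, _, _, _ = small_dataset
        _, _, gwas, _ = simulate_triplet(geno, "shared", cfg)
        assert (gwas["n"] == cfg.gwas_n_samples).all()
        assert set(["snp", "beta", "se", "p"]).issubset(gwas.columns)
        assert (gwas["se"] > 0).all()

    def test_planted_mediation_recorded(self, small_dataset):
        cfg, geno, _, _, _ = small_dataset
        _, _, _, truth = simulate_triplet(
            geno, "shared", cfg, mediation_rho=0.4
        )
        assert truth.mediation_proportion["pair1"] == 0.4
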