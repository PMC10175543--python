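import numpy as np
import pandas as pd
import pytest

from meqtlkit.assoc import (
    KinshipEigen,
    cis_scan,
    conditional_stepwise,
    empirical_fdr_curve,
    fit_lmm_wald,
    permutation_fdr,
)
from meqtlkit.containers import PhenotypeMatrix
from meqtlkit.studies import normalize_for_mapping
from meqtlkit.synth import SimConfig, simulate_genotypes, simulate_methylation


class TestFitLmmWald:
    def test_ols_textbook_example(self):
        # with K = I the fit is ordinary least squares: Sxy/Sxx = 6.5/5
        res = fit_lmm_wald([1.0, 2, 3, 5], [0.0, 1, 2, 3], np.eye(4))
        assert res.beta == pytest.approx(1.3, abs=1e-9)

    def test_identity_kinship_matches_ols_oracle(self):
        from scipy.stats import norm

        rng = np.random.default_rng(0)
        n = 80
        I = np.eye(n)
        for _ in range(25):
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            fit = fit_lmm_wald(y, x, I)
            xc, yc = x - x.mean(), y - y.mean()
            beta = xc @ yc / (xc @ xc)
            rss = yc @ yc - beta**2 * (xc @ xc)
            se = np.sqrt(rss / (n - 2) / (xc @ xc))
            assert fit.beta == pytest.approx(beta, rel=1e-6)
            assert fit.se == pytest.approx(se, rel=1e-6)
            assert fit.p == pytest.approx(2 * norm.sf(abs(beta / se)), rel=1e-5)

    def test_perfect_fit_flagged_degenerate(self):
        x = np.arange(6, dtype=float)
        res = fit_lmm_wald(x.copy(), x, np.eye(6))
        assert res.degenerate
        assert 0 < res.p <= 1e-290

    def test_constant_snp_rejected(self):
        with pytest.raises(ValueError):
            fit_lmm_wald([1.0, 2, 3], [1.0, 1, 1], np.eye(3))

    def test_covariates_shift_estimate(self):
        rng = np.random.default_rng(1)
        n = 100
        c = rng.normal(size=n)
        x = 0.8 * c + rng.normal(size=n)
        y = 1.0 * c + rng.normal(size=n)  # y depends on c, not x given c
        naive = fit_lmm_wald(y, x, np.eye(n))
        adjusted = fit_lmm_wald(y, x, np.eye(n), covars=c)
        assert abs(adjusted.beta) < abs(naive.beta)

    def test_nonpsd_kinship_rejected(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError):
            KinshipEigen.from_kinship(
                __import__("meqtlkit").KinshipMatrix(K, ["a", "b"])
            )

    def test_sibship_variance_component_detected(self):
        # phenotype with strong family effect: lambda should be large
        rng = np.random.default_rng(2)
        cfg = SimConfig(n_samples=200, n_cpgs=1, seed=3)
        geno, kin = simulate_genotypes(cfg)
        L = np.linalg.cholesky(kin.K + 1e-8 * np.eye(200))
        y = 3.0 * (L @ rng.normal(size=200)) + rng.normal(size=200)
        x = geno.dosages[:, 0]
        res = fit_lmm_wald(y, x, kin)
        assert res.sigma_u2 / res.sigma_e2 > 1.0


class TestCisScan:
    def test_batch_agrees_with_scalar_fit(self, small_dataset):
        _, geno, kin, pheno, _ = small_dataset
        ph = normalize_for_mapping(pheno)
        scan = cis_scan(ph, geno, kin)
        snp_idx = {s: j for j, s in enumerate(geno.snp_ids)}
        fid_row = {f: i for i, f in enumerate(ph.feature_ids)}
        sub = scan.records.sample(12, random_state=0)
        for _, r in sub.iterrows():
            f = fit_lmm_wald(
                ph.values[fid_row[r["feature"]]],
                geno.dosages[:, snp_idx[r["snp"]]], kin,
            )
            assert r["beta"] == pytest.approx(f.beta, rel=5e-3, abs=1e-8)
            assert r["se"] == pytest.approx(f.se, rel=5e-3)

    def test_feature_without_cis_snp_excluded(self, small_dataset):
        _, geno, kin, pheno, _ = small_dataset
        fmap = pheno.feature_map.copy()
        fmap.loc[fmap.index[0], "pos"] = 10  # far from every SNP
        ph = normalize_for_mapping(
            PhenotypeMatrix(pheno.values, fmap, pheno.sample_ids, "beta")
        )
        scan = cis_scan(ph, geno, kin)
        assert fmap.index[0] not in scan.min_p.index
        assert scan.min_p.shape[0] == pheno.n_features - 1

    def test_zero_window_only_exact_position(self, small_dataset):
        _, geno, kin, pheno, _ = small_dataset
        # place one feature exactly on a SNP
        fmap = pheno.feature_map.copy()
        fmap["pos"] = 0
        fmap.loc[fmap.index[0], "pos"] = int(geno.snp_map["pos"].iloc[0])
        ph = normalize_for_mapping(
            PhenotypeMatrix(pheno.values, fmap, pheno.sample_ids, "beta")
        )
        scan = cis_scan(ph, geno, kin, window_bp=0)
        assert list(scan.min_p.index) == [fmap.index[0]]
        assert scan.min_p["n_cis_snps"].iloc[0] == 1

    def test_no_cis_snps_anywhere_raises(self, small_dataset):
        _, geno, kin, pheno, _ = small_dataset
        fmap = pheno.feature_map.copy()
        fmap["pos"] = 2  # nowhere near any SNP
        ph = normalize_for_mapping(
            PhenotypeMatrix(pheno.values, fmap, pheno.sample_ids, "beta")
        )
        with pytest.raises(ValueError):
            cis_scan(ph, geno, kin, window_bp=0)

    def test_planted_causal_is_argmin_or_proxy(self):
        cfg = SimConfig(
            n_samples=300, n_cpgs=15, prop_mecpg=1.0, n_causal_per_mecpg=1,
            cis_pve_target=0.3, trans_pve_target=0.1, seed=31,
        )
        geno, kin = simulate_genotypes(cfg)
        pheno, truth = simulate_methylation(geno, kin, cfg)
        scan = cis_scan(normalize_for_mapping(pheno), geno, kin)
        snp_idx = {s: j for j, s in enumerate(geno.snp_ids)}
        hits = 0
        for fid in scan.min_p.index:
            (causal, _), = truth.causal_map[fid]
            best = scan.min_p.loc[fid, "best_snp"]
            g1 = geno.dosages[:, snp_idx[causal]]
            g2 = geno.dosages[:, snp_idx[best]]
            r2 = np.corrcoef(g1, g2)[0, 1] ** 2
            hits += (best == causal) or (r2 > 0.8)
        assert hits >= 14  # >= ~95% of 15 features


class TestEmpiricalFdr:
    def test_hand_evaluated_toy(self):
        # observed minima {1e-4, 0.2, 0.9}; two null replicates each with
        # minima {0.3, 0.5, 0.7}: FDR(1e-4)=0/1, FDR(0.2)=0/2, FDR(0.9)=3/3
        obs = np.array([1e-4, 0.2, 0.9])
        perm = np.array([[0.3, 0.3], [0.5, 0.5], [0.7, 0.7]])
        curve, t_star = empirical_fdr_curve(obs, perm, target_fdr=0.05)
        fdr = dict(zip(curve["threshold"], curve["fdr"]))
        assert fdr[1e-4] == 0.0
        assert fdr[0.2] == 0.0
        assert fdr[0.9] == pytest.approx(1.0)
        assert t_star == 0.2

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        obs = rng.uniform(size=50)
        perm = rng.uniform(size=(50, 10))
        curve, _ = empirical_fdr_curve(obs, perm, 0.05)
        # ratio of two monotone counts with matched support: check the
        # documented trend on a null where obs and perm share a distribution
        assert curve["fdr"].iloc[-1] >= curve["fdr"].iloc[0]

    def test_null_scan_calls_nothing(self):
        cfg = SimConfig(
            n_samples=150, n_cpgs=60, n_snps_per_window=4, prop_mecpg=0.0,
            cis_pve_target=0.0, trans_pve_target=0.1, seed=41,
        )
        geno, kin = simulate_genotypes(cfg)
        pheno, _ = simulate_methylation(geno, kin, cfg)
        res = permutation_fdr(
            normalize_for_mapping(pheno), geno, kin, n_perm=5,
            target_fdr=0.05, seed=1,
        )
        assert len(res.mecpgs) <= 2

    def test_planted_signals_called(self):
        cfg = SimConfig(
            n_samples=200, n_cpgs=50, n_snps_per_window=5, prop_mecpg=0.2,
            cis_pve_target=0.3, trans_pve_target=0.1, seed=42,
        )
        geno, kin = simulate_genotypes(cfg)
        pheno, truth = simulate_methylation(geno, kin, cfg)
        res = permutation_fdr(
            normalize_for_mapping(pheno), geno, kin, n_perm=10,
            target_fdr=0.05, seed=2,
        )
        true_me = {f for f, v in truth.causal_map.items() if v}
        assert len(set(res.mecpgs) & true_me) >= 8  # most of the 10 planted
        # every meQTL record respects the threshold
        assert (res.meqtls["p"] <= res.t_star).all()

    def test_invalid_params(self, small_dataset):
        _, geno, kin, pheno, _ = small_dataset
        ph = normalize_for_mapping(pheno)
        with pytest.raises(ValueError):
            permutation_fdr(ph, geno, kin, n_perm=0)
        with pytest.raises(ValueError):
            permutation_fdr(ph, geno, kin, target_fdr=1.5)


class TestConditionalStepwise:
    def _planted(self, n_causal, seed, ld_decay=0.0):
        cfg = SimConfig(
            n_samples=400, n_cpgs=1, n_snps_per_window=30, ld_decay=ld_decay,
            prop_mecpg=1.0, n_causal_per_mecpg=n_causal, cis_pve_target=0.3,
            trans_pve_target=0.1, standardized_effects=True,
            equal_causal_effects=True, seed=seed,
        )
        geno, kin = simulate_genotypes(cfg)
        pheno, truth = simulate_methylation(geno, kin, cfg)
        ph = normalize_for_mapping(pheno)
        return geno, kin, ph, truth

    def test_single_signal_gives_singleton(self):
        geno, kin, ph, truth = self._planted(1, seed=51)
        cset = conditional_stepwise(
            "cg00000", ph.values[0], geno, kin, threshold=2.27e-4
        )
        assert len(cset.snps) == 1

    def test_two_independent_signals_recovered(self):
        geno, kin, ph, truth = self._planted(2, seed=52)
        cset = conditional_stepwise(
            "cg00000", ph.values[0], geno, kin, threshold=2.27e-4
        )
        assert len(cset.snps) == 2
        # final joint model: every retained SNP significant at threshold
        assert (cset.stats["p"] <= cset.threshold).all()

    def test_collinear_proxy_absorbed(self):
        # duplicate the causal SNP: only one of the pair can be selected
        geno, kin, ph, truth = self._planted(1, seed=53)
        causal = truth.causal_map["cg00000"][0][0]
        j = list(geno.snp_ids).index(causal)
        geno.dosages[:, (j + 1) % geno.n_snps] = geno.dosages[:, j]
        cset = conditional_stepwise(
            "cg00000", ph.values[0], geno, kin, threshold=2.27e-4
        )
        assert len(cset.snps) == 1

    def test_final_model_reproducible(self):
        geno, kin, ph, _ = self._planted(2, seed=54)
        c1 = conditional_stepwise("f", ph.values[0], geno, kin, 2.27e-4)
        c2 = conditional_stepwise("f", ph.values[0], geno, kin, 2.27e-4)
        assert c1.snps == c2.snps
        pd.testing.assert_frame_equal(c1.stats, c2.stats)
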