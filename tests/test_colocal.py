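import itertools

import numpy as np
import pytest

from meqtlkit.colocal import (
    ColocPriors,
    build_pairs,
    calibrate_p12,
    coloc_pair,
    prior_hypothesis_probs,
    set_priors_from_counts,
    wakefield_log_abf,
)


def brute_force_coloc(lb1, lb2, priors):
    """Oracle: enumerate every causal-variant assignment explicitly.

    H1/H2: one causal SNP for one trait; H3: an ordered pair of distinct
    SNPs; H4: one shared SNP. Weights accumulate per-assignment priors.
    """
    bf1 = np.exp(lb1)
    bf2 = np.exp(lb2)
    m = len(bf1)
    w = np.zeros(5)
    w[0] = 1.0
    for i in range(m):
        w[1] += priors.p1 * bf1[i]
        w[2] += priors.p2 * bf2[i]
        w[4] += priors.p12 * bf1[i] * bf2[i]
    for i, j in itertools.product(range(m), range(m)):
        if i != j:
            w[3] += priors.p1 * priors.p2 * bf1[i] * bf2[j]
    return w / w.sum()


class TestWakefieldAbf:
    def test_null_z_favors_h0(self):
        lab = wakefield_log_abf(0.0, 0.1, W=0.0225)
        r = 0.0225 / 0.0325
        assert lab == pytest.approx(0.5 * np.log(1 - r))
        assert np.exp(lab) < 1

    def test_vanishing_prior_gives_unit_bf(self):
        assert wakefield_log_abf(0.5, 0.1, W=0.0) == pytest.approx(0.0)

    def test_direct_formula_evaluation(self):
        # z = 5, r = 0.0225/0.0325: 0.5*ln(1-r) + z^2 r/2 = 8.0645
        lab = wakefield_log_abf(0.5, 0.1, W=0.0225)
        z, r = 5.0, 0.0225 / 0.0325
        expected = 0.5 * np.log(1 - r) + 0.5 * z**2 * r
        assert lab == pytest.approx(expected, abs=1e-12)
        assert lab == pytest.approx(8.0645, abs=1e-3)

    def test_no_overflow_for_huge_z(self):
        lab = wakefield_log_abf(10.0, 0.1, W=0.0225)  # z = 100
        assert np.isfinite(lab)

    def test_invalid_se(self):
        with pytest.raises(ValueError):
            wakefield_log_abf(0.1, 0.0)


class TestColocPair:
    priors = ColocPriors(p1=1e-4, p2=1e-4, p12=1e-5)

    def test_single_snp_pp3_exactly_zero(self):
        res = coloc_pair([0.5], [0.1], [0.4], [0.1], self.priors)
        assert res.pp[3] == 0.0
        assert res.pp.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_snp_unit_bfs_hand_normalization(self):
        # both ABFs forced to 1 via W=0: weights (1, p1, p2, 0, p12)
        pri = ColocPriors(p1=0.2, p2=0.1, p12=0.05, W=0.0)
        res = coloc_pair([0.3], [0.1], [0.2], [0.1], pri)
        expected = np.array([1, 0.2, 0.1, 0.0, 0.05])
        np.testing.assert_allclose(res.pp, expected / expected.sum(),
                                   atol=1e-12)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for m in (2, 3, 5):
            for _ in range(5):
                b1, b2 = rng.normal(0, 0.3, (2, m))
                s1, s2 = rng.uniform(0.05, 0.2, (2, m))
                res = coloc_pair(b1, s1, b2, s2, self.priors)
                lb1 = wakefield_log_abf(b1, s1, self.priors.W)
                lb2 = wakefield_log_abf(b2, s2, self.priors.W)
                oracle = brute_force_coloc(lb1, lb2, self.priors)
                np.testing.assert_allclose(res.pp, oracle, atol=1e-10)

    def test_pp4_monotone_in_p12(self):
        rng = np.random.default_rng(1)
        b1, b2 = rng.normal(0, 0.3, (2, 20))
        s1, s2 = rng.uniform(0.05, 0.2, (2, 20))
        pp4s = [
            coloc_pair(b1, s1, b2, s2,
                       ColocPriors(p1=1e-4, p2=1e-4, p12=p12)).pp4
            for p12 in (1e-6, 1e-5, 1e-4)
        ]
        assert pp4s[0] <= pp4s[1] <= pp4s[2]

    def test_empty_snp_set(self):
        with pytest.raises(ValueError):
            coloc_pair([], [], [], [], self.priors)


class TestPriorsFromCounts:
    def test_eqtl_discovery_rate(self):
        pri = set_priors_from_counts(5406, 6432684, 254113, 8993056, 0.75)
        assert pri.p1 + pri.p12 == pytest.approx(0.00084, abs=5e-6)

    def test_shared_fraction_75pct(self):
        pri = set_priors_from_counts(5406, 6432684, 254113, 8993056, 0.75)
        assert pri.p12 == pytest.approx(6.3e-4, rel=0.01)

    def test_meqtl_discovery_rate(self):
        pri = set_priors_from_counts(5406, 6432684, 254113, 8993056, 0.75)
        assert pri.p2 + pri.p12 == pytest.approx(0.028, abs=5e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            set_priors_from_counts(0, 10, 1, 10, 0.5)
        with pytest.raises(ValueError):
            set_priors_from_counts(5, 10, 1, 10, 0.99)  # p1 would go <= 0


class TestCalibrateP12:
    def _shared_pairs(self, n_pairs, rng, frac_shared=0.75):
        pairs = []
        for k in range(n_pairs):
            m = 30
            g_eff = rng.normal(0, 0.5)
            shared = rng.random() < frac_shared
            b1 = np.zeros(m)
            b2 = np.zeros(m)
            i = rng.integers(m)
            b1[i] = g_eff
            b2[i if shared else (i + 1) % m] = rng.normal(0, 0.5)
            s = np.full(m, 0.05)
            b1 = b1 + rng.normal(0, 0.05, m)
            b2 = b2 + rng.normal(0, 0.05, m)
            pairs.append((b1, s, b2, s))
        return pairs

    def test_single_candidate_passthrough(self):
        rng = np.random.default_rng(2)
        pairs = self._shared_pairs(5, rng)
        chosen, diag = calibrate_p12(pairs, [6.3e-4], s1=8.4e-4, s2=0.03)
        assert chosen == 6.3e-4
        assert len(diag) == 1

    def test_null_pairs_choose_smallest_and_warn(self):
        rng = np.random.default_rng(3)
        m = 30
        pairs = [
            (rng.normal(0, 0.05, m), np.full(m, 0.05),
             rng.normal(0, 0.05, m), np.full(m, 0.05))
            for _ in range(10)
        ]
        cands = [4.2e-5, 2.1e-4, 6.3e-4]
        chosen, diag = calibrate_p12(pairs, cands, s1=8.4e-4, s2=0.03)
        assert chosen == min(cands)
        assert "warning" in diag.attrs

    def test_calibration_tracks_planted_sharing(self):
        rng = np.random.default_rng(4)
        pairs = self._shared_pairs(60, rng, frac_shared=0.75)
        s1 = 8.4e-4
        cands = [f * s1 for f in (0.05, 0.10, 0.25, 0.50, 0.75, 0.90)]
        chosen, diag = calibrate_p12(pairs, cands, s1=s1, s2=0.03)
        assert chosen >= 0.5 * s1  # picks a high-sharing candidate


class TestBuildPairs:
    def _setup(self):
        import pandas as pd

        from meqtlkit.synth import SimConfig, simulate_genotypes

        cfg = SimConfig(n_samples=100, n_cpgs=1, n_snps_per_window=6,
                        ld_decay=0.9, seed=5)
        geno, _ = simulate_genotypes(cfg)
        fmap = pd.DataFrame(
            {"chrom": "1", "pos": [110000, 110500, 111000]},
            index=pd.Index(["cgA", "cgB", "cgC"], name="feature"),
        )
        return geno, fmap

    def test_max_r2_rule(self):
        import pandas as pd

        geno, fmap = self._setup()
        snps = list(geno.snp_ids)
        esnp = snps[0]
        records = pd.DataFrame(
            {
                "feature": ["cgA", "cgB"],
                "snp": [esnp, esnp],
                "p": [1e-8, 1e-8],
            }
        )
        # cgA's primary is the eQTL SNP itself (r2=1); cgB's is a far SNP
        primary = {"cgA": esnp, "cgB": snps[5]}
        eqtls = pd.DataFrame({"gene": ["g1"], "snp": [esnp]})
        pairs = build_pairs(eqtls, records, primary, fmap, geno, 1e-4)
        assert len(pairs) == 1
        assert pairs.iloc[0]["cpg"] == "cgA"

    def test_no_associated_mecpg_no_pair(self):
        import pandas as pd

        geno, fmap = self._setup()
        records = pd.DataFrame({"feature": [], "snp": [], "p": []})
        eqtls = pd.DataFrame({"gene": ["g1"], "snp": [list(geno.snp_ids)[0]]})
        pairs = build_pairs(eqtls, records, {}, fmap, geno, 1e-4)
        assert pairs.empty

    def test_prior_hypothesis_probs_sum_to_one(self):
        pri = ColocPriors(p1=1e-4, p2=1e-3, p12=1e-5)
        pr = prior_hypothesis_probs(100, pri)
        assert pr.sum() == pytest.approx(1.0)
        assert pr[0] > 0.8  # null dominates a priori
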