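import numpy as np
import pandas as pd
import pytest

from meqtlkit.containers import PhenotypeMatrix
from meqtlkit.synth import SimConfig, simulate_genotypes, simulate_methylation


@pytest.fixture(scope="session")
def small_dataset():
    """A small sibship dataset with planted cis signals, shared read-only."""
    cfg = SimConfig(
        n_samples=120, sibship_size=2, n_cpgs=20, n_snps_per_window=8,
        prop_mecpg=0.3, cis_pve_target=0.3, trans_pve_target=0.15, seed=101,
    )
    geno, kin = simulate_genotypes(cfg)
    pheno, truth = simulate_methylation(geno, kin, cfg)
    return cfg, geno, kin, pheno, truth


@pytest.fixture
def toy_pheno():
    """Tiny hand-buildable phenotype matrix on the beta scale."""
    rng = np.random.default_rng(0)
    values = rng.uniform(0.05, 0.95, size=(10, 6))
    chroms = ["1", "1", "1", "X", "X", "Y", "2", "2", "2", "2"]
    fmap = pd.DataFrame(
        {"chrom": chroms, "pos": np.arange(1, 11) * 1000},
        index=pd.Index([f"cg{i}" for i in range(10)], name="feature"),
    )
    return PhenotypeMatrix(values, fmap, [f"s{i}" for i in range(6)], "beta")
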