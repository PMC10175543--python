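"""Genetic relatedness: the standardized GRM and genotype principal
components used as the LMM random-effect covariance and as fixed covariates.
"""

from __future__ import annotations

import numpy as np

from .containers import GenotypeSet, KinshipMatrix

__all__ = ["centered_grm", "genotype_pcs"]


def centered_grm(geno: GenotypeSet, maf_min: float = 0.01) -> KinshipMatrix:
    """Standardized genetic relatedness matrix.

    K = (1/p) * sum_j z_j z_j^T with z_j = (g_j - 2 f_j) / sqrt(2 f_j (1-f_j))
    over the p SNPs passing the in-sample MAF filter. Monomorphic SNPs carry
    no information and are skipped. For outbred unrelated samples the
    diagonal averages ~1.
    """
    f = geno.allele_freqs()
    maf = np.minimum(f, 1.0 - f)
    keep = maf >= maf_min
    # zero-variance guard: monomorphic SNPs contribute nothing
    keep &= (f > 0) & (f < 1)
    if keep.sum() < 1:
        raise ValueError("no SNPs pass the MAF filter; cannot build GRM")
    G = geno.dosages[:, keep]
    fk = f[keep]
    Z = (G - 2.0 * fk) / np.sqrt(2.0 * fk * (1.0 - fk))
    K = Z @ Z.T / Z.shape[1]
    K = (K + K.T) / 2.0  # enforce exact symmetry
    return KinshipMatrix(K, list(geno.sample_ids), method="centered-GRM")


def genotype_pcs(kin: KinshipMatrix, k: int) -> np.ndarray:
    """Top-k genotype principal components from the GRM spectrum.

    Returns the eigenvectors of K scaled by sqrt(eigenvalue) (columns are
    mutually orthogonal; negative eigenvalues from numerical noise are
    clamped at 0 before the square root).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = kin.n_samples
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    w, V = np.linalg.eigh(kin.K)
    order = np.argsort(w)[::-1][:k]
    w = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(w)
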