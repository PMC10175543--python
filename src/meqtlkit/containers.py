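"""Core in-memory containers shared across the pipeline.

Conventions: genomic positions are 1-based; genotype dosages live in [0, 2]
counting copies of the alternate allele; phenotype matrices are feature (row)
by sample (column).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["GenotypeSet", "PhenotypeMatrix", "KinshipMatrix", "CovariateTable"]


@dataclass
class GenotypeSet:
    """Sample-by-SNP dosage matrix with a SNP map.

    Attributes
    ----------
    dosages : (n_samples, n_snps) float array, values in [0, 2].
    snp_map : DataFrame indexed by SNP id with columns
        ``chrom``, ``pos`` (1-based), ``ref``, ``alt``.
    sample_ids : ordered sample identifiers.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_map)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_map)} SNPs"
            )
        if self.dosages.size and (
            self.dosages.min() < -1e-9 or self.dosages.max() > 2 + 1e-9
        ):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return self.snp_map.shape[0]

    @property
    def snp_ids(self) -> pd.Index:
        return self.snp_map.index

    def allele_freqs(self) -> np.ndarray:
        """In-sample alternate-allele frequencies."""
        return self.dosages.mean(axis=0) / 2.0

    def mafs(self) -> np.ndarray:
        f = self.allele_freqs()
        return np.minimum(f, 1.0 - f)

    def subset_snps(self, ids) -> "GenotypeSet":
        idx = self.snp_map.index.get_indexer(ids)
        if (idx < 0).any():
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise KeyError(f"unknown SNP ids: {missing[:5]}")
        return GenotypeSet(
            self.dosages[:, idx], self.snp_map.iloc[idx], list(self.sample_ids)
        )


@dataclass
class PhenotypeMatrix:
    """Feature-by-sample value matrix (methylation or expression).

    ``scale`` tags the value space: ``beta`` (proportions in (0,1)), ``M``
    (log2 beta/(1-beta)), or ``residual-normalized`` (covariate residuals
    after rank-based inverse-normal transform).
    """

    values: np.ndarray
    feature_map: pd.DataFrame  # indexed by feature id: chrom, pos (1-based)
    sample_ids: list[str]
    scale: str = "beta"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_map), len(self.sample_ids)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.feature_map)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if self.scale == "beta" and self.values.size:
            if self.values.min() <= 0 or self.values.max() >= 1:
                raise ValueError("beta-scale values must lie strictly in (0,1)")

    @property
    def n_features(self) -> int:
        return self.feature_map.shape[0]

    @property
    def feature_ids(self) -> pd.Index:
        return self.feature_map.index

    def subset_features(self, ids) -> "PhenotypeMatrix":
        idx = self.feature_map.index.get_indexer(ids)
        if (idx < 0).any():
            raise KeyError("unknown feature ids in subset")
        return PhenotypeMatrix(
            self.values[idx], self.feature_map.iloc[idx],
            list(self.sample_ids), self.scale,
        )

    def subset_samples(self, ids: list[str]) -> "PhenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return PhenotypeMatrix(
            self.values[:, idx], self.feature_map, list(ids), self.scale
        )


@dataclass
class KinshipMatrix:
    """Symmetric genetic relatedness matrix K used as the LMM random-effect
    covariance (u ~ MVN(0, sigma_u^2 K))."""

    K: np.ndarray
    sample_ids: list[str]
    method: str = "centered-GRM"  # or "pedigree"

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.sample_ids)
        if self.K.shape != (n, n):
            raise ValueError("K must be n x n matching sample_ids")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("K must be symmetric (tolerance 1e-10)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def check_psd(self, tol: float = 1e-8) -> None:
        w = np.linalg.eigvalsh(self.K)
        if w.min() < -tol:
            raise ValueError(f"K is not PSD: min eigenvalue {w.min():.3g}")


@dataclass
class CovariateTable:
    """One row per sample; arbitrary named numeric/categorical columns."""

    table: pd.DataFrame  # indexed by sample id

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in covariate table")
        if self.table.isna().any().any():
            raise ValueError("covariate table contains missing values")

    def design_matrix(self, names: list[str]) -> np.ndarray:
        """Numeric design matrix for the named covariates.

        Categorical / string columns are expanded into 0/1 indicator columns
        (first level dropped), which is how batch labels enter the model.
        """
        missing = [c for c in names if c not in self.table.columns]
        if missing:
            raise KeyError(f"covariates not found: {missing}")
        cols = []
        for name in names:
            col = self.table[name]
            if col.dtype.kind in "OUSb" or isinstance(
                col.dtype, pd.CategoricalDtype
            ):
                dummies = pd.get_dummies(col, prefix=name, drop_first=True)
                cols.append(dummies.to_numpy(dtype=float))
            else:
                cols.append(col.to_numpy(dtype=float)[:, None])
        if not cols:
            return np.empty((len(self.table), 0))
        return np.hstack(cols)

    def aligned(self, sample_ids: list[str]) -> "CovariateTable":
        missing = set(sample_ids) - set(self.table.index)
        if missing:
            raise KeyError(f"samples missing from covariate table: {sorted(missing)[:5]}")
        return CovariateTable(self.table.loc[list(sample_ids)])
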