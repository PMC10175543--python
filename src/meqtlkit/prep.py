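"""Phenotype preparation: the beta/M transform, probe filtering, and
covariate residualization with rank-based inverse-normal transform.

Methylation beta values (proportion methylated, in (0,1)) are heteroskedastic
near the boundaries; analysis is carried out on the M scale,
M = log2(beta / (1 - beta)), with residuals of an ordinary least-squares fit
on the covariates then mapped to normal quantiles per feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .containers import CovariateTable, PhenotypeMatrix

__all__ = [
    "beta_to_m",
    "m_to_beta",
    "filter_probes",
    "FilterReport",
    "residualize_and_normalize",
    "rank_inverse_normal",
]

#: Clip for beta values at exactly 0 or 1 before the logit.
BETA_EPS = 1e-6


def beta_to_m(beta, eps: float = BETA_EPS):
    """log2(beta / (1 - beta)), the M-value transform.

    Values at exactly 0 or 1 are clipped to ``eps`` / ``1 - eps``; values
    outside [0, 1] are rejected.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0) or np.any(beta > 1):
        raise ValueError("beta values must lie in [0, 1]")
    b = np.clip(beta, eps, 1.0 - eps)
    return np.log2(b / (1.0 - b))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    m = np.asarray(m, dtype=float)
    # logistic in base 2, computed stably on both tails
    out = np.empty_like(m)
    pos = m >= 0
    out[pos] = 1.0 / (1.0 + np.exp2(-m[pos]))
    e = np.exp2(m[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class FilterReport:
    """Per-rule removal counts from :func:`filter_probes`."""

    removed: dict[str, int] = field(default_factory=dict)
    unknown_ids: dict[str, int] = field(default_factory=dict)
    n_in: int = 0
    n_out: int = 0


def filter_probes(
    pheno: PhenotypeMatrix,
    exclude_lists: dict[str, set] | None = None,
    drop_sex_chroms: bool = False,
) -> tuple[PhenotypeMatrix, FilterReport]:
    """Drop features on sex chromosomes and/or in named exclusion lists.

    Each feature is removed at most once and the report attributes the
    removal to the first applicable rule, in order: sex chromosomes first,
    then the exclusion lists in their given order. Unknown ids in a list are
    ignored but counted.
    """
    exclude_lists = exclude_lists or {}
    report = FilterReport(n_in=pheno.n_features)
    ids = pheno.feature_map.index
    removed = pd.Series(False, index=ids)

    if drop_sex_chroms:
        chrom = pheno.feature_map["chrom"].astype(str).str.lower().str.lstrip("chr")
        on_sex = chrom.isin(["x", "y"]).to_numpy()
        report.removed["sex_chromosomes"] = int(on_sex.sum())
        removed |= on_sex

    for name, id_set in exclude_lists.items():
        id_set = set(id_set)
        in_matrix = ids.isin(id_set)
        report.unknown_ids[name] = len(id_set - set(ids[in_matrix]))
        newly = in_matrix & ~removed.to_numpy()
        report.removed[name] = int(newly.sum())
        removed |= in_matrix

    keep = ids[~removed.to_numpy()]
    out = pheno.subset_features(keep)
    report.n_out = out.n_features
    return out, report


def rank_inverse_normal(x: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offsets.

    Maps values to Phi^{-1}((rank - c) / (n - 2c + 1)) with c = 3/8; ties get
    the average rank, so the transform is invariant to any strictly monotone
    pre-transformation of ``x``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    ranks = pd.Series(x).rank(method="average").to_numpy()
    return ndtri((ranks - offset) / (n - 2.0 * offset + 1.0))


def residualize_and_normalize(
    pheno: PhenotypeMatrix,
    covars: CovariateTable,
    covariate_names: list[str],
    rank_normalize: bool = True,
) -> tuple[PhenotypeMatrix, list]:
    """Per-feature OLS residuals on the named covariates, then (optionally)
    the rank-based inverse-normal transform across samples.

    Batch labels (categorical columns) enter as fixed-effect indicator
    columns. Collinear covariate columns are dropped via a rank-revealing
    least-squares fit (lstsq), which handles them implicitly. Features that
    are constant, or exactly linear in the covariates, come back as all-zero
    residual rows and are returned in the ``flagged`` list.
    """
    if pheno.scale not in ("M", "residual-normalized"):
        raise ValueError("residualize_and_normalize expects M-scale input")
    covars = covars.aligned(pheno.sample_ids)
    C = covars.design_matrix(covariate_names)
    n = len(pheno.sample_ids)
    X = np.hstack([np.ones((n, 1)), C])

    Y = pheno.values  # features x samples
    # residuals of Y' on X via a single pseudo-inverse solve
    coef, _, _, _ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ coef).T

    flagged = []
    out = np.empty_like(resid)
    for i, fid in enumerate(pheno.feature_ids):
        r = resid[i]
        if np.allclose(r, 0.0, atol=1e-10) or np.std(r) < 1e-12:
            flagged.append(fid)
            out[i] = 0.0
        elif rank_normalize:
            out[i] = rank_inverse_normal(r)
        else:
            out[i] = r
    return (
        PhenotypeMatrix(
            out, pheno.feature_map, list(pheno.sample_ids), "residual-normalized"
        ),
        flagged,
    )
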